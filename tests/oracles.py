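"""Independent brute-force oracles shared by the acceptance tests.

These deliberately avoid the package's own enumeration code paths: path
weights come from a hand-rolled recursive DFS, and positive circuits from
an explicit rooted cycle search.
"""


def dfs_path_weight(net, targets, u):
    """Sum of weights of all simple paths from u to any node in `targets`."""
    g = net.graph
    total = 0.0

    def dfs(path, weight):
        nonlocal total
        v = path[-1]
        for _, w in g.out_edges(v):
            if w in path:
                continue
            wt = weight / g.in_degree(w)
            if w in targets:
                total += wt
            dfs(path + [w], wt)

    dfs([u], 1.0)
    return total


def has_positive_cycle(net, comp):
    """Rooted DFS enumeration of simple cycles inside one node set."""
    comp = set(comp)
    g = net.graph

    def dfs(path, start):
        v = path[-1]
        for _, w, d in g.out_edges(v, data=True):
            if w not in comp:
                continue
            if w == start:
                prod = 1
                cyc = path + [start]
                for a, b in zip(cyc, cyc[1:]):
                    prod *= g[a][b]["sign"]
                if prod > 0:
                    return True
            elif w > path[0] and w not in path:
                if dfs(path + [w], start):
                    return True
        return False

    return any(dfs([v], v) for v in sorted(comp))
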