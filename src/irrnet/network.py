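"""Signed regulatory networks: parsing, origons, core trimming, SCCs, path weights.

A regulatory network is a directed graph whose edges carry a polarity
W(v, u) in {+1, -1} (activation / repression).  The analysis operates on an
*origon* — the subnetwork reachable from a root gene with no incoming edges
other than autoregulatory ones — and on its *core*, the subnetwork left after
recursively pruning nodes that cannot influence any other node.  Strongly
connected components (SCCs) that contain a positive circuit (a directed cycle
with an even number of repressions) are the structures capable of
multistability; the weighted number of simple paths from a gene into such
components, K_u, is the structural predictor of irreversibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

__all__ = [
    "SignedNetwork", "Origon", "SccDecomposition", "PathStats", "ParseReport",
    "ParseError", "CycleCapExceeded", "PathCapExceeded",
    "parse_regulatory_table", "find_origons", "trim_to_core",
    "decompose_sccs", "weighted_paths", "write_edge_list",
]


class ParseError(ValueError):
    """Raised for malformed rows or unknown effect tokens in an edge table."""


class CycleCapExceeded(RuntimeError):
    """Simple-cycle enumeration exceeded the configured cap for an SCC."""


class PathCapExceeded(RuntimeError):
    """Simple-path enumeration exceeded the configured cap.

    Attributes
    ----------
    partial_weight : float
        Lower bound on K_u accumulated before the cap was hit.
    """

    def __init__(self, msg: str, partial_weight: float):
        super().__init__(msg)
        self.partial_weight = partial_weight


class SignedNetwork:
    """A directed graph with ±1 edge polarities.

    At most one edge per ordered (regulator, target) pair; every polarity is
    exactly +1 or -1.  Gene identifiers are whitespace-trimmed, case-preserved
    strings compared exactly.
    """

    def __init__(self, edges: Iterable[tuple[str, str, int]] = (),
                 nodes: Iterable[str] = ()):
        g = nx.DiGraph()
        g.add_nodes_from(str(n).strip() for n in nodes)
        for v, u, w in edges:
            v, u = str(v).strip(), str(u).strip()
            if w not in (1, -1):
                raise ValueError(f"polarity must be +1 or -1, got {w!r}")
            if g.has_edge(v, u) and g[v][u]["sign"] != w:
                raise ValueError(f"conflicting polarities for edge ({v}, {u})")
            g.add_edge(v, u, sign=w)
        self._g = g

    # -- container protocol -------------------------------------------------
    @property
    def graph(self) -> nx.DiGraph:
        """Underlying networkx digraph (edge attribute ``sign``)."""
        return self._g

    @property
    def nodes(self) -> list[str]:
        return sorted(self._g.nodes)

    @property
    def edges(self) -> list[tuple[str, str, int]]:
        return sorted((v, u, d["sign"]) for v, u, d in self._g.edges(data=True))

    def __contains__(self, node: str) -> bool:
        return node in self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    def __eq__(self, other) -> bool:
        return (isinstance(other, SignedNetwork)
                and self.nodes == other.nodes and self.edges == other.edges)

    def __repr__(self) -> str:
        return (f"SignedNetwork({self._g.number_of_nodes()} nodes, "
                f"{self._g.number_of_edges()} edges)")

    def sign(self, v: str, u: str) -> int:
        return self._g[v][u]["sign"]

    def in_degree(self, u: str) -> int:
        """k_u^+: number of edges with head u, self-loops included."""
        return self._g.in_degree(u)

    def out_degree(self, u: str) -> int:
        """k_u^-: number of edges with tail u, self-loops included."""
        return self._g.out_degree(u)

    def in_edges(self, u: str) -> list[tuple[str, int]]:
        """Regulators of u as (source, polarity), sorted by source id."""
        return sorted((v, d["sign"]) for v, _, d in self._g.in_edges(u, data=True))

    def subnetwork(self, nodes: Iterable[str]) -> "SignedNetwork":
        keep = set(nodes)
        sub = SignedNetwork()
        sub._g = self._g.subgraph(keep).copy()
        return sub

    def copy(self) -> "SignedNetwork":
        out = SignedNetwork()
        out._g = self._g.copy()
        return out


@dataclass(frozen=True)
class Origon:
    """Root gene with no non-self incoming edges plus its forward closure."""
    root: str
    members: frozenset[str]


@dataclass
class SccDecomposition:
    components: list[frozenset[str]]
    nontrivial: list[bool]
    has_positive_circuit: list[bool]
    #: node -> index into `components`
    component_of: dict[str, int]
    #: K-set: for each node u, nodes of downstream positive-circuit SCCs
    #: (including u's own SCC when positive), excluding u itself.
    k_sets: dict[str, frozenset[str]]


@dataclass
class PathStats:
    """All simple paths from one node into its K-set, with weights."""
    node: str
    paths: list[tuple[str, ...]]
    weights: list[float]

    @property
    def K(self) -> float:
        return float(sum(self.weights))


@dataclass
class ParseReport:
    """Rows excluded while parsing a regulatory edge table."""
    dual_rows: list[tuple[int, str, str, str]] = field(default_factory=list)
    unknown_rows: list[tuple[int, str, str, str]] = field(default_factory=list)
    duplicate_rows: list[tuple[int, str, str, str]] = field(default_factory=list)
    #: regulator-target pairs seen with both polarities, dropped as dual
    conflicting_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_dropped(self) -> int:
        return (len(self.dual_rows) + len(self.unknown_rows)
                + len(self.duplicate_rows))


DEFAULT_EFFECT_TOKENS: Mapping[str, object] = {
    "+": 1, "-": -1, "+-": "dual", "?": "unknown",
    "activation": 1, "repression": -1, "dual": "dual", "unknown": "unknown",
}


def parse_regulatory_table(text: str,
                           effect_tokens: Mapping[str, object] = DEFAULT_EFFECT_TOKENS,
                           ) -> tuple[SignedNetwork, ParseReport]:
    """Parse a RegulonDB-dialect TSV of (regulator, target, effect) rows.

    Only rows with a definite activation (+1) or repression (-1) effect enter
    the network.  Dual/unknown rows, exact duplicates, and pairs recorded with
    both polarities (treated as dual) are dropped and itemized in the report.
    Lines beginning with ``#`` and blank lines are ignored.
    """
    report = ParseReport()
    seen: dict[tuple[str, str], int] = {}
    rows: list[tuple[str, str, int]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = [p.strip() for p in line.split("\t")]
        if len(parts) < 3 or any(p == "" for p in parts[:3]):
            raise ParseError(f"line {lineno}: expected 3 tab-separated fields "
                             f"(regulator, target, effect), got {line!r}")
        reg, tgt, eff = parts[0], parts[1], parts[2]
        if eff not in effect_tokens:
            raise ParseError(f"line {lineno}: unknown effect token {eff!r}")
        mapped = effect_tokens[eff]
        if mapped == "dual":
            report.dual_rows.append((lineno, reg, tgt, eff))
            continue
        if mapped == "unknown":
            report.unknown_rows.append((lineno, reg, tgt, eff))
            continue
        key = (reg, tgt)
        if key in seen:
            if seen[key] != mapped and key not in report.conflicting_pairs:
                report.conflicting_pairs.append(key)
            report.duplicate_rows.append((lineno, reg, tgt, eff))
            continue
        seen[key] = mapped
        rows.append((reg, tgt, mapped))

    # pairs recorded with both polarities behave like dual edges: drop them
    conflicts = set(report.conflicting_pairs)
    net_edges = [(v, u, w) for v, u, w in rows if (v, u) not in conflicts]
    nodes = {n for v, u, _ in rows for n in (v, u)}
    return SignedNetwork(net_edges, nodes=nodes), report


def write_edge_list(net: SignedNetwork) -> str:
    """Serialize a network back to the TSV dialect (± rows only)."""
    lines = ["#regulator\ttarget\teffect"]
    for v, u, w in net.edges:
        lines.append(f"{v}\t{u}\t{'+' if w > 0 else '-'}")
    return "\n".join(lines) + "\n"


def find_origons(net: SignedNetwork) -> list[Origon]:
    """Origons: one per root whose only incoming edges are self-loops.

    Sorted by descending member count (ties by root id).  Networks whose
    every node sits on a non-self incoming edge yield an empty list.
    """
    g = net.graph
    origons = []
    for r in g.nodes:
        if all(v == r for v, _ in g.in_edges(r)):
            members = frozenset(nx.descendants(g, r)) | {r}
            origons.append(Origon(root=r, members=members))
    return sorted(origons, key=lambda o: (-len(o.members), o.root))


def trim_to_core(net: SignedNetwork) -> SignedNetwork:
    """Recursively remove nodes with no outgoing edges to *other* nodes.

    A node kept alive only by a self-loop cannot influence upstream nodes, so
    self-loops do not count toward the out-degree here.  Idempotent; may
    return the empty network.
    """
    g = net.graph.copy()
    while True:
        leaves = [u for u in g.nodes
                  if all(w == u for _, w in g.out_edges(u))]
        if not leaves:
            break
        g.remove_nodes_from(leaves)
    return net.subnetwork(g.nodes)


def _scc_has_positive_circuit(net: SignedNetwork, comp: frozenset[str],
                              cap: int) -> bool:
    """Exact check via simple-cycle enumeration inside one SCC."""
    sub = net.graph.subgraph(comp)
    count = 0
    for cycle in nx.simple_cycles(sub):
        count += 1
        if count > cap:
            raise CycleCapExceeded(
                f"cycle enumeration cap ({cap}) exceeded in SCC containing "
                f"{sorted(comp)[0]!r}; raise cycle_cap")
        prod = 1
        for a, b in zip(cycle, cycle[1:] + cycle[:1]):
            prod *= sub[a][b]["sign"]
        if prod > 0:
            return True
    return False


def decompose_sccs(net: SignedNetwork, cycle_cap: int = 10**6) -> SccDecomposition:
    """SCC partition with positive-circuit flags and per-node K-sets.

    An SCC is nontrivial if it has more than one node or a self-loop.  A
    self-activation loop counts as a positive 1-cycle.  The K-set of node u
    collects nodes of SCCs downstream of u (u's own included) that carry a
    positive circuit, excluding u itself.
    """
    g = net.graph
    comps = [frozenset(c) for c in nx.strongly_connected_components(g)]
    comps.sort(key=lambda c: sorted(c)[0])
    comp_of = {n: i for i, c in enumerate(comps) for n in c}
    nontrivial = [len(c) > 1 or g.has_edge(next(iter(c)), next(iter(c)))
                  for c in comps]
    positive = []
    for c, nt in zip(comps, nontrivial):
        positive.append(nt and _scc_has_positive_circuit(net, c, cycle_cap))

    # condensation reachability: which SCCs lie downstream of each SCC
    cond = nx.condensation(g, scc=[set(c) for c in comps])
    reach: list[set[int]] = []
    for i in range(len(comps)):
        reach.append(set(nx.descendants(cond, i)) | {i})

    k_sets = {}
    for u in g.nodes:
        members: set[str] = set()
        for j in reach[comp_of[u]]:
            if positive[j]:
                members |= comps[j]
        members.discard(u)
        k_sets[u] = frozenset(members)
    return SccDecomposition(components=comps, nontrivial=nontrivial,
                            has_positive_circuit=positive,
                            component_of=comp_of, k_sets=k_sets)


def weighted_paths(net: SignedNetwork, scc: SccDecomposition, u: str,
                   path_cap: int = 10**6) -> PathStats:
    """All simple paths from u into its K-set, with weight ω = Π 1/k^+.

    The weight of a path H = (H_1=u, ..., H_l) is the product over i = 2..l
    of 1/k^+ of H_i, interpretable as the probability that a state change at
    u propagates along the path when each input of a rule is equally likely
    to control its output.  K_u is the sum over all simple paths ending at
    any node of the K-set; intermediate nodes are unrestricted apart from
    path simplicity.
    """
    if u not in net:
        raise KeyError(f"node {u!r} not in network")
    targets = scc.k_sets[u]
    paths: list[tuple[str, ...]] = []
    weights: list[float] = []
    g = net.graph
    total = 0.0
    count = 0
    for t in sorted(targets):
        for p in nx.all_simple_paths(g, u, t):
            count += 1
            if count > path_cap:
                raise PathCapExceeded(
                    f"path enumeration cap ({path_cap}) exceeded at node {u!r}; "
                    f"accumulated weight is a lower bound", total)
            w = 1.0
            for node in p[1:]:
                w /= g.in_degree(node)
            paths.append(tuple(p))
            weights.append(w)
            total += w
    return PathStats(node=u, paths=paths, weights=weights)
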