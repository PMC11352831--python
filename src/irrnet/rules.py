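"""Network-consistent Boolean update rules and their (r, s) ensemble.

Each gene u with k = k_u^+ regulators gets a read-once rule over literals
y_i — the regulator's state x_v for an activating edge, its negation for a
repressing edge — joined left-to-right by k-1 binary operators drawn from
{×, +, ×(}.  The nesting operator "×(" opens a parenthesized group that
closes at the end of the expression; inside each group × binds tighter
than +.  Operators are sampled independently: ×( with probability r,
+ with (1-r)s, × with (1-r)(1-s).  The two limiting orderings of the
inputs by regulator out-degree — ascending (diffuse control) and
descending (concentrated control) — are supported, with lexicographic
tie-breaks so sampling is reproducible.

Autorepression is silenced: a negated self-literal evaluates to constant 0
(by ordinary negation when x_u = 1, by assumption when x_u = 0).  This
removes artifactual oscillations — a pure autorepressor becomes constant
0, hence monostable — and creates the stated exceptions to edge
essentiality: the self-edge is non-essential when it sits in its own
monomial, and the partner inputs of its monomial are non-essential when
conjoined with it.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field

import numpy as np

from .network import SignedNetwork

__all__ = [
    "OP_AND", "OP_OR", "OP_NEST",
    "EnsembleParams", "BooleanRule", "RuleSet", "RuleDistribution",
    "ConsistencyReport", "ensure_root_selfloop", "sample_ruleset",
    "enumerate_rules", "enumerate_rulesets", "rule_bias",
    "canalization_depths", "check_consistency",
]

OP_AND = "*"
OP_OR = "+"
OP_NEST = "*("

_OP_DISPLAY = {OP_AND: "×", OP_OR: "+", OP_NEST: "×("}


def params_unique(r: float, s: float) -> bool:
    """True when (r, s) admits a single rule per node (all-AND or all-OR)."""
    return r == 1.0 or s == 0.0 or (r == 0.0 and s == 1.0)


@dataclass(frozen=True)
class EnsembleParams:
    """Sampling parameters of the rule ensemble.

    r : probability of the nesting operator ×( between consecutive inputs.
    s : probability of + among the non-nesting choices.
    ordering : 'ascending' (diffuse control) or 'descending' (concentrated).
    M : number of rule realizations (forced to 1 when rules are unique).
    seed : master seed; per-(node, realization) substreams are derived from
        it by counter-based splitting, so results are independent of
        iteration order.
    """
    r: float
    s: float
    ordering: str = "ascending"
    M: int = 20
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.r <= 1.0 and 0.0 <= self.s <= 1.0):
            raise ValueError("r and s must lie in [0, 1]")
        if self.ordering not in ("ascending", "descending"):
            raise ValueError("ordering must be 'ascending' or 'descending'")
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if params_unique(self.r, self.s) and self.M != 1:
            object.__setattr__(self, "M", 1)

    @property
    def op_probs(self) -> dict[str, float]:
        return {OP_NEST: self.r, OP_OR: (1 - self.r) * self.s,
                OP_AND: (1 - self.r) * (1 - self.s)}


def _eval_chain(vals: list[int], ops: tuple[str, ...]) -> int:
    """Evaluate the read-once operator chain; ×( groups close at the end."""
    def group(i: int) -> int:
        or_acc = 0
        and_acc = vals[i]
        j = i
        while j < len(ops):
            op = ops[j]
            j += 1
            if op == OP_OR:
                or_acc |= and_acc
                and_acc = vals[j]
            elif op == OP_AND:
                and_acc &= vals[j]
            else:  # OP_NEST: the group it opens runs to the end
                and_acc &= group(j)
                return or_acc | and_acc
        return or_acc | and_acc
    return group(0)


def _truth_table(k: int, polarities: list[int], ops: tuple[str, ...],
                 silenced: list[bool]) -> np.ndarray:
    """Truth table over the 2^k regulator states; bit i of the index is
    the state of input i.  A silenced literal is constant 0."""
    tt = np.zeros(1 << k, dtype=np.uint8)
    for m in range(1 << k):
        vals = []
        for i in range(k):
            if silenced[i]:
                vals.append(0)
            else:
                x = (m >> i) & 1
                vals.append(x if polarities[i] > 0 else 1 - x)
        tt[m] = _eval_chain(vals, ops)
    return tt


@dataclass
class BooleanRule:
    """One update rule B_u in sampled (read-once) form.

    inputs : ordered (source gene, polarity) pairs; polarity +1 puts x_v in
        the literal, -1 its negation.
    ops : the k-1 operator tokens between consecutive literals.
    truth_table : output for each of the 2^k input vectors, indexed so bit i
        of the vector index is the state of input i.
    silenced : marks literals evaluated as constant 0 (negated self-inputs).
    """
    target: str
    inputs: list[tuple[str, int]]
    ops: tuple[str, ...]
    truth_table: np.ndarray
    silenced: list[bool] = field(default_factory=list)

    @classmethod
    def from_chain(cls, target: str, inputs: list[tuple[str, int]],
                   ops: tuple[str, ...]) -> "BooleanRule":
        k = len(inputs)
        if k == 0:
            raise ValueError(f"node {target!r} has no inputs; apply "
                             "ensure_root_selfloop first")
        if len(ops) != k - 1:
            raise ValueError("need exactly k-1 operators")
        silenced = [src == target and pol < 0 for src, pol in inputs]
        pols = [p for _, p in inputs]
        tt = _truth_table(k, pols, ops, silenced)
        return cls(target=target, inputs=inputs, ops=ops,
                   truth_table=tt, silenced=silenced)

    @property
    def k(self) -> int:
        return len(self.inputs)

    @property
    def bias(self) -> float:
        return float(self.truth_table.mean())

    def expression(self) -> str:
        """Human-readable form, e.g. ``y1×(y2+y3``."""
        parts = []
        for i, (src, pol) in enumerate(self.inputs):
            lit = src if pol > 0 else f"~{src}"
            parts.append(lit)
            if i < len(self.ops):
                parts.append(_OP_DISPLAY[self.ops[i]])
        return "".join(parts)

    def __call__(self, states: dict[str, int]) -> int:
        idx = 0
        for i, (src, _) in enumerate(self.inputs):
            idx |= (states[src] & 1) << i
        return int(self.truth_table[idx])


@dataclass
class RuleSet:
    """One network-consistent rule per node of a fixed core network."""
    network: SignedNetwork
    rules: dict[str, BooleanRule]
    params: EnsembleParams | None = None
    realization: int | None = None

    def __post_init__(self):
        if set(self.rules) != set(self.network.nodes):
            raise ValueError("rule domain must equal the network node set")

    @property
    def node_order(self) -> list[str]:
        """Fixed state-vector order: sorted gene identifiers."""
        return self.network.nodes

    def to_json_dict(self) -> dict:
        out = {}
        for u in self.node_order:
            r = self.rules[u]
            bits = np.packbits(r.truth_table[::-1]).tobytes().hex()
            out[u] = {
                "inputs": [[src, pol] for src, pol in r.inputs],
                "expression": r.expression(),
                "truth_table_hex": bits,
                "bias": r.bias,
            }
        return out


def ensure_root_selfloop(core: SignedNetwork) -> SignedNetwork:
    """Give every zero-in-degree node a self-activating loop (identity rule).

    The synchronous dynamics need every node to have at least one input; a
    root gene with none is frozen at its initial state.  Idempotent.
    """
    missing = [u for u in core.nodes if core.in_degree(u) == 0]
    if not missing:
        return core
    out = core.copy()
    for u in missing:
        out.graph.add_edge(u, u, sign=1)
    return out


def ordered_inputs(net: SignedNetwork, u: str, ordering: str) -> list[tuple[str, int]]:
    """Inputs of u sorted by regulator out-degree (ties lexicographic)."""
    ins = net.in_edges(u)
    if ordering == "ascending":
        return sorted(ins, key=lambda e: (net.out_degree(e[0]), e[0]))
    return sorted(ins, key=lambda e: (-net.out_degree(e[0]), e[0]))


def _substream(seed: int, realization: int, node: str) -> np.random.Generator:
    tag = zlib.crc32(node.encode())
    return np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, realization, tag]))


def sample_ruleset(core: SignedNetwork, params: EnsembleParams,
                   realization: int = 0) -> RuleSet:
    """Draw one rule realization for every node of the core.

    Operators between consecutive inputs are drawn independently with the
    (r, s) probabilities; deterministic given (seed, params, realization),
    independent of node iteration order.
    """
    rules = {}
    probs = params.op_probs
    tokens = [OP_NEST, OP_OR, OP_AND]
    pvec = [probs[t] for t in tokens]
    for u in core.nodes:
        ins = ordered_inputs(core, u, params.ordering)
        if not ins:
            raise ValueError(f"node {u!r} has no inputs; apply "
                             "ensure_root_selfloop first")
        k = len(ins)
        if k == 1:
            ops: tuple[str, ...] = ()
        else:
            rng = _substream(params.seed, realization, u)
            ops = tuple(rng.choice(tokens, size=k - 1, p=pvec))
        rules[u] = BooleanRule.from_chain(u, ins, ops)
    return RuleSet(network=core, rules=rules, params=params,
                   realization=realization)


@dataclass
class RuleDistribution:
    """All distinct truth functions reachable for one node's input signature.

    Functions are merged over the 3^(k-1) operator chains; each carries its
    total sampling probability under (r, s), its bias, and the average
    canalization depth of its sampled (read-once) representative.
    """
    k: int
    polarities: list[int]
    truth_tables: list[np.ndarray]
    probabilities: list[float]
    biases: list[float]
    avg_depths: list[float]
    representative_ops: list[tuple[str, ...]]
    #: per distinct function: (n_nest, n_or, n_and) of each merged chain,
    #: so probabilities can be re-evaluated on an (r, s) grid cheaply
    chain_op_counts: list[list[tuple[int, int, int]]] = field(default_factory=list)

    def probabilities_at(self, r: float, s: float) -> np.ndarray:
        """Sampling probability of each distinct function at (r, s)."""
        out = np.zeros(self.n_distinct)
        for i, chains in enumerate(self.chain_op_counts):
            for a, b, c in chains:
                out[i] += (r ** a) * ((1 - r) * s) ** b * ((1 - r) * (1 - s)) ** c
        return out

    def mean_bias_at(self, r: float, s: float) -> float:
        return float(np.dot(self.probabilities_at(r, s), self.biases))

    def mean_depth_at(self, r: float, s: float) -> float:
        return float(np.dot(self.probabilities_at(r, s), self.avg_depths))

    @property
    def n_distinct(self) -> int:
        return len(self.truth_tables)

    @property
    def mean_bias(self) -> float:
        return float(np.dot(self.probabilities, self.biases))

    @property
    def mean_depth(self) -> float:
        return float(np.dot(self.probabilities, self.avg_depths))


def enumerate_rules(k: int, polarities: list[int],
                    params: EnsembleParams) -> RuleDistribution:
    """Enumerate every operator chain for a k-input node and merge duplicates.

    The number of distinct functions is at least 2^(k-1) (the sum-of-products
    partitions of an ordered read-once form); probabilities sum to 1.
    """
    if not (1 <= k <= 10):
        raise ValueError("k must be in 1..10")
    if len(polarities) != k:
        raise ValueError("need one polarity per input")
    probs = params.op_probs
    merged: dict[bytes, int] = {}
    tts: list[np.ndarray] = []
    ps: list[float] = []
    reps: list[tuple[str, ...]] = []
    op_counts: list[list[tuple[int, int, int]]] = []
    silenced = [False] * k
    for ops in itertools.product([OP_NEST, OP_OR, OP_AND], repeat=k - 1):
        tt = _truth_table(k, polarities, ops, silenced)
        p = 1.0
        for op in ops:
            p *= probs[op]
        counts = (sum(o == OP_NEST for o in ops), sum(o == OP_OR for o in ops),
                  sum(o == OP_AND for o in ops))
        key = tt.tobytes()
        if key in merged:
            ps[merged[key]] += p
            op_counts[merged[key]].append(counts)
        else:
            merged[key] = len(tts)
            tts.append(tt)
            ps.append(p)
            reps.append(ops)
            op_counts.append([counts])
    biases = [float(tt.mean()) for tt in tts]
    depths = []
    for tt, ops in zip(tts, reps):
        d, avg = _depths_from_table(tt, k)
        depths.append(avg)
    return RuleDistribution(k=k, polarities=list(polarities),
                            truth_tables=tts, probabilities=ps,
                            biases=biases, avg_depths=depths,
                            representative_ops=reps,
                            chain_op_counts=op_counts)


def enumerate_rulesets(core: SignedNetwork, ordering: str = "ascending",
                       cap: int = 10**5):
    """Yield every distinct-function RuleSet combination of a small core.

    Iterates the Cartesian product of each node's distinct consistent
    functions (operator-chain enumeration, duplicates merged).  Raises
    RuntimeError if the product exceeds `cap`.
    """
    per_node: list[tuple[str, list[BooleanRule]]] = []
    total = 1
    for u in core.nodes:
        ins = ordered_inputs(core, u, ordering)
        if not ins:
            raise ValueError(f"node {u!r} has no inputs")
        k = len(ins)
        seen: dict[bytes, BooleanRule] = {}
        for ops in itertools.product([OP_NEST, OP_OR, OP_AND], repeat=k - 1):
            rule = BooleanRule.from_chain(u, ins, ops)
            seen.setdefault(rule.truth_table.tobytes(), rule)
        choices = list(seen.values())
        per_node.append((u, choices))
        total *= len(choices)
        if total > cap:
            raise RuntimeError(f"ruleset enumeration exceeds cap ({cap})")
    names = [u for u, _ in per_node]
    for combo in itertools.product(*[c for _, c in per_node]):
        yield RuleSet(network=core, rules=dict(zip(names, combo)))


def rule_bias(rule: BooleanRule) -> float:
    """Fraction of input vectors mapping to 1 (probability of updating to 1)."""
    return rule.bias


def _constancy_table(tt: np.ndarray, k: int) -> np.ndarray:
    """For every partial assignment (ternary code: digit i of the code is
    0 = input i free, 1 = fixed to 0, 2 = fixed to 1) record whether the
    restricted function is constant: -1 no, else the constant value.

    Bottom-up dynamic program: a restriction is constant iff freeing any
    one fixed... rather, iff both refinements of any free variable are
    constant and agree; full assignments seed the recursion.
    """
    pow3 = [3 ** i for i in range(k + 1)]
    table = np.full(pow3[k], -2, dtype=np.int8)  # -2 unvisited

    def solve(code: int) -> int:
        val = table[code]
        if val != -2:
            return val
        # find a free variable
        free = -1
        c = code
        for i in range(k):
            if c % 3 == 0:
                free = i
                break
            c //= 3
        if free < 0:  # full assignment: read the truth table
            idx = 0
            c = code
            for i in range(k):
                d = c % 3
                c //= 3
                idx |= (d - 1) << i
            res = int(tt[idx])
        else:
            lo = solve(code + pow3[free])
            hi = solve(code + 2 * pow3[free])
            res = lo if (lo >= 0 and lo == hi) else -1
        table[code] = res
        return res

    for code in range(pow3[k] - 1, -1, -1):
        solve(code)
    return table


def _depths_from_table(tt: np.ndarray, k: int,
                       skip: set[int] | None = None) -> tuple[list, float]:
    """Minimal-certificate canalization depth per input.

    depth(i) = size of the smallest partial assignment containing input i
    that forces the function constant while the assignment without i does
    not.  Inputs in `skip` (autorepression exemptions) get depth None and
    are excluded from the average.  A variable of depth 1 is canalizing.
    """
    skip = skip or set()
    depths: list[int | None] = [None] * k
    if len(set(tt.tolist())) == 1:
        # constant function: every (non-exempt) input is non-essential
        return depths, float("nan")
    pow3 = [3 ** i for i in range(k + 1)]
    const = _constancy_table(tt, k)
    best = [None] * k
    for code in range(len(const)):
        if const[code] < 0:
            continue
        digits = []
        c = code
        for i in range(k):
            digits.append(c % 3)
            c //= 3
        size = sum(1 for d in digits if d)
        for i in range(k):
            if digits[i] == 0 or i in skip:
                continue
            if best[i] is not None and best[i] <= size:
                continue
            rest = code - digits[i] * pow3[i]
            if rest != 0 and const[rest] >= 0:
                continue  # i is not essential to this certificate
            if rest == 0 and size == 1 and const[0] >= 0:
                continue
            best[i] = size
    for i in range(k):
        if i in skip:
            continue
        if best[i] is None:
            raise ValueError(f"input {i} is non-essential; rule inconsistent")
        depths[i] = best[i]
    present = [d for d in depths if d is not None]
    avg = float(np.mean(present)) if present else float("nan")
    return depths, avg


def canalization_depths(rule: BooleanRule) -> tuple[list, float]:
    """Per-input canalization depths and their average for one rule.

    Silenced (autorepression-exempt) inputs, and inputs made non-essential
    by a silenced partner in their monomial, receive depth None and are
    excluded from the average.
    """
    k = rule.k
    skip = {i for i, s in enumerate(rule.silenced) if s}
    # partners made non-essential by silencing are exempt too
    for i in range(k):
        if i in skip:
            continue
        if not _essential(rule.truth_table, k, i) and any(rule.silenced):
            skip.add(i)
    return _depths_from_table(rule.truth_table, k, skip)


def _essential(tt: np.ndarray, k: int, i: int) -> bool:
    idx = np.arange(1 << k)
    lo = idx[(idx >> i) & 1 == 0]
    return bool(np.any(tt[lo] != tt[lo | (1 << i)]))


@dataclass
class ConsistencyReport:
    ok: bool
    violations: list[str]
    exemptions: list[str]


def check_consistency(rule: BooleanRule, net: SignedNetwork) -> ConsistencyReport:
    """Verify edge consistency, edge essentiality, and sign consistency.

    Nodes with a repressive self-loop follow the silencing convention: the
    self input, and any inputs whose essentiality it destroys, are exempted
    from the essentiality requirement (listed, not flagged).
    """
    violations: list[str] = []
    exemptions: list[str] = []
    u = rule.target
    expected = dict(net.in_edges(u))
    got = dict(rule.inputs)
    if set(expected) != set(got):
        violations.append(
            f"edge consistency: rule inputs {sorted(got)} != network "
            f"regulators {sorted(expected)}")
    else:
        for v, pol in rule.inputs:
            if expected[v] != pol:
                violations.append(f"edge consistency: polarity of ({v}, {u}) "
                                  f"is {expected[v]}, rule uses {pol}")
    k = rule.k
    tt = rule.truth_table
    autorepressed = any(src == u and pol < 0 for src, pol in rule.inputs)
    for i, (v, pol) in enumerate(rule.inputs):
        if not _essential(tt, k, i):
            if autorepressed:
                exemptions.append(f"input {v} non-essential "
                                  "(autorepression silencing)")
            else:
                violations.append(f"essentiality: input {v} never flips output")
    for i, (v, pol) in enumerate(rule.inputs):
        if rule.silenced[i]:
            continue  # constant literal: trivially monotone
        idx = np.arange(1 << k)
        lo = idx[(idx >> i) & 1 == 0]
        diff = tt[lo | (1 << i)].astype(int) - tt[lo].astype(int)
        if pol > 0 and np.any(diff < 0):
            violations.append(f"sign consistency: not nondecreasing in "
                              f"activator {v}")
        if pol < 0 and np.any(diff > 0):
            violations.append(f"sign consistency: not nonincreasing in "
                              f"repressor {v}")
    return ConsistencyReport(ok=not violations, violations=violations,
                             exemptions=exemptions)
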