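"""Synthetic networks, synthetic expression data, and canonical toy fixtures.

The generators provide inputs with the statistical structure the analysis
assumes — signed regulatory graphs with controllable positive-circuit
content, and wild-type/evolved count tables whose log-fold-change signs
follow the shortest-path polarities from a perturbed source gene — so every
pipeline stage is testable without external downloads.  All artifacts are
bit-reproducible from their seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .expression import AMBIGUOUS, NOT_REGULATED, predicted_signs
from .network import SignedNetwork, decompose_sccs
from .rules import OP_OR, BooleanRule, RuleSet

__all__ = [
    "SynthNetworkParams", "SynthExpressionParams", "Fixture",
    "generate_network", "generate_expression", "fixtures",
    "random_core_network", "sample_network_without_positive_circuit",
]


@dataclass(frozen=True)
class SynthNetworkParams:
    n: int
    edge_prob: float = 0.15
    repression_fraction: float = 0.3
    two_cycles: int = 0          # mutual-activation pairs to inject
    guarantee_root: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("need at least 2 nodes")
        if self.two_cycles > self.n // 2:
            raise ValueError("cannot place more disjoint two-cycles than n/2")
        if not 0 <= self.repression_fraction <= 1:
            raise ValueError("repression fraction must lie in [0, 1]")


def _rng(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, *tags]))


def _gene_names(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"g{i:0{width}d}" for i in range(n)]


def generate_network(params: SynthNetworkParams) -> SignedNetwork:
    """Random signed digraph with optional injected positive two-cycles.

    Edges are drawn independently at `edge_prob`; each is repressive with
    `repression_fraction`.  The requested number of mutual-activation
    two-cycles (each a positive circuit) is injected among disjoint random
    node pairs.  With `guarantee_root`, node pair injection avoids the
    first node and its non-self in-edges are removed.
    """
    rng = _rng(params.seed, 11)
    names = _gene_names(params.n)
    edges: dict[tuple[str, str], int] = {}
    for v in names:
        for u in names:
            if v == u:
                continue
            if rng.random() < params.edge_prob:
                sign = -1 if rng.random() < params.repression_fraction else 1
                edges[(v, u)] = sign
    candidates = names[1:] if params.guarantee_root else names
    perm = rng.permutation(len(candidates))
    for c in range(params.two_cycles):
        a = candidates[perm[2 * c]]
        b = candidates[perm[2 * c + 1]]
        edges[(a, b)] = 1
        edges[(b, a)] = 1
    if params.guarantee_root:
        root = names[0]
        for key in [k for k in edges if k[1] == root and k[0] != root]:
            del edges[key]
    return SignedNetwork([(v, u, w) for (v, u), w in edges.items()],
                         nodes=names)


def random_core_network(seed: int, n: int, edge_prob: float | None = None,
                        repression_fraction: float = 0.3,
                        require_connected: bool = True,
                        max_tries: int = 1000) -> SignedNetwork:
    """Random network in which every node has at least one input.

    Mirrors a trimmed origon core: weakly connected, minimum in-degree 1
    (each deficient node is given one extra random signed input), suitable
    for rule sampling without added root self-loops.
    """
    p = edge_prob if edge_prob is not None else min(0.9, 1.6 / n)
    for t in range(max_tries):
        rng = _rng(seed, 13, t)
        names = _gene_names(n)
        edges: dict[tuple[str, str], int] = {}
        for v in names:
            for u in names:
                if v != u and rng.random() < p:
                    sign = -1 if rng.random() < repression_fraction else 1
                    edges[(v, u)] = sign
        for u in names:
            if not any(k[1] == u for k in edges):
                others = [v for v in names if v != u]
                v = others[rng.integers(len(others))]
                sign = -1 if rng.random() < repression_fraction else 1
                edges[(v, u)] = sign
        net = SignedNetwork([(v, u, w) for (v, u), w in edges.items()],
                            nodes=names)
        if require_connected and not nx.is_weakly_connected(net.graph):
            continue
        return net
    raise RuntimeError("could not generate a connected network")


def sample_network_without_positive_circuit(seed: int, n: int,
                                            max_tries: int = 2000
                                            ) -> SignedNetwork:
    """Random min-in-degree-1 connected network with no positive circuit.

    Rejection-samples `random_core_network` candidates until the SCC
    decomposition finds no positive circuit.
    """
    for t in range(max_tries):
        net = random_core_network(seed * 7919 + t, n, max_tries=50)
        scc = decompose_sccs(net)
        if not any(scc.has_positive_circuit):
            return net
    raise RuntimeError("no positive-circuit-free network found")


@dataclass(frozen=True)
class SynthExpressionParams:
    source: str
    perturbation: str = "KO"          # 'KO' | 'OE'
    effect: float = 1.0               # log-scale shift for regulated genes
    noise_sigma: float = 0.0          # multiplicative lognormal noise
    replicates: int = 3
    library_sigma: float = 0.1        # per-replicate library-size lognormal
    mean_log_expression: float = 6.0  # baseline lognormal location
    length_range_kb: tuple[float, float] = (0.3, 3.0)
    seed: int = 0


@dataclass
class SynthExpression:
    counts: pd.DataFrame          # genes x samples, columns "wt_i"/"evo_i"
    lengths_kb: pd.Series
    truth_signs: pd.Series        # recorded true sign per gene (0/±1)
    predicted: pd.Series          # predicted_signs output used to generate
    wt_columns: list[str]
    evo_columns: list[str]


def generate_expression(net: SignedNetwork,
                        params: SynthExpressionParams) -> SynthExpression:
    """Counts for wild-type vs evolved samples with sign structure from
    shortest-path polarities.

    Baseline means are lognormal; evolved means multiply the baseline by
    exp(true_sign * effect) and by lognormal multiplicative noise.  Genes
    with ambiguous polarity receive a recorded random ±1 so the
    ambiguity-handling branch of the precision pipeline is exercised;
    unregulated genes and the source itself carry sign 0.  Integer counts
    are the rounded mean times a per-replicate lognormal library factor.
    """
    if params.source not in net:
        raise KeyError(f"source {params.source!r} not in network")
    rng = _rng(params.seed, 17)
    genes = net.nodes
    pred = predicted_signs(net, params.source, params.perturbation)
    truth = {}
    for g in genes:
        if g == params.source:
            truth[g] = 0
        else:
            sig = pred[g]
            if sig == NOT_REGULATED:
                truth[g] = 0
            elif sig == AMBIGUOUS:
                truth[g] = int(rng.choice([-1, 1]))
            else:
                truth[g] = int(sig)
    truth = pd.Series(truth).loc[genes]
    baseline = np.exp(rng.normal(params.mean_log_expression, 1.0, len(genes)))
    noise = np.exp(rng.normal(0.0, params.noise_sigma, len(genes))) \
        if params.noise_sigma > 0 else np.ones(len(genes))
    evolved = baseline * np.exp(truth.to_numpy() * params.effect) * noise
    lengths = pd.Series(
        rng.uniform(*params.length_range_kb, len(genes)), index=genes)
    data = {}
    wt_cols, evo_cols = [], []
    for rep in range(params.replicates):
        for label, mean in (("wt", baseline), ("evo", evolved)):
            lib = float(np.exp(rng.normal(0.0, params.library_sigma)))
            col = f"{label}_{rep}"
            # counts scale with gene length: longer genes yield more reads
            data[col] = np.rint(mean * lengths.to_numpy() * lib).astype(int)
            (wt_cols if label == "wt" else evo_cols).append(col)
    counts = pd.DataFrame(data, index=genes)
    return SynthExpression(counts=counts, lengths_kb=lengths,
                           truth_signs=truth, predicted=pred,
                           wt_columns=wt_cols, evo_columns=evo_cols)


@dataclass
class Fixture:
    name: str
    network: SignedNetwork
    rules: RuleSet | None
    n_attractors: int | None
    note: str = ""


def _literal_rules(net: SignedNetwork) -> RuleSet:
    rules = {}
    for u in net.nodes:
        ins = net.in_edges(u)
        ops = tuple([OP_OR] * (len(ins) - 1))
        rules[u] = BooleanRule.from_chain(u, ins, ops)
    return RuleSet(network=net, rules=rules)


def fixtures() -> dict[str, Fixture]:
    """Canonical toy systems with documented attractor structure.

    T1 mutual activation (3 attractors), T2 the three-gene irreversibility
    exemplar with rules x1'=x1, x2'=x1+x3, x3'=x2 (4 attractors), T3
    negative two-cycle (one period-4 attractor), T4 pure autorepressor
    (single fixed point 0 under the silencing convention), T5 the
    path-weight example chain into a positive two-cycle.
    """
    out = {}

    t1_net = SignedNetwork([("a", "b", 1), ("b", "a", 1)])
    out["T1"] = Fixture("T1", t1_net, _literal_rules(t1_net), 3,
                        "mutual activation: {00}, {11}, {01<->10}")

    t2_net = SignedNetwork([("g1", "g1", 1), ("g1", "g2", 1),
                            ("g3", "g2", 1), ("g2", "g3", 1)])
    t2_rules = {
        "g1": BooleanRule.from_chain("g1", [("g1", 1)], ()),
        "g2": BooleanRule.from_chain("g2", [("g1", 1), ("g3", 1)], (OP_OR,)),
        "g3": BooleanRule.from_chain("g3", [("g2", 1)], ()),
    }
    out["T2"] = Fixture("T2", t2_net, RuleSet(network=t2_net, rules=t2_rules),
                        4, "three-gene OR exemplar: transient OE of g1 "
                           "leaves g2 and g3 on")

    t3_net = SignedNetwork([("a", "b", 1), ("b", "a", -1)])
    out["T3"] = Fixture("T3", t3_net, _literal_rules(t3_net), 1,
                        "negative two-cycle: single period-4 attractor")

    t4_net = SignedNetwork([("a", "a", -1)])
    out["T4"] = Fixture("T4", t4_net, _literal_rules(t4_net), 1,
                        "pure autorepressor: constant 0 under silencing")

    t5_net = SignedNetwork([("u", "v", 1), ("v", "s1", 1),
                            ("s1", "s2", 1), ("s2", "s1", 1)])
    out["T5"] = Fixture("T5", t5_net, None, None,
                        "path-weight example: K_u = 1.0")
    return out
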