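"""Transient knockout/overexpression perturbations and irreversibility.

The protocol follows five time points.  From a phase x^O of an attractor A
(t = O), the perturbed gene u is flipped to its clamp value — 0 for a
knockout (applicable when x_u = 1), 1 for an overexpression (x_u = 0) —
and the dynamics run with u clamped until the trajectory becomes recurrent
(t = Q, entry state x^Q).  The perturbation is then removed by inverting u
back, x^R = g_u(x^Q) (t = R), and the free dynamics run to the final
attractor A' (t = S).  The perturbation is irreversible when A' != A.

Two consequences of the definitions are checked as theorems: an
irreversible perturbation requires a nonempty set W of *other* genes whose
state at Q differs from O (necessary condition), and x^R falling outside
the basin of A forces A' != A (sufficient condition).

Per-gene probabilities across attractors and rule realizations are
aggregated as p_hat_u = mean_i [ p^KO_{u,i} q_{u,i} + p^OE_{u,i} (1 - q_{u,i}) ],
where q_{u,i} is the fraction of attractors in which gene u is on.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import (Attractor, AttractorSet, BasinMap, CompiledDynamics,
                       _walk_to_cycle, basin_map, find_attractors)
from .network import SignedNetwork
from .rules import EnsembleParams, RuleSet, sample_ruleset

__all__ = [
    "Perturbation", "PerturbationOutcome", "GeneClassification",
    "IrreversibilityTable", "ConvergenceReport", "ConditionReport",
    "apply_transient_perturbation", "classify_gene",
    "irreversibility_profile", "verify_conditions",
    "ensemble_rmsd", "convergence", "iter_perturbation_outcomes",
]


@dataclass(frozen=True)
class Perturbation:
    node: str
    kind: str  # 'KO' | 'OE'

    def __post_init__(self):
        if self.kind not in ("KO", "OE"):
            raise ValueError("kind must be 'KO' or 'OE'")

    @property
    def clamp_value(self) -> int:
        return 0 if self.kind == "KO" else 1


@dataclass
class PerturbationOutcome:
    perturbation: Perturbation
    applicable: bool
    initial_attractor: Attractor
    phase: int                      # x^O
    clamped_trajectory: list[int] = field(default_factory=list)
    x_q: int | None = None
    x_r: int | None = None
    final_attractor: Attractor | None = None
    x_s: int | None = None
    irreversible: bool = False
    changed_set: frozenset[str] = frozenset()       # W
    response_genes: frozenset[str] = frozenset()


@dataclass
class GeneClassification:
    gene: str
    p_ko: float
    p_oe: float
    q: float
    #: True when no attractor admitted the corresponding perturbation, so
    #: the conditional probability is undefined and recorded as 0.
    ko_undefined: bool = False
    oe_undefined: bool = False


@dataclass
class ConditionReport:
    necessary_holds: bool
    sufficient_consistent: bool
    violations: list[str]


@dataclass
class ConvergenceReport:
    """RMSD between averaged profiles of disjoint sub-ensembles, by size."""
    M: int
    rmsd: dict[int, np.ndarray]        # M' -> sampled RMSD values
    n_pairs: dict[int, int]

    def median(self, m_prime: int) -> float:
        return float(np.median(self.rmsd[m_prime]))


class IrreversibilityTable:
    """Per-gene, per-realization irreversibility components and Eq-style
    aggregate p_hat; backed by a tidy DataFrame."""

    def __init__(self, frame: pd.DataFrame, params: EnsembleParams | None,
                 weighting: str = "uniform", mode: str = "exhaustive"):
        required = {"gene", "realization", "p_ko", "p_oe", "q"}
        if not required <= set(frame.columns):
            raise ValueError(f"frame must have columns {sorted(required)}")
        self.frame = frame.reset_index(drop=True)
        self.params = params
        self.weighting = weighting
        self.mode = mode

    @property
    def genes(self) -> list[str]:
        return sorted(self.frame["gene"].unique())

    @property
    def realizations(self) -> list[int]:
        return sorted(self.frame["realization"].unique())

    def p_hat(self, realizations: list[int] | None = None) -> pd.Series:
        """Weighted average irreversibility probability per gene."""
        df = self.frame
        if realizations is not None:
            df = df[df["realization"].isin(realizations)]
        per = df["p_ko"] * df["q"] + df["p_oe"] * (1.0 - df["q"])
        return per.groupby(df["gene"]).mean().reindex(self.genes)

    def to_csv_frame(self) -> pd.DataFrame:
        out = self.frame.copy()
        out["p_hat_component"] = out["p_ko"] * out["q"] + out["p_oe"] * (1 - out["q"])
        if self.params is not None:
            out["r"] = self.params.r
            out["s"] = self.params.s
            out["ordering"] = self.params.ordering
        out["weighting"] = self.weighting
        return out


def _attractor_from_state(dyn: CompiledDynamics, state: int) -> tuple[Attractor, int]:
    """Free-dynamics attractor reached from `state` and its entry state."""
    _, cycle = _walk_to_cycle(dyn, state)
    return Attractor.from_cycle(cycle), cycle[0]


def apply_transient_perturbation(rules: RuleSet, attractors: AttractorSet,
                                 attractor: Attractor, phase: int,
                                 p: Perturbation,
                                 _free: CompiledDynamics | None = None,
                                 ) -> PerturbationOutcome:
    """Run the five-point transient perturbation protocol from one phase.

    A KO is applicable only when the gene is on in the phase, an OE only
    when it is off; an inapplicable perturbation returns an outcome flagged
    not-applicable rather than raising.
    """
    free = _free or CompiledDynamics(rules)
    if phase not in attractor:
        raise ValueError("phase must belong to the initial attractor")
    i = free.index[p.node]
    bit = (phase >> i) & 1
    if bit == p.clamp_value:
        return PerturbationOutcome(perturbation=p, applicable=False,
                                   initial_attractor=attractor, phase=phase)
    clamped = CompiledDynamics(rules, clamp=(p.node, p.clamp_value))
    x_p = phase ^ (1 << i)
    # follow the clamped dynamics until a state repeats; the first recurrent
    # state is the entry into the clamped-system attractor (x^Q)
    transient, cycle = _walk_to_cycle(clamped, x_p)
    x_q = cycle[0]
    x_r = x_q ^ (1 << i)            # g_u inverts the perturbed gene back
    final, x_s = _attractor_from_state(free, x_r)
    irreversible = final != attractor
    changed = frozenset(
        u for u, j in free.index.items()
        if u != p.node and ((x_q >> j) & 1) != ((phase >> j) & 1))
    response = frozenset(
        u for u, j in free.index.items()
        if {(s >> j) & 1 for s in attractor.states}
        != {(s >> j) & 1 for s in final.states})
    return PerturbationOutcome(
        perturbation=p, applicable=True, initial_attractor=attractor,
        phase=phase, clamped_trajectory=transient + cycle, x_q=x_q, x_r=x_r,
        final_attractor=final, x_s=x_s, irreversible=irreversible,
        changed_set=changed, response_genes=response)


def iter_perturbation_outcomes(rules: RuleSet, attractors: AttractorSet,
                               genes: list[str] | None = None,
                               _free: CompiledDynamics | None = None):
    """Yield the outcome of every applicable perturbation of every attractor.

    Perturbations are applied from every applicable phase of periodic
    attractors; callers aggregate with their own convention.
    """
    free = _free or CompiledDynamics(rules)
    genes = genes if genes is not None else rules.node_order
    for att in attractors.attractors:
        for u in genes:
            for kind in ("KO", "OE"):
                p = Perturbation(node=u, kind=kind)
                for phase in att.states:
                    out = apply_transient_perturbation(
                        rules, attractors, att, phase, p, _free=free)
                    if out.applicable:
                        yield out


def classify_gene(rules: RuleSet, attractors: AttractorSet, u: str,
                  basins: BasinMap | None = None,
                  weighting: str = "uniform",
                  _free: CompiledDynamics | None = None) -> GeneClassification:
    """Per-gene irreversibility probabilities over one rule realization.

    q is the fraction of attractors with gene u on in at least one state
    (the KO-applicability convention).  p^KO is the fraction of those
    attractors for which some applicable phase yields an irreversible
    outcome; p^OE is the analogue over attractors containing an off state.
    With basin weighting, attractors are weighted by basin size inside the
    fractions instead of uniformly.
    """
    if u not in rules.rules:
        raise KeyError(f"gene {u!r} not in the rule set")
    if weighting not in ("uniform", "basin"):
        raise ValueError("weighting must be 'uniform' or 'basin'")
    if weighting == "basin" and basins is None:
        raise ValueError("basin weighting requires an exhaustive basin map")
    free = _free or CompiledDynamics(rules)
    i = free.index[u]
    num = {"KO": 0.0, "OE": 0.0}
    den = {"KO": 0.0, "OE": 0.0}
    n_on = 0
    for att in attractors.attractors:
        bits = {(s >> i) & 1 for s in att.states}
        if 1 in bits:
            n_on += 1
        w = (basins.basin_sizes[basins.attractors.index(att)]
             if weighting == "basin" else 1.0)
        for kind, need in (("KO", 1), ("OE", 0)):
            if need not in bits:
                continue
            den[kind] += w
            p = Perturbation(node=u, kind=kind)
            irr = False
            for phase in att.states:
                if ((phase >> i) & 1) != need:
                    continue
                out = apply_transient_perturbation(rules, attractors, att,
                                                   phase, p, _free=free)
                if out.irreversible:
                    irr = True
                    break
            if irr:
                num[kind] += w
    q = n_on / len(attractors.attractors) if len(attractors.attractors) else 0.0
    p_ko = num["KO"] / den["KO"] if den["KO"] else 0.0
    p_oe = num["OE"] / den["OE"] if den["OE"] else 0.0
    return GeneClassification(gene=u, p_ko=p_ko, p_oe=p_oe, q=q,
                              ko_undefined=den["KO"] == 0,
                              oe_undefined=den["OE"] == 0)


def irreversibility_profile(core: SignedNetwork, params: EnsembleParams,
                            weighting: str = "uniform",
                            mode: str = "exhaustive",
                            budget: int | None = None) -> IrreversibilityTable:
    """Sample M rule realizations and classify every gene in each.

    Basin weighting requires exhaustive attractor discovery.  The aggregate
    p_hat is recoverable from the stored per-realization components.
    """
    if len(core) == 0:
        raise ValueError("core network is empty")
    if weighting == "basin" and mode != "exhaustive":
        raise ValueError("basin weighting requires exhaustive mode")
    rows = []
    for i in range(params.M):
        rules = sample_ruleset(core, params, realization=i)
        free = CompiledDynamics(rules)
        if mode == "exhaustive":
            bm = basin_map(rules)
            atts = AttractorSet(attractors=bm.attractors, mode="exhaustive",
                                n_nodes=free.n)
        else:
            bm = None
            atts = find_attractors(rules, mode="sampled", budget=budget,
                                   seed=params.seed + i)
        for u in rules.node_order:
            c = classify_gene(rules, atts, u, basins=bm, weighting=weighting,
                              _free=free)
            rows.append({"gene": u, "realization": i, "p_ko": c.p_ko,
                         "p_oe": c.p_oe, "q": c.q,
                         "ko_undefined": c.ko_undefined,
                         "oe_undefined": c.oe_undefined})
    frame = pd.DataFrame(rows)
    return IrreversibilityTable(frame, params=params, weighting=weighting,
                                mode=mode)


def verify_conditions(outcome: PerturbationOutcome,
                      basins: BasinMap) -> ConditionReport:
    """Check the necessary and sufficient irreversibility conditions.

    Necessary: irreversible implies the changed set W is nonempty.
    Sufficient: x^R outside the basin of the initial attractor implies (and,
    via the basin map, is equivalent to) a different final attractor.  Any
    violation signals a bug in the dynamics, never an expected outcome.
    """
    violations = []
    if not outcome.applicable:
        return ConditionReport(True, True, [])
    if outcome.irreversible and not outcome.changed_set:
        violations.append("irreversible outcome with empty changed set W")
    idx = basins.attractors.index(outcome.initial_attractor)
    outside = int(basins.attractor_of[outcome.x_r]) != idx
    if outside != outcome.irreversible:
        violations.append(
            "basin membership of x^R disagrees with direct simulation")
    return ConditionReport(necessary_holds=not (outcome.irreversible
                                                and not outcome.changed_set),
                           sufficient_consistent=outside == outcome.irreversible,
                           violations=violations)


def ensemble_rmsd(p_hat_u: pd.Series, p_hat_v: pd.Series) -> float:
    """Root mean square difference between two per-gene profiles."""
    if sorted(p_hat_u.index) != sorted(p_hat_v.index):
        raise ValueError("profiles must cover the same genes")
    a = p_hat_u.sort_index().to_numpy(dtype=float)
    b = p_hat_v.sort_index().to_numpy(dtype=float)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def _n_disjoint_pairs(M: int, m: int) -> int:
    return math.comb(M, m) * math.comb(M - m, m)


def convergence(table: IrreversibilityTable, m_primes: range | list[int],
                max_pairs: int = 1000, seed: int = 0) -> ConvergenceReport:
    """RMSD between disjoint sub-ensemble pairs as the ensemble size grows.

    For each M', draws all Z(M, M') = C(M, M') C(M-M', M') disjoint ordered
    pairs of realization subsets when Z <= max_pairs, else max_pairs random
    ones, and computes the RMSD between the two averaged profiles.
    """
    reals = table.realizations
    M = len(reals)
    df = table.frame
    comp = (df["p_ko"] * df["q"] + df["p_oe"] * (1.0 - df["q"]))
    # genes x realizations matrix of per-realization p_hat components
    mat = (pd.DataFrame({"gene": df["gene"], "realization": df["realization"],
                         "c": comp})
           .pivot(index="gene", columns="realization", values="c")
           .loc[:, reals].to_numpy(dtype=float))

    def pair_rmsd(u_cols: tuple[int, ...], v_cols: tuple[int, ...]) -> float:
        diff = mat[:, list(u_cols)].mean(axis=1) - mat[:, list(v_cols)].mean(axis=1)
        return float(np.sqrt(np.mean(diff ** 2)))

    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 5]))
    out: dict[int, np.ndarray] = {}
    n_pairs: dict[int, int] = {}
    for m in m_primes:
        if 2 * m > M:
            raise ValueError(f"M'={m} needs at least 2M'={2*m} realizations")
        Z = _n_disjoint_pairs(M, m)
        vals = []
        if Z <= max_pairs:
            cols = range(M)
            for u_cols in itertools.combinations(cols, m):
                rest = [x for x in cols if x not in u_cols]
                for v_cols in itertools.combinations(rest, m):
                    vals.append(pair_rmsd(u_cols, v_cols))
        else:
            for _ in range(max_pairs):
                perm = rng.permutation(M)
                vals.append(pair_rmsd(tuple(perm[:m]), tuple(perm[m:2 * m])))
        out[m] = np.asarray(vals)
        n_pairs[m] = len(vals)
    return ConvergenceReport(M=M, rmsd=out, n_pairs=n_pairs)
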