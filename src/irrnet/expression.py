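"""Comparing network-predicted regulation signs with expression changes.

Raw RNA counts are converted to transcripts per million (TPM),
z_i = 1e6 (c_i / L_i) / sum_j (c_j / L_j), with gene lengths in kilobases.
For each core gene the fold change rho_u between evolved and wild-type
mean expression is referenced to the global shift <rho> (the mean over
core genes), giving an observed sign sgn(ln(rho_u / <rho>)) and magnitude
|ln(rho_u / <rho>)|.  The model-predicted sign follows the polarity
product along a shortest path from the perturbed source gene, negated for
a knockout; genes with equal-length shortest paths of opposite polarity
are ambiguous, and unreachable genes are not regulated.

Agreement is summarized by the precision of the top-n genes ranked by
magnitude, P(n) — ambiguous predictions count as matches whenever the
observed sign is nonzero — and its running average <P>(n), evaluated up
to the last gene above a log-fold-change threshold (default 0.5).
Significance comes from shuffling the predicted signs: the standard
exceedance p-value N_exc / N_samp is primary, and the complementary
printed convention 1 - N_exc / N_samp is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import SignedNetwork

__all__ = [
    "AMBIGUOUS", "NOT_REGULATED", "SignComparison", "BootstrapResult",
    "tpm_convert", "observed_signs", "predicted_signs", "precision_curve",
    "bootstrap_p", "irr_vs_rev_stat",
]

AMBIGUOUS = "ambiguous"
NOT_REGULATED = "not_regulated"


def tpm_convert(counts, lengths_kb) -> np.ndarray:
    """Transcripts per million from raw counts and gene lengths (kb).

    The output sums to 1e6 per sample; zero counts map to zero.  Accepts a
    1-D vector or a (genes x samples) 2-D array / DataFrame.
    """
    c = np.asarray(counts, dtype=float)
    L = np.asarray(lengths_kb, dtype=float)
    if np.any(L <= 0):
        raise ValueError("gene lengths must be positive")
    one_d = c.ndim == 1
    if one_d:
        c = c[:, None]
    if np.any(c.sum(axis=0) <= 0):
        raise ValueError("each sample needs at least one positive count")
    rate = c / L[:, None]
    z = 1e6 * rate / rate.sum(axis=0, keepdims=True)
    return z[:, 0] if one_d else z


def observed_signs(rho: pd.Series) -> pd.DataFrame:
    """Observed sign and magnitude of expression change per core gene.

    `rho` maps core genes to fold changes mu_evo / mu_wt.  Genes with
    nonpositive or nonfinite rho (e.g. zero wild-type mean) are excluded
    and flagged.  Returns a DataFrame with columns sign, magnitude,
    excluded.
    """
    rho = pd.Series(rho, dtype=float)
    bad = ~np.isfinite(rho) | (rho <= 0)
    good = rho[~bad]
    if good.empty:
        raise ValueError("no usable fold changes")
    mean_rho = float(good.mean())
    logratio = np.log(good / mean_rho)
    out = pd.DataFrame(index=rho.index)
    out["sign"] = 0
    out.loc[good.index, "sign"] = np.sign(logratio).astype(int)
    out["magnitude"] = 0.0
    out.loc[good.index, "magnitude"] = np.abs(logratio)
    out["excluded"] = bad
    return out


def predicted_signs(net: SignedNetwork, source: str,
                    perturbation: str = "KO") -> pd.Series:
    """Model-predicted sign of each gene's response to perturbing `source`.

    BFS over shortest paths; the sign is (-1 for KO, +1 for OE) times the
    polarity product along a shortest path.  Genes reached by equal-length
    paths of both polarities are 'ambiguous'; unreachable genes are
    'not_regulated'.
    """
    if source not in net:
        raise KeyError(f"source {source!r} not in network")
    if perturbation not in ("KO", "OE"):
        raise ValueError("perturbation must be 'KO' or 'OE'")
    factor = -1 if perturbation == "KO" else 1
    g = net.graph
    dist = {source: 0}
    pols: dict[str, set[int]] = {source: {1}}
    frontier = [source]
    while frontier:
        nxt = []
        for v in frontier:
            for _, u, data in g.out_edges(v, data=True):
                d = dist[v] + 1
                if u not in dist:
                    dist[u] = d
                    pols[u] = {p * data["sign"] for p in pols[v]}
                    nxt.append(u)
                elif dist[u] == d:
                    pols[u] |= {p * data["sign"] for p in pols[v]}
        frontier = nxt
    out = {}
    for u in net.nodes:
        if u == source:
            continue
        if u not in dist:
            out[u] = NOT_REGULATED
        elif len(pols[u]) > 1:
            out[u] = AMBIGUOUS
        else:
            out[u] = factor * next(iter(pols[u]))
    return pd.Series(out).sort_index()


@dataclass
class SignComparison:
    """Ranked precision curve of observed vs predicted signs."""
    genes: list[str]                 # rank order (decreasing magnitude)
    matches: np.ndarray              # indicator per ranked gene
    precision: np.ndarray            # P(n), cumulative
    avg_precision: float             # <P> up to the threshold rank
    n_threshold: int                 # genes with magnitude > threshold
    threshold: float
    undefined: bool = False          # empty above-threshold set

    def running_avg_precision(self) -> np.ndarray:
        return np.cumsum(self.precision) / np.arange(1, len(self.precision) + 1)


def _match_indicator(obs: int, mod) -> bool:
    if mod == AMBIGUOUS:
        return obs != 0
    return obs == mod


def precision_curve(obs_signs: pd.Series, mod_signs: pd.Series,
                    magnitudes: pd.Series, threshold: float = 0.5
                    ) -> SignComparison:
    """Precision of the top-n magnitude-ranked genes, and its average.

    Genes predicted 'not_regulated' are dropped before ranking.  Ties in
    magnitude break lexicographically by gene id.  <P> averages P(m) over
    the ranks m up to the number of genes with magnitude strictly above
    the threshold.
    """
    genes = [g for g in obs_signs.index
             if g in mod_signs.index and mod_signs[g] != NOT_REGULATED]
    if not genes:
        raise ValueError("no comparable genes")
    order = sorted(genes, key=lambda g: (-magnitudes[g], g))
    matches = np.array([_match_indicator(int(obs_signs[g]), mod_signs[g])
                        for g in order], dtype=float)
    precision = np.cumsum(matches) / np.arange(1, len(order) + 1)
    n_thr = int(sum(magnitudes[g] > threshold for g in order))
    if n_thr == 0:
        return SignComparison(genes=order, matches=matches,
                              precision=precision, avg_precision=float("nan"),
                              n_threshold=0, threshold=threshold,
                              undefined=True)
    avg = float(np.mean(precision[:n_thr]))
    return SignComparison(genes=order, matches=matches, precision=precision,
                          avg_precision=avg, n_threshold=n_thr,
                          threshold=threshold)


@dataclass
class BootstrapResult:
    observed: float
    n_samp: int
    n_exc: int
    p_value: float          # standard exceedance N_exc / N_samp
    p_printed: float        # complementary convention 1 - N_exc / N_samp
    seed: int


_AMB_CODE = 9  # numeric stand-in for the ambiguous label in vectorized paths


def _encode_mod(mod) -> np.ndarray:
    return np.array([_AMB_CODE if m == AMBIGUOUS else int(m) for m in mod],
                    dtype=np.int64)


def _match_matrix(obs: np.ndarray, mod_codes: np.ndarray) -> np.ndarray:
    """Indicator of sign agreement; ambiguous matches any nonzero obs.

    Broadcasts over leading axes of `mod_codes`.
    """
    return (mod_codes == obs) | ((mod_codes == _AMB_CODE) & (obs != 0))


def _avg_precision_stat(obs: np.ndarray, mod: np.ndarray,
                        n_thr: int) -> float:
    """<P> for pre-ranked sign arrays (mod entries may be AMBIGUOUS)."""
    matches = _match_matrix(np.asarray(obs, dtype=np.int64),
                            _encode_mod(mod)).astype(float)
    precision = np.cumsum(matches) / np.arange(1, len(obs) + 1)
    return float(np.mean(precision[:n_thr]))


def bootstrap_p(statistic: str, data: dict, n_samp: int = 25_000,
                seed: int = 0) -> BootstrapResult:
    """Shuffle-based significance of sign concordance.

    statistic='avg_precision': data holds pre-aligned arrays `obs`, `mod`
    (rank order by decreasing magnitude) and `n_threshold`; the predicted
    signs are shuffled while observed signs and magnitudes stay fixed.

    statistic='gamma_diff': data holds per-condition dicts under
    `conditions`, each with `obs`, `mod`, `above_threshold` (bool mask) and
    `irreversible` (bool mask); a shuffle counts toward N_exc only when the
    shuffled gamma_irr - gamma_rev exceeds the observed difference in every
    condition.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 7]))
    if n_samp < 1:
        raise ValueError("n_samp must be >= 1")
    if statistic == "avg_precision":
        obs = np.asarray(data["obs"], dtype=np.int64)
        codes = _encode_mod(data["mod"])
        n = len(codes)
        n_thr = int(data["n_threshold"])
        observed = _avg_precision_stat(data["obs"], data["mod"], n_thr)
        # all shuffles at once: permutation matrix via random-key argsort
        perms = np.argsort(rng.random((n_samp, n)), axis=1)
        matches = _match_matrix(obs[None, :], codes[perms]).astype(float)
        precision = np.cumsum(matches, axis=1) / np.arange(1, n + 1)
        stats = precision[:, :n_thr].mean(axis=1)
        n_exc = int(np.sum(stats > observed + 1e-12))
    elif statistic == "gamma_diff":
        conds = data["conditions"]
        exceed = np.ones(n_samp, dtype=bool)
        observed_diffs = []
        for c in conds:
            obs = np.asarray(c["obs"], dtype=np.int64)
            codes = _encode_mod(c["mod"])
            above = np.asarray(c["above_threshold"], dtype=bool)
            irrev = np.asarray(c["irreversible"], dtype=bool)
            *_, od = _gamma_counts(obs, np.asarray(c["mod"], dtype=object),
                                   above, irrev)
            observed_diffs.append(od)
            n = len(codes)
            perms = np.argsort(rng.random((n_samp, n)), axis=1)
            hits = _match_matrix(obs[None, :], codes[perms]) & above[None, :]
            diffs = (hits & irrev[None, :]).sum(axis=1) \
                - (hits & ~irrev[None, :]).sum(axis=1)
            exceed &= diffs > od
        observed = float(min(observed_diffs))  # reported scalar: worst case
        n_exc = int(exceed.sum())
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    p = n_exc / n_samp
    return BootstrapResult(observed=observed, n_samp=n_samp, n_exc=n_exc,
                           p_value=p, p_printed=1.0 - p, seed=seed)


def _gamma_counts(obs, mod, above, irrev) -> tuple[int, int, int]:
    match = np.array([_match_indicator(int(o), m) for o, m in zip(obs, mod)],
                     dtype=bool)
    hits = match & above
    g_irr = int(np.sum(hits & irrev))
    g_rev = int(np.sum(hits & ~irrev))
    return g_irr, g_rev, g_irr - g_rev


def irr_vs_rev_stat(obs_signs: pd.Series, mod_signs: pd.Series,
                    magnitudes: pd.Series, irreversible_genes: set[str],
                    threshold: float = 0.5) -> tuple[int, int, int]:
    """gamma_irr, gamma_rev, and their difference.

    Counts genes whose observed sign matches the prediction and whose
    magnitude exceeds the threshold, split by membership in the
    irreversible-response set.
    """
    genes = [g for g in obs_signs.index
             if g in mod_signs.index and mod_signs[g] != NOT_REGULATED]
    obs = np.array([int(obs_signs[g]) for g in genes])
    mod = np.array([mod_signs[g] for g in genes], dtype=object)
    above = np.array([magnitudes[g] > threshold for g in genes], dtype=bool)
    irrev = np.array([g in irreversible_genes for g in genes], dtype=bool)
    return _gamma_counts(obs, mod, above, irrev)
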