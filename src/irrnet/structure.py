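"""Power-law link between irreversibility and path weights: p_hat = a K^b.

The fit is ordinary least squares on (log K, log p_hat) over the genes with
both quantities positive; zero-valued genes are excluded and reported
rather than pseudo-counted, keeping the exponent interpretable.  R^2 is the
coefficient of determination in log space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["FitResult", "fit_power_law"]


@dataclass
class FitResult:
    a: float
    b: float
    r_squared: float
    stderr_b: float
    n_points: int
    excluded: list[str] = field(default_factory=list)
    degenerate: bool = False  # SS_tot == 0 (constant p_hat); R^2 set to 0


def fit_power_law(p_hat, K, genes=None) -> FitResult:
    """Least-squares power-law fit of per-gene irreversibility vs K_u.

    Parameters are aligned sequences (or pandas Series sharing an index).
    Requires at least 3 genes with p_hat > 0 and K > 0.
    """
    p = np.asarray(p_hat, dtype=float)
    k = np.asarray(K, dtype=float)
    if p.shape != k.shape:
        raise ValueError("p_hat and K must align")
    if genes is None:
        genes = [str(i) for i in range(len(p))]
    genes = list(genes)
    mask = (p > 0) & (k > 0)
    excluded = [g for g, m in zip(genes, mask) if not m]
    n = int(mask.sum())
    if n < 3:
        raise ValueError(f"need at least 3 genes with positive p_hat and K, "
                         f"got {n}")
    x = np.log(k[mask])
    y = np.log(p[mask])
    if np.allclose(y, y[0]):
        return FitResult(a=float(np.exp(y[0])), b=0.0, r_squared=0.0,
                         stderr_b=0.0, n_points=n, excluded=excluded,
                         degenerate=True)
    res = stats.linregress(x, y)
    return FitResult(a=float(np.exp(res.intercept)), b=float(res.slope),
                     r_squared=float(res.rvalue ** 2),
                     stderr_b=float(res.stderr), n_points=n,
                     excluded=excluded)
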