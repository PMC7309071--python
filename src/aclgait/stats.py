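"""Group statistics for gait temporal parameters.

Implements the analysis chain applied to the per-step parameters:
Levene's test for homogeneity of variances, a 2x2 (condition x limb)
ANOVA with Type III sums of squares, Cohen's d standardized mean
differences with the conventional interpretation bands, and exact
noncentral-t power / sample-size calculations for a two-sided
two-sample t-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "levene_test",
    "two_way_anova",
    "cohens_d",
    "interpret_d",
    "power_two_sample_t",
    "sample_size_for_power",
]

# Cohen's d interpretation band boundaries
D_BANDS = (0.2, 0.5, 0.8, 1.3)
D_LABELS = ("very small", "small", "medium", "large", "very large")


@dataclass
class AnovaResult:
    effect: str
    F: float
    df1: int
    df2: int
    p: float
    ss: float


def levene_test(groups: Sequence[np.ndarray], center: str = "mean") -> Tuple[float, float]:
    """Levene's test for homogeneity of variances.

    A one-way ANOVA on the absolute deviations from each group's center
    (mean by default; median gives the Brown-Forsythe variant).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    zs: List[np.ndarray] = []
    for g in groups:
        g = np.asarray(g, float)
        if g.size < 2:
            raise ValueError("each group needs at least two observations")
        c = np.mean(g) if center == "mean" else np.median(g)
        zs.append(np.abs(g - c))
    k = len(zs)
    n_total = sum(z.size for z in zs)
    grand = np.concatenate(zs).mean()
    ssb = sum(z.size * (z.mean() - grand) ** 2 for z in zs)
    ssw = sum(((z - z.mean()) ** 2).sum() for z in zs)
    df1, df2 = k - 1, n_total - k
    if ssw == 0:
        return (0.0, 1.0) if ssb == 0 else (np.inf, 0.0)
    F = (ssb / df1) / (ssw / df2)
    p = float(sps.f.sf(F, df1, df2))
    return float(F), p


def two_way_anova(
    values: np.ndarray,
    factor_condition: Sequence,
    factor_limb: Sequence,
) -> Dict[str, AnovaResult]:
    """2x2 ANOVA with Type III sums of squares (sum-to-zero contrasts).

    Unbalanced cells are allowed; every cell must be non-empty.  Returns
    results for the two main effects and the interaction, plus the
    full-model and residual sums of squares under keys ``"model"`` and
    ``"residual"`` (with F/p set to NaN for those bookkeeping entries).
    """
    y = np.asarray(values, float)
    fa = np.asarray(factor_condition)
    fb = np.asarray(factor_limb)
    if not (y.shape == fa.shape == fb.shape) or y.ndim != 1:
        raise ValueError("values and factors must be equal-length 1-D")
    la, lb = np.unique(fa), np.unique(fb)
    if la.size != 2 or lb.size != 2:
        raise ValueError("both factors must have exactly two levels")
    for a in la:
        for b in lb:
            if not np.any((fa == a) & (fb == b)):
                raise ValueError(f"empty cell ({a}, {b})")

    # sum-to-zero (effect) coding
    ca = np.where(fa == la[0], 1.0, -1.0)
    cb = np.where(fb == lb[0], 1.0, -1.0)
    X = np.column_stack([np.ones_like(y), ca, cb, ca * cb])
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sse = float(resid @ resid)
    n = y.size
    df2 = n - 4
    if df2 <= 0:
        raise ValueError("not enough observations")
    mse = sse / df2
    xtx_inv = np.linalg.inv(X.T @ X)

    out: Dict[str, AnovaResult] = {}
    for name, j in (("condition", 1), ("limb", 2), ("interaction", 3)):
        # Type III SS of a single effect-coded column: beta_j^2 / [(X'X)^-1]_jj
        ss = float(beta[j] ** 2 / xtx_inv[j, j])
        F = ss / mse if mse > 0 else (0.0 if ss == 0 else np.inf)
        p = float(sps.f.sf(F, 1, df2)) if np.isfinite(F) else 0.0
        out[name] = AnovaResult(name, float(F), 1, df2, p, ss)

    sst = float(((y - y.mean()) ** 2).sum())
    out["model"] = AnovaResult("model", np.nan, 3, df2, np.nan, sst - sse)
    out["residual"] = AnovaResult("residual", np.nan, df2, df2, np.nan, sse)
    return out


def cohens_d(
    mean1: float, sd1: float, mean2: float, sd2: float,
    n1: Optional[int] = None, n2: Optional[int] = None,
) -> float:
    """Cohen's d from group descriptives.

    By default the pooled sd weighs both groups equally,
    ``sqrt((sd1^2 + sd2^2) / 2)``; passing ``n1``/``n2`` switches to the
    sample-size-weighted pooled sd.
    """
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    if sd1 == 0 and sd2 == 0:
        raise ValueError("both standard deviations are zero")
    if n1 is not None and n2 is not None:
        pooled = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    else:
        pooled = np.sqrt((sd1**2 + sd2**2) / 2.0)
    return float(abs(mean1 - mean2) / pooled)


def interpret_d(d: float) -> str:
    """Interpretation band of a Cohen's d magnitude."""
    idx = int(np.searchsorted(D_BANDS, abs(d), side="right"))
    return D_LABELS[idx]


def power_two_sample_t(n_per_group: int, d: float, alpha: float = 0.05) -> float:
    """Exact power of a two-sided two-sample t-test at equal group sizes.

    Uses the noncentral t distribution with ``df = 2n - 2`` and
    noncentrality ``d * sqrt(n / 2)``.
    """
    if n_per_group < 2:
        raise ValueError("need at least 2 per group")
    df = 2 * n_per_group - 2
    nc = d * np.sqrt(n_per_group / 2.0)
    tcrit = sps.t.ppf(1 - alpha / 2, df)
    return float(sps.nct.sf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc))


def sample_size_for_power(
    d: float, alpha: float = 0.05, power: float = 0.8, n_max: int = 1_000_000
) -> int:
    """Smallest per-group n giving at least the target power.

    Exact noncentral-t power for a two-sided two-sample t-test; raises
    if the target is unreachable within ``n_max``.
    """
    if d <= 0:
        raise ValueError("effect size d must be positive")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    # bracket by doubling, then binary search for the threshold
    lo, hi = 2, 2
    while power_two_sample_t(hi, d, alpha) < power:
        lo, hi = hi, hi * 2
        if hi > n_max:
            raise ValueError("target power unreachable within n_max")
    while lo < hi:
        mid = (lo + hi) // 2
        if power_two_sample_t(mid, d, alpha) >= power:
            hi = mid
        else:
            lo = mid + 1
    return int(hi)
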