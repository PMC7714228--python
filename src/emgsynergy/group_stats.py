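"""Statistical comparisons of synergy counts across groups and covariates.

Thin, contract-checked wrappers over :mod:`scipy.stats`: Spearman rank
correlation (synergy count vs. clinical covariates), Wilcoxon signed-rank
(paired, e.g. 8- vs 10-electrode counts within subjects), Mann-Whitney U
(unpaired group comparison) and Welch's t-test (anthropometrics). All
tests are two-sided and no multiple-testing correction is applied by
default; :func:`holm_adjust` is available for reuse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

from .errors import DegenerateDataError


@dataclass
class StatResult:
    statistic_name: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    effect_direction: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate and not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if not np.isfinite(arr).all():
        raise ValueError(f"{name} contains non-finite values")
    return arr


def spearman_assoc(x, y) -> StatResult:
    """Spearman rank correlation with mid-rank ties, two-sided p."""
    x = _as_1d(x, "x")
    y = _as_1d(y, "y")
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 4:
        raise ValueError("need at least 4 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("Spearman undefined for constant input")
    rho, p = scipy.stats.spearmanr(x, y)
    return StatResult(
        statistic_name="spearman_rho",
        statistic=float(rho),
        p_value=float(p),
        n=(len(x),),
        effect_direction=int(np.sign(rho)),
    )


def _exact_signed_rank_p(d: np.ndarray) -> tuple[float, float]:
    """Exact two-sided signed-rank p over all 2^n sign patterns.

    Handles midrank ties by working with doubled ranks (integers) and a
    generating-polynomial convolution, so no explicit enumeration is
    needed. Returns (W+, p).
    """
    ranks = scipy.stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    r2 = np.round(2 * ranks).astype(int)
    total2 = int(r2.sum())
    counts = np.zeros(total2 + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: len(counts) - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = np.arange(total2 + 1)
    m2 = min(round(2 * w_plus), total2 - round(2 * w_plus))
    p = float(counts[np.minimum(w2, total2 - w2) <= m2].sum())
    return w_plus, min(1.0, p)


def paired_compare(a, b) -> StatResult:
    """Wilcoxon signed-rank test on paired samples.

    Zero differences are excluded; the p-value is exact (full sign-
    permutation null, mid-rank ties included) for up to 25 nonzero
    differences, otherwise a tie-corrected normal approximation is used.
    All-zero differences yield a degenerate result (flagged, p = 1).
    """
    a = _as_1d(a, "a")
    b = _as_1d(b, "b")
    if len(a) != len(b):
        raise ValueError("paired samples must have equal length")
    d = a - b
    nz = d[d != 0]
    if len(nz) == 0:
        return StatResult("wilcoxon_W", float("nan"), 1.0, (len(a),), 0,
                          degenerate=True)
    if len(nz) <= 25:
        stat, p = _exact_signed_rank_p(nz)
    else:
        stat, p = scipy.stats.wilcoxon(a, b, zero_method="wilcox",
                                       method="approx")
    return StatResult(
        statistic_name="wilcoxon_W",
        statistic=float(stat),
        p_value=float(p),
        n=(len(nz),),
        effect_direction=int(np.sign(np.sum(np.sign(nz) *
                                            scipy.stats.rankdata(np.abs(nz))))),
    )


def unpaired_compare(a, b) -> StatResult:
    """Mann-Whitney U test, two-sided, tie-corrected.

    Exact when both groups are small (<= 25) and untied, otherwise the
    tie-corrected normal approximation.
    """
    a = _as_1d(a, "a")
    b = _as_1d(b, "b")
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 observations")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (max(len(a), len(b)) <= 25 and not has_ties) \
        else "asymptotic"
    stat, p = scipy.stats.mannwhitneyu(a, b, alternative="two-sided",
                                       method=method)
    return StatResult(
        statistic_name="mannwhitney_U",
        statistic=float(stat),
        p_value=float(p),
        n=(len(a), len(b)),
        effect_direction=int(np.sign(stat - len(a) * len(b) / 2.0)),
    )


def welch_compare(a, b) -> StatResult:
    """Welch's t-test (no equal-variance assumption), two-sided."""
    a = _as_1d(a, "a")
    b = _as_1d(b, "b")
    stat, p = scipy.stats.ttest_ind(a, b, equal_var=False)
    return StatResult(
        statistic_name="welch_t",
        statistic=float(stat),
        p_value=float(p),
        n=(len(a), len(b)),
        effect_direction=int(np.sign(stat)),
    )


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjustment of a family of p-values."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
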