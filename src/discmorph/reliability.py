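"""Reliability statistics: weighted kappa, ICC(2,1) and sample-size formulas.

Weighted Cohen's kappa handles the ordinal start/end-slice choices (start
slice in {1,2,3,4}, end slice in {6,7,8,9}): agreement weights
``w_ij = 1 - |i-j|/(m-1)`` (linear, the default) or
``w_ij = 1 - ((i-j)/(m-1))^2`` (quadratic) on the m x m cross-tabulation give

    K_w = (p_o(w) - p_e(w)) / (1 - p_e(w)),

with the 95% CI from the large-sample (Fleiss-Cohen-Everitt) standard error,
or optionally a seeded nonparametric bootstrap.

ICC(2,1) is the two-way random-effects, absolute-agreement, single-measurement
intraclass correlation (Shrout & Fleiss): with mean squares for rows/subjects
(MS_R), columns/raters (MS_C) and error (MS_E) from the two-way ANOVA of an
n x k rating table,

    ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E)),

and the 95% CI follows the F-distribution interval with Satterthwaite degrees
of freedom.

Sample-size planning: ``n = 2 k^2`` participants for a kappa study with k
ordinal response categories, and Bonett's approximation for the number of
subjects needed to estimate an ICC of ``rho`` with a CI of width ``w`` at
level ``alpha`` using ``k`` raters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ReliabilityResult",
    "weighted_kappa",
    "icc_2_1",
    "kappa_sample_size",
    "bonett_icc_n",
    "crosstab",
]


@dataclass(frozen=True)
class ReliabilityResult:
    """A reliability coefficient with its 95% confidence interval."""

    estimate: float
    ci_lower: float
    ci_upper: float
    method: str
    n: int

    def __post_init__(self) -> None:
        if not (self.ci_lower <= self.estimate <= self.ci_upper):
            raise ValueError("CI must contain the point estimate")


def crosstab(
    pairs: Sequence[tuple], categories: Sequence | None = None
) -> tuple[np.ndarray, list]:
    """m x m contingency table of ordinal (choice_a, choice_b) pairs.

    ``categories`` fixes the ordered category set; by default it is the sorted
    union of observed choices.  Choices outside the category set are an error.
    """
    a = [p[0] for p in pairs]
    b = [p[1] for p in pairs]
    if categories is None:
        cats = sorted(set(a) | set(b))
    else:
        cats = list(categories)
    index = {c: i for i, c in enumerate(cats)}
    table = np.zeros((len(cats), len(cats)))
    for x, y in zip(a, b):
        if x not in index or y not in index:
            raise ValueError(f"choice {x!r}/{y!r} outside category set {cats}")
        table[index[x], index[y]] += 1
    return table, cats


def _weight_matrix(m: int, weights: str) -> np.ndarray:
    i = np.arange(m)
    dist = np.abs(i[:, None] - i[None, :]) / (m - 1)
    if weights == "linear":
        return 1.0 - dist
    if weights == "quadratic":
        return 1.0 - dist**2
    raise ValueError("weights must be 'linear' or 'quadratic'")


def _kappa_from_table(table: np.ndarray, w: np.ndarray) -> tuple[float, float, float]:
    n = table.sum()
    p = table / n
    pr = p.sum(axis=1)
    pc = p.sum(axis=0)
    po = float((w * p).sum())
    pe = float((w * np.outer(pr, pc)).sum())
    if 1.0 - pe <= 0:
        raise ValueError(
            "chance-expected weighted agreement is 1 (all mass in one cell); "
            "weighted kappa is undefined"
        )
    return (po - pe) / (1.0 - pe), po, pe


def weighted_kappa(
    pairs: Sequence[tuple],
    categories: Sequence | None = None,
    weights: str = "linear",
    ci_method: str = "asymptotic",
    alpha: float = 0.05,
    n_boot: int = 2000,
    seed: int = 0,
) -> ReliabilityResult:
    """Weighted Cohen's kappa for paired ordinal choices, with 95% CI.

    ``ci_method`` is ``"asymptotic"`` (Fleiss-Cohen-Everitt large-sample SE,
    deterministic) or ``"bootstrap"`` (seeded percentile bootstrap over pairs).
    """
    pairs = list(pairs)
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs")
    table, cats = crosstab(pairs, categories)
    if len(cats) < 2:
        raise ValueError("need at least 2 ordinal categories")
    w = _weight_matrix(len(cats), weights)
    kappa, po, pe = _kappa_from_table(table, w)

    z = stats.norm.ppf(1 - alpha / 2)
    if ci_method == "asymptotic":
        n = table.sum()
        p = table / n
        pr = p.sum(axis=1)
        pc = p.sum(axis=0)
        wbar_row = w @ pc          # row-wise expected weight
        wbar_col = pr @ w          # column-wise expected weight
        term = (
            w * (1 - pe) - (wbar_row[:, None] + wbar_col[None, :]) * (1 - po)
        ) ** 2
        var = (float((p * term).sum()) - (po * pe - 2 * pe + po) ** 2) / (
            n * (1 - pe) ** 4
        )
        se = math.sqrt(max(var, 0.0))
        lo, hi = kappa - z * se, kappa + z * se
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        idx = np.arange(len(pairs))
        reps = []
        for _ in range(n_boot):
            sample = [pairs[i] for i in rng.choice(idx, size=len(pairs))]
            t, _ = crosstab(sample, cats)
            try:
                reps.append(_kappa_from_table(t, w)[0])
            except ValueError:
                continue
        lo, hi = np.quantile(reps, [alpha / 2, 1 - alpha / 2])
    else:
        raise ValueError("ci_method must be 'asymptotic' or 'bootstrap'")

    lo = min(max(lo, -1.0), kappa)
    hi = max(min(hi, 1.0), kappa)
    return ReliabilityResult(
        estimate=float(kappa),
        ci_lower=float(lo),
        ci_upper=float(hi),
        method=f"weighted kappa ({weights}, {ci_method} CI)",
        n=len(pairs),
    )


def icc_2_1(ratings: np.ndarray, alpha: float = 0.05) -> ReliabilityResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measurement.

    ``ratings`` is a complete n x k matrix (n subjects, k raters).  Raises
    ``ValueError`` when both the between-subject and the residual variance are
    zero, where the coefficient is undefined.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("ratings must be an n x k matrix with n >= 2, k >= 2")
    if np.isnan(x).any():
        raise ValueError("rating table must be complete")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((x - grand) ** 2).sum())
    ss_err = max(ss_total - ss_rows - ss_cols, 0.0)
    if ss_err <= 1e-12 * ss_total:  # float residue of an exact decomposition
        ss_err = 0.0
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0:
        raise ValueError(
            "zero between-subject and error variance: ICC(2,1) undefined"
        )
    icc = (msr - mse) / denom

    if mse == 0.0:
        # noiseless table: estimate is exact, interval collapses
        return ReliabilityResult(icc, icc, icc, "ICC(2,1), degenerate (MSE=0)", n)

    # Satterthwaite df for the F-based interval
    fj = msc / mse
    vn = (k - 1) * (n - 1) * (k * icc * fj + n * (1 + (k - 1) * icc) - k * icc) ** 2
    vd = (n - 1) * k**2 * icc**2 * fj**2 + (n * (1 + (k - 1) * icc) - k * icc) ** 2
    v = vn / vd
    f_lower = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_upper = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lo = n * (msr - f_lower * mse) / (
        f_lower * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    hi = n * (f_upper * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_upper * msr
    )
    lo = min(max(float(lo), -1.0), icc)
    hi = max(min(float(hi), 1.0), icc)
    return ReliabilityResult(float(icc), lo, hi, "ICC(2,1)", n)


def kappa_sample_size(k_categories: int) -> int:
    """Participants needed for a kappa study with k ordinal categories: 2 k^2."""
    if k_categories < 2:
        raise ValueError("need at least 2 response categories")
    return 2 * k_categories**2


def bonett_icc_n(
    rho: float, alpha: float = 0.05, width: float = 0.2, k_raters: int = 2
) -> int:
    """Bonett's approximate sample size to estimate an ICC to a CI width.

    ``n = 8 z^2 (1-rho)^2 (1+(k-1)rho)^2 / (k (k-1) w^2) + 1``, rounded up,
    for an expected coefficient ``rho``, two-sided level ``alpha``, total CI
    width ``width`` and ``k_raters`` raters.
    """
    if not (0.0 < rho < 1.0):
        raise ValueError("rho must lie in (0, 1)")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if width <= 0:
        raise ValueError("width must be > 0")
    if k_raters < 2:
        raise ValueError("need at least 2 raters")
    z = stats.norm.ppf(1 - alpha / 2)
    n = 8 * z**2 * (1 - rho) ** 2 * (1 + (k_raters - 1) * rho) ** 2 / (
        k_raters * (k_raters - 1) * width**2
    ) + 1
    return math.ceil(n - 1e-9)
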