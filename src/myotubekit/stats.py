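"""Statistical layer: per-field medians, rank-sum and t tests, mean ± SEM.

Comparisons between culture substrates are made on one summary value
per acquired field (the per-field median), compared with a Wilcoxon
rank-sum test using midranks for ties and a tie-corrected normal
approximation without continuity correction — the convention that
reproduces the printed (z, p) pairs of the source assay, e.g.
z = 4.023 ↔ p = 5.76 × 10⁻⁵.  All other comparisons use a two-sample
Student t test (equal variance by default, Welch optional) on
mean ± SEM summaries.

Significance stars follow the assay's mapping:
* p < 0.05, ** p < 0.01, *** p < 0.001, **** p < 0.00001.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

#: star thresholds, strict inequalities, most significant first
STAR_LEVELS = (
    (1e-5, "****"),
    (1e-3, "***"),
    (1e-2, "**"),
    (5e-2, "*"),
)


@dataclass
class TestResult:
    test: str
    statistic: float  # z for rank-sum, t for t test
    two_sided_p: float
    n_a: int
    n_b: int
    stars: str
    degenerate: bool = False  # e.g. all values identical


def significance_stars(p: float) -> str:
    """Map a p value to the assay's star notation ('' when p ≥ 0.05)."""
    for thr, stars in STAR_LEVELS:
        if p < thr:
            return stars
    return ""


def normal_two_sided_p(z: float) -> float:
    """Two-sided normal tail probability 2·(1 − Φ(|z|))."""
    if not math.isfinite(z):
        raise ValueError("z must be finite")
    return float(2.0 * sps.norm.sf(abs(z)))


def per_unit_median(
    values_by_unit: Mapping[object, Sequence[float]],
) -> dict[object, float]:
    """One median per unit (field/experiment); empty units are dropped.

    Downstream tests operate on these medians, one observation per
    field, never on pooled per-object values.
    """
    out = {}
    for unit, vals in values_by_unit.items():
        vals = np.asarray(list(vals), dtype=float)
        if vals.size == 0:
            continue
        out[unit] = float(np.median(vals))
    return out


def mean_sem(values: Iterable[float]) -> tuple[float, float]:
    """Sample mean and standard error (sample SD / √n); n ≥ 2 required."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size < 2:
        raise ValueError("SEM undefined for n < 2")
    return float(vals.mean()), float(vals.std(ddof=1) / math.sqrt(vals.size))


def wilcoxon_ranksum(
    group_a: Sequence[float], group_b: Sequence[float]
) -> TestResult:
    """Wilcoxon rank-sum test, normal approximation.

    Midranks for ties; z from the rank sum of group A with
    tie-corrected variance and no continuity correction;
    ``p = 2·(1 − Φ(|z|))``.  When every value in both groups is
    identical the variance is 0 and the result is degenerate with
    p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs ≥ 2 values")
    combined = np.concatenate([a, b])
    ranks = sps.rankdata(combined)  # midranks
    W = float(ranks[:n1].sum())
    N = n1 + n2
    mu = n1 * (N + 1) / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (N * (N - 1)))
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        return TestResult(
            test="wilcoxon_ranksum",
            statistic=0.0,
            two_sided_p=1.0,
            n_a=n1,
            n_b=n2,
            stars="",
            degenerate=True,
        )
    z = (W - mu) / math.sqrt(var)
    p = normal_two_sided_p(z)
    return TestResult(
        test="wilcoxon_ranksum",
        statistic=float(z),
        two_sided_p=p,
        n_a=n1,
        n_b=n2,
        stars=significance_stars(p),
    )


def students_t(
    group_a: Sequence[float],
    group_b: Sequence[float],
    equal_var: bool = True,
) -> TestResult:
    """Two-sample t test (classical Student by default, Welch optional)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs ≥ 2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return TestResult(
                test="students_t",
                statistic=0.0,
                two_sided_p=1.0,
                n_a=len(a),
                n_b=len(b),
                stars="",
                degenerate=True,
            )
        return TestResult(
            test="students_t",
            statistic=math.copysign(math.inf, a.mean() - b.mean()),
            two_sided_p=0.0,
            n_a=len(a),
            n_b=len(b),
            stars="****",
            degenerate=True,
        )
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return TestResult(
        test="students_t" if equal_var else "welch_t",
        statistic=float(t),
        two_sided_p=float(p),
        n_a=len(a),
        n_b=len(b),
        stars=significance_stars(float(p)),
    )
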