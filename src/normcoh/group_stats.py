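"""Rank-based group comparison of abnormality indices and confound checks.

The hypothesis for a case-vs-control contrast is directional: case
subjects are expected to be *more abnormal*, i.e. to have a greater
median abnormality index, so the Mann-Whitney U test is one-tailed in
that direction.  Confound checks follow the same scheme used for the
main contrast: a two-tailed Mann-Whitney test for sex effects and a
quadratic least-squares regression of index on age (overall F-test for
the joint nullity of the linear and quadratic terms).

scipy provides the rank tests (exact enumeration for small untied
samples, tie-corrected normal approximation with continuity correction
otherwise) and statsmodels the regression F-test.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "ComparisonReport",
    "mann_whitney_one_tailed",
    "sex_effect_test",
    "age_effect_quadratic",
]

#: Largest pooled sample size for which the exact null distribution is used.
EXACT_MAX_N = 12


@dataclasses.dataclass
class ComparisonReport:
    """Outcome of a rank-based two-group comparison."""

    contrast: str
    u_statistic: float
    p_value: float
    median_a: float
    median_b: float
    n_a: int
    n_b: int
    direction: str  # "a-greater", "b-greater" or "two-sided"


def _mwu(a, b, alternative: str) -> tuple[float, float]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    if a.size + b.size <= EXACT_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"  # midranks, tie-corrected variance, continuity correction
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def mann_whitney_one_tailed(a, b, alternative: str = "a-greater", *, contrast: str = "") -> ComparisonReport:
    """One-tailed Mann-Whitney U test between two index samples.

    ``alternative="a-greater"`` tests whether sample ``a`` is
    stochastically greater than ``b`` (the case-vs-control direction);
    ``"b-greater"`` the reverse.
    """
    if alternative not in ("a-greater", "b-greater"):
        raise ValueError("alternative must be 'a-greater' or 'b-greater'")
    u, p = _mwu(a, b, "greater" if alternative == "a-greater" else "less")
    return ComparisonReport(
        contrast=contrast,
        u_statistic=u,
        p_value=p,
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        n_a=len(a),
        n_b=len(b),
        direction=alternative,
    )


def sex_effect_test(indices, sexes) -> float:
    """Two-tailed Mann-Whitney p for an index difference between sexes."""
    indices = np.asarray(indices, dtype=float)
    sexes = np.asarray(sexes)
    levels = np.unique(sexes)
    if levels.size != 2:
        raise ValueError(f"need exactly two sex levels, found {levels.tolist()}")
    a = indices[sexes == levels[0]]
    b = indices[sexes == levels[1]]
    _, p = _mwu(a, b, "two-sided")
    return p


def age_effect_quadratic(indices, ages) -> float:
    """Overall F-test p for index = b0 + b1 age + b2 age^2.

    Tests the joint hypothesis (b1, b2) = 0; a small p indicates that
    age explains index variation and is a potential confound.
    """
    y = np.asarray(indices, dtype=float)
    age = np.asarray(ages, dtype=float)
    if y.size < 4:
        raise ValueError("need at least 4 observations for the quadratic fit")
    if np.var(age) <= 0:
        raise ValueError("age has zero variance")
    X = sm.add_constant(np.column_stack([age, age**2]))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("degenerate (collinear) quadratic design in age")
    fit = sm.OLS(y, X).fit()
    return float(fit.f_pvalue)
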