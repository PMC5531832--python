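"""The inferential battery for within-subject medication-state designs.

Paired and independent t-tests, Wilcoxon signed-rank (exact null for
small samples), a 2x2 within-subject ANOVA computed through contrast
scores, one-way between-groups ANOVA, Pearson correlation, Cohen's d
variants, partial eta squared, and the Bonferroni threshold.

Degenerate inputs (zero-variance differences, fewer than two complete
pairs) return NaN-statistic sentinels rather than raising, so a battery
over many measures can run to completion and report what was undefined.

Two Cohen's d variants are attached to every paired test because
published effect sizes for paired designs are computed inconsistently in
the literature: ``d_z`` standardises by the SD of the differences
(d_z = t/sqrt(n)) and ``d_av`` by the average of the two condition SDs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class TestResult:
    """One inferential test: statistic, degrees of freedom, p, and n."""

    statistic_name: str   # t, F, W, r, chi2
    statistic: float
    df: float | tuple[float, float] | None
    p: float
    n: int

    @property
    def significant(self) -> bool:
        return bool(self.p < 0.05)


@dataclass(frozen=True)
class EffectSize:
    """Effect sizes attached to a test; NaN where a variant is undefined."""

    d_z: float = float("nan")
    d_av: float = float("nan")
    eta_p2: float = float("nan")


_DEGENERATE = TestResult("t", float("nan"), None, float("nan"), 0)


def p_from_t(t: float, df: int) -> float:
    """Two-tailed p-value of a central-t statistic."""
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    return float(2.0 * sps.t.sf(abs(t), df))


def partial_eta_squared(F: float, df1: float, df2: float) -> float:
    """Partial eta squared of an ANOVA effect: F*df1 / (F*df1 + df2)."""
    if F < 0:
        raise ValueError(f"F must be >= 0, got {F}")
    return float(F * df1 / (F * df1 + df2))


def bonferroni_alpha(family_alpha: float, m: int) -> float:
    """Per-comparison significance threshold controlling the family rate."""
    if m < 1:
        raise ValueError(f"number of comparisons must be >= 1, got {m}")
    return family_alpha / m


def _drop_pairwise(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    return x[ok], y[ok]


def paired_t(x, y) -> tuple[TestResult, EffectSize]:
    """Paired-samples t-test with d_z and d_av effect sizes.

    Incomplete pairs are dropped pairwise; zero variance of the
    differences yields the degenerate NaN sentinel.
    """
    x, y = _drop_pairwise(x, y)
    n = len(x)
    if n < 2:
        return _DEGENERATE, EffectSize()
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        return TestResult("t", float("nan"), n - 1, float("nan"), n), EffectSize()
    t = d.mean() / (sd / np.sqrt(n))
    d_z = d.mean() / sd
    d_av = d.mean() / ((x.std(ddof=1) + y.std(ddof=1)) / 2)
    return (
        TestResult("t", float(t), n - 1, p_from_t(t, n - 1), n),
        EffectSize(d_z=float(d_z), d_av=float(d_av)),
    )


def independent_t(x, y) -> tuple[TestResult, EffectSize]:
    """Independent-samples t-test (pooled variance) with pooled Cohen's d."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        return _DEGENERATE, EffectSize()
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0:
        return TestResult("t", float("nan"), n1 + n2 - 2, float("nan"), n1 + n2), EffectSize()
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    d = (x.mean() - y.mean()) / np.sqrt(sp2)
    return (
        TestResult("t", float(t), n1 + n2 - 2, p_from_t(t, n1 + n2 - 2), n1 + n2),
        EffectSize(d_av=float(d)),
    )


def one_way_anova(*groups) -> tuple[TestResult, EffectSize]:
    """One-way between-groups ANOVA with partial eta squared."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    arrs = [a[~np.isnan(a)] for a in arrs]
    if len(arrs) < 2 or any(len(a) < 2 for a in arrs):
        return _DEGENERATE, EffectSize()
    F, p = sps.f_oneway(*arrs)
    k = len(arrs)
    n = sum(len(a) for a in arrs)
    df1, df2 = k - 1, n - k
    return (
        TestResult("F", float(F), (df1, df2), float(p), n),
        EffectSize(eta_p2=partial_eta_squared(float(F), df1, df2)),
    )


def pearson_r(x, y) -> TestResult:
    """Pearson correlation with its two-tailed p."""
    x, y = _drop_pairwise(x, y)
    n = len(x)
    if n < 3:
        return TestResult("r", float("nan"), None, float("nan"), n)
    r, p = sps.pearsonr(x, y)
    return TestResult("r", float(r), n - 2, float(p), n)


def rm_anova_2x2(scores) -> dict[str, tuple[TestResult, EffectSize]]:
    """2x2 within-subject ANOVA via contrast scores.

    ``scores`` is an (n_subjects, 4) array whose columns are the cells
    (A1B1, A1B2, A2B1, A2B2) of a factorial within-subject design, e.g.
    the four medication conditions (ON-ON, ON-OFF, OFF-ON, OFF-OFF).
    Each 1-df effect is a one-sample t-test on the corresponding contrast
    score, reported as F = t^2 with df (1, n-1) and partial eta squared
    -- exactly equivalent to the classical sums-of-squares decomposition
    for a 2x2 design.  Subjects with any missing cell are dropped.

    Returns a dict with keys ``"A"``, ``"B"`` (main effects) and
    ``"AxB"`` (interaction).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] != 4:
        raise ValueError("scores must be an (n_subjects, 4) array")
    scores = scores[~np.isnan(scores).any(axis=1)]
    n = len(scores)
    if n < 3:
        raise ValueError(f"need >= 3 complete subjects, got {n}")
    c1, c2, c3, c4 = scores.T
    contrasts = {
        "A": (c1 + c2 - c3 - c4) / 2.0,
        "B": (c1 - c2 + c3 - c4) / 2.0,
        "AxB": (c1 - c2 - c3 + c4) / 2.0,
    }
    out = {}
    for name, c in contrasts.items():
        sd = c.std(ddof=1)
        if sd == 0:
            F = 0.0
            p = 1.0
        else:
            t = c.mean() / (sd / np.sqrt(n))
            F = float(t**2)
            p = p_from_t(t, n - 1)
        df = (1, n - 1)
        out[name] = (
            TestResult("F", F, df, p, n),
            EffectSize(eta_p2=partial_eta_squared(F, *df)),
        )
    return out


def wilcoxon_signed_rank(x, y) -> TestResult:
    """Wilcoxon signed-rank test on paired vectors.

    Zero differences are dropped (Wilcoxon's convention); the exact null
    distribution is used for n <= 25 and the normal approximation with
    continuity correction above.  All-zero differences yield the
    degenerate sentinel.
    """
    x, y = _drop_pairwise(x, y)
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return TestResult("W", float("nan"), None, float("nan"), 0)
    method = "exact" if n <= 25 else "approx"
    res = sps.wilcoxon(d, zero_method="wilcox", correction=(method == "approx"),
                       alternative="two-sided", method=method)
    return TestResult("W", float(res.statistic), None, float(res.pvalue), n)
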