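"""Statistical battery for the axis analyses, with the effect sizes the
study design reports: Cramer's V for contingency tables, omega for one-way
ANOVA, r-from-t for two-sample t-tests and r^2 for Pearson correlations.

Thin, typed wrappers over scipy primitives where a standard procedure
exists; the effect-size conventions (pooled-variance t, omega clipped at
zero, two-sided p throughout) are fixed here so every caller reports the
same quantities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats as sps

ALPHA = 0.05


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class TestResult:
    """One test: statistic, degrees of freedom, p, named effect size."""

    name: str
    statistic: float
    df: Union[float, Tuple[float, float], None]
    pvalue: float
    effect_name: Optional[str] = None
    effect_value: Optional[float] = None
    extra: Optional[Mapping[str, float]] = None


@dataclass(frozen=True)
class ContingencyTable:
    counts: np.ndarray
    row_labels: Tuple[str, ...]
    col_labels: Tuple[str, ...]

    @classmethod
    def from_pairs(cls, rows: Sequence[str], cols: Sequence[str]) -> "ContingencyTable":
        """Cross-tabulate two equal-length label sequences."""
        if len(rows) != len(cols):
            raise StatsError("row and column label sequences differ in length")
        r_labels = tuple(sorted(set(rows)))
        c_labels = tuple(sorted(set(cols)))
        counts = np.zeros((len(r_labels), len(c_labels)), dtype=int)
        for r, c in zip(rows, cols):
            counts[r_labels.index(r), c_labels.index(c)] += 1
        return cls(counts=counts, row_labels=r_labels, col_labels=c_labels)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
            raise StatsError(f"contingency table must be at least 2x2, got {counts.shape}")
        if (counts < 0).any() or counts.sum() == 0:
            raise StatsError("contingency table needs nonnegative counts with a positive total")


def chi_square(table: ContingencyTable) -> TestResult:
    """Pearson chi-squared test of independence (no continuity correction),
    with Cramer's V attached."""
    counts = table.counts
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise StatsError("zero marginal: drop empty rows/columns before testing")
    chi2, p, df, _ = sps.chi2_contingency(counts, correction=False)
    v = cramers_v(chi2, int(counts.sum()), counts.shape[0], counts.shape[1])
    return TestResult(
        name="chi_square", statistic=float(chi2), df=float(df), pvalue=float(p),
        effect_name="cramers_v", effect_value=v,
    )


def cramers_v(chi2: float, n: int, r: int, c: int) -> float:
    """V = sqrt(chi2 / (n * (min(r, c) - 1))), clipped into [0, 1]."""
    if n <= 0 or min(r, c) < 2:
        raise StatsError("Cramer's V needs n > 0 and at least a 2x2 table")
    return float(np.clip(math.sqrt(chi2 / (n * (min(r, c) - 1))), 0.0, 1.0))


def fisher_exact(
    table: ContingencyTable,
    mc_reps: int = 20000,
    seed: Optional[int] = None,
) -> TestResult:
    """Fisher's exact test of independence.

    2x2 tables use the exact two-sided hypergeometric p.  Larger tables use
    a Monte-Carlo estimate of the Freeman-Halton p (probability, under
    fixed margins, of a table no more probable than the observed one), with
    its standard error in ``extra``.
    """
    counts = table.counts
    if counts.shape == (2, 2):
        res = sps.fisher_exact(counts, alternative="two-sided")
        return TestResult(
            name="fisher_exact", statistic=float(res.statistic), df=None,
            pvalue=float(res.pvalue),
        )
    rows, cols = counts.sum(axis=1), counts.sum(axis=0)
    dist = sps.random_table(rows, cols)
    logp_obs = dist.logpmf(counts)
    rng = np.random.default_rng(seed)
    samples = dist.rvs(size=mc_reps, method="patefield", random_state=rng)
    logp = dist.logpmf(samples)
    hits = int(np.sum(logp <= logp_obs + 1e-10))
    p = (hits + 1) / (mc_reps + 1)
    se = math.sqrt(p * (1 - p) / mc_reps)
    return TestResult(
        name="fisher_exact_mc", statistic=float("nan"), df=None, pvalue=float(p),
        extra={"mc_se": se, "mc_reps": mc_reps},
    )


class GroupedSamples(Dict[str, np.ndarray]):
    """group label -> 1-D array of values."""

    @classmethod
    def from_mapping(cls, groups: Mapping[str, Sequence[float]]) -> "GroupedSamples":
        out = cls()
        for k, v in groups.items():
            out[k] = np.asarray(v, dtype=float)
        return out


def one_way_anova(groups: Mapping[str, Sequence[float]]) -> TestResult:
    """One-way fixed-effects ANOVA with omega effect size.

    omega = sqrt(max(0, (SS_between - (k-1) MS_within) / (SS_total + MS_within)));
    the clipping makes omega well defined when F < 1.
    """
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    k = len(arrays)
    if k < 2:
        raise StatsError("ANOVA needs at least two groups")
    ns = np.array([len(a) for a in arrays])
    if (ns < 1).any():
        raise StatsError("every group needs at least one observation")
    n_total = int(ns.sum())
    df_b, df_w = k - 1, n_total - k
    if df_w < 1:
        raise StatsError("within-group degrees of freedom must be >= 1")
    grand = np.concatenate(arrays).mean()
    ss_b = float(sum(len(a) * (a.mean() - grand) ** 2 for a in arrays))
    ss_w = float(sum(((a - a.mean()) ** 2).sum() for a in arrays))
    if ss_w == 0:
        raise StatsError("zero within-group variance everywhere")
    ss_t = ss_b + ss_w
    ms_w = ss_w / df_w
    f = (ss_b / df_b) / ms_w
    p = float(sps.f.sf(f, df_b, df_w))
    omega_sq = (ss_b - df_b * ms_w) / (ss_t + ms_w)
    omega = math.sqrt(max(0.0, omega_sq))
    return TestResult(
        name="one_way_anova", statistic=float(f), df=(float(df_b), float(df_w)),
        pvalue=p, effect_name="omega", effect_value=omega,
    )


def tukey_hsd(groups: Mapping[str, Sequence[float]]) -> Dict[Tuple[str, str], TestResult]:
    """Tukey's HSD pairwise comparisons (family-wise studentized-range p)."""
    labels = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in labels]
    if len(arrays) < 2:
        raise StatsError("Tukey HSD needs at least two groups")
    res = sps.tukey_hsd(*arrays)
    out: Dict[Tuple[str, str], TestResult] = {}
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            out[(labels[i], labels[j])] = TestResult(
                name="tukey_hsd",
                statistic=float(res.statistic[i, j]),
                df=None,
                pvalue=float(res.pvalue[i, j]),
            )
    return out


def r_from_t(t: float, df: float) -> float:
    """Effect size r = sqrt(t^2 / (t^2 + df)) for a two-sample t-test."""
    if df <= 0:
        raise StatsError("df must be positive")
    return math.sqrt(t * t / (t * t + df))


def t_test_ind(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Pooled-variance two-sample t-test with effect size r.

    df = n_a + n_b - 2 (the pooled convention).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) + len(b) < 3:
        raise StatsError("need at least three observations in total")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and len(a) > 1 and len(b) > 1:
        raise StatsError("zero pooled variance")
    res = sps.ttest_ind(a, b, equal_var=True)
    df = len(a) + len(b) - 2
    return TestResult(
        name="t_test_ind", statistic=float(res.statistic), df=float(df),
        pvalue=float(res.pvalue), effect_name="r", effect_value=r_from_t(res.statistic, df),
    )


def pearson(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Pearson correlation with r^2 and two-sided p (t transform)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise StatsError("Pearson correlation needs paired samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise StatsError("constant input")
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    return TestResult(
        name="pearson", statistic=r, df=float(len(x) - 2), pvalue=float(res.pvalue),
        effect_name="r_squared", effect_value=r * r,
    )
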