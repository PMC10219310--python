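"""Cohort comparison statistics.

Counts mutated vs wild-type peptides passing percentile-rank thresholds
per patient and MHC class, summarizes the percentages, and runs the
normality-gated two-sample and paired one-sided t-tests. No multiple-
testing correction is applied across the comparisons, and no
non-parametric fallback is provided (normality is assumed throughout).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

#: IEDB-recommended percentile-rank cutoffs for covering most binders
CLASS1_THRESHOLD = 1.0
CLASS2_THRESHOLD = 10.0

#: sample-size boundary between the small-n and large-n normality tests
NORMALITY_SIZE_RULE = 30


@dataclass(frozen=True)
class BinderCount:
    """Peptides of one (patient, class, mutated-flag) group passing a cutoff."""

    sample_id: str
    mhc_class: str
    is_mutated: bool
    n_pass: int
    n_total: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_pass <= self.n_total):
            raise ValueError(f"n_pass {self.n_pass} outside [0, n_total={self.n_total}]")

    @property
    def pct(self) -> float:
        return 100.0 * self.n_pass / self.n_total if self.n_total else 0.0


@dataclass(frozen=True)
class TestReport:
    """Outcome of one statistical comparison."""

    test_name: str
    statistic: float
    p_value: float
    ci: tuple[float, float] | None
    alternative: str  # "two_sided" | "greater"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "test_name": self.test_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "ci": list(self.ci) if self.ci is not None else None,
            "alternative": self.alternative,
            "alpha": self.alpha,
        }


def count_passing(
    records: pd.DataFrame,
    mhc_class: str,
    threshold: float,
    *,
    per_allele: bool = False,
) -> list[BinderCount]:
    """Count windows whose best percentile rank meets the cutoff.

    ``records`` holds one row per (window, allele) with columns
    sample_id, mhc_class, is_mutated, window_id, allele, rank. By default
    a window passes when its minimum rank over the patient's alleles of
    the class is <= threshold (per-peptide, best-allele counting);
    ``per_allele=True`` switches to counting (window, allele) pairs.
    """
    if not (0.0 < threshold <= 100.0):
        raise ValueError(f"threshold {threshold} outside (0, 100]")
    needed = {"sample_id", "mhc_class", "is_mutated", "window_id", "allele", "rank"}
    missing = needed - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    sub = records[records["mhc_class"] == mhc_class]
    out: list[BinderCount] = []
    for (sample, mutated), grp in sub.groupby(["sample_id", "is_mutated"], sort=True):
        if per_allele:
            n_total = len(grp)
            n_pass = int((grp["rank"] <= threshold).sum())
        else:
            best = grp.groupby("window_id")["rank"].min()
            n_total = len(best)
            n_pass = int((best <= threshold).sum())
        out.append(
            BinderCount(
                sample_id=str(sample),
                mhc_class=mhc_class,
                is_mutated=bool(mutated),
                n_pass=n_pass,
                n_total=n_total,
            )
        )
    return out


def summarize_pct(counts: list[BinderCount]) -> tuple[float, float, float, float]:
    """(mean, sd, min, max) of per-patient passing percentages; sd uses the
    n-1 denominator. Requires at least two patients."""
    if len(counts) < 2:
        raise ValueError("need at least 2 patients to summarize")
    pcts = np.array([c.pct for c in counts])
    return (float(pcts.mean()), float(pcts.std(ddof=1)), float(pcts.min()), float(pcts.max()))


def normality_check(sample, alpha: float = 0.05) -> TestReport:
    """Normality test gated on sample size: Shapiro-Wilk for n <= 30, a
    Kolmogorov-Smirnov-type test (Lilliefors-corrected for estimated mean
    and variance) for larger samples."""
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise ValueError(f"need n >= 3 for a normality test, got {x.size}")
    if x.size <= NORMALITY_SIZE_RULE:
        res = sps.shapiro(x)
        name, stat, p = "shapiro_wilk", float(res.statistic), float(res.pvalue)
    else:
        stat, p = lilliefors(x, dist="norm")
        name, stat, p = "kolmogorov_smirnov_lilliefors", float(stat), float(min(max(p, 0.0), 1.0))
    return TestReport(test_name=name, statistic=stat, p_value=p, ci=None,
                      alternative="two_sided", alpha=alpha)


def two_sample_ttest(a, b, *, equal_var: bool = True, alpha: float = 0.05) -> TestReport:
    """Two-sided independent t-test (Student's by default, Welch via
    ``equal_var=False``) with a 95% CI for the mean difference.

    Convention: two degenerate identical samples report statistic 0, p 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    name = "two_sample_t" if equal_var else "welch_t"
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
        return TestReport(test_name=name, statistic=0.0, p_value=1.0,
                          ci=(0.0, 0.0), alternative="two_sided", alpha=alpha)
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    lo, hi = res.confidence_interval(confidence_level=1 - alpha)
    return TestReport(
        test_name=name,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        ci=(float(lo), float(hi)),
        alternative="two_sided",
        alpha=alpha,
    )


def paired_ttest_greater(mut, nm, *, alpha: float = 0.05) -> TestReport:
    """One-sided paired t-test of H1: mean(mut - nm) > 0, pairing by
    patient order, with the one-sided 95% CI (lower bound, +inf).

    Conventions for degenerate inputs: all-zero differences give
    statistic 0 and p 0.5 (symmetric null); constant non-zero differences
    have zero variance, and the test reports p -> 0 (positive shift) or
    p -> 1 (negative shift) with an infinite statistic.
    """
    mut = np.asarray(mut, dtype=float)
    nm = np.asarray(nm, dtype=float)
    if mut.shape != nm.shape:
        raise ValueError(f"length mismatch: {mut.shape} vs {nm.shape}")
    if mut.size < 2:
        raise ValueError("need n >= 2 pairs")
    d = mut - nm
    if d.std(ddof=1) == 0:
        if d[0] == 0:
            stat, p, lo = 0.0, 0.5, 0.0
        else:
            stat = math.inf if d[0] > 0 else -math.inf
            p = 0.0 if d[0] > 0 else 1.0
            lo = float(d[0])
        return TestReport(test_name="paired_t_greater", statistic=stat, p_value=p,
                          ci=(lo, math.inf), alternative="greater", alpha=alpha)
    res = sps.ttest_rel(mut, nm, alternative="greater")
    lo, hi = res.confidence_interval(confidence_level=1 - alpha)
    return TestReport(
        test_name="paired_t_greater",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        ci=(float(lo), math.inf),
        alternative="greater",
        alpha=alpha,
    )
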