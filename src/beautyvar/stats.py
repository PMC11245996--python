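"""Reliability, variance-contrast, and estimation-accuracy statistics.

Covers the analysis battery run on quartet rating data: pooled and
paired one-sided t-tests with Cohen's d for the high- vs. low-variance
quartet contrasts, test-retest Pearson reliability of per-participant
mean ratings, per-participant "normalized" ratings (quartet-mean
subtracted), per-participant actual quartet mean/SD, and the
estimated-vs-actual accuracy correlations (with the >= 18 estimated-mean
outlier exclusion).

Directionality of every one-sided test is an explicit parameter, never
inferred from the data.  The two-sample test pools variances (Student,
df = n_a + n_b - 2).  Cohen's d is |mean difference| over the pooled SD
(two-sample) or over the SD of pairwise differences (paired).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data import (EstimationRecord, NumberSet, OUTLIER_ESTIMATED_MEAN,
                   RatingTable, apply_exclusion_rule, sample_sd)

Alternative = Literal["greater", "less"]


@dataclass(frozen=True)
class TestResult:
    """A one-sided t-test outcome with its effect size."""

    statistic: float
    df: float
    p_value: float
    one_sided: bool
    alternative: Alternative
    cohens_d: float
    paired: bool


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with its t-transform p-value (df = n - 2)."""

    r: float
    n: int
    p_value: float


def _one_sided_p(t: float, df: float, alternative: Alternative) -> float:
    if alternative == "greater":
        return float(sps.t.sf(t, df))
    return float(sps.t.cdf(t, df))


def two_sample_t_one_sided(a: Sequence[float], b: Sequence[float],
                           alternative: Alternative = "greater") -> TestResult:
    """Pooled-variance Student t-test of mean(a) vs mean(b), one-sided.

    df = n_a + n_b - 2.  With zero pooled variance the statistic is 0
    for equal means and a signed infinity otherwise (sentinel, no
    exception).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    na, nb = a.size, b.size
    df = na + nb - 2
    diff = a.mean() - b.mean()
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    pooled_sd = math.sqrt(pooled_var)
    if pooled_sd == 0.0:
        t = 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
        d = 0.0 if diff == 0.0 else math.inf
    else:
        t = diff / (pooled_sd * math.sqrt(1.0 / na + 1.0 / nb))
        d = abs(diff) / pooled_sd
    return TestResult(statistic=float(t), df=float(df),
                      p_value=_one_sided_p(t, df, alternative),
                      one_sided=True, alternative=alternative,
                      cohens_d=float(d), paired=False)


def paired_t_one_sided(a: Sequence[float], b: Sequence[float],
                       alternative: Alternative = "greater") -> TestResult:
    """Paired t-test on elementwise differences a - b, df = n - 1.

    Pairing is by index order.  Cohen's d is |mean difference| over the
    SD of the differences.  Zero-variance differences give the same
    0 / signed-infinity sentinels as the two-sample test.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 2:
        raise ValueError("need at least two pairs")
    diffs = a - b
    n = diffs.size
    df = n - 1
    mean_d = diffs.mean()
    sd_d = diffs.std(ddof=1)
    if sd_d == 0.0:
        t = 0.0 if mean_d == 0.0 else math.copysign(math.inf, mean_d)
        d = 0.0 if mean_d == 0.0 else math.inf
    else:
        t = mean_d / (sd_d / math.sqrt(n))
        d = abs(mean_d) / sd_d
    return TestResult(statistic=float(t), df=float(df),
                      p_value=_one_sided_p(t, df, alternative),
                      one_sided=True, alternative=alternative,
                      cohens_d=float(d), paired=True)


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points for a correlation")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(r=float(r), n=int(x.size), p_value=float(p))


def test_retest(table: RatingTable,
                image_subset: Sequence[str] | None = None) -> CorrelationResult:
    """Reliability: Pearson r across participants between their session-1
    and session-2 mean ratings over ``image_subset`` (default: all images
    rated in both sessions)."""
    m1 = table.ratings_matrix(session=1, images=image_subset)
    m2 = table.ratings_matrix(session=2,
                              images=image_subset if image_subset is not None else None)
    common_img = m1.columns.intersection(m2.columns)
    common_par = m1.index.intersection(m2.index)
    if len(common_par) < 3:
        raise ValueError(
            f"only {len(common_par)} participant(s) with both sessions; need >= 3")
    s1 = m1.loc[common_par, common_img].mean(axis=1)
    s2 = m2.loc[common_par, common_img].mean(axis=1)
    return pearson(s1.to_numpy(), s2.to_numpy())


def normalize_ratings(table: RatingTable, quartet: Sequence[str],
                      session: int = 1) -> pd.DataFrame:
    """Each participant's quartet ratings minus their own quartet mean.

    Rows are participants with complete coverage (incomplete ones are
    dropped), columns the four images; every row sums to zero.  Removes
    per-participant level differences so that the across-participant SD
    of a column isolates disagreement about that image.
    """
    mat = table.ratings_matrix(session=session, images=list(quartet), complete_only=True)
    if mat.empty:
        raise ValueError(f"no participant rated all of {sorted(quartet)}")
    return mat.sub(mat.mean(axis=1), axis=0)


def group_sds(table: RatingTable, quartet: Sequence[str], session: int = 1,
              normalized: bool = False) -> pd.Series:
    """Across-participant SD of each quartet image's ratings (optionally
    of the normalized ratings)."""
    if normalized:
        mat = normalize_ratings(table, quartet, session=session)
    else:
        mat = table.ratings_matrix(session=session, images=list(quartet),
                                   complete_only=True)
    return mat.std(ddof=1)


def quartet_actuals(table: RatingTable, quartet: Sequence[str],
                    session: int = 1) -> pd.DataFrame:
    """Per participant: mean and sample SD of their four quartet ratings."""
    mat = table.ratings_matrix(session=session, images=list(quartet), complete_only=True)
    if mat.empty:
        raise ValueError(f"no participant rated all of {sorted(quartet)}")
    return pd.DataFrame({"actual_mean": mat.mean(axis=1),
                         "actual_sd": mat.std(axis=1, ddof=1)})


@dataclass(frozen=True)
class AccuracyResult:
    """Estimated-vs-actual correlation after outlier exclusion."""

    correlation: CorrelationResult
    measure: str
    n_excluded: int


def estimation_accuracy(records: Sequence[EstimationRecord],
                        measure: Literal["mean", "sd"],
                        exclusion_threshold: float = OUTLIER_ESTIMATED_MEAN
                        ) -> AccuracyResult:
    """Pearson r between estimated and actual quartet mean or SD.

    Records whose *estimated mean* is at or above the threshold are
    excluded first (extreme-outlier rule), whatever the measure.
    """
    if measure not in ("mean", "sd"):
        raise ValueError(f"measure must be 'mean' or 'sd', got {measure!r}")
    flagged = apply_exclusion_rule(records, threshold=exclusion_threshold)
    kept = [r for r in flagged if not r.excluded]
    n_excluded = len(flagged) - len(kept)
    if len(kept) < 3:
        raise ValueError(f"only {len(kept)} record(s) survive exclusion; need >= 3")
    if measure == "mean":
        est = [r.estimated_mean for r in kept]
        act = [r.actual_mean for r in kept]
    else:
        est = [r.estimated_sd for r in kept]
        act = [r.actual_sd for r in kept]
    return AccuracyResult(correlation=pearson(est, act), measure=measure,
                          n_excluded=n_excluded)


@dataclass(frozen=True)
class NumberSetReport:
    """Actual per-set statistics and accuracy correlations by set size."""

    actuals: pd.DataFrame                      # set_id, set_size, mean, sd
    accuracy_by_size: dict[int, dict[str, CorrelationResult]]


def number_set_stats(sets: Sequence[NumberSet],
                     estimates: Sequence[EstimationRecord] | None = None
                     ) -> NumberSetReport:
    """Actual mean/SD per number set; if estimates are supplied, Pearson
    accuracy correlations stratified by set size (2, 4 and 8 in the
    standard design)."""
    actuals = pd.DataFrame([{"set_id": s.set_id, "set_size": s.set_size,
                             "mean": s.mean, "sd": s.sd} for s in sets])
    size_of = {s.set_id: s.set_size for s in sets}
    accuracy: dict[int, dict[str, CorrelationResult]] = {}
    if estimates:
        recs = [r for r in estimates if r.target_kind == "number_set"]
        for size in sorted({s.set_size for s in sets}):
            grp = [r for r in recs if size_of.get(r.target_id) == size]
            if len(grp) < 3:
                continue
            accuracy[size] = {
                "mean": pearson([r.estimated_mean for r in grp],
                                [r.actual_mean for r in grp]),
                "sd": pearson([r.estimated_sd for r in grp],
                              [r.actual_sd for r in grp]),
            }
    return NumberSetReport(actuals=actuals, accuracy_by_size=accuracy)
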