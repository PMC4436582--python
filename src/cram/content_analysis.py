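"""Content summaries, temporal weighting, feature profiles and effect sizes.

*Total content* is the summed element count over the eight features of a
scored memory.  Because the scoring design deliberately over-samples rare
lifespan bins (to maximize lifespan coverage), aggregate content measures
that span life periods must be re-weighted by the applicable retrieval
distribution: the temporally weighted mean is ``sum_b p_b * m_b`` over bins
holding scored memories, with the retrieval weights renormalized over those
bins.

Effect sizes use Cohen's d with the root-mean-square pooled standard
deviation ``sqrt((s1^2 + s2^2)/2)`` by default; sample SDs use the n-1
denominator throughout.

The subject-level replication path restricts the analysis to subjects with
at least five scored memories, weights each subject's mean content by that
subject's own dated temporal distribution, and restricts Recent/Remote
comparisons to subjects with at least one scored memory in each period.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_model import (
    FEATURES,
    RECENT,
    REMOTE,
    ConfigError,
    InsufficientDataError,
    UndefinedResultError,
    age_group_label,
    assign_age_group,
)
from .temporal_analysis import TemporalDistribution, retrieval_distribution

__all__ = [
    "ContentSummary",
    "group_summary",
    "weighted_mean_content",
    "feature_profile",
    "feature_contribution",
    "cohens_d",
    "percent_change",
    "feature_correlations",
    "per_bin_scored_means",
    "group_weighted_mean",
    "subject_level_pipeline",
    "compare_event_age_windows",
    "period_summaries",
]


@dataclass(frozen=True)
class ContentSummary:
    """Descriptive statistics of total content for one group x life period."""

    grouping: str
    period: str
    n: int
    mean: float
    sd: float
    cv: float
    median: float
    iqr: float

    def to_dict(self) -> dict:
        return {
            "group": self.grouping,
            "period": self.period,
            "n": self.n,
            "mean": self.mean,
            "sd": self.sd,
            "cv": self.cv,
            "median": self.median,
            "iqr": self.iqr,
        }


def group_summary(
    totals: Iterable[float],
    grouping: str = "",
    period: str = "all",
    quantile_method: str = "linear",
) -> ContentSummary:
    """Mean/SD/CV/median/IQR of total content for a set of scored memories."""
    arr = np.asarray([t for t in totals if not pd.isna(t)], dtype=float)
    if arr.size == 0:
        raise InsufficientDataError("no scored memories to summarize")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    cv = sd / mean if mean > 0 else np.nan
    q25, q50, q75 = np.quantile(arr, [0.25, 0.5, 0.75], method=quantile_method)
    return ContentSummary(
        grouping=grouping,
        period=period,
        n=int(arr.size),
        mean=mean,
        sd=sd,
        cv=float(cv),
        median=float(q50),
        iqr=float(q75 - q25),
    )


def weighted_mean_content(
    per_bin_means: Sequence[float],
    dist: TemporalDistribution | Sequence[float],
) -> float:
    """Temporally weighted mean content: ``sum_b p_b * m_b``.

    ``per_bin_means`` may contain NaN for bins without scored memories; the
    retrieval weights are renormalized over the bins that do have a mean and
    positive weight.
    """
    means = np.asarray(per_bin_means, dtype=float)
    p = (
        dist.probabilities
        if isinstance(dist, TemporalDistribution)
        else np.asarray(dist, dtype=float)
    )
    if means.shape != p.shape:
        raise ConfigError(
            f"bin support mismatch: {means.shape} means vs {p.shape} weights"
        )
    usable = ~np.isnan(means) & (p > 0)
    if not usable.any():
        raise InsufficientDataError(
            "no bin has both a scored mean and positive retrieval weight"
        )
    w = p[usable] / p[usable].sum()
    return float(np.sum(w * means[usable]))


def feature_profile(memories: pd.DataFrame) -> pd.DataFrame:
    """Per-feature mean elements, share of summed content, presence proportion.

    ``memories`` must hold scored rows with the 8 feature columns.  Shares
    sum to 1; presence is the fraction of memories with >= 1 element of the
    feature.
    """
    scored = memories.loc[memories["scored"].astype(bool)] if "scored" in memories else memories
    if scored.empty:
        raise InsufficientDataError("no scored memories")
    feats = scored[list(FEATURES)].astype(float)
    means = feats.mean(axis=0)
    total = means.sum()
    if total <= 0:
        raise UndefinedResultError("all feature means are zero; shares undefined")
    return pd.DataFrame(
        {
            "mean": means,
            "share": means / total,
            "presence": (feats >= 1).mean(axis=0),
        }
    )


def feature_contribution(
    means_a: Mapping[str, float] | pd.Series,
    means_b: Mapping[str, float] | pd.Series,
) -> pd.Series:
    """Per-feature share of the total mean difference between two groups.

    ``(mean_b[f] - mean_a[f]) / (total_b - total_a)``; the shares sum to 1.
    Raises :class:`UndefinedResultError` when the total difference is zero.
    """
    a = pd.Series({f: float(means_a[f]) for f in FEATURES})
    b = pd.Series({f: float(means_b[f]) for f in FEATURES})
    diff = b - a
    total = diff.sum()
    if total == 0:
        raise UndefinedResultError("zero total mean difference between groups")
    return diff / total


def cohens_d(
    mean1: float,
    sd1: float,
    mean2: float,
    sd2: float,
    pooling: str = "rms",
    n1: int | None = None,
    n2: int | None = None,
) -> float:
    """Cohen's d effect size ``|mean2 - mean1| / s_pooled``.

    ``pooling='rms'`` (default) uses the unweighted root-mean-square pooled
    SD ``sqrt((sd1^2 + sd2^2)/2)``; ``pooling='n_weighted'`` uses the
    classical (n-weighted) pooled SD and requires both sample sizes.
    """
    if sd1 < 0 or sd2 < 0:
        raise ConfigError("standard deviations must be nonnegative")
    if pooling == "rms":
        pooled = np.sqrt((sd1**2 + sd2**2) / 2.0)
    elif pooling == "n_weighted":
        if n1 is None or n2 is None or n1 < 2 or n2 < 2:
            raise ConfigError("n_weighted pooling requires n1, n2 >= 2")
        pooled = np.sqrt(
            ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
        )
    else:
        raise ConfigError(f"unknown pooling {pooling!r}")
    if pooled == 0:
        if mean1 == mean2:
            return 0.0
        raise UndefinedResultError("zero pooled SD with unequal means")
    return float(abs(mean2 - mean1) / pooled)


def percent_change(reference_mean: float, comparison_mean: float) -> float:
    """Percent change of ``comparison`` relative to ``reference`` (in %)."""
    if reference_mean == 0:
        raise UndefinedResultError("reference mean is zero")
    return float(100.0 * (comparison_mean - reference_mean) / reference_mean)


def feature_correlations(
    memories: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series]:
    """Pearson correlations across scored memories, plus rest-correlations.

    Returns the 8x8 feature correlation matrix and, per feature, the
    correlation between that feature and the sum of all other content
    (``corr(x_f, total - x_f)``).  Zero-variance features yield NaN entries.
    """
    scored = memories.loc[memories["scored"].astype(bool)] if "scored" in memories else memories
    if len(scored) < 3:
        raise InsufficientDataError("need >= 3 scored memories for correlations")
    feats = scored[list(FEATURES)].astype(float)
    corr = feats.corr()
    total = feats.sum(axis=1)
    rest = pd.Series(
        {f: feats[f].corr(total - feats[f]) for f in FEATURES}, name="rest_correlation"
    )
    return corr, rest


# ---------------------------------------------------------------------------
# Group-level weighted analysis on dating tables
# ---------------------------------------------------------------------------


def per_bin_scored_means(
    dated: pd.DataFrame, n_bins: int = 10, column: str = "total_content"
) -> np.ndarray:
    """Mean of ``column`` among scored memories in each lifespan bin.

    A k-bin memory contributes to each of its bins with weight 1/k, matching
    the fractional weighting of retrieval distributions.  Bins without
    scored memories get NaN.
    """
    scored = dated.loc[dated["scored"].astype(bool)]
    sums = np.zeros(n_bins)
    weights = np.zeros(n_bins)
    for bins, value in zip(scored["bins"], scored[column]):
        if pd.isna(value):
            continue
        w = 1.0 / len(bins)
        for b in bins:
            sums[b - 1] += w * value
            weights[b - 1] += w
    with np.errstate(invalid="ignore"):
        means = np.where(weights > 0, sums / np.maximum(weights, 1e-300), np.nan)
    return means


def group_weighted_mean(
    dated: pd.DataFrame, n_bins: int = 10, column: str = "total_content"
) -> float:
    """Temporally weighted mean content of one group's dating table.

    Combines the group's pooled retrieval distribution (all dated memories)
    with the per-bin means of its scored memories.
    """
    dist = retrieval_distribution(dated, n_bins=n_bins)
    means = per_bin_scored_means(dated, n_bins=n_bins, column=column)
    return weighted_mean_content(means, dist)


def period_summaries(
    dated: pd.DataFrame,
    groups: Sequence[tuple[int, int]],
    quantile_method: str = "linear",
) -> pd.DataFrame:
    """Table-shaped summary: total-content statistics per group x period."""
    label = assign_age_group(dated, groups)
    rows = []
    for lo, hi in groups:
        g = age_group_label(lo, hi)
        for period in (REMOTE, RECENT, "all"):
            sub = dated.loc[
                (label == g)
                & dated["scored"].astype(bool)
                & ((dated["recency"] == period) if period != "all" else True)
            ]
            if sub.empty:
                continue
            rows.append(
                group_summary(
                    sub["total_content"],
                    grouping=g,
                    period=period,
                    quantile_method=quantile_method,
                ).to_dict()
            )
    return pd.DataFrame(rows)


def compare_event_age_windows(
    dated: pd.DataFrame,
    window_a: tuple[float, float],
    window_b: tuple[float, float],
) -> dict:
    """Compare mean total content between two event-age windows.

    Windows are half-open ``[lo, hi)`` in event-age years; each scored
    memory is assigned by its midpoint event age.  Returns the two group
    summaries and Cohen's d.  Used e.g. to contrast reminiscence-bump
    (ages 11-20) with post-bump (ages 31-40) memories.
    """
    scored = dated.loc[dated["scored"].astype(bool)]

    def window(sel: tuple[float, float]) -> pd.Series:
        lo, hi = sel
        return scored.loc[
            (scored["event_age"] >= lo) & (scored["event_age"] < hi),
            "total_content",
        ]

    ta, tb = window(window_a), window(window_b)
    if ta.empty or tb.empty:
        raise InsufficientDataError("a window contains no scored memories")
    sa = group_summary(ta, grouping=f"{window_a[0]}-{window_a[1]}")
    sb = group_summary(tb, grouping=f"{window_b[0]}-{window_b[1]}")
    return {
        "window_a": sa,
        "window_b": sb,
        "d": cohens_d(sa.mean, sa.sd, sb.mean, sb.sd),
    }


# ---------------------------------------------------------------------------
# Subject-level replication path
# ---------------------------------------------------------------------------


def subject_level_pipeline(
    dated: pd.DataFrame,
    min_scored: int = 5,
    n_bins: int = 10,
) -> pd.DataFrame:
    """Per-subject temporally weighted content summaries.

    Keeps subjects with >= ``min_scored`` scored memories.  Each subject's
    mean content is weighted by that subject's own dated temporal
    distribution.  Recent/Remote means are reported per subject, with
    ``period_eligible`` True only when the subject has >= 1 scored memory in
    each period (the inclusion rule for Recent-vs-Remote comparisons).
    """
    rows = []
    for sid, sub in dated.groupby("subject_id", sort=False):
        scored = sub.loc[sub["scored"].astype(bool)]
        if len(scored) < min_scored:
            continue
        wmean = group_weighted_mean(sub, n_bins=n_bins)
        recent = scored.loc[scored["recency"] == RECENT, "total_content"]
        remote = scored.loc[scored["recency"] == REMOTE, "total_content"]
        rows.append(
            {
                "subject_id": sid,
                "age_years": int(sub["age_years"].iloc[0]),
                "n_scored": int(len(scored)),
                "n_dated": int(len(sub)),
                "weighted_mean": wmean,
                "simple_mean": float(scored["total_content"].mean()),
                "recent_mean": float(recent.mean()) if len(recent) else np.nan,
                "remote_mean": float(remote.mean()) if len(remote) else np.nan,
                "period_eligible": bool(len(recent) and len(remote)),
            }
        )
    if not rows:
        raise InsufficientDataError(
            f"no subject has >= {min_scored} scored memories"
        )
    return pd.DataFrame(rows)
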