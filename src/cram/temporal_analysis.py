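"""Lifespan retrieval distributions and the reminiscence-bump clarity ratio.

The retrieval probability of a temporal bin is the number of dated memories
falling in that bin divided by the total number of dated memories.  A memory
assigned to k bins contributes fractional weight 1/k to each, so every dated
memory carries total weight 1.

Event-age distributions aggregate memories across subjects by the midpoint
event-age estimate, on a fixed grid of event-age intervals; this accepts
that bin width grows with subject age (no deconvolution is attempted).

The *bump clarity* ratio quantifies how clearly the reminiscence bump (the
elevated retrieval of adolescent/early-adult events seen in older adults)
stands out: the peak retrieval probability outside the retention interval,
divided by the minimum retrieval probability over later non-retention bins.
It is undefined (None) when no later non-retention bin exists or when that
minimum is zero, which is the expected outcome in the youngest adults whose
distributions decay monotonically into the retention interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_model import (
    RECENT,
    ConfigError,
    InsufficientDataError,
    age_group_label,
    assign_age_group,
    bin_scheme,
)

__all__ = [
    "TemporalDistribution",
    "EventAgeDistribution",
    "retrieval_distribution",
    "recent_share",
    "recent_remote_split",
    "event_age_distribution",
    "bump_clarity",
    "retention_bins",
]


@dataclass(frozen=True)
class TemporalDistribution:
    """Per-bin retrieval probabilities for a group of dated memories."""

    probabilities: np.ndarray
    n_dated: float
    grouping: str = ""

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "probabilities", p)
        if np.any(p < 0):
            raise ConfigError("probabilities must be nonnegative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ConfigError(f"probabilities must sum to 1, got {p.sum()!r}")

    @property
    def n_bins(self) -> int:
        return len(self.probabilities)


@dataclass(frozen=True)
class EventAgeDistribution:
    """Probabilities over contiguous event-age intervals ``[edges[i], edges[i+1])``."""

    edges: np.ndarray
    probabilities: np.ndarray
    grouping: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "edges", np.asarray(self.edges, dtype=float))
        p = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "probabilities", p)
        if abs(p.sum() - 1.0) > 1e-9:
            raise ConfigError("probabilities must sum to 1")

    def peak_interval(self) -> tuple[float, float]:
        i = int(np.argmax(self.probabilities))
        return (float(self.edges[i]), float(self.edges[i + 1]))


def _bin_weights(bins_column: Iterable, n_bins: int) -> np.ndarray:
    """Fractional per-bin weights: a k-bin memory adds 1/k to each of its bins."""
    weights = np.zeros(n_bins, dtype=float)
    for bins in bins_column:
        w = 1.0 / len(bins)
        for b in bins:
            if not 1 <= b <= n_bins:
                raise ConfigError(f"bin index {b} outside 1..{n_bins}")
            weights[b - 1] += w
    return weights


def retrieval_distribution(
    memories: pd.DataFrame | Iterable[Sequence[int]],
    n_bins: int = 10,
    grouping: str = "",
    mode: str = "pooled",
) -> TemporalDistribution:
    """Retrieval probability per lifespan bin for a set of dated memories.

    ``memories`` is either a dating table with a ``bins`` column or an
    iterable of bin-index collections.  ``mode='pooled'`` gives every memory
    weight 1 (the default for group-level distributions); ``mode='subject_mean'``
    averages each subject's own distribution with equal subject weight and
    requires a DataFrame with a ``subject_id`` column.
    """
    if isinstance(memories, pd.DataFrame):
        if memories.empty:
            raise InsufficientDataError("no dated memories")
        if mode == "subject_mean":
            per_subject = [
                retrieval_distribution(g, n_bins=n_bins).probabilities
                for _, g in memories.groupby("subject_id", sort=False)
            ]
            p = np.mean(per_subject, axis=0)
            p = p / p.sum()
            return TemporalDistribution(p, n_dated=float(len(memories)), grouping=grouping)
        bins_column = memories["bins"].tolist()
    else:
        bins_column = list(memories)
        if not bins_column:
            raise InsufficientDataError("no dated memories")
    if mode not in ("pooled", "subject_mean"):
        raise ConfigError(f"unknown mode {mode!r}")
    weights = _bin_weights(bins_column, n_bins)
    total = weights.sum()
    return TemporalDistribution(weights / total, n_dated=float(total), grouping=grouping)


def recent_share(n_recent: float, n_remote: float) -> float:
    """Fraction of dated memories that are Recent, from period counts."""
    total = n_recent + n_remote
    if total <= 0:
        raise InsufficientDataError("no dated memories")
    return n_recent / total


def recent_remote_split(
    dated: pd.DataFrame,
    groups: Sequence[tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Recent/Remote counts and shares per age group.

    ``dated`` is a dating table (see :func:`cram.core_model.date_memories`);
    its ``recency`` column already encodes the cutoff used.  With
    ``groups=None`` a single row covering all memories is returned.
    """
    df = dated
    if groups is None:
        label = pd.Series("all", index=df.index)
    else:
        label = assign_age_group(df, groups)
    rows = []
    for group in (["all"] if groups is None else [age_group_label(*g) for g in groups]):
        sub = df.loc[label == group]
        n_recent = int((sub["recency"] == RECENT).sum())
        n_remote = int(len(sub) - n_recent)
        share = recent_share(n_recent, n_remote) if len(sub) else np.nan
        rows.append(
            {
                "group": group,
                "n_recent": n_recent,
                "n_remote": n_remote,
                "recent_share": share,
            }
        )
    return pd.DataFrame(rows)


def event_age_distribution(
    dated: pd.DataFrame,
    interval_width: float = 2.0,
    grouping: str = "",
    max_age: float | None = None,
) -> EventAgeDistribution:
    """Distribution of midpoint event ages over fixed-width intervals."""
    if interval_width <= 0:
        raise ConfigError("interval_width must be positive")
    if dated.empty:
        raise InsufficientDataError("no dated memories")
    ages = dated["event_age"].to_numpy(dtype=float)
    top = max_age if max_age is not None else float(ages.max())
    n_intervals = max(1, int(np.ceil(top / interval_width - 1e-9)))
    edges = np.arange(n_intervals + 1, dtype=float) * interval_width
    counts, _ = np.histogram(ages, bins=edges)
    # events exactly at the top edge belong to the last interval
    counts[-1] += int((ages == edges[-1]).sum())
    p = counts / counts.sum()
    return EventAgeDistribution(edges, p, grouping=grouping)


def retention_bins(
    subject_age: float, cutoff: float = 10.0, n_bins: int = 10
) -> frozenset[int]:
    """Bins whose span lies wholly or partly within the last ``cutoff`` years.

    This is the default retention interval used by :func:`bump_clarity`;
    for a group, call with a representative (e.g. mean) subject age.
    """
    return frozenset(bin_scheme(subject_age, n_bins).recent_bins(cutoff))


def bump_clarity(
    dist: TemporalDistribution, retention: Iterable[int]
) -> float | None:
    """Peak-to-subsequent-minimum retrieval ratio outside the retention bins.

    The peak is the maximum retrieval probability over non-retention bins.
    The subsequent minimum is the smallest probability among non-retention
    bins strictly later than the peak that form a *local* minimum of the
    whole 10-bin sequence (no larger than either neighbor).  Returns None
    (undefined) when no later non-retention bin exists, when no such bin is
    a local minimum (the distribution decays monotonically into the
    retention interval — the typical picture in the youngest adults, whose
    curves lack a trough), or when the minimum is zero.  Whenever defined
    the ratio is >= 1.
    """
    retention_set = {int(b) for b in retention}
    if not retention_set <= set(range(1, dist.n_bins + 1)):
        raise ConfigError(f"retention bins outside 1..{dist.n_bins}")
    interior = [b for b in range(1, dist.n_bins + 1) if b not in retention_set]
    if not interior:
        return None
    p = dist.probabilities
    peak_bin = max(interior, key=lambda b: p[b - 1])
    later = [b for b in interior if b > peak_bin]
    if not later:
        return None
    troughs = [
        b
        for b in later
        if p[b - 1] <= p[b - 2]
        and (b == dist.n_bins or p[b - 1] <= p[b])
    ]
    if not troughs:
        return None
    trough = min(p[b - 1] for b in troughs)
    if trough <= 0:
        return None
    return float(p[peak_bin - 1] / trough)
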