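"""Content-retrieval maps: where in the lifespan does retrieved detail come from?

Combining a group's per-bin mean content ``m_{g,b}`` with its retrieval
probabilities ``p_{g,b}`` gives the raw product ``m_{g,b} * p_{g,b}``: the
expected amount of detail a typical retrieval event contributes from bin
``b``.  Normalizing within a group yields the probability that a retrieved
element of that group's recall stems from each life period; normalizing
across all groups (with group weights summing to 1, equal by default —
encoding the assumption that recollection frequency is stable across age
groups) yields a global content-retrieval probability per (age group, life
period) cell.

Because lifespan bins of different groups span different event-age ranges,
window queries (e.g. "content a 60 year old retrieves from their 20s") use
proportional overlap between the query window and each bin's event-age span.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_model import ConfigError, UndefinedResultError, bin_scheme
from .temporal_analysis import TemporalDistribution

__all__ = ["ContentRetrievalMap", "build_map", "query_map"]


@dataclass(frozen=True)
class ContentRetrievalMap:
    """Age-group x life-period matrix of content-retrieval probabilities.

    ``cells`` columns: group, bin, bin_age_lo, bin_age_hi, mean_content,
    retrieval_p, raw, within_group_p, global_p.  Within-group probabilities
    sum to 1 per group, global probabilities sum to 1 over all cells.
    """

    cells: pd.DataFrame
    group_weights: dict[str, float]

    def __post_init__(self) -> None:
        within = self.cells.groupby("group")["within_group_p"].sum()
        if not np.allclose(within, 1.0, atol=1e-9):
            raise ConfigError("within-group probabilities must sum to 1 per group")
        if abs(self.cells["global_p"].sum() - 1.0) > 1e-9:
            raise ConfigError("global probabilities must sum to 1")

    @property
    def groups(self) -> list[str]:
        return list(self.group_weights)

    def group_cells(self, group: str) -> pd.DataFrame:
        sub = self.cells.loc[self.cells["group"] == group]
        if sub.empty:
            raise ConfigError(f"unknown group {group!r}")
        return sub


def build_map(
    per_group_bin_content: Mapping[str, Sequence[float]],
    per_group_dist: Mapping[str, TemporalDistribution],
    group_ages: Mapping[str, float],
    group_weights: Mapping[str, float] | None = None,
    n_bins: int = 10,
) -> ContentRetrievalMap:
    """Build the content-retrieval map from per-group content and retrieval.

    ``per_group_bin_content[g]`` holds the per-bin mean content of group
    ``g`` (NaN allowed where retrieval probability is zero);
    ``group_ages[g]`` is the representative subject age used to translate
    bins into event-age spans.  Group weights default to equal.
    """
    groups = list(per_group_bin_content)
    if set(groups) != set(per_group_dist) or set(groups) != set(group_ages):
        raise ConfigError("content, distributions and ages must share group keys")
    if group_weights is None:
        weights = {g: 1.0 / len(groups) for g in groups}
    else:
        total_w = float(sum(group_weights[g] for g in groups))
        if total_w <= 0:
            raise ConfigError("group weights must have positive sum")
        weights = {g: float(group_weights[g]) / total_w for g in groups}

    rows = []
    for g in groups:
        m = np.asarray(per_group_bin_content[g], dtype=float)
        dist = per_group_dist[g]
        p = dist.probabilities
        if m.shape != p.shape or len(m) != n_bins:
            raise ConfigError(f"group {g!r}: misaligned bin support")
        raw = np.where(p > 0, np.nan_to_num(m, nan=0.0) * p, 0.0)
        if np.any(raw < 0):
            raise ConfigError(f"group {g!r}: negative content")
        total_raw = raw.sum()
        if total_raw <= 0:
            raise UndefinedResultError(
                f"group {g!r}: all cells are zero; within-group map undefined"
            )
        within = raw / total_raw
        scheme = bin_scheme(group_ages[g], n_bins)
        for b in range(1, n_bins + 1):
            lo, hi = scheme.boundaries[b - 1]
            rows.append(
                {
                    "group": g,
                    "bin": b,
                    "bin_age_lo": lo,
                    "bin_age_hi": hi,
                    "mean_content": m[b - 1],
                    "retrieval_p": p[b - 1],
                    "raw": raw[b - 1],
                    "within_group_p": within[b - 1],
                    "global_p": within[b - 1] * weights[g],
                }
            )
    return ContentRetrievalMap(pd.DataFrame(rows), weights)


def query_map(
    cmap: ContentRetrievalMap,
    group: str,
    window: tuple[float, float],
    normalization: str = "global",
) -> float:
    """Probability mass of one group's cells overlapping an event-age window.

    Each bin contributes proportionally to the fraction of its event-age
    span covered by ``window = (lo, hi)``.  ``normalization`` selects the
    ``global`` (default) or ``within_group`` probabilities.  An empty
    intersection yields 0.
    """
    lo, hi = window
    if hi <= lo:
        raise ConfigError(f"empty window {window!r}")
    if normalization not in ("global", "within_group"):
        raise ConfigError(f"unknown normalization {normalization!r}")
    col = "global_p" if normalization == "global" else "within_group_p"
    cells = cmap.group_cells(group)
    total = 0.0
    for row in cells.itertuples():
        overlap = min(hi, row.bin_age_hi) - max(lo, row.bin_age_lo)
        if overlap <= 0:
            continue
        frac = overlap / (row.bin_age_hi - row.bin_age_lo)
        total += getattr(row, col) * frac
    return float(total)
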