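"""Multi-stage data-quality screening of scored memories.

Self-scored questionnaire data contain careless or inauthentic responses.
Screening proceeds in three ordered stages:

1. **memory-level pattern flags** — a scored memory whose eight feature
   counts are all identical (including all-zero) is flagged as a
   ``uniform_vector``;
2. **subject-level pattern flags** — a subject is flagged (and all of their
   memories excluded) when strictly more than half of their scored memories
   are uniform-vector, or when they scored at least two memories and every
   scored memory carries one identical 8-feature vector;
3. **stratified extreme-content removal** — within each of six age strata
   (18–25, 26–35, 36–45, 46–55, 56–65, 66–78 by default), surviving scored
   memories whose total content exceeds the Tukey-style fence
   ``Q75 + 3·IQR`` (strict inequality) are removed.

Each removed memory carries exactly one reason — the first rule that caught
it.  Removal applies to *content* analyses only: flagged memories are marked
unscored in the clean dataset (counts cleared) and keep contributing to
temporal-distribution analyses, which use dating information only.

The quantile convention (linear interpolation between order statistics by
default) is configurable and recorded in the report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_model import (
    FEATURES,
    ConfigError,
    Dataset,
    InsufficientDataError,
    MemoryRecord,
    age_group_label,
    assign_age_group,
)

__all__ = [
    "DEFAULT_STRATA",
    "UNIFORM_VECTOR",
    "PATTERN_SUBJECT",
    "CONTENT_OUTLIER",
    "ScreeningReport",
    "flag_uniform_memory",
    "uniform_memory_mask",
    "flag_pattern_subjects",
    "outlier_threshold",
    "apply_screening",
]

#: Default age strata for the fence computation (inclusive year ranges).
DEFAULT_STRATA: tuple[tuple[int, int], ...] = (
    (18, 25),
    (26, 35),
    (36, 45),
    (46, 55),
    (56, 65),
    (66, 78),
)

UNIFORM_VECTOR = "uniform_vector"
PATTERN_SUBJECT = "pattern_subject"
CONTENT_OUTLIER = "content_outlier"


def flag_uniform_memory(memory: MemoryRecord | Mapping[str, int] | Sequence[int]) -> bool:
    """True iff all eight feature counts are identical (all-zero included)."""
    if isinstance(memory, MemoryRecord):
        if not memory.scored:
            raise InsufficientDataError("cannot screen an unscored memory")
        counts = [memory.feature_counts[f] for f in FEATURES]
    elif isinstance(memory, Mapping):
        counts = [int(memory[f]) for f in FEATURES]
    else:
        counts = [int(v) for v in memory]
        if len(counts) != len(FEATURES):
            raise ConfigError(f"expected {len(FEATURES)} counts, got {len(counts)}")
    return len(set(counts)) == 1


def uniform_memory_mask(memories: pd.DataFrame) -> pd.Series:
    """Vectorized uniform-vector flag over scored rows of a memories table."""
    feats = memories[list(FEATURES)]
    uniform = feats.nunique(axis=1) == 1
    return uniform & memories["scored"].astype(bool)


def flag_pattern_subjects(
    dataset: Dataset | pd.DataFrame, majority: float = 0.5
) -> set[str]:
    """Subjects whose scoring follows a degenerate pattern.

    A subject is flagged when (a) strictly more than ``majority`` of their
    scored memories are uniform-vector, or (b) they scored >= 2 memories and
    all scored memories share one identical 8-feature vector.  All of a
    flagged subject's memories are excluded from content analyses.
    """
    mem = dataset.memories if isinstance(dataset, Dataset) else dataset
    scored = mem.loc[mem["scored"].astype(bool)]
    if scored.empty:
        return set()
    uniform = uniform_memory_mask(scored)
    flagged: set[str] = set()
    grouped = scored.groupby("subject_id", sort=False)
    n_uniform = uniform.groupby(scored["subject_id"], sort=False).sum()
    n_scored = grouped.size()
    flagged |= set(n_scored.index[n_uniform > majority * n_scored])
    # identical-vector rule: >=2 scored memories, one distinct feature vector
    vectors = scored[list(FEATURES)].apply(tuple, axis=1)
    n_distinct = vectors.groupby(scored["subject_id"], sort=False).nunique()
    flagged |= set(n_scored.index[(n_scored >= 2) & (n_distinct == 1)])
    return flagged


def outlier_threshold(
    values: Iterable[float], multiplier: float = 3.0, method: str = "linear"
) -> float:
    """Tukey-style upper fence ``Q75 + multiplier * IQR``.

    Values *strictly* greater than the fence are outliers.  ``method`` is the
    quantile convention passed to :func:`numpy.quantile` (default linear
    interpolation between order statistics).
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 4:
        raise InsufficientDataError(
            f"need >= 4 values to place an outlier fence, got {arr.size}"
        )
    q25, q75 = np.quantile(arr, [0.25, 0.75], method=method)
    return float(q75 + multiplier * (q75 - q25))


@dataclass
class ScreeningReport:
    """Audit trail of one screening pass."""

    strata: tuple[tuple[int, int], ...]
    quantile_method: str
    multiplier: float
    majority: float
    thresholds: dict[str, float]
    removed_ids: dict[str, list[str]]
    pattern_subject_ids: list[str]
    n_scored_input: int
    n_scored_retained: int

    @property
    def removed_counts(self) -> dict[str, int]:
        return {rule: len(ids) for rule, ids in self.removed_ids.items()}

    @property
    def n_removed(self) -> int:
        return sum(self.removed_counts.values())

    def all_removed_ids(self) -> set[str]:
        return set().union(*self.removed_ids.values()) if self.removed_ids else set()

    def to_dict(self) -> dict:
        return {
            "strata": [list(s) for s in self.strata],
            "quantile_method": self.quantile_method,
            "multiplier": self.multiplier,
            "majority": self.majority,
            "thresholds": self.thresholds,
            "removed_counts": self.removed_counts,
            "removed_ids": {k: sorted(v) for k, v in self.removed_ids.items()},
            "pattern_subject_ids": sorted(self.pattern_subject_ids),
            "n_scored_input": self.n_scored_input,
            "n_scored_retained": self.n_scored_retained,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def apply_screening(
    dataset: Dataset,
    strata: Sequence[tuple[int, int]] = DEFAULT_STRATA,
    multiplier: float = 3.0,
    quantile_method: str = "linear",
    majority: float = 0.5,
) -> tuple[Dataset, ScreeningReport]:
    """Run the three screening stages and return (clean dataset, report).

    The clean dataset keeps every row; flagged memories are marked unscored
    with feature counts cleared, so they still contribute to dating analyses.
    Every subject with scored memories must fall in exactly one stratum.
    """
    mem = dataset.memories
    scored_mask = mem["scored"].astype(bool)
    n_scored_input = int(scored_mask.sum())

    # stage 1: memory-level uniform vectors
    uniform = uniform_memory_mask(mem)

    # stage 2: subject-level patterns, evaluated on the original scored set
    pattern_subjects = flag_pattern_subjects(dataset, majority=majority)
    pattern = scored_mask & mem["subject_id"].isin(pattern_subjects)

    reason = pd.Series(np.full(len(mem), None, dtype=object), index=mem.index)
    reason[pattern] = PATTERN_SUBJECT
    reason[uniform] = UNIFORM_VECTOR  # first-removal reason wins over pattern

    # stage 3: stratified fences on the survivors
    survivors = scored_mask & reason.isna()
    merged_age = mem["subject_id"].map(
        dataset.subjects.set_index("subject_id")["age_years"]
    )
    stratum = assign_age_group(
        pd.DataFrame({"age_years": merged_age}), strata
    )
    bad_age = survivors & stratum.isna()
    if bad_age.any():
        sid = mem.loc[bad_age, "subject_id"].iloc[0]
        raise ConfigError(
            f"subject {sid!r} has age outside all screening strata"
        )

    totals = mem[list(FEATURES)].sum(axis=1)
    thresholds: dict[str, float] = {}
    outlier = pd.Series(False, index=mem.index)
    for lo, hi in strata:
        label = age_group_label(lo, hi)
        in_stratum = survivors & (stratum == label)
        values = totals[in_stratum]
        if len(values) == 0:
            continue
        if len(values) < 4:
            raise InsufficientDataError(
                f"stratum {label}: need >= 4 scored memories to place a fence"
            )
        fence = outlier_threshold(
            values, multiplier=multiplier, method=quantile_method
        )
        thresholds[label] = fence
        outlier |= in_stratum & (totals > fence)
    reason[outlier] = CONTENT_OUTLIER

    removed_ids = {
        UNIFORM_VECTOR: mem.loc[reason == UNIFORM_VECTOR, "memory_id"].tolist(),
        PATTERN_SUBJECT: mem.loc[reason == PATTERN_SUBJECT, "memory_id"].tolist(),
        CONTENT_OUTLIER: mem.loc[reason == CONTENT_OUTLIER, "memory_id"].tolist(),
    }

    clean_mem = mem.copy()
    removed_mask = reason.notna()
    clean_mem.loc[removed_mask, "scored"] = False
    clean_mem.loc[removed_mask, list(FEATURES)] = np.nan
    clean = Dataset(dataset.subjects.copy(), clean_mem)

    report = ScreeningReport(
        strata=tuple(tuple(s) for s in strata),
        quantile_method=quantile_method,
        multiplier=multiplier,
        majority=majority,
        thresholds=thresholds,
        removed_ids=removed_ids,
        pattern_subject_ids=sorted(pattern_subjects),
        n_scored_input=n_scored_input,
        n_scored_retained=int(clean_mem["scored"].astype(bool).sum()),
    )
    return clean, report
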