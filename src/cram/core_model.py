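"""Core domain model for word-cued autobiographical memory (AM) datasets.

The word-cue paradigm elicits autobiographical memories with naturalistic
word cues; each memory is then *dated* by the participant into one of ten
temporal bins that divide their lifespan into equal intervals, and a subset
of memories is *scored* by counting remembered details (elements) within
eight feature categories (Things, Feelings, People, Places, Times, Episodes,
Contexts, Details).

This module provides:

* the lifespan :class:`BinScheme` and midpoint dating arithmetic,
* Recent/Remote classification (an event within the most recent 10 years of
  life is Recent),
* total-content accounting (the summed element count over the 8 features),
* typed records (:class:`SubjectRecord`, :class:`MemoryRecord`) and a
  :class:`Dataset` container wrapping two pandas DataFrames,
* CSV readers/writers for the two tabular interchange formats
  (``subjects.csv`` and ``memories.csv``).

Event ages are real-valued years; bins are half-open ``[lo, hi)`` with the
last bin closed at the subject's age. No calendar handling is performed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FEATURES",
    "GENDERS",
    "TEST_TYPES",
    "CONDITIONS",
    "RECENT",
    "REMOTE",
    "CramError",
    "DataError",
    "ConfigError",
    "InsufficientDataError",
    "UndefinedResultError",
    "BinScheme",
    "SubjectRecord",
    "MemoryRecord",
    "Dataset",
    "bin_scheme",
    "event_age",
    "event_age_years",
    "classify_recency",
    "total_content",
    "date_memories",
    "read_dataset",
    "write_dataset",
    "parse_age_ranges",
    "assign_age_group",
]

#: The eight feature (detail-category) columns, in canonical order.
FEATURES: tuple[str, ...] = (
    "things",
    "feelings",
    "people",
    "places",
    "times",
    "episodes",
    "contexts",
    "details",
)

GENDERS = frozenset({"female", "male", "unspecified"})
TEST_TYPES = frozenset({"in_person", "atomic", "mini", "extended", "full"})
CONDITIONS = frozenset({"in_person", "internet"})

RECENT = "Recent"
REMOTE = "Remote"

SUBJECT_COLUMNS = (
    "subject_id",
    "age_years",
    "gender",
    "native_speaker",
    "test_type",
    "condition",
)
MEMORY_COLUMNS = ("memory_id", "subject_id", "bins", "scored", *FEATURES)


class CramError(Exception):
    """Base class for all package errors."""


class DataError(CramError, ValueError):
    """A record violates the data contract (bad bin index, negative count...)."""


class ConfigError(CramError, ValueError):
    """A configuration value is invalid or inconsistent."""


class InsufficientDataError(CramError, ValueError):
    """An operation was asked to summarize an empty or too-small input."""


class UndefinedResultError(CramError, ArithmeticError):
    """The requested quantity is mathematically undefined for this input."""


# ---------------------------------------------------------------------------
# Lifespan binning and dating
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BinScheme:
    """Equal division of a subject's lifespan ``[0, subject_age)`` into bins.

    Bin ``i`` (1-based) covers ``[subject_age*(i-1)/n, subject_age*i/n)``;
    the last bin is closed at ``subject_age``.  Bin width therefore grows
    linearly with subject age: a 40 year old's bins are twice as wide as a
    20 year old's.
    """

    subject_age: float
    n_bins: int = 10

    def __post_init__(self) -> None:
        if not self.subject_age > 0:
            raise ConfigError(f"subject_age must be positive, got {self.subject_age}")
        if self.n_bins < 1:
            raise ConfigError(f"n_bins must be >= 1, got {self.n_bins}")

    @property
    def width(self) -> float:
        return self.subject_age / self.n_bins

    @property
    def boundaries(self) -> tuple[tuple[float, float], ...]:
        a, n = self.subject_age, self.n_bins
        return tuple((a * i / n, a * (i + 1) / n) for i in range(n))

    def span(self, bins: Iterable[int]) -> tuple[float, float]:
        """Union span ``[lo, hi)`` of a contiguous set of 1-based bin indices."""
        idx = sorted(set(int(b) for b in bins))
        if not idx:
            raise DataError("empty bin set")
        if idx[0] < 1 or idx[-1] > self.n_bins:
            raise DataError(f"bin index outside 1..{self.n_bins}: {idx}")
        if idx != list(range(idx[0], idx[-1] + 1)):
            raise DataError(f"multi-bin assignment must be contiguous: {idx}")
        a, n = self.subject_age, self.n_bins
        return (a * (idx[0] - 1) / n, a * idx[-1] / n)

    def midpoint(self, bin_index: int) -> float:
        lo, hi = self.span([bin_index])
        return (lo + hi) / 2.0

    def union_midpoint(self, bins: Iterable[int]) -> float:
        lo, hi = self.span(bins)
        return (lo + hi) / 2.0

    def bin_of(self, event_age: float) -> int:
        """1-based bin containing ``event_age`` (last bin closed at age)."""
        if not 0 <= event_age <= self.subject_age:
            raise DataError(
                f"event_age {event_age} outside [0, {self.subject_age}]"
            )
        return min(self.n_bins, int(event_age / self.width) + 1)

    def recent_bins(self, cutoff: float = 10.0) -> tuple[int, ...]:
        """Bins whose span lies wholly or partly within the last ``cutoff`` years."""
        lo = self.subject_age - cutoff
        return tuple(
            i + 1 for i, (_, hi) in enumerate(self.boundaries) if hi > lo
        )

    def midpoint_recent_bins(self, cutoff: float = 10.0) -> tuple[int, ...]:
        """Bins whose *midpoint* falls within the last ``cutoff`` years.

        This is the set of bins that midpoint dating classifies as Recent.
        """
        return tuple(
            i
            for i in range(1, self.n_bins + 1)
            if self.subject_age - self.midpoint(i) <= cutoff
        )


def bin_scheme(subject_age: float, n_bins: int = 10) -> BinScheme:
    """Build the lifespan bin scheme for a subject of the given age."""
    return BinScheme(float(subject_age), int(n_bins))


def event_age_years(
    bins: Iterable[int], subject_age: float, n_bins: int = 10
) -> float:
    """Midpoint event-age estimate for a (possibly multi-bin) dated memory.

    A single bin dates the event to that bin's midpoint; a contiguous
    multi-bin assignment dates it to the midpoint of the union span.
    """
    return bin_scheme(subject_age, n_bins).union_midpoint(bins)


def classify_recency(
    subject_age: float, event_age: float, cutoff: float = 10.0
) -> str:
    """Classify an event as Recent (within ``cutoff`` years of now) or Remote."""
    if event_age < 0 or event_age > subject_age:
        raise DataError(
            f"event_age {event_age} outside [0, subject_age={subject_age}]"
        )
    return RECENT if subject_age - event_age <= cutoff else REMOTE


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    age_years: int
    gender: str = "unspecified"
    native_speaker: bool = True
    test_type: str = "full"
    condition: str = "internet"

    def __post_init__(self) -> None:
        if self.age_years < 1:
            raise DataError(f"age_years must be >= 1, got {self.age_years}")
        if self.gender not in GENDERS:
            raise DataError(f"unknown gender {self.gender!r}")
        if self.test_type not in TEST_TYPES:
            raise DataError(f"unknown test_type {self.test_type!r}")
        if self.condition not in CONDITIONS:
            raise DataError(f"unknown condition {self.condition!r}")


@dataclass(frozen=True)
class MemoryRecord:
    """One dated, optionally content-scored memory.

    ``feature_counts`` is ``None`` for a dated-but-unscored memory; unscored
    content is always represented as *absent*, never zero, so content
    summaries cannot silently include unscored memories.
    """

    memory_id: str
    subject_id: str
    bins: tuple[int, ...]
    feature_counts: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        bins = tuple(sorted(set(int(b) for b in self.bins)))
        object.__setattr__(self, "bins", bins)
        if not 1 <= len(bins) <= 3:
            raise DataError(
                f"memory {self.memory_id}: between 1 and 3 bins required, got {bins}"
            )
        if bins[0] < 1 or bins[-1] > 10:
            raise DataError(f"memory {self.memory_id}: bin outside 1..10: {bins}")
        if self.feature_counts is not None:
            counts = dict(self.feature_counts)
            if set(counts) != set(FEATURES):
                raise DataError(
                    f"memory {self.memory_id}: features must be exactly {FEATURES}"
                )
            for k, v in counts.items():
                if int(v) < 0:
                    raise DataError(
                        f"memory {self.memory_id}: negative count for {k}"
                    )
            object.__setattr__(
                self, "feature_counts", {k: int(counts[k]) for k in FEATURES}
            )

    @property
    def scored(self) -> bool:
        return self.feature_counts is not None


def event_age(memory: MemoryRecord, subject: SubjectRecord, n_bins: int = 10) -> float:
    """Midpoint event-age estimate (years) for one memory of one subject."""
    return event_age_years(memory.bins, subject.age_years, n_bins)


def total_content(memory: MemoryRecord | Mapping[str, int]) -> int:
    """Summed element count across the 8 features of a scored memory."""
    counts = memory.feature_counts if isinstance(memory, MemoryRecord) else memory
    if counts is None:
        raise InsufficientDataError(
            "total_content is undefined for an unscored memory"
        )
    return int(sum(int(counts[f]) for f in FEATURES))


# ---------------------------------------------------------------------------
# Dataset container
# ---------------------------------------------------------------------------


@dataclass
class Dataset:
    """A subjects table and a memories table.

    ``subjects`` columns: subject_id, age_years, gender, native_speaker,
    test_type, condition.  ``memories`` columns: memory_id, subject_id,
    bins (tuple of ints), scored (bool), and the 8 feature columns (float,
    NaN when unscored).  Extra columns are preserved untouched.
    """

    subjects: pd.DataFrame
    memories: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for col in SUBJECT_COLUMNS:
            if col not in self.subjects.columns:
                raise DataError(f"subjects table missing column {col!r}")
        for col in MEMORY_COLUMNS:
            if col not in self.memories.columns:
                raise DataError(f"memories table missing column {col!r}")
        if self.subjects["subject_id"].duplicated().any():
            dup = self.subjects.loc[
                self.subjects["subject_id"].duplicated(), "subject_id"
            ].iloc[0]
            raise DataError(f"duplicate subject_id {dup!r}")
        if self.memories["memory_id"].duplicated().any():
            dup = self.memories.loc[
                self.memories["memory_id"].duplicated(), "memory_id"
            ].iloc[0]
            raise DataError(f"duplicate memory_id {dup!r}")
        unknown = set(self.memories["subject_id"]) - set(self.subjects["subject_id"])
        if unknown:
            raise DataError(f"memories reference unknown subjects: {sorted(unknown)[:5]}")

    # -- convenience views ---------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_memories(self) -> int:
        return len(self.memories)

    def scored_memories(self) -> pd.DataFrame:
        return self.memories.loc[self.memories["scored"].astype(bool)]

    def dated(self, cutoff: float = 10.0, n_bins: int = 10) -> pd.DataFrame:
        """Per-memory dating table; see :func:`date_memories`."""
        return date_memories(self, cutoff=cutoff, n_bins=n_bins)

    def copy(self) -> "Dataset":
        return Dataset(self.subjects.copy(), self.memories.copy())

    def to_records(self) -> tuple[list[SubjectRecord], list[MemoryRecord]]:
        subs = [
            SubjectRecord(
                subject_id=str(r.subject_id),
                age_years=int(r.age_years),
                gender=str(r.gender),
                native_speaker=bool(r.native_speaker),
                test_type=str(r.test_type),
                condition=str(r.condition),
            )
            for r in self.subjects.itertuples()
        ]
        mems = []
        for r in self.memories.itertuples():
            counts = None
            if bool(r.scored):
                counts = {f: int(getattr(r, f)) for f in FEATURES}
            mems.append(
                MemoryRecord(
                    memory_id=str(r.memory_id),
                    subject_id=str(r.subject_id),
                    bins=tuple(r.bins),
                    feature_counts=counts,
                )
            )
        return subs, mems

    @classmethod
    def from_records(
        cls,
        subjects: Sequence[SubjectRecord],
        memories: Sequence[MemoryRecord],
    ) -> "Dataset":
        sdf = pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in subjects],
                "age_years": [s.age_years for s in subjects],
                "gender": [s.gender for s in subjects],
                "native_speaker": [s.native_speaker for s in subjects],
                "test_type": [s.test_type for s in subjects],
                "condition": [s.condition for s in subjects],
            }
        )
        mdf = pd.DataFrame(
            {
                "memory_id": [m.memory_id for m in memories],
                "subject_id": [m.subject_id for m in memories],
                "bins": [m.bins for m in memories],
                "scored": [m.scored for m in memories],
            }
        )
        for f in FEATURES:
            mdf[f] = [
                float(m.feature_counts[f]) if m.scored else np.nan for m in memories
            ]
        return cls(sdf, mdf)


def date_memories(
    dataset: Dataset, cutoff: float = 10.0, n_bins: int = 10
) -> pd.DataFrame:
    """Build the per-memory dating table used by all downstream analyses.

    Columns: memory_id, subject_id, age_years, test_type, condition, bins,
    n_bins_assigned, bin_lo, bin_hi, event_age (union-span midpoint, years),
    time_from_present, recency (Recent/Remote), scored, the 8 feature
    columns, total_content (NaN when unscored).
    """
    mem = dataset.memories
    sub = dataset.subjects[["subject_id", "age_years", "test_type", "condition"]]
    df = mem.merge(sub, on="subject_id", how="left", validate="many_to_one")

    bins = df["bins"].tolist()
    bin_lo = np.array([b[0] for b in bins], dtype=float)
    bin_hi = np.array([b[-1] for b in bins], dtype=float)
    age = df["age_years"].to_numpy(dtype=float)
    if np.any(bin_lo < 1) or np.any(bin_hi > n_bins):
        bad = df.loc[(bin_lo < 1) | (bin_hi > n_bins), "memory_id"].iloc[0]
        raise DataError(f"memory {bad!r}: bin index outside 1..{n_bins}")

    # union-span midpoint: [age*(lo-1)/n, age*hi/n) -> age*(lo-1+hi)/(2n)
    ev = age * (bin_lo - 1.0 + bin_hi) / (2.0 * n_bins)
    out = df.copy()
    out["n_bins_assigned"] = [len(b) for b in bins]
    out["bin_lo"] = bin_lo.astype(int)
    out["bin_hi"] = bin_hi.astype(int)
    out["event_age"] = ev
    out["time_from_present"] = age - ev
    out["recency"] = np.where(age - ev <= cutoff, RECENT, REMOTE)
    out["total_content"] = out[list(FEATURES)].sum(axis=1, min_count=len(FEATURES))
    out.loc[~out["scored"].astype(bool), "total_content"] = np.nan
    return out


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------


def _parse_bins_cell(cell: str, row_label: str) -> tuple[int, ...]:
    tokens = [t for t in str(cell).split(";") if t.strip() != ""]
    if not tokens:
        raise DataError(f"{row_label}: empty bins cell")
    try:
        idx = tuple(sorted(set(int(t) for t in tokens)))
    except ValueError as exc:
        raise DataError(f"{row_label}: bad bin token in {cell!r}") from exc
    if idx[0] < 1 or idx[-1] > 10:
        raise DataError(f"{row_label}: bin token outside 1..10 in {cell!r}")
    if len(idx) > 3:
        raise DataError(f"{row_label}: more than 3 bins in {cell!r}")
    return idx


def read_dataset(subjects_path: str | Path, memories_path: str | Path) -> Dataset:
    """Read ``subjects.csv`` and ``memories.csv`` into a validated Dataset.

    Parse errors name the offending row.  Unknown columns are preserved.
    """
    sdf = pd.read_csv(subjects_path, dtype={"subject_id": str})
    for col in SUBJECT_COLUMNS:
        if col not in sdf.columns:
            raise DataError(f"{subjects_path}: missing required column {col!r}")
    sdf["age_years"] = sdf["age_years"].astype(int)
    sdf["native_speaker"] = sdf["native_speaker"].astype(int).astype(bool)
    for i, row in enumerate(sdf.itertuples()):
        label = f"{subjects_path} row {i + 2}"
        if row.age_years < 1:
            raise DataError(f"{label}: age_years must be >= 1")
        if row.gender not in GENDERS:
            raise DataError(f"{label}: unknown gender {row.gender!r}")
        if row.test_type not in TEST_TYPES:
            raise DataError(f"{label}: unknown test_type {row.test_type!r}")
        if row.condition not in CONDITIONS:
            raise DataError(f"{label}: unknown condition {row.condition!r}")

    mdf = pd.read_csv(memories_path, dtype={"memory_id": str, "subject_id": str})
    for col in ("memory_id", "subject_id", "bins", "scored"):
        if col not in mdf.columns:
            raise DataError(f"{memories_path}: missing required column {col!r}")
    for f in FEATURES:
        if f not in mdf.columns:
            raise DataError(f"{memories_path}: missing required column {f!r}")
        mdf[f] = pd.to_numeric(mdf[f], errors="coerce")
    mdf["scored"] = mdf["scored"].astype(int).astype(bool)

    parsed_bins = []
    for i, row in enumerate(mdf.itertuples()):
        label = f"{memories_path} row {i + 2} (memory {row.memory_id})"
        parsed_bins.append(_parse_bins_cell(row.bins, label))
        if bool(row.scored):
            for f in FEATURES:
                v = getattr(row, f)
                if pd.isna(v):
                    raise DataError(f"{label}: scored memory missing count for {f!r}")
                if v < 0:
                    raise DataError(f"{label}: negative count for {f!r}")
        else:
            for f in FEATURES:
                if not pd.isna(getattr(row, f)):
                    raise DataError(
                        f"{label}: unscored memory carries a count for {f!r}"
                    )
    mdf = mdf.copy()
    mdf["bins"] = parsed_bins
    return Dataset(sdf, mdf)


def write_dataset(
    dataset: Dataset, subjects_path: str | Path, memories_path: str | Path
) -> None:
    """Write a Dataset back to the two CSV files (UTF-8, deterministic order)."""
    extra_s = [c for c in dataset.subjects.columns if c not in SUBJECT_COLUMNS]
    sdf = dataset.subjects[list(SUBJECT_COLUMNS) + extra_s].copy()
    sdf["native_speaker"] = sdf["native_speaker"].astype(int)
    sdf.to_csv(subjects_path, index=False, encoding="utf-8")

    extra_m = [c for c in dataset.memories.columns if c not in MEMORY_COLUMNS]
    mdf = dataset.memories[list(MEMORY_COLUMNS) + extra_m].copy()
    mdf["bins"] = [";".join(str(b) for b in bins) for bins in mdf["bins"]]
    mdf["scored"] = mdf["scored"].astype(int)
    for f in FEATURES:
        mdf[f] = mdf[f].map(lambda v: "" if pd.isna(v) else str(int(v)))
    mdf.to_csv(memories_path, index=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# Age-group helpers
# ---------------------------------------------------------------------------


def parse_age_ranges(spec: str) -> list[tuple[int, int]]:
    """Parse ``"18-25,26-45,46-78"`` into a list of inclusive (lo, hi) pairs."""
    out = []
    for token in spec.split(","):
        token = token.strip()
        if not token:
            continue
        lo, _, hi = token.partition("-")
        try:
            pair = (int(lo), int(hi))
        except ValueError as exc:
            raise ConfigError(f"bad age range {token!r}") from exc
        if pair[0] > pair[1]:
            raise ConfigError(f"bad age range {token!r}")
        out.append(pair)
    if not out:
        raise ConfigError(f"no age ranges in {spec!r}")
    return out


def age_group_label(lo: int, hi: int) -> str:
    return f"{lo}-{hi}"


def assign_age_group(
    df: pd.DataFrame, groups: Sequence[tuple[int, int]], column: str = "age_years"
) -> pd.Series:
    """Label each row with its (inclusive) age-group; NaN when outside all."""
    age = df[column].to_numpy()
    labels = pd.Series(np.full(len(df), None, dtype=object), index=df.index)
    for lo, hi in groups:
        mask = (age >= lo) & (age <= hi)
        labels[mask] = age_group_label(lo, hi)
    return labels
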