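"""Frequency-proportional sampling of word-cue lists.

The word-cue paradigm presents each participant with short lists of words
(seven by default) drawn at random from a large word-frequency corpus, so
that common words are proportionally more likely to appear as cues than rare
ones: a word occurring 474 times in the corpus is ~6.7 times more likely to
be drawn than one occurring 71 times.

A :class:`FrequencyTable` maps words to occurrence counts; cue lists are
sampled with probability proportional to counts, with replacement by default
(a without-replacement flag is available).  The real reference corpus is not
bundled; :func:`synthetic_frequency_table` builds a small Zipf-like stand-in
suitable for tests and demonstrations.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core_model import ConfigError, InsufficientDataError

__all__ = [
    "FrequencyTable",
    "selection_probability",
    "sample_cue_list",
    "synthetic_frequency_table",
]


@dataclass(frozen=True)
class FrequencyTable:
    """An immutable word -> occurrence-count table."""

    words: tuple[str, ...]
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.words) == 0:
            raise ConfigError("frequency table must have at least one entry")
        if len(self.words) != len(self.counts):
            raise ConfigError("words and counts must have equal length")
        if len(set(self.words)) != len(self.words):
            raise ConfigError("duplicate words in frequency table")
        if any(int(c) < 1 for c in self.counts):
            raise ConfigError("all counts must be >= 1")
        object.__setattr__(self, "counts", tuple(int(c) for c in self.counts))

    @property
    def total(self) -> int:
        return int(sum(self.counts))

    @property
    def probabilities(self) -> np.ndarray:
        c = np.asarray(self.counts, dtype=float)
        return c / c.sum()

    def count(self, word: str) -> int:
        try:
            return self.counts[self.words.index(word)]
        except ValueError:
            return 0

    @classmethod
    def from_mapping(cls, mapping: dict[str, int]) -> "FrequencyTable":
        items = list(mapping.items())
        return cls(tuple(w for w, _ in items), tuple(c for _, c in items))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FrequencyTable":
        """Read a two-column TSV (word<TAB>count); ``#`` lines are comments."""
        words: list[str] = []
        counts: list[int] = []
        for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ConfigError(f"{path} line {lineno}: expected 'word<TAB>count'")
            words.append(parts[0])
            try:
                counts.append(int(parts[1]))
            except ValueError as exc:
                raise ConfigError(f"{path} line {lineno}: bad count {parts[1]!r}") from exc
        return cls(tuple(words), tuple(counts))

    def to_tsv(self, path: str | Path) -> None:
        lines = ["# word\tcount"]
        lines += [f"{w}\t{c}" for w, c in zip(self.words, self.counts)]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def selection_probability(table: FrequencyTable, word: str) -> float:
    """Probability that a single cue draw yields ``word`` (0 if absent)."""
    return table.count(word) / table.total


def sample_cue_list(
    table: FrequencyTable,
    list_length: int = 7,
    rng: np.random.Generator | int | None = None,
    replace: bool = True,
) -> list[str]:
    """Draw one ordered cue list, each word with probability ∝ its count.

    With ``replace=False`` the table must contain at least ``list_length``
    distinct words.  A fixed generator (or integer seed) makes the draw
    reproducible.
    """
    if list_length < 1:
        raise ConfigError(f"list_length must be >= 1, got {list_length}")
    if not replace and len(table.words) < list_length:
        raise InsufficientDataError(
            f"need >= {list_length} distinct words to sample without replacement"
        )
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    draw = gen.choice(
        len(table.words), size=list_length, replace=replace, p=table.probabilities
    )
    return [table.words[i] for i in draw]


def synthetic_frequency_table(
    n_words: int = 1200, exponent: float = 1.05, scale: int = 60000
) -> FrequencyTable:
    """Deterministic Zipf-like frequency table used as a corpus stand-in.

    Synthetic: counts follow ``max(1, scale / rank**exponent)`` over
    ``n_words`` generated tokens.  Two real tokens, ``waiting`` (count 474)
    and ``yard`` (count 71), replace the generated tokens whose Zipf counts
    are closest, so worked examples about their 6.7-fold selection-odds ratio
    run against this table.
    """
    if n_words < 10:
        raise ConfigError("n_words must be >= 10")
    ranks = np.arange(1, n_words + 1, dtype=float)
    counts = np.maximum(1, np.round(scale / ranks**exponent)).astype(int)
    words = [f"token{r:05d}" for r in range(1, n_words + 1)]
    for word, count in (("waiting", 474), ("yard", 71)):
        idx = int(np.argmin(np.abs(counts - count)))
        words[idx] = word
        counts[idx] = count
    return FrequencyTable(tuple(words), tuple(int(c) for c in counts))
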