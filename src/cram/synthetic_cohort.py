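"""Synthetic cohort generator with the statistical structure the pipeline assumes.

The generator emulates, with ground truth, the joint structure of a
word-cued autobiographical memory study:

* **subjects** — ages drawn from configurable age-range weights (defaults
  reproduce a cohort with mean age ~34 spanning 18–78), assigned to test
  types that differ in how many memories are cued/dated and scored;
* **temporal structure** — each memory's life period (Recent = within the
  most recent 10 years, by the same bin-midpoint convention the analysis
  uses) is drawn with the age group's configured Recent share; the event
  time within the period follows a truncated mixture of an exponential
  retention component (Recent), and a reminiscence-bump normal over event
  age plus a uniform background (Remote), with zero mass before the
  childhood-amnesia cutoff; ~4% of memories are assigned to 2–3 contiguous
  bins;
* **content structure** — total content per (age group x period) cell
  follows a gamma-mixed Poisson (negative-binomial-like) count model whose
  mean and SD are calibrated to the configured cell moments; the eight
  feature counts share a single multiplicative latent gain (attenuated for
  People, making it the most independent feature) plus independent
  per-feature noise, with the two variance components solved per cell so
  that the total SD and the mean pairwise inter-feature correlation both
  match their configured targets;
* **scoring design** — one memory is scored per represented lifespan bin,
  then remaining slots fill from the least to the most represented bin in
  the whole cohort, so the scored subset deliberately over-represents rare
  bins (what temporal weighting must correct);
* **contaminants** — optional injection of uniform-vector memories, pattern
  subjects, and extreme-content records above the stratum fence, with a
  manifest naming every affected record.

Every generated number is reproducible from ``(config, seed)``.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .core_model import (
    FEATURES,
    RECENT,
    REMOTE,
    ConfigError,
    Dataset,
    age_group_label,
)
from .screening import DEFAULT_STRATA, outlier_threshold, uniform_memory_mask

__all__ = [
    "TemporalGroupParams",
    "ContentCell",
    "ContaminantRates",
    "CohortConfig",
    "GroundTruth",
    "default_config",
    "generate_cohort",
    "inject_contaminants",
    "scoring_selection",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TemporalGroupParams:
    """Temporal mixture for one subject age group."""

    age_lo: int
    age_hi: int
    recent_share: float
    retention_tau: float = 4.0  # years; exp decay of time-from-present
    bump_weight: float = 0.0  # fraction of Remote mass in the bump component
    bump_mean: float = 15.0  # event-age years
    bump_sd: float = 4.0

    @property
    def label(self) -> str:
        return age_group_label(self.age_lo, self.age_hi)


@dataclass(frozen=True)
class ContentCell:
    """Total-content moments for one (age group x life period) cell."""

    mean: float
    sd: float


@dataclass(frozen=True)
class ContaminantRates:
    uniform_memory: float = 0.0
    pattern_subject: float = 0.0
    outlier: float = 0.0


#: Younger-group feature composition (shares of total content).
_COMPOSITION_YOUNGER = {
    "things": 0.145,
    "feelings": 0.125,
    "people": 0.135,
    "places": 0.185,
    "times": 0.105,
    "episodes": 0.075,
    "contexts": 0.100,
    "details": 0.130,
}
#: Older-group composition: Things and Episodes shifted upward, People and
#: Times down, so their mean element counts rise ~30% / stay nearly flat when
#: total content rises ~16%.
_COMPOSITION_OLDER = {
    "things": 0.160,
    "feelings": 0.125,
    "people": 0.120,
    "places": 0.180,
    "times": 0.095,
    "episodes": 0.085,
    "contexts": 0.100,
    "details": 0.135,
}

#: Latent-gain loadings: People attenuated, making it the feature most
#: independent of the rest.
_DEFAULT_LOADINGS = {f: (0.5 if f == "people" else 0.85) for f in FEATURES}


@dataclass(frozen=True)
class CohortConfig:
    """Full generating configuration; defaults encode the study conditions."""

    n_subjects: int = 2000
    age_group_weights: tuple[tuple[int, int, float], ...] = (
        (18, 25, 0.35),
        (26, 35, 0.28),
        (36, 45, 0.15),
        (46, 55, 0.10),
        (56, 65, 0.08),
        (66, 78, 0.04),
    )
    temporal_groups: tuple[TemporalGroupParams, ...] = (
        TemporalGroupParams(18, 25, recent_share=0.77, bump_weight=0.0),
        TemporalGroupParams(26, 45, recent_share=0.42, bump_weight=0.45),
        TemporalGroupParams(46, 78, recent_share=0.19, bump_weight=0.65),
    )
    # (group label, period) -> total-content moments; values are the
    # calibration targets of the emulated study, not measurements.
    content: Mapping[str, Mapping[str, ContentCell]] = field(
        default_factory=lambda: {
            "18-25": {
                REMOTE: ContentCell(19.05, 11.70),
                RECENT: ContentCell(21.04, 12.23),
            },
            "26-45": {
                REMOTE: ContentCell(20.68, 14.83),
                RECENT: ContentCell(22.17, 15.30),
            },
            "46-78": {
                REMOTE: ContentCell(24.23, 16.07),
                RECENT: ContentCell(27.46, 18.02),
            },
        }
    )
    composition: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "18-25": dict(_COMPOSITION_YOUNGER),
            "26-45": dict(_COMPOSITION_YOUNGER),
            "46-78": dict(_COMPOSITION_OLDER),
        }
    )
    loadings: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_LOADINGS)
    )
    target_mean_correlation: float = 0.37
    amnesia_cutoff: float = 3.5  # years; zero memory mass before this age
    recency_cutoff: float = 10.0
    n_bins: int = 10
    multi_bin_prob_recent: float = 0.037
    multi_bin_prob_remote: float = 0.050
    triple_bin_fraction: float = 0.15  # of multi-bin memories
    test_type_weights: Mapping[str, float] = field(
        default_factory=lambda: {
            "in_person": 0.12,
            "atomic": 0.56,
            "mini": 0.10,
            "extended": 0.05,
            "full": 0.17,
        }
    )
    # test type -> (memories dated, memories scored)
    test_design: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "in_person": (28, 10),
            "atomic": (1, 1),
            "mini": (5, 5),
            "extended": (20, 10),
            "full": (20, 10),
        }
    )
    p_female: float = 0.67
    p_native: float = 0.81
    # Within-cell event-age trend of mean content ("temporal decay of
    # content": remote events carry fewer details).  "auto" derives each age
    # group's slope (elements per event-age year) from its own two cell
    # means divided by the gap between the cells' scored-subset mean event
    # ages; "none" disables the trend; a mapping {group label: slope} sets
    # it explicitly.  The intercept is always anchored so each scored cell
    # mean equals its configured target exactly.
    event_age_trend: str | Mapping[str, float] = "auto"
    contaminants: ContaminantRates = field(default_factory=ContaminantRates)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        wsum = sum(w for _, _, w in self.age_group_weights)
        if not math.isclose(wsum, 1.0, abs_tol=1e-6):
            raise ConfigError(f"age group weights must sum to 1, got {wsum}")
        for tg in self.temporal_groups:
            if not 0.0 <= tg.recent_share <= 1.0:
                raise ConfigError(f"recent_share outside [0,1] for {tg.label}")
            if not 0.0 <= tg.bump_weight <= 1.0:
                raise ConfigError(f"bump_weight outside [0,1] for {tg.label}")
            if tg.bump_weight > 0 and tg.bump_mean >= tg.age_hi:
                raise ConfigError(
                    f"{tg.label}: bump mean {tg.bump_mean} beyond subject ages"
                )
        for label, cells in self.content.items():
            for period, cell in cells.items():
                if cell.sd**2 <= cell.mean:
                    raise ConfigError(
                        f"cell {label}/{period}: sd^2 must exceed mean "
                        "(overdispersed count model)"
                    )
        for label, comp in self.composition.items():
            if set(comp) != set(FEATURES):
                raise ConfigError(f"composition {label}: must name the 8 features")
            s = sum(comp.values())
            if not math.isclose(s, 1.0, abs_tol=1e-6):
                raise ConfigError(f"composition {label}: shares sum to {s}, not 1")
        for f, w in self.loadings.items():
            if not 0.0 < w <= 1.0:
                raise ConfigError(f"loading for {f} must be in (0, 1]")
        if isinstance(self.event_age_trend, str):
            if self.event_age_trend not in ("auto", "none"):
                raise ConfigError(
                    f"event_age_trend must be 'auto', 'none' or a mapping, "
                    f"got {self.event_age_trend!r}"
                )
        for rate in (
            self.contaminants.uniform_memory,
            self.contaminants.pattern_subject,
            self.contaminants.outlier,
        ):
            if not 0.0 <= rate <= 1.0:
                raise ConfigError("contaminant rates must be in [0, 1]")
        twsum = sum(self.test_type_weights.values())
        if not math.isclose(twsum, 1.0, abs_tol=1e-6):
            raise ConfigError("test type weights must sum to 1")

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["temporal_groups"] = [asdict(tg) for tg in self.temporal_groups]
        d["content"] = {
            label: {period: asdict(cell) for period, cell in cells.items()}
            for label, cells in self.content.items()
        }
        d["contaminants"] = asdict(self.contaminants)
        d["age_group_weights"] = [list(t) for t in self.age_group_weights]
        d["test_design"] = {k: list(v) for k, v in self.test_design.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        d = dict(d)
        if "temporal_groups" in d:
            d["temporal_groups"] = tuple(
                TemporalGroupParams(**tg) for tg in d["temporal_groups"]
            )
        if "content" in d:
            d["content"] = {
                label: {period: ContentCell(**cell) for period, cell in cells.items()}
                for label, cells in d["content"].items()
            }
        if "contaminants" in d:
            d["contaminants"] = ContaminantRates(**d["contaminants"])
        if "age_group_weights" in d:
            d["age_group_weights"] = tuple(
                tuple(t) for t in d["age_group_weights"]
            )
        if "test_design" in d:
            d["test_design"] = {k: tuple(v) for k, v in d["test_design"].items()}
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=False), encoding="utf-8"
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text(encoding="utf-8")))


def default_config(**overrides) -> CohortConfig:
    """The default study-scale configuration, with optional field overrides."""
    return replace(CohortConfig(), **overrides) if overrides else CohortConfig()


# ---------------------------------------------------------------------------
# Latent variance calibration
# ---------------------------------------------------------------------------


def _solve_latent_variances(
    mu_total: float,
    sd_total: float,
    shares: np.ndarray,
    loadings: np.ndarray,
    target_corr: float,
) -> tuple[float, float]:
    """Solve (shared-gain variance a, per-feature noise variance h).

    Feature f is Poisson with rate ``mu_f * (1 - w_f + w_f*G) * H_f`` where
    ``G ~ Gamma(1/a, a)`` is shared and ``H_f ~ Gamma(1/h, h)`` independent
    (both mean 1).  The two variances are chosen so that Var(total) matches
    ``sd_total**2`` and the mean pairwise Pearson correlation matches
    ``target_corr``:

        Var(X_f) = mu_f + mu_f^2 * (w_f^2 a + h + w_f^2 a h)
        Cov(X_i, X_j) = mu_i mu_j w_i w_j a          (i != j)
        Var(T) = mu_T + a * (sum_f mu_f w_f)^2 + h * sum_f mu_f^2 (1 + a w_f^2)
    """
    mu = mu_total * shares
    w = loadings
    var_t = sd_total**2
    s1 = float(np.sum(mu * w))
    budget = var_t - mu_total
    if budget <= 0:
        raise ConfigError("total variance must exceed the mean (overdispersion)")

    def h_of(a: float) -> float:
        return (budget - a * s1**2) / float(np.sum(mu**2 * (1 + a * w**2)))

    def mean_corr(a: float) -> float:
        h = max(h_of(a), 0.0)
        v = mu + mu**2 * (w**2 * a + h + w**2 * a * h)
        cov = np.outer(mu * w, mu * w) * a
        sd = np.sqrt(v)
        corr = cov / np.outer(sd, sd)
        n = len(mu)
        off = corr[~np.eye(n, dtype=bool)]
        return float(off.mean())

    a_max = budget / s1**2
    reachable = mean_corr(a_max)
    if reachable < target_corr - 0.01:
        raise ConfigError(
            f"target mean correlation {target_corr} unreachable with "
            f"mean {mu_total}, sd {sd_total} (max {reachable:.3f})"
        )
    if reachable <= target_corr:
        # boundary: the pure shared-gain model (no per-feature noise) is the
        # closest admissible point
        return float(a_max), 0.0
    a = brentq(lambda x: mean_corr(x) - target_corr, 1e-12, a_max, xtol=1e-12)
    return float(a), float(max(h_of(a), 0.0))


def _analytic_feature_moments(
    mu_total: float, shares: np.ndarray, loadings: np.ndarray, a: float, h: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact (variances, correlation matrix, rest-correlations) of the model."""
    mu = mu_total * shares
    w = loadings
    v = mu + mu**2 * (w**2 * a + h + w**2 * a * h)
    cov = np.outer(mu * w, mu * w) * a
    np.fill_diagonal(cov, v)
    sd = np.sqrt(v)
    corr = cov / np.outer(sd, sd)
    n = len(mu)
    rest = np.empty(n)
    for i in range(n):
        others = [j for j in range(n) if j != i]
        cov_i_rest = cov[i, others].sum()
        var_rest = cov[np.ix_(others, others)].sum()
        rest[i] = cov_i_rest / np.sqrt(v[i] * var_rest)
    return v, corr, rest


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Everything needed to reproduce and verify a generated cohort."""

    config: CohortConfig
    seed: int
    cells: dict  # (group, period) -> generating parameters
    memory_truth: pd.DataFrame  # per-memory latent values

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "config": self.config.to_dict(),
            "cells": self.cells,
        }


def scoring_selection(
    primary_bins: Sequence[int],
    cohort_bin_counts: Mapping[int, int] | np.ndarray,
    n_to_score: int = 10,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Indices of the memories selected for content scoring.

    One memory per represented lifespan bin first (random within bin), then
    remaining slots fill with memories from the least to the most
    represented bin in the whole cohort, until ``n_to_score`` are selected
    or the subject runs out of memories.
    """
    bins = np.asarray(primary_bins, dtype=int)
    n = len(bins)
    if n_to_score >= n:
        return np.arange(n)
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)

    def rarity(i: int) -> int:
        return int(cohort_bin_counts[bins[i]])

    perm = gen.permutation(n)
    seen: set[int] = set()
    representatives: list[int] = []
    rest: list[int] = []
    for i in perm:
        b = int(bins[i])
        if b not in seen:
            seen.add(b)
            representatives.append(int(i))
        else:
            rest.append(int(i))
    representatives.sort(key=rarity)  # if over budget, keep rarest bins
    selected = representatives[:n_to_score]
    slots = n_to_score - len(selected)
    if slots > 0:
        rest.sort(key=rarity)
        selected += rest[:slots]
    return np.array(sorted(selected), dtype=int)


def _midpoint_recent_first_bin(age: np.ndarray, cutoff: float, n_bins: int) -> np.ndarray:
    """First bin index whose midpoint lies within the last ``cutoff`` years."""
    i0 = np.ceil(n_bins + 0.5 - n_bins * cutoff / age).astype(int)
    return np.clip(i0, 1, n_bins)


def generate_cohort(
    config: CohortConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[Dataset, GroundTruth]:
    """Generate a dataset with the configured statistical structure.

    Returns the dataset (subjects + memories tables) and a
    :class:`GroundTruth` record holding every generating parameter and the
    per-memory latent values (true event age, drawn period, shared gain).
    If the config carries nonzero contaminant rates, contaminants are
    injected and the manifest is stored under ``truth.cells['contaminants']``.
    """
    cfg = config or CohortConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_bins = cfg.n_bins
    cutoff = cfg.recency_cutoff

    # -- subjects ------------------------------------------------------------
    n = cfg.n_subjects
    gw = np.array([w for _, _, w in cfg.age_group_weights], dtype=float)
    g_idx = rng.choice(len(gw), size=n, p=gw / gw.sum())
    lo = np.array([lo for lo, _, _ in cfg.age_group_weights])
    hi = np.array([hi for _, hi, _ in cfg.age_group_weights])
    ages = rng.integers(lo[g_idx], hi[g_idx] + 1)

    types = list(cfg.test_type_weights)
    tw = np.array([cfg.test_type_weights[t] for t in types], dtype=float)
    t_idx = rng.choice(len(types), size=n, p=tw / tw.sum())
    test_type = np.array(types, dtype=object)[t_idx]
    condition = np.where(test_type == "in_person", "in_person", "internet")
    gender = np.where(
        rng.random(n) < cfg.p_female, "female", "male"
    )
    native = rng.random(n) < cfg.p_native
    subject_ids = np.array([f"S{i + 1:06d}" for i in range(n)], dtype=object)

    subjects = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "age_years": ages.astype(int),
            "gender": gender,
            "native_speaker": native,
            "test_type": test_type,
            "condition": condition,
        }
    )

    # -- memory skeleton -----------------------------------------------------
    n_dated = np.array([cfg.test_design[t][0] for t in test_type], dtype=int)
    n_to_score = np.array([cfg.test_design[t][1] for t in test_type], dtype=int)
    subj_of_mem = np.repeat(np.arange(n), n_dated)
    m = len(subj_of_mem)
    mem_age = ages[subj_of_mem].astype(float)

    # temporal group per memory
    tg_lo = np.array([tg.age_lo for tg in cfg.temporal_groups])
    tg_hi = np.array([tg.age_hi for tg in cfg.temporal_groups])
    tg_idx = np.full(m, -1, dtype=int)
    for k in range(len(cfg.temporal_groups)):
        tg_idx[(mem_age >= tg_lo[k]) & (mem_age <= tg_hi[k])] = k
    if np.any(tg_idx < 0):
        raise ConfigError("a subject age falls outside all temporal groups")

    recent_share = np.array([tg.recent_share for tg in cfg.temporal_groups])
    tau = np.array([tg.retention_tau for tg in cfg.temporal_groups])
    bump_w = np.array([tg.bump_weight for tg in cfg.temporal_groups])
    bump_mu = np.array([tg.bump_mean for tg in cfg.temporal_groups])
    bump_sd = np.array([tg.bump_sd for tg in cfg.temporal_groups])

    i0 = _midpoint_recent_first_bin(mem_age, cutoff, n_bins)
    recent_lo_age = mem_age * (i0 - 1) / n_bins  # lower event-age edge of Recent bins
    remote_hi_age = recent_lo_age

    # degenerate Remote window (possible only for very young ages): force Recent
    remote_ok = remote_hi_age > cfg.amnesia_cutoff + 1e-9
    is_recent = (rng.random(m) < recent_share[tg_idx]) | ~remote_ok

    event_age = np.empty(m)
    # Recent: exponential decay of time-from-present, truncated to the Recent span
    r = is_recent
    t_max = mem_age[r] - recent_lo_age[r]
    u = rng.random(r.sum())
    tau_r = tau[tg_idx[r]]
    t = -tau_r * np.log1p(-u * (1.0 - np.exp(-t_max / tau_r)))
    event_age[r] = np.clip(mem_age[r] - t, recent_lo_age[r], mem_age[r])

    # Remote: bump normal + uniform background over [amnesia, remote_hi)
    rm = ~r
    if rm.any():
        n_rm = rm.sum()
        hi_rm = remote_hi_age[rm]
        in_bump = rng.random(n_rm) < bump_w[tg_idx[rm]]
        e_rm = np.empty(n_rm)
        if in_bump.any():
            mu_b = bump_mu[tg_idx[rm]][in_bump]
            sd_b = bump_sd[tg_idx[rm]][in_bump]
            a_std = (cfg.amnesia_cutoff - mu_b) / sd_b
            b_std = (hi_rm[in_bump] - mu_b) / sd_b
            e_rm[in_bump] = truncnorm.rvs(
                a_std, b_std, loc=mu_b, scale=sd_b, random_state=rng
            )
        n_unif = int((~in_bump).sum())
        if n_unif:
            e_rm[~in_bump] = rng.uniform(
                cfg.amnesia_cutoff, hi_rm[~in_bump], size=n_unif
            )
        event_age[rm] = e_rm

    width = mem_age / n_bins
    primary_bin = np.clip((event_age / width).astype(int) + 1, 1, n_bins)

    # multi-bin assignments (contiguous, 2-3 bins)
    p_mb = np.where(is_recent, cfg.multi_bin_prob_recent, cfg.multi_bin_prob_remote)
    is_mb = rng.random(m) < p_mb
    extra = np.where(rng.random(m) < cfg.triple_bin_fraction, 2, 1)
    go_left = rng.random(m) < 0.5
    bins_list: list[tuple[int, ...]] = []
    for j in range(m):
        b = int(primary_bin[j])
        if not is_mb[j]:
            bins_list.append((b,))
            continue
        k = 1 + int(extra[j])
        if go_left[j]:
            start = max(1, b - (k - 1))
        else:
            start = min(b, n_bins - (k - 1))
            start = max(1, start)
        bins_list.append(tuple(range(start, start + k)))

    # -- scoring selection ---------------------------------------------------
    cohort_bin_counts = np.bincount(primary_bin, minlength=n_bins + 1)
    scored = np.zeros(m, dtype=bool)
    offsets = np.concatenate([[0], np.cumsum(n_dated)])
    for s in range(n):
        a, b = offsets[s], offsets[s + 1]
        if a == b:
            continue
        picked = scoring_selection(
            primary_bin[a:b], cohort_bin_counts, int(n_to_score[s]), rng
        )
        scored[a + picked] = True

    # -- content -------------------------------------------------------------
    group_labels = [tg.label for tg in cfg.temporal_groups]
    loadings = np.array([cfg.loadings[f] for f in FEATURES], dtype=float)
    cell_params: dict[str, dict] = {}
    cell_index = tg_idx * 2 + is_recent.astype(int)
    counts = np.full((m, len(FEATURES)), np.nan)
    gains = np.full(m, np.nan)
    # midpoint event age of the assigned bins (the dating the analysis sees)
    bins_lo_arr = np.array([b[0] for b in bins_list], dtype=float)
    bins_hi_arr = np.array([b[-1] for b in bins_list], dtype=float)
    e_mid = mem_age * (bins_lo_arr - 1.0 + bins_hi_arr) / (2.0 * n_bins)

    for k, label in enumerate(group_labels):
        shares = np.array(
            [cfg.composition[label][f] for f in FEATURES], dtype=float
        )
        # scored-subset mean/variance of event age per cell, for the trend
        cell_sel = {
            period: scored & (cell_index == 2 * k + p_i)
            for p_i, period in enumerate((REMOTE, RECENT))
        }
        e_mean = {
            period: float(e_mid[sel].mean()) if sel.any() else np.nan
            for period, sel in cell_sel.items()
        }
        e_var = {
            period: float(e_mid[sel].var()) if sel.any() else 0.0
            for period, sel in cell_sel.items()
        }
        if cfg.event_age_trend == "none":
            slope = 0.0
        elif cfg.event_age_trend == "auto":
            gap = e_mean[RECENT] - e_mean[REMOTE]
            dmu = cfg.content[label][RECENT].mean - cfg.content[label][REMOTE].mean
            slope = dmu / gap if np.isfinite(gap) and abs(gap) > 1e-9 else 0.0
        else:
            slope = float(cfg.event_age_trend[label])

        for period in (REMOTE, RECENT):
            cell = cfg.content[label][period]
            sel = cell_sel[period]
            # remove the variance the event-age trend adds so the cell's
            # total-content SD still matches its target
            sd_eff = math.sqrt(
                max(cell.sd**2 - slope**2 * e_var[period], cell.mean * 1.21)
            )
            a_var, h_var = _solve_latent_variances(
                cell.mean, sd_eff, shares, loadings, cfg.target_mean_correlation
            )
            cell_params[f"{label}/{period}"] = {
                "mean": cell.mean,
                "sd": cell.sd,
                "sd_latent": sd_eff,
                "event_age_slope": slope,
                "scored_mean_event_age": e_mean[period],
                "shared_gain_var": a_var,
                "feature_noise_var": h_var,
            }
            n_sel = int(sel.sum())
            if n_sel == 0:
                continue
            # per-memory mean: cell target plus the event-age trend, anchored
            # at the scored-subset mean event age so the cell mean is exact
            mu_mem = cell.mean + slope * (e_mid[sel] - e_mean[period])
            mu_mem = np.maximum(mu_mem, 1.0)
            g = rng.gamma(shape=1.0 / a_var, scale=a_var, size=n_sel)
            if h_var > 1e-12:
                noise = rng.gamma(
                    shape=1.0 / h_var, scale=h_var, size=(n_sel, len(FEATURES))
                )
            else:
                noise = 1.0
            lam = (
                mu_mem[:, None]
                * shares
                * (1.0 - loadings + loadings * g[:, None])
                * noise
            )
            counts[sel] = rng.poisson(lam)
            gains[sel] = g

    memory_ids = np.array([f"M{i + 1:07d}" for i in range(m)], dtype=object)
    memories = pd.DataFrame(
        {
            "memory_id": memory_ids,
            "subject_id": subject_ids[subj_of_mem],
            "bins": bins_list,
            "scored": scored,
        }
    )
    for j, f in enumerate(FEATURES):
        memories[f] = counts[:, j]

    dataset = Dataset(subjects, memories)
    truth = GroundTruth(
        config=cfg,
        seed=int(seed) if not isinstance(seed, np.random.Generator) else -1,
        cells=cell_params,
        memory_truth=pd.DataFrame(
            {
                "memory_id": memory_ids,
                "true_event_age": event_age,
                "period": np.where(is_recent, RECENT, REMOTE),
                "gain": gains,
            }
        ),
    )

    rates = cfg.contaminants
    if rates.uniform_memory or rates.pattern_subject or rates.outlier:
        dataset, manifest = inject_contaminants(dataset, rates, rng)
        truth.cells["contaminants"] = manifest
    return dataset, truth


# ---------------------------------------------------------------------------
# Contaminant injection
# ---------------------------------------------------------------------------


def _random_uniform_vector(rng: np.random.Generator) -> np.ndarray:
    return np.full(len(FEATURES), float(rng.integers(0, 9)))


def _random_identical_vector(rng: np.random.Generator) -> np.ndarray:
    vec = rng.integers(0, 7, size=len(FEATURES)).astype(float)
    if len(set(vec.tolist())) == 1:
        vec[0] += 1.0
    return vec


def inject_contaminants(
    dataset: Dataset,
    rates: ContaminantRates,
    seed: int | np.random.Generator = 0,
    strata: Sequence[tuple[int, int]] = DEFAULT_STRATA,
) -> tuple[Dataset, dict]:
    """Inject screening-target contaminants; return (dataset, manifest).

    * ``uniform_memory``: per scored memory (of subjects with >= 3 scored
      memories, at most a minority per subject so the subject itself is not
      flagged), replace the counts with one constant value;
    * ``pattern_subject``: per eligible subject (>= 2 scored), either make a
      strict majority of their scored memories uniform-vector (kind
      ``majority_uniform``) or give every scored memory one identical
      non-uniform vector (kind ``identical_vector``), alternating kinds;
    * ``outlier``: per scored memory of untouched subjects, replace the
      counts with a vector whose total clearly exceeds the current stratum
      fence (Q75 + 3*IQR plus a half-IQR margin).

    The manifest lists every affected record; all injected records are
    recoverable by :func:`cram.screening.apply_screening` applied to a
    previously screened (fence-clean) dataset.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ds = dataset.copy()
    mem = ds.memories
    feats = list(FEATURES)
    scored_mask = mem["scored"].astype(bool)
    ages = mem["subject_id"].map(ds.subjects.set_index("subject_id")["age_years"])

    per_subject = mem.loc[scored_mask].groupby("subject_id", sort=False).indices
    manifest: dict = {
        "uniform_memories": [],
        "pattern_subjects": [],
        "outlier_memories": [],
    }
    touched_subjects: set[str] = set()

    # pattern subjects first (they own all their memories)
    eligible = [sid for sid, idx in per_subject.items() if len(idx) >= 2]
    n_pattern = rng.binomial(len(eligible), rates.pattern_subject) if eligible else 0
    pattern_ids = list(
        rng.choice(np.array(eligible, dtype=object), size=n_pattern, replace=False)
    ) if n_pattern else []
    for j, sid in enumerate(pattern_ids):
        rows = mem.index[scored_mask & (mem["subject_id"] == sid)]
        kind = "majority_uniform" if j % 2 == 0 else "identical_vector"
        if kind == "majority_uniform":
            k = len(rows) // 2 + 1
            chosen = rng.choice(rows, size=k, replace=False)
            for ridx in chosen:
                mem.loc[ridx, feats] = _random_uniform_vector(rng)
        else:
            vec = _random_identical_vector(rng)
            for ridx in rows:
                mem.loc[ridx, feats] = vec
        touched_subjects.add(sid)
        manifest["pattern_subjects"].append(
            {
                "subject_id": str(sid),
                "kind": kind,
                "memory_ids": mem.loc[rows, "memory_id"].tolist(),
            }
        )

    # single uniform memories (subjects keep a non-uniform majority)
    candidates = [
        (sid, idx)
        for sid, idx in per_subject.items()
        if len(idx) >= 3 and sid not in touched_subjects
    ]
    uniform_rows: list[int] = []
    for sid, idx in candidates:
        budget = (len(idx) - 1) // 2  # strictly fewer than half
        if budget < 1:
            continue
        k = rng.binomial(len(idx), rates.uniform_memory)
        k = min(k, budget)
        if k:
            rows = mem.index[scored_mask & (mem["subject_id"] == sid)]
            chosen = rng.choice(rows, size=k, replace=False)
            uniform_rows.extend(int(c) for c in chosen)
            touched_subjects.add(sid)
    for ridx in uniform_rows:
        mem.loc[ridx, feats] = _random_uniform_vector(rng)
    manifest["uniform_memories"] = mem.loc[uniform_rows, "memory_id"].tolist()

    # extreme-content outliers above the current stratum fence
    totals = mem[feats].sum(axis=1)
    out_rows: list[int] = []
    if rates.outlier > 0:
        pool = mem.index[
            scored_mask & ~mem["subject_id"].isin(touched_subjects)
        ]
        n_out = rng.binomial(len(pool), rates.outlier) if len(pool) else 0
        if n_out:
            out_rows = [int(i) for i in rng.choice(pool, size=n_out, replace=False)]
        for lo, hi in strata:
            stratum_rows = [
                ridx for ridx in out_rows if lo <= int(ages.loc[ridx]) <= hi
            ]
            if not stratum_rows:
                continue
            basis = totals[
                scored_mask & (ages >= lo) & (ages <= hi)
            ]
            if len(basis) < 4:
                continue
            fence = outlier_threshold(basis)
            iqr = float(np.subtract(*np.quantile(basis, [0.75, 0.25])))
            for ridx in stratum_rows:
                target = int(round(fence + 0.5 * max(iqr, 1.0) + rng.uniform(10, 40)))
                shares = np.array(
                    [1.0 + rng.random() for _ in feats]
                )
                vec = rng.multinomial(target, shares / shares.sum()).astype(float)
                if len(set(vec.tolist())) == 1:
                    vec[0] += 1.0
                mem.loc[ridx, feats] = vec
    manifest["outlier_memories"] = mem.loc[out_rows, "memory_id"].tolist()

    affected = set(manifest["uniform_memories"]) | set(manifest["outlier_memories"])
    for entry in manifest["pattern_subjects"]:
        affected |= set(entry["memory_ids"])
    manifest["all_memory_ids"] = sorted(affected)
    return Dataset(ds.subjects, mem), manifest
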