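"""End-to-end orchestration: simulate -> screen -> temporal -> content -> map.

One top-level seed drives the whole run; each stage uses an independent
stream derived deterministically as ``numpy.random.default_rng([seed, k])``
with a fixed per-stage index ``k``.  Every run writes a machine-readable
``manifest.json`` recording the package version, a stable hash of the
configuration, the seeds, output paths, per-stage record counts and wall
time, plus a reproduction report that sets the simulated cohort's key
statistics against published reference values from the word-cue aging study
the generator emulates, with explicit tolerances.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .content_analysis import (
    cohens_d,
    feature_contribution,
    feature_profile,
    group_summary,
    group_weighted_mean,
    per_bin_scored_means,
    percent_change,
)
from .content_map import build_map
from .core_model import (
    FEATURES,
    CramError,
    Dataset,
    age_group_label,
    assign_age_group,
    date_memories,
    read_dataset,
    write_dataset,
)
from .screening import DEFAULT_STRATA, apply_screening
from .synthetic_cohort import CohortConfig, generate_cohort
from .temporal_analysis import recent_remote_split, retrieval_distribution

__all__ = [
    "ANALYSIS_GROUPS",
    "REFERENCE_ANCHORS",
    "ReportTolerances",
    "RunManifest",
    "run_pipeline",
    "reproduce_report",
]

#: The coarse analysis grouping: younger (18-45) vs older (46-78) adults.
ANALYSIS_GROUPS: tuple[tuple[int, int], ...] = ((18, 45), (46, 78))

#: The three temporal groups used for retrieval-share anchors.
TEMPORAL_GROUPS: tuple[tuple[int, int], ...] = ((18, 25), (26, 45), (46, 78))

#: Published reference values the reproduction report compares against.
REFERENCE_ANCHORS: dict[str, float] = {
    "recent_share_18-25": 77.0,  # % of dated memories that are Recent
    "recent_share_26-45": 42.0,
    "recent_share_46-78": 19.0,
    "cohens_d_46-55": 0.24,  # vs the 18-25 group, total content
    "cohens_d_56-65": 0.30,
    "cohens_d_66-78": 0.20,
    "percent_increase": 16.0,  # older vs younger weighted mean content, %
}


@dataclass(frozen=True)
class ReportTolerances:
    """All reproduction-report tolerances in one place."""

    recent_share_points: float = 5.0
    cohens_d: float = 0.15
    percent_increase_points: float = 3.0


@dataclass
class RunManifest:
    version: str
    config_hash: str
    seed: int
    stage_seeds: dict
    paths: dict
    counts: dict
    settings: dict
    wall_time_s: float

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2)


def _config_hash(config: CohortConfig) -> str:
    canonical = yaml.safe_dump(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode("utf-8")).hexdigest()


def _stage_rng(seed: int, stage_index: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stage_index)])


_STAGES = {"simulate": 0, "screen": 1, "temporal": 2, "content": 3, "map": 4}


def temporal_tables(
    dated: pd.DataFrame, groups=TEMPORAL_GROUPS, n_bins: int = 10
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(per-bin retrieval table, Recent/Remote split table) per age group."""
    label = assign_age_group(dated, groups)
    rows = []
    for lo, hi in groups:
        g = age_group_label(lo, hi)
        sub = dated.loc[label == g]
        if sub.empty:
            continue
        dist = retrieval_distribution(sub, n_bins=n_bins, grouping=g)
        for b in range(1, n_bins + 1):
            rows.append(
                {
                    "group": g,
                    "bin": b,
                    "probability": dist.probabilities[b - 1],
                    "n": dist.n_dated,
                }
            )
    split = recent_remote_split(dated, groups)
    return pd.DataFrame(rows), split


def content_tables(
    dated: pd.DataFrame,
    analysis_groups=ANALYSIS_GROUPS,
    strata=DEFAULT_STRATA,
    n_bins: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(content summary table, comparison table) for the reproduction report.

    The summary table holds total-content statistics and per-feature means
    per group and life period.  The comparison table holds Cohen's d of each
    age stratum against the youngest, and the temporally weighted
    older-vs-younger percent increase with per-feature contributions.
    """
    summaries = []
    label6 = assign_age_group(dated, strata)
    scored = dated.loc[dated["scored"].astype(bool)]

    def summary_row(sub: pd.DataFrame, group: str, period: str) -> dict:
        row = group_summary(sub["total_content"], group, period).to_dict()
        for f in FEATURES:
            row[f"mean_{f}"] = float(sub[f].mean())
        return row

    for lo, hi in strata:
        g = age_group_label(lo, hi)
        sub = scored.loc[label6.loc[scored.index] == g]
        if sub.empty:
            continue
        summaries.append(summary_row(sub, g, "all"))
    label2 = assign_age_group(dated, analysis_groups)
    for lo, hi in analysis_groups:
        g = age_group_label(lo, hi)
        sub = scored.loc[label2.loc[scored.index] == g]
        if sub.empty:
            continue
        for period in ("all", "Recent", "Remote"):
            part = sub if period == "all" else sub.loc[sub["recency"] == period]
            if part.empty:
                continue
            summaries.append(summary_row(part, g, period))
    summary_df = pd.DataFrame(summaries)

    comparisons = []
    youngest = age_group_label(*strata[0])
    base = summary_df.loc[
        (summary_df["group"] == youngest) & (summary_df["period"] == "all")
    ]
    if not base.empty:
        b = base.iloc[0]
        for lo, hi in strata[1:]:
            g = age_group_label(lo, hi)
            other = summary_df.loc[
                (summary_df["group"] == g) & (summary_df["period"] == "all")
            ]
            if other.empty:
                continue
            o = other.iloc[0]
            comparisons.append(
                {
                    "pair": f"{youngest} vs {g}",
                    "period": "all",
                    "kind": "cohens_d_unweighted",
                    "value": cohens_d(b["mean"], b["sd"], o["mean"], o["sd"]),
                }
            )

    # temporally weighted older-vs-younger percent increase
    glabels = [age_group_label(lo, hi) for lo, hi in analysis_groups]
    weighted = {}
    for (lo, hi), g in zip(analysis_groups, glabels):
        sub = dated.loc[label2 == g]
        if sub.empty or not sub["scored"].astype(bool).any():
            continue
        weighted[g] = group_weighted_mean(sub, n_bins=n_bins)
    if len(weighted) == 2:
        younger_g, older_g = glabels
        comparisons.append(
            {
                "pair": f"{older_g} vs {younger_g}",
                "period": "all",
                "kind": "percent_increase_weighted",
                "value": percent_change(weighted[younger_g], weighted[older_g]),
            }
        )
        prof = {
            g: feature_profile(scored.loc[label2.loc[scored.index] == g])
            for g in glabels
        }
        try:
            contrib = feature_contribution(
                prof[younger_g]["mean"], prof[older_g]["mean"]
            )
            for f in FEATURES:
                comparisons.append(
                    {
                        "pair": f"{older_g} vs {younger_g}",
                        "period": "all",
                        "kind": f"contribution_{f}",
                        "value": float(contrib[f]),
                    }
                )
        except CramError:
            pass
    return summary_df, pd.DataFrame(comparisons)


def map_table(
    dated: pd.DataFrame, strata=DEFAULT_STRATA, n_bins: int = 10
) -> pd.DataFrame:
    """Content-retrieval map cells across the age strata (equal group weights)."""
    label = assign_age_group(dated, strata)
    content: dict[str, np.ndarray] = {}
    dists = {}
    ages = {}
    for lo, hi in strata:
        g = age_group_label(lo, hi)
        sub = dated.loc[label == g]
        if sub.empty or not sub["scored"].astype(bool).any():
            continue
        content[g] = per_bin_scored_means(sub, n_bins=n_bins)
        dists[g] = retrieval_distribution(sub, n_bins=n_bins, grouping=g)
        ages[g] = float(sub["age_years"].mean())
    cmap = build_map(content, dists, ages, n_bins=n_bins)
    return cmap.cells


def run_pipeline(
    config: CohortConfig | None = None,
    out_dir: str | Path = "results",
    seed: int = 0,
    subjects_path: str | Path | None = None,
    memories_path: str | Path | None = None,
) -> RunManifest:
    """Run the full pipeline and write all stage outputs under ``out_dir``.

    When ``subjects_path``/``memories_path`` are given, the simulate stage
    is skipped and the user's data flow through the identical downstream
    stages.
    """
    t0 = time.perf_counter()
    cfg = config or CohortConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    counts: dict[str, int] = {}

    if subjects_path is None:
        dataset, truth = generate_cohort(cfg, _stage_rng(seed, _STAGES["simulate"]))
        write_dataset(dataset, out / "subjects.csv", out / "memories.csv")
        with open(out / "truth.json", "w", encoding="utf-8") as fh:
            json.dump(truth.to_dict(), fh, indent=2)
        paths["truth"] = str(out / "truth.json")
    else:
        if memories_path is None:
            raise CramError("memories_path required when subjects_path is given")
        dataset = read_dataset(subjects_path, memories_path)
        write_dataset(dataset, out / "subjects.csv", out / "memories.csv")
    paths["subjects"] = str(out / "subjects.csv")
    paths["memories"] = str(out / "memories.csv")
    counts["subjects"] = dataset.n_subjects
    counts["memories_dated"] = dataset.n_memories
    counts["memories_scored"] = int(dataset.memories["scored"].astype(bool).sum())

    clean, report = apply_screening(dataset)
    write_dataset(clean, out / "clean_subjects.csv", out / "clean_memories.csv")
    report.to_json(out / "screening.json")
    paths["clean_memories"] = str(out / "clean_memories.csv")
    paths["screening"] = str(out / "screening.json")
    counts["screened_removed"] = report.n_removed
    counts["screened_retained"] = report.n_scored_retained

    dated = date_memories(clean)
    temporal_df, split_df = temporal_tables(dated)
    temporal_df.to_csv(out / "temporal.csv", index=False)
    split_df.to_csv(out / "recent_remote.csv", index=False)
    paths["temporal"] = str(out / "temporal.csv")
    paths["recent_remote"] = str(out / "recent_remote.csv")

    summary_df, comparison_df = content_tables(dated)
    summary_df.to_csv(out / "content.csv", index=False)
    comparison_df.to_csv(out / "comparisons.csv", index=False)
    paths["content"] = str(out / "content.csv")
    paths["comparisons"] = str(out / "comparisons.csv")

    map_df = map_table(dated)
    map_df.to_csv(out / "map.csv", index=False)
    paths["map"] = str(out / "map.csv")

    manifest = RunManifest(
        version=__version__,
        config_hash=_config_hash(cfg),
        seed=int(seed),
        stage_seeds={name: [int(seed), k] for name, k in _STAGES.items()},
        paths=paths,
        counts=counts,
        settings={
            "quantile_method": report.quantile_method,
            "fence_multiplier": report.multiplier,
            "majority_rule": report.majority,
            "cohens_d_pooling": "rms",
            "map_normalization": "global_and_within_group",
        },
        wall_time_s=time.perf_counter() - t0,
    )
    manifest.to_json(out / "manifest.json")
    return manifest


def reproduce_report(
    out_dir: str | Path, tolerances: ReportTolerances | None = None
) -> str:
    """Markdown report comparing a completed run to published anchor values."""
    tol = tolerances or ReportTolerances()
    out = Path(out_dir)
    missing = [
        name
        for name in ("recent_remote.csv", "comparisons.csv", "screening.json", "manifest.json")
        if not (out / name).exists()
    ]
    if missing:
        raise CramError(f"incomplete run in {out}: missing {missing}")

    split = pd.read_csv(out / "recent_remote.csv")
    comparisons = pd.read_csv(out / "comparisons.csv")
    with open(out / "screening.json", encoding="utf-8") as fh:
        screening = json.load(fh)
    with open(out / "manifest.json", encoding="utf-8") as fh:
        manifest = json.load(fh)

    rows: list[tuple[str, float, float, float]] = []
    for g in ("18-25", "26-45", "46-78"):
        ref = REFERENCE_ANCHORS[f"recent_share_{g}"]
        got = split.loc[split["group"] == g, "recent_share"]
        if not got.empty:
            rows.append(
                (f"Recent share, {g} (%)", 100 * float(got.iloc[0]), ref, tol.recent_share_points)
            )
    for g in ("46-55", "56-65", "66-78"):
        ref = REFERENCE_ANCHORS[f"cohens_d_{g}"]
        got = comparisons.loc[
            (comparisons["kind"] == "cohens_d_unweighted")
            & (comparisons["pair"] == f"18-25 vs {g}"),
            "value",
        ]
        if not got.empty:
            rows.append((f"Cohen's d, 18-25 vs {g}", float(got.iloc[0]), ref, tol.cohens_d))
    got = comparisons.loc[
        comparisons["kind"] == "percent_increase_weighted", "value"
    ]
    if not got.empty:
        rows.append(
            (
                "Weighted content increase, older vs younger (%)",
                float(got.iloc[0]),
                REFERENCE_ANCHORS["percent_increase"],
                tol.percent_increase_points,
            )
        )

    lines = [
        "# Reproduction report",
        "",
        f"Package version {manifest['version']}, seed {manifest['seed']}, "
        f"config hash `{manifest['config_hash'][:12]}`.",
        "",
        "| Quantity | Simulated | Reference | Tolerance | Within |",
        "|---|---|---|---|---|",
    ]
    for name, got_v, ref_v, tol_v in rows:
        ok = "yes" if abs(got_v - ref_v) <= tol_v else "NO"
        lines.append(f"| {name} | {got_v:.2f} | {ref_v:.2f} | ±{tol_v:.2f} | {ok} |")
    lines += [
        "",
        "## Screening",
        "",
        f"Removed per rule: {screening['removed_counts']}; "
        f"fences per stratum: "
        + ", ".join(f"{k}: {v:.1f}" for k, v in screening["thresholds"].items())
        + ".",
        "",
        "Settings in effect: "
        + ", ".join(f"{k}={v}" for k, v in manifest["settings"].items())
        + ".",
    ]
    return "\n".join(lines) + "\n"
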