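# cram

Analysis pipeline for **word-cued autobiographical memory (AM) content
across the adult lifespan**, modeled on the Cue-Recalled Autobiographical
Memory (CRAM) paradigm: naturalistic word cues elicit memories, the
participant dates each memory into one of ten equal lifespan bins, and a
subset of memories is scored by counting remembered details (*elements*)
within eight *features* (Things, Feelings, People, Places, Times, Episodes,
Contexts, Details). The package is written for memory researchers and
psychometricians who need the full quantitative machinery of this paradigm
— cue sampling, dating arithmetic, data screening, retrieval and content
analytics — plus a calibrated synthetic cohort generator so every stage can
be exercised, with ground truth, without access to raw participant data.

## The model in brief

* **Cue sampling.** A cue word `w` is drawn from a frequency table with
  probability `P(w) = count(w) / Σ count`, emulating exposure frequencies in
  everyday language.
* **Dating.** A subject of age `A` has bins `[A(i−1)/10, A·i/10)`; a
  memory's event age is the midpoint of its assigned bin (or of the union
  span of up to three contiguous bins). An event within the most recent 10
  years of life is *Recent*, otherwise *Remote*.
* **Retrieval distribution.** `p_b` = (memories dated to bin `b`) / (all
  dated memories), with a k-bin memory contributing 1/k per bin. The
  *bump clarity* of a distribution is the ratio of the peak retrieval
  probability outside the retention interval to the subsequent minimal
  (local-minimum) retrieval probability.
* **Screening.** Scored memories with an identical count in all eight
  features are excluded; then subjects whose scoring is degenerate
  (majority-uniform, or all memories identically scored); then, within six
  age strata, memories whose total content exceeds the fence
  `Q75 + 3·IQR`.
* **Temporal weighting.** Because scoring deliberately over-covers rare
  bins, aggregate content is computed as `Σ_b p_b · m_b` over bins with
  scored memories (`m_b` = mean total content of scored memories in bin
  `b`), with weights renormalized over those bins.
* **Effect sizes.** Cohen's `d = |m₂ − m₁| / √((s₁² + s₂²)/2)`.
* **Content-retrieval map.** Cell `raw = m_{g,b} · p_{g,b}`, normalized
  within a group and globally (equal group weights by default), estimates
  where in the lifespan a retrieved detail comes from.

## Worked example

Printed-value arithmetic straight from the library:

```pycon
>>> from cram import synthetic_frequency_table, selection_probability, cohens_d
>>> table = synthetic_frequency_table()          # Zipf-like corpus stand-in
>>> selection_probability(table, "waiting") / selection_probability(table, "yard")
6.676056338028169
>>> round(cohens_d(21.3, 12.1, 24.8, 16.3), 2)   # youngest vs 46-55 content
0.24
```

The first number says a cue word with 474 corpus occurrences is ~6.7 times
more likely to be presented than one with 71. The second is the effect size
of the age-related content increase between two groups with the given
means/SDs.

A full simulated study, end to end (simulate → screen → temporal → content
→ map → report):

```bash
cram run --out-dir results --seed 4
cram report results
```

which prints, for the default 2,000-subject cohort:

```
| Quantity | Simulated | Reference | Tolerance | Within |
|---|---|---|---|---|
| Recent share, 18-25 (%) | 76.56 | 77.00 | ±5.00 | yes |
| Recent share, 26-45 (%) | 42.49 | 42.00 | ±5.00 | yes |
| Recent share, 46-78 (%) | 19.59 | 19.00 | ±5.00 | yes |
| Cohen's d, 18-25 vs 46-55 | 0.34 | 0.24 | ±0.15 | yes |
| Cohen's d, 18-25 vs 56-65 | 0.35 | 0.30 | ±0.15 | yes |
| Cohen's d, 18-25 vs 66-78 | 0.23 | 0.20 | ±0.15 | yes |
| Weighted content increase, older vs younger (%) | 18.00 | 16.00 | ±3.00 | yes |
```

Rows compare the simulated cohort's key statistics with published reference
values: the steep age decline of Recent retrieval (77/42/19%), the moderate
effect of subject age on reported content, and the ~16% temporally weighted
older-vs-younger content increase. `results/` also holds the per-stage CSV
tables (retrieval distributions, content summaries, comparisons, the
content-retrieval map) and a `manifest.json` with seeds, counts and a
config hash.

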