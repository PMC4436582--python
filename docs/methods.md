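# Methods

This note documents the statistical model behind each pipeline stage, the
generative model of the synthetic cohort, the defaults and why they were
chosen, and the numerical conventions that a reader reproducing results
needs to know.

## The paradigm and its data model

A participant of age `A` (integer years, 18–78 in the default cohort) is
cued with word lists, labels the first memory each list brings to mind,
dates each memory into one of `n = 10` equal lifespan bins
`[A(i−1)/n, A·i/n)` (up to three contiguous bins when unsure), and counts
remembered details within eight feature categories for a scored subset of
memories. Total content is the sum of the eight counts. Unscored content is
represented as *absent* (never zero), so content summaries cannot silently
absorb unscored memories.

Dating uses the midpoint of the assigned bin. For a multi-bin assignment we
take the midpoint of the union span — the unbiased point estimate under
uncertainty spread across the assigned range (the single-bin midpoint is
the standard convention; the multi-bin case is our extension, and multi-bin
sets are required to be contiguous). A memory is *Recent* when
`A − event_age ≤ 10` years (closed at 10; with midpoint dating, exact ties
are practically impossible), otherwise *Remote*.

Bin width grows linearly with subject age, so event-age resolution is
coarser in older subjects. Event-age aggregation accepts this (each memory
lands in the fixed-width interval containing its midpoint); no
deconvolution is attempted.

## Cue sampling

Cues are drawn with probability proportional to corpus occurrence counts,
with replacement within a list by default (a without-replacement flag
exists); a seeded generator makes lists reproducible. The package ships a
deterministic Zipf-like synthetic table (1,200 tokens,
`count ∝ rank^−1.05`, including the real tokens *waiting* = 474 and
*yard* = 71 so the canonical 6.7-fold odds example runs against it). The
real reference corpus, and the tokenization that produced it, are out of
scope.

## Screening

Three ordered stages, each memory carrying the first reason that removed
it:

1. **uniform vector** — all eight counts identical (including all-zero);
2. **pattern subject** — strictly more than half of a subject's scored
   memories uniform, or ≥ 2 scored memories all sharing one identical
   vector; all the subject's memories are excluded;
3. **stratified fence** — within age strata 18–25, 26–35, 36–45, 46–55,
   56–65, 66–78, total content strictly greater than `Q75 + 3·IQR`.

Conventions the source procedure leaves open, fixed here and recorded in
every report: quantiles use linear interpolation between order statistics
(the common spreadsheet/statistics default; configurable), "majority" means
strictly greater than 50% of the subject's *scored* memories, and the fence
is a strict inequality. Removal applies to content analyses only: flagged
memories are marked unscored in the clean dataset and keep contributing to
temporal (dating-only) analyses.

Two practical notes. First, a heavy-tailed count sample exceeds its own
`Q75 + 3·IQR` fence with probability ~0.1–0.2% under the default content
model, so even a contaminant-free cohort yields a few fence removals — the
fence is a property of the sample, not a fixed threshold. Second,
re-screening a screened dataset is a fixed point in practice, but records
sitting within a fraction of an element of the fence can in principle flip
when the fence basis changes; tests that require exact contaminant
recovery therefore construct baselines pre-trimmed at `2·IQR`, leaving one
IQR of margin below the operating fence.

## Temporal analysis

A k-bin memory contributes weight 1/k to each assigned bin; retrieval
probabilities are these weights normalized by the total dated weight, so
every memory carries total weight 1 and the dated count is conserved.
Group distributions pool memories (each memory weight 1); a
per-subject-average mode (each *subject* weight 1) exists for the
subject-level analysis.

**Bump clarity** quantifies the reminiscence bump: over bins outside the
retention interval, find the peak; the trough is the smallest probability
among later non-retention bins that are *local* minima of the whole
sequence; the ratio is peak/trough. It is undefined (an explicit `None`,
not an error) when no later non-retention bin exists, none is a local
minimum (the curve decays monotonically into the retention interval — the
typical young-adult picture, which "lacks a minimum"), or the trough is
zero. The local-minimum requirement resolves the ambiguity between "global
minimum after the peak" and "nearest local minimum": we take the global
minimum *among local minima*, which treats a monotone decay as bump-free
while tolerating the flat trough between bump and retention interval seen
in older groups. The retention interval defaults to the bins whose spans
lie wholly or partly within the most recent 10 years of a representative
(e.g. group-mean) subject age; it is configurable because the source
convention is unstated.

## Content analysis

Sample SDs use the n−1 denominator; CV = SD/mean. Temporal weighting
computes `Σ_b p_b · m_b` with the retrieval weights renormalized over bins
that actually contain scored memories — necessary because the scoring
design (one memory per represented bin, then rarest-bin-first fill)
deliberately over-covers rare bins.

Cohen's d uses the unweighted root-mean-square pooled SD
`√((s₁² + s₂²)/2)`. This choice reproduces published worked examples to
two decimals, whereas n-weighted pooling cannot be verified without group
sizes; the n-weighted variant is available. Feature *shares* divide each
feature's mean by the summed means (they sum to 1); *presence* is the
fraction of memories with ≥ 1 element; *contribution* divides each
feature's between-group mean difference by the total mean difference
(undefined when the total difference is zero). Rest-correlation is
`corr(x_f, total − x_f)` across memories; zero-variance features yield NaN
and are flagged rather than imputed.

The subject-level replication path keeps subjects with ≥ 5 scored
memories, weights each subject's content by that subject's own dated
distribution, and marks subjects eligible for Recent-vs-Remote comparisons
only when they have ≥ 1 scored memory in each period. Group content can be
aggregated memory-pooled (default) or subject-averaged; both modes exist
because the source aggregation is not fully specified.

## Content-retrieval map

Cell raw value `m_{g,b} · p_{g,b}`; within-group cells are normalized per
group and global cells multiply by group weights summing to 1. Group
weights default to equal — encoding the assumption that recollection
frequency is stable across age groups — with data-proportional weighting
available. Whether the published normalization is global or per-group is
ambiguous, so both are computed and reported. Window queries sum global
cells proportionally to the overlap between the query window and each
bin's event-age span, since bins of different groups span different ranges.

## The synthetic cohort generator

The generator is first-class, tested code: it defines the conditions every
stochastic test and the acceptance run operate under.

**Subjects.** Ages are drawn from six range-weights
(0.35/0.28/0.15/0.10/0.08/0.04 over 18–25 … 66–78; mean ≈ 34, ~22% older
than 45, emulating the study-scale cohort), genders 67% female, 81% native
speakers. Test types (in-person 28 dated/10 scored, atomic 1/1, mini 5/5,
extended 20/10, full 20/10) are assigned with weights
0.12/0.56/0.10/0.05/0.17, independent of age.

**Temporal structure.** Per age group (18–25, 26–45, 46–78) a memory's
period is drawn Bernoulli with the group's Recent share (defaults 0.77,
0.42, 0.19), where Recent bins are those whose *midpoint* lies within the
last 10 years — the same convention the analysis applies — so recovered
shares are unbiased. Within Recent, time-from-present is exponential
(τ = 4 y) truncated to the Recent span; within Remote, event age is a
mixture of a reminiscence-bump normal (mean 15 y, SD 4 y — mass over event
ages ~8–22) with weight 0 / 0.45 / 0.65 by group, and a uniform background,
both truncated to [3.5 y, Remote span]. Childhood amnesia is a hard cutoff
at 3.5 years (a ramp would also be admissible; the cutoff is simpler and
configurable). Memories are assigned 2–3 contiguous bins with probability
0.037 (Recent) / 0.050 (Remote), ~4% overall.

**Content structure.** Within each (group × period) cell, total content
targets the configured mean/SD (defaults: means 19.05–27.46, SDs
11.70–18.02, CVs ≈ 0.6–0.7). Feature counts are conditionally Poisson:
`x_f ~ Poisson(μ_mem · s_f · (1 − w_f + w_f·G) · H_f)` with a shared
gamma gain `G` (mean 1), independent per-feature gamma noise `H_f`, shares
`s_f` per composition (younger: Places .185, Things .145, People .135,
Details .130, Feelings .125, Times .105, Contexts .100, Episodes .075;
older: Things and Episodes shifted up, People and Times down, so their
element counts rise ~30% / stay nearly flat while total content rises
~16%), and loadings `w_f` = 0.85 except People = 0.5. The two gamma
variances are solved per cell (closed form plus a 1-D root find) so that
the cell's total-content SD and the mean pairwise inter-feature
correlation (target 0.37) are both matched exactly in expectation; the
People attenuation makes its rest-correlation the lowest of the eight
(~0.41 vs ~0.53–0.62 analytically), and emergent per-feature CVs are ≈ 1.
A single shared gain cannot hit both targets (matching the total SD alone
forces mean r ≈ 0.44), which is why the second, independent noise
component exists. When the correlation target exactly equals the feasible
maximum, the solver returns the boundary (pure shared-gain) solution;
clearly infeasible configurations raise a configuration error.

**Event-age trend.** Mean content additionally declines with event age
*within* periods (remote events carry fewer details — a continuous
phenomenon, not a period step). Each group's slope is derived from its own
two cell means divided by the gap between the cells' scored-subset mean
event ages (defaults land near −0.1 to −0.2 elements per year of memory
age), and the intercept is anchored at the scored-subset mean event age so
every cell mean still equals its target exactly; the variance the trend
adds is subtracted from the cell's latent SD so total SDs are preserved.
Without this trend the temporally weighted group contrast overstates the
older-vs-younger increase, because weighting corrects the scored subset's
bin coverage and therefore probes the within-period structure that a
period-step model lacks. The trend can be disabled or set explicitly.

**Scoring selection.** One memory per represented bin (random within bin),
then remaining slots fill from the least to the most represented bin in
the whole cohort. This makes the scored bin distribution measurably flatter
than the dated one — the condition temporal weighting exists to correct.

**Contaminants.** Optional injection of (i) uniform-vector memories (at
most a minority per subject, so the subject rule is not triggered), (ii)
pattern subjects of both kinds (majority-uniform; identical-vector), and
(iii) extremes placed half an IQR plus a margin above the current stratum
fence. A manifest lists every affected record, making screening recovery
exactly checkable.

**Ground truth.** Every generated number is reproducible from
(config, seed); the truth record carries all cell-level parameters and
per-memory latents (true event age, drawn period, shared gain).

### What the generator does not emulate

Between-subject heterogeneity in content is purely sampling variation:
there is no per-subject random effect on mean content or composition, no
gender/language/condition effects, and no response-time or order structure.
Passing subject-level tests therefore shows the subject-level *machinery*
works, not that it would detect individual-difference structure in real
data. The joint distribution of feature counts beyond means, shares and
correlations is one admissible choice (gamma-mixed Poisson), not an
empirical fit. Temporal dating error beyond bin quantization, and the
recruitment process, are not modeled.

## Numerical choices and conventions

* One RNG family (numpy Generator/PCG64) throughout; the pipeline derives
  per-stage streams as `default_rng([seed, stage_index])` and records the
  scheme in the run manifest.
* Quantiles: linear interpolation (configurable, logged).
* Bins are half-open with the last bin closed; degenerate Remote windows
  (possible only below the adult age range) fall back to Recent draws.
* Undefined quantities (bump clarity without a trough; contributions with
  zero total difference; maps for all-zero groups) are explicit result
  states (`None` / a raised `UndefinedResultError`), never silent zeros.
* Problem sizes: unit tests use cohorts of 150–2,500 subjects; the
  end-to-end weighted-contrast check and the acceptance script use 10,000
  subjects (~90k dated, ~45k scored memories), at which the percent-change
  estimate has a sampling SD of about one point. Exhaustive
  screening-oracle checks enumerate all ~75k sorted integer lists of
  length 4–8 with values 0–10 (quantiles are permutation-invariant, so
  sorted multisets cover all ordered lists).

## Known limitations

* The retention-interval bin set for bump clarity uses a representative
  age per group; subjects far from the group mean can have a different
  midpoint-recency bin boundary.
* The fence rule's idempotence is empirical, not guaranteed: removing the
  tail can lower the recomputed fence by a fraction of an element.
* Recovered older-vs-younger weighted contrasts center near ~17% under the
  default calibration — consistent with the published ~16% within the
  sampling tolerance the pipeline itself reports, but sensitive to the
  within-period content trend, which printed two-period moments only
  partially constrain.
* Window queries distribute a bin's mass uniformly over its span; fine
  structure within a bin is unrecoverable by construction.
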