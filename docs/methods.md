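# Methods

## Annotation model

The unit of analysis is one annotator's assessment of one generated
image. An annotation carries the generator model label, the prompt
label, the number of people depicted, one expected part count `m_i` per
anatomical region, and sparse error counts `n_(ij)k` per
(region, error type, severity) cell; a missing cell means zero.

The denominator is stored **once per region**, not per (region, error
type): `m_i` is "the number of parts of this region present, or expected
present", a property of the image, not of the error category. Two
validation rules give every proportion a clean [0, 1] interpretation:

* `Σ_k n_(ij)k ≤ m_i` for every (region, error type) — a cell's errors
  cannot outnumber the parts it is counted against. A spurious extra
  part (e.g. a sixth finger) is charged against the region's part count.
* `m_i ≤ person_count × anatomical maximum` with per-person maxima
  face 1, torso 1, hands 2, limbs 4, feet 2.

`m_i = 0` with zero counts is valid (region cropped out of frame) and
scores 0 for every cell of that region.

On disk, sets are stored as long-format CSV (one row per nonzero error
cell plus one `_expected` row per region) or as a JSON array of
annotation objects; writes are canonically ordered so identical sets
produce byte-identical files. Model, prompt and annotator labels are
free strings so the rubric extends beyond any particular study design.

## Scoring

Per cell, the proportion of errors is `PE_(ij)k = n_(ij)k / m_i`; the
cumulative image score contracts the 25 cells with severity weights

`C = Σ_ij (w_a PE_a + w_b PE_b + w_c PE_c)`, defaults
`w_a = 0.2, w_b = 0.5, w_c = 1.0` (dimensionless; chosen so one fully
affected region-type cell at severe grade contributes 1.0 and a mild one
a fifth of that). `C` is linear in the weights and monotone in every
count, bounded by `25 w_c`.

`PE` is a *proportion*, not a raw count. The per-severity aggregates of a
group are the **unweighted** sums of PE over annotations and cells, and
satisfy the identity `(w_a A + w_b B + w_c C̃)/n = mean cumulative
score` — used both as an internal invariant and as the bridge between the
per-severity and per-image views of a dataset.

Overall severity discretizes each annotation's score against its *own
annotator's* score distribution: at or below that annotator's 0.5
quantile → low, at or below the 0.75 quantile → medium, above → high.
Quantiles use linear interpolation between order statistics (the numpy
default) and boundaries are inclusive (`≤`) at both thresholds; an
annotator needs at least two scored images for the thresholds to exist.
Thresholding per annotator absorbs systematic strictness differences but
has a consequence worth knowing: even two *identical* annotations of the
same image can receive different labels when the two annotators' overall
distributions place their thresholds differently. Agreement on the
severity-label variant therefore tops out slightly below alpha = 1 even
for perfect duplication, while the cumulative-score and binary variants
reach exactly 1.

Double annotations are scored independently; nothing is averaged or
reconciled, so a campaign of 240 images with 25% doubling yields 300
observations.

## Inter-rater reliability

Krippendorff's alpha is implemented from first principles in its
coincidence-matrix form: every ordered pair of values assigned to the
same unit by different raters contributes `1/(m_u − 1)` to the
coincidence counts; `α = 1 − D_o/D_e` with `D_o` the delta-weighted
coincidence average and `D_e` its expectation under random pairing of
the pooled values. Units observed by fewer than two raters are dropped;
`D_e = 0` (no value diversity) raises an explicit undefined-alpha error
rather than returning a number.

Difference functions per measurement level: nominal `1[v ≠ v′]`;
interval `(v − v′)²`; ordinal the squared cumulative coincidence-
frequency distance `(Σ_{g=c..k} n_g − (n_c + n_k)/2)²`. Interval alpha
is invariant under affine transforms of the values; this is tested.

Three data variants mirror the evaluation design: cumulative score per
image (interval), overall severity per image (ordinal, with thresholds
computed from each annotator's full set before restriction to doubled
images), and a severity-blind 0/1 indicator per (image × region ×
error-type) cell (nominal; the 25 cells of an image are pooled as
separate units into a single coefficient per annotator pair). Alphas are
computed pairwise on exactly the units both members annotated — no
chaining through third raters — and averaged arithmetically over defined
pairs; undefined pairs are flagged, not dropped silently.

The implementation is cross-checked in the test suite against an
independent brute-force enumeration oracle (exact agreement on all small
two-rater binary matrices and on random multi-rater matrices at all
three levels) and against the two-rater limit `α → 2p − 1` for uniform
binary marginals with agreement probability p.

## Group comparison

Model and prompt groups partition annotations and carry mean and sample
variance (n − 1) of the cumulative score plus per-severity PE sums;
error-type and region groups slice within annotations and carry only the
severity aggregates (the cumulative score is a per-image quantity).
Location differences use Welch's t with Welch–Satterthwaite degrees of
freedom and a two-sided p from the t distribution; it is cross-checked
against scipy to 1e-10. p-values are reported raw; a warning is emitted
once more than three comparisons run in a session. Every annotation —
including both copies of doubled images — enters as one observation.

## Allocation

`allocate` deals annotation slots (each image once, doubled images
twice) cyclically to a seeded random rotation of the annotators, with
slots ordered so each model forms a contiguous block and a doubled
image's two slots are adjacent. This gives, by construction: total loads
within ±1, per-model shares within ±1 of proportional, and distinct
annotators on every doubled image. Per-prompt shares are then driven
within ±1 by a seeded hill-climbing repair that exchanges same-model
slots between annotators (preserving everything already guaranteed),
with sideways moves to escape plateaus and a hard iteration cap that
fails loudly rather than returning an unbalanced plan. Doubled images
are chosen by proportional stratified sampling over (model, prompt)
cells with largest-remainder rounding; the doubled-count itself uses
round-half-to-even. The whole procedure is deterministic given the seed;
the invariants are property-tested over 1000 random configurations.

## Synthetic annotation generator

The generator emulates an annotation campaign, not any particular
model's failure physiology. Per image and (region, error-type) cell the
error count is `Binomial(m_i, rate × difficulty)` — so `E[PE] = rate ×
difficulty` exactly — and the drawn total is split across severities by a
multinomial over the model's severity mix, which enforces the `Σ_k n ≤
m_i` ceiling by construction (no truncation step is ever needed).
Effective rates are clamped at 1. Visibility profiles scale a prompt's
expected part counts (e.g. feet cropped out of a portrait scene).

A doubled image's second annotation is the first one *re-read with
noise*: each of the 25 cells flips its error presence with probability
ε (an occupied cell is cleared; an empty cell gains a single error with
mix-drawn severity). ε = 0 reproduces the first annotation exactly;
ε = 0.5 on cells with near-symmetric presence drives binary agreement to
chance. Count-level perturbation is deliberately out of scope: presence
flipping is the simplest mechanism that spans alpha from 1 to ~0.

`study_design_config` fixes the campaign shape to 3 models × 10 prompts
× 8 images with 4 annotators and 25% doubling (240 images, 300
annotations, 60 doubled, 75 per annotator). Its defaults portray a
stronger commercial model (rate 0.076, a-heavy severity mix) against two
weaker open models (rates 0.124 and 0.137 with severity mixes tilted to
b/c), and prompt difficulties averaging 1 with group scenes (five people
sunbathing / playing volleyball) two or more times harder than a parent
holding a baby; these values were set once, from the magnitudes such
campaigns report, so that synthetic per-model means land near 0.8–2.1
and agreement sits in the moderate band at ε ≈ 0.1.

What the generator does *not* model: correlated errors across regions
(a fused hand often accompanies a configuration error on the limb),
annotator-specific strictness biases, count-level disagreement between
raters, and heavy-tailed image difficulty within a prompt. Passing tests
therefore demonstrate that the pipeline measures what the binomial
campaign encodes — not that real annotation data satisfies these
independence assumptions.

`recover` closes the loop: the closed-form expectation
`E[C] = Σ_ij min(rate·difficulty, 1) · (mix · weights)` (averaged over
prompts, visible cells only; `25 r` in the uniform full-visibility case)
is compared with the empirical mean of fresh annotations, and the
pairwise binary alpha is reported next to the configured ε.

## Numerical and design choices

* Quantile estimator and `≤` boundaries as above; documented because
  different conventions relabel boundary images.
* Sample variance uses n − 1 throughout.
* Welch p-values come from `scipy.stats.t.sf`; alpha and scoring are
  pure numpy.
* Degenerate inputs fail loudly: both-zero variances, single-score
  annotators, all-identical alpha values, unpairable matrices and
  over-ceiling counts raise typed errors naming the offending quantity.
* Severity weights are validated to be non-negative; a non-monotone
  ordering warns but is allowed for sensitivity analyses.
* File writes are canonically sorted; two writes of one set are
  byte-identical.

## Problem sizes

The shipped test suite and acceptance script run the study-shaped
campaign (300 annotations) for pipeline checks, 200–400 images for
law-of-large-numbers and recovery checks, 1000 random configurations for
the allocation sweep, 1000 seeded replicates of 60-annotation campaigns
for the Welch type-I calibration, and 1500-unit matrices for the
agreement null — sizes at which Monte-Carlo bands (±2 points on the
type-I rate, |z| < 3 on recovery, |α| < 0.1 at the null) are tight
enough to catch implementation defects while each run stays in the tens
of seconds.

## Known limitations

* The on-disk schema is this package's own; converting another study's
  deposited annotation files requires a format-specific converter.
* The binary-category variant pools all 25 cells of an image into one
  coefficient per pair; a per-cell-alpha-then-average alternative is a
  plausible reading of the same design and would give different numbers.
* No multiple-testing correction and no mixed-effects modelling of
  annotator effects; both are future work.
* The generator's independence assumptions understate the correlation
  structure of real anatomical errors (see above).
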