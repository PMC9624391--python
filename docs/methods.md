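# Methods

## The estimation problem

Multi-task sequence-to-function models (CNNs mapping one-hot DNA to
several genomic marks, such as TF binding signals) may implicitly learn
*relationships between* their output tasks, not just the mapping from
sequence to each task. `seqmr` asks whether such a model has learned a
linear causal effect of one mark (the exposure, X) on another (the
outcome, Y), and estimates that effect with Mendelian randomization (MR),
using single-base in-silico mutations as instruments.

For each reference sequence region the pipeline:

1. enumerates all single-base substitutions (L × 3 mutants for the
   4-letter alphabet);
2. queries every member of a deep ensemble on the reference and all
   mutants;
3. forms per-mutation effect sizes `beta = E[task | mutant] − E[task |
   reference]` (ensemble-mean differences) for both tasks, with the
   variance of the *paired per-member differences* as the squared
   standard error — equivalently `var_m + var_r − 2 cov(m, r)`, which
   removes the large common component of mutant and reference
   predictions that is due to the shared member weights;
4. filters instruments on exposure strength, `|beta_X / se_X| ≥ 2` by
   default (relevance; the threshold is exposed as a parameter);
5. fits one local causal effect per region — a Wald-ratio baseline
   (mean of `beta_Y / beta_X`, with the sample SD of the ratios as the
   interval basis) and MR-Egger (intercept + slope regression of
   `beta_Y` on `beta_X`, instruments oriented to `beta_X ≥ 0`, weighted
   `1 / se_Y²`, Huber M-estimated by default);
6. pools local effects across regions with a DerSimonian–Laird
   random-effects meta-analysis, reporting the global mean, its standard
   error σ, and the between-region SD τ.

The estimand lives in the model's output space; in the simulation that
space is Anscombe-transformed counts, so all causal effects are slopes in
Anscombe space.

## The simulation harness

The built-in generator creates a world whose causal structure is known:

* Sequences of L = 100 bp are uniform-random; for each TF (exposure
  GATA-like, outcome TAL1-like, confounder SOX2-like) a PWM-sampled
  subsequence is implanted with probability 0.5 at a uniform position.
  Implants are placed confounder → exposure → outcome, later implants
  overwriting earlier bases. The bundled PWMs are synthetic stand-ins
  built from the canonical consensus motifs with realistic widths
  (8/10/9) and information content.
* Binding probabilities: each window w is scored with the likelihood
  ratio `LR_w = P(w|PWM) / P(w|background)` and converted to the
  posterior probability of the motif occupying that window under a 50%
  prior of being present anywhere: `s_w = qLR_w / (1 + qLR_w)` with
  prior odds `q = 0.5 / n_windows`. Windows combine by soft-or
  (probabilistic union) `p = 1 − Π(1 − s_w)`. Scanning is forward-strand
  only (reverse-complement scanning is available via a flag). The
  un-normalized convention `s_w = LR/(1+LR)` is selectable but saturates
  on 100 bp sequences (nearly every sequence then has p ≈ 1) and is kept
  only for comparison.
* Affinities: `c_e = α·p_e + η·p_c + τ·z + 1` and
  `c_o = max(α·γ·p_o·p_e, 0) + ν·p_c + τ·z + 1`, with η = 20, ν = 30,
  τ = 25 fixed, α ~ N(100, 3) and γ ~ ½N(10, 0.5) + ½N(1, 0.5) drawn
  once per run. The outcome is *gated* by the exposure (no exposure
  binding ⇒ no outcome binding); γ is the causal coefficient in raw
  count space. The floor at 0 covers the rare γ < 0 draws from the low
  mixture component, since binding cannot push counts below the
  confounder-plus-baseline level. Observed counts are Poisson with mean
  equal to the affinity; models are trained on `y = 2√(count + 3/8)`
  (Anscombe), which stabilizes the Poisson noise variance near 1.
* Scenarios: four combinations of two confounder switches — the
  sequence confounder (SOX2 motif, η/ν terms) and the sequence-
  independent z ~ Bernoulli(0.5) (τ term). With a switch off, the
  corresponding draws are still consumed from the per-region RNG
  streams, so scenarios nest: re-generating with the same seed and a
  switch flipped changes only confounder-dependent fields.
* Ground truth: for a region carrying the exposure motif, every point
  mutation inside the implant (width × 3) is applied, noiseless
  affinities are recomputed and Anscombe transformed, and the true local
  causal effect is the no-intercept least-squares slope of the outcome
  deltas on the exposure deltas (both deltas are exactly zero at the
  reference, hence no intercept). The true *global* effect of a round is
  the mean of its true local effects. Note γ itself is not the true
  effect: the truth lives in Anscombe space.

### What the generator does and does not emulate

It emulates motif-driven binding with graded match strength, chance
background motif occurrences, two kinds of confounding, and Poisson
measurement noise. It does not emulate reverse-strand binding, motif
cooperativity/spacing effects, profile (base-resolution) readouts, or
overdispersed noise beyond what random sequence content induces. Passing
tests therefore demonstrate correct recovery of causal structure *within
this model class*, not performance on experimental ChIP data — external
models plug in through the ensemble adapter for that.

## The model

Each ensemble member is a small CNN: three same-padded conv layers
(15 filters, width 7, ReLU), global max-pool, two hidden layers of width
30, and a linear two-task head, trained jointly with MSE, Adam at 1e-3,
batch 128, early stopping (patience 10 on a 10% validation split,
best-weights restore) within 100 epochs. Members share data and differ
only by initialization/shuffling seed; the across-member spread of
predictions is the predictive uncertainty. The implementation is plain
numpy (im2col convolutions, handwritten backprop), which is fast enough
on one CPU at these sizes and keeps the dependency footprint small.
Pooling, padding and activation choices are defaults of this package;
ensemble size defaults to 5 and the study protocol uses 3.

Deep-ensemble uncertainties are typically overconfident, so the
standard errors are recalibrated before MR by quantile recalibration:
isotonic regression of the empirical CDF on the predicted CDF values of
validation residuals, with a per-task SE multiplier chosen so that the
recalibrated central 95% interval has nominal empirical coverage on the
validation set. Calibration is on by default in the simulation-study
protocol; without it, the overconfident `se_X` lets many weak
out-of-motif mutations pass the relevance filter (the in-implant
fraction of kept instruments drops from ~0.85 to ~0.55) and the
Wald-ratio spread inflates.

## Numerical and design choices

* R² convention for study accuracy: squared Pearson correlation between
  estimated and true global effects across rounds (a regression-R²
  variant is available). This reads accuracy as cluster discrimination
  and is insensitive to the mild attenuation bias of the estimates.
* Per-round seeds derive from the master seed via `SeedSequence`;
  every region has its own stream keyed on (seed, split, index), making
  datasets bit-reproducible and scenario-nested.
* MR-Egger weights use outcome-side variance only (the standard
  no-measurement-error convention); exposure-side error is reflected in
  instrument filtering instead. The Huber tuning constant is 1.345.
* Regions with fewer than 3 instruments are skipped for Egger; regions
  with a single usable Wald ratio have an undefined SD and are excluded
  from pooling. Local fits with essentially zero standard error
  (perfect small-k regressions) would absorb all inverse-variance
  weight; they are dropped from the meta-analysis with a warning
  (threshold: 1e-4 of the median SE).
* DerSimonian–Laird τ² is clamped at zero; REML and a SD/√k Wald
  interval variant are available behind flags.

## Known limitations

* MR-Egger's per-region CI reflects only within-region instrument
  scatter. When the trained model carries a region-level bias (shared
  by all instruments of that region), those CIs are anti-conservative:
  measured local coverage for Egger is far below nominal at reduced
  training scale, while the deliberately conservative Wald-SD band
  sits near the nominal level. The global ±2τ interval absorbs the
  between-region spread and is the reliable uncertainty statement.
* In this generator the outcome task is learned about as well as the
  exposure task (the outcome motif is longer and sharper), so model
  accuracy does not show the exposure > outcome ordering that real
  multi-TF data can show, and held-out R² at full scale (~0.95)
  exceeds what is typically reported for noisy experimental data.
* The study protocol used by the test suite is reduced — 5 rounds per
  scenario, 3000/200 sequences, 3 members, ≤30 epochs — sized so the
  whole suite runs in tens of minutes on one CPU. Cross-round metrics
  at this scale are coarser (5 rounds) than the headline 50-round
  protocol, which `seqmr study --rounds 50` reproduces given the time.
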