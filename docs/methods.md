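# Methods

## The problem

Whether beauty is "in the eye of the beholder" is, statistically, a
question about variance. Two images can share the same mean beauty
rating while one is *contested* (ratings pile up at both ends of the
scale) and the other is *consensual* (ratings cluster at the middle).
This package implements the quantitative machinery for characterizing
that distinction on 1–7 Likert rating data: a mixture-model test of
unimodality vs. multimodality per image, a brute-force search for
matched-mean quartets at both variance extremes, and the reliability and
self-estimation statistics used to ask whether raters can perceive their
own rating variance.

## Mixture model with a Poisson count likelihood

Each image's ratings are binned into counts `y_i` over the seven Likert
values `x_i ∈ {1..7}`. The model treats each bin count as an independent
Poisson draw with intensity

    λ(x_i) = c · Σ_j A_j f(x_i; μ_j, σ),   j = 1..k,  k ∈ {1,2,3}

where `f` is the Gaussian density, the weights satisfy `Σ A_j = 1` with
`A_j ∈ [0,1]`, and the shared width σ is fixed during fitting (default
1.43, the average per-image SD of the low-variance reference quartet; a
helper recomputes it from whatever data is loaded, where the printed
reference SDs average 1.45). The negative log-likelihood is

    NLL = Σ_i [ λ_i − y_i ln λ_i + ln(y_i!) ],

with `ln(y!)` via log-gamma so count-normalized (non-integer) histograms
are also handled.

**Count scale.** A weighted sum of unit-area densities cannot on its own
reach raw-count magnitudes while the weights are confined to [0,1] and
sum to one. The intensity therefore carries a scale `c`, defaulting to
the histogram total `N` (so `λ` lives on the raw-count scale and the
weights keep their mixture-proportion meaning); `count_scale=1`
reproduces the literal unit-area form for count-normalized histograms.

**Free parameters.** With the last weight eliminated by the sum
constraint, the one-, two- and three-component variants have 1, 3 and 5
free parameters (the means, plus k−1 free weights).

**Fitting.** Bounded L-BFGS-B minimization of the NLL with
`μ_j ∈ [1,7]` and free weights in [0,1]; the eliminated weight is kept
nonnegative by a quadratic penalty that is inactive at any valid
optimum. Multi-start over a deterministic grid — all k-subsets of
means {2,3,4,5,6}, uniform starting weights — so fits are reproducible
without a seed; ties between starts break by grid order. Convergence
tolerance 1e−8 on the NLL. Fitted means are reported ascending, which
removes label switching. Gaussians are evaluated on the scale without
truncation correction (no renormalization for mass outside [1,7]).

**Model comparison.** `BIC = p·ln(n) + 2·NLL`, lower is better, with the
sample size `n` taken as the number of bins (7) by default: the Poisson
likelihood has one observation per bin. `bic_sample_size="total"`
instead uses the rating count. A best-vs-second margin ΔBIC ≥ 4 is
labelled "positive" evidence, smaller margins "weak", exact equality
"tie" (resolved toward fewer parameters). Note a structural consequence
of the default: because the three-component model can imitate the
two-component one exactly, the margin between nested best and runner-up
is capped at `2·ln 7 ≈ 3.89` in bins mode, so the "positive" label is
only reachable in total mode (`2·ln 25 ≈ 6.44` at 25 raters). Both modes
are exposed; selection (the arg-min) is unaffected.

## Quartet search

Eligible images have mean beauty inside a closed window (default
[3.5, 4.0]) and mean typicality at or above a floor (default 3);
boundaries are inclusive. All C(n,4) combinations of eligible images are
enumerated (guarded by a configurable cap, default 200 eligible images,
since C(n,4) grows quartically). Each combination is scored by the
*range statistic*: the mean over participants of (max − min) of that
participant's four ratings, dropping participants with incomplete
coverage per-quartet and reporting the retained count. The top (high
mode) or bottom (low mode) `ceil(q · n_combinations)` sets by range
statistic (q = 0.25 by default) are then ranked by *group variance* —
the mean over the four images of the across-participant rating SD —
descending in high mode, ascending in low mode. Ties break by range
statistic, then lexicographic image ids, making the output a pure
function of the data. The final human selection step (category
diversity, faces, copyright) is out of algorithmic scope; the exclusion
list and the full ranked output support it.

## Statistics

* Sample SDs use the n−1 denominator throughout, fixed by the
  estimation-task convention that the dispersion of {1,3,5} is 2.
  An image with a single rater reports a *missing* SD, never 0.
* The two-sample t-test pools variances (Student, df = n_a + n_b − 2),
  which is what makes two groups of four images give df = 6. Cohen's d
  is |mean difference| / pooled SD; the identity
  `d = |t|·√(1/n_a + 1/n_b)` is asserted in tests.
* The paired test uses index-order pairing (for quartets: images paired
  by within-quartet position — a convention, flagged as such), df = n−1,
  d = |mean difference| / SD of differences.
* One-sided directions are explicit parameters (high-variance SD >
  low-variance SD; the mean contrast direction likewise), never inferred
  from the data. Degenerate zero-variance inputs return 0 (equal means)
  or a signed-infinity sentinel (unequal), never an exception.
* Test–retest reliability: per participant, the mean rating over an
  image subset in each session; Pearson r across participants (≥ 3
  required). p-values for r use the t-transform with df = n − 2.
* "Normalized" ratings subtract each participant's own quartet mean,
  so per-image SDs of normalized ratings isolate disagreement about the
  image from overall rater generosity.
* Estimation accuracy: records with an estimated *mean* of 18 or above
  (an off-scale answer on a 1–7 task) are excluded as extreme outliers
  before any accuracy correlation, whichever measure is analysed; the
  exclusion count is reported.
* Reported statistics are rounded to two decimals in rendered output
  only; full precision is retained everywhere internally.

## Synthetic data generator

The generator emulates the structure the analyses assume, so the whole
pipeline is testable without any collected dataset:

* **Archetypes.** Each image has a latent Gaussian mixture: one
  component for consensus-like images (default: mean 3.75, SD 1.5,
  which lands near an observed SD of 1.4 after discretization,
  matching the printed consensus quartet SDs of 1.3–1.6), two
  components for contested-like images (default: means 2 and 6, equal
  weights, SD 1, giving an overall SD near √(1+4) ≈ 2.2, matching the
  printed contested SDs of 2.0–2.2). Both keep the mean inside the
  3.5–4 selection window.
* **Discretization.** Latent values are rounded half-away-from-zero and
  clipped to [1,7] — one fixed rule keeps fixtures reproducible.
* **Retest.** Session-2 latents correlate with session-1 latents at a
  configured ρ (default 0.93) *before* discretization; the observed r is
  therefore slightly attenuated, and tests compare against simulated,
  not nominal, values. ρ = 1 reproduces session 1 exactly.
* **Self-estimates.** Estimated means/SDs are a fidelity blend
  `est = m + φ(actual − m) + √(1−φ²)·s·z` on the actual's scale, so the
  population estimate–actual correlation equals the configured fidelity
  φ (defaults 0.74 for means, 0.18 for SDs, mirroring the asymmetry the
  analyses are designed to detect).
* **Reproducibility.** One RNG stream per logical block (ratings,
  retest, estimations), spawned from the master seed, with
  per-participant substreams so enlarging the sample leaves earlier
  participants' draws unchanged. Default sample size is 52 participants.
* `simulate_model_histogram` additionally draws bin counts directly
  from the Poisson-count mixture — the correctly-specified design used
  for parameter-recovery checks of the fitter.

**What the generator does not model:** conformity, expertise,
sequential/order effects, per-participant response styles beyond the
level captured by quartet-mean normalization, attention lapses, and the
bounded-scale variance compression near the scale ends. Passing
recovery tests therefore show the estimators work when their
assumptions hold, not that real rating data satisfies them.

**A deliberate distinction in the recovery design:** when histograms are
produced through the latent-rating path, end-clipping piles probability
at bins 1 and 7 and biases fitted component means *outward* by roughly
0.25 for components at 2 and 6 — a fact about model misfit, not about
the optimizer (which matches an independent grid search on those same
histograms). Recovery of the fitter itself is therefore assessed on
model-generated histograms; the latent path is used to validate
selection rates and the unimodal-mean recovery, which are robust to the
misfit.

## Problem sizes used in tests and the acceptance script

Model-recovery experiments use 20 replicate histograms of 200 ratings;
grid-oracle comparisons use 20 random Poisson histograms against a
0.25-step mean grid; the quartet-search recovery uses 150 participants
on 10 images (4 contested planted among 6 consensus); fidelity recovery
uses 1000 participants; the shared test fixture uses 60. These sizes
give Monte-Carlo error comfortably inside the asserted tolerances while
keeping a full run in well under a minute.

## Known limitations

* σ is shared and fixed; no free-σ or per-component-σ fitting, no k > 3,
  no unbinned likelihood.
* The Poisson likelihood ignores the multinomial constraint that the
  bin counts sum to the number of raters.
* With 7 bins, the 5-parameter model is near the identifiability limit;
  the deterministic multi-start grid makes the reported optimum
  reproducible but the k = 3 means are weakly determined whenever two
  components merge.
* The search's range statistic is a (max − min) proxy for per-participant
  quartet SD; the two order images identically but differ in scale.
* No linear mixed-effects modeling and no correction for variance
  compression near the Likert bounds.
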