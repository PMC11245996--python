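# beautyvar

Consensus and contention in beauty judgment, quantified. Two images can
share the same mean beauty rating on a 1–7 Likert scale while differing
radically in *variance*: a contested image splits raters toward both
ends of the scale, a consensual one clusters them in the middle. This
package implements, as a tested and reusable pipeline, the statistical
machinery for characterizing that difference:

* **Mixture modeling of rating histograms.** Per-image counts
  `y_i` over bins `x_i ∈ {1..7}` are modeled as independent Poisson
  draws with intensity `λ(x_i) = c · Σ_j A_j f(x_i; μ_j, σ)`, a
  one/two/three-component Gaussian mixture with shared fixed σ
  (default 1.43), weights summing to 1, and count scale `c` defaulting
  to the histogram total. Bounded multi-start maximum likelihood; model
  comparison by `BIC = p·ln n + 2·NLL` with free-parameter counts
  p = 1, 3, 5 and a ΔBIC ≥ 4 positive-evidence rule. A bimodal best fit
  is the signature of a contested image.
* **Brute-force quartet search.** Enumerate all C(n,4) four-image sets
  whose images have mean beauty in [3.5, 4.0] and typicality ≥ 3, score
  each by the mean over participants of their (max − min) rating range,
  keep the top (or bottom) 25%, and rank by group variance (mean
  across-participant SD) — yielding matched-mean, extreme-variance
  "disputed" and "undisputed" candidate quartets.
* **Reliability and estimation-accuracy statistics.** Pooled and paired
  one-sided t-tests with Cohen's d for quartet variance contrasts,
  test–retest Pearson reliability, participant-normalized ratings, and
  estimated-vs-actual quartet mean/SD correlations with the ≥ 18
  estimated-mean outlier rule.
* **A seeded synthetic-data generator** producing rating tables,
  retest sessions, self-estimates and number-set control stimuli with
  the statistical structure the analyses assume, so everything above is
  exercisable end to end without collected data.

The mixture fitter is a scikit-learn-style estimator
(`HistogramGaussianMixture`, with `fit`, `get_params`, and fitted
`weights_`, `means_`, `nll_`, `bic_` attributes); the module-level
functions are thin wrappers around it.

See `docs/methods.md` for the model, its assumptions, and the design
choices.

## Worked example

Simulate a 52-participant study (4 contested images, 4 consensus
images, 4 unimodal foils, two rating sessions, self-estimates), then run
the full analysis:

```bash
beautyvar simulate --n-participants 52 --n-foils 4 --seed 7 --out demo
beautyvar run-all --ratings demo/ratings.csv \
    --estimations demo/estimations.csv \
    --number-sets demo/number_sets.csv --out demo/run
```

which prints (abridged):

```
Model selection (BIC)
  disputed_1: k = 2 (dBIC = 3.89, weak)
  disputed_2: k = 2 (dBIC = 3.89, weak)
  disputed_3: k = 2 (dBIC = 3.89, weak)
  disputed_4: k = 2 (dBIC = 3.89, weak)
  ...
  undisputed_2: k = 1 (dBIC = 3.47, weak)
  undisputed_3: k = 1 (dBIC = 2.42, weak)

Test-retest reliability
  all_images: r = 0.97, n = 52, p = 0.00

Estimation accuracy
  disputed: mean r = 0.83 (excluded 0), SD r = -0.13
  undisputed: mean r = 0.78 (excluded 0), SD r = 0.05
```

Reading this: every planted contested image is best fit by two
Gaussians and every consensus image by one — the bimodality signature.
Participants are highly reliable raters (r = 0.97 across sessions) and
good at estimating their own quartet *mean* (r ≈ 0.8) but near chance at
estimating their quartet *SD* (r ≈ 0) — the generator's configured
fidelities (0.74 and 0.18) made visible by the accuracy analysis. The
`dBIC` column is the BIC margin over the runner-up model; with the
default 7-bin BIC the margin between nested models is capped at
2·ln 7 ≈ 3.89 (see `docs/methods.md` for the `--bic-n total`
alternative). In this draw the top-ranked high-variance quartet in
`demo/run/quartets_high_variance.csv` mixes image types because two
contested images drifted outside the 3.5–4.0 mean-eligibility window at
n = 52 — the sampling fragility that motivates the matched-mean window
in the first place; at larger n the search recovers the planted quartet
exactly.

The same steps are available as library calls (`simulate_ratings`,
`fit_and_compare`, `search_quartets`, `run_pipeline`, ...):

```python
import beautyvar as bv

cfg = bv.SimulationConfig(n_participants=200,
                          archetypes=bv.default_archetypes(4, 4, 2), seed=3)
table = bv.simulate_ratings(cfg)
cmp_ = bv.fit_and_compare(bv.histogram(table, "disputed_1"))
print(cmp_.best_k, cmp_.best.spec.means)   # 2 (1.9308..., 6.0646...)
```

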