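# Methods

This package analyses the spatial patterning of "fairy circles" — roughly
circular barren patches, 2–12 m across, embedded in an arid short-grass
matrix — and the environmental and soil signals associated with them. No
field data ship with the package; a synthetic-data layer generates inputs
with the statistical structure the analyses assume, so the full chain is
exercisable and testable offline. This note records the models, the
parameter choices and their rationale, the numerical decisions, and what
the synthetic benchmarks do and do not demonstrate.

## Point patterns and the dispersion index

Circle centers are modelled as planar point processes in a rectangular
window. Four generators span the dispersion continuum:

* **Matérn cluster** (clumped): Poisson parents of intensity κ, each with
  Poisson(μ) offspring uniform in a disc of radius r. Children are wrapped
  toroidally so realized intensity equals κμ.
* **CSR** (random): n i.i.d. uniform points (binomial process).
* **Sequential hard-core inhibition** (over-dispersed): uniform proposals
  accepted only at distance ≥ δ from all accepted points. The simplest
  mechanism producing the over-dispersion attributed to inter-circle
  competition; a Strauss process would add an interaction parameter the
  data cannot constrain.
* **Jittered triangular lattice** (maximum dispersion): lattice spacing s
  with isotropic Gaussian positional jitter.

Dispersion is diagnosed by the Clark–Evans index
R = r̄_obs / r_exp with r_exp = 1 / (2√ρ), ρ = n/|W|. R = 1 under
randomness, R < 1 indicates clumping, and R = 2.149... (2.15 to 2 d.p.) is
the triangular-lattice ceiling. Significance uses the normal test
Z = (r̄_obs − r_exp) / (0.26136 / √(nρ)), two-sided at α = 0.05. No
finite-sample or perimeter edge correction is applied — instead a
**toroidal distance mode** (periodic window) is the default in simulation
studies, which removes edge bias exactly; plain euclidean distances are
the default for field tables, whose survey designs already embed their own
conventions. Empirically the Z-test's type-I error on toroidal CSR
(n = 100) is ≈ 6%, slightly liberal, consistent with the known small-n
behaviour of the normal approximation.

Landscape metrics per site: occupancy = 100·Σπr²/|W| (%), nearest-neighbor
periphery gap = center NN distance minus both radii floored at 0,
cumulative circumference = Σ2πr per hectare, plus mean/median/5th/95th
percentiles of areas and diameters, with SEs across sites for ensembles.

## Circle diameters

Field summaries constrain the diameter distribution only through its
median (4.8 m) and 5/95 percentiles (3.2 / 7.9 m). Diameters are drawn
lognormal: positive support and right skew (mean 5 > median 4.8) make it
the natural two-parameter choice. μ = ln(median) matches the median
exactly; σ is the average of the two one-sided percentile solutions
(≈ 0.275), leaving both tail percentiles within ~5% of their targets — a
two-parameter law cannot honour three quantiles exactly. An optional
non-overlap constraint resamples radii of intersecting pairs (bounded
retries).

## Rendering and detection

Scenes are rasterized at a configurable meters-per-pixel scale (default
0.5 m/px, matching high-zoom satellite tiles): barren discs bright
(default level 0.85) over a darker grass matrix (0.35) textured with a
smoothed Gaussian speckle field (tussocks), plus i.i.d. sensor noise,
clipped to [0, 1].

Detection is classical mathematical morphology: (1) orient polarity so
targets are foreground; (2) threshold (Otsu by default — the original
workflow's binarization rule is unstated, and Otsu is the standard
parameter-free choice for bimodal scenes); (3) opening with a disk
structuring element to erase sub-circle speckle; (4) 8-connected
labelling; (5) filters: area band in m², circularity 4πA/P² ≥ 0.6
(capped at 1; perimeter from the component boundary), and exclusion of
border-touching components (their areas are censored). All detection
parameters live in one declarative profile per run; there is no per-image
manual curation, trading a little accuracy for full reproducibility.

The structuring-element radius must be smaller than the smallest expected
circle radius in pixels: at 0.5 m/px the 5th-percentile diameter (3.2 m)
is a 3.2 px radius, so the default is 2 px; radius 3 would erase the
small-circle tail by construction.

Detection quality is scored against ground truth by greedy one-to-one
centroid matching within 2.5 m: precision, recall and the relative area
bias over matched pairs. On the default benchmark scene (100 hard-core
circles, 25 ha⁻¹, speckle sd 0.06, noise sd 0.04) the detector reaches
precision 1.00 / recall 0.98 with ~4% area underestimation — the same
direction and order as aerial-photograph analysis scored against ground
survey. The benchmark draws centers in an inset window so no disc touches
the border (border components are excluded by policy, which would
otherwise censor recall).

## Quantile envelopes

The upper limit of landscape occupancy along an environmental gradient is
summarized by the 90th conditional quantile, fitted as a **continuous
two-segment linear** function: basis [1, x, max(x − b, 0)] with the
breakpoint b grid-searched (default: 21 interior quantiles of x), each
candidate minimizing the pinball loss ρ_τ(u) = u(τ − 1[u<0]) via iteratively
reweighted least squares. A plain one-segment line competes as a
degenerate candidate, so the returned loss never exceeds the best single
line's; ties break toward the smaller breakpoint; identical x falls back
to the constant empirical quantile. One breakpoint suffices for the
unimodal envelopes the analysis targets; smoothing splines and confidence
bands are out of scope. The tent-surface benchmark draws
y | x ~ U(0, tent(x)/τ) so the true τ-quantile is exactly the tent; the
fit recovers the breakpoint to grid resolution and leaves 10 ± 3% of
points above the envelope.

## Boosted regression trees

Presence/absence is modelled by stagewise logistic boosting written from
first principles. With F₀ the log-odds of training prevalence, each stage
computes p = logistic(F), pseudo-residuals r = y − p, grows a regression
tree on a bag-fraction subsample by least-squares split gain (best-first,
at most `tree_complexity` splits — "tree complexity" read as the split
budget, i.e. interaction depth, with leaves = splits + 1), replaces each
leaf value with one Newton step Σr / Σp(1−p) over in-bag members, and
updates F by `learning_rate` times the tree. Minimum 10 observations per
leaf. All randomness flows from the config seed; identical inputs give
identical models.

Defaults mirror the field protocol: tree complexity 8, learning rate
5·10⁻⁴, bag fraction 0.5, binomial deviance, 10 stratified CV folds, and a
tree count keeping learning_rate × n_trees ≈ 3.6. The synthetic analyses
and benchmarks run the same product at learning rate 0.01 with 360 trees —
the boosting trajectory depends on lr·n_trees to first order, and 20×
fewer stages makes the repeated-CV experiments practical at these problem
sizes; simplification experiments use 5 CV folds for the same reason.

On top of the learner:

* **AUC**: rank-based (Mann–Whitney), ties half-credit; CV AUC is the
  mean ± SE over stratified held-out folds.
* **Relative influence**: per-variable sum of split squared-error
  improvements across all trees, normalized to 100%.
* **Simplification**: backward elimination of the lowest-influence
  predictor with CV deviance recorded for every candidate set on identical
  folds; the selected set is the most parsimonious within one SE of the
  minimum (the 1-SE rule). Evaluating the full path rather than stopping
  at the first deviance increase avoids stranding noise predictors on one
  noisy fold estimate.
* **Partial dependence**: response over a grid with other covariates at
  training means, reported on the link (log-odds) scale.
* **Pairwise interaction size**: joint partial dependence on a quantile
  grid minus its best additive (row + column) approximation; size =
  1000 × variance of the residual surface. The scale is arbitrary — only
  ordering and zero-vs-nonzero are meaningful (stump ensembles are exactly
  additive and score 0).
* **Grid prediction**: per-cell presence probability over co-registered
  covariate layers.

## Synthetic environmental survey

Sites draw covariates uniformly over the observed background ranges
(MAP 29–324 mm, EVI1 593–2067, BIO4 193–417); presence is 1 exactly inside
the nested niche box (MAP 52–135, EVI1 715–1281, BIO4 193–315) and 0
outside, then **every label is flipped independently with probability
`label_noise`** (default experiments use 0.05). The box volume ratio puts
noise-free prevalence at ≈ 5.9%, similar to a real image-curation survey.

A consequence worth stating plainly: with ≈ 5.9% prevalence, symmetric 5%
flips mean roughly half the *labelled* presences are false. The
Bayes-optimal score for the noisy labels is then box membership itself,
whose AUC against those labels is
P(in box | ỹ=1)·P(out | ỹ=0) + ½·(ties) ≈ 0.77. No model evaluated
against the noisy labels can beat this ceiling in expectation, so CV AUC
on these data plateaus near 0.77–0.80 — a property of the noise model, not
of the learner. The niche *structure* remains recoverable: the informative
covariates carry ≈ 90% of relative influence, simplification discards the
added pure-noise covariates, and the MAP partial-dependence curve steps up
inside the generating niche bounds. With label_noise = 0 the same learner
reaches CV AUC ≥ 0.95.

## Soil statistics

* **Depth weight-summing**: areal totals (kg m⁻²) over a profile as
  Σ (pct/100) · ρ_b · thickness with bulk density ρ_b = 1738 kg m⁻³;
  invariant to re-slicing layers; overlapping layers are rejected.
* **Summary t tests**: Welch by default from (mean, SE, n) —
  t = Δm/√(se₁²+se₂²) with Welch–Satterthwaite df; pooled variance
  optional; paired tests require raw pairs and are refused from summaries.
  Per-observation SD is reconstructed as SE·√n where raw draws are needed.
  No multiple-testing correction is applied across the soil variable set,
  matching the original presentation.
* **Fold ratios**: larger/smaller mean, rounded to one decimal (2.3-fold
  moisture contrast, 1.4-fold biomass contrast).
* **OLS**: ordinary least squares with intercept; coefficients, r², and
  the overall-F p value (e.g. the rainfall ~ latitude + longitude
  regression).
* **Interior correlation**: Pearson correlation of depth-summed soil
  moisture vs organic carbon restricted to transect stations within the
  circle radius.

The transect generator builds the inverse moisture–carbon relation in by
construction (moisture decays as exp(−(d/r)²) from the center; carbon
mirrors it), so the interior-correlation test demonstrates the statistic's
correctness, not an independent discovery.

## What the synthetic benchmarks do not show

The generators emulate summary structure (dispersion regimes, diameter
percentiles, niche box ranges, mean contrasts), not real landscapes: no
geographic gradients or projections, no multi-band spectra, no spatially
autocorrelated covariates, no partial circles/irregular margins, uniform
rather than survey-biased site sampling. Passing benchmarks therefore
validates the algorithms' correctness and calibration under the stated
models — it does not certify performance on real imagery or survey data,
where manual curation, autocorrelation and censored areas matter.

## Problem sizes

Default test/benchmark sizes: 500 CSR patterns of 200 points (plus 2000
patterns of 100 points for the type-I check), a 100-circle scene at
400×400 px, n = 2000 environmental sites, 10 seeded simplification runs at
5 CV folds, n = 2000 envelope points. These sizes keep every stochastic
assertion comfortably stable across seeds while the full suite runs in a
few minutes on one CPU.
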