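# Methods

This note documents the models, the numerical choices, and what the
synthetic validation does and does not establish.

## Trees and covariance structure

A `Phylogeny` is a rooted tree with strictly positive branch lengths in
time units; polytomies are preserved, zero-length branches are rejected
(or collapsed into polytomies with `collapse_zero=True`). A tree is
flagged ultrametric when all root-to-tip depths agree within 1e-6 of the
tree height — the tolerance is ours; time-calibrated trees from Bayesian
dating are ultrametric only up to annotation rounding.

The Brownian covariance `vcv` has entries C_ij = depth of MRCA(i, j).
Branch-length transforms:

* **Pagel's λ** multiplies off-diagonal entries by λ ∈ [0, 1]; values
  slightly above 1 from optimization are clipped with a warning. λ is
  bounded at 1 because values > 1 can leave the matrix non-PSD on trees
  with short tip branches.
* **OU (fixed root, single optimum)** on an ultrametric tree of height T:
  V_ij = e^{−2α(T − t_ij)}(1 − e^{−2α t_ij})/(2α) with t_ij = C_ij,
  scaled by σ² downstream. This is the common default of phylogenetic
  regression implementations; a non-ultrametric tree is an error rather
  than silently switching to the random-root form.
* **Early burst**: V_ij = (e^{a·t_ij} − 1)/a with a ≤ 0 and the a → 0
  limit t_ij, i.e. the rate decays as σ²e^{at}.

## Sprint-speed extraction

Per-interval speeds are Euclidean frame-to-frame displacements converted
to cm/s; gaps in the frame index divide by the actual frame delta. The
speed series (assigned to interval-midpoint times — immaterial at
100+ fps) is fitted with a penalized cubic B-spline: K = ⌊N/2⌋+1 knots at
quantiles of the observation times, exact integrated-squared-second-
derivative penalty, and penalty weight chosen by minimizing the GCV score
(coarse log-grid then bounded refinement). This reproduces the behaviour
of R's `smooth.spline` with `nknots = N/2+1` — checked to four decimals
on identical series during development. Negative fitted speeds are
clipped to zero. Mean speed is reported from the smoothed series (the raw
mean is also kept, since conventions differ).

Two caveats discovered while validating:

* With K ≈ N/2 knots the basis resolves an 8 Hz gait oscillation, so a
  *clean* oscillation is not attenuated — it is the tracking jitter that
  drives GCV toward smoothing. Oscillation removal therefore depends on
  the noise level; see the generator defaults below.
* The straightness filter (net displacement / path length ≥ 0.9, whole
  trials dropped) is computed on a ~20-segment coarsening of the path;
  on raw 500 fps coordinates the denominator is dominated by pixel
  jitter and even a perfectly straight run would fail.

Aggregation follows the study design: an individual's sprint is the
maximum over its trials; a species' value is the mean over individuals.

## Morphometrics

Spination index = Σ spine lengths / Σ front-leg segment lengths (coxa,
trochanter, pretarsus excluded); all spines are counted, including
permanently erect dorsal/lateral ones. Relative leg length = Σ hind-leg
segments / carapace width. Both are homogeneous of degree 0 in the length
unit. Species values average specimens arithmetically (the aggregation
used for morphology is not otherwise specified).

## Mk models of web evolution

The likelihood uses Felsenstein pruning with per-node rescaling; 2-state
transition probabilities are closed-form (no matrix exponential needed),
with a general-k expm fallback. Root priors: equal (½, ½) for ER/ARD;
for the Dollo model the root is fixed web-present, since with q₀₁ = 0 any
observed web requires a web-bearing ancestor. Rates are optimized on the
log scale in [1e-8, 1e3]; one-parameter models use bounded scalar search,
ARD uses L-BFGS-B from 5 seeded starts. AICc uses n = number of tips and
returns +inf when n ≤ k+1 (the correction diverges).

Marginal ancestral posteriors come from the up-down (re-rooting)
algorithm. Stochastic maps sample node states backward from the pruning
partials (joint conditional distribution), then branch histories
conditional on endpoints by forward rejection — with the first event
drawn from a truncated exponential when the endpoints differ — falling
back to exact uniformization sampling after 1000 rejections on a branch.

## Continuous-trait models and regression

All four models are Gaussian: z ~ N(z₀·1, σ²·T(C)). z₀ and σ² are
profiled analytically (GLS estimators) inside a bounded 1-D search over
the shape parameter (α ∈ [1e-8, 50]/T, a ∈ [−10/T, 0], λ ∈ [0, 1]), with
a 25-point grid before local refinement because these profiles can be
flat or multimodal. The OU optimum is tied to z₀ (single-regime, fixed
root). Within-species measurement error is not modelled. Ancestral values
(BM and λ; λ via the equivalent branch-length rescaling) use the two-pass
recursive GLS algorithm, which matches explicit joint-normal conditioning
to 1e-8 in tests.

`phylo_lm` maximizes the profile ML of the transformation parameter
(matching the referenced implementation's default of ML rather than
REML); coefficient tests are two-sided t with n − p df and the unbiased
residual variance. Binary predictors are coded 0/1 with the "absent"
level as baseline, so positive coefficients mean larger trait values in
web builders / cribellate / ground-dwelling species.

Effect sizes are unstandardized group mean differences over species means
(the species is the analysis unit), with percentile bootstrap CIs from
within-group resampling, B = 5000 by default; BCa intervals are available
as an option but percentile is the default because contrasts are reported
in trait units.

## Synthetic study generator

The generator is the test bed standing in for the field data. Defaults
(one choice each, documented here):

* **Trees**: birth–death, "simulate until n extant tips" plus one extra
  waiting time, retry cap 1000 (simplicity over exact conditioned
  samplers); fixtures rescale to height 50, a plausible crown age in Myr.
* **Web history**: ER with one change per lineage per tree height, which
  yields on the order of 20 transitions on a 60-species tree — emulating
  the highly dynamic foraging-mode evolution of the focal clade.
* **Sprint speeds**: λ-model on log speed (λ = 0.7, root 30 bl/s);
  spination: OU around 0.25.
* **Trajectories**: 500 fps, 100 px/cm, 1 cm body length, triangular
  speed profile peaking at 40 cm/s over 1 s, gait oscillation 0.15 body
  lengths at 8 Hz (lateral, with half-amplitude fore-aft component), and
  Gaussian tracking jitter of 2 px. The jitter value is an assumption
  (the empirical distribution of tracking error in the study's videos is
  unknown): 2 px ≈ 2% body length is a plausible localization accuracy
  for a soft abdomen-edge landmark, and sits in the middle of the regime
  where GCV smoothing removes the gait signal — below ~1.5 px the
  oscillation survives smoothing, above ~2.5 px the speed-magnitude noise
  bias (E‖v + ε‖ > ‖v‖) dominates. Per-trial peak speeds are drawn at
  85–100% of the species' true sprint, so species-level estimates sit a
  few percent below truth by construction, as in real trials where not
  every run elicits maximum performance.

All generators derive their RNG stream from (seed, call-tag), so outputs
are reproducible and adding calls does not disturb earlier ones.

What passing on synthetic data does **not** show: robustness to real
tracking artefacts (occlusions, lens distortion, non-Gaussian jitter),
to non-ultrametric empirical trees, to intraspecific trait variance, or
to model misspecification beyond the four fitted covariance families.

## Problem sizes used in validation

Likelihood oracles run on 100 random 2–6-tip trees (exhaustive
enumeration is exact there). Parameter recovery uses 300 tips (ER rate)
and 200 tips (σ², λ) with 100 seeds; PGLS type-I calibration uses 100
tips and 500 seeds; simmap-vs-posterior consistency uses 10,000 maps on a
fixed 6-tip instance; the end-to-end synthetic study uses 60 species with
2 individuals × 2 trials each. These sizes give Monte-Carlo error well
inside the asserted tolerances while keeping the full suite to a few
minutes on one core.

## Known limitations

* Likelihood cores are binary-state in the fitting surface (the pruning
  core accepts k states but nothing exposes it).
* No hidden-rate models, multi-optimum OU, rate shifts, or phylogenetic
  logistic regression.
* The Dollo root convention (fixed web-present) is one defensible choice;
  a configurable prior is exposed on `fit_mk`.
* AICc sample size n = tips is a convention; with few tips the correction
  dominates and model weights should be read cautiously.
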