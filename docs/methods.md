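# Methods

This note records the scientific and numerical choices behind
`weanabc`: the turnover model and its calibration, the forward isotope
model, the ABC-SMC sampler, the posterior summaries, and what the
synthetic-data tests do and do not demonstrate.

## Subadult bone turnover from tissue-level physiology

Bone collagen in a growing child is laid down by **modeling** (net
addition of tissue with skeletal growth) and replaced by **remodeling**
(coupled resorption and formation). We define the turnover rate over
the year [x, x+1] as the proportion of newly synthesized tissue
relative to the total at the end of the year, summing both processes;
it can exceed 1/yr when remodeling cycles tissue more than once.

Three ingredients are parameterized in `src/weanabc/_constants.yaml`:

- **Mineral mass growth** *M(x)*: a sum of three logistic components
  (grams vs years), anchored to reference skeletal-calcium values
  (~28 g at birth, ~100 g at 1 y, ~220 g at 5 y, ~400 g at 10 y,
  ~800 g at 15 y, plateau ≈ 1.1 kg). The modeling contribution to
  turnover is 1 − M(x)/M(x+1), the fraction of end-of-year mineral
  added during the year.
- **Trabecular remodeling** *R(x)*: log-quartic in age, ≈ 0.5/yr in
  infancy declining to ≈ 0.09/yr by the late teens, evaluated at
  mid-interval. Cancellous (rib-like) bone is intended; cortical bone
  turns over several-fold slower and is out of scope.
- **Mineralization law** *m(lag)*: cumulative fraction of a collagen
  cohort's final mineral load acquired by `lag` whole years after
  matrix formation; m(0) ≈ 0.825 (fast primary mineralization), with
  the secondary remainder split between a fast phase (≈ 27 % annual
  decay of the deficit) and a very slow phase. The slow phase is slower
  than most histomorphometric estimates of secondary mineralization;
  it functions here as a long-memory correction that the calibration
  required.

Mineral turnover is observed through the mineral phase, which lags
collagen formation: `k_min(x) = Σ_l Δm(l) · k_col(x−l)`. Collagen rates
are recovered by solving this triangular system from the 0–1 interval
upward — the only causally well-posed order. The inverse is exact: the
test suite re-convolves the collagen rates through the law and requires
the mineral signal back to 1e-6.

**Calibration.** The functional families above are standard, but
several constants are only loosely pinned by the tissue-level
literature. They were calibrated jointly — growth-curve parameters
within ±15 % of the mass anchors, remodeling and law parameters within
physiologically plausible ranges — against published estimates of
cancellous-bone mineral and collagen turnover in subadults, and then
frozen. The packaged constants reproduce those discrete rates to better
than ±0.01/yr in both phases. They are data, not code: revising them
requires no code change.

**Quartic smoothing.** The 20 discrete collagen rates are fitted by
least squares with a quartic polynomial in age, each interval's rate
attached to the interval **end** age (the rate over [x, x+1] recorded
at x+1). The end-age abscissa is what makes the polynomial's cumulative
integral behave correctly near birth: the fitted curve extrapolates to
≈ 1.78/yr at age 0 and integrates to 1.586 over [0, 1], with 96.6 %
cumulative replacement reached at 0.58 yr (~30 weeks). Evaluation
clamps the polynomial at a 1e-6/yr floor; the quartic is positive on
[0, 20] under the packaged constants, so the floor only matters for
user-supplied tables. Integrals use the closed-form antiderivative, not
quadrature.

## Forward model of bone-collagen δ¹⁵N

The diet signal (δ¹⁵N of newly synthesized collagen) is

- δ_mother + E for age ≤ t₁,
- δ_wnfood for age ≥ t₂,
- between them, a decaying exponential in normalized age
  u = (t − t₁)/(t₂ − t₁) with shape constant c = 3, affinely rescaled to
  hit both plateaus exactly. c = 3 leaves ~5 % of the gap to the
  rescaling, giving a visibly convex transition without a discontinuity;
  t₁ = t₂ degenerates to a step. The exact transition shape is a design
  choice — any smooth monotone interpolant consistent with "exponential
  change during weaning" differs by at most a few tenths of a permil at
  intermediate ages.

Collagen formed in utero carries the maternal value exactly (no
gestational enrichment), so the bone pool starts at δ_mother and
relaxes toward the diet signal: d(bone)/dt = rate(age)·(signal − bone).

**Integration.** The production integrator takes 0.02-yr steps; per
step it uses the closed-form integral of the quartic rate and the
closed-form step-average of the piecewise diet signal, updating
bone ← s̄ + (bone − s̄)·exp(−∫rate dt). Because the step-average is
exact even when a step straddles t₁ or t₂, no per-particle grid
splitting is needed and the scheme vectorizes across thousands of
parameter sets. Against a brute-force 0.001-yr Euler oracle of the same
mixing rule the worst disagreement across random parameter sets is
below 0.002 ‰ — an order of magnitude inside the 0.01 ‰ design target.
Note that exponential relaxation never replaces the pool completely: a
cumulative turnover integral of 0.966 corresponds to
1 − e^(−0.966) ≈ 62 % of the isotopic gap closed, not 96.6 %; the
"full reflection by ~31 weeks" reading treats integrated turnover ≈ 1
as complete replacement, which is exact only in whole-year bookkeeping.

Distance between an assemblage and a simulation is the mean squared
δ¹⁵N difference across subadult individuals, simulated at the observed
ages-at-death. The maternal reference is the adult-female mean with the
all-adult mean as fallback; Δwnfood is standardized against the
all-adult mean.

## ABC sequential Monte Carlo

The sampler (`abc_smc.run_abc_smc`) is generic over a batched
simulator. Per stage:

- tolerance = weighted median of the previous stage's distances (or a
  user-fixed, strictly decreasing schedule); the adaptive default is
  robust across datasets with different noise levels,
- particles already within tolerance are kept; the rest are replaced by
  resampling ancestors from the previous weighted population and
  perturbing with a component-wise Gaussian kernel of SD
  √(2 × weighted variance), retried until accepted (partial rejection
  control), with proposal batches oversized by the inverse running
  acceptance rate,
- every particle is reweighted by prior(θ) / Σⱼ wⱼ K(θ | θⱼ) (the
  kernel-corrected importance weight), and the population is
  systematically resampled whenever the effective sample size
  1/Σw² drops below n/2,
- support constraints (t₁ ≥ 0, t₂ ≥ t₁) are enforced by rejection in
  both prior sampling and perturbation, keeping the prior consistently
  truncated; the truncation normalizer cancels in the weights.

A stage aborts with a diagnostic naming the stage and tolerance if the
acceptance rate stays below 0.1 % after 50 proposals per particle. All
randomness flows from a single seeded generator, so identical seed +
config + data give bit-identical particle systems.

With the deterministic weaning simulator the tolerance cannot shrink
below the best achievable mean squared residual (≈ the noise variance),
so the posterior width is governed by the tolerance floor — the
behaviour that makes credible intervals conservative on recovery tests.
The sampler itself is validated on a stochastic conjugate-normal toy
(one free parameter, known σ), where 4 000 particles over 11 stages
reproduce the analytic posterior mean and SD to well within 5 %.

Defaults follow the archaeological application: 10 000 particles and
seven tolerance stages, priors N(0.5, 3.0²), N(3.0, 3.0²), N(1.9, 0.9²)
for (t₁, t₂, E) and N(adult mean, 3.0²) for δ_wnfood. The fourth prior
mean defaults to the population's all-adult mean (not an offset from
it); all means and SDs are per-run configurable, which also covers
populations needing tighter age priors.

## Posterior summaries

Posteriors are reported to one decimal place per parameter: weighted
Gaussian KDE (Silverman bandwidth via the effective sample size, with a
configurable scalar multiplier) evaluated on 0.1-wide cells centered on
multiples of 0.1, spanning the particle range padded by three
bandwidths, normalized to total mass 1. The MDE is the argmax cell —
joint over (t₁, t₂), marginal for E and δ_wnfood — with ties broken
toward smaller values and reported. The headline probabilities are the
masses of the single MDE cell (0.1 × 0.1 for the ages), matching the
flag thresholds of 0.0025 (joint) and 0.05 (marginal); arbitrary
windows are available through `range_probability`, which is additive
over disjoint windows and sums cells by center. Credible intervals use
weighted empirical quantiles of the raw particles (positions reduce to
the standard linear-interpolation quantile under uniform weights), not
the smoothed grid.

Suspect fits are flagged, never silently dropped: MDE cell
probabilities below the thresholds, and Δwnfood < −E (a weaning-food
value so depleted relative to the mother that the fitted trajectory is
biologically doubtful — the situation that warrants excluding a
population from comparative syntheses).

## Synthetic data, and what the tests show

`synthetic.generate_population` draws ages on [0, 10) — uniform by
default, or with half the deaths below 3 years to echo attritional
subadult mortality — evaluates the forward model under known
parameters, and adds independent Gaussian scatter (default 0.3 ‰, the
scale of within-population isotopic variability after measurement
error). The standard fixture uses ~20–30 subadults, weaning from 1.0
to 3.0 years, E = 2.4 ‰, and a weaning-food value 0.5 ‰ below the adult
mean — magnitudes typical of Holocene assemblages. Age estimates are
treated as exact; osteological age error is deliberately not simulated
(configurable data could be added, but it would convolve two error
sources the method does not separate).

Recovery tests run 20 seeded replicates at 2 000 particles and five
stages (a deliberate scale-down from the 10 000/seven defaults; the
posterior is slightly wider, which only makes coverage conservative)
and require each true parameter inside its 95 % interval in ≥ 18/20
replicates; observed coverage is 20/20. Passing these tests shows the
estimator is consistent **under its own generative model**. It does not
validate the model against real skeletal series — individual
heterogeneity in E, diagenesis, age-estimation error, and secular diet
change are all outside the synthetic generator — and no ground-truthed
human assemblage exists to test against.

## Known limitations

- The turnover constants are a calibration, not a measurement; rib-like
  cancellous bone is assumed, and applying the model to femora or
  crania will overstate how quickly bone tracks diet.
- The weaning-curve shape between t₁ and t₂ is conventional; data
  rarely constrain it beyond monotonicity.
- With deterministic simulation the ABC tolerance floor, not the data
  alone, sets the final posterior width; interpret absolute cell
  probabilities comparatively rather than as calibrated probabilities.
- The model always fits something: assemblages without a genuine
  nursing signal (flat δ¹⁵N, biased age structure) still yield MDEs.
  The flags catch the gross cases; inspect the data first.
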