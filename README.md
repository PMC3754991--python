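# weanabc

Quantitative reconstruction of breastfeeding and weaning practices from
cross-sectional nitrogen-isotope data of subadult skeletons.

Bone-collagen δ¹⁵N tracks dietary protein one trophic level up: an
exclusively breastfed infant forms collagen 2–3 ‰ above its mother, and
the signal decays toward the local diet as weaning foods replace breast
milk. A skeletal assemblage of subadults who died at different ages is
therefore a noisy, turnover-blurred snapshot of the weaning process —
blurred because bone is only partially rebuilt each year, so bone
collagen at death averages over the preceding diet history. `weanabc`
turns such data into posterior distributions over four weaning
parameters:

| parameter | meaning |
|---|---|
| *t₁* | age at the start of weaning (years) |
| *t₂* | age at the end of weaning (years) |
| *E* | maternal-to-infant δ¹⁵N enrichment (‰) |
| *δ¹⁵N_wnfood* | δ¹⁵N of collagen synthesized entirely from weaning foods (‰) |

It is written for bioarchaeologists and palaeodemographers working with
per-individual (age-at-death, δ¹⁵N) tables plus adult reference means.

## The model

**Turnover.** Subadult bone-collagen turnover is estimated from
tissue-level physiology rather than tracer extrapolation: a skeletal
mineral-mass growth curve *M(x)* and an age-dependent trabecular
remodeling rate *R(x)* give the per-year mineral turnover
*k_min(x) = 1 − M(x)/M(x+1) + R(x+½)*; the collagen rates *k_col* are
recovered by deconvolving the mineralization delay
*k_min(x) = Σ_l Δm(l)·k_col(x−l)*, where *m(lag)* is the cumulative
mineralization law (≈82 % primary, slow two-phase secondary). The 20
discrete collagen rates are smoothed into a quartic polynomial (QP) in
age; its closed-form integral is the cumulative replaced fraction
(1.586 over the first year of life under the packaged constants).

**Forward model.** Newly synthesized collagen carries δ¹⁵N_mother + *E*
before *t₁*, the weaning-food value after *t₂*, and a continuous
exponential transition in between. The bulk-bone pool relaxes toward
that diet signal at the QP turnover rate,
d(bone)/dt = rate(age)·(signal − bone), starting from the maternal value
at birth.

**Inference.** ABC sequential Monte Carlo with partial rejection
control: particles are drawn from truncated normal priors
(means {0.5, 3.0, 1.9, adult mean}, SDs {3.0, 3.0, 0.9, 3.0}), scored by
the mean squared difference between observed and simulated δ¹⁵N at the
observed ages, and resampled/perturbed through stages of shrinking
tolerance (default: seven stages, each tolerance the median of the
previous stage's distances, 10 000 particles). The weighted posterior is
smoothed by weighted kernel density estimation onto 0.1-resolution
cells; reported are maximum density estimators (MDEs), cell and range
probabilities, Δwnfood = δ¹⁵N_wnfood − adult mean, and weighted-quantile
credible intervals.

## Worked example

`python examples/fit_synthetic.py` generates 40 subadults from known
parameters (t₁=1.0, t₂=3.0, E=2.4, weaning food 0.5 ‰ below the adult
mean, 0.3 ‰ individual scatter) and refits them:

```
final tolerance: 0.166 (mean squared permil)
effective sample size: 2841 of 3000

parameter        truth    MDE     95% credible interval
t1               1.00    0.90     ( 0.06,  1.50)
t2               3.00    3.00     ( 1.55,  7.29)
enrichment       2.40    2.20     ( 1.82,  3.39)
d15n_wnfood      9.00    8.90     ( 8.57,  9.31)

delta_wnfood (weaning food minus adult mean): -0.60 permil
joint (t1,t2) cell probability:  0.0021
marginal cell probabilities:     E 0.087, weaning food 0.173
```

Every MDE lands within a grid cell or two of the truth and each true
value lies inside its 95 % interval; the joint (t₁, t₂) cell probability
is the posterior mass of the single 0.1 yr × 0.1 yr cell at the mode, so
small values simply mean the weaning-age posterior is spread over many
cells. `examples/turnover_table.py` and `examples/forward_trajectory.py`
walk the two underlying components.

The same pipeline is scriptable from the shell:

```sh
weanabc synth --t1 1 --t2 3 --e 2.4 --wnfood 9 --n 25 --seed 4 --out pop.csv
weanabc fit pop.csv --particles 2000 --stages 7 --seed 1 --out results/
weanabc turnover --out table.csv
```

A population CSV is one subadult per row (`id,age,d15n`) preceded by
`# adult_female_mean: …`-style header lines for the adult reference
statistics; individuals aged ≥ 10 years are excluded (with a log
message) and assemblages with six or fewer subadults are flagged.

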