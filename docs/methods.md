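# Methods

## System and scope

The package models a closed single-species metapopulation on a
microfluidic chip: 50 chambers ("patches", 2 mm diameter) connected by
channels, each chamber interfacing with three neighbours except the two
end chambers. Abundance in every patch is recorded each 6 min 20 s scan
cycle for 105 timesteps (~12 h). Conditions are spatially uniform; all
structure must therefore arise from movement and growth, which is what
the analysis battery is built to decide.

The raw experimental counts are not publicly deposited, so the package
generates experiment-like data itself (`synthetic_data`), under the
published study conditions: 14 runs, inoculation totals drawn uniformly
from 1159–5869 cells and spread over patches by uniform multinomial
sampling, growth 4.51 ± 0.76 d⁻¹, per-patch transition rate
60% ± 15% min⁻¹.

## Chip graph

The true channel wiring is not machine-readable from the publication;
`chip_topology.default_chip_layout()` ships a *reconstruction*: a
far-left and a far-right collector patch joined by two parallel 2×12
ladders. All 48 ladder patches have exactly three neighbours, the two
collectors have four, and the pairwise graph-distance set is exactly
1..13 — the range over which distance-resolved correlation summaries
are meaningful. Coordinates are in mm, x along the chip length
(origin at the far-left patch), y across the width; PERMANOVA position
terms use these two axes. Any other layout can be supplied as YAML/JSON
(`patches:`/`edges:`) or an edge-list CSV; validation enforces symmetry,
no self-loops and connectivity.

## Dynamical models

Both models integrate the linear mass balance

    dy_i/dt = g·y_i − y_i·Σ_k a_ik + Σ_k a_ki·y_k

with rates held constant within one recording interval, so each
interval is solved exactly by a matrix exponential (no Euler error; with
g = 0 the total is conserved to ~1e−15 per step, and the suite checks
1e−6 over a full run). Abundance is continuous-valued (no demographic
integer noise); observation noise, when wanted, is binomial thinning
(`add_detection_noise`), kept separate from the dynamics.

**Stochastic null model.** `A_t` is redrawn at every recorded timestep.
The calibration statement "60% ± 15% per minute" is read as the *total*
per-patch efflux (mode `per_patch_total`, the default): each patch's
total efflux ~ N(0.60, 0.15) min⁻¹ truncated at 0, split equally over
its neighbours. Because the published matrix notation could also mean
per-edge draws, mode `per_edge` (N(μ/deg, σ/deg) per directed edge) is
provided. Growth g is drawn once per run; the publication does not
state a redraw frequency, and a per-run draw reproduces the variance of
run-level growth fits.

**Density-dependent deterministic model.** The channel rate responds to
the *cumulative* abundance difference,

    a_ik(t) = clamp( μ/deg(i) + β·f( D_ik(t) / (scale·M(t)) ), a_min, a_max ),

where `D_ik(t) = Σ_{τ≤t}(y_i − y_k)` and `M(t) = Σ_{τ≤t} ȳ(τ)`
normalizes the argument so it stays dimensionless under growth. `f` is
an odd saturating response (tanh; swappable, since the published
functional form lives in supplementary material that is not part of the
text). The baseline μ/deg(i) makes β = 0 reduce *exactly* to the σ = 0
null model.

The sign of β selects the phenomenology. β > 0 (crowding-driven
dispersal down the cumulative gradient; default β = 0.6, scale = 0.2,
clamp [0, 1.2] min⁻¹) damps short-wavelength differences fastest and
leaves slowly decaying long-wavelength structure — smooth, global,
positively autocorrelated fields, the regime that reproduces the
ordering "deterministic model ≫ stochastic null" in both the
positive-autocorrelation rate and the significant-correlation rate.
β < 0 (retention/aggregation) amplifies peaks that are sensitive to the
initial condition but anti-correlated between direct neighbours. The
defaults were fixed once, on the criterion that the deterministic
hypothesis should produce positive spatial autocorrelation, and are not
tuned per analysis.

## Calibration generator and estimators

The single-patch calibration experiment (≥500 counts at 2-min
intervals) is emulated at event level: per interval a rate r ~ N(μ, σ)
truncated at 0 is drawn, efflux is binomial thinning of the occupants
at 1 − exp(−2r), influx is Poisson from a constant-density neighbour
pool (keeping the focal count stationary, as in the short calibration
recordings; a self-proportional influx would make the count a critical
random walk and destabilize the estimator). Only the per-minute summary
rate is constrained by the study; the event-level scheme is a modelling
stand-in and is documented as such. `estimate_transition_rate` inverts
each interval's efflux fraction to a per-minute exponential rate
(censoring complete-efflux intervals at (n−½)/n) and reports mean ± SD;
`estimate_growth_rate` is the OLS slope of log total abundance vs time,
converted to d⁻¹ — exact on model output because transitions cancel in
the total.

## Chaos battery

All estimators run per patch series. Abundances are analysed on a
log(1+count) scale by default to temper the exponential trend (raw
scale by flag; see Limitations).

**Embedding.** Lag τ = first local minimum of the average mutual
information (rank-uniformized histogram, lags 1–10), with a guard: a
minimum whose AMI sits at the estimator's independence floor
((bins−1)²/2n) means the series has simply decorrelated, and τ falls
back to 1 — this yields the standard τ = 1 for map-like and white-noise
series. Dimension E = smallest dimension whose false-nearest-neighbour
fraction (Kennel criteria, Rtol 15, Atol 2) drops below 10%, capped at
6 and by series length.

**Rosenstein LE.** Nearest neighbours under a Theiler exclusion of τ;
λ = least-squares slope of the mean log divergence over steps
1..min(10, T/10), per timestep. On the r = 4 logistic map the suite
requires λ ≈ ln 2 within 0.1. The estimator deliberately retains its
known defect — it cannot separate noise-driven from chaos-driven
divergence — because that defect is part of the study design.

**S-map Jacobian LE.** For each θ in {0, 0.1, …, 8} a locally weighted
linear map (intercept + E lag coefficients, weights exp(−θ‖Δx‖/d̄),
ridge 1e−8, leave-one-out) predicts the next value. θ* minimizes the
LOO RMSE, with two conservative guards: a larger θ must improve RMSE by
>1% (chance fluctuations cannot flag nonlinearity), and an essentially
perfect linear fit (RMSE < 1e−6 on standardized data) is never
overridden. λ is the leading growth rate of the product of per-point
companion Jacobians, accumulated by QR; for τ > 1 the companion product
is the standard approximation. The lower bound is the 5th percentile of
a stationary block bootstrap (200 resamples, mean block √T) over the
per-step QR log-stretching factors computed along the original
trajectory — bootstrapping the stretching increments rather than
re-multiplying resampled matrices is exact for E = 1 and orders of
magnitude faster for E > 1. The published analysis inherits its bound
construction from earlier software without restating it; this is the
package's documented stand-in.

**Classification.** `chaotic_nonlinear` iff lower bound > 0.01 per step
AND θ* > 0; lower bound > 0.01 with θ* = 0 is `chaos_growth_mix`
(exponential growth is a linear map and produces exactly this
signature); otherwise `not_chaotic`. The sliding-window variant uses
50-point windows at stride 1 and reports T − w windows (55 for
T = 105, matching the published count rather than the arithmetic
T − w + 1; the discrepancy is one window).

## Spatial and multivariate statistics

Moran's I uses binary chip adjacency, row-standardized by default; the
permutation test (default 12 000 draws, vectorized) is one-sided for
positive autocorrelation, since clustering is the phenomenon of
interest and negative autocorrelation was never observed in this
system. Note the interaction between permutation resolution and the
Holm family over 105 timesteps: with fewer than ~4 000 permutations the
smallest achievable p-value (1/(n_perm+1)) cannot clear the Holm
threshold 0.05/105, so reduced-permutation runs can only be used for
uncorrected screening. Pairwise Spearman correlations are computed on
total-normalized abundances (columns sum to 1, removing the shared
growth trend); all P(P−1)/2 tests form one Holm family; pairs with a
constant series are reported undefined.

Bray–Curtis dissimilarities between timepoint vectors and DTW distances
(classic symmetric-step dynamic programming, no window constraint)
between patch series feed a distance-based PERMANOVA: Gower-centred
matrix G, hat-matrix projection H of the (centred) covariates,
SS_term = tr(HGH), R² = SS_term/SS_total, pseudo-F with residual
degrees of freedom, p by permuting object labels. Time enters as the
continuous timestep index; position as continuous x and y coordinates
(separately and jointly), so length- and width-explained variance can
be compared. Categorical covariates are dummy-coded; on categorical
instances the implementation agrees with the brute-force
sum-of-squares partition and with scikit-bio's PERMANOVA statistic.
NMDS uses non-metric SMACOF (20 random starts, 500 iterations,
stress-1), reproducible from the seed.

## Study pipeline

Per experiment: mean normalized variance (population variance across
patches divided by the timestep total — doubling all counts doubles the
statistic), % timesteps with significant positive Moran I, % patch
pairs significantly correlated, % series positive under each LE method,
% chaotic after the θ filter, optional % locally unstable windows, and
PERMANOVA R² for time and position. Experiments are grouped into
HV/MV/LV by 1-D k-means (k = 3) on log mean normalized variance, labels
ordered by group mean; cut-points are user-overridable since the
published category thresholds are not printed. Group differences use
one-way ANOVA + Tukey HSD; the model-vs-experiment comparison uses
two-sided Wilcoxon rank-sum per metric with Holm correction across the
metric family. A single master seed fixes every stochastic stage; the
JSON report is byte-identical across reruns.

## Problem sizes

The shipped analysis defaults match the study protocol (12 000 Moran
permutations, 999 PERMANOVA permutations, 200 bootstrap resamples).
The test suite and the acceptance script run reduced but statistically
adequate versions chosen once: a 20-run null ensemble (1000 patch
series) for the chaos rates, 4 999 Moran permutations and 3 replicates
per arm for the model-ordering check, 99–499 permutations for
calibration-of-null checks.

## Limitations

- The chip wiring and the deterministic model's response function are
  reconstructions; both are inputs/options, not ground truth.
- The LE analysis scale (raw vs log) is not stated in the publication.
  On log scale the null model's Jacobian exponents are slightly
  negative (matching the published qualitative description) and the
  positive-classification rate is ~0%, slightly below the published
  model-side 0.8%; on raw scale growth dominates and the rate is far
  too high. The log default is kept; the residual sub-percent gap is
  attributable to unstated details of the original pipeline.
- The synthetic experiments emulate the study's sampling design, not
  real ciliate behaviour: no behavioural states, no resource or oxygen
  feedbacks, no video/detection artefacts beyond optional binomial
  thinning. Passing tests therefore validate the machinery and its
  statistical properties, not biological claims about real data.
- Continuous-state ODEs ignore demographic stochasticity, which matters
  at very low per-patch counts.
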