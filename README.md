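# patchchaos

Simulation and analysis of single-species spatio-temporal pattern
formation on a microfluidic patch network — a metapopulation of 50
interconnected 2-mm chambers in which a growing ciliate population
redistributes itself by active movement. The package asks the question
such experiments pose: are the observed distribution patterns
deterministic self-organization, or just stochastic fluctuation? It is
aimed at ecologists and biostatisticians analysing patch-resolved
abundance time series.

## What it provides

**Two dynamical models** on a chip graph `G` with patches `i = 1..50`:

- a **stochastic null model**: 50 coupled ODEs
  `dy_i/dt = g·y_i − y_i·Σ_k a_ik + Σ_k a_ki·y_k`, where the per-minute
  transition matrix `A_t = (a_ik)` is redrawn every recorded timestep
  (6 min 20 s) from a truncated normal calibrated at 60% ± 15% total
  per-patch efflux per minute, and `g ~ N(4.51, 0.76) d⁻¹` is drawn once
  per run. All spatial structure it produces is noise.
- a **density-dependent deterministic model**: the same mass balance,
  but `a_ik(t) = clamp(μ/deg(i) + β·f(D_ik(t)), a_min, a_max)` with
  `D_ik` the (normalized) cumulative abundance difference across the
  channel and `f` a saturating odd response. Movement that responds to
  accumulated crowding generates self-organized structure from the
  initial condition alone.

**The detection battery** applied per experiment (P×T abundance matrix):

- Lyapunov exponents per patch series: the direct Rosenstein estimator
  (slope of the mean log divergence of embedded nearest neighbours) and
  the S-map Jacobian estimator (leave-one-out–selected local weighting
  θ; λ from QR products of fitted companion Jacobians, with a block-
  bootstrap lower bound). A series counts as chaotic only when the
  lower bound exceeds 0.01 **and** θ > 0 — a positive exponent under a
  globally linear model (θ = 0) is classified as a growth/chaos mixture.
  A 50-point sliding window gives local instability (55 windows for
  T = 105).
- Moran's I spatial autocorrelation per timestep on the chip adjacency,
  with a 12 000-draw permutation test and Holm correction.
- Pairwise Spearman correlations between total-normalized patch series
  (Holm-corrected), summarized against graph distance.
- Bray–Curtis dissimilarity between timepoints and DTW distance between
  patch series, each fed into a distance-based PERMANOVA (`R²` for time
  and for chip position), plus NMDS ordination.
- Study level: normalized variance (across-patch variance / total),
  HV/MV/LV experiment categories, ANOVA + Tukey across categories, and
  Wilcoxon rank-sum (Holm family) for model-vs-experiment comparison.

## Worked example

```python
from patchchaos import default_chip_layout, SimulationConfig, run_stochastic_model
from patchchaos.synthetic_data import (estimate_growth_rate,
                                       generate_calibration_series,
                                       estimate_transition_rate)
from patchchaos.study_pipeline import summarize_experiment, AnalysisConfig

chip = default_chip_layout()                       # 50 patches, degree 3
series = run_stochastic_model(chip, SimulationConfig(seed=0), init=2500.0)
print("growth rate (d^-1):", round(estimate_growth_rate(series), 2))

cal = generate_calibration_series(mu=0.60, sigma=0.15, n_obs=500, seed=0)
mean, sd = estimate_transition_rate(cal)
print(f"transition rate: {100*mean:.1f}% +/- {100*sd:.1f}% per minute")

summary = summarize_experiment(series, chip, AnalysisConfig(seed=0))
print(f"moran+ {summary.pct_moran_positive:.1f}%  "
      f"corr {summary.pct_pairs_correlated:.1f}%  "
      f"rosenstein+ {summary.pct_rosenstein_positive:.1f}%")
```

prints

```
growth rate (d^-1): 4.12
transition rate: 59.6% +/- 17.3% per minute
moran+ 0.0%  corr 0.0%  rosenstein+ 94.0%
```

Read: the null run grew at 4.12 d⁻¹ (one draw from N(4.51, 0.76)); the
synthetic calibration recovered the 60%/min movement rate; and the null
model shows **no** significant spatial autocorrelation or inter-patch
correlation — while its Rosenstein exponents are overwhelmingly
"positive", the known failure mode of the direct method on noisy data.
Running the same summary on the density-dependent model from the same
inoculation gives `moran+ 77.1%  corr 32.3%`: deterministic
self-organized structure that the null cannot produce.

A CLI wraps these steps:

```
patchchaos simulate --model deterministic --seed 1 --out-dir out
patchchaos calibrate --seed 1
patchchaos analyze out/deterministic_seed1.csv
patchchaos study --n-experiments 14 --n-model 50 --seed 1
patchchaos fixtures --out-dir fixtures
```

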