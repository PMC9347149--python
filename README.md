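# tmbbias

Statistical bias and depth-inconsistency in tumour mutation burden (TMB)
estimation.

TMB — the number of somatic mutations per megabase with variant allele
frequency (VAF) above a threshold τ (typically 0.05) — is used as a
biomarker for immunotherapy response. This package quantifies two reasons
why the standard "count mutations above τ" estimator is biased and unstable
across sequencing depths, and implements a spectrum-model alternative:

1. **Truncation bias.** A mutation is only recorded when enough mutant
   reads are seen, so the retained mutant-read count at depth *N* is a
   left-truncated binomial. The retained proportion overestimates the true
   frequency *f*; for the zero-truncated case its expectation is
   *f* / (1 − (1 − *f*)^*N*), and truncation at τ·*N* inflates it much
   further. Fisher's maximum-likelihood estimator for the truncated
   binomial removes this bias.
2. **Threshold-crossing asymmetry.** Even with unbiased frequency
   estimates, sampling noise moves sites across the threshold
   asymmetrically. For a Beta(α, β) subclonal frequency spectrum the true
   above-threshold count is

   T = (1 − F_B(τ; α, β)) · S,

   while the expected observed count at per-site depths d_i is

   E = Σ_i (1 − F_BB(⌈d_i·τ⌉ − 1; d_i, α, β)),

   with F_B the beta CDF, F_BB the beta-binomial CDF and S the total number
   of somatic mutations. The relative error (E − T)/T is large and positive
   at moderate depth whenever the spectrum is steep at τ (many low-frequency
   subclonal mutations), and vanishes only as depth → ∞. The same mechanism,
   combined with depth-dependent detection, makes threshold TMB correlate
   with sequencing depth and drop when reads are down-sampled.

The proposed remedy is to use *all* detected mutant-read counts: fit a
truncated beta-binomial likelihood for (α, β), recover the total abundance
by inverse-probability weighting Ŝ = Σ_i 1 / P(X ≥ c_i; d_i, α̂, β̂), and
report TMB = [n_clonal + Ŝ·(1 − F_B(τ; α̂, β̂))] / Mb.

## Layout

- `src/tmbbias/` — the library: `trunc_binom` (truncated binomials +
  Fisher ML), `spectrum_model` (T, E and relative-error theory),
  `synthetic_data` (tumour-sample simulator with purity, depth models,
  read thinning, TSV/VCF output), `tmb_pipeline` (threshold and
  spectrum-model TMB estimators), `experiments` (cohort-level drivers).
- `analysis/01…06_*.py` — numbered narrative analyses writing tables to
  `results/`.
- `tests/` — pytest suite, including end-to-end acceptance checks.

## Worked example

```sh
python analysis/06_model_vs_threshold.py
```

```
True TMB (above tau=0.05): 50.64 mutations/Mb
  threshold estimator: mean 56.08, mean |relative error| 0.108
  model estimator:     mean 50.67, mean |relative error| 0.015
  model closer to truth in 99/100 replicates
```

Each replicate simulates 50 clonal plus 5,000 subclonal mutations with a
steep Beta(0.1, 100) VAF spectrum at depth 100 over 1 Mb. Only ~0.6
subclonal mutations truly exceed τ = 0.05, but threshold counting reports
~6 — an order-of-magnitude overestimate of the subclonal contribution —
because noise pushes sub-threshold sites upward. The spectrum-model
estimator, fitted to every detected count, recovers the truth to ~1.5%.

The library is also scriptable directly:

```python
from tmbbias import (BetaSpectrum, SimulationConfig, DepthModel,
                     simulate_sample, estimate_tmb_threshold)

cfg = SimulationConfig(n_clonal=50, n_subclonal=5000,
                       subclonal_spectrum=BetaSpectrum(0.1, 100),
                       depth_model=DepthModel.fixed(100), seed=1)
sample = simulate_sample(cfg)
print(estimate_tmb_threshold(sample, tau=0.05, min_alt_reads=3).tmb)
```

and exposes a CLI (`tmbbias bias-curve`, `tmbbias simulate`, `tmbbias tmb`,
`tmbbias experiment`); see `tmbbias --help`.

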