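# tfkinetics

Quantitative analysis of how a transcription factor engages chromatin,
implemented as a tested, reusable Python library with a thin command-line
front end. It was built around the measurements used to characterize the
melanocyte master regulator MITF and its acetylation-mimetic mutants — but
every stage is generic: it applies to any factor imaged by single-molecule
tracking (SMT), titrated by fluorescence anisotropy, or profiled by ChIP.

The package covers four analyses, each exercisable end-to-end on synthetic
data with known ground truth:

1. **Diffusion-state decomposition (fast imaging, 100 fps).** Single-molecule
   displacement magnitudes r between consecutive frames are histogrammed
   (Δr = 20 nm) and fitted with a three-component Brownian mixture,

       p(r) = r Δr Σᵢ Fᵢ / (2 Dᵢ Δt) · exp(−r² / (4 Dᵢ Δt)),   i = 1..3,

   where Δt is the frame interval (10 ms), Fᵢ the state occupancies and Dᵢ
   the diffusion coefficients with D₁ < D₂ < D₃. The slowest state
   (D₁ ≈ 0.034 μm²/s, histone-like) represents chromatin-bound molecules, so
   F₁ is the bound fraction. Per-cell statistics are compared across
   conditions with the Kruskal–Wallis rank test.

2. **Residence times (slow imaging, 2 fps, 200 ms exposure).** Immobile-track
   dwell durations (≥ 5 frames = 2.5 s) populate the empirical survival
   function S(t) = 1 − CDF. Apparent unbinding caused by photobleaching is
   removed by dividing S(t) by exp(−k_b t), with k_b the slowest rate of a
   two-exponential fit to an H2B control (k_b ≈ 0.0316 s⁻¹). The corrected
   curve is summarized as the restricted mean survival time
   RMST = ∫ S(t) dt over [2.5, 100] s and the fraction of events outliving
   100 s, with delete-half resampling (1000 replicates) error bars.

3. **Binding affinity by fluorescence anisotropy.** With probe concentration
   C (1.33 nM) comparable to K_D, the bound fraction follows the quadratic
   ligand-depletion isotherm

       y = B₀ + (B_max − B₀) · (C + x + K_D − √((C + x + K_D)² − 4Cx)) / (2C),

   fitted per replicate; the reported K_D is the replicate mean ± SD, and
   conditions are compared by affinity ratios with unpaired two-tailed
   t-tests.

4. **E-box motif classes under ChIP peaks.** Each peak sequence is scanned on
   both strands for CACGTG / CATGTG cores and assigned one extended-E-box
   class by priority (TCACGTGA > TCACGTGB > TCATGTGA > TCATGTGB >
   CACGTG_other > CATGTG_other > none, B = C/G/T), yielding per-condition
   class-ratio tables and a 100-peak moving average of motif incidence along
   the peak-score ranking.

A seeded synthetic-data module (`tfkinetics.sim`) generates displacement
mixtures, censored dwell times, noisy titrations and peak sequences with
planted motif classes, recording the ground truth of every call.

## Worked example

```python
from tfkinetics import WT_MITF, simulate_jumps, fit_three_component
from tfkinetics.diffusion import histogram_from_jumps

jumps = simulate_jumps(WT_MITF, 200_000, seed=1)   # 44/34/22% mixture
fit = fit_three_component(histogram_from_jumps(jumps, WT_MITF.dt))
print(fit.params.fractions, fit.params.coeffs)
```

prints (run `python examples/01_diffusion_fit.py` for the narrated version):

```
fitted   F = (0.429, 0.340, 0.231)  D = (0.0354, 0.452, 3.51) um^2/s
bound fraction F1 = 42.9%  (sse=7.59e-06, converged=True)
```

i.e. from 2×10⁵ simulated displacements the fit recovers the generating
bound fraction (44%), slow fraction (34%) and all three diffusion
coefficients (0.034 / 0.46 / 3.4 μm²/s) to within a few percent. The other
scripts in `examples/` walk through the residence-time, K_D and motif
analyses the same way, and the `tfkinetics` console command exposes each
stage (`simulate`, `diffusion-fit`, `residence`, `anisotropy`, `motif`,
`all`) with TSV outputs and a JSON run manifest.

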