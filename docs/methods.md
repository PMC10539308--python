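# Methods

This note documents the models, conventions and design choices behind
`tfkinetics`, in the spirit of a statistical-methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Displacement-distribution model (fast regime)

Molecules imaged at 100 fps (Δt = 10 ms) are modelled as a population in
three non-interconverting Brownian states. For a 2-D Brownian state with
coefficient D, each displacement component is Gaussian with variance 2DΔt,
so the displacement magnitude is Rayleigh with scale √(2DΔt) and the
probability of landing in a histogram bin of width Δr centred at r is
approximated by the midpoint rule as

    p(r) = r Δr Σᵢ Fᵢ/(2DᵢΔt) · exp(−r²/(4DᵢΔt)).

Assumptions: free 2-D diffusion within the acquisition interval (no motion
blur or defocalization correction), no localization error in the model
(the simulator can add a per-axis Gaussian σ_loc for robustness studies, off
by default), and no state switching within a jump. A Dᵢ = 0 component is a
point mass in the first bin.

**Fitting.** The objective is least squares between empirical per-bin jump
fractions and p(r), matching the histogram-based procedure standard in SMT
kinetic modelling; an optional MLE on raw jumps is deliberately not the
default. Fractions are parameterized by stick-breaking on the simplex and
coefficients on log₁₀ scale inside the default boxes D₁ ∈ [10⁻³, 0.1],
D₂ ∈ [0.05, 2], D₃ ∈ [0.5, 20] μm²/s. Eight multi-starts on a log-spaced D
grid guard against local minima; the lowest residual sum of squares wins,
ties broken toward smaller D₁. Components are reported sorted D₁ < D₂ < D₃.
D₁ is free by default because histone-like values emerge from the data on
their own; `fix_d1` pins it for the fixed-coefficient convention. Per-cell
fits are the primary mode; pooled fitting is explicit and labelled.

**Reference parameter sets.** `WT_MITF` encodes the median WT state
occupancies (44% bound, 34% slow, 22% fast) and coefficients (0.034, 0.46,
3.4 μm²/s); `HALO_CONTROL` encodes the 13% bound fraction of the
unconjugated-tag control. Only the control's bound fraction is an observed
reference; the split of its mobile 87% is not, so the package adopts
(0.13, 0.27, 0.60) — free tag mostly fast-diffusing — with the WT
coefficients.

**Group comparison** uses the tie-corrected Kruskal–Wallis H test per
statistic across per-cell values, with medians and quartiles reported; two
groups with no rank variation yield H = 0, p = 1 rather than an error.

## Residence-time analysis (slow regime)

Slow movies (0.5 s frames, long exposure) blur diffusing molecules; tracked
spots are treated as bound. Dwell extraction substitutes an explicit
algorithmic criterion for visual kymograph scoring: a dwell is a maximal run
of consecutive-frame localizations whose inter-frame displacements stay
below `r_immobile` (default 0.2 μm, configurable); this is a documented
deviation from purely visual scoring. A run of n localizations scores
n × frame_interval seconds (5 frames ↔ 2.5 s), runs shorter than
`min_frames` = 5 are dropped, and runs reaching the end of a track are
flagged censored.

The empirical survival is S(t) = P(T ≥ t), normalized to 1 at the minimum
scoreable duration. Censored dwells are **included** as observed durations by
default, mirroring a raw 1−CDF of track durations whose bleaching component
is removed analytically afterwards; `censoring="exclude"` and a Kaplan–Meier
mode are provided for sensitivity analysis.

**Photobleaching correction.** The H2B control survival is fitted with a sum
of two (configurable) exponentials by weighted least squares (binomial
weights), rates log-scaled, weights on the simplex, multi-start over a rate
grid; the slowest rate is taken as k_b, with an identifiability warning when
rates are within 3×. The observed curve is divided by exp(−k_b t) — the
absolute-time convention — and renormalized at 2.5 s; the offset convention
exp(−k_b (t − 2.5)) differs only by that normalization constant. Correction
can push S above 1 when unbinding is slower than sampling noise; curves are
not clipped. A warning fires when the correction inflates the curve more
than 10-fold (over-correction).

**Summaries.** RMST is the trapezoidal integral of the (step-interpolated)
corrected curve over [2.5, 100] s, bounded by 97.5 s; the long-binder
fraction is S(100). Error bars are the standard deviations of both
statistics across 1000 delete-half replicates (drop ⌊n/2⌋ dwells, rebuild
the curve with the same k_b, recompute); no SEM rescaling is applied because
the delete-half convention does not define one — a multiplier can be applied
downstream if desired. A window end beyond the observed support raises an
error instructing truncation rather than silently extrapolating.

## Anisotropy isotherm

The quadratic (ligand-depletion) isotherm is evaluated with the discriminant
clipped at zero against round-off; it is monotone in protein concentration
for B_max > B₀ and reduces to the hyperbolic isotherm as C → 0. Baseline
(free-probe) subtraction happens before fitting; the raw-plus-baseline CSV
path performs it internally. Each replicate is fitted independently with
K_D, B₀ and B_max free and C fixed (default 1.33 nM); initialization uses
the half-maximal concentration for K_D and the observed extremes for
B₀/B_max. The reported K_D is the replicate mean ± SD. Affinity comparisons
default to unpaired two-tailed t-tests on replicate K_D values; a
per-measurement-point t-test mode (`pointwise_tests`) is also provided, and
neither mode is asserted to be the only valid reading of triplicate assays.

## E-box classification

The seven-class scheme (TCACGTGA, TCACGTGB, TCATGTGA, TCATGTGB,
CACGTG_other, CATGTG_other, none; B = C/G/T) covers every extended E-box
variant the analyses distinguish and is an interpretation choice — consensus
sets in the literature are not always enumerated explicitly. Both strands
are scanned with overlapping matches; flanks are read on the strand of the
match, N never matches a core or flank, and edge cores lacking a flank fall
to their core's `_other` class. The highest-priority class wins; ties break
toward the leftmost plus-strand core. Scanning both strands makes the label
strand-symmetric by construction. The moving-average analysis sorts peaks by
descending score and uses a centred window (pandas convention: an even
window of 100 covers ranks i−50..i+49) truncated at the edges.

## Synthetic-data generators

The generators emulate exactly the statistical structure the estimators
assume: displacement mixtures with per-axis variance 2DᵢΔt; dwell times as
exponential mixtures competing with Exp(k_bleach) bleaching and movie-end
truncation (uniform start times, durations floored to whole frames);
titrations as the quadratic isotherm plus i.i.d. Gaussian noise; peak
sequences as i.i.d. background at GC 0.41 (human-like, configurable) with
exactly one planted class 8-mer on a random strand, resampled on background
collision so the planted class is guaranteed. Features of real data that
are **not** emulated — and that passing recovery tests therefore say nothing
about — include localization error and tracking mistakes, state
interconversion within trajectories, non-exponential (e.g. power-law) dwell
distributions, spatially varying background composition, and motif
multiplicity under real peaks. The dwell-time distribution family of real
factors is unknown; the exponential mixture is a modelling choice for
testing, not a biological claim.

Every generator takes an explicit integer seed (same seed ⇒ bit-identical
output) and returns a `GroundTruth` record that round-trips through JSON;
the CLI writes these into run manifests together with input digests and the
package version.

## Problem sizes and numerical choices

Recovery checks use 2×10⁵ jumps for the displacement fit (the per-cell
order of magnitude of the assay), 10⁵ molecules for bleach-rate and
survival recovery, triplicate 12-point titrations, and 5×10³–10⁴ peaks for
motif proportions — sizes chosen so Monte-Carlo error sits well inside each
tolerance while the whole suite runs in well under a minute per module.
The bleach-rate simulation uses a 2000 s movie so uniform-start movie-end
truncation (a (1 − t/L) factor on the observed survival) is negligible over
the observed support. Optimizer tolerances are 10⁻¹² (xtol/ftol) throughout;
trapezoidal RMST error on a 0.5 s grid is far below the 0.1 s check used in
tests.

## Known limitations

* No defocalization / z-escape correction in the diffusion model; bound
  fractions from thick nuclei will be biased accordingly.
* The immobility-radius dwell criterion is a proxy for kymograph scoring;
  its r_immobile threshold interacts with localization precision.
* The bleach correction assumes a single, time-homogeneous bleaching rate
  shared between the control and the factor of interest.
* The isotherm assumes 1:1 binding; cooperative or dimerization-coupled
  models are out of scope.
* Motif classification is literal 8-mer matching; no position-weight-matrix
  scoring or de novo discovery.
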