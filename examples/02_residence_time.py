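"""Residence-time survival analysis with photobleaching correction.

Simulates a slow-movie experiment (2 fps, 200 ms exposure regime): a
two-population binder (70% with k_off = 0.05/s, 30% with 0.01/s) imaged under
photobleaching at k_b = 0.0316/s, plus an H2B-like control whose slowest
decay estimates k_b. The corrected survival curve is summarized as the
restricted mean survival time (RMST) on [2.5, 100] s and the fraction of
binding events outliving 100 s, with delete-half resampling error bars.
"""

from tfkinetics import (
    SlowMovieConfig,
    correct_bleaching,
    estimate_bleach_rate,
    simulate_slow_movie_dwells,
    summarize_residence,
    survival_curve,
)

K_BLEACH = 0.0316  # s^-1

# H2B control: stable incorporation (no unbinding) + a fast exchange component
h2b_cfg = SlowMovieConfig(
    frame_interval=0.5, movie_length=2000.0,
    k_off_components=((0.4, 0.15 - K_BLEACH), (0.6, 0.0)), k_bleach=K_BLEACH,
)
h2b_dwells, _ = simulate_slow_movie_dwells(h2b_cfg, 50_000, seed=11)
bleach = estimate_bleach_rate(h2b_dwells, n_components=2)
print(f"estimated photobleaching rate k_b = {bleach.k_b:.4f}/s (truth {K_BLEACH})")

# factor of interest: mixture of transient and stable binding
tf_cfg = SlowMovieConfig(
    frame_interval=0.5, movie_length=300.0,
    k_off_components=((0.7, 0.05), (0.3, 0.01)), k_bleach=K_BLEACH,
)
dwells, _ = simulate_slow_movie_dwells(tf_cfg, 20_000, seed=12)
curve = correct_bleaching(survival_curve(dwells), bleach.k_b)
summary = summarize_residence(curve, dwells, n_resamples=200, seed=13)

print(f"n = {summary.n_molecules} scored binding events (>= 2.5 s)")
print(f"RMST [2.5, 100] s = {summary.rmst:.1f} +/- {summary.err_rmst:.1f} s")
print(f"fraction bound > 100 s = {summary.frac_gt_end:.3f} +/- {summary.err_frac:.3f}")
# The RMST is the average time a scored molecule stays bound within the
# window; without the bleach correction it would be biased low because
# fluorophore loss masquerades as unbinding.
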