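import numpy as np
import pytest

from tfkinetics import WT_MITF, DiffusionParams, SlowMovieConfig


@pytest.fixture(scope="session")
def wt_params() -> DiffusionParams:
    """Median WT parameter set used throughout recovery tests."""
    return WT_MITF


@pytest.fixture(scope="session")
def wt_jumps_large(wt_params):
    """2x10^5 displacement magnitudes from the WT mixture (shared, seeded)."""
    from tfkinetics import simulate_jumps

    return simulate_jumps(wt_params, 200_000, seed=20_001)


@pytest.fixture(scope="session")
def h2b_like_config() -> SlowMovieConfig:
    """H2B-like slow-movie conditions: slow exchange + bleaching at 0.0316/s.

    Observed decay rates are the sum of unbinding and bleaching, so a
    0.1184/s exchange component plus the 0.0316/s bleach rate yields apparent
    rates of 0.15 and 0.0316 per second. The long movie keeps uniform-start
    movie-end truncation negligible over the observed support.
    """
    return SlowMovieConfig(
        frame_interval=0.5,
        movie_length=2000.0,
        k_off_components=((0.4, 0.15 - 0.0316), (0.6, 0.0)),
        k_bleach=0.0316,
        min_frames=5,
    )


def mixture_survival_at(params: DiffusionParams, r: float) -> float:
    """Closed-form mixture CDF used as an independent oracle in tests."""
    return float(
        sum(
            f * (1.0 - np.exp(-(r**2) / (4.0 * d * params.dt)))
            for f, d in zip(params.fractions, params.coeffs)
        )
    )
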