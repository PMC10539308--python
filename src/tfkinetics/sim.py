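"""Synthetic-data generators with recorded ground truth.

Every generator here emulates the statistical structure that the downstream
analyses assume, so that each estimator in the package can be exercised
end-to-end against known truth:

* fast-regime displacements — a three-state Brownian mixture (per-axis
  variance ``2 D_i Δt``, so displacement magnitudes are Rayleigh mixtures);
* slow-regime dwell times — exponential-mixture unbinding competing with
  exponential photobleaching and movie-end truncation, discretized to whole
  frames;
* anisotropy titrations — the quadratic (ligand-depletion) isotherm plus
  i.i.d. Gaussian noise;
* ChIP-peak sequences — random background of a stated GC content with exactly
  one planted extended E-box of a chosen class.

All generators take an explicit integer seed and are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np

from .tracks_io import Track, TrackSet

__all__ = [
    "DiffusionParams",
    "SlowMovieConfig",
    "GroundTruth",
    "WT_MITF",
    "HALO_CONTROL",
    "H2B_BLEACH_RATE",
    "simulate_jumps",
    "simulate_tracks",
    "simulate_slow_movie_dwells",
    "simulate_slow_movie_tracks",
    "simulate_titration",
    "simulate_peakset",
]


@dataclass(frozen=True)
class DiffusionParams:
    """Three-component Brownian mixture: fractions, coefficients, frame interval.

    ``fractions`` are the occupancies F1..F3 (sum to one) of the immobile,
    slow and fast states; ``coeffs`` the matching diffusion coefficients
    D1 < D2 < D3 in μm²/s; ``dt`` the acquisition interval Δt in seconds.
    """

    fractions: tuple[float, float, float]
    coeffs: tuple[float, float, float]
    dt: float

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        d = np.asarray(self.coeffs, dtype=float)
        if f.shape != (3,) or d.shape != (3,):
            raise ValueError("need exactly three fractions and three coefficients")
        if np.any(f < 0):
            raise ValueError("fractions must be nonnegative")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1 (got {f.sum():.12f})")
        if d[0] < 0 or not (d[0] < d[1] < d[2]):
            raise ValueError("diffusion coefficients must satisfy 0 <= D1 < D2 < D3")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def as_dict(self) -> dict:
        return {"fractions": list(self.fractions), "coeffs": list(self.coeffs), "dt": self.dt}


#: Median WT MITF parameter set (fractions immobile/slow/fast and their
#: diffusion coefficients in μm²/s) at the 10 ms fast-imaging interval.
WT_MITF = DiffusionParams(fractions=(0.44, 0.34, 0.22), coeffs=(0.034, 0.46, 3.4), dt=0.01)

#: Unconjugated-HaloTag control: 13% immobile fraction; the split of the
#: remaining mobile molecules (mostly fast, as expected for free protein)
#: and the coefficients are taken from the WT set.
HALO_CONTROL = DiffusionParams(fractions=(0.13, 0.27, 0.60), coeffs=(0.034, 0.46, 3.4), dt=0.01)

#: Photobleaching rate (s⁻¹) of the slow-imaging regime, as estimated from
#: the slowest decay component of H2B survival.
H2B_BLEACH_RATE = 0.0316


@dataclass(frozen=True)
class SlowMovieConfig:
    """Conditions of a slow-regime (residence-time) movie simulation.

    ``k_off_components`` is a list of ``(weight, rate s⁻¹)`` pairs defining an
    exponential-mixture dwell distribution; ``k_bleach`` the photobleaching
    rate; molecules shorter than ``min_frames`` frames are not scored.
    """

    frame_interval: float = 0.5
    movie_length: float = 300.0
    k_off_components: tuple[tuple[float, float], ...] = ((1.0, 0.02),)
    k_bleach: float = H2B_BLEACH_RATE
    min_frames: int = 5

    def __post_init__(self) -> None:
        w = np.array([c[0] for c in self.k_off_components], dtype=float)
        r = np.array([c[1] for c in self.k_off_components], dtype=float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("k_off weights must be nonnegative and sum to 1")
        if np.any(r < 0) or self.k_bleach < 0:
            raise ValueError("rates must be nonnegative")
        if self.min_frames < 1:
            raise ValueError("min_frames must be >= 1")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.movie_length < self.min_frames * self.frame_interval:
            raise ValueError(
                "movie_length shorter than the minimum scoreable dwell "
                f"({self.min_frames} frames x {self.frame_interval} s)"
            )

    @property
    def min_duration(self) -> float:
        return self.min_frames * self.frame_interval

    def as_dict(self) -> dict:
        return {
            "frame_interval": self.frame_interval,
            "movie_length": self.movie_length,
            "k_off_components": [list(c) for c in self.k_off_components],
            "k_bleach": self.k_bleach,
            "min_frames": self.min_frames,
        }


@dataclass
class GroundTruth:
    """Record of the exact parameters and seed behind one simulate_* call."""

    generator: str
    seed: int
    params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True, default=list)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(**json.loads(text))


# ---------------------------------------------------------------------------
# fast regime: displacements and tracks
# ---------------------------------------------------------------------------

def simulate_jumps(
    params: DiffusionParams,
    n_jumps: int,
    seed: int,
    sigma_loc: float = 0.0,
) -> np.ndarray:
    """Draw displacement magnitudes (μm) from the three-state Brownian mixture.

    Each jump picks a state with probability ``F_i`` and draws a 2-D Gaussian
    displacement with per-axis variance ``2 D_i Δt`` (magnitude Rayleigh with
    scale ``sqrt(2 D_i Δt)``). ``sigma_loc`` adds the static localization
    error of both endpoints (per-axis variance ``2 σ_loc²``); it is zero by
    default since the displacement model fitted downstream has no noise term.
    """
    if n_jumps < 1:
        raise ValueError("n_jumps must be >= 1")
    rng = np.random.default_rng(seed)
    comp = rng.choice(3, size=n_jumps, p=np.asarray(params.fractions))
    scale = np.sqrt(2.0 * np.asarray(params.coeffs)[comp] * params.dt + 2.0 * sigma_loc**2)
    dx = rng.normal(0.0, 1.0, n_jumps) * scale
    dy = rng.normal(0.0, 1.0, n_jumps) * scale
    return np.hypot(dx, dy)


def simulate_tracks(
    params: DiffusionParams,
    n_tracks: int,
    track_len: int,
    seed: int,
    cell_id: str = "sim_cell",
    sigma_loc: float = 0.0,
) -> tuple[TrackSet, GroundTruth]:
    """Simulate fast-regime Brownian tracks (each molecule stays in one state).

    Because every track has the same length, pooled consecutive-frame jumps
    follow the same mixture as :func:`simulate_jumps`.
    """
    if n_tracks < 1 or track_len < 2:
        raise ValueError("need n_tracks >= 1 and track_len >= 2")
    rng = np.random.default_rng(seed)
    comps = rng.choice(3, size=n_tracks, p=np.asarray(params.fractions))
    tracks = []
    for i, c in enumerate(comps):
        sigma = math.sqrt(2.0 * params.coeffs[c] * params.dt)
        steps = rng.normal(0.0, sigma, size=(track_len - 1, 2))
        xy = np.vstack([np.zeros(2), np.cumsum(steps, axis=0)]) + rng.uniform(0, 20, 2)
        if sigma_loc > 0:
            xy = xy + rng.normal(0.0, sigma_loc, size=xy.shape)
        tracks.append(
            Track(cell_id=cell_id, track_id=f"t{i}", dt=params.dt,
                  frames=np.arange(track_len), xy=xy)
        )
    gt = GroundTruth(
        generator="simulate_tracks",
        seed=seed,
        params={"diffusion": params.as_dict(), "n_tracks": n_tracks,
                "track_len": track_len, "sigma_loc": sigma_loc},
    )
    return TrackSet(tracks, regime="fast"), gt


# ---------------------------------------------------------------------------
# slow regime: dwell times under bleaching and movie-end censoring
# ---------------------------------------------------------------------------

def _sample_dwell_frames(cfg: SlowMovieConfig, n_molecules: int, rng: np.random.Generator):
    """Vectorized draw of observed frame counts and censoring flags."""
    weights = np.array([c[0] for c in cfg.k_off_components])
    rates = np.array([c[1] for c in cfg.k_off_components])
    comp = rng.choice(len(weights), size=n_molecules, p=weights)
    with np.errstate(divide="ignore"):
        t_true = np.where(
            rates[comp] > 0,
            rng.exponential(1.0, n_molecules) / np.where(rates[comp] > 0, rates[comp], 1.0),
            np.inf,
        )
    t_bleach = (
        rng.exponential(1.0 / cfg.k_bleach, n_molecules)
        if cfg.k_bleach > 0
        else np.full(n_molecules, np.inf)
    )
    t_end = cfg.movie_length - rng.uniform(0.0, cfg.movie_length, n_molecules)
    observed = np.minimum(np.minimum(t_true, t_bleach), t_end)
    censored = observed < t_true  # truncated by bleaching or movie end
    n_frames = np.floor(observed / cfg.frame_interval).astype(int)
    return n_frames, censored


def simulate_slow_movie_dwells(
    cfg: SlowMovieConfig, n_molecules: int, seed: int
):
    """Simulate observed immobile-segment durations from a slow movie.

    Each molecule draws a true dwell from the exponential ``k_off`` mixture, a
    bleach time from ``Exp(k_bleach)`` and a uniform start time; the observed
    duration is the minimum of the three horizons, discretized to whole
    frames (duration = n_frames × frame_interval). Molecules observed for
    fewer than ``min_frames`` frames are dropped.

    Returns a :class:`~tfkinetics.residence.DwellSet` and the ground truth.
    """
    from .residence import DwellSet

    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    rng = np.random.default_rng(seed)
    n_frames, censored = _sample_dwell_frames(cfg, n_molecules, rng)
    keep = n_frames >= cfg.min_frames
    dwells = DwellSet(
        durations=n_frames[keep] * cfg.frame_interval,
        censored=censored[keep],
        frame_interval=cfg.frame_interval,
        min_duration=cfg.min_duration,
    )
    gt = GroundTruth(
        generator="simulate_slow_movie_dwells",
        seed=seed,
        params={"config": cfg.as_dict(), "n_molecules": n_molecules,
                "n_retained": int(keep.sum())},
    )
    return dwells, gt


def simulate_slow_movie_tracks(
    cfg: SlowMovieConfig,
    n_molecules: int,
    seed: int,
    cell_id: str = "sim_cell",
    jitter: float = 0.02,
) -> tuple[TrackSet, GroundTruth]:
    """Materialize slow-movie dwells as near-stationary tracks.

    Each retained molecule becomes a track of ``n_frames`` localizations at a
    random position with per-frame Gaussian jitter well below any sensible
    immobility radius, so dwell extraction recovers the generated durations
    exactly.
    """
    rng = np.random.default_rng(seed)
    n_frames, _ = _sample_dwell_frames(cfg, n_molecules, rng)
    n_frames = n_frames[n_frames >= cfg.min_frames]
    tracks = []
    for i, nf in enumerate(n_frames):
        center = rng.uniform(0, 20, 2)
        xy = center + rng.normal(0.0, jitter, size=(nf, 2))
        tracks.append(
            Track(cell_id=cell_id, track_id=f"m{i}", dt=cfg.frame_interval,
                  frames=np.arange(nf), xy=xy)
        )
    gt = GroundTruth(
        generator="simulate_slow_movie_tracks",
        seed=seed,
        params={"config": cfg.as_dict(), "n_molecules": n_molecules, "jitter": jitter},
    )
    return TrackSet(tracks, regime="slow"), gt


# ---------------------------------------------------------------------------
# anisotropy titrations
# ---------------------------------------------------------------------------

def simulate_titration(
    kd: float,
    b0: float,
    bmax: float,
    c: float,
    x_grid,
    noise_sd: float,
    n_replicates: int,
    seed: int,
    probe_id: str = "sim_probe",
) -> list:
    """Simulate replicate anisotropy titrations from the quadratic isotherm.

    Returns one :class:`~tfkinetics.anisotropy.TitrationSeries` per replicate,
    with i.i.d. Gaussian noise of standard deviation ``noise_sd`` added to the
    model curve.
    """
    from .anisotropy import TitrationSeries, eq1_model

    x = np.asarray(x_grid, dtype=float)
    if kd <= 0 or c <= 0:
        raise ValueError("kd and c must be positive")
    if bmax == b0:
        raise ValueError("bmax must differ from b0")
    if np.any(x < 0) or np.any(np.diff(x) < 0):
        raise ValueError("x_grid must be nonnegative and ascending")
    rng = np.random.default_rng(seed)
    y_true = eq1_model(x, kd=kd, b0=b0, bmax=bmax, c=c)
    out = []
    for rep in range(n_replicates):
        y = y_true + rng.normal(0.0, noise_sd, size=x.size) if noise_sd > 0 else y_true.copy()
        out.append(
            TitrationSeries(probe_id=probe_id, replicate=f"rep{rep + 1}", c=c, x=x, y=y)
        )
    return out


def write_dwells_tsv(dwells, path) -> None:
    """Write a dwell set as TSV (duration_s, censored)."""
    import pandas as pd

    pd.DataFrame(
        {"duration_s": dwells.durations, "censored": dwells.censored.astype(int)}
    ).to_csv(path, sep="\t", index=False)


def write_titrations_csv(series_list, path) -> None:
    """Write titration series as CSV (probe_id, replicate, protein_nM, anisotropy)."""
    import pandas as pd

    rows = [
        {"probe_id": s.probe_id, "replicate": s.replicate,
         "protein_nM": x, "anisotropy": y}
        for s in series_list
        for x, y in zip(s.x, s.y)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# peak sequences with planted E-box classes
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _planted_8mer(label: str, rng: np.random.Generator) -> str | None:
    """One concrete 8-mer whose classification is exactly ``label``."""
    if label == "none":
        return None
    if label == "TCACGTGA":
        return "TCACGTGA"
    if label == "TCACGTGB":
        return "TCACGTG" + rng.choice(list("CGT"))
    if label == "TCATGTGA":
        return "TCATGTGA"
    if label == "TCATGTGB":
        return "TCATGTG" + rng.choice(list("CGT"))
    if label == "CACGTG_other":
        # 5' flank not T on either strand: x != T and y != A (CACGTG is palindromic)
        return rng.choice(list("ACG")) + "CACGTG" + rng.choice(list("CGT"))
    if label == "CATGTG_other":
        return rng.choice(list("ACG")) + "CATGTG" + rng.choice(list("ACGT"))
    raise ValueError(f"unknown motif class {label!r}")


def simulate_peakset(
    n_peaks: int,
    class_probs: dict[str, float],
    peak_len: int = 200,
    seed: int = 0,
    gc: float = 0.41,
    score_by_class: dict[str, tuple[float, float]] | None = None,
    chrom: str = "chrSim",
    max_resample: int = 200,
):
    """Simulate scored peaks, each carrying exactly one planted E-box class.

    Background sequence is i.i.d. with the given GC fraction (0.41 by default,
    human-genome-like). One 8-mer of the drawn class is planted at a random
    position on a random strand; sequences in which the background creates a
    spurious core (changing the classification) are resampled, so the
    classifier's input is guaranteed to contain exactly the planted class.
    Scores are drawn from a class-conditional normal distribution recorded in
    the ground truth.

    Returns ``(peaks, ground_truth)`` with peaks as
    :class:`~tfkinetics.motif.PeakSeq`.
    """
    from .motif import MOTIF_CLASSES, PeakSeq, classify_peak_ebox

    probs = {k: float(v) for k, v in class_probs.items()}
    unknown = set(probs) - set(MOTIF_CLASSES)
    if unknown:
        raise ValueError(f"unknown motif classes {sorted(unknown)}")
    if abs(sum(probs.values()) - 1.0) > 1e-9:
        raise ValueError("class proportions must sum to 1")
    if peak_len < 8:
        raise ValueError("peak_len must be >= 8")
    if score_by_class is None:
        score_by_class = {}

    rng = np.random.default_rng(seed)
    labels = list(probs)
    p = np.array([probs[k] for k in labels])
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))

    drawn = rng.choice(len(labels), size=n_peaks, p=p)
    peaks, truth_rows = [], []
    pos = 0
    for i, li in enumerate(drawn):
        label = labels[li]
        for _ in range(max_resample):
            seq = "".join(rng.choice(bases, size=peak_len, p=base_p))
            planted = _planted_8mer(label, rng)
            strand = "+"
            if planted is not None:
                strand = rng.choice(["+", "-"])
                ins = planted if strand == "+" else _revcomp(planted)
                start = int(rng.integers(0, peak_len - 8 + 1))
                seq = seq[:start] + ins + seq[start + 8:]
            if classify_peak_ebox(seq).label == label:
                break
        else:
            raise RuntimeError(
                f"could not place class {label} without background collision"
            )
        mu, sd = score_by_class.get(label, (100.0, 20.0))
        score = float(max(rng.normal(mu, sd), 1.0))
        peaks.append(
            PeakSeq(chrom=chrom, start=pos, end=pos + peak_len, score=score, seq=seq)
        )
        truth_rows.append({"peak_index": i, "class": label, "strand": strand, "score": score})
        pos += peak_len + 100
    gt = GroundTruth(
        generator="simulate_peakset",
        seed=seed,
        params={
            "n_peaks": n_peaks,
            "class_probs": probs,
            "peak_len": peak_len,
            "gc": gc,
            "peaks": truth_rows,
        },
    )
    return peaks, gt
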