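"""Reading, writing and grouping of single-molecule track tables.

Tracks are consumed as tracker-export CSV tables (one localization per row)
and held in memory as :class:`Track` / :class:`TrackSet` objects with
coordinates in micrometres. Displacements ("jumps") are only ever computed
between frames differing by exactly one, so gap-closed links produced by an
upstream tracker never contribute artificially long displacements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default column mapping for tracker-export CSVs (TrackMate-style spots table).
DEFAULT_DIALECT: dict[str, str] = {
    "track_id": "TRACK_ID",
    "frame": "FRAME",
    "x": "POSITION_X",
    "y": "POSITION_Y",
    "cell_id": "CELL_ID",  # optional; filename stem used when absent
}

#: Default frame intervals (s) for the two imaging regimes.
REGIME_DT = {"fast": 0.01, "slow": 0.5}


@dataclass
class Track:
    """A single trajectory: ordered localizations of one molecule in one cell.

    Parameters
    ----------
    cell_id, track_id
        Labels identifying the cell and the trajectory within it.
    dt
        Frame interval in seconds.
    frames
        Strictly increasing integer frame indices.
    xy
        ``(n, 2)`` array of positions in micrometres.
    """

    cell_id: str
    track_id: str
    dt: float
    frames: np.ndarray
    xy: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.dt <= 0:
            raise ValueError("frame interval dt must be positive")
        if self.frames.size < 1:
            raise ValueError("a track needs at least one point")
        if self.xy.shape != (self.frames.size, 2):
            raise ValueError("xy must be (n_frames, 2)")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing")

    def __len__(self) -> int:
        return self.frames.size

    def jumps(self) -> np.ndarray:
        """Euclidean displacements between consecutive frames (μm).

        Pairs of localizations whose frame indices differ by more than one
        (tracker gap closing) are excluded.
        """
        if len(self) < 2:
            return np.empty(0)
        consecutive = np.diff(self.frames) == 1
        d = np.diff(self.xy, axis=0)
        return np.hypot(d[:, 0], d[:, 1])[consecutive]


@dataclass
class TrackSet:
    """Tracks from one imaging session, grouped by cell, with a regime tag."""

    tracks: list[Track]
    regime: str = "fast"

    def __post_init__(self) -> None:
        if self.regime not in REGIME_DT:
            raise ValueError(f"regime must be one of {sorted(REGIME_DT)}")
        dts = {t.dt for t in self.tracks}
        if len(dts) > 1:
            raise ValueError(f"all tracks must share dt, got {sorted(dts)}")

    @property
    def dt(self) -> float:
        if not self.tracks:
            return REGIME_DT[self.regime]
        return self.tracks[0].dt

    def cells(self) -> list[str]:
        return sorted({t.cell_id for t in self.tracks})

    def by_cell(self) -> dict[str, list[Track]]:
        out: dict[str, list[Track]] = {}
        for t in self.tracks:
            out.setdefault(t.cell_id, []).append(t)
        return out

    def jumps_by_cell(self) -> dict[str, np.ndarray]:
        """Consecutive-frame displacement magnitudes pooled per cell (μm)."""
        return {
            cell: np.concatenate([t.jumps() for t in trs] or [np.empty(0)])
            for cell, trs in self.by_cell().items()
        }

    def all_jumps(self) -> np.ndarray:
        parts = [t.jumps() for t in self.tracks]
        return np.concatenate(parts) if parts else np.empty(0)

    def n_jumps(self) -> int:
        return int(sum(t.jumps().size for t in self.tracks))


def read_tracks_csv(
    path,
    dialect: dict[str, str] | None = None,
    dt: float | None = None,
    regime: str = "fast",
    pixel_size: float | None = None,
) -> TrackSet:
    """Read a tracker-export CSV into a :class:`TrackSet`.

    Parameters
    ----------
    path
        CSV file with one localization per row.
    dialect
        Column mapping with keys ``track_id``, ``frame``, ``x``, ``y`` and
        optionally ``cell_id``; defaults to :data:`DEFAULT_DIALECT`.
    dt
        Frame interval (s); defaults to the regime default (0.01 s fast,
        0.5 s slow).
    pixel_size
        If given, x/y columns are in pixels and multiplied by this μm/px
        factor.

    Rows with missing coordinates are dropped (count reported in the log).
    Numbers are parsed with a decimal point regardless of locale.
    """
    dialect = dict(DEFAULT_DIALECT, **(dialect or {}))
    if dt is None:
        dt = REGIME_DT[regime]
    df = pd.read_csv(path)
    if df.empty:
        logger.warning("empty track table: %s", path)
        return TrackSet([], regime=regime)
    required = {k: dialect[k] for k in ("track_id", "frame", "x", "y")}
    missing = [col for col in required.values() if col not in df.columns]
    if missing:
        raise ValueError(
            f"columns {missing} not found; available headers: {list(df.columns)}"
        )
    cell_col = dialect.get("cell_id")
    if cell_col not in df.columns:
        from pathlib import Path

        df = df.assign(**{cell_col: Path(path).stem})

    n_before = len(df)
    df = df.dropna(subset=[required["x"], required["y"], required["frame"]])
    if len(df) < n_before:
        logger.info("dropped %d rows with missing coordinates", n_before - len(df))

    scale = pixel_size if pixel_size is not None else 1.0
    tracks = []
    for (cell, tid), grp in df.groupby([cell_col, required["track_id"]], sort=True):
        grp = grp.sort_values(required["frame"])
        tracks.append(
            Track(
                cell_id=str(cell),
                track_id=str(tid),
                dt=dt,
                frames=grp[required["frame"]].to_numpy(dtype=int),
                xy=grp[[required["x"], required["y"]]].to_numpy(dtype=float) * scale,
            )
        )
    return TrackSet(tracks, regime=regime)


def write_tracks_csv(trackset: TrackSet, path, dialect: dict[str, str] | None = None) -> None:
    """Write a :class:`TrackSet` in the (default) CSV track dialect."""
    dialect = dict(DEFAULT_DIALECT, **(dialect or {}))
    rows = []
    for t in trackset.tracks:
        for f, (x, y) in zip(t.frames, t.xy):
            rows.append(
                {
                    dialect["cell_id"]: t.cell_id,
                    dialect["track_id"]: t.track_id,
                    dialect["frame"]: int(f),
                    dialect["x"]: x,
                    dialect["y"]: y,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def jump_count_table(trackset: TrackSet) -> pd.DataFrame:
    """Per-cell table of extractable consecutive-frame jump counts."""
    return pd.DataFrame(
        [
            {"cell_id": cell, "n_jumps": int(j.size)}
            for cell, j in sorted(trackset.jumps_by_cell().items())
        ]
    )
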