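"""Fast-regime displacement-distribution analysis.

A molecule population imaged at short intervals is modelled as a mixture of
three Brownian states. The probability of observing a displacement of
magnitude r in a histogram bin of width Δr is

    p(r) = r Δr Σ_i  F_i / (2 D_i Δt) · exp(−r² / (4 D_i Δt))

where F_i is the occupancy and D_i the diffusion coefficient of state i and
Δt the frame interval. The slowest state (D1, typically ≲ 0.05 μm²/s)
represents chromatin-bound molecules, so F1 is the bound fraction. Fits are
performed per cell on displacement histograms (default bin width 20 nm) by
nonlinear least squares with multi-start initialization; per-cell statistics
are compared across conditions with the Kruskal–Wallis rank test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .sim import DiffusionParams
from .tracks_io import TrackSet

__all__ = [
    "JumpHistogram",
    "DiffusionFit",
    "GroupComparison",
    "eq2_pdf",
    "mixture_cdf",
    "build_jump_histogram",
    "histogram_from_jumps",
    "fit_three_component",
    "compare_groups",
]

DEFAULT_BIN_WIDTH = 0.020  # μm
DEFAULT_R_MAX = 1.5  # μm

# default box constraints for the three diffusion coefficients (μm²/s)
DEFAULT_D_BOUNDS = ((1e-3, 0.1), (0.05, 2.0), (0.5, 20.0))


@dataclass
class JumpHistogram:
    """Binned displacement magnitudes of one cell (or a pooled set)."""

    counts: np.ndarray
    bin_width: float
    dt: float
    n_jumps: int
    overflow: int = 0
    cell_id: str = "pooled"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if abs(self.counts.sum() + self.overflow - self.n_jumps) > 1e-6 * max(self.n_jumps, 1):
            raise ValueError("counts + overflow must equal n_jumps")

    @property
    def bin_centers(self) -> np.ndarray:
        return (np.arange(self.counts.size) + 0.5) * self.bin_width

    @property
    def fractions(self) -> np.ndarray:
        """Empirical per-bin fractions of all jumps (overflow included in n)."""
        return self.counts / self.n_jumps


@dataclass
class DiffusionFit:
    """Result of the three-component fit on one histogram."""

    params: DiffusionParams
    sse: float
    converged: bool
    n_jumps: int
    cell_id: str = "pooled"

    @property
    def bound_fraction(self) -> float:
        return self.params.fractions[0]

    def as_row(self) -> dict:
        f, d = self.params.fractions, self.params.coeffs
        return {
            "cell_id": self.cell_id,
            "F1": f[0], "F2": f[1], "F3": f[2],
            "D1": d[0], "D2": d[1], "D3": d[2],
            "sse": self.sse, "converged": self.converged, "n_jumps": self.n_jumps,
        }


@dataclass
class GroupComparison:
    """Kruskal–Wallis comparison of per-cell statistics across conditions."""

    table: pd.DataFrame  # one row per statistic: H, p, per-condition medians
    per_condition: dict[str, pd.DataFrame] = field(default_factory=dict)


def eq2_pdf(params: DiffusionParams, bin_centers, bin_width: float) -> np.ndarray:
    """Per-bin displacement probabilities of the three-component model.

    A component with D_i = 0 is an immobile point mass: its whole weight goes
    into the first bin.
    """
    r = np.asarray(bin_centers, dtype=float)
    if np.any(r <= 0):
        raise ValueError("bin centers must be positive")
    if params.dt <= 0:
        raise ValueError("dt must be positive")
    p = np.zeros_like(r)
    for f_i, d_i in zip(params.fractions, params.coeffs):
        if d_i == 0:
            p[0] += f_i
        else:
            s2 = 4.0 * d_i * params.dt
            p += f_i * r * bin_width / (s2 / 2.0) * np.exp(-(r**2) / s2)
    return p


def mixture_cdf(params: DiffusionParams, r) -> np.ndarray:
    """Closed-form CDF of displacement magnitude: Σ F_i (1 − exp(−r²/4D_iΔt))."""
    r = np.asarray(r, dtype=float)
    out = np.zeros_like(r)
    for f_i, d_i in zip(params.fractions, params.coeffs):
        if d_i == 0:
            out += f_i * (r >= 0)
        else:
            out += f_i * (1.0 - np.exp(-(r**2) / (4.0 * d_i * params.dt)))
    return out


def histogram_from_jumps(
    jumps,
    dt: float,
    bin_width: float = DEFAULT_BIN_WIDTH,
    r_max: float = DEFAULT_R_MAX,
    cell_id: str = "pooled",
) -> JumpHistogram:
    """Bin displacement magnitudes into [k·Δr, (k+1)·Δr) up to ``r_max``."""
    jumps = np.asarray(jumps, dtype=float)
    if jumps.size == 0:
        raise ValueError(f"no jumps to histogram for cell {cell_id!r}")
    n_bins = int(np.ceil(r_max / bin_width))
    counts, _ = np.histogram(jumps, bins=n_bins, range=(0.0, n_bins * bin_width))
    overflow = int(np.sum(jumps >= n_bins * bin_width))
    return JumpHistogram(
        counts=counts, bin_width=bin_width, dt=dt,
        n_jumps=int(jumps.size), overflow=overflow, cell_id=cell_id,
    )


def build_jump_histogram(
    trackset: TrackSet,
    bin_width: float = DEFAULT_BIN_WIDTH,
    r_max: float = DEFAULT_R_MAX,
    pooled: bool = False,
) -> dict[str, JumpHistogram]:
    """Per-cell displacement histograms from a fast-regime track set.

    With ``pooled=True`` a single histogram over all cells is returned under
    the key ``"pooled"`` instead.
    """
    if trackset.regime != "fast":
        raise ValueError("displacement histograms require the fast imaging regime")
    if pooled:
        return {
            "pooled": histogram_from_jumps(
                trackset.all_jumps(), trackset.dt, bin_width, r_max, "pooled"
            )
        }
    return {
        cell: histogram_from_jumps(jumps, trackset.dt, bin_width, r_max, cell)
        for cell, jumps in trackset.jumps_by_cell().items()
    }


def _theta_to_params(theta: np.ndarray, dt: float) -> DiffusionParams:
    """(g1, g2, log10 D1..D3) -> DiffusionParams via stick-breaking fractions."""
    g1, g2 = theta[0], theta[1]
    f1 = g1
    f2 = (1.0 - g1) * g2
    f3 = max(1.0 - f1 - f2, 0.0)
    d = np.sort(10.0 ** theta[2:5])
    # guarantee strict ordering for the container invariant
    for k in (1, 2):
        if d[k] <= d[k - 1]:
            d[k] = d[k - 1] * (1.0 + 1e-12)
    total = f1 + f2 + f3
    return DiffusionParams(
        fractions=(f1 / total, f2 / total, f3 / total), coeffs=tuple(d), dt=dt
    )


def _sorted_init(init: DiffusionParams) -> np.ndarray:
    order = np.argsort(init.coeffs)
    f = np.asarray(init.fractions)[order]
    d = np.asarray(init.coeffs)[order]
    g1 = f[0]
    g2 = f[1] / (1.0 - f[0]) if f[0] < 1.0 else 0.5
    return np.array([g1, g2, *np.log10(np.maximum(d, 1e-6))])


def fit_three_component(
    hist: JumpHistogram,
    init: DiffusionParams | None = None,
    bounds=DEFAULT_D_BOUNDS,
    fix_d1: float | None = None,
    min_jumps: int = 1000,
    n_starts: int = 8,
) -> DiffusionFit:
    """Least-squares fit of the three-component model to a jump histogram.

    The objective is the residual between the empirical per-bin jump
    fractions and :func:`eq2_pdf`. Fractions are parameterized on the simplex
    (stick-breaking) and diffusion coefficients on a log scale within
    ``bounds``. A multi-start strategy over a log-spaced D grid (``n_starts``
    starts, plus the user initialization if given) guards against local
    minima; the lowest residual sum of squares wins, ties broken by lower D1.
    ``fix_d1`` pins the slowest coefficient instead of fitting it.
    """
    if hist.n_jumps < min_jumps:
        warnings.warn(
            f"only {hist.n_jumps} jumps in cell {hist.cell_id!r} "
            f"(fewer than {min_jumps}); fit attempted anyway",
            stacklevel=2,
        )
    y = hist.fractions
    centers = hist.bin_centers
    lo_d = np.log10([b[0] for b in bounds])
    hi_d = np.log10([b[1] for b in bounds])

    def residuals(theta: np.ndarray) -> np.ndarray:
        full = theta if fix_d1 is None else np.insert(theta, 2, np.log10(fix_d1))
        p = _theta_to_params(full, hist.dt)
        return eq2_pdf(p, centers, hist.bin_width) - y

    starts: list[np.ndarray] = []
    if init is not None:
        starts.append(_sorted_init(init))
    rng_grid = np.linspace(0.15, 0.85, max(2, int(np.ceil(np.sqrt(n_starts)))))
    d_grid = [
        np.array([lo + frac * (hi - lo) for lo, hi in zip(lo_d, hi_d)])
        for frac in np.linspace(0.2, 0.8, max(2, n_starts // len(rng_grid)))
    ]
    for g in rng_grid:
        for dvec in d_grid:
            starts.append(np.array([g, 0.5, *dvec]))
            if len(starts) >= n_starts + (init is not None):
                break
        if len(starts) >= n_starts + (init is not None):
            break

    lower = np.array([0.0, 0.0, *lo_d])
    upper = np.array([1.0, 1.0, *hi_d])
    if fix_d1 is not None:
        lower = np.delete(lower, 2)
        upper = np.delete(upper, 2)
        starts = [np.delete(s, 2) for s in starts]

    best = None
    for x0 in starts:
        x0c = np.clip(x0, lower + 1e-9, upper - 1e-9)
        try:
            res = optimize.least_squares(
                residuals, x0c, bounds=(lower, upper), method="trf", xtol=1e-12, ftol=1e-12
            )
        except Exception:
            continue
        sse = float(np.sum(res.fun**2))
        full = res.x if fix_d1 is None else np.insert(res.x, 2, np.log10(fix_d1))
        cand = (sse, _theta_to_params(full, hist.dt), bool(res.success))
        if (
            best is None
            or cand[0] < best[0] * (1 - 1e-9)
            or (abs(cand[0] - best[0]) <= 1e-9 * max(best[0], 1e-30)
                and cand[1].coeffs[0] < best[1].coeffs[0])
        ):
            best = cand
    if best is None:
        raise RuntimeError("all optimization starts failed")
    sse, params, success = best
    if not success:
        warnings.warn(f"fit for cell {hist.cell_id!r} did not report convergence", stacklevel=2)
    return DiffusionFit(
        params=params, sse=sse, converged=success,
        n_jumps=hist.n_jumps, cell_id=hist.cell_id,
    )


def fits_to_table(fits) -> pd.DataFrame:
    """Stack per-cell :class:`DiffusionFit` results into a tidy table."""
    return pd.DataFrame([f.as_row() for f in fits])


def compare_groups(stats_by_condition: dict[str, pd.DataFrame]) -> GroupComparison:
    """Kruskal–Wallis rank test of per-cell statistics across conditions.

    ``stats_by_condition`` maps a condition label to a table with one row per
    cell and one column per statistic (e.g. F1, F2, D1, D2, D3). One H test
    is run per statistic (tie-corrected); medians and quartiles are reported
    per condition.
    """
    conditions = list(stats_by_condition)
    if len(conditions) < 2:
        raise ValueError("need at least two conditions")
    for cond, df in stats_by_condition.items():
        if len(df) < 2:
            raise ValueError(f"condition {cond!r} has fewer than two cells")
    stat_names = list(stats_by_condition[conditions[0]].columns)
    rows = []
    for name in stat_names:
        samples = [stats_by_condition[c][name].to_numpy(dtype=float) for c in conditions]
        if np.ptp(np.concatenate(samples)) == 0:
            h, p = 0.0, 1.0
        else:
            h, p = stats.kruskal(*samples)
        row = {"statistic": name, "H": float(h), "p": float(p)}
        for c, s in zip(conditions, samples):
            row[f"{c}_median"] = float(np.median(s))
            row[f"{c}_q1"] = float(np.percentile(s, 25))
            row[f"{c}_q3"] = float(np.percentile(s, 75))
        rows.append(row)
    per_condition = {
        c: stats_by_condition[c].describe().loc[["25%", "50%", "75%"]]
        for c in conditions
    }
    return GroupComparison(table=pd.DataFrame(rows), per_condition=per_condition)
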