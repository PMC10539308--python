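"""Quadratic (ligand-depletion) binding isotherm for anisotropy titrations.

When the labelled probe concentration C is comparable to the dissociation
constant K_D, the usual hyperbolic isotherm underestimates affinity; the
bound fraction must instead be solved from the binding quadratic, giving

    y = B0 + (Bmax − B0) · (C + x + K_D − sqrt((C + x + K_D)² − 4 C x)) / (2 C)

with x the total protein concentration, B0 the anisotropy of the free probe
(after baseline subtraction, B0 ≈ 0) and Bmax the anisotropy at saturation.
K_D is fitted per replicate; the reported value is the mean across replicates
with its standard deviation, matching triplicate-assay practice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from lmfit import Model
from scipy import stats

__all__ = [
    "PROBE_DUPLEXES",
    "DEFAULT_PROBE_CONC_NM",
    "TitrationSeries",
    "KdFit",
    "eq1_model",
    "fit_kd",
    "compare_kd",
    "pointwise_tests",
    "read_titrations_csv",
]

#: Fluorescein-labelled probe duplex top strands used in the binding assay,
#: shared with the motif module (extended E-box classes CLEAR-box, TYR
#: enhancer and M-box).
PROBE_DUPLEXES = {
    "CLEAR-box": "GAGATCACGTGATGAC",
    "TYR": "GAGATCATGTGATGAC",
    "M-box": "GAGATCATGTGTTGAC",
}

#: Probe duplex concentration in the assay (nM).
DEFAULT_PROBE_CONC_NM = 1.33


@dataclass
class TitrationSeries:
    """One replicate titration: anisotropy versus protein concentration (nM)."""

    probe_id: str
    replicate: str
    c: float  # probe concentration, nM
    x: np.ndarray  # protein concentrations, nM, ascending
    y: np.ndarray  # anisotropy, baseline-subtracted
    baseline: float = 0.0  # free-probe anisotropy already subtracted from y

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.c <= 0:
            raise ValueError("probe concentration must be positive")
        if self.x.size != self.y.size:
            raise ValueError("x and y must be the same length")
        if np.any(self.x < 0) or np.any(np.diff(self.x) < 0):
            raise ValueError("x must be nonnegative and ascending")

    @classmethod
    def from_raw(cls, probe_id, replicate, c, x, y_raw, baseline):
        """Build a series from raw anisotropy plus a free-probe baseline."""
        return cls(probe_id, replicate, c, x, np.asarray(y_raw, float) - baseline,
                   baseline=baseline)


@dataclass
class KdFit:
    """Replicate-averaged quadratic-isotherm fit."""

    kd: float  # nM, mean across replicates
    kd_sd: float  # nM, SD across replicates
    b0: float
    bmax: float
    replicate_kds: np.ndarray = field(default_factory=lambda: np.empty(0))
    converged: bool = True
    probe_id: str = ""

    def __post_init__(self) -> None:
        self.replicate_kds = np.asarray(self.replicate_kds, dtype=float)
        if self.kd <= 0:
            raise ValueError("kd must be positive")


def eq1_model(x, kd: float, b0: float, bmax: float, c: float) -> np.ndarray:
    """Quadratic ligand-depletion isotherm (anisotropy versus protein).

    Numerically stable near the discriminant: for valid inputs the
    discriminant (C+x+K_D)² − 4Cx is nonnegative; tiny negative values from
    round-off are clipped to zero.
    """
    x = np.asarray(x, dtype=float)
    if kd <= 0 or c <= 0:
        raise ValueError("kd and c must be positive")
    if np.any(x < 0):
        raise ValueError("x must be nonnegative")
    s = c + x + kd
    disc = s**2 - 4.0 * c * x
    if np.any(disc < -1e-9 * np.maximum(s**2, 1.0)):
        raise ArithmeticError("negative discriminant in the binding quadratic")
    bound = (s - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * c)
    return b0 + (bmax - b0) * bound


def _fit_one(series: TitrationSeries, c: float):
    model = Model(eq1_model, independent_vars=["x"])
    y = series.y
    half = series.y.min() + 0.5 * (y.max() - y.min())
    kd0 = float(np.interp(half, y, series.x)) if y.max() > y.min() else 1.0
    params = model.make_params(
        kd=max(kd0, 1e-3),
        b0=float(y.min()),
        bmax=float(y.max()),
        c=c,
    )
    params["kd"].set(min=1e-6, max=1e7)
    params["c"].set(vary=False)
    result = model.fit(y, params, x=series.x)
    return result


def fit_kd(series: list[TitrationSeries], c: float | None = None, pooled: bool = False) -> KdFit:
    """Fit the quadratic isotherm to replicate titrations.

    By default each replicate is fitted independently (free K_D, B0, Bmax; C
    fixed at the assay probe concentration) and the reported K_D is the mean
    of the replicate values with their standard deviation. ``pooled=True``
    instead fits all points jointly in a single regression.
    """
    if not series:
        raise ValueError("no titration series")
    for s in series:
        if np.unique(s.x).size < 4:
            raise ValueError(
                f"replicate {s.replicate!r} has fewer than 4 distinct protein concentrations"
            )
    c = c if c is not None else series[0].c
    if pooled:
        merged = TitrationSeries(
            probe_id=series[0].probe_id, replicate="pooled", c=c,
            x=np.sort(np.concatenate([s.x for s in series])),
            y=np.concatenate([s.y for s in series])[
                np.argsort(np.concatenate([s.x for s in series]), kind="stable")
            ],
        )
        res = _fit_one(merged, c)
        kd = float(res.params["kd"].value)
        return KdFit(kd=kd, kd_sd=0.0, b0=float(res.params["b0"].value),
                     bmax=float(res.params["bmax"].value),
                     replicate_kds=np.array([kd]), converged=bool(res.success),
                     probe_id=series[0].probe_id)

    kds, b0s, bmaxs, ok = [], [], [], []
    for s in series:
        res = _fit_one(s, c)
        if not res.success:
            warnings.warn(
                f"replicate {s.replicate!r} did not converge; excluded from the mean",
                stacklevel=2,
            )
            continue
        kds.append(float(res.params["kd"].value))
        b0s.append(float(res.params["b0"].value))
        bmaxs.append(float(res.params["bmax"].value))
        ok.append(True)
    if not kds:
        raise RuntimeError("no replicate converged")
    kds = np.array(kds)
    return KdFit(
        kd=float(kds.mean()),
        kd_sd=float(kds.std(ddof=1)) if kds.size > 1 else 0.0,
        b0=float(np.mean(b0s)),
        bmax=float(np.mean(bmaxs)),
        replicate_kds=kds,
        converged=len(kds) == len(series),
        probe_id=series[0].probe_id,
    )


def compare_kd(fits: dict[str, KdFit], reference: str | None = None) -> pd.DataFrame:
    """Pairwise affinity ratios and unpaired two-tailed t-tests on replicate K_Ds.

    With ``reference`` given, every condition is compared against it;
    otherwise all pairs are compared. Conditions with fewer than two replicate
    K_Ds report the ratio but skip the test (p = NaN, with a warning).
    """
    if len(fits) < 2:
        raise ValueError("need at least two conditions")
    pairs = (
        [(c, reference) for c in fits if c != reference]
        if reference is not None
        else list(combinations(fits, 2))
    )
    rows = []
    for a, b in pairs:
        fa, fb = fits[a], fits[b]
        ratio = fa.kd / fb.kd
        if fa.replicate_kds.size < 2 or fb.replicate_kds.size < 2:
            warnings.warn(
                f"fewer than two replicates for {a!r} vs {b!r}; t-test skipped",
                stacklevel=2,
            )
            t, p = np.nan, np.nan
        else:
            t, p = stats.ttest_ind(fa.replicate_kds, fb.replicate_kds)
        rows.append({
            "condition": a, "versus": b, "kd_ratio": ratio,
            "t": float(t), "p": float(p),
        })
    return pd.DataFrame(rows)


def pointwise_tests(
    series_a: list[TitrationSeries], series_b: list[TitrationSeries]
) -> pd.DataFrame:
    """Unpaired two-tailed t-test of anisotropy at each shared concentration.

    This is the per-measurement-point significance mode: replicate anisotropy
    values of the two conditions are compared at every protein concentration
    present in both.
    """
    def stack(series):
        return {
            x: np.array([s.y[np.where(s.x == x)[0][0]] for s in series if x in s.x])
            for x in np.unique(np.concatenate([s.x for s in series]))
        }

    ya, yb = stack(series_a), stack(series_b)
    rows = []
    for x in sorted(set(ya) & set(yb)):
        if ya[x].size < 2 or yb[x].size < 2:
            continue
        t, p = stats.ttest_ind(ya[x], yb[x])
        rows.append({"protein_nM": x, "t": float(t), "p": float(p),
                     "mean_a": float(ya[x].mean()), "mean_b": float(yb[x].mean())})
    return pd.DataFrame(rows)


def read_titrations_csv(path, probe_conc: float = DEFAULT_PROBE_CONC_NM) -> list[TitrationSeries]:
    """Read titrations from CSV (probe_id, replicate, protein_nM, anisotropy[, baseline]).

    When a ``baseline`` column is present, it is subtracted from the raw
    anisotropy before the series is built.
    """
    df = pd.read_csv(path)
    required = {"probe_id", "replicate", "protein_nM", "anisotropy"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns {sorted(missing)}; found {list(df.columns)}")
    out = []
    for (probe, rep), grp in df.groupby(["probe_id", "replicate"], sort=True):
        grp = grp.sort_values("protein_nM")
        y = grp["anisotropy"].to_numpy(dtype=float)
        baseline = 0.0
        if "baseline" in grp.columns:
            baseline = float(grp["baseline"].iloc[0])
            y = y - baseline
        out.append(
            TitrationSeries(
                probe_id=str(probe), replicate=str(rep), c=probe_conc,
                x=grp["protein_nM"].to_numpy(dtype=float), y=y, baseline=baseline,
            )
        )
    return out
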