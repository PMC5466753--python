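"""Band-level lipid indicators extracted from preprocessed spectra.

After Savitzky-Golay second differentiation, absorbance maxima appear as
local *minima*, so band intensity on preprocessed spectra is the negated
second-derivative minimum inside a search window.  Two bands carry the lipid
story: the ester carbonyl stretch near 1745 cm^-1 (intensity tracks total
cellular lipid) and the olefinic =C-H stretch near 3006-3012 cm^-1 (position
shifts up with fatty-acid unsaturation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Union

import numpy as np
import pandas as pd

from .errors import EmptySelectionError, FtirlipError
from .spectra import SpectrumSet, WavenumberRegion


@dataclass(frozen=True)
class BandDefinition:
    name: str
    center: float  # cm^-1
    search_window: WavenumberRegion
    mode: str = "second-derivative-minimum"  # or "absorbance-maximum"

    def __post_init__(self):
        if not (self.search_window.low <= self.center <= self.search_window.high):
            raise ValueError(f"band center {self.center} outside search window")
        if self.mode not in ("second-derivative-minimum", "absorbance-maximum"):
            raise ValueError(f"unknown band mode {self.mode!r}")


#: C=O stretch of triacylglycerol esters; intensity follows lipid content.
ESTER_CARBONYL = BandDefinition(
    "ester_carbonyl", 1745.0, WavenumberRegion(1760.0, 1730.0)
)
#: =C-H stretch; position follows the unsaturation index.
OLEFINIC = BandDefinition("olefinic", 3008.0, WavenumberRegion(3020.0, 2995.0))


@dataclass
class TrendSeries:
    """Per-(species, temperature) time course of a band statistic."""

    species: str
    temperature: float
    days: np.ndarray
    value: np.ndarray  # mean over biological replicates
    dispersion: np.ndarray  # SD over biological replicates (0 for n=1)
    n: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": self.species,
                "temperature": self.temperature,
                "day": self.days,
                "n": self.n,
                "mean": self.value,
                "sd": self.dispersion,
            }
        )


def _window_slice(wavenumbers: np.ndarray, band: BandDefinition) -> np.ndarray:
    mask = band.search_window.contains(wavenumbers)
    if not mask.any():
        raise EmptySelectionError(
            f"band {band.name}: window [{band.search_window.low}, "
            f"{band.search_window.high}] cm^-1 overlaps no grid points"
        )
    return np.flatnonzero(mask)


def peak_height(
    wavenumbers: np.ndarray,
    values: np.ndarray,
    band: BandDefinition,
) -> Union[float, np.ndarray]:
    """Band intensity inside the search window.

    For ``second-derivative-minimum`` the negated window minimum is returned
    (a nonnegative intensity for a real band); for ``absorbance-maximum`` the
    window maximum.  ``values`` may be one spectrum (1-D) or a stack (2-D);
    the result is a scalar or a per-row vector accordingly.
    """
    idx = _window_slice(np.asarray(wavenumbers, float), band)
    v = np.atleast_2d(np.asarray(values, float))[:, idx]
    out = -v.min(axis=1) if band.mode == "second-derivative-minimum" else v.max(axis=1)
    return float(out[0]) if np.asarray(values).ndim == 1 else out


def _parabolic_vertex(x: np.ndarray, y: np.ndarray) -> float:
    # vertex of the parabola through three (x, y) points
    a, b, _ = np.polyfit(x, y, 2)
    if a == 0:
        return float(x[1])
    return float(-b / (2 * a))


def peak_position(
    wavenumbers: np.ndarray,
    values: np.ndarray,
    band: BandDefinition,
) -> Union[float, np.ndarray]:
    """Band position in cm^-1, refined below the grid spacing.

    The discrete extremum inside the window is located, then refined by a
    three-point parabolic interpolation through the extremum and its two
    neighbours.  An extremum sitting on the window boundary triggers a
    warning and is returned unrefined.
    """
    wn = np.asarray(wavenumbers, float)
    idx = _window_slice(wn, band)
    vals = np.atleast_2d(np.asarray(values, float))
    window = vals[:, idx]
    arg = window.argmin(axis=1) if band.mode == "second-derivative-minimum" else window.argmax(axis=1)
    out = np.empty(vals.shape[0])
    for i, j in enumerate(arg):
        if j == 0 or j == idx.size - 1:
            warnings.warn(
                f"band {band.name}: extremum on window boundary at "
                f"{wn[idx[j]]:g} cm^-1; position not refined",
                stacklevel=2,
            )
            out[i] = wn[idx[j]]
            continue
        sl = idx[j - 1 : j + 2]
        out[i] = _parabolic_vertex(wn[sl], vals[i, sl])
    return float(out[0]) if np.asarray(values).ndim == 1 else out


def lipid_trend(s: SpectrumSet, band: BandDefinition = ESTER_CARBONYL) -> List[TrendSeries]:
    """Mean +/- SD of the band intensity over biological replicates, per
    (species, temperature) group and cultivation day."""
    heights = peak_height(s.wavenumbers, s.absorbance, band)
    df = s.meta_frame()
    df["height"] = np.atleast_1d(heights)
    series = []
    for (species, temp), g in df.groupby(["species", "temperature"], sort=True):
        agg = g.groupby("day")["height"].agg(["mean", "std", "count"]).sort_index()
        series.append(
            TrendSeries(
                species=species,
                temperature=float(temp),
                days=agg.index.to_numpy(),
                value=agg["mean"].to_numpy(),
                dispersion=np.nan_to_num(agg["std"].to_numpy()),
                n=agg["count"].to_numpy(),
            )
        )
    return series


def trend_frame(series: List[TrendSeries]) -> pd.DataFrame:
    """Tidy (species, temperature, day, n, mean, sd) table of trend curves."""
    return pd.concat([t.to_frame() for t in series], ignore_index=True)


@dataclass
class ReplicateCorrelation:
    mean: float
    min: float
    per_group: pd.DataFrame  # columns: group, n, mean_correlation


def replicate_correlation(
    s: SpectrumSet,
    level: str = "technical",
    region: Optional[WavenumberRegion] = None,
) -> ReplicateCorrelation:
    """Average pairwise Pearson correlation between replicate spectra.

    ``level="technical"`` groups spectra sharing (species, temperature, day,
    bio_rep); ``level="biological"`` groups by (species, temperature, day).
    Restricted to ``region`` when given, else the full stored grid.  Groups
    with fewer than two members are ignored; all-singleton input is an error.
    """
    if level not in ("technical", "biological"):
        raise ValueError(f"unknown level {level!r}")
    if region is not None:
        mask = region.contains(s.wavenumbers)
        if not mask.any():
            raise EmptySelectionError("correlation region overlaps no grid points")
        X = s.absorbance[:, mask]
    else:
        X = s.absorbance
    groups: dict = {}
    for i, m in enumerate(s.meta):
        key = m.bio_key if level == "technical" else m.condition_key
        groups.setdefault(key, []).append(i)

    rows = []
    for key in sorted(groups):
        idx = groups[key]
        if len(idx) < 2:
            continue
        C = np.corrcoef(X[idx])
        iu = np.triu_indices(len(idx), k=1)
        rows.append({"group": key, "n": len(idx), "mean_correlation": float(C[iu].mean())})
    if not rows:
        raise FtirlipError(
            f"no {level} group has >= 2 members; replicate correlation undefined"
        )
    per_group = pd.DataFrame(rows)
    return ReplicateCorrelation(
        mean=float(per_group["mean_correlation"].mean()),
        min=float(per_group["mean_correlation"].min()),
        per_group=per_group,
    )
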