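"""Spectral preprocessing: Savitzky-Golay second derivative and EMSC.

The preprocessing chain used throughout the package is

1. average technical replicates (``spectra.average_technical_replicates``),
2. Savitzky-Golay second derivative (window 9 points, 2nd-degree polynomial),
3. extended multiplicative signal correction (EMSC) with linear and quadratic
   baseline terms, fitted on the combined 3100-2800 + 1800-500 cm^-1 range.

EMSC models each (derivative) spectrum z as

    z = a*1 + c*p1 + d*p2 + b*r + e

with r a reference spectrum (by default the set mean), p1 the wavenumber axis
mapped affinely to [-1, 1] and p2 its square; the corrected spectrum is
(z - a - c*p1 - d*p2) / b.  Fitting the baseline in the mapped basis keeps
the normal equations well conditioned (raw wavenumbers up to 3100 squared
are numerically hostile).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy.signal import savgol_filter

from .errors import DegenerateSampleError, GridError
from .spectra import (
    DEFAULT_REGIONS,
    SpectrumSet,
    WavenumberRegion,
    average_technical_replicates,
    select_region,
)


@dataclass(frozen=True)
class EMSCCoefficients:
    """Per-sample EMSC fit: additive offset a, multiplicative factor b,
    linear (c) and quadratic (d) baseline coefficients in the [-1,1] basis."""

    sample_id: str
    a: float
    b: float
    c: float
    d: float


@dataclass
class PreprocessConfig:
    sg_window: int = 9
    sg_polyorder: int = 2
    sg_deriv: int = 2
    #: scale the derivative by 1/h**deriv so units are absorbance * cm^deriv;
    #: disable for cosmetic parity with vendor software output.
    sg_scale_spacing: bool = True
    emsc_regions: Tuple[WavenumberRegion, ...] = DEFAULT_REGIONS
    emsc_poly_order: int = 2
    #: "mean-of-set" or "supplied" (a reference passed explicitly)
    reference_policy: str = "mean-of-set"

    def __post_init__(self):
        if self.sg_window % 2 != 1 or self.sg_window <= self.sg_polyorder:
            raise ValueError("sg_window must be odd and > sg_polyorder")
        if self.sg_deriv > self.sg_polyorder:
            raise ValueError("sg_deriv must be <= sg_polyorder")

    def to_dict(self) -> dict:
        return {
            "sg": {
                "window": self.sg_window,
                "polyorder": self.sg_polyorder,
                "deriv": self.sg_deriv,
                "scale_spacing": self.sg_scale_spacing,
            },
            "emsc": {
                "regions": [[r.high, r.low] for r in self.emsc_regions],
                "poly_order": self.emsc_poly_order,
                "reference": self.reference_policy,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessConfig":
        sg = d.get("sg", {})
        emsc = d.get("emsc", {})
        regions = tuple(
            WavenumberRegion(high, low) for high, low in emsc.get(
                "regions", [[r.high, r.low] for r in DEFAULT_REGIONS]
            )
        )
        return cls(
            sg_window=sg.get("window", 9),
            sg_polyorder=sg.get("polyorder", 2),
            sg_deriv=sg.get("deriv", 2),
            sg_scale_spacing=sg.get("scale_spacing", True),
            emsc_regions=regions,
            emsc_poly_order=emsc.get("poly_order", 2),
            reference_policy=emsc.get("reference", "mean-of-set"),
        )


def grid_spacing(wavenumbers: np.ndarray, tol: float = 0.01) -> float:
    """Absolute grid spacing; raises GridError if non-uniform beyond tol."""
    diffs = np.diff(wavenumbers)
    h = np.abs(diffs).mean()
    if h == 0 or np.any(np.abs(np.abs(diffs) - h) > tol * h):
        raise GridError("wavenumber grid is not uniform within 1% tolerance")
    return float(h)


def savitzky_golay_derivative(
    s: SpectrumSet, cfg: PreprocessConfig = PreprocessConfig()
) -> SpectrumSet:
    """Savitzky-Golay derivative of each spectrum with respect to wavenumber.

    Edge points where the full window does not fit are dropped (half-window
    trimmed at each end), so the returned grid is shorter by sg_window - 1
    points.  With ``sg_scale_spacing`` the output carries the 1/h**deriv
    factor (units absorbance * cm^deriv for the default second derivative).
    """
    if s.n_wavenumbers < cfg.sg_window:
        raise GridError(
            f"grid of {s.n_wavenumbers} points shorter than SG window {cfg.sg_window}"
        )
    h = grid_spacing(s.wavenumbers)
    delta = h if cfg.sg_scale_spacing else 1.0
    deriv = savgol_filter(
        s.absorbance,
        window_length=cfg.sg_window,
        polyorder=cfg.sg_polyorder,
        deriv=cfg.sg_deriv,
        delta=delta,
        axis=1,
    )
    half = cfg.sg_window // 2
    sl = slice(half, s.n_wavenumbers - half)
    return SpectrumSet(s.wavenumbers[sl].copy(), deriv[:, sl].copy(), list(s.meta))


def _emsc_design(wavenumbers: np.ndarray, reference: np.ndarray, poly_order: int):
    """Columns [1, p1, ..., p_k, r] with p_j = t**j, t the affine map to [-1,1]."""
    wmin, wmax = wavenumbers.min(), wavenumbers.max()
    t = 2.0 * (wavenumbers - wmin) / (wmax - wmin) - 1.0 if wmax > wmin else np.zeros_like(wavenumbers)
    cols = [np.ones_like(wavenumbers)]
    for j in range(1, poly_order + 1):
        cols.append(t**j)
    cols.append(reference)
    return np.column_stack(cols)


def emsc_correct(
    s: SpectrumSet,
    cfg: PreprocessConfig = PreprocessConfig(),
    reference: Optional[np.ndarray] = None,
    b_tol: float = 1e-8,
) -> Tuple[SpectrumSet, List[EMSCCoefficients]]:
    """EMSC-correct every spectrum against a common reference.

    ``s`` must already be restricted to the correction range (the fit is one
    least-squares problem over the concatenated regions, not per region).
    ``reference`` defaults to the mean spectrum of ``s``; pass the training
    reference when correcting held-out data to avoid information leak.
    """
    ref = s.absorbance.mean(axis=0) if reference is None else np.asarray(reference, float)
    if ref.shape != (s.n_wavenumbers,):
        raise ValueError("reference length does not match the grid")
    D = _emsc_design(s.wavenumbers, ref, cfg.emsc_poly_order)
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise np.linalg.LinAlgError("EMSC design matrix is rank deficient")
    coef, *_ = np.linalg.lstsq(D, s.absorbance.T, rcond=None)  # (k+2, n_samples)
    b = coef[-1]
    bad = np.abs(b) < b_tol
    if bad.any():
        ids = [s.meta[i].sample_id for i in np.flatnonzero(bad)]
        raise DegenerateSampleError(
            f"EMSC multiplicative coefficient below {b_tol} for samples {ids}"
        )
    baseline = D[:, :-1] @ coef[:-1]  # (n_wn, n_samples)
    corrected = (s.absorbance - baseline.T) / b[:, None]
    n_poly = cfg.emsc_poly_order
    records = [
        EMSCCoefficients(
            sample_id=m.sample_id,
            a=float(coef[0, i]),
            b=float(b[i]),
            c=float(coef[1, i]) if n_poly >= 1 else 0.0,
            d=float(coef[2, i]) if n_poly >= 2 else 0.0,
        )
        for i, m in enumerate(s.meta)
    ]
    return SpectrumSet(s.wavenumbers.copy(), corrected, list(s.meta)), records


def preprocess_pipeline(
    raw: SpectrumSet,
    cfg: PreprocessConfig = PreprocessConfig(),
    reference: Optional[np.ndarray] = None,
) -> Tuple[SpectrumSet, List[EMSCCoefficients]]:
    """Full chain: replicate averaging -> SG derivative -> region selection -> EMSC.

    The output grid is the combined-region subset of the half-window-trimmed
    grid.  Pass ``reference`` (on that output grid) to correct against a
    fixed training reference instead of the mean of the processed set.
    """
    averaged = average_technical_replicates(raw)
    deriv = savitzky_golay_derivative(averaged, cfg)
    restricted = select_region(deriv, cfg.emsc_regions)
    return emsc_correct(restricted, cfg, reference=reference)
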