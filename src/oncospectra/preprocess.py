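"""Spectral pre-processing chain for liquid-phase FTIR fingerprints.

Order of operations (each per-sample, no cross-sample statistics):

1. water-displacement correction: add alpha x water reference so the OLS
   slope over the solute-free 2000-2300 cm^-1 window vanishes;
2. truncation to 1000-3000 cm^-1 and removal of the silent region between
   1750 and 2800 cm^-1 (endpoints retained);
3. Euclidean (L2) vector normalization;
4. optional Savitzky-Golay second derivative, computed per contiguous
   segment so the silent-region gap is never smoothed across.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .spectra import CohortSet, Spectrum, contiguous_segments

__all__ = [
    "PreprocessConfig",
    "water_correct",
    "restrict_and_mask",
    "vector_normalize",
    "second_derivative",
    "apply_pipeline",
]


@dataclass(frozen=True)
class PreprocessConfig:
    do_water_correction: bool = True
    do_normalize: bool = True
    do_second_derivative: bool = False
    flat_window: tuple = (2000.0, 2300.0)
    keep_range: tuple = (1000.0, 3000.0)
    silent_region: tuple = (1750.0, 2800.0)
    sg_window: int = 9
    sg_polyorder: int = 3

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ValueError("sg_window must be odd and > sg_polyorder")
        lo, hi = self.keep_range
        a, b = self.silent_region
        if not (lo <= a < b <= hi):
            raise ValueError("silent_region must lie within keep_range")


def _ols_slope(wn: np.ndarray, y: np.ndarray) -> np.ndarray:
    """OLS slope of y against wn; y may be 1-D or (n_samples, n_points)."""
    wc = wn - wn.mean()
    denom = float(np.dot(wc, wc))
    return np.asarray(y) @ wc / denom


def water_correct(s: Spectrum, water: Spectrum,
                  flat_window: tuple = (2000.0, 2300.0)):
    """Flatten the solute-free window by adding a multiple of the water
    reference; returns ``(corrected, alpha)`` with alpha possibly negative.

    alpha = -slope(s)/slope(water), slopes being OLS linear slopes of
    absorbance against wavenumber restricted to the flat window; this is the
    closed-form minimizer of the absolute window slope of ``s + alpha*water``.
    """
    if not s.same_grid(water):
        raise ValueError("spectrum and water reference must share a grid")
    lo, hi = flat_window
    win = (s.wavenumbers >= lo) & (s.wavenumbers <= hi)
    if win.sum() < 3:
        raise ValueError("flat window contains fewer than 3 grid points")
    wnw = s.wavenumbers[win]
    slope_w = float(_ols_slope(wnw, water.absorbance[win]))
    if abs(slope_w) <= 1e-12:
        raise ValueError(
            "water reference has (numerically) zero slope in the flat "
            "window; the correction coefficient is unidentifiable")
    slope_s = float(_ols_slope(wnw, s.absorbance[win]))
    alpha = -slope_s / slope_w
    return Spectrum(s.wavenumbers, s.absorbance + alpha * water.absorbance), alpha


def restrict_and_mask(s: Spectrum,
                      cfg: PreprocessConfig = PreprocessConfig()) -> Spectrum:
    """Truncate to ``keep_range`` (inclusive) and drop the open silent
    interval; the printed endpoints 1750 and 2800 cm^-1 are retained."""
    keep = _mask(s.wavenumbers, cfg)
    if not keep.any():
        raise ValueError("masking removed every grid point")
    return Spectrum(s.wavenumbers[keep], s.absorbance[keep])


def _mask(wn: np.ndarray, cfg: PreprocessConfig) -> np.ndarray:
    lo, hi = cfg.keep_range
    a, b = cfg.silent_region
    return (wn >= lo) & (wn <= hi) & ~((wn > a) & (wn < b))


def vector_normalize(s: Spectrum) -> Spectrum:
    nrm = float(np.linalg.norm(s.absorbance))
    if nrm <= 0:
        raise ValueError("cannot normalize a zero spectrum")
    return Spectrum(s.wavenumbers, s.absorbance / nrm)


def second_derivative(s: Spectrum,
                      cfg: PreprocessConfig = PreprocessConfig()) -> Spectrum:
    """Savitzky-Golay second derivative per contiguous grid segment."""
    out = np.empty_like(s.absorbance)
    for seg in contiguous_segments(s.wavenumbers):
        wn = s.wavenumbers[seg]
        if wn.size < cfg.sg_window:
            raise ValueError("grid segment shorter than sg_window")
        delta = float(np.median(np.diff(wn)))
        out[seg] = savgol_filter(s.absorbance[seg], cfg.sg_window,
                                 cfg.sg_polyorder, deriv=2, delta=delta,
                                 mode="interp")
    return Spectrum(s.wavenumbers, out)


def apply_pipeline(cohort: CohortSet,
                   cfg: PreprocessConfig = PreprocessConfig(),
                   water: Spectrum | None = None) -> CohortSet:
    """Run the per-sample chain over a whole cohort (vectorized).

    Stage order: water_correct -> restrict_and_mask -> vector_normalize ->
    optional second_derivative. The water-correction coefficients are kept
    in ``provenance["water_alpha"]``.
    """
    wn = cohort.wavenumbers
    X = cohort.X.copy()
    prov = dict(cohort.provenance)
    prov["preprocess_config"] = cfg.__dict__.copy()

    if cfg.do_water_correction:
        w = water or cohort.water
        if w is None:
            raise ValueError("water correction requested but no water "
                             "reference is available")
        if not np.allclose(w.wavenumbers, wn, atol=1e-9):
            raise ValueError("water reference grid does not match cohort grid")
        lo, hi = cfg.flat_window
        win = (wn >= lo) & (wn <= hi)
        wnw = wn[win]
        slope_w = float(_ols_slope(wnw, w.absorbance[win]))
        if abs(slope_w) <= 1e-12:
            raise ValueError("water reference slope numerically zero")
        alphas = -_ols_slope(wnw, X[:, win]) / slope_w
        X = X + np.outer(alphas, w.absorbance)
        prov["water_alpha"] = dict(zip(cohort.sample_ids, alphas.tolist()))

    keep = _mask(wn, cfg)
    if not keep.any():
        raise ValueError("masking removed every grid point")
    wn = wn[keep]
    X = X[:, keep]

    if cfg.do_normalize:
        norms = np.linalg.norm(X, axis=1)
        if np.any(norms <= 0):
            raise ValueError("zero spectrum cannot be normalized")
        X = X / norms[:, None]

    if cfg.do_second_derivative:
        for seg in contiguous_segments(wn):
            if wn[seg].size < cfg.sg_window:
                raise ValueError("grid segment shorter than sg_window")
            delta = float(np.median(np.diff(wn[seg])))
            X[:, seg] = savgol_filter(X[:, seg], cfg.sg_window,
                                      cfg.sg_polyorder, deriv=2, delta=delta,
                                      mode="interp", axis=1)

    spectra = pd.DataFrame(X, index=cohort.sample_ids, columns=wn)
    return CohortSet(spectra, cohort.meta.copy(), water=cohort.water,
                     provenance=prov)


def fig_variants(base: PreprocessConfig = PreprocessConfig()):
    """The four preprocessing variants compared in the study: raw (masked
    only), normalized, water-corrected + normalized, and the latter plus a
    second derivative."""
    return {
        "masked": replace(base, do_water_correction=False, do_normalize=False,
                          do_second_derivative=False),
        "normalized": replace(base, do_water_correction=False,
                              do_normalize=True, do_second_derivative=False),
        "water+norm": replace(base, do_water_correction=True,
                              do_normalize=True, do_second_derivative=False),
        "water+norm+d2": replace(base, do_water_correction=True,
                                 do_normalize=True, do_second_derivative=True),
    }
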