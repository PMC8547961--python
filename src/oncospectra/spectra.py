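"""Core containers for liquid-phase FTIR spectra and cohorts.

A *spectrum* is an absorbance vector aligned to a wavenumber grid (cm^-1).
After the silent region is masked the grid is no longer contiguous, so
:class:`Spectrum` only requires strictly increasing wavenumbers, while
:class:`WavenumberGrid` enforces the uniform acquisition grid of the
instrument (950-3050 cm^-1 at 2 cm^-1 sampling by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "WavenumberGrid",
    "Spectrum",
    "CohortSet",
    "contiguous_segments",
]


@dataclass(frozen=True)
class WavenumberGrid:
    """Uniform acquisition grid in cm^-1, strictly increasing."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("grid must be a 1-D array with at least 2 points")
        d = np.diff(v)
        if np.any(d <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.ptp(d) > 1e-9:
            raise ValueError("grid spacing must be uniform (within 1e-9)")
        object.__setattr__(self, "values", v)

    @classmethod
    def default(cls, start: float = 950.0, stop: float = 3050.0,
                step: float = 2.0) -> "WavenumberGrid":
        n = int(round((stop - start) / step)) + 1
        return cls(start + step * np.arange(n))

    @property
    def spacing(self) -> float:
        return float(self.values[1] - self.values[0])

    def __len__(self) -> int:
        return self.values.size

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)


def _as_wavenumbers(grid) -> np.ndarray:
    if isinstance(grid, WavenumberGrid):
        return grid.values
    return np.asarray(grid, dtype=float)


@dataclass
class Spectrum:
    """Absorbance (AU) on a strictly increasing, possibly gapped grid."""

    wavenumbers: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        self.wavenumbers = _as_wavenumbers(self.wavenumbers)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavenumbers.shape != self.absorbance.shape:
            raise ValueError("wavenumbers and absorbance must have equal length")
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise ValueError("wavenumbers must be strictly increasing")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance must be finite")

    def copy(self) -> "Spectrum":
        return Spectrum(self.wavenumbers.copy(), self.absorbance.copy())

    def same_grid(self, other: "Spectrum", tol: float = 1e-9) -> bool:
        return (self.wavenumbers.shape == other.wavenumbers.shape
                and np.allclose(self.wavenumbers, other.wavenumbers, atol=tol))


def contiguous_segments(wavenumbers: np.ndarray,
                        gap_factor: float = 1.5) -> list[slice]:
    """Slices of runs with no gap larger than ``gap_factor`` x median spacing.

    A masked spectrum (silent region removed) has exactly two such segments;
    derivative filtering and trapezoidal integration must never bridge them.
    """
    wn = np.asarray(wavenumbers, dtype=float)
    if wn.size == 0:
        return []
    if wn.size == 1:
        return [slice(0, 1)]
    d = np.diff(wn)
    step = np.median(d)
    breaks = np.flatnonzero(d > gap_factor * step)
    starts = np.concatenate([[0], breaks + 1])
    stops = np.concatenate([breaks + 1, [wn.size]])
    return [slice(int(a), int(b)) for a, b in zip(starts, stops)]


@dataclass
class CohortSet:
    """A cohort: wide spectra matrix plus aligned sample metadata.

    ``spectra`` is a DataFrame with one row per sample (index = sample id)
    and one float column per wavenumber; ``meta`` is indexed identically and
    carries group / age / sex / bmi / site / t_class / grade.
    """

    spectra: pd.DataFrame
    meta: pd.DataFrame
    water: Spectrum | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.spectra.index.equals(self.meta.index):
            raise ValueError("spectra and meta must share the same sample index")
        self.spectra.columns = self.spectra.columns.astype(float)

    @property
    def wavenumbers(self) -> np.ndarray:
        return self.spectra.columns.to_numpy(dtype=float)

    @property
    def X(self) -> np.ndarray:
        return self.spectra.to_numpy(dtype=float)

    @property
    def sample_ids(self) -> pd.Index:
        return self.spectra.index

    def groups(self) -> pd.Series:
        return self.meta["group"]

    def subset(self, ids) -> "CohortSet":
        ids = pd.Index(ids)
        return CohortSet(self.spectra.loc[ids].copy(), self.meta.loc[ids].copy(),
                         water=self.water, provenance=dict(self.provenance))

    def copy(self) -> "CohortSet":
        return self.subset(self.sample_ids)

    # ---------------------------------------------------------------- I/O
    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        sp = self.spectra.copy()
        sp.insert(0, "sample_id", sp.index)
        sp.to_csv(d / "spectra.csv", index=False)
        meta = self.meta.copy()
        meta.insert(0, "sample_id", meta.index)
        meta.to_csv(d / "metadata.csv", index=False)
        if self.water is not None:
            pd.DataFrame({"wavenumber": self.water.wavenumbers,
                          "absorbance": self.water.absorbance}
                         ).to_csv(d / "water_reference.csv", index=False)

    @classmethod
    def load(cls, directory: str | Path) -> "CohortSet":
        d = Path(directory)
        sp = pd.read_csv(d / "spectra.csv").set_index("sample_id")
        meta = pd.read_csv(d / "metadata.csv").set_index("sample_id")
        meta = meta.loc[sp.index]
        water = None
        wpath = d / "water_reference.csv"
        if wpath.exists():
            w = pd.read_csv(wpath)
            water = Spectrum(w["wavenumber"].to_numpy(),
                             w["absorbance"].to_numpy())
        return cls(sp, meta, water=water)
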