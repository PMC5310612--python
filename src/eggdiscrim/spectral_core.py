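"""Reflectance / sensitivity spectra: reading, validation and regridding.

All downstream colour computation happens on a common wavelength grid.
The canonical working grid is 300-700 nm at 1 nm steps (avian-visible
range, including the UV receptor).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_GRID",
    "Spectrum",
    "SpectrumSet",
    "read_spectra",
    "write_spectra",
    "resample_to_grid",
]

logger = logging.getLogger(__name__)

#: Canonical working grid, 300-700 nm at 1 nm.
CANONICAL_GRID = np.arange(300.0, 701.0, 1.0)

# Small calibration overshoot tolerated on reflectance proportions.
_REFLECTANCE_MAX = 1.05


@dataclass
class Spectrum:
    """A single spectrum sampled on a strictly increasing wavelength grid.

    Parameters
    ----------
    wavelengths_nm : array-like
        Strictly increasing wavelengths in nanometres.
    values : array-like
        Spectral values at each wavelength.  For ``kind="reflectance"``
        these are dimensionless proportions in [0, 1.05]; negatives are
        clipped to zero with a logged warning.
    label : str
        Sample identifier.
    kind : str
        One of ``reflectance``, ``sensitivity``, ``irradiance``.  Only
        reflectance values are range-checked.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    label: str = ""
    kind: str = "reflectance"

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths_nm.ndim != 1 or self.values.ndim != 1:
            raise ValueError("wavelengths and values must be 1-D")
        if self.wavelengths_nm.shape != self.values.shape:
            raise ValueError("wavelengths and values must have equal length")
        if not np.all(np.isfinite(self.wavelengths_nm)):
            raise ValueError("non-finite wavelengths")
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ValueError("non-monotonic wavelengths")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite values in spectrum {self.label!r}")
        if np.any(self.values < 0):
            logger.warning(
                "negative values in spectrum %r clipped to 0", self.label
            )
            self.values = np.clip(self.values, 0.0, None)
        if self.kind == "reflectance" and np.any(self.values > _REFLECTANCE_MAX):
            raise ValueError(
                f"reflectance above {_REFLECTANCE_MAX} in spectrum "
                f"{self.label!r}; check units (percent vs proportion)"
            )

    @property
    def wl_min(self) -> float:
        return float(self.wavelengths_nm[0])

    @property
    def wl_max(self) -> float:
        return float(self.wavelengths_nm[-1])


@dataclass
class SpectrumSet:
    """An ordered collection of spectra sharing one wavelength grid."""

    grid: np.ndarray
    spectra: list[Spectrum]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        labels = [s.label for s in self.spectra]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate spectrum labels")
        for s in self.spectra:
            if s.wavelengths_nm.shape != self.grid.shape or not np.allclose(
                s.wavelengths_nm, self.grid
            ):
                raise ValueError(
                    f"spectrum {s.label!r} is not on the common grid"
                )

    def __len__(self) -> int:
        return len(self.spectra)

    def __getitem__(self, label: str) -> Spectrum:
        for s in self.spectra:
            if s.label == label:
                return s
        raise KeyError(label)

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.spectra]

    def to_frame(self) -> pd.DataFrame:
        data = {"wl": self.grid}
        for s in self.spectra:
            data[s.label] = s.values
        return pd.DataFrame(data)


def read_spectra(path, units: str = "proportion", kind: str = "reflectance") -> SpectrumSet:
    """Read a spectra CSV (column 1 = wavelength, one column per sample).

    ``units="percent"`` divides sample columns by 100 on read.
    """
    if units not in ("proportion", "percent"):
        raise ValueError(f"unknown units {units!r}")
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("need a wavelength column plus >=1 sample column")
    cols = list(df.columns)
    if len(set(cols)) != len(cols):
        raise ValueError("duplicate column names")
    for col in cols:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            row = int(np.argmax((bad | df[col].isna()).to_numpy()))
            raise ValueError(f"non-numeric cell at row {row}, column {col!r}")
    wl = df[cols[0]].to_numpy(dtype=float)
    if np.any(np.diff(wl) <= 0):
        raise ValueError("non-monotonic wavelengths")
    scale = 0.01 if units == "percent" else 1.0
    spectra = [
        Spectrum(wl, df[c].to_numpy(dtype=float) * scale, label=c, kind=kind)
        for c in cols[1:]
    ]
    return SpectrumSet(
        grid=wl,
        spectra=spectra,
        metadata={"source": str(path), "units": units},
    )


def write_spectra(sset: SpectrumSet, path) -> None:
    """Write a SpectrumSet back to CSV (proportion units, full precision)."""
    sset.to_frame().to_csv(path, index=False, float_format="%.12g")


def resample_to_grid(s: Spectrum, grid: np.ndarray) -> Spectrum:
    """Linearly interpolate a spectrum onto ``grid``.

    Exact at shared nodes; raises if the grid extends beyond the
    spectrum's coverage.
    """
    grid = np.asarray(grid, dtype=float)
    if grid[0] < s.wl_min or grid[-1] > s.wl_max:
        raise ValueError(
            "insufficient spectral coverage: spectrum "
            f"[{s.wl_min}, {s.wl_max}] nm cannot cover grid "
            f"[{grid[0]}, {grid[-1]}] nm"
        )
    vals = np.interp(grid, s.wavelengths_nm, s.values)
    return Spectrum(grid, vals, label=s.label, kind=s.kind)
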