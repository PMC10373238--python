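"""Spectral data model, delimited-text I/O and wavelength masking.

A :class:`SpectraSet` holds a sample-by-wavelength absorbance matrix on a
strictly increasing wavelength grid (nm).  The on-disk format is plain CSV:
first column ``wavelength_nm``, one further column per sample, absorbance in
AU, header row required, ``.`` decimal separator.  Wavelength masking keeps
only user-chosen closed intervals, which is how noise-dominated spectral
regions are excluded before model building.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WavelengthGrid",
    "SpectraSet",
    "WavelengthMask",
    "SpectraParseError",
    "MaskError",
    "read_spectra",
    "write_spectra",
    "apply_mask",
]


class SpectraParseError(ValueError):
    """Raised when a spectra file is malformed (with row/column context)."""


class MaskError(ValueError):
    """Raised when a wavelength mask does not overlap the grid or empties it."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing wavelengths in nm.

    The default grid is 220..400 nm inclusive at 1 nm steps (181 points),
    the scan range of a conventional UV-Vis spectrophotometer run.
    """

    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.ndim != 1 or wl.size == 0:
            raise ValueError("wavelength grid must be a non-empty 1-D array")
        if not np.all(np.isfinite(wl)):
            raise ValueError("wavelength grid contains non-finite values")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths", wl)

    @classmethod
    def default(cls) -> "WavelengthGrid":
        return cls(np.arange(220.0, 401.0, 1.0))

    def __len__(self) -> int:
        return int(self.wavelengths.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return np.array_equal(self.wavelengths, other.wavelengths)

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash(self.wavelengths.tobytes())


@dataclass
class SpectraSet:
    """Absorbance matrix (samples x wavelengths) on a wavelength grid."""

    grid: WavelengthGrid
    absorbance: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        a = np.asarray(self.absorbance, dtype=float)
        if a.ndim != 2:
            raise ValueError("absorbance must be a 2-D samples x wavelengths matrix")
        if a.shape[1] != len(self.grid):
            raise ValueError(
                f"absorbance has {a.shape[1]} wavelength columns but grid has "
                f"{len(self.grid)} points"
            )
        if not np.all(np.isfinite(a)):
            raise ValueError("absorbance contains non-finite values")
        if not self.sample_ids:
            self.sample_ids = [f"S{i + 1}" for i in range(a.shape[0])]
        if len(self.sample_ids) != a.shape[0]:
            raise ValueError("sample_ids length does not match number of rows")
        self.absorbance = a

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    def subset(self, indices: Sequence[int]) -> "SpectraSet":
        """Return a new set containing the given sample rows (order kept)."""
        idx = list(indices)
        return SpectraSet(
            grid=self.grid,
            absorbance=self.absorbance[idx, :],
            sample_ids=[self.sample_ids[i] for i in idx],
        )

    def to_frame(self) -> pd.DataFrame:
        """Wavelength-indexed frame, one column per sample (the file layout)."""
        return pd.DataFrame(
            self.absorbance.T,
            index=pd.Index(self.grid.wavelengths, name="wavelength_nm"),
            columns=self.sample_ids,
        )


@dataclass(frozen=True)
class WavelengthMask:
    """Included closed intervals [lo, hi] in nm; wavelengths outside are dropped."""

    intervals: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        ivs = tuple((float(lo), float(hi)) for lo, hi in self.intervals)
        if not ivs:
            raise MaskError("mask must contain at least one interval")
        for lo, hi in ivs:
            if hi < lo:
                raise MaskError(f"mask interval [{lo}, {hi}] has hi < lo")
        object.__setattr__(self, "intervals", ivs)

    def contains(self, wavelengths: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths, dtype=float)
        keep = np.zeros(wl.shape, dtype=bool)
        for lo, hi in self.intervals:
            keep |= (wl >= lo) & (wl <= hi)
        return keep


def apply_mask(spectra: SpectraSet, mask: WavelengthMask) -> SpectraSet:
    """Keep only the wavelengths inside the mask's included intervals.

    Idempotent; sample order is preserved.  Raises :class:`MaskError` when no
    wavelength survives (mask outside the grid, or degenerate intervals).
    """
    keep = mask.contains(spectra.grid.wavelengths)
    if not keep.any():
        raise MaskError(
            f"mask {list(mask.intervals)} excludes every wavelength of the grid "
            f"[{spectra.grid.wavelengths[0]:g}, {spectra.grid.wavelengths[-1]:g}] nm"
        )
    return SpectraSet(
        grid=WavelengthGrid(spectra.grid.wavelengths[keep]),
        absorbance=spectra.absorbance[:, keep],
        sample_ids=list(spectra.sample_ids),
    )


def write_spectra(spectra: SpectraSet, path: str | Path) -> None:
    """Write the CSV layout: wavelength_nm column then one column per sample."""
    spectra.to_frame().to_csv(path, float_format="%.12g")


def read_spectra(path: str | Path) -> SpectraSet:
    """Parse the spectra CSV, reporting the offending row/column on failure."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, header=0)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise SpectraParseError(f"{path}: malformed delimited text: {exc}") from exc
    if frame.shape[1] < 2:
        raise SpectraParseError(f"{path}: need a wavelength column plus >=1 sample column")
    wl_col = frame.columns[0]
    for col in frame.columns:
        numeric = pd.to_numeric(frame[col], errors="coerce")
        bad = numeric.isna() & frame[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise SpectraParseError(
                f"{path}: non-numeric cell at row {row}, column '{col}': "
                f"{frame[col][bad.idxmax()]!r}"
            )
        if numeric.isna().any():
            row = int(numeric.isna().idxmax()) + 2
            raise SpectraParseError(f"{path}: missing cell at row {row}, column '{col}'")
        frame[col] = numeric
    wl = frame[wl_col].to_numpy(dtype=float)
    diffs = np.diff(wl)
    if np.any(diffs == 0):
        row = int(np.argmax(diffs == 0)) + 3
        raise SpectraParseError(f"{path}: duplicated wavelength at row {row}")
    if np.any(diffs < 0):
        row = int(np.argmax(diffs < 0)) + 3
        raise SpectraParseError(f"{path}: wavelengths not increasing at row {row}")
    return SpectraSet(
        grid=WavelengthGrid(wl),
        absorbance=frame.iloc[:, 1:].to_numpy(dtype=float).T,
        sample_ids=[str(c) for c in frame.columns[1:]],
    )
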