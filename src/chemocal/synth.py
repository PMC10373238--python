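"""Synthetic UV-Vis spectra generator.

Pure-component absorptivity spectra are modeled as sums of Gaussian bands,
a(lambda) = sum_b h_b * exp(-(lambda - c_b)^2 / (2 s_b^2)) in AU*mL/ug, so a
mixture obeys Beer-Lambert additivity A = C.K exactly before noise.  The
default two components mimic a pair of antiviral drugs whose UV spectra
overlap in the 230-280 nm window (band maxima near 323 nm and 246 nm), which
is the regime that motivates multivariate rather than single-wavelength
calibration.  Instrument noise is homoscedastic Gaussian (default
sd 0.002 AU); an optional broad "plasma" interferent band can be added with
per-sample level jitter to emulate an endogenous matrix background that the
calibration components do not account for.

All randomness is driven by an explicit seed; identical seeds give
bit-identical spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .design import MixtureDesign
from .spectra import SpectraSet, WavelengthGrid

__all__ = [
    "GaussianBand",
    "PureComponentModel",
    "NoiseModel",
    "DEFAULT_COMPONENTS",
    "PLASMA_INTERFERENT",
    "pure_spectrum",
    "simulate_concentrations",
    "simulate_mixtures",
    "simulate_plasma_set",
]


@dataclass(frozen=True)
class GaussianBand:
    center_nm: float
    sigma_nm: float
    height: float  # AU*mL/ug at unit concentration

    def __post_init__(self) -> None:
        if self.sigma_nm <= 0:
            raise ValueError("band sigma must be > 0")
        if self.height < 0:
            raise ValueError("band height must be >= 0")


@dataclass(frozen=True)
class PureComponentModel:
    """Absorptivity spectrum of one analyte as a Gaussian band sum."""

    name: str
    bands: tuple[GaussianBand, ...]

    def absorptivity(self, grid: WavelengthGrid) -> np.ndarray:
        wl = grid.wavelengths
        lo, hi = wl[0], wl[-1]
        a = np.zeros_like(wl)
        for b in self.bands:
            if not (lo <= b.center_nm <= hi):
                raise ValueError(
                    f"{self.name}: band center {b.center_nm} nm outside grid "
                    f"[{lo:g}, {hi:g}] nm"
                )
            a += b.height * np.exp(-((wl - b.center_nm) ** 2) / (2 * b.sigma_nm**2))
        return a


# Surrogate shapes for the two-drug system: maxima near 323 and 246 nm with
# shared absorption in 230-280 nm.  These are configuration defaults, not
# physically calibrated absorptivities.
DEFAULT_COMPONENTS: tuple[PureComponentModel, ...] = (
    PureComponentModel(
        name="favipiravir",
        bands=(GaussianBand(323.0, 20.0, 0.055), GaussianBand(245.0, 14.0, 0.020)),
    ),
    PureComponentModel(
        name="remdesivir",
        bands=(GaussianBand(246.0, 16.0, 0.065), GaussianBand(278.0, 14.0, 0.030)),
    ),
)

# Broad featureless background standing in for endogenous plasma absorbance.
PLASMA_INTERFERENT = PureComponentModel(
    name="plasma_background",
    bands=(GaussianBand(265.0, 45.0, 0.050), GaussianBand(228.0, 12.0, 0.040)),
)


@dataclass(frozen=True)
class NoiseModel:
    """Instrument noise and background terms; ``seed`` is mandatory."""

    seed: int
    noise_sd: float = 0.002          # AU, homoscedastic Gaussian
    baseline_offset: float = 0.0     # AU
    baseline_slope: float = 0.0      # AU/nm, relative to the first grid point
    interferent: PureComponentModel | None = None
    interferent_level: float = 0.0   # nominal "concentration" of the interferent
    interferent_jitter: float = 0.0  # fractional per-sample level variation

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 <= self.interferent_jitter <= 1):
            raise ValueError("interferent_jitter must be in [0, 1]")


def pure_spectrum(model: PureComponentModel, grid: WavelengthGrid) -> np.ndarray:
    """Absorptivity spectrum at unit concentration (AU*mL/ug), length = grid."""
    return model.absorptivity(grid)


def _simulate(
    conc: np.ndarray,
    components: Sequence[PureComponentModel],
    noise: NoiseModel,
    grid: WavelengthGrid,
    sample_ids: list[str],
    with_interferent: bool,
) -> SpectraSet:
    conc = np.asarray(conc, dtype=float)
    if conc.ndim != 2 or conc.shape[1] != len(components):
        raise ValueError(
            f"concentration matrix has {conc.shape[1] if conc.ndim == 2 else '?'} "
            f"columns but {len(components)} component models were given"
        )
    wl = grid.wavelengths
    K = np.vstack([c.absorptivity(grid) for c in components])  # (m, p)
    A = conc @ K
    A += noise.baseline_offset + noise.baseline_slope * (wl - wl[0])
    rng = np.random.default_rng(noise.seed)
    # draw order fixed (noise matrix, then jitter) so a zero-level interferent
    # reproduces the clean set bit-exactly at the same seed
    if noise.noise_sd > 0:
        A = A + rng.normal(0.0, noise.noise_sd, size=A.shape)
    if with_interferent:
        if noise.interferent is None:
            raise ValueError("plasma simulation requires noise.interferent")
        levels = np.full(conc.shape[0], noise.interferent_level)
        if noise.interferent_jitter > 0:
            levels = levels * (
                1.0 + noise.interferent_jitter * rng.uniform(-1.0, 1.0, conc.shape[0])
            )
        A = A + np.outer(levels, noise.interferent.absorptivity(grid))
    return SpectraSet(grid=grid, absorbance=A, sample_ids=sample_ids)


def simulate_concentrations(
    conc: np.ndarray,
    components: Sequence[PureComponentModel],
    noise: NoiseModel,
    grid: WavelengthGrid,
    sample_ids: list[str] | None = None,
) -> SpectraSet:
    """Simulate spectra for an arbitrary concentration matrix (n x m, ug/mL)."""
    conc = np.atleast_2d(np.asarray(conc, dtype=float))
    ids = sample_ids or [f"S{i + 1}" for i in range(conc.shape[0])]
    return _simulate(conc, components, noise, grid, ids, with_interferent=False)


def simulate_mixtures(
    design: MixtureDesign,
    components: Sequence[PureComponentModel],
    noise: NoiseModel,
    grid: WavelengthGrid,
) -> SpectraSet:
    """Simulate the spectra of every design mixture (Beer-Lambert + noise)."""
    if design.conc.shape[1] != len(components):
        raise ValueError(
            f"design has {design.conc.shape[1]} factors but "
            f"{len(components)} component models were given"
        )
    ids = [f"S{i}" for i in design.sample_id]
    return _simulate(design.conc, components, noise, grid, ids, with_interferent=False)


def simulate_plasma_set(
    design: MixtureDesign,
    components: Sequence[PureComponentModel],
    noise: NoiseModel,
    grid: WavelengthGrid,
) -> SpectraSet:
    """Like :func:`simulate_mixtures` plus an additive interferent background.

    Each sample receives ``interferent_level`` (optionally jittered per
    sample) times the interferent absorptivity spectrum, emulating an
    endogenous plasma matrix that is absent from the calibration model.
    """
    if noise.interferent is None:
        raise ValueError("simulate_plasma_set requires a NoiseModel with an interferent")
    ids = [f"S{i}" for i in design.sample_id]
    return _simulate(design.conc, components, noise, grid, ids, with_interferent=True)
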