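"""Figures of merit for analytical method validation.

Covers the standard ICH-style validation machinery around a fitted
calibration model: percentage recoveries with mean/SD/RSD, detection and
quantitation limits from the residual standard deviation of the
predicted-vs-nominal line (LOD = 3.3 SD/slope, LOQ = 10 SD/slope), the
3-level x 3-replicate accuracy protocol, intra-/inter-day precision,
standard-addition selectivity, and the two-sample t / variance-ratio F
comparison against a reference method at the 95% confidence level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .models import CalibrationModel, predict
from .spectra import WavelengthGrid
from .synth import NoiseModel, PureComponentModel, simulate_concentrations

__all__ = [
    "RecoverySummary",
    "MeritInputs",
    "StdAdditionRow",
    "StdAdditionResult",
    "MethodComparison",
    "AccuracyResult",
    "PrecisionResult",
    "recovery_summary",
    "linearity_merit",
    "lod_loq",
    "accuracy_protocol",
    "precision_protocol",
    "standard_addition",
    "compare_methods",
]

LINEARITY_RANGE = (1.0, 17.0)  # ug/mL, the calibrated design range


@dataclass
class RecoverySummary:
    """Percent recoveries (100*predicted/nominal) with mean, SD (n-1), RSD."""

    recoveries: np.ndarray
    n: int
    mean: float
    sd: float
    rsd: float

    def __str__(self) -> str:
        return f"{self.mean:.2f} +/- {self.rsd:.3g} %RSD (n={self.n})"


def recovery_summary(
    predicted: Sequence[float], nominal: Sequence[float] | float
) -> RecoverySummary:
    pred = np.asarray(predicted, dtype=float)
    nom = np.asarray(nominal, dtype=float)
    if nom.ndim == 0:
        nom = np.full_like(pred, float(nom))
    if pred.shape != nom.shape:
        raise ValueError(f"length mismatch: {pred.shape} predicted vs {nom.shape} nominal")
    if np.any(nom <= 0):
        raise ValueError("nominal concentrations must be > 0")
    rec = 100.0 * pred / nom
    n = rec.size
    mean = float(rec.mean())
    sd = float(rec.std(ddof=1)) if n >= 2 else 0.0
    if mean <= 0:
        raise ValueError("mean recovery must be > 0 for an RSD")
    return RecoverySummary(recoveries=rec, n=n, mean=mean, sd=sd, rsd=100.0 * sd / mean)


@dataclass(frozen=True)
class MeritInputs:
    """Slope and residual SD of the predicted-vs-nominal regression line."""

    slope: float
    sd_residual: float
    linearity_range: tuple[float, float] = LINEARITY_RANGE

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("slope must be nonzero")
        if self.sd_residual < 0:
            raise ValueError("residual SD must be >= 0")


def linearity_merit(
    nominal: Sequence[float],
    predicted: Sequence[float],
    linearity_range: tuple[float, float] = LINEARITY_RANGE,
) -> MeritInputs:
    """OLS of predicted on nominal; residual SD is s_{y/x} with divisor n-2."""
    x = np.asarray(nominal, dtype=float)
    y = np.asarray(predicted, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired points for a residual SD")
    res = stats.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    s_yx = float(np.sqrt((resid**2).sum() / (x.size - 2)))
    return MeritInputs(slope=float(res.slope), sd_residual=s_yx, linearity_range=linearity_range)


def lod_loq(inputs: MeritInputs) -> tuple[float, float]:
    """(LOD, LOQ) in ug/mL: 3.3*SD/|slope| and 10*SD/|slope|."""
    scale = inputs.sd_residual / abs(inputs.slope)
    return 3.3 * scale, 10.0 * scale


@dataclass
class AccuracyResult:
    levels: np.ndarray                 # (L,), ug/mL
    per_level_mean: np.ndarray         # (L, m), mean %R per level
    pooled: list[RecoverySummary]      # per component, n = L*reps


def _protocol_concentrations(levels: Sequence[float], reps: int, m: int) -> np.ndarray:
    """Concentration matrix of the protocol: all components at each level."""
    rows = [[lvl] * m for lvl in levels for _ in range(reps)]
    return np.asarray(rows, dtype=float)


def accuracy_protocol(
    model: CalibrationModel,
    components: Sequence[PureComponentModel],
    noise: NoiseModel,
    grid: WavelengthGrid,
    levels: Sequence[float] = (4.0, 8.0, 16.0),
    reps: int = 3,
) -> AccuracyResult:
    """Mean %R from ``reps`` determinations at each concentration level.

    Simulates len(levels)*reps mixture spectra (every component at the
    level), predicts with the fitted model and pools the recoveries.  Seeded
    through the noise model; identical seeds reproduce bit-exactly.
    """
    lo, hi = LINEARITY_RANGE
    for lvl in levels:
        if not (lo <= lvl <= hi):
            warnings.warn(
                f"level {lvl} ug/mL outside calibrated range {lo}-{hi} ug/mL",
                stacklevel=2,
            )
    m = model.n_components
    conc = _protocol_concentrations(levels, reps, m)
    spectra = simulate_concentrations(conc, components, noise, grid)
    pred = predict(model, spectra)
    rec = 100.0 * pred / conc
    per_level = rec.reshape(len(levels), reps, m).mean(axis=1)
    pooled = [recovery_summary(pred[:, j], conc[:, j]) for j in range(m)]
    return AccuracyResult(
        levels=np.asarray(levels, dtype=float), per_level_mean=per_level, pooled=pooled
    )


@dataclass
class PrecisionResult:
    repeatability_rsd: np.ndarray          # (m,), day-1 %RSD of recoveries
    intermediate_rsd: np.ndarray           # (m,), pooled over all days
    recoveries_by_day: np.ndarray          # (days, L*reps, m)


def precision_protocol(
    model: CalibrationModel,
    components: Sequence[PureComponentModel],
    noise: NoiseModel,
    grid: WavelengthGrid,
    levels: Sequence[float] = (4.0, 8.0, 16.0),
    reps: int = 3,
    day_seeds: Sequence[int] = (0, 1, 2),
    between_day_sd: float = 0.0,
) -> PrecisionResult:
    """Repeatability (day 1) and intermediate precision (all days) %RSD.

    Each day reruns the accuracy protocol with its own seed; an optional
    between-day absorbance offset (drawn once per day from N(0,
    ``between_day_sd``)) emulates day-to-day instrument drift.
    """
    from dataclasses import replace

    m = model.n_components
    conc = _protocol_concentrations(levels, reps, m)
    by_day = []
    for d, seed in enumerate(day_seeds):
        offset = 0.0
        if between_day_sd > 0:
            offset = float(np.random.default_rng(int(seed) + 7919).normal(0.0, between_day_sd))
        day_noise = replace(
            noise, seed=int(seed), baseline_offset=noise.baseline_offset + offset
        )
        spectra = simulate_concentrations(conc, components, day_noise, grid)
        by_day.append(100.0 * predict(model, spectra) / conc)
    rec = np.stack(by_day)  # (days, n, m)

    def _rsd(values: np.ndarray) -> np.ndarray:
        mean = values.mean(axis=0)
        sd = values.std(axis=0, ddof=1)
        return 100.0 * sd / mean

    return PrecisionResult(
        repeatability_rsd=_rsd(rec[0]),
        intermediate_rsd=_rsd(rec.reshape(-1, m)),
        recoveries_by_day=rec,
    )


@dataclass(frozen=True)
class StdAdditionRow:
    """One standard-addition spike: base sample plus a known pure addition."""

    base_taken: float
    base_found: float
    pure_added: float
    pure_found: float

    def __post_init__(self) -> None:
        if self.pure_added <= 0:
            raise ValueError("pure_added must be > 0")

    @property
    def recovery(self) -> float:
        return 100.0 * self.pure_found / self.pure_added


@dataclass
class StdAdditionResult:
    rows: list[StdAdditionRow]
    recoveries: np.ndarray
    mean: float
    rsd: float


def standard_addition(rows: Sequence[StdAdditionRow]) -> StdAdditionResult:
    """%R per spiked row (100*found/added) and the mean +/- RSD summary."""
    rows = list(rows)
    if not rows:
        raise ValueError("need at least one standard-addition row")
    summary = recovery_summary([r.pure_found for r in rows], [r.pure_added for r in rows])
    return StdAdditionResult(
        rows=rows, recoveries=summary.recoveries, mean=summary.mean, rsd=summary.rsd
    )


@dataclass
class MethodComparison:
    """Two-sample t (pooled variance) and variance-ratio F at level alpha."""

    n1: int
    n2: int
    mean1: float
    mean2: float
    var1: float
    var2: float
    t_stat: float
    t_crit: float
    t_df: int
    f_stat: float
    f_crit: float
    f_df: tuple[int, int]
    alpha: float
    t_significant: bool
    f_significant: bool

    @property
    def verdict(self) -> str:
        return (
            "significant"
            if (self.t_significant or self.f_significant)
            else "not significant"
        )


def compare_methods(
    sample1: Sequence[float], sample2: Sequence[float], alpha: float = 0.05
) -> MethodComparison:
    """Compare two methods' recovery sets by pooled t and F ratio.

    t uses the pooled variance with df = n1+n2-2 (two-sided critical); F is
    larger variance over smaller with df ordered accordingly (upper-tail
    critical).  Symmetric in its arguments up to the sign of t.
    """
    x = np.asarray(sample1, dtype=float)
    y = np.asarray(sample2, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 observations per sample")
    v1 = float(x.var(ddof=1))
    v2 = float(y.var(ddof=1))
    if v1 == 0 and v2 == 0:
        raise ValueError("both samples have zero variance; t is undefined")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    t_stat = float((x.mean() - y.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2)))
    t_crit = float(stats.t.ppf(1 - alpha / 2, df))
    if v1 >= v2:
        f_stat, f_df = (v1 / v2 if v2 > 0 else np.inf), (n1 - 1, n2 - 1)
    else:
        f_stat, f_df = v2 / v1, (n2 - 1, n1 - 1)
    f_crit = float(stats.f.ppf(1 - alpha, *f_df))
    return MethodComparison(
        n1=n1, n2=n2,
        mean1=float(x.mean()), mean2=float(y.mean()),
        var1=v1, var2=v2,
        t_stat=t_stat, t_crit=t_crit, t_df=df,
        f_stat=float(f_stat), f_crit=f_crit, f_df=f_df,
        alpha=alpha,
        t_significant=abs(t_stat) > t_crit,
        f_significant=bool(f_stat > f_crit),
    )
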