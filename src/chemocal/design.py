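"""Five-level, two-factor multilevel calibration design.

The calibration/validation mixtures follow a 25-run multilevel design: a
cyclic generator sequence of coded levels {-2,-1,0,1,2} gives factor 1, and
factor 2 is the same sequence rotated left by one position.  Real
concentrations are ``center + step * coded`` (default 9 +/- 4 ug/mL, i.e.
levels 1, 5, 9, 13, 17 ug/mL per drug).  Odd-numbered runs form the
13-sample calibration set, even-numbered runs the 12-sample validation set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_GENERATOR",
    "DesignSpec",
    "MixtureDesign",
    "InvalidDesignError",
    "generate_design",
    "split_design",
    "read_design",
    "write_design",
]

# Coded factor-1 sequence of the default 25-run design (levels 1..17 ug/mL,
# center 9, step 4).  Factor 2 is this sequence rotated left by one.
DEFAULT_GENERATOR: tuple[int, ...] = (
    0, 0, -2, -2, 2, -1, 2, 0, -1, -1, 1, 2, 1, 0, 2, 2, -2, 1, -2, 0, 1, 1, -1, -2, -1,
)

ROLE_CALIBRATION = "calibration"
ROLE_VALIDATION = "validation"
ROLE_UNASSIGNED = "unassigned"


class InvalidDesignError(ValueError):
    """Raised for a generator/spec that cannot produce a valid balanced design."""


@dataclass(frozen=True)
class DesignSpec:
    """Parameters of the multilevel two-factor design.

    ``generator`` must list each of the ``n_levels`` coded levels exactly
    ``n_levels`` times (length ``n_levels**2``), starting at 0.  Coded levels
    are symmetric around 0: for five levels, {-2,-1,0,1,2}.
    """

    n_levels: int = 5
    n_factors: int = 2
    center: float = 9.0
    step: float = 4.0
    generator: tuple[int, ...] = DEFAULT_GENERATOR

    def __post_init__(self) -> None:
        if self.n_levels < 2 or self.n_levels % 2 == 0:
            raise InvalidDesignError("n_levels must be an odd integer >= 3")
        if self.n_factors < 1:
            raise InvalidDesignError("n_factors must be >= 1")
        if self.step <= 0:
            raise InvalidDesignError("step must be > 0")
        half = self.n_levels // 2
        if self.center - half * self.step <= 0:
            raise InvalidDesignError(
                f"center - {half}*step = {self.center - half * self.step:g} ug/mL; "
                "all real concentrations must be positive"
            )
        gen = tuple(int(g) for g in self.generator)
        if len(gen) != self.n_levels**2:
            raise InvalidDesignError(
                f"generator length {len(gen)} != n_levels**2 = {self.n_levels**2}"
            )
        expected = set(range(-half, half + 1))
        counts = {lvl: gen.count(lvl) for lvl in expected}
        if set(gen) != expected or any(c != self.n_levels for c in counts.values()):
            raise InvalidDesignError(
                f"generator must contain each coded level in {sorted(expected)} "
                f"exactly {self.n_levels} times (got counts {counts})"
            )
        if gen[0] != 0:
            raise InvalidDesignError("generator must start at coded level 0")
        object.__setattr__(self, "generator", gen)

    @property
    def levels(self) -> np.ndarray:
        """Real concentration levels, ug/mL."""
        half = self.n_levels // 2
        return self.center + self.step * np.arange(-half, half + 1)


@dataclass
class MixtureDesign:
    """Concrete mixture layout: 1-based ids, coded and real levels, roles."""

    sample_id: np.ndarray  # (n,), int, 1-based
    coded: np.ndarray      # (n, n_factors), int
    conc: np.ndarray       # (n, n_factors), ug/mL
    role: np.ndarray       # (n,), str
    component_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sample_id = np.asarray(self.sample_id, dtype=int)
        self.coded = np.asarray(self.coded)
        self.conc = np.asarray(self.conc, dtype=float)
        self.role = np.asarray(self.role, dtype=object)
        if not self.component_names:
            self.component_names = [f"comp{j + 1}" for j in range(self.conc.shape[1])]

    @property
    def n_samples(self) -> int:
        return self.sample_id.size

    @property
    def is_orthogonal(self) -> bool:
        """True when all pairs of coded factor columns have zero dot product."""
        g = self.coded.astype(float)
        k = g.shape[1]
        return all(
            abs(float(g[:, i] @ g[:, j])) < 1e-9 for i in range(k) for j in range(i + 1, k)
        )

    def subset(self, role: str) -> "MixtureDesign":
        sel = self.role == role
        return MixtureDesign(
            sample_id=self.sample_id[sel],
            coded=self.coded[sel],
            conc=self.conc[sel],
            role=self.role[sel],
            component_names=list(self.component_names),
        )

    @property
    def calibration(self) -> "MixtureDesign":
        return self.subset(ROLE_CALIBRATION)

    @property
    def validation(self) -> "MixtureDesign":
        return self.subset(ROLE_VALIDATION)

    def to_frame(self) -> pd.DataFrame:
        cols = {"sample_id": self.sample_id}
        for j, name in enumerate(self.component_names):
            cols[f"comp{j + 1}_ug_mL"] = self.conc[:, j]
        cols["role"] = self.role
        return pd.DataFrame(cols)


def generate_design(spec: DesignSpec = DesignSpec()) -> MixtureDesign:
    """Build the full factor layout from the cyclic generator.

    Factor ``j`` (0-based) is the generator rotated left by ``j`` positions;
    real concentrations are ``center + step * coded``.  Roles start
    unassigned; use :func:`split_design`.
    """
    gen = np.array(spec.generator, dtype=int)
    n = gen.size
    coded = np.column_stack([np.roll(gen, -j) for j in range(spec.n_factors)])
    conc = spec.center + spec.step * coded.astype(float)
    return MixtureDesign(
        sample_id=np.arange(1, n + 1),
        coded=coded,
        conc=conc,
        role=np.array([ROLE_UNASSIGNED] * n, dtype=object),
    )


def split_design(
    design: MixtureDesign,
    scheme: str | Sequence[int] = "odd_even",
) -> MixtureDesign:
    """Assign calibration/validation roles.

    ``"odd_even"`` (default) makes odd sample ids the calibration set (13 of
    the default 25 runs) and even ids the validation set (12 runs).  An
    explicit sequence of sample ids marks those as calibration and the rest
    as validation; the ids must all exist in the design.
    """
    ids = design.sample_id
    if isinstance(scheme, str):
        if scheme != "odd_even":
            raise ValueError(f"unknown split scheme {scheme!r}")
        cal_mask = ids % 2 == 1
    else:
        chosen = set(int(i) for i in scheme)
        missing = chosen - set(int(i) for i in ids)
        if missing:
            raise ValueError(f"split ids not in design: {sorted(missing)}")
        cal_mask = np.array([int(i) in chosen for i in ids])
        if not (~cal_mask).any():
            warnings.warn("explicit split leaves the validation set empty", stacklevel=2)
    role = np.where(cal_mask, ROLE_CALIBRATION, ROLE_VALIDATION).astype(object)
    return replace(design, role=role)


def write_design(design: MixtureDesign, path: str | Path) -> None:
    design.to_frame().to_csv(path, index=False, float_format="%.12g")


def read_design(path: str | Path) -> MixtureDesign:
    frame = pd.read_csv(path)
    conc_cols = [c for c in frame.columns if c.endswith("_ug_mL")]
    if "sample_id" not in frame.columns or not conc_cols:
        raise ValueError(f"{path}: expected columns sample_id, comp*_ug_mL, role")
    conc = frame[conc_cols].to_numpy(dtype=float)
    role = (
        frame["role"].astype(str).to_numpy(dtype=object)
        if "role" in frame.columns
        else np.array([ROLE_UNASSIGNED] * len(frame), dtype=object)
    )
    # coded levels are recovered only when concentrations sit on a symmetric grid
    center = float(np.median(np.unique(conc)))
    uniq = np.unique(conc)
    step = float(np.min(np.diff(uniq))) if uniq.size > 1 else 1.0
    coded = np.round((conc - center) / step).astype(int)
    return MixtureDesign(
        sample_id=frame["sample_id"].to_numpy(dtype=int),
        coded=coded,
        conc=conc,
        role=role,
    )
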