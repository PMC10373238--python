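"""Latent-variable selection by leave-one-out cross-validation.

For each candidate number of latent variables a = 1..max, every calibration
sample is left out once, the model is refit on the remaining samples and the
left-out spectrum predicted; RMSECV(a) per component is
sqrt(sum_i e_i^2 / n).  The 0-LV baseline (predicting the training-fold mean
concentration) is reported alongside.  Two selection rules are available:
the pooled-RMSECV global minimum, and a Haaland-Thomas-style parsimony rule
taking the smallest a whose pooled RMSECV is within a factor (default 1.25)
of the minimum.  RMSEC/RMSEP use the same root-mean-square formula with
divisor n on the stated sample set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .models import CalibrationModel, fit_cls, fit_pcr, fit_pls, predict

__all__ = [
    "CVResult",
    "ErrorSummary",
    "loo_rmsecv",
    "loo_rmsecv_cls",
    "select_n_latent",
    "error_summary",
]

#: pooled-RMSECV ratio threshold of the parsimony selection rule
PARSIMONY_FACTOR = 1.25

_FITTERS = {"pcr": fit_pcr, "pls": fit_pls}


@dataclass
class CVResult:
    """RMSECV per component for candidates 0..max_latent (0 = mean baseline)."""

    method: str
    component_names: list[str]
    n_latent_values: np.ndarray   # (max_latent+1,), starts at 0
    rmsecv: np.ndarray            # (max_latent+1, m)
    pooled: np.ndarray            # (max_latent+1,)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.rmsecv,
            columns=[f"rmsecv_{c}" for c in self.component_names],
        )
        frame.insert(0, "n_latent", self.n_latent_values)
        frame["rmsecv_pooled"] = self.pooled
        return frame


@dataclass
class ErrorSummary:
    """Per-component RMSE on a stated set ('calibration' or 'prediction')."""

    which: str
    component_names: list[str]
    rmse: np.ndarray  # (m,)


def loo_rmsecv(
    method: str,
    C_cal: np.ndarray,
    A_cal: np.ndarray,
    max_latent: int,
    *,
    component_names: Sequence[str] | None = None,
) -> CVResult:
    """Leave-one-out RMSECV curve versus number of latent variables.

    CLS has no latent-variable axis and is rejected here; use
    :func:`loo_rmsecv_cls` for its single LOO error number.
    """
    method = method.lower()
    if method == "cls":
        raise ValueError("CLS has no latent-variable axis; use loo_rmsecv_cls")
    if method not in _FITTERS:
        raise ValueError(f"unknown method {method!r}; expected 'pcr' or 'pls'")
    C = np.asarray(C_cal, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    A = np.asarray(A_cal, dtype=float)
    n, p = A.shape
    if max_latent < 1 or max_latent > min(n - 2, p):
        raise ValueError(
            f"max_latent must be in [1, min(n-2, p)] = [1, {min(n - 2, p)}]"
        )
    names = list(component_names) if component_names else [f"comp{j+1}" for j in range(C.shape[1])]
    fit = _FITTERS[method]
    m = C.shape[1]
    sq = np.zeros((max_latent + 1, n, m))
    for i in range(n):
        keep = np.arange(n) != i
        Ctr, Atr = C[keep], A[keep]
        sq[0, i] = (Ctr.mean(axis=0) - C[i]) ** 2  # 0-LV mean baseline
        for a in range(1, max_latent + 1):
            mdl = fit(Ctr, Atr, a, component_names=names)
            sq[a, i] = (predict(mdl, A[i:i + 1])[0] - C[i]) ** 2
    rmsecv = np.sqrt(sq.mean(axis=1))
    pooled = np.sqrt(sq.mean(axis=(1, 2)))
    return CVResult(
        method=method,
        component_names=names,
        n_latent_values=np.arange(max_latent + 1),
        rmsecv=rmsecv,
        pooled=pooled,
    )


def loo_rmsecv_cls(
    C_cal: np.ndarray,
    A_cal: np.ndarray,
    *,
    intercept: bool = False,
    component_names: Sequence[str] | None = None,
) -> np.ndarray:
    """Single leave-one-out RMSE per component for the CLS model."""
    C = np.asarray(C_cal, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    A = np.asarray(A_cal, dtype=float)
    n = A.shape[0]
    sq = np.zeros((n, C.shape[1]))
    for i in range(n):
        keep = np.arange(n) != i
        mdl = fit_cls(C[keep], A[keep], intercept=intercept, component_names=component_names)
        sq[i] = (predict(mdl, A[i:i + 1])[0] - C[i]) ** 2
    return np.sqrt(sq.mean(axis=0))


def select_n_latent(cv: CVResult, rule: str = "one_se_like_fratio") -> int:
    """Pick the number of latent variables from a CV curve.

    ``global_min``: argmin of pooled RMSECV over a >= 1, smallest a on ties.
    ``one_se_like_fratio``: smallest a >= 1 with pooled RMSECV within
    ``PARSIMONY_FACTOR`` times the minimum (parsimonious default).
    """
    if cv.pooled.size < 2:
        raise ValueError("CVResult holds no latent-variable candidates")
    cand = cv.n_latent_values[1:]
    pooled = cv.pooled[1:]
    if rule == "global_min":
        return int(cand[int(np.argmin(pooled))])
    if rule == "one_se_like_fratio":
        threshold = PARSIMONY_FACTOR * float(pooled.min())
        return int(cand[int(np.argmax(pooled <= threshold))])
    raise ValueError(f"unknown selection rule {rule!r}")


def error_summary(
    model: CalibrationModel,
    C: np.ndarray,
    A: np.ndarray,
    which: str,
) -> ErrorSummary:
    """RMSEC ('calibration') or RMSEP ('prediction'): sqrt(mean sq residual)."""
    if which not in ("calibration", "prediction"):
        raise ValueError("which must be 'calibration' or 'prediction'")
    C = np.asarray(C, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if C.shape[0] == 0:
        raise ValueError("empty sample set")
    resid = predict(model, np.asarray(A, dtype=float)) - C
    return ErrorSummary(
        which=which,
        component_names=list(model.component_names),
        rmse=np.sqrt((resid**2).mean(axis=0)),
    )
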