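"""CLS, PCR and PLS multivariate calibration with a common contract.

All three models fit concentration matrix C (n samples x m components)
against absorbance matrix A (n x p wavelengths) and predict through

    c_hat = (a - mean_spectrum) . B + mean_conc

CLS estimates the pure-component absorptivity matrix K from the direct
Beer-Lambert model A = C.K via the normal equations and inverts it at
prediction time; it does not center (an optional intercept row models a
constant background).  PCR regresses centered C on the leading principal
component scores of centered A.  PLS is NIPALS PLS2: latent variables chosen
to maximize covariance between the spectral and concentration blocks, both
blocks deflated per component.  Sign convention throughout: every singular
vector / weight vector is flipped so its largest-magnitude element is
positive, making the decompositions deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .spectra import SpectraSet

__all__ = [
    "CalibrationModel",
    "SingularDesignError",
    "GridMismatchError",
    "NonConvergenceError",
    "fit_cls",
    "fit_pcr",
    "fit_pls",
    "predict",
    "save_model",
    "load_model",
]

#: relative singular-value threshold deciding numerical rank
RANK_RTOL = 1e-10
#: NIPALS inner-loop convergence (relative change of the score vector)
NIPALS_TOL = 1e-12
NIPALS_MAX_ITER = 500


class SingularDesignError(ValueError):
    """Concentration design is rank deficient (collinear columns named)."""


class GridMismatchError(ValueError):
    """Prediction spectra are not on the model's wavelength grid."""


class NonConvergenceError(RuntimeError):
    """NIPALS failed to converge for some latent variable."""


@dataclass
class CalibrationModel:
    """Fitted calibration: method tag, centering vectors, coefficients B."""

    method: str                       # "cls" | "pcr" | "pls"
    component_names: list[str]
    wavelengths: np.ndarray           # (p,)
    mean_spectrum: np.ndarray         # (p,) — zeros / intercept for CLS
    mean_conc: np.ndarray             # (m,)
    B: np.ndarray                     # (p, m)
    n_latent: int | None = None       # PCR/PLS only
    internals: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return self.B.shape[1]


def _sign_fix(v: np.ndarray) -> float:
    """Sign making the largest-magnitude element of v positive."""
    return 1.0 if v[np.argmax(np.abs(v))] >= 0 else -1.0


def _check_blocks(C: np.ndarray, A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    C = np.asarray(C, dtype=float)
    A = np.asarray(A, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if C.shape[0] != A.shape[0]:
        raise ValueError(f"C has {C.shape[0]} rows but A has {A.shape[0]}")
    return C, A


def _names(C: np.ndarray, component_names: Sequence[str] | None) -> list[str]:
    if component_names is None:
        return [f"comp{j + 1}" for j in range(C.shape[1])]
    if len(component_names) != C.shape[1]:
        raise ValueError("component_names length does not match C columns")
    return list(component_names)


def _collinear_columns(C: np.ndarray) -> list[int]:
    """Indices of columns involved in a rank deficiency (via the null space)."""
    _, s, vt = np.linalg.svd(C, full_matrices=True)
    null = vt[np.sum(s > RANK_RTOL * s[0]):, :]
    involved: set[int] = set()
    for v in null:
        involved |= set(np.flatnonzero(np.abs(v) > 1e-8))
    return sorted(involved)


def fit_cls(
    C: np.ndarray,
    A: np.ndarray,
    *,
    wavelengths: np.ndarray | None = None,
    component_names: Sequence[str] | None = None,
    intercept: bool = False,
) -> CalibrationModel:
    """Classical least squares: K_hat = (C'C)^-1 C'A, predict by inverting K.

    ``intercept=True`` augments C with a constant column whose K row models
    a concentration-independent background; prediction subtracts it.
    Requires every absorbing species to be represented in C — the model's
    well-known limitation in the presence of unmodeled interferents.
    """
    C, A = _check_blocks(C, A)
    names = _names(C, component_names)
    n, m = C.shape
    Caug = np.column_stack([C, np.ones(n)]) if intercept else C
    if n < Caug.shape[1]:
        raise SingularDesignError(
            f"need at least {Caug.shape[1]} samples for {Caug.shape[1]} regressors, got {n}"
        )
    s = np.linalg.svd(Caug, compute_uv=False)
    if s[-1] <= RANK_RTOL * s[0]:
        cols = _collinear_columns(Caug)
        labels = [names[j] if j < m else "intercept" for j in cols]
        raise SingularDesignError(f"concentration design is singular; collinear columns: {labels}")
    K_full = np.linalg.solve(Caug.T @ Caug, Caug.T @ A)   # (m[+1], p)
    K = K_full[:m, :]
    background = K_full[m, :] if intercept else np.zeros(A.shape[1])
    # prediction c_hat = (a - background) K' (K K')^-1  ==  centering contract
    B = K.T @ np.linalg.inv(K @ K.T)                      # (p, m)
    p = A.shape[1]
    wl = np.arange(p, dtype=float) if wavelengths is None else np.asarray(wavelengths, float)
    return CalibrationModel(
        method="cls",
        component_names=names,
        wavelengths=wl,
        mean_spectrum=background,
        mean_conc=np.zeros(m),
        B=B,
        n_latent=None,
        internals={"K": K, "background": background},
    )


def _validate_n_latent(n_latent: int, n: int, p: int) -> None:
    if not isinstance(n_latent, (int, np.integer)) or n_latent < 1:
        raise ValueError(f"n_latent must be a positive integer, got {n_latent!r}")
    if n_latent > min(n - 1, p):
        raise ValueError(
            f"n_latent={n_latent} exceeds min(n_samples-1, n_wavelengths) = {min(n - 1, p)}"
        )


def fit_pcr(
    C: np.ndarray,
    A: np.ndarray,
    n_latent: int,
    *,
    wavelengths: np.ndarray | None = None,
    component_names: Sequence[str] | None = None,
) -> CalibrationModel:
    """Principal component regression on column-centered blocks.

    Keeps the first ``n_latent`` left singular directions of centered A
    (capped at the numerical rank, so a full-rank request reproduces the
    minimum-norm least-squares solution) and regresses centered C on the
    scores.
    """
    C, A = _check_blocks(C, A)
    names = _names(C, component_names)
    n, p = A.shape
    _validate_n_latent(n_latent, n, p)
    mean_a = A.mean(axis=0)
    mean_c = C.mean(axis=0)
    Ac = A - mean_a
    Cc = C - mean_c
    U, s, Vt = np.linalg.svd(Ac, full_matrices=False)
    rank = int(np.sum(s > RANK_RTOL * s[0])) if s[0] > 0 else 0
    if rank == 0:
        raise ValueError("centered absorbance matrix is zero; nothing to fit")
    k = min(n_latent, rank)
    signs = np.array([_sign_fix(Vt[j]) for j in range(k)])
    Vk = (Vt[:k].T) * signs            # (p, k)
    Uk = U[:, :k] * signs              # (n, k)
    sk = s[:k]
    # scores T = Ac Vk = Uk diag(sk); regression of Cc on T
    coef = (Uk.T @ Cc) / sk[:, None]   # (k, m)
    B = Vk @ coef
    wl = np.arange(p, dtype=float) if wavelengths is None else np.asarray(wavelengths, float)
    return CalibrationModel(
        method="pcr",
        component_names=names,
        wavelengths=wl,
        mean_spectrum=mean_a,
        mean_conc=mean_c,
        B=B,
        n_latent=int(n_latent),
        internals={
            "loadings": Vk,
            "singular_values": sk,
            "scores": Uk * sk,
            "effective_rank": np.array([k]),
        },
    )


def fit_pls(
    C: np.ndarray,
    A: np.ndarray,
    n_latent: int,
    *,
    wavelengths: np.ndarray | None = None,
    component_names: Sequence[str] | None = None,
) -> CalibrationModel:
    """NIPALS PLS2 on column-centered blocks.

    Per latent variable: unit-norm weight w, scores t = A_def.w, loadings
    p = A_def't/(t't), q = C_def't/(t't); both blocks deflated by t.  The
    inner u<->t loop runs to relative tolerance 1e-12 (max 500 iterations).
    B = W (P'W)^-1 Q'.
    """
    C, A = _check_blocks(C, A)
    names = _names(C, component_names)
    n, p = A.shape
    m = C.shape[1]
    _validate_n_latent(n_latent, n, p)
    mean_a = A.mean(axis=0)
    mean_c = C.mean(axis=0)
    Ad = A - mean_a
    Cd = C - mean_c
    W = np.zeros((p, n_latent))
    P = np.zeros((p, n_latent))
    Q = np.zeros((m, n_latent))
    T = np.zeros((n, n_latent))
    for lv in range(n_latent):
        if not np.any(np.abs(Cd) > 0):
            raise NonConvergenceError(
                f"concentration block fully deflated before latent variable {lv + 1}"
            )
        u = Cd[:, int(np.argmax(np.var(Cd, axis=0)))].copy()
        t_old = np.zeros(n)
        for _ in range(NIPALS_MAX_ITER):
            w = Ad.T @ u
            nw = np.linalg.norm(w)
            if nw == 0:
                raise NonConvergenceError(
                    f"zero weight vector at latent variable {lv + 1}"
                )
            w /= nw
            w *= _sign_fix(w)
            t = Ad @ w
            tt = t @ t
            if tt == 0:
                raise NonConvergenceError(f"zero scores at latent variable {lv + 1}")
            q = Cd.T @ t / tt
            if m == 1:
                break  # single response: one pass is exact
            if q @ q == 0:
                raise NonConvergenceError(f"zero loadings at latent variable {lv + 1}")
            u = Cd @ q / (q @ q)
            if np.linalg.norm(t - t_old) <= NIPALS_TOL * np.linalg.norm(t):
                break
            t_old = t
        else:
            raise NonConvergenceError(
                f"NIPALS did not converge at latent variable {lv + 1} "
                f"within {NIPALS_MAX_ITER} iterations"
            )
        tt = t @ t
        p_load = Ad.T @ t / tt
        q = Cd.T @ t / tt
        Ad = Ad - np.outer(t, p_load)
        Cd = Cd - np.outer(t, q)
        W[:, lv], P[:, lv], Q[:, lv], T[:, lv] = w, p_load, q, t
    B = W @ np.linalg.solve(P.T @ W, Q.T)
    wl = np.arange(p, dtype=float) if wavelengths is None else np.asarray(wavelengths, float)
    return CalibrationModel(
        method="pls",
        component_names=names,
        wavelengths=wl,
        mean_spectrum=mean_a,
        mean_conc=mean_c,
        B=B,
        n_latent=int(n_latent),
        internals={"weights": W, "x_loadings": P, "y_loadings": Q, "scores": T},
    )


def predict(model: CalibrationModel, spectra: SpectraSet | np.ndarray) -> np.ndarray:
    """Predicted concentrations, one row per sample (ug/mL)."""
    if isinstance(spectra, SpectraSet):
        wl = spectra.grid.wavelengths
        if not np.array_equal(wl, model.wavelengths):
            extra = np.setdiff1d(wl, model.wavelengths)
            missing = np.setdiff1d(model.wavelengths, wl)
            raise GridMismatchError(
                f"spectra grid differs from model grid; "
                f"unexpected wavelengths {extra[:5].tolist()}"
                f"{'...' if extra.size > 5 else ''}, "
                f"missing {missing[:5].tolist()}{'...' if missing.size > 5 else ''}"
            )
        A = spectra.absorbance
    else:
        A = np.atleast_2d(np.asarray(spectra, dtype=float))
        if A.shape[1] != model.wavelengths.size:
            raise GridMismatchError(
                f"expected {model.wavelengths.size} wavelengths, got {A.shape[1]}"
            )
    return (A - model.mean_spectrum) @ model.B + model.mean_conc


def save_model(model: CalibrationModel, path: str | Path) -> None:
    """Serialize to a structured JSON text file (lossless round-trip)."""
    payload = {
        "method": model.method,
        "component_names": model.component_names,
        "n_latent": model.n_latent,
        "wavelengths": model.wavelengths.tolist(),
        "mean_spectrum": model.mean_spectrum.tolist(),
        "mean_conc": model.mean_conc.tolist(),
        "B": model.B.tolist(),
        "internals": {k: v.tolist() for k, v in model.internals.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path) -> CalibrationModel:
    d = json.loads(Path(path).read_text())
    return CalibrationModel(
        method=d["method"],
        component_names=list(d["component_names"]),
        wavelengths=np.array(d["wavelengths"], dtype=float),
        mean_spectrum=np.array(d["mean_spectrum"], dtype=float),
        mean_conc=np.array(d["mean_conc"], dtype=float),
        B=np.array(d["B"], dtype=float),
        n_latent=d["n_latent"],
        internals={k: np.array(v, dtype=float) for k, v in d["internals"].items()},
    )
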