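"""End-to-end pipeline: design -> simulate -> mask -> fit -> CV -> predict
-> figures of merit -> greenness, driven by a single YAML config.

The pipeline is a pure function of its config: every stochastic stage takes
an explicit seed from the config, so the same config produces byte-identical
numeric outputs.  Files are written to a temporary name and atomically
renamed, so a failed run never leaves a half-written table behind.
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import merit as fom
from .design import DesignSpec, generate_design, split_design, write_design
from .greenness import eco_scale
from .models import fit_cls, fit_pcr, fit_pls, predict, save_model
from .selection import error_summary, loo_rmsecv, loo_rmsecv_cls, select_n_latent
from .spectra import SpectraSet, WavelengthGrid, WavelengthMask, apply_mask, write_spectra
from .synth import (
    DEFAULT_COMPONENTS,
    PLASMA_INTERFERENT,
    GaussianBand,
    NoiseModel,
    PureComponentModel,
    simulate_mixtures,
    simulate_plasma_set,
)

__all__ = ["RunConfig", "ConfigError", "load_config", "default_config", "run_pipeline"]

log = logging.getLogger("chemocal")


class ConfigError(ValueError):
    """Raised before any computation when the run config is invalid."""


@dataclass
class RunConfig:
    """Validated pipeline configuration (see ``default_config`` for values)."""

    seed: int
    design_center: float = 9.0
    design_step: float = 4.0
    split_scheme: str | list[int] = "odd_even"
    components: tuple[PureComponentModel, ...] = DEFAULT_COMPONENTS
    noise_sd: float = 0.002
    baseline_offset: float = 0.0
    baseline_slope: float = 0.0
    mask: tuple[tuple[float, float], ...] = ((220.0, 400.0),)
    methods: tuple[str, ...] = ("cls", "pcr", "pls")
    max_latent: int = 8
    cv_rule: str = "one_se_like_fratio"
    plasma_enabled: bool = True
    plasma_interferent: PureComponentModel = PLASMA_INTERFERENT
    plasma_level: float = 1.0
    plasma_jitter: float = 0.2
    accuracy_levels: tuple[float, ...] = (4.0, 8.0, 16.0)
    accuracy_reps: int = 3
    precision_days: int = 3
    greenness_penalties: dict[str, dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("config must set an explicit seed")
        if not (0 <= int(self.seed) < 2**31):
            raise ConfigError("seed must be a non-negative integer below 2**31")
        for m in self.methods:
            if m not in ("cls", "pcr", "pls"):
                raise ConfigError(f"unknown method {m!r}")


def _parse_component(d: dict[str, Any]) -> PureComponentModel:
    return PureComponentModel(
        name=str(d["name"]),
        bands=tuple(GaussianBand(*map(float, b)) for b in d["bands"]),
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run config; fails before any computation."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    if "seed" not in raw:
        raise ConfigError(f"{path}: config must set a seed for every stochastic stage")
    kwargs: dict[str, Any] = {"seed": int(raw["seed"])}
    design = raw.get("design", {})
    kwargs["design_center"] = float(design.get("center", 9.0))
    kwargs["design_step"] = float(design.get("step", 4.0))
    kwargs["split_scheme"] = design.get("scheme", "odd_even")
    if "components" in raw:
        kwargs["components"] = tuple(_parse_component(c) for c in raw["components"])
    noise = raw.get("noise", {})
    kwargs["noise_sd"] = float(noise.get("noise_sd", 0.002))
    kwargs["baseline_offset"] = float(noise.get("baseline_offset", 0.0))
    kwargs["baseline_slope"] = float(noise.get("baseline_slope", 0.0))
    if "mask" in raw:
        kwargs["mask"] = tuple((float(lo), float(hi)) for lo, hi in raw["mask"])
    if "methods" in raw:
        kwargs["methods"] = tuple(str(m).lower() for m in raw["methods"])
    cv = raw.get("cv", {})
    kwargs["max_latent"] = int(cv.get("max_latent", 8))
    kwargs["cv_rule"] = str(cv.get("rule", "one_se_like_fratio"))
    plasma = raw.get("plasma", {})
    kwargs["plasma_enabled"] = bool(plasma.get("enabled", True))
    if "interferent" in plasma:
        kwargs["plasma_interferent"] = _parse_component(plasma["interferent"])
    kwargs["plasma_level"] = float(plasma.get("level", 1.0))
    kwargs["plasma_jitter"] = float(plasma.get("jitter", 0.2))
    mer = raw.get("merit", {})
    if "accuracy_levels" in mer:
        kwargs["accuracy_levels"] = tuple(float(x) for x in mer["accuracy_levels"])
    kwargs["accuracy_reps"] = int(mer.get("reps", 3))
    kwargs["precision_days"] = int(mer.get("days", 3))
    if "greenness" in raw:
        kwargs["greenness_penalties"] = {
            str(k): {str(l): int(p) for l, p in v.items()} for k, v in raw["greenness"].items()
        }
    return RunConfig(**kwargs)


def default_config(seed: int = 20230727) -> RunConfig:
    from .greenness import EXAMPLE_PENALTIES

    return RunConfig(seed=seed, greenness_penalties=EXAMPLE_PENALTIES)


def _atomic_write(path: Path, writer) -> None:
    """Write via a temp file in the target directory, then atomic rename."""
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    os.close(fd)
    try:
        writer(Path(tmp))
        os.replace(tmp, path)
    except BaseException:
        Path(tmp).unlink(missing_ok=True)
        raise


def _write_csv(frame: pd.DataFrame, path: Path, **kw) -> None:
    _atomic_write(path, lambda p: frame.to_csv(p, index=False, float_format="%.10g", **kw))


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict[str, Any]:
    """Run the full workflow and write the report bundle under ``outdir``.

    Returns the in-memory report dict (also written as ``report.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    grid = WavelengthGrid.default()
    report: dict[str, Any] = {"seed": config.seed}

    log.info("stage=design center=%g step=%g", config.design_center, config.design_step)
    spec = DesignSpec(center=config.design_center, step=config.design_step)
    design = split_design(generate_design(spec), config.split_scheme)
    design.component_names = [c.name for c in config.components]
    _atomic_write(outdir / "design.csv", lambda p: write_design(design, p))

    log.info("stage=simulate noise_sd=%g seed=%d", config.noise_sd, config.seed)
    noise = NoiseModel(
        seed=config.seed,
        noise_sd=config.noise_sd,
        baseline_offset=config.baseline_offset,
        baseline_slope=config.baseline_slope,
        interferent=config.plasma_interferent,
        interferent_level=config.plasma_level,
        interferent_jitter=config.plasma_jitter,
    )
    spectra = simulate_mixtures(design, config.components, noise, grid)
    _atomic_write(outdir / "spectra.csv", lambda p: write_spectra(spectra, p))

    mask = WavelengthMask(config.mask)
    masked = apply_mask(spectra, mask)
    cal_idx = [i for i, r in enumerate(design.role) if r == "calibration"]
    val_idx = [i for i, r in enumerate(design.role) if r == "validation"]
    A_cal, A_val = masked.absorbance[cal_idx], masked.absorbance[val_idx]
    C_cal, C_val = design.conc[cal_idx], design.conc[val_idx]
    names = design.component_names

    chosen: dict[str, int | None] = {}
    cv_frames = []
    for method in config.methods:
        if method == "cls":
            chosen[method] = None
            continue
        log.info("stage=crossval method=%s max_latent=%d", method, config.max_latent)
        cv = loo_rmsecv(method, C_cal, A_cal, config.max_latent, component_names=names)
        k = select_n_latent(cv, config.cv_rule)
        chosen[method] = k
        frame = cv.to_frame()
        frame.insert(0, "method", method)
        cv_frames.append(frame)
    if cv_frames:
        _write_csv(pd.concat(cv_frames, ignore_index=True), outdir / "rmsecv.csv")

    models = {}
    recovery_rows = []
    error_rows = []
    for method in config.methods:
        log.info("stage=fit method=%s n_latent=%s", method, chosen[method])
        if method == "cls":
            mdl = fit_cls(C_cal, A_cal, wavelengths=masked.grid.wavelengths,
                          component_names=names)
        else:
            fitter = fit_pcr if method == "pcr" else fit_pls
            mdl = fitter(C_cal, A_cal, chosen[method],
                         wavelengths=masked.grid.wavelengths, component_names=names)
        models[method] = mdl
        _atomic_write(outdir / f"model_{method}.json", lambda p, m=mdl: save_model(m, p))

        for which, C, A, ids in (
            ("calibration", C_cal, A_cal, design.sample_id[cal_idx]),
            ("validation", C_val, A_val, design.sample_id[val_idx]),
        ):
            pred = predict(mdl, A)
            err = error_summary(mdl, C, A, "calibration" if which == "calibration" else "prediction")
            for j, name in enumerate(names):
                summ = fom.recovery_summary(pred[:, j], C[:, j])
                recovery_rows.append({
                    "method": method, "set": which, "component": name,
                    "n": summ.n, "mean_recovery_pct": round(summ.mean, 2),
                    "rsd_pct": round(summ.rsd, 3),
                    "rmse": err.rmse[j],
                })
                error_rows.extend(
                    {"method": method, "set": which, "component": name,
                     "sample_id": int(sid), "nominal_ug_mL": C[i, j],
                     "predicted_ug_mL": pred[i, j],
                     "recovery_pct": round(100 * pred[i, j] / C[i, j], 2)}
                    for i, sid in enumerate(ids)
                )
    _write_csv(pd.DataFrame(recovery_rows), outdir / "recovery_summary.csv")
    _write_csv(pd.DataFrame(error_rows), outdir / "predictions.csv")

    log.info("stage=merit levels=%s reps=%d", config.accuracy_levels, config.accuracy_reps)
    merit_rows = []
    protocol_noise = replace(noise, seed=config.seed + 1)
    for method, mdl in models.items():
        # protocols simulate directly on the model's (masked) grid
        acc = fom.accuracy_protocol(
            mdl, config.components, protocol_noise, masked.grid,
            levels=config.accuracy_levels, reps=config.accuracy_reps,
        )
        prec = fom.precision_protocol(
            mdl, config.components, protocol_noise, masked.grid,
            levels=config.accuracy_levels, reps=config.accuracy_reps,
            day_seeds=tuple(config.seed + 10 + d for d in range(config.precision_days)),
        )
        for j, name in enumerate(names):
            nominal = np.concatenate([C_cal[:, j], C_val[:, j]])
            predicted = np.concatenate([
                predict(mdl, A_cal)[:, j], predict(mdl, A_val)[:, j]
            ])
            mi = fom.linearity_merit(nominal, predicted)
            lod, loq = fom.lod_loq(mi)
            merit_rows.append({
                "method": method, "component": name,
                "accuracy_mean_recovery_pct": round(acc.pooled[j].mean, 2),
                "repeatability_rsd_pct": round(float(prec.repeatability_rsd[j]), 3),
                "intermediate_rsd_pct": round(float(prec.intermediate_rsd[j]), 3),
                "lod_ug_mL": round(lod, 3), "loq_ug_mL": round(loq, 3),
            })
    _write_csv(pd.DataFrame(merit_rows), outdir / "merit_report.csv")

    if config.plasma_enabled:
        log.info("stage=plasma level=%g jitter=%g", config.plasma_level, config.plasma_jitter)
        plasma_noise = replace(noise, seed=config.seed + 3)
        plasma = simulate_plasma_set(design, config.components, plasma_noise, grid)
        _atomic_write(outdir / "spectra_plasma.csv", lambda p: write_spectra(plasma, p))
        plasma_masked = apply_mask(plasma, mask)
        plasma_rows = []
        Ap_cal = plasma_masked.absorbance[cal_idx]
        Ap_val = plasma_masked.absorbance[val_idx]
        for method in config.methods:
            if method == "cls":
                mdl_p = fit_cls(C_cal, Ap_cal, wavelengths=plasma_masked.grid.wavelengths,
                                component_names=names)
            else:
                fitter = fit_pcr if method == "pcr" else fit_pls
                k = min((chosen[method] or 2) + 1, min(len(cal_idx) - 1, Ap_cal.shape[1]))
                mdl_p = fitter(C_cal, Ap_cal, k, wavelengths=plasma_masked.grid.wavelengths,
                               component_names=names)
            pred = predict(mdl_p, Ap_val)
            for j, name in enumerate(names):
                summ = fom.recovery_summary(pred[:, j], C_val[:, j])
                plasma_rows.append({
                    "method": method, "component": name, "n": summ.n,
                    "mean_recovery_pct": round(summ.mean, 2),
                    "sd_pct": round(summ.sd, 2),
                    "rmsep": float(np.sqrt(((pred[:, j] - C_val[:, j]) ** 2).mean())),
                })
        _write_csv(pd.DataFrame(plasma_rows), outdir / "plasma_report.csv")
        report["plasma"] = plasma_rows

    green_rows = []
    for method, penalties in config.greenness_penalties.items():
        assessment = eco_scale(penalties)
        green_rows.append({
            "method": method, "total_penalty": assessment.total_penalty,
            "score": assessment.score, "category": assessment.category,
        })
    if green_rows:
        _write_csv(pd.DataFrame(green_rows), outdir / "greenness.csv")
        report["greenness"] = green_rows

    report["chosen_n_latent"] = chosen
    report["recoveries"] = recovery_rows
    report["merit"] = merit_rows
    _atomic_write(
        outdir / "report.json",
        lambda p: p.write_text(json.dumps(report, indent=1, default=str)),
    )
    log.info("stage=done outdir=%s", outdir)
    return report
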