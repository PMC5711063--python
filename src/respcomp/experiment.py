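"""Seven-group experiment runner.

Reproduces the film study's design in silico: three uncompensated motion
arms, three compensated arms, and one standstill arm, for sinusoidal
(5/10/15 mm amplitude, 4 s period) or irregular-breathing (10/20/30 mm
displacement) input. Each arm runs the full chain

    target trace -> strain gauge -> affine calibration -> couch tracking
    (47 ms latency, optional noise budget) -> residual film motion ->
    44.4 s dose accumulation -> dosimetric + kinematic metrics vs standstill

and all randomness derives from a single experiment seed.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from . import compensation as comp
from . import dose as dosemod
from . import metrics as metmod
from . import signals as sig
from .errors import ConfigError
from .geometry import fit_affine

log = logging.getLogger("respcomp")

SINE = "sine"
BREATHING = "breathing"
FILE = "file"


@dataclass(frozen=True)
class ArmSpec:
    name: str
    signal: str  # sine | breathing | file
    displacement_pp: float = 0.0
    compensated: bool = False
    path: Optional[str] = None

    def __post_init__(self) -> None:
        if self.signal not in (SINE, BREATHING, FILE):
            raise ConfigError(f"arm {self.name!r}: unknown signal {self.signal!r}")
        if self.signal == FILE and not self.path:
            raise ConfigError(f"arm {self.name!r}: file signal needs a path")
        if self.signal != FILE and self.displacement_pp <= 0:
            raise ConfigError(f"arm {self.name!r}: displacement_pp must be positive")


@dataclass(frozen=True)
class ExperimentConfig:
    arms: tuple[ArmSpec, ...]
    standstill: bool = True
    seed: int = 0
    dt: float = 0.01
    period: float = 4.0
    delivery_s: float = dosemod.DEFAULT_DELIVERY_S
    dose_cgy: float = dosemod.DEFAULT_DOSE_CGY
    field_mm: tuple[float, float] = (30.0, 30.0)
    calibrate_area95_cm2: Optional[float] = 5.36
    grid: dosemod.GridSpec = field(default_factory=dosemod.GridSpec)
    gauge_volts_per_mm: float = 0.1
    gauge_offset_v: float = 2.5
    gauge_noise_sd_v: float = 0.005
    latency_s: float = comp.DEFAULT_LATENCY
    #: per-displacement residual budget (mm); actuator noise is solved so the
    #: simulated residual motion matches the measured compensating error
    residual_budget_mm: dict = field(default_factory=dict)
    #: which statistic of |residual| the budget bounds: "max" (the measured
    #: compensating errors behave as worst-case tracking bounds), "mae" or "rms"
    residual_budget_stat: str = "max"
    gamma: metmod.GammaParams = field(default_factory=metmod.GammaParams)
    breathing_period_sd: float = 0.25
    breathing_amplitude_cv: float = 0.15
    breathing_drift_sd: float = 0.02
    breathing_duration_s: float = 60.0

    def __post_init__(self) -> None:
        if not self.standstill:
            raise ConfigError("an experiment needs its standstill reference arm")
        names = [a.name for a in self.arms]
        if len(set(names)) != len(names):
            raise ConfigError("arm names must be unique")


def config_from_dict(raw: dict) -> ExperimentConfig:
    """Build an :class:`ExperimentConfig` from a parsed YAML mapping."""
    try:
        arms = tuple(
            ArmSpec(
                name=a["name"],
                signal=a["signal"],
                displacement_pp=float(a.get("displacement_pp", 0.0)),
                compensated=bool(a.get("compensated", False)),
                path=a.get("path"),
            )
            for a in raw["arms"]
        )
        beam = raw.get("beam", {})
        grid = raw.get("grid", {})
        gauge = raw.get("gauge", {})
        cmp_ = raw.get("compensation", {})
        gam = raw.get("gamma", {})
        br = raw.get("breathing", {})
        delivery = raw.get("delivery", {})
        residual_budget = {
            float(k): float(v) for k, v in (cmp_.get("residual_budget_mm") or {}).items()
        }
        return ExperimentConfig(
            arms=arms,
            standstill=bool(raw.get("standstill", True)),
            seed=int(raw.get("seed", 0)),
            dt=float(raw.get("dt_s", 0.01)),
            period=float(raw.get("period_s", 4.0)),
            delivery_s=float(delivery.get("duration_s", dosemod.DEFAULT_DELIVERY_S)),
            dose_cgy=float(delivery.get("dose_cgy", dosemod.DEFAULT_DOSE_CGY)),
            field_mm=(
                float(beam.get("field_x_mm", 30.0)),
                float(beam.get("field_y_mm", 30.0)),
            ),
            calibrate_area95_cm2=beam.get("calibrate_area95_cm2", 5.36),
            grid=dosemod.GridSpec(
                spacing=float(grid.get("spacing_mm", 0.25)),
                extent_x=float(grid.get("extent_mm", 100.0)),
                extent_y=float(grid.get("extent_mm", 100.0)),
            ),
            gauge_volts_per_mm=float(gauge.get("volts_per_mm", 0.1)),
            gauge_offset_v=float(gauge.get("offset_v", 2.5)),
            gauge_noise_sd_v=float(gauge.get("noise_sd_v", 0.005)),
            latency_s=float(cmp_.get("latency_s", comp.DEFAULT_LATENCY)),
            residual_budget_mm=residual_budget,
            residual_budget_stat=str(cmp_.get("residual_budget_stat", "max")),
            gamma=metmod.GammaParams(
                dose_tol=float(gam.get("dose_tol_pct", 3.0)),
                dta=float(gam.get("dta_mm", 3.0)),
            ),
            breathing_period_sd=float(br.get("period_sd_s", 0.25)),
            breathing_amplitude_cv=float(br.get("amplitude_cv", 0.15)),
            breathing_drift_sd=float(br.get("drift_sd_mm", 0.02)),
            breathing_duration_s=float(br.get("duration_s", 60.0)),
        )
    except (KeyError, TypeError, ValueError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(f"invalid experiment config: {exc}") from exc


def load_config(path) -> ExperimentConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return config_from_dict(raw)


def paper_profile_path() -> Path:
    """Path of the shipped seven-group sine replication profile."""
    return Path(__file__).parent / "profiles" / "paper.yaml"


def _arm_seed(base: int, index: int, purpose: int) -> int:
    ss = np.random.SeedSequence([base, index, purpose])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % 2**31)


def make_target_trace(cfg: ExperimentConfig, arm: ArmSpec, seed: int) -> sig.Trace:
    duration = max(cfg.delivery_s, cfg.breathing_duration_s if arm.signal == BREATHING else 0.0)
    if arm.signal == SINE:
        return sig.gen_sine(arm.displacement_pp / 2.0, cfg.period, duration, cfg.dt)
    if arm.signal == BREATHING:
        return sig.gen_breathing(
            sig.BreathingParams(
                displacement_pp=arm.displacement_pp,
                period_mean=cfg.period,
                period_sd=cfg.breathing_period_sd,
                amplitude_cv=cfg.breathing_amplitude_cv,
                drift_sd=cfg.breathing_drift_sd,
                duration=duration,
                dt=cfg.dt,
                seed=seed,
            )
        )
    return sig.read_trace(arm.path)


_BUDGET_STATS = {
    "max": lambda r: float(np.abs(r).max()),
    "mae": lambda r: float(np.abs(r).mean()),
    "rms": lambda r: float(np.sqrt(np.mean(r**2))),
}


def solve_actuator_noise(
    residual_base: np.ndarray,
    unit_noise: np.ndarray,
    budget: float,
    stat: str = "max",
) -> float:
    """Noise sd such that stat(|residual_base + sd * unit_noise|) = budget.

    The couch noise passes straight through to the residual, so the
    match can be solved on the noise scale alone (Brent root find on a
    fixed standard-normal draw, keeping the arm deterministic). Returns
    0 when the latency alone already exhausts the budget.
    """
    try:
        measure = _BUDGET_STATS[stat]
    except KeyError:
        raise ConfigError(f"unknown residual budget statistic {stat!r}") from None
    if budget <= measure(residual_base):
        return 0.0

    def f(s: float) -> float:
        return measure(residual_base + s * unit_noise) - budget

    hi = 2.0 * budget + 1.0
    while f(hi) < 0:
        hi *= 2.0
    return float(brentq(f, 0.0, hi, xtol=1e-6))


@dataclass
class ArmResult:
    spec: ArmSpec
    target: sig.Trace
    film_motion: Optional[sig.Trace]
    grid: dosemod.DoseGrid
    dose_report: metmod.DoseReport
    kinematics: Optional[comp.KinematicsReport]
    actuator_noise_sd: float = 0.0


@dataclass
class ExperimentResult:
    beam: dosemod.BeamModel
    standstill: dosemod.DoseGrid
    arms: dict
    summary: pd.DataFrame
    errors: dict


def run_arm(
    cfg: ExperimentConfig,
    beam: dosemod.BeamModel,
    standstill: dosemod.DoseGrid,
    arm: ArmSpec,
    index: int,
) -> ArmResult:
    target = make_target_trace(cfg, arm, _arm_seed(cfg.seed, index, 0))
    actuator_noise = 0.0
    kin = None
    if arm.compensated:
        gauge = sig.GaugeModel(
            cfg.gauge_volts_per_mm,
            cfg.gauge_offset_v,
            cfg.gauge_noise_sd_v,
            seed=_arm_seed(cfg.seed, index, 1),
        )
        surrogate = sig.transduce(target, gauge)
        cal = fit_affine(surrogate, target)
        command = cal.apply(surrogate)
        ccfg = comp.CompensationConfig(latency=cfg.latency_s)
        couch_clean = comp.simulate_couch(command, ccfg)
        residual_base = target.values + couch_clean.values
        budget = cfg.residual_budget_mm.get(float(arm.displacement_pp))
        if budget is not None:
            rng = np.random.default_rng(_arm_seed(cfg.seed, index, 2))
            unit = rng.normal(0.0, 1.0, target.n)
            actuator_noise = solve_actuator_noise(
                residual_base, unit, budget, cfg.residual_budget_stat
            )
            couch = couch_clean.with_values(couch_clean.values + actuator_noise * unit)
        else:
            couch = couch_clean
        film_motion = comp.residual(target, couch)
        kin = comp.kinematics_report(target, couch, command)
    else:
        film_motion = target
        zero = target.with_values(np.zeros(target.n))
        kin = comp.kinematics_report(target, zero) if target.peak_to_peak > 0 else None
    grid = dosemod.accumulate(beam, film_motion, cfg.delivery_s, cfg.grid)
    half_x, half_y = cfg.field_mm[0] / 2.0, cfg.field_mm[1] / 2.0
    rect = (-half_x, half_x, -half_y, half_y)
    gamma_params = replace(cfg.gamma, eval_region=rect)
    report = metmod.dose_report(grid, standstill, gamma_params, rect)
    return ArmResult(arm, target, film_motion, grid, report, kin, actuator_noise)


def run_experiment(cfg: ExperimentConfig, outdir=None) -> ExperimentResult:
    """Run every arm plus the standstill reference; optionally write artifacts."""
    beam = dosemod.BeamModel(
        field_x=cfg.field_mm[0],
        field_y=cfg.field_mm[1],
        dose_rate=cfg.dose_cgy / cfg.delivery_s,
        norm_dose=cfg.dose_cgy,
    )
    if cfg.calibrate_area95_cm2 is not None:
        beam = dosemod.calibrate_penumbra(float(cfg.calibrate_area95_cm2), beam, cfg.grid)
        log.info("calibrated penumbra sigma = %.4f mm", beam.penumbra_sigma)
    log.info("dose rate = %.4f cGy/s", beam.dose_rate)

    standstill = dosemod.accumulate(beam, None, cfg.delivery_s, cfg.grid)
    half_x, half_y = cfg.field_mm[0] / 2.0, cfg.field_mm[1] / 2.0
    rect = (-half_x, half_x, -half_y, half_y)
    gamma_params = replace(cfg.gamma, eval_region=rect)

    arms: dict = {}
    errors: dict = {}
    rows = []
    still_report = metmod.dose_report(standstill, standstill, gamma_params, rect)
    rows.append(_summary_row("standstill", False, 0.0, still_report, None))
    for i, arm in enumerate(cfg.arms):
        try:
            res = run_arm(cfg, beam, standstill, arm, i)
        except Exception as exc:  # keep other arms running
            log.error("arm %s failed: %s", arm.name, exc)
            errors[arm.name] = exc
            continue
        arms[arm.name] = res
        rows.append(
            _summary_row(arm.name, arm.compensated, arm.displacement_pp, res.dose_report, res.kinematics)
        )
    summary = pd.DataFrame(rows)
    result = ExperimentResult(beam, standstill, arms, summary, errors)
    if outdir is not None:
        _write_artifacts(cfg, result, Path(outdir))
    return result


def _summary_row(name, compensated, pp, rep: metmod.DoseReport, kin) -> dict:
    row = {
        "arm": name,
        "compensated": compensated,
        "displacement_pp_mm": pp,
        "area95_cm2": rep.area95,
        "area5_cm2": rep.area5,
        "mean_field_dose_pct": rep.mean_field_dose_pct,
        "gamma_pass_pct": rep.gamma_pass,
    }
    if kin is not None:
        row.update(
            {
                "comp_rate_mean_pct": kin.comp_rate_mean,
                "residual_mae_mm": kin.compensating_error,
                "pearson_r": kin.pearson_r,
            }
        )
    else:
        row.update({"comp_rate_mean_pct": np.nan, "residual_mae_mm": np.nan, "pearson_r": np.nan})
    return row


def _write_artifacts(cfg: ExperimentConfig, result: ExperimentResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.summary.to_csv(
        outdir / "summary.csv", index=False, float_format="%.6g", lineterminator="\n"
    )
    dosemod.write_grid(result.standstill, outdir / "standstill.grid")
    for name, arm in result.arms.items():
        dosemod.write_grid(arm.grid, outdir / f"{name}.grid")
        payload = {"dose": arm.dose_report.to_dict()}
        if arm.kinematics is not None:
            payload["kinematics"] = arm.kinematics.to_dict()
            arm.kinematics.per_cycle.to_csv(
                outdir / f"{name}_cycles.csv", index=False, float_format="%.6g",
                lineterminator="\n",
            )
        payload["actuator_noise_sd_mm"] = arm.actuator_noise_sd
        with open(outdir / f"{name}_report.json", "w") as fh:
            json.dump(payload, fh, indent=1)
            fh.write("\n")
    run_log = {
        "seed": cfg.seed,
        "penumbra_sigma_mm": result.beam.penumbra_sigma,
        "dose_rate_cgy_per_s": result.beam.dose_rate,
        "latency_s": cfg.latency_s,
        "grid_spacing_mm": cfg.grid.spacing,
        "failed_arms": {k: str(v) for k, v in result.errors.items()},
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=1)
        fh.write("\n")
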