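"""Configuration and orchestration: scenario -> solve -> thermal -> lesion
-> report, plus the study-metrics stage on segmentations and EGM tables.

Configs are TOML; physical quantities carry explicit unit suffixes in their
key names (``..._mm``, ``..._v``, ``..._ms``) to keep units out of the code
path.  Every report embeds the config hash and seed so identical inputs
reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .protocol import BurstSpec, duty_power_factor
from .scenario import (
    MYOCARDIUM,
    MaterialTable,
    ScenarioGrid,
    assign_materials,
    build_atrial_wall,
    build_pv_ostium,
    build_septal,
)
from .electrics import solve_potential, total_current
from .thermal import joule_source, make_flow_field, simulate_transient
from .lesion import build_lesion_report, fit_exponential_decay
from .study_metrics import (
    SegmentationVolume,
    ablated_fraction,
    extrusion_reference_ratio,
    one_sample_t_summary,
    paired_change_stats,
    volume_fractions,
    EgmSample,
)

__all__ = ["load_config", "config_hash", "build_scenario", "run_scenario", "run_study_metrics"]

log = logging.getLogger("pfasim")

LABEL_BY_NAME = {"myocardium": MYOCARDIUM}


def load_config(path: str | Path) -> dict:
    """Parse a TOML run config."""
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def config_hash(config: dict) -> str:
    """Stable short hash of the canonicalized config."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _require(config: dict, key: str) -> dict:
    if key not in config:
        raise KeyError(f"config is missing the required '{key}' block")
    return config[key]


def build_scenario(config: dict) -> ScenarioGrid:
    """Build the labeled grid named by ``scenario.kind`` and attach
    materials (with any ``materials.<label>.<prop>`` overrides)."""
    sc = _require(config, "scenario")
    kind = sc.get("kind")
    spacing = float(sc.get("spacing_mm", 0.25))
    if kind == "pv_ostium":
        grid = build_pv_ostium(
            diameter_mm=float(sc.get("diameter_mm", 13.0)),
            wall_mm=float(sc.get("wall_mm", 3.0)),
            spacing_mm=spacing,
        )
    elif kind == "atrial_wall":
        grid = build_atrial_wall(
            wall_mm=float(sc.get("wall_mm", 5.85)),
            loop_diameter_mm=float(sc.get("loop_diameter_mm", 13.0)),
            spacing_mm=spacing,
        )
    elif kind == "septal":
        grid = build_septal(
            septum_mm=float(sc.get("septum_mm", 15.0)),
            offset_mm=float(sc.get("offset_mm", 0.0)),
            tilt_deg=float(sc.get("tilt_deg", 0.0)),
            spacing_mm=spacing,
        )
    else:
        raise KeyError(
            f"scenario.kind must be pv_ostium, atrial_wall or septal, got {kind!r}"
        )
    table = MaterialTable()
    from .scenario import LABEL_NAMES

    name_to_label = {v: k for k, v in LABEL_NAMES.items()}
    for name, props in config.get("materials", {}).items():
        if name == "baseline_temp_c":
            table.baseline_temp_c = float(props)
            continue
        if name not in name_to_label:
            raise KeyError(f"materials block names unknown label '{name}'")
        table.override(name_to_label[name], **props)
    assign_materials(grid, table)
    return grid


def run_scenario(config: dict, out_dir: str | Path | None = None) -> dict:
    """Run one scenario end to end and return (optionally write) the report.

    Stages: build grid, solve the conduction problem at the burst voltage,
    form the duty-scaled Joule source, integrate the single-burst thermal
    transient (optional, ``thermal.enabled``), fit the interface decay and
    assemble the lesion report.  The JSON report embeds the config hash and
    seed; per-stage timings and the solver residual go to the log.
    """
    t_start = time.perf_counter()
    burst_cfg = _require(config, "burst")
    _require(config, "materials")
    spec = BurstSpec(
        amplitude_volts=float(burst_cfg.get("amplitude_v", 900.0)),
        duration_us=float(burst_cfg.get("duration_us", 100.0)),
        internal_freq_khz=float(burst_cfg.get("freq_khz", 100.0)),
        duty=float(burst_cfg.get("duty", 0.5)),
        n_bursts=int(burst_cfg.get("n", 60)),
    )
    grid = build_scenario(config)
    log.info("scenario built: %s %s voxels", grid.meta.get("kind"), grid.labels.shape)

    sol = solve_potential(grid, spec.amplitude_volts)
    current, over = total_current(sol, grid)
    log.info(
        "conduction solve done: residual %.2e, current %.2f A", sol.residual, current
    )
    if over:
        log.warning("current %.2f A exceeds the generator compliance", current)

    thermal_cfg = config.get("thermal", {})
    trace = None
    decay = None
    if thermal_cfg.get("enabled", True):
        velocity = float(thermal_cfg.get("velocity_m_s", 0.0))
        flow = make_flow_field(
            grid, velocity, thermal_cfg.get("profile", "poiseuille")
        )
        q = joule_source(sol, grid, duty_power_factor(spec))
        trace = simulate_transient(
            grid,
            q,
            flow=flow,
            burst_s=spec.duration_s,
            relax_s=float(thermal_cfg.get("relax_s", 0.1)),
            dt_burst=float(thermal_cfg.get("dt_burst_s", 1e-6)),
            dt_relax=float(thermal_cfg.get("dt_relax_s", 1e-3)),
        )
        try:
            decay = fit_exponential_decay(
                trace.times_s, trace.probes["tissue_interface"]
            )
        except ValueError as exc:
            log.warning("decay fit skipped: %s", exc)

    thresholds = config.get("thresholds", {})
    report_obj = build_lesion_report(
        sol,
        grid,
        trace,
        threshold_v_per_cm=float(thresholds.get("ire_v_per_cm", 400.0)),
    )
    report = {
        "scenario": grid.meta.get("kind"),
        "config_hash": config_hash(config),
        "seed": int(config.get("seed", 0)),
        "current_a": current,
        "current_compliance_exceeded": over,
        "lesion": report_obj.to_dict(),
        "decay_fit": (
            {
                "amplitude_c": decay.amplitude_c,
                "tau_ms": decay.tau_ms,
                "baseline_c": decay.baseline_c,
                "r_squared": decay.r_squared,
            }
            if decay is not None
            else None
        ),
    }
    log.info("scenario run finished in %.1f s", time.perf_counter() - t_start)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pio.write_json(report, out / "report.json")
        if trace is not None:
            pio.save_trace_csv(trace.times_s, trace.probes, out / "probes.csv")
    return report


def run_study_metrics(
    seg: SegmentationVolume | None = None,
    control: SegmentationVolume | None = None,
    egm_csv: str | Path | None = None,
    config: dict | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Volumetrics and/or electrogram statistics report.

    With a treated and a control segmentation: non-myocardial percentages,
    the ablated percentage (their difference) and the loop-extrusion
    reference ratio.  With an EGM CSV (columns id, metric, pre, post):
    paired pre/post change statistics per metric.  ``summary_t`` in the
    config (mean, sd, n, mu0) adds a one-sample t from printed summary
    statistics.
    """
    config = config or {}
    report: dict = {"config_hash": config_hash(config), "seed": int(config.get("seed", 0))}
    if seg is not None:
        vf = volume_fractions(seg)
        report["nonmyo_pct"] = vf.nonmyo_pct
        report["v_pct"] = vf.v_pct
        if control is not None:
            vc = volume_fractions(control)
            report["control_nonmyo_pct"] = vc.nonmyo_pct
            abl = ablated_fraction(vf.nonmyo_pct, vc.nonmyo_pct)
            report["ablated_pct"] = abl
            loop_d = float(config.get("loop_diameter_mm", 13.0))
            ablated_mm3 = abl / 100.0 * vf.total_volume_mm3
            report["extrusion_ratio"] = extrusion_reference_ratio(
                seg, ablated_mm3, loop_d
            )
    if egm_csv is not None:
        frame = pd.read_csv(egm_csv)
        if frame.empty:
            raise ValueError("EGM table is empty")
        needed = {"id", "metric", "pre", "post"}
        if not needed <= set(frame.columns):
            raise ValueError(f"EGM table must have columns {sorted(needed)}")
        egm_stats = {}
        for metric, sub in frame.groupby("metric"):
            samples = _egm_samples_from_frame(sub, str(metric))
            egm_stats[str(metric)] = paired_change_stats(samples, str(metric))
        report["egm"] = egm_stats
    if "summary_t" in config:
        st = config["summary_t"]
        t, p = one_sample_t_summary(
            float(st["mean"]), float(st["sd"]), int(st["n"]), float(st["mu0"])
        )
        report["summary_t"] = {"t": t, "p": p}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pio.write_json(report, out / "study_metrics.json")
    return report


def _egm_samples_from_frame(frame: pd.DataFrame, metric: str) -> list[EgmSample]:
    kw = {
        "amplitude": ("pre_amplitude_mv", "post_amplitude_mv"),
        "duration": ("pre_duration_ms", "post_duration_ms"),
        "impedance": ("pre_impedance_ohm", "post_impedance_ohm"),
    }[metric]
    samples = []
    for _, row in frame.iterrows():
        args = {
            "pre_amplitude_mv": 1.0,
            "post_amplitude_mv": 1.0,
            "pre_duration_ms": 1.0,
            "post_duration_ms": 1.0,
        }
        args[kw[0]] = float(row["pre"])
        args[kw[1]] = float(row["post"])
        samples.append(EgmSample(**args))
    return samples
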