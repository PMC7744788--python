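"""Temperature transient of one gated burst: Joule heating, diffusion and
convective blood cooling.

The tissue obeys a bioheat balance
``rho c dT/dt = div(k grad T) - rho_b c_b (u . grad T) + q``
with the Joule source ``q = duty * sigma |E|^2`` active only during the
100-us burst; over the sub-second single-burst horizon no perfusion sink is
included by default.  Blood motion is a static analytic laminar profile
(plug or Poiseuille-like), not a Navier-Stokes solve — the study design only
requires a fixed advective field.

Time stepping is fully explicit: forward-Euler diffusion on the 7-point
harmonic-mean stencil plus first-order upwind advection.  At the voxel
sizes used (>= 0.25 mm) the explicit diffusion stability bound is tens of
milliseconds, far above the 1 us (burst) / 1 ms (relaxation) steps, so an
implicit solve would add cost without accuracy; both stability and CFL
bounds are enforced and violated steps are rejected with the bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .scenario import (
    BLOOD,
    ELECTRODE_LINE,
    ELECTRODE_NEUTRAL,
    INSULATOR,
    MYOCARDIUM,
    ScenarioGrid,
    assign_materials,
)
from .electrics import FieldSolution

__all__ = ["FlowField", "ThermalTrace", "make_flow_field", "joule_source", "simulate_transient"]


@dataclass
class FlowField:
    """Static blood velocity field: one axial component on the voxel grid.

    ``velocity`` (m/s) is nonzero only in blood voxels away from tissue
    (no-slip layer at walls); ``axis`` is the flow direction.
    """

    velocity: np.ndarray
    axis: int
    peak_velocity: float


@dataclass
class ThermalTrace:
    """Probe temperature series and running peak map from one transient.

    Probes: ``tissue_interface`` — hottest myocardial voxel face-adjacent to
    an electrode (falls back to hottest myocardium when no electrodes);
    ``blood`` — hottest blood voxel; ``domain_max`` — global maximum.
    """

    times_s: np.ndarray
    probes: dict[str, np.ndarray]
    peak_map: np.ndarray
    final_temp: np.ndarray
    baseline_c: float
    meta: dict = field(default_factory=dict)


def make_flow_field(
    grid: ScenarioGrid,
    peak_velocity: float,
    profile: str = "poiseuille",
) -> FlowField:
    """Build the analytic laminar profile over the blood pool.

    ``poiseuille`` shapes the speed by normalized wall distance ``s``:
    ``v = peak * (2 s - s^2)``, which reproduces the parabolic
    ``peak * (1 - r^2/R^2)`` profile exactly in a cylindrical lumen and
    degrades gracefully for slab-shaped pools.  ``plug`` is uniform at
    ``peak`` with a one-voxel no-slip layer at tissue walls.
    """
    if peak_velocity < 0:
        raise ValueError("peak_velocity must be >= 0")
    if profile not in ("plug", "poiseuille"):
        raise ValueError(f"unknown profile '{profile}'")
    blood = grid.labels == BLOOD
    if not blood.any():
        raise ValueError("grid has no blood voxels")
    axis = int(grid.meta.get("flow_axis", 2))
    v = np.zeros(grid.labels.shape)
    if peak_velocity == 0.0:
        return FlowField(velocity=v, axis=axis, peak_velocity=0.0)
    # wall distance in voxels (0 at non-blood); the outer domain boundary is
    # an open cut through the pool, not a wall
    d = ndimage.distance_transform_edt(blood)
    wall_layer = blood & (d <= 1.0)
    if profile == "plug":
        v[blood] = peak_velocity
        v[wall_layer] = 0.0
    else:
        dmax = d.max()
        s = np.clip(d / dmax, 0.0, 1.0)
        v = np.where(blood, peak_velocity * (2.0 * s - s**2), 0.0)
        v[wall_layer] = 0.0  # no-slip layer
    return FlowField(velocity=v, axis=axis, peak_velocity=float(peak_velocity))


def joule_source(
    sol: FieldSolution, grid: ScenarioGrid, duty_factor: float
) -> np.ndarray:
    """Time-averaged resistive heating density ``q = duty sigma |E|^2``
    (W/m^3), zero in insulator and electrode voxels."""
    if not (0.0 <= duty_factor <= 1.0):
        raise ValueError("duty_factor must lie in [0, 1]")
    if grid.materials is None:
        assign_materials(grid)
    e_si = sol.e_mag * 100.0  # V/cm -> V/m
    q = duty_factor * grid.materials.sigma * e_si**2
    dead = (
        (grid.labels == INSULATOR)
        | (grid.labels == ELECTRODE_LINE)
        | (grid.labels == ELECTRODE_NEUTRAL)
    )
    q[dead] = 0.0
    return q


def _diffusion_step_arrays(grid: ScenarioGrid):
    """Precompute face conductances (W/K) and heat capacity per voxel (J/K)."""
    mat = grid.materials
    s_m = grid.spacing_mm * 1e-3
    faces = []
    for axis in range(3):
        a = [slice(None)] * 3
        b = [slice(None)] * 3
        a[axis] = slice(None, -1)
        b[axis] = slice(1, None)
        ka, kb = mat.k[tuple(a)], mat.k[tuple(b)]
        g = np.where(ka + kb > 0, 2.0 * ka * kb / (ka + kb), 0.0) * s_m
        faces.append(g)
    cap = mat.rho * mat.c_p * s_m**3  # J/K per voxel
    return faces, cap


def _stability_dt(grid: ScenarioGrid, faces, cap) -> float:
    """Largest stable explicit step: dt <= min(cap / sum of face conductances)."""
    gsum = np.zeros(grid.labels.shape)
    for axis, g in enumerate(faces):
        a = [slice(None)] * 3
        b = [slice(None)] * 3
        a[axis] = slice(None, -1)
        b[axis] = slice(1, None)
        gsum[tuple(a)] += g
        gsum[tuple(b)] += g
    return float(np.min(cap / np.maximum(gsum, 1e-300)))


def simulate_transient(
    grid: ScenarioGrid,
    source: np.ndarray,
    flow: FlowField | None = None,
    burst_s: float = 100e-6,
    relax_s: float = 0.8,
    dt_burst: float = 1e-6,
    dt_relax: float = 1e-3,
    boundary: str = "fixed",
    initial_excess: np.ndarray | None = None,
    record_stride: int = 1,
) -> ThermalTrace:
    """Integrate the bioheat transient of one burst plus relaxation.

    The source is active during ``burst_s`` (default 100 us, one AC burst)
    and the field then relaxes for ``relax_s`` (default 0.8 s, one R-R
    interval at the study's resting 75 bpm).  The outer boundary is held at
    baseline (``boundary='fixed'``) or left adiabatic; ``initial_excess``
    adds a temperature perturbation at t = 0 (used for verification against
    closed-form diffusion solutions).

    Raises ``ValueError`` when a step size violates the diffusion stability
    or advective CFL bound, and ``RuntimeError`` on non-finite temperatures.
    """
    if boundary not in ("fixed", "adiabatic"):
        raise ValueError(f"unknown boundary '{boundary}'")
    if grid.materials is None:
        assign_materials(grid)
    faces, cap = _diffusion_step_arrays(grid)
    dt_max = _stability_dt(grid, faces, cap)
    checks = []
    if burst_s > 0:
        checks.append(("dt_burst", dt_burst))
    if relax_s > 0:
        checks.append(("dt_relax", dt_relax))
    for name, dt in checks:
        if dt > dt_max:
            raise ValueError(
                f"{name}={dt:g} s exceeds the explicit stability bound "
                f"{dt_max:.3g} s"
            )
    s_m = grid.spacing_mm * 1e-3
    if flow is not None and flow.peak_velocity > 0:
        cfl_dt = s_m / flow.peak_velocity
        for name, dt in (("dt_burst", dt_burst), ("dt_relax", dt_relax)):
            if dt > cfl_dt:
                raise ValueError(
                    f"{name}={dt:g} s exceeds the advective CFL bound {cfl_dt:.3g} s"
                )

    baseline = grid.materials.baseline_temp_c
    T = np.full(grid.labels.shape, baseline, dtype=float)
    if initial_excess is not None:
        T += initial_excess

    labels = grid.labels
    elec = (labels == ELECTRODE_LINE) | (labels == ELECTRODE_NEUTRAL)
    myo = labels == MYOCARDIUM
    interface = np.zeros_like(myo)
    if elec.any():
        grown = ndimage.binary_dilation(
            elec, structure=ndimage.generate_binary_structure(3, 1)
        )
        interface = myo & grown
    if not interface.any():
        interface = myo
    blood = labels == BLOOD

    src_per_cap = source * s_m**3 / cap  # K/s during the burst
    vol_rate = None
    if flow is not None and flow.peak_velocity > 0:
        vol_rate = flow.velocity / s_m  # 1/s, multiplies upwind temperature difference

    n_burst = int(round(burst_s / dt_burst)) if burst_s > 0 else 0
    n_relax = int(round(relax_s / dt_relax)) if relax_s > 0 else 0
    n_total = n_burst + n_relax

    times = np.empty(n_total + 1)
    probes = {
        "tissue_interface": np.empty(n_total + 1),
        "blood": np.empty(n_total + 1),
        "domain_max": np.empty(n_total + 1),
    }
    peak_map = T.copy()

    def record(i: int, t: float) -> None:
        times[i] = t
        probes["tissue_interface"][i] = T[interface].max() if interface.any() else np.nan
        probes["blood"][i] = T[blood].max() if blood.any() else np.nan
        probes["domain_max"][i] = T.max()

    record(0, 0.0)
    t = 0.0
    axis = flow.axis if flow is not None else 0
    for step in range(n_total):
        in_burst = step < n_burst
        dt = dt_burst if in_burst else dt_relax
        dT = np.zeros_like(T)
        for ax, g in enumerate(faces):
            a = [slice(None)] * 3
            b = [slice(None)] * 3
            a[ax] = slice(None, -1)
            b[ax] = slice(1, None)
            a, b = tuple(a), tuple(b)
            flux = g * (T[b] - T[a])  # W, from b into a
            dT[a] += flux
            dT[b] -= flux
        T_new = T + dt * dT / cap
        if vol_rate is not None:
            # first-order upwind advection along the flow axis (u >= 0)
            a = [slice(None)] * 3
            b = [slice(None)] * 3
            a[axis] = slice(1, None)
            b[axis] = slice(None, -1)
            gradT = np.zeros_like(T)
            gradT[tuple(a)] = T[tuple(a)] - T[tuple(b)]
            T_new -= dt * vol_rate * gradT
        if in_burst:
            T_new += dt * src_per_cap
        if boundary == "fixed":
            T_new[0, :, :] = baseline
            T_new[-1, :, :] = baseline
            T_new[:, 0, :] = baseline
            T_new[:, -1, :] = baseline
            T_new[:, :, 0] = baseline
            T_new[:, :, -1] = baseline
        T = T_new
        if not np.isfinite(T).all():
            raise RuntimeError(
                f"non-finite temperature at step {step} (t={t:.6g} s); "
                "check step sizes and source magnitude"
            )
        np.maximum(peak_map, T, out=peak_map)
        t += dt
        record(step + 1, t)

    return ThermalTrace(
        times_s=times,
        probes=probes,
        peak_map=peak_map,
        final_temp=T,
        baseline_c=baseline,
        meta={
            "burst_s": burst_s,
            "relax_s": relax_s,
            "dt_burst": dt_burst,
            "dt_relax": dt_relax,
            "boundary": boundary,
            "stability_dt_s": dt_max,
        },
    )
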