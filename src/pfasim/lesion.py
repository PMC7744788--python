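"""Lesion-extent metrics derived from the solved field and thermal traces.

Irreversible electroporation is modeled as a field-threshold effect: tissue
seeing a burst-plateau field above 400 V/cm (the muscle IRE threshold used
throughout) is counted as treated.  From the super-threshold mask this
module measures the effective lesion radius around the electrodes, the
untreated gap between opposing septal electrodes, and the sensitivity of
the radius to catheter misalignment; the temperature spike of a burst is
condensed to an exponential-decay fit (amplitude, time constant).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage, optimize

from .scenario import (
    ELECTRODE_LINE,
    ELECTRODE_NEUTRAL,
    MYOCARDIUM,
    ScenarioGrid,
)
from .electrics import FieldSolution, field_metrics

__all__ = [
    "DecayFit",
    "LesionReport",
    "fit_exponential_decay",
    "effective_field_radius",
    "untreated_gap",
    "alignment_sensitivity",
    "build_lesion_report",
]

#: Muscle irreversible-electroporation field threshold (V/cm).
IRE_THRESHOLD_V_PER_CM = 400.0


@dataclass(frozen=True)
class DecayFit:
    """Exponential temperature-decay parameters T(t) = baseline + A e^(-t/tau)."""

    amplitude_c: float
    tau_ms: float
    baseline_c: float
    r_squared: float


@dataclass
class LesionReport:
    """Table-shaped per-scenario summary of the electro-thermal outcome."""

    applied_volts: float
    e_field_max_kv_per_cm: float
    e_field_mean_v_per_cm: float
    j_mean_ka_per_m2: float
    j_max_ka_per_m2: float
    t_interface_max_c: float | None
    effective_radius_mm: float
    untreated_gap_mm: float | None
    threshold_v_per_cm: float

    def to_dict(self) -> dict:
        return asdict(self)


def fit_exponential_decay(
    times_s: np.ndarray,
    temps_c: np.ndarray,
    window_s: tuple[float, float] | None = None,
) -> DecayFit:
    """Least-squares fit of a single-exponential relaxation to a probe series.

    The fit starts at the series peak (which must sit at the start of the
    selected window) and estimates amplitude A, decay constant tau and the
    asymptotic baseline.  Initial values come from a log-linear regression
    against the final temperature, refined by ``scipy.optimize.curve_fit``.

    Raises ``ValueError`` for a constant series (tau unidentifiable) or a
    series that does not decay over the window.
    """
    t = np.asarray(times_s, dtype=float)
    y = np.asarray(temps_c, dtype=float)
    if window_s is not None:
        sel = (t >= window_s[0]) & (t <= window_s[1])
        t, y = t[sel], y[sel]
    if t.size < 10:
        raise ValueError("need at least 10 samples in the fit window")
    i0 = int(np.argmax(y))
    if y.size - i0 < 10 and y[-1] > y[0]:
        raise ValueError("series does not decay over the fit window")
    t, y = t[i0:] - t[i0], y[i0:]
    if t.size < 10:
        raise ValueError("peak too close to the window end (< 10 samples after)")
    span = float(y.max() - y.min())
    if span <= 1e-12 * max(1.0, abs(float(y[0]))):
        raise ValueError("constant series: decay constant unidentifiable")
    if y[-1] >= y[0] - 0.05 * span:
        raise ValueError("series does not decay over the fit window")

    base0 = float(y[-1])
    a0 = max(float(y[0]) - base0, span * 1e-3)
    excess = np.clip(y - base0, a0 * 1e-6, None)
    # log-linear slope for the initial tau guess, using the early decay
    m = excess > 0.05 * a0
    if m.sum() >= 2:
        slope = np.polyfit(t[m], np.log(excess[m]), 1)[0]
        tau0 = -1.0 / slope if slope < 0 else (t[-1] - t[0]) / 3.0
    else:
        tau0 = (t[-1] - t[0]) / 3.0

    def model(tt, a, tau, base):
        return base + a * np.exp(-tt / tau)

    popt, _ = optimize.curve_fit(
        model,
        t,
        y,
        p0=(a0, max(tau0, 1e-9), base0),
        bounds=([0.0, 1e-12, -np.inf], [np.inf, np.inf, np.inf]),
        maxfev=20000,
    )
    resid = y - model(t, *popt)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else -np.inf
    return DecayFit(
        amplitude_c=float(popt[0]),
        tau_ms=float(popt[1]) * 1e3,
        baseline_c=float(popt[2]),
        r_squared=r2,
    )


def _electrode_distance_mm(grid: ScenarioGrid, which: str = "any") -> np.ndarray:
    """Distance (mm) from each voxel to the nearest electrode voxel."""
    if which == "any":
        elec = (grid.labels == ELECTRODE_LINE) | (grid.labels == ELECTRODE_NEUTRAL)
    elif which == "line":
        elec = grid.labels == ELECTRODE_LINE
    else:
        elec = grid.labels == ELECTRODE_NEUTRAL
    if not elec.any():
        raise ValueError("grid has no electrode voxels")
    return ndimage.distance_transform_edt(~elec) * grid.spacing_mm


def effective_field_radius(
    sol: FieldSolution,
    grid: ScenarioGrid,
    threshold_v_per_cm: float = IRE_THRESHOLD_V_PER_CM,
    reference: str = "electrode_surface",
) -> float:
    """Extent (mm) of the super-threshold tissue region.

    ``electrode_surface``: maximum distance from the nearest electrode voxel
    over the super-threshold myocardium mask — how far the treatable field
    reaches into tissue.  ``inter_electrode``: the same distance restricted
    to the mid-surface equidistant from the two polarities, where the field
    sags between adjacent electrodes.  An empty mask gives 0 (nothing above
    threshold is a result, not an error).
    """
    if threshold_v_per_cm <= 0:
        raise ValueError("threshold must be > 0")
    mask = (sol.e_mag >= threshold_v_per_cm) & (grid.labels == MYOCARDIUM)
    if not mask.any():
        return 0.0
    d_any = _electrode_distance_mm(grid, "any")
    if reference == "electrode_surface":
        return float(d_any[mask].max())
    if reference == "inter_electrode":
        d_line = _electrode_distance_mm(grid, "line")
        d_neutral = _electrode_distance_mm(grid, "neutral")
        mid = np.abs(d_line - d_neutral) <= grid.spacing_mm
        sel = mask & mid
        if not sel.any():
            return 0.0
        return float(d_any[sel].max())
    raise ValueError(f"unknown reference '{reference}'")


def untreated_gap(
    sol: FieldSolution,
    grid: ScenarioGrid,
    threshold_v_per_cm: float = IRE_THRESHOLD_V_PER_CM,
    axis_mm: tuple[np.ndarray, np.ndarray] | None = None,
) -> float:
    """Longest contiguous sub-threshold myocardium span (mm) along the
    inter-electrode axis.

    By default the axis runs between the line and neutral electrode
    centroids (the septal catheter axis); an explicit pair of endpoint
    coordinates (mm) overrides it.  Raises if the axis crosses no tissue.
    """
    s = grid.spacing_mm
    if axis_mm is None:
        p0 = _centroid_mm(grid, ELECTRODE_LINE)
        p1 = _centroid_mm(grid, ELECTRODE_NEUTRAL)
    else:
        p0, p1 = np.asarray(axis_mm[0], float), np.asarray(axis_mm[1], float)
    length = float(np.linalg.norm(p1 - p0))
    n = max(int(np.ceil(length / (s / 2.0))), 2)
    step = length / (n - 1)
    pts = p0[None, :] + np.linspace(0, 1, n)[:, None] * (p1 - p0)[None, :]
    idx = np.clip(
        np.floor(pts / s).astype(int),
        0,
        np.array(grid.labels.shape) - 1,
    )
    lab = grid.labels[idx[:, 0], idx[:, 1], idx[:, 2]]
    e = sol.e_mag[idx[:, 0], idx[:, 1], idx[:, 2]]
    tissue = lab == MYOCARDIUM
    if not tissue.any():
        raise ValueError("inter-electrode axis crosses no myocardium")
    sub = tissue & (e < threshold_v_per_cm)
    best = run = 0
    for flag in sub:
        run = run + 1 if flag else 0
        best = max(best, run)
    return best * step


def _centroid_mm(grid: ScenarioGrid, label: int) -> np.ndarray:
    w = np.argwhere(grid.labels == label)
    if w.size == 0:
        raise ValueError("electrode label absent from grid")
    return (w.mean(axis=0) + 0.5) * grid.spacing_mm


def alignment_sensitivity(radii_mm: list[float] | np.ndarray) -> float:
    """Coefficient of variation (%) of lesion radii across catheter
    alignment configurations: sample SD (n-1) over mean, times 100."""
    r = np.asarray(radii_mm, dtype=float)
    if r.size < 2:
        raise ValueError("need at least 2 values")
    mean = float(r.mean())
    if mean == 0.0:
        raise ValueError("mean of the radii is zero; CV undefined")
    return float(r.std(ddof=1)) / mean * 100.0


def build_lesion_report(
    sol: FieldSolution,
    grid: ScenarioGrid,
    trace=None,
    threshold_v_per_cm: float = IRE_THRESHOLD_V_PER_CM,
) -> LesionReport:
    """Assemble the per-scenario summary: field/current statistics over the
    myocardium, interface temperature peak (when a thermal trace is given),
    effective radius, and — for two-catheter septal grids — the untreated gap."""
    fm = field_metrics(sol, grid, MYOCARDIUM)
    gap = None
    if grid.meta.get("kind") == "septal":
        gap = untreated_gap(sol, grid, threshold_v_per_cm)
    t_max = None
    if trace is not None:
        t_max = float(np.max(trace.probes["tissue_interface"]))
    return LesionReport(
        applied_volts=fm["voltage_applied_v"],
        e_field_max_kv_per_cm=fm["e_field_max_kv_per_cm"],
        e_field_mean_v_per_cm=fm["e_field_mean_v_per_cm"],
        j_mean_ka_per_m2=fm["j_mean_ka_per_m2"],
        j_max_ka_per_m2=fm["j_max_ka_per_m2"],
        t_interface_max_c=t_max,
        effective_radius_mm=effective_field_radius(
            sol, grid, threshold_v_per_cm, "electrode_surface"
        ),
        untreated_gap_mm=gap,
        threshold_v_per_cm=threshold_v_per_cm,
    )
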