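"""Voxelized labeled geometries for the three simulated ablation scenarios.

Each scenario is a uniform Cartesian voxel grid (cell-centered coordinates,
0-based indices, lengths in mm, half-open extents) whose voxels carry one of
five labels: blood, myocardium, the two electrode polarities (line = driven,
neutral = grounded) and catheter-body insulator.  Electrode voxel groups are
perfect conductors handled as Dirichlet boundary patches by the field
solver; the insulating catheter shaft is explicit so current cannot short
through the catheter body.

Three builders mirror the study's simulated settings:

* a pulmonary-vein ostium with a 10-electrode circular catheter on the
  lumen rim, electrodes in alternating line/neutral polarity (odd-numbered
  electrodes on the line pole);
* a flat atrial wall with the same loop catheter resting on the
  endocardial face;
* an interventricular septum with two tip catheters facing each other
  across the wall, with configurable lateral offset and tilt.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "BLOOD",
    "MYOCARDIUM",
    "ELECTRODE_LINE",
    "ELECTRODE_NEUTRAL",
    "INSULATOR",
    "LABEL_NAMES",
    "ScenarioGrid",
    "MaterialTable",
    "MaterialGrid",
    "validate_grid",
    "build_pv_ostium",
    "build_atrial_wall",
    "build_septal",
    "assign_materials",
]

BLOOD = 1
MYOCARDIUM = 2
ELECTRODE_LINE = 3
ELECTRODE_NEUTRAL = 4
INSULATOR = 5

LABEL_NAMES = {
    BLOOD: "blood",
    MYOCARDIUM: "myocardium",
    ELECTRODE_LINE: "electrode_line",
    ELECTRODE_NEUTRAL: "electrode_neutral",
    INSULATOR: "insulator",
}
ALLOWED_LABELS = frozenset(LABEL_NAMES)


@dataclass
class ScenarioGrid:
    """Labeled voxel grid for one ablation scenario.

    ``labels`` is an int array of shape ``dims``; ``spacing_mm`` the isotropic
    voxel edge; ``electrode_voltage`` maps electrode labels to their relative
    Dirichlet level (line 1, neutral 0 — scaled by the applied voltage at
    solve time).  ``meta`` carries builder provenance (scenario kind, flow
    axis, lumen radius) consumed by the flow and lesion modules.
    """

    spacing_mm: float
    labels: np.ndarray
    electrode_voltage: dict[int, float] = field(
        default_factory=lambda: {ELECTRODE_LINE: 1.0, ELECTRODE_NEUTRAL: 0.0}
    )
    meta: dict[str, Any] = field(default_factory=dict)
    materials: "MaterialGrid | None" = None
    #: optional signed distance (mm) to the nearest conductor surface,
    #: positive outside the conductor; enables the solver's sub-voxel
    #: (embedded-boundary) electrode-face correction
    conductor_sdf_mm: np.ndarray | None = None

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def coords_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Cell-centered coordinate arrays (open-grid), in mm."""
        s = self.spacing_mm
        return np.ogrid[
            0.5 * s : self.dims[0] * s : s,
            0.5 * s : self.dims[1] * s : s,
            0.5 * s : self.dims[2] * s : s,
        ]


def _face_adjacent(mask_a: np.ndarray, mask_b: np.ndarray) -> bool:
    """True if any voxel of ``mask_a`` shares a face with one of ``mask_b``."""
    for ax in range(3):
        for sl_a, sl_b in (
            (slice(None, -1), slice(1, None)),
            (slice(1, None), slice(None, -1)),
        ):
            ia = [slice(None)] * 3
            ib = [slice(None)] * 3
            ia[ax], ib[ax] = sl_a, sl_b
            if np.any(mask_a[tuple(ia)] & mask_b[tuple(ib)]):
                return True
    return False


def validate_grid(grid: ScenarioGrid) -> None:
    """Check the structural invariants every scenario must satisfy.

    Raises ``ValueError`` on: unknown labels, a missing electrode polarity,
    or line/neutral electrode voxels sharing a face (grid-level short
    circuit).
    """
    present = set(np.unique(grid.labels).tolist())
    unknown = present - ALLOWED_LABELS
    if unknown:
        raise ValueError(f"unknown voxel labels: {sorted(unknown)}")
    line = grid.labels == ELECTRODE_LINE
    neutral = grid.labels == ELECTRODE_NEUTRAL
    if not line.any():
        raise ValueError("grid has no line-electrode voxels")
    if not neutral.any():
        raise ValueError("grid has no neutral-electrode voxels")
    if _face_adjacent(line, neutral):
        raise ValueError(
            "line and neutral electrode voxels are face-adjacent (short circuit "
            "at grid resolution)"
        )


# ---------------------------------------------------------------------------
# material properties


@dataclass(frozen=True)
class Materials:
    """Bulk properties of one material: electrical conductivity sigma (S/m),
    thermal conductivity k (W/m/K), density rho (kg/m^3), specific heat
    c_p (J/kg/K)."""

    sigma: float
    k: float
    rho: float
    c_p: float


@dataclass
class MaterialTable:
    """Per-label material properties plus the baseline tissue temperature.

    Defaults are standard literature-range values for myocardium and blood
    at body temperature, platinum for the electrodes and nylon for the
    catheter shaft; every entry is overridable through config.
    """

    by_label: dict[int, Materials] = field(
        default_factory=lambda: {
            MYOCARDIUM: Materials(sigma=0.381, k=0.56, rho=1081.0, c_p=3686.0),
            BLOOD: Materials(sigma=0.70, k=0.52, rho=1050.0, c_p=3617.0),
            ELECTRODE_LINE: Materials(sigma=9.4e6, k=71.6, rho=21450.0, c_p=133.0),
            ELECTRODE_NEUTRAL: Materials(sigma=9.4e6, k=71.6, rho=21450.0, c_p=133.0),
            INSULATOR: Materials(sigma=1e-10, k=0.26, rho=1150.0, c_p=1700.0),
        }
    )
    baseline_temp_c: float = 37.0

    def __post_init__(self) -> None:
        for lbl in (BLOOD, MYOCARDIUM):
            if lbl in self.by_label:
                m = self.by_label[lbl]
                if min(m.sigma, m.k, m.rho, m.c_p) <= 0:
                    raise ValueError(
                        f"{LABEL_NAMES[lbl]} properties must all be positive"
                    )
        if INSULATOR in self.by_label and self.by_label[INSULATOR].sigma > 1e-6:
            raise ValueError("insulator conductivity must be <= 1e-6 S/m")

    def override(self, label: int, **kwargs: float) -> None:
        """Replace selected properties of one label in place."""
        cur = self.by_label[label]
        self.by_label[label] = Materials(
            sigma=kwargs.get("sigma", cur.sigma),
            k=kwargs.get("k", cur.k),
            rho=kwargs.get("rho", cur.rho),
            c_p=kwargs.get("c_p", cur.c_p),
        )


@dataclass
class MaterialGrid:
    """Per-voxel material fields attached to a scenario grid (SI units)."""

    sigma: np.ndarray
    k: np.ndarray
    rho: np.ndarray
    c_p: np.ndarray
    baseline_temp_c: float


def assign_materials(grid: ScenarioGrid, table: MaterialTable | None = None) -> ScenarioGrid:
    """Populate per-voxel sigma/k/rho/c_p fields from a material table.

    Every label present in the grid must have a table entry; the grid is
    returned with its ``materials`` attribute set (in place).
    """
    if table is None:
        table = MaterialTable()
    present = np.unique(grid.labels)
    missing = [int(l) for l in present if int(l) not in table.by_label]
    if missing:
        names = ", ".join(LABEL_NAMES.get(l, str(l)) for l in missing)
        raise ValueError(f"material table is missing entries for: {names}")
    shape = grid.labels.shape
    sigma = np.empty(shape)
    k = np.empty(shape)
    rho = np.empty(shape)
    c_p = np.empty(shape)
    for lbl in present:
        m = table.by_label[int(lbl)]
        sel = grid.labels == lbl
        sigma[sel] = m.sigma
        k[sel] = m.k
        rho[sel] = m.rho
        c_p[sel] = m.c_p
    grid.materials = MaterialGrid(
        sigma=sigma, k=k, rho=rho, c_p=c_p, baseline_temp_c=table.baseline_temp_c
    )
    return grid


# ---------------------------------------------------------------------------
# builders


def _loop_electrodes(
    labels: np.ndarray,
    grid_spacing: float,
    center_xy: tuple[float, float],
    loop_radius_mm: float,
    z_lo_mm: float,
    z_hi_mm: float,
    n_groups: int,
    segment_mm: float,
    radial_mm: float,
) -> None:
    """Stamp an ``n_groups``-electrode ring with alternating polarity.

    Electrode k (0-based; electrode number k+1) is on the line pole when
    its number is odd, on the neutral pole when even.  The shaft arcs
    between electrodes become insulator so groups are never face-adjacent.
    """
    x, y, z = np.ogrid[
        0.5 * grid_spacing : labels.shape[0] * grid_spacing : grid_spacing,
        0.5 * grid_spacing : labels.shape[1] * grid_spacing : grid_spacing,
        0.5 * grid_spacing : labels.shape[2] * grid_spacing : grid_spacing,
    ]
    dx = x - center_xy[0]
    dy = y - center_xy[1]
    r = np.sqrt(dx**2 + dy**2)
    theta = np.mod(np.arctan2(dy, dx), 2 * np.pi)
    in_band = (
        (r >= loop_radius_mm - radial_mm)
        & (r < loop_radius_mm)
        & (z >= z_lo_mm)
        & (z < z_hi_mm)
    )
    in_band = np.broadcast_to(in_band, labels.shape)
    half_arc = segment_mm / (2.0 * loop_radius_mm)  # radians
    step = 2 * np.pi / n_groups
    theta_b = np.broadcast_to(theta, labels.shape)
    ring = in_band & (labels == BLOOD)
    labels[ring] = INSULATOR
    for kk in range(n_groups):
        ang = kk * step
        d_ang = np.abs(np.mod(theta_b - ang + np.pi, 2 * np.pi) - np.pi)
        grp = ring & (d_ang <= half_arc)
        lbl = ELECTRODE_LINE if (kk + 1) % 2 == 1 else ELECTRODE_NEUTRAL
        labels[grp] = lbl


def build_pv_ostium(
    diameter_mm: float = 13.0,
    wall_mm: float = 3.0,
    spacing_mm: float = 0.25,
    *,
    length_mm: float = 8.0,
    pad_mm: float = 2.0,
    n_electrodes: int = 10,
    electrode_mm: float = 1.0,
) -> ScenarioGrid:
    """Pulmonary-vein ostium: blood lumen through a myocardial sleeve.

    A circular catheter with ``n_electrodes`` ring segments rests on the
    lumen rim at mid-length, polarity alternating around the ring (odd
    electrode numbers on the line pole).  Lumen diameters outside the
    study's 12-14 mm range are accepted with a warning.
    """
    if diameter_mm <= 0:
        raise ValueError("diameter_mm must be > 0")
    if not (12.0 <= diameter_mm <= 14.0):
        warnings.warn(
            f"PV ostium diameter {diameter_mm} mm outside the studied 12-14 mm range",
            stacklevel=2,
        )
    if spacing_mm > electrode_mm:
        raise ValueError(
            f"spacing {spacing_mm} mm too coarse to resolve {electrode_mm} mm electrodes"
        )
    # group centers are pi*d/n apart along the ring; require a clear gap
    gap_mm = np.pi * diameter_mm / n_electrodes - electrode_mm
    if gap_mm < 2 * spacing_mm:
        raise ValueError("electrode groups would touch at this resolution")
    radius = diameter_mm / 2.0
    half_xy = radius + wall_mm + pad_mm
    nx = int(np.ceil(2 * half_xy / spacing_mm))
    nz = int(np.ceil(length_mm / spacing_mm))
    labels = np.full((nx, nx, nz), BLOOD, dtype=np.int8)
    cx = nx * spacing_mm / 2.0
    x, y, _ = np.ogrid[
        0.5 * spacing_mm : nx * spacing_mm : spacing_mm,
        0.5 * spacing_mm : nx * spacing_mm : spacing_mm,
        0.5 * spacing_mm : nz * spacing_mm : spacing_mm,
    ]
    r = np.sqrt((x - cx) ** 2 + (y - cx) ** 2)
    sleeve = (r >= radius) & (r < radius + wall_mm)
    labels[np.broadcast_to(sleeve, labels.shape)] = MYOCARDIUM
    z_mid = nz * spacing_mm / 2.0
    _loop_electrodes(
        labels,
        spacing_mm,
        (cx, cx),
        loop_radius_mm=radius,
        z_lo_mm=z_mid - electrode_mm / 2.0,
        z_hi_mm=z_mid + electrode_mm / 2.0,
        n_groups=n_electrodes,
        segment_mm=electrode_mm,
        radial_mm=electrode_mm,
    )
    grid = ScenarioGrid(
        spacing_mm=spacing_mm,
        labels=labels,
        meta={
            "kind": "pv_ostium",
            "flow_axis": 2,
            "lumen_radius_mm": radius,
            "lumen_center_mm": (cx, cx),
            "n_electrode_groups": n_electrodes,
        },
    )
    validate_grid(grid)
    return grid


def build_atrial_wall(
    wall_mm: float = 5.85,
    loop_diameter_mm: float = 13.0,
    spacing_mm: float = 0.25,
    *,
    blood_mm: float = 8.0,
    pad_mm: float = 3.0,
    n_electrodes: int = 10,
    electrode_mm: float = 1.0,
) -> ScenarioGrid:
    """Flat atrial wall (default 5.85 mm, the measured mean thickness) under
    a blood pool, with the loop catheter resting on the endocardial face."""
    if wall_mm <= 0:
        raise ValueError("wall_mm must be > 0")
    half_xy = loop_diameter_mm / 2.0 + pad_mm
    if loop_diameter_mm <= 0:
        raise ValueError("loop_diameter_mm must be > 0")
    nx = int(np.ceil(2 * half_xy / spacing_mm))
    if loop_diameter_mm + 2 * spacing_mm > nx * spacing_mm:
        raise ValueError("loop larger than the lateral domain")
    nz = int(np.ceil((wall_mm + blood_mm) / spacing_mm))
    labels = np.full((nx, nx, nz), BLOOD, dtype=np.int8)
    _, _, z = np.ogrid[
        0.5 * spacing_mm : nx * spacing_mm : spacing_mm,
        0.5 * spacing_mm : nx * spacing_mm : spacing_mm,
        0.5 * spacing_mm : nz * spacing_mm : spacing_mm,
    ]
    slab = z < wall_mm
    labels[np.broadcast_to(slab, labels.shape)] = MYOCARDIUM
    cx = nx * spacing_mm / 2.0
    # loop lies flat on the endocardial face: ring band just above the slab
    n_slab = int(np.sum((np.arange(nz) + 0.5) * spacing_mm < wall_mm))
    z_lo = n_slab * spacing_mm
    _loop_electrodes_flat(
        labels,
        spacing_mm,
        (cx, cx),
        loop_radius_mm=loop_diameter_mm / 2.0,
        z_lo_mm=z_lo,
        z_hi_mm=z_lo + max(electrode_mm, spacing_mm),
        n_groups=n_electrodes,
        segment_mm=electrode_mm,
        tube_mm=electrode_mm,
    )
    grid = ScenarioGrid(
        spacing_mm=spacing_mm,
        labels=labels,
        meta={
            "kind": "atrial_wall",
            "flow_axis": 0,
            "wall_mm": wall_mm,
            "n_electrode_groups": n_electrodes,
        },
    )
    validate_grid(grid)
    return grid


def _loop_electrodes_flat(
    labels: np.ndarray,
    grid_spacing: float,
    center_xy: tuple[float, float],
    loop_radius_mm: float,
    z_lo_mm: float,
    z_hi_mm: float,
    n_groups: int,
    segment_mm: float,
    tube_mm: float,
) -> None:
    """Ring lying in a horizontal plane (atrial-wall catheter), polarity
    alternating; shaft arcs are insulator."""
    x, y, z = np.ogrid[
        0.5 * grid_spacing : labels.shape[0] * grid_spacing : grid_spacing,
        0.5 * grid_spacing : labels.shape[1] * grid_spacing : grid_spacing,
        0.5 * grid_spacing : labels.shape[2] * grid_spacing : grid_spacing,
    ]
    dx = x - center_xy[0]
    dy = y - center_xy[1]
    r = np.sqrt(dx**2 + dy**2)
    theta = np.mod(np.arctan2(dy, dx), 2 * np.pi)
    band = (
        (np.abs(r - loop_radius_mm) <= tube_mm / 2.0)
        & (z >= z_lo_mm)
        & (z < z_hi_mm)
    )
    band = np.broadcast_to(band, labels.shape) & (labels == BLOOD)
    labels[band] = INSULATOR
    theta_b = np.broadcast_to(theta, labels.shape)
    half_arc = segment_mm / (2.0 * loop_radius_mm)
    step = 2 * np.pi / n_groups
    for kk in range(n_groups):
        ang = kk * step
        d_ang = np.abs(np.mod(theta_b - ang + np.pi, 2 * np.pi) - np.pi)
        grp = band & (d_ang <= half_arc)
        labels[grp] = ELECTRODE_LINE if (kk + 1) % 2 == 1 else ELECTRODE_NEUTRAL


def _stamp_tip(
    labels: np.ndarray,
    spacing: float,
    tip_point_mm: np.ndarray,
    direction: np.ndarray,
    length_mm: float,
    radius_mm: float,
    label: int,
) -> None:
    """Rasterize a cylindrical catheter tip: axis from ``tip_point`` along
    ``direction`` (unit vector pointing away from the tissue face)."""
    shape = labels.shape
    x, y, z = np.ogrid[
        0.5 * spacing : shape[0] * spacing : spacing,
        0.5 * spacing : shape[1] * spacing : spacing,
        0.5 * spacing : shape[2] * spacing : spacing,
    ]
    px = x - tip_point_mm[0]
    py = y - tip_point_mm[1]
    pz = z - tip_point_mm[2]
    t = px * direction[0] + py * direction[1] + pz * direction[2]
    d2 = (
        (px - t * direction[0]) ** 2
        + (py - t * direction[1]) ** 2
        + (pz - t * direction[2]) ** 2
    )
    inside = (t >= 0.0) & (t <= length_mm) & (d2 <= radius_mm**2)
    inside = np.broadcast_to(inside, shape)
    # the catheter axis must stay out of the tissue; a tilted tip's corner
    # merely contacts the face and is clipped at the tissue boundary
    for tt in np.linspace(0.75 * spacing, length_mm, 32):
        p = tip_point_mm + tt * direction
        idx = np.floor(p / spacing).astype(int)
        if np.all(idx >= 0) and np.all(idx < np.array(shape)):
            if labels[tuple(idx)] == MYOCARDIUM:
                raise ValueError("electrode tip overlaps the tissue interior")
    sel = inside & (labels == BLOOD)
    labels[sel] = label


def build_septal(
    septum_mm: float = 15.0,
    offset_mm: float = 0.0,
    tilt_deg: float = 0.0,
    spacing_mm: float = 0.5,
    *,
    blood_mm: float = 6.0,
    pad_mm: float = 8.0,
    line_tip_mm: float = 4.0,
    line_diam_mm: float = 2.3,
    neutral_tip_mm: float = 2.0,
    neutral_diam_mm: float = 2.0,
) -> ScenarioGrid:
    """Interventricular septum: two tip catheters facing each other across
    the wall.

    The line (ablation, 4 mm tip) catheter touches one face; the neutral
    (diagnostic, 2 mm tip) catheter touches the opposite face, displaced
    laterally by ``offset_mm`` and with the line catheter tilted ``tilt_deg``
    from the septal normal (relative tilt between the catheters).
    """
    if septum_mm <= 0:
        raise ValueError("septum_mm must be > 0")
    if offset_mm < 0:
        raise ValueError("offset_mm must be >= 0")
    if not (0.0 <= tilt_deg < 90.0):
        raise ValueError("tilt_deg must lie in [0, 90)")
    tilt = np.deg2rad(tilt_deg)
    if line_tip_mm * np.cos(tilt) > blood_mm or neutral_tip_mm > blood_mm:
        raise ValueError(
            "electrode tip does not fit in the blood pool and would overlap "
            "the tissue interior or leave the domain; increase blood_mm"
        )
    reach = max(line_tip_mm, neutral_tip_mm) * np.sin(tilt) + max(
        line_diam_mm, neutral_diam_mm
    )
    half_x = offset_mm / 2.0 + pad_mm + reach
    nx = int(np.ceil(2 * half_x / spacing_mm))
    ny = int(np.ceil(2 * (pad_mm + max(line_diam_mm, neutral_diam_mm)) / spacing_mm))
    nz = int(np.ceil((septum_mm + 2 * blood_mm) / spacing_mm))
    labels = np.full((nx, ny, nz), BLOOD, dtype=np.int8)
    _, _, z = np.ogrid[
        0.5 * spacing_mm : nx * spacing_mm : spacing_mm,
        0.5 * spacing_mm : ny * spacing_mm : spacing_mm,
        0.5 * spacing_mm : nz * spacing_mm : spacing_mm,
    ]
    z_lo = blood_mm
    z_hi = blood_mm + septum_mm
    slab = (z >= z_lo) & (z < z_hi)
    labels[np.broadcast_to(slab, labels.shape)] = MYOCARDIUM
    cx = nx * spacing_mm / 2.0
    cy = ny * spacing_mm / 2.0
    # line tip below the slab, tilted in the y-z plane (perpendicular to the
    # offset direction, so lateral offset and tilt stay independent);
    # neutral tip above, normal incidence, offset along x
    line_point = np.array([cx - offset_mm / 2.0, cy, z_lo])
    line_dir = np.array([0.0, np.sin(tilt), -np.cos(tilt)])
    _stamp_tip(
        labels, spacing_mm, line_point, line_dir, line_tip_mm, line_diam_mm / 2.0,
        ELECTRODE_LINE,
    )
    neutral_point = np.array([cx + offset_mm / 2.0, cy, z_hi])
    neutral_dir = np.array([0.0, 0.0, 1.0])
    _stamp_tip(
        labels, spacing_mm, neutral_point, neutral_dir, neutral_tip_mm,
        neutral_diam_mm / 2.0, ELECTRODE_NEUTRAL,
    )
    grid = ScenarioGrid(
        spacing_mm=spacing_mm,
        labels=labels,
        meta={
            "kind": "septal",
            "flow_axis": 0,
            "septum_mm": septum_mm,
            "offset_mm": offset_mm,
            "tilt_deg": tilt_deg,
        },
    )
    validate_grid(grid)
    return grid
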