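"""Quasi-static conduction solve on a labeled scenario grid.

During the 100-us burst plateau the tissue is treated as a resistive
conductor: the potential obeys the generalized Laplace equation
``div(sigma grad(phi)) = 0`` with Dirichlet values on the electrode voxel
groups (applied voltage on the line pole, 0 V on the neutral pole) and
zero-flux outer boundaries.  No 100-kHz dispersion or skin effect is
modeled — static conductivities at the plateau voltage.

Discretization is a 7-point finite-volume stencil with harmonic-mean face
conductivities, which keeps the normal current continuous across material
interfaces and the discrete operator symmetric positive definite.  The
reduced system over non-electrode voxels is solved with Jacobi-preconditioned
conjugate gradients to a relative residual of 1e-8.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import cg

from .scenario import (
    ELECTRODE_LINE,
    ELECTRODE_NEUTRAL,
    LABEL_NAMES,
    ScenarioGrid,
    assign_materials,
)

__all__ = ["FieldSolution", "solve_potential", "total_current", "field_metrics"]

#: Generator current compliance (A); currents above this trip the flag.
CURRENT_COMPLIANCE_A = 12.0


@dataclass
class FieldSolution:
    """Solved conduction problem on one grid at one applied voltage.

    ``potential`` in V, ``e_mag`` in V/cm, ``j_mag`` in kA/m^2 (per voxel);
    ``total_current`` in A is the net current leaving the line electrodes.
    """

    potential: np.ndarray
    e_mag: np.ndarray
    j_mag: np.ndarray
    total_current: float
    applied_volts: float
    current_line_a: float
    current_neutral_a: float
    residual: float
    n_iter: int


def _face_conductance(sigma: np.ndarray, axis: int, spacing_m: float) -> np.ndarray:
    """Harmonic-mean conductance (S) of the faces along ``axis``."""
    a = [slice(None)] * 3
    b = [slice(None)] * 3
    a[axis] = slice(None, -1)
    b[axis] = slice(1, None)
    sa = sigma[tuple(a)]
    sb = sigma[tuple(b)]
    with np.errstate(divide="ignore", invalid="ignore"):
        hm = np.where(sa + sb > 0, 2.0 * sa * sb / (sa + sb), 0.0)
    return hm * spacing_m  # face area / distance = spacing


def solve_potential(
    grid: ScenarioGrid,
    applied_volts: float,
    rtol: float = 1e-8,
    maxiter: int | None = None,
) -> FieldSolution:
    """Solve the quasi-static potential for one applied voltage.

    Line electrodes are held at ``applied_volts`` (scaled by the grid's
    relative electrode levels), neutral electrodes at 0 V, outer boundary
    zero-flux.  Field magnitude comes from central differences of the
    potential; current density is ``sigma * E``.

    Raises
    ------
    ValueError
        For a negative applied voltage or a grid without both electrode
        polarities.
    RuntimeError
        If CG fails to reach the requested residual.
    """
    if applied_volts < 0:
        raise ValueError("applied_volts must be >= 0")
    if grid.materials is None:
        assign_materials(grid)
    sigma = grid.materials.sigma
    labels = grid.labels
    s_m = grid.spacing_mm * 1e-3
    dir_mask = (labels == ELECTRODE_LINE) | (labels == ELECTRODE_NEUTRAL)
    if not (labels == ELECTRODE_LINE).any() or not (labels == ELECTRODE_NEUTRAL).any():
        raise ValueError("grid must contain both electrode polarities")
    dir_vals = np.zeros(labels.shape)
    for lbl, rel in grid.electrode_voltage.items():
        dir_vals[labels == lbl] = rel * applied_volts

    n_all = labels.size
    unknown = ~dir_mask
    idx = -np.ones(n_all, dtype=np.int64)
    flat_unknown = unknown.ravel()
    n_unk = int(flat_unknown.sum())
    idx[flat_unknown] = np.arange(n_unk)
    idx3 = idx.reshape(labels.shape)

    sdf = grid.conductor_sdf_mm
    face_g = []
    for axis in range(3):
        g = _face_conductance(sigma, axis, s_m)
        if sdf is not None:
            g = _embedded_boundary_faces(g, sigma, sdf, dir_mask, axis, s_m)
        face_g.append(g)

    diag = np.zeros(labels.shape)
    rhs = np.zeros(labels.shape)
    rows, cols, vals = [], [], []
    for axis in range(3):
        g = face_g[axis]
        a = [slice(None)] * 3
        b = [slice(None)] * 3
        a[axis] = slice(None, -1)
        b[axis] = slice(1, None)
        a, b = tuple(a), tuple(b)
        ua, ub = unknown[a], unknown[b]
        # every face contributes to the diagonal of its unknown endpoints
        diag[a] += np.where(ua, g, 0.0)
        diag[b] += np.where(ub, g, 0.0)
        # unknown-unknown faces: off-diagonal entries
        both = ua & ub
        if both.any():
            ia = idx3[a][both]
            ib = idx3[b][both]
            gv = g[both]
            rows.append(ia)
            cols.append(ib)
            vals.append(-gv)
            rows.append(ib)
            cols.append(ia)
            vals.append(-gv)
        # unknown-Dirichlet faces: move the known value to the rhs
        ad = ua & ~ub
        if ad.any():
            r = np.zeros_like(g)
            r[ad] = g[ad] * dir_vals[b][ad]
            rhs[a] += r
        bd = ub & ~ua
        if bd.any():
            r = np.zeros_like(g)
            r[bd] = g[bd] * dir_vals[a][bd]
            rhs[b] += r

    d = diag[unknown]
    if np.any(d <= 0):
        raise RuntimeError(
            "singular system: voxels with no conductive connection "
            "(disconnected electrode graph or zero conductivity)"
        )
    iu = idx3[unknown]
    rows.append(iu)
    cols.append(iu)
    vals.append(d)
    A = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_unk, n_unk),
    )
    b_vec = rhs[unknown]

    # Jacobi preconditioner
    M = sparse.diags(1.0 / d)
    x0 = np.full(n_unk, 0.5 * applied_volts)
    x, info = cg(A, b_vec, x0=x0, rtol=rtol, atol=0.0, maxiter=maxiter, M=M)
    res = float(np.linalg.norm(b_vec - A @ x))
    b_norm = float(np.linalg.norm(b_vec))
    if info != 0 or (b_norm > 0 and res / b_norm > 10 * rtol):
        raise RuntimeError(
            f"conduction solve did not converge (info={info}, "
            f"relative residual={res / max(b_norm, 1e-300):.3e})"
        )

    phi = dir_vals.copy()
    phi[unknown] = x

    e_si = _field_magnitude(phi, dir_mask, s_m)
    e_si[dir_mask] = 0.0  # field inside a perfect conductor
    j_si = sigma * e_si  # A/m^2

    i_line = _electrode_current(phi, face_g, labels, ELECTRODE_LINE)
    i_neutral = -_electrode_current(phi, face_g, labels, ELECTRODE_NEUTRAL)

    return FieldSolution(
        potential=phi,
        e_mag=e_si / 100.0,
        j_mag=j_si / 1000.0,
        total_current=i_line,
        applied_volts=float(applied_volts),
        current_line_a=i_line,
        current_neutral_a=i_neutral,
        residual=res / max(b_norm, 1e-300),
        n_iter=-1,
    )


def _embedded_boundary_faces(
    g: np.ndarray,
    sigma: np.ndarray,
    sdf_mm: np.ndarray,
    dir_mask: np.ndarray,
    axis: int,
    s_m: float,
) -> np.ndarray:
    """Sub-voxel correction of electrode-material face conductances.

    With a signed distance to the conductor surface available, the surface
    crossing along each electrode-tissue link is located by linear
    interpolation of the distance field; the face conductance becomes
    ``sigma_tissue * s / theta`` where ``theta`` is the fraction of the
    link on the tissue side (Shortley-Weller boundary treatment).  The
    plain harmonic mean corresponds to ``theta = 1/2``.
    """
    a = [slice(None)] * 3
    b = [slice(None)] * 3
    a[axis] = slice(None, -1)
    b[axis] = slice(1, None)
    a, b = tuple(a), tuple(b)
    da, db = sdf_mm[a], sdf_mm[b]
    ea, eb = dir_mask[a], dir_mask[b]
    out = g.copy()
    # electrode on the a side, material on the b side
    sel = ea & ~eb
    if sel.any():
        theta = np.clip(db[sel] / np.maximum(db[sel] - da[sel], 1e-12), 0.05, 1.0)
        out[sel] = sigma[b][sel] * s_m / theta
    sel = eb & ~ea
    if sel.any():
        theta = np.clip(da[sel] / np.maximum(da[sel] - db[sel], 1e-12), 0.05, 1.0)
        out[sel] = sigma[a][sel] * s_m / theta
    return out


def _field_magnitude(phi: np.ndarray, dir_mask: np.ndarray, s_m: float) -> np.ndarray:
    """|grad phi| by central differences, switching to the one-sided
    difference on the tissue side next to electrode voxels (the potential
    kink at a perfect-conductor face makes the central difference biased
    there)."""
    comps = []
    for axis in range(3):
        central = np.gradient(phi, s_m, axis=axis, edge_order=1)
        if phi.shape[axis] < 2:
            comps.append(central)
            continue
        fwd = np.empty_like(phi)
        bwd = np.empty_like(phi)
        a = [slice(None)] * 3
        b = [slice(None)] * 3
        a[axis] = slice(None, -1)
        b[axis] = slice(1, None)
        a, b = tuple(a), tuple(b)
        d = (phi[b] - phi[a]) / s_m
        fwd[a] = d
        last = [slice(None)] * 3
        last[axis] = slice(-1, None)
        first = [slice(None)] * 3
        first[axis] = slice(None, 1)
        fwd[tuple(last)] = 0.0
        bwd[b] = d
        bwd[tuple(first)] = 0.0
        nbr_fwd = np.zeros_like(dir_mask)
        nbr_bwd = np.zeros_like(dir_mask)
        nbr_fwd[a] = dir_mask[b]
        nbr_bwd[b] = dir_mask[a]
        comp = np.where(
            nbr_fwd & ~nbr_bwd & ~dir_mask,
            bwd,
            np.where(nbr_bwd & ~nbr_fwd & ~dir_mask, fwd, central),
        )
        comps.append(comp)
    return np.sqrt(comps[0] ** 2 + comps[1] ** 2 + comps[2] ** 2)


def _electrode_current(
    phi: np.ndarray,
    face_g: list[np.ndarray],
    labels: np.ndarray,
    electrode_label: int,
) -> float:
    """Net current (A) leaving the given electrode group through its faces."""
    elec = labels == electrode_label
    other = (labels == ELECTRODE_LINE) | (labels == ELECTRODE_NEUTRAL)
    total = 0.0
    for axis in range(3):
        g = face_g[axis]
        a = [slice(None)] * 3
        b = [slice(None)] * 3
        a[axis] = slice(None, -1)
        b[axis] = slice(1, None)
        a, b = tuple(a), tuple(b)
        ea, eb = elec[a], elec[b]
        oa, ob = other[a], other[b]
        # faces from this electrode into non-electrode material
        f = ea & ~ob
        total += float(np.sum(g[f] * (phi[a][f] - phi[b][f])))
        f = eb & ~oa
        total += float(np.sum(g[f] * (phi[b][f] - phi[a][f])))
    return total


def total_current(
    sol: FieldSolution,
    grid: ScenarioGrid,
    compliance_a: float = CURRENT_COMPLIANCE_A,
) -> tuple[float, bool]:
    """Total line-electrode current and whether it trips the generator's
    current compliance (default 12 A)."""
    i = sol.current_line_a
    return i, bool(i > compliance_a)


def field_metrics(
    sol: FieldSolution, grid: ScenarioGrid, region: int
) -> dict[str, float]:
    """Masked field/current-density statistics over one label region.

    Returns the simulation-report fields: applied voltage, electric field
    max (kV/cm) and mean (reported in both V/cm and kV/cm — the mean's
    printed unit convention is ambiguous in the source material), current
    density mean and max (kA/m^2).
    """
    mask = grid.labels == region
    if not mask.any():
        name = LABEL_NAMES.get(region, str(region))
        raise ValueError(f"region '{name}' has no voxels in this grid")
    e = sol.e_mag[mask]
    j = sol.j_mag[mask]
    return {
        "voltage_applied_v": sol.applied_volts,
        "e_field_max_kv_per_cm": float(e.max()) / 1000.0,
        "e_field_max_v_per_cm": float(e.max()),
        "e_field_mean_v_per_cm": float(e.mean()),
        "e_field_mean_kv_per_cm": float(e.mean()) / 1000.0,
        "j_mean_ka_per_m2": float(j.mean()),
        "j_max_ka_per_m2": float(j.max()),
    }
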