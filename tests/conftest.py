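"""Shared fixtures: analytic benchmark grids and solved fields.

The concentric-spheres problem is built as an octant (spheres centered on a
domain corner) so the solver's natural zero-flux boundary acts as the
symmetry planes of the full problem; the analytic solution is unchanged and
the grid is 8x smaller.
"""

from __future__ import annotations

import numpy as np
import pytest

from pfasim import scenario as sc
from pfasim import electrics as el
from pfasim import thermal as th

SPHERE_A_MM = 2.0
SPHERE_B_MM = 20.0
SPHERE_VOLTS = 900.0


def make_spheres_grid(spacing_mm: float) -> tuple[sc.ScenarioGrid, np.ndarray]:
    """Octant concentric-spheres grid with the analytic conductor SDF."""
    n = int(np.ceil((SPHERE_B_MM + 2 * spacing_mm) / spacing_mm))
    labels = np.full((n, n, n), sc.MYOCARDIUM, dtype=np.int8)
    x, y, z = np.ogrid[
        0.5 * spacing_mm : n * spacing_mm : spacing_mm,
        0.5 * spacing_mm : n * spacing_mm : spacing_mm,
        0.5 * spacing_mm : n * spacing_mm : spacing_mm,
    ]
    r = np.broadcast_to(np.sqrt(x**2 + y**2 + z**2), labels.shape).copy()
    labels[r <= SPHERE_A_MM] = sc.ELECTRODE_LINE
    labels[r >= SPHERE_B_MM] = sc.ELECTRODE_NEUTRAL
    grid = sc.ScenarioGrid(
        spacing_mm=spacing_mm,
        labels=labels,
        conductor_sdf_mm=np.minimum(r - SPHERE_A_MM, SPHERE_B_MM - r),
    )
    sc.assign_materials(grid)
    return grid, r


def spheres_exact_potential(r_mm: np.ndarray) -> np.ndarray:
    a, b, v = SPHERE_A_MM, SPHERE_B_MM, SPHERE_VOLTS
    return v * (1.0 / r_mm - 1.0 / b) / (1.0 / a - 1.0 / b)


@pytest.fixture(scope="session")
def spheres_fine():
    """Concentric spheres at 0.25 mm: (grid, radius array, solution)."""
    grid, r = make_spheres_grid(0.25)
    sol = el.solve_potential(grid, SPHERE_VOLTS)
    return grid, r, sol


@pytest.fixture(scope="session")
def atrial_coarse():
    """Coarse atrial-wall scenario solved at 900 V, with the Joule source."""
    grid = sc.build_atrial_wall(5.85, 13.0, 0.5)
    sol = el.solve_potential(grid, 900.0)
    q = th.joule_source(sol, grid, 0.5)
    return grid, sol, q


@pytest.fixture(scope="session")
def septal_solutions():
    """Aligned and misaligned septal grids solved at equal voltage."""
    out = {}
    for name, (off, tilt) in {
        "aligned": (0.0, 0.0),
        "offset": (10.0, 0.0),
    }.items():
        grid = sc.build_septal(15.0, off, tilt, 0.75)
        sol = el.solve_potential(grid, 1500.0)
        out[name] = (grid, sol)
    return out
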