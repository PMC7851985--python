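"""Shared fixtures: phantom solutions and vein-model runs reused across tests.

The expensive vein-model solves are session-scoped and keep only scalar
summaries (contribution reports, impedances, balance residuals), not the
field arrays.
"""

from __future__ import annotations

import numpy as np
import pytest

from veincuff import (
    GeometryConfig,
    PhantomSpec,
    analytic_impedance,
    assemble_and_solve,
    default_material_table,
    electrode_current,
    make_phantom,
    region_contributions,
    sensitivity_field,
    single_terminal_scan,
)
from veincuff.experiments import RunSpec, build_vein_excitation

# problem sizes used by the shared vein-model fixtures
RES_ORDERING = (24, 48, 96)  # printed-ordering comparisons
RES_COARSE = (32, 64, 128)  # terminal-position scan (study coarse grid)
RES_SMALL = (16, 32, 64)  # frequency sweeps and variant comparisons


def run_case(
    cfg: GeometryConfig,
    mode: str = "simultaneous",
    position: str = "middle",
    resolution=RES_ORDERING,
    f: float = 1.0e6,
    with_vein: bool = True,
) -> dict:
    """Solve one vein-model case and return scalar summaries only."""
    exc = build_vein_excitation(
        cfg, resolution, mode=mode, position=position, with_vein=with_vein
    )
    materials = default_material_table()
    sol = assemble_and_solve(exc.grid, materials, exc, f)
    fld = sensitivity_field(sol)
    report = region_contributions(fld, descriptor=RunSpec(cfg, mode, position).label())
    Z_solver = exc.U / sol.I
    balance = sum(
        electrode_current(sol, m) for m in exc.terminal_masks.values()
    ) + electrode_current(sol, exc.ground_mask)
    return {
        "report": report,
        "Z_solver": Z_solver,
        "Z_recon": fld.Z,
        "geselowitz_rel": abs(fld.Z - Z_solver) / abs(Z_solver),
        "balance_rel": abs(balance) / abs(sol.I),
        "frequency": f,
    }


@pytest.fixture(scope="session")
def slab_solution():
    """Homogeneous slab phantom solved at DC (15 axial cells => a cell center
    sits exactly on the midplane)."""
    spec = PhantomSpec(kind="slab", length=0.01, area=1e-4, sigma=1.0)
    grid, exc, table = make_phantom(spec, resolution=(8, 8, 15))
    sol = assemble_and_solve(grid, table, exc, 0.0)
    return spec, grid, exc, table, sol


@pytest.fixture(scope="session")
def bilayer_solution():
    spec = PhantomSpec(kind="series_bilayer", length=0.01, area=1e-4, sigma=1.0, sigma2=2.0)
    grid, exc, table = make_phantom(spec, resolution=(8, 8, 16))
    sol = assemble_and_solve(grid, table, exc, 0.0)
    return spec, grid, exc, table, sol


@pytest.fixture(scope="session")
def coax_convergence():
    """Coaxial phantom relative errors over three radial refinements."""
    spec = PhantomSpec(
        kind="coaxial", radius_inner=1e-3, radius_outer=2e-3, length=0.06, sigma=1.0
    )
    Za = analytic_impedance(spec, 0.0)
    errors = {}
    for n_r in (16, 32, 64):
        grid, exc, table = make_phantom(spec, resolution=(n_r, 32, 64))
        sol = assemble_and_solve(grid, table, exc, 0.0)
        Z = exc.U / sol.I
        errors[n_r] = abs(Z - Za) / abs(Za)
    return spec, Za, errors


@pytest.fixture(scope="session")
def ordering_sweep():
    """The printed-ordering comparison runs at 1 MHz (7 solves)."""
    cases = {}
    for n in (28, 32, 44, 48):
        cases[f"simultaneous_N{n}"] = run_case(GeometryConfig(n_electrodes=n))
    cases["simultaneous_N28_rg1"] = run_case(GeometryConfig(r_ground=1e-3))
    cases["single_rt1"] = run_case(GeometryConfig(), mode="single")
    cases["single_rt2.5"] = run_case(GeometryConfig(r_terminal=2.5e-3), mode="single")
    return cases


@pytest.fixture(scope="session")
def position_scan():
    """Single-terminal position scan at the study's coarse grid (3 solves)."""
    return single_terminal_scan(GeometryConfig(), resolution=RES_COARSE, f=1.0e6)


@pytest.fixture(scope="session")
def vein_spectrum():
    """Default vein model over the standard 10 Hz - 1 MHz sweep
    (5 points/decade, 26 points)."""
    from veincuff import frequency_grid

    cfg = GeometryConfig()
    freqs = frequency_grid(10.0, 1.0e6, 5)
    cases = [run_case(cfg, resolution=RES_SMALL, f=f) for f in freqs]
    return freqs, cases
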