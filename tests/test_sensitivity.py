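"""Sensitivity field, volume impedance density, and region contributions."""

import copy

import numpy as np
import pytest

from veincuff import (
    MaterialSpec,
    SensitivityField,
    analytic_contributions,
    assemble_and_solve,
    make_phantom,
    reconstruct_impedance,
    region_contributions,
    sensitivity_field,
    uniform_table,
)
from veincuff.sensitivity import SensitivityError


def test_slab_sensitivity_uniform(slab_solution):
    """Uniform axial current in a slab gives S = 1/A^2 everywhere inside."""
    spec, grid, exc, table, sol = slab_solution
    fld = sensitivity_field(sol)
    expect = 1.0 / spec.area**2
    saline = grid.region_mask("saline")
    assert np.allclose(fld.S[saline].real, expect, rtol=1e-6)
    assert np.allclose(fld.S[saline].imag, 0.0, atol=1e-6 * expect)


def test_slab_impedance_density_integral(slab_solution):
    """Volume integral of z = rho*S reproduces Z = rho*L/A."""
    spec, grid, exc, table, sol = slab_solution
    fld = sensitivity_field(sol)
    Z_expected = spec.length / (spec.sigma * spec.area)
    assert fld.integral_z().real == pytest.approx(Z_expected, rel=1e-2)
    assert fld.Z.real == pytest.approx(Z_expected, rel=1e-2)


def test_reconstruction_matches_solver_impedance(slab_solution, bilayer_solution):
    for spec, grid, exc, table, sol in (slab_solution, bilayer_solution):
        fld = sensitivity_field(sol)
        Z_solver = exc.U / sol.I
        assert abs(reconstruct_impedance(fld) - Z_solver) / abs(Z_solver) < 1e-9


def test_bilayer_contributions_match_series_resistors(bilayer_solution):
    spec, grid, exc, table, sol = bilayer_solution
    fld = sensitivity_field(sol)
    report = region_contributions(fld)
    want = analytic_contributions(spec)  # saline 66.67 %, vein_wall 33.33 %
    assert report.z_pct["saline"] == pytest.approx(want["saline"], abs=0.05)
    assert report.z_pct["vein_wall"] == pytest.approx(want["vein_wall"], abs=0.05)
    assert report.power_pct["saline"] == pytest.approx(want["saline"], abs=0.05)
    assert report.power_pct["vein_wall"] == pytest.approx(want["vein_wall"], abs=0.05)
    # each measure partitions 100 % over the regions
    assert sum(report.z_pct.values()) == pytest.approx(100.0, abs=1e-9)
    assert sum(report.power_pct.values()) == pytest.approx(100.0, abs=1e-9)


def test_zero_volume_regions_flagged(bilayer_solution):
    spec, grid, exc, table, sol = bilayer_solution
    report = region_contributions(sensitivity_field(sol))
    assert any("zero volume" in f for f in report.flags)
    assert report.z_pct["glass_tube"] == 0.0


def test_single_region_takes_everything(slab_solution):
    """In a homogeneous slab the conducting region carries ~100 %."""
    spec, grid, exc, table, sol = slab_solution
    report = region_contributions(sensitivity_field(sol))
    # the gold electrode layers take a vanishing share
    assert report.z_pct["saline"] == pytest.approx(100.0, abs=1e-3)
    assert report.power_pct["saline"] == pytest.approx(100.0, abs=1e-3)


def test_conductivity_scaling_halves_impedance(slab_solution):
    spec, grid, exc, table, sol = slab_solution
    sol2 = assemble_and_solve(grid, uniform_table(2.0 * spec.sigma), exc, 0.0)
    fld1 = sensitivity_field(sol)
    fld2 = sensitivity_field(sol2)
    # the gold electrode layers keep their own conductivity, leaving a
    # nanoohm-scale offset
    assert fld2.Z == pytest.approx(0.5 * fld1.Z, rel=1e-8)


def test_blocked_parallel_branch_has_near_zero_sensitivity():
    """Halving the cross-section with an insulator: the blocked half carries
    almost no current, so its z-density contribution is negligible even
    though its resistivity is enormous, and Z doubles."""
    from veincuff import PhantomSpec

    spec = PhantomSpec(kind="slab", length=0.01, area=1e-4, sigma=1.0)
    grid, exc, table = make_phantom(spec, resolution=(8, 8, 15))
    nx = grid.shape[0]
    wall = grid.region_id("vein_wall")
    saline = grid.region_mask("saline").copy()
    half = np.zeros(grid.shape, dtype=bool)
    half[: nx // 2] = True
    grid.labels[half & saline] = wall
    table = table.replace(
        vein_wall=MaterialSpec("vein_wall", sigma=1e-12, eps_r=1.0)
    )
    sol = assemble_and_solve(grid, table, exc, 0.0)
    report = region_contributions(sensitivity_field(sol))
    assert report.z_pct["vein_wall"] < 0.1
    assert report.power_pct["vein_wall"] < 0.1
    Z_full = spec.length / (spec.sigma * spec.area)
    assert (exc.U / sol.I).real == pytest.approx(2.0 * Z_full, rel=1e-2)


def test_zero_current_rejected(slab_solution):
    spec, grid, exc, table, sol = slab_solution
    degenerate = copy.copy(sol)
    degenerate.I = 0.0
    with pytest.raises(SensitivityError, match="zero total current"):
        sensitivity_field(degenerate)


def test_negative_region_contribution_warns(bilayer_solution):
    spec, grid, exc, table, sol = bilayer_solution
    fld = sensitivity_field(sol)
    cell_z = fld.cell_z.copy()
    wall = grid.region_mask("vein_wall")
    cell_z[wall] = -np.abs(cell_z[wall])  # craft a negative-sensitivity region
    crafted = SensitivityField(
        grid=grid,
        frequency=fld.frequency,
        I=fld.I,
        S=fld.S,
        z=fld.z,
        p=fld.p,
        cell_z=cell_z,
        cell_power=fld.cell_power,
    )
    with pytest.warns(UserWarning, match="negative impedance contribution"):
        report = region_contributions(crafted)
    assert report.z_pct["vein_wall"] < 0  # reported as-is, never clipped
    assert any("negative contribution" in f for f in report.flags)


def test_shape_mismatch_rejected(slab_solution, bilayer_solution):
    spec, grid, exc, table, sol = slab_solution
    _, other_grid, *_ = bilayer_solution
    fld = sensitivity_field(sol)
    with pytest.raises(SensitivityError, match="shapes differ"):
        reconstruct_impedance(fld, grid=other_grid)
    with pytest.raises(SensitivityError, match="shapes differ"):
        region_contributions(fld, grid=other_grid)
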