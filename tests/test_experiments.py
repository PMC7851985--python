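"""Experiment driver: frequency grids, plans, sweeps, slices, variants."""

import math

import numpy as np
import pytest

from veincuff import (
    ExperimentPlan,
    GeometryConfig,
    GeometryError,
    PhantomSpec,
    RunSpec,
    assemble_and_solve,
    build_vein_excitation,
    default_material_table,
    export_slice,
    frequency_grid,
    make_phantom,
    run_configuration_sweep,
    single_terminal_scan,
    table1_plan,
    table2_plan,
    table3_plan,
)
from veincuff.experiments import position_to_electrode

from conftest import RES_SMALL


def test_frequency_grid_decades_exact():
    g = frequency_grid(10.0, 1.0e6, 1)
    assert g.size == 6
    assert np.allclose(g, [10.0, 100.0, 1e3, 1e4, 1e5, 1e6], rtol=1e-12)
    assert g[0] == 10.0 and g[-1] == 1.0e6  # endpoints exact


def test_frequency_grid_points_per_decade():
    g = frequency_grid(10.0, 1.0e6, 2)
    assert g.size == 11
    ratios = g[1:] / g[:-1]
    assert np.allclose(ratios, math.sqrt(10.0), rtol=1e-12)


@pytest.mark.parametrize(
    "args", [(0.0, 1e6, 5), (1e6, 10.0, 5), (10.0, 1e6, 0), (-1.0, 1e6, 5)]
)
def test_frequency_grid_rejects_bad_input(args):
    with pytest.raises(ValueError):
        frequency_grid(*args)


def test_position_to_electrode_mapping():
    cfg = GeometryConfig()  # 28 electrodes, 4 rings -> 7 per ring
    assert position_to_electrode(cfg, "first_end") == 0
    assert position_to_electrode(cfg, "middle") == 14
    assert position_to_electrode(cfg, "second_end") == 21
    with pytest.raises(ValueError, match="unknown position"):
        position_to_electrode(cfg, "center")


def test_builtin_plans_mirror_study_layout():
    p1, p2, p3 = table1_plan(), table2_plan(), table3_plan()
    assert [r.config.n_electrodes for r in p1.runs] == [28, 32, 44, 48]
    assert all(r.mode == "simultaneous" for r in p1.runs)
    assert all(r.config.r_ground == 1e-3 for r in p2.runs)
    assert len(p3.runs) == 6
    assert all(r.mode == "single" for r in p3.runs)
    assert {r.position for r in p3.runs} == {"middle", "first_end", "second_end"}
    for p in (p1, p2, p3):
        p.validate()


def test_plan_validation_reports_all_failures():
    plan = ExperimentPlan(
        runs=[
            RunSpec(GeometryConfig(n_electrodes=30)),  # not divisible by rings
            RunSpec(GeometryConfig(n_electrodes=48, r_terminal=2.5e-3)),  # overlap
        ]
    )
    with pytest.raises(GeometryError) as exc:
        plan.validate()
    msg = str(exc.value)
    assert "run 0" in msg and "run 1" in msg


def test_configuration_sweep_table_and_provenance(tmp_path):
    plan = ExperimentPlan(
        runs=[RunSpec(GeometryConfig())], resolution=RES_SMALL, frequencies=(1.0e6,)
    )
    result = run_configuration_sweep(plan)
    assert len(result.table) == 1
    row = result.table.iloc[0]
    assert 0 < row["z_density_vein_pct"] < 100
    assert abs(row["z_density_vein_pct"] - row["power_loss_vein_pct"]) < 0.1
    assert row["absZ"] == pytest.approx(math.hypot(row["ReZ"], row["ImZ"]), rel=1e-12)
    for key in ("resolution", "tolerance", "material_table_sha256", "code_version"):
        assert key in result.provenance
    out = tmp_path / "sweep.csv"
    result.to_csv(out)
    assert out.exists() and out.stat().st_size > 0


def test_removing_vein_raises_conductance(vein_spectrum):
    """Replacing the vein wall by saline removes a resistive layer, so the
    measured conductance rises and the vein share drops to zero."""
    freqs, cases = vein_spectrum
    with_vein = cases[-1]  # 1 MHz case of the sweep
    assert with_vein["frequency"] == 1.0e6
    cfg = GeometryConfig()
    exc = build_vein_excitation(cfg, RES_SMALL, with_vein=False)
    sol = assemble_and_solve(exc.grid, default_material_table(), exc, 1.0e6)
    from veincuff import region_contributions, sensitivity_field

    report = region_contributions(sensitivity_field(sol))
    assert report.vein_z_pct == 0.0
    assert any("zero volume" in f for f in report.flags)
    G_without = (sol.I / exc.U).real
    G_with = (1.0 / with_vein["Z_solver"]).real
    assert G_without > G_with


def test_scan_requires_distinct_electrodes():
    cfg = GeometryConfig(n_electrodes=28, n_rings=2)
    with pytest.raises(GeometryError, match="distinct"):
        single_terminal_scan(cfg, resolution=RES_SMALL)


def test_slice_export_cartesian(slab_solution):
    spec, grid, exc, table, sol = slab_solution
    arr, meta = export_slice(sol, "potential")
    assert arr.shape == (grid.shape[1], grid.shape[2])
    assert arr.min() >= 0.0 and arr.max() <= 1.0 + 1e-12
    assert meta["units"] == "V"
    arrJ, metaJ = export_slice(sol, "J")
    assert np.all(arrJ >= 0)
    with pytest.raises(ValueError, match="quantity"):
        export_slice(sol, "S")  # field quantity requested on a raw solution
    with pytest.raises(ValueError, match="plane"):
        export_slice(sol, "potential", plane="xy")


def test_slice_export_cylindrical_current_decay():
    """In the coaxial annulus |J| falls as 1/r; the exported midplane slice
    must reproduce that profile on both sides of the axis."""
    spec = PhantomSpec(
        kind="coaxial", radius_inner=1e-3, radius_outer=2e-3, length=0.02, sigma=1.0
    )
    grid, exc, table = make_phantom(spec, resolution=(24, 16, 16))
    sol = assemble_and_solve(grid, table, exc, 0.0)
    arr, meta = export_slice(sol, "J")
    y = meta["y_m"]
    assert arr.shape == (y.size, grid.shape[2])
    k = grid.shape[2] // 2
    inside = (np.abs(y) > spec.radius_inner * 1.2) & (np.abs(y) < spec.radius_outer * 0.9)
    prod = arr[inside, k] * np.abs(y[inside])
    assert prod.std() / prod.mean() < 0.03  # |J| * r constant within 3 %


def test_solution_is_deterministic(slab_solution):
    spec, grid, exc, table, sol = slab_solution
    sol2 = assemble_and_solve(grid, table, exc, 0.0)
    assert np.array_equal(sol.V, sol2.V)  # bitwise identical re-solve
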