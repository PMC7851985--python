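"""Vein-model geometry: voxelization, electrode layout, Dirichlet masks."""

import math

import numpy as np
import pytest

from veincuff import (
    GeometryConfig,
    GeometryError,
    LayoutError,
    ResolutionError,
    build_grid,
    electrode_masks,
    place_surface_electrodes,
)


@pytest.fixture(scope="module")
def default_grid():
    return build_grid(GeometryConfig(), (32, 64, 128))


def test_vein_wall_volume_matches_hollow_cylinder(default_grid):
    # pi*(7^2 - 6.5^2)*60 mm^3
    cfg = GeometryConfig()
    analytic = (
        math.pi
        * (cfg.vein_outer_radius**2 - cfg.vein_inner_radius**2)
        * cfg.vein_length
    )
    got = default_grid.region_volume("vein_wall")
    assert got == pytest.approx(analytic, rel=0.05)
    assert analytic == pytest.approx(1272.3e-9, rel=1e-3)


def test_labels_partition_domain(default_grid):
    cfg = GeometryConfig()
    domain = math.pi * cfg.chamber_radius**2 * cfg.chamber_length
    total = sum(default_grid.region_volume(n) for n in default_grid.region_names)
    assert total == pytest.approx(domain, rel=1e-10)
    assert total == pytest.approx(default_grid.cell_volumes().sum(), rel=1e-12)


def test_region_volumes_exact_with_conforming_edges(default_grid):
    """Every interface is grid-aligned, so voxelized volumes are analytic."""
    cfg = GeometryConfig()
    g0, g1 = cfg.ground_span
    gold_analytic = math.pi * cfg.r_ground**2 * (g1 - g0)
    # only the ground wire is gold at build time (electrodes come later)
    assert default_grid.region_volume("gold_electrode") == pytest.approx(
        gold_analytic, rel=1e-9
    )
    glass_analytic = (
        math.pi
        * (cfg.tube_outer_radius**2 - cfg.tube_inner_radius**2)
        * (cfg.chamber_length - cfg.vein_length)
    )
    assert default_grid.region_volume("glass_tube") == pytest.approx(
        glass_analytic, rel=1e-9
    )


def test_thin_wall_raises_resolution_error():
    cfg = GeometryConfig(vein_wall_thickness=1e-6)
    with pytest.raises(ResolutionError, match="vein_wall"):
        build_grid(cfg, (32, 64, 128))


def test_minimum_resolution_enforced():
    with pytest.raises(ResolutionError):
        build_grid(GeometryConfig(), (4, 64, 128))


@pytest.mark.parametrize(
    "kwargs,match",
    [
        ({"r_ground": 8e-3}, "r_ground"),
        ({"n_electrodes": 30, "n_rings": 4}, "divisible"),
        ({"ground_length": 0.08}, "ground"),
        ({"r_terminal": 8e-3}, "r_terminal"),
    ],
)
def test_config_invariants(kwargs, match):
    with pytest.raises(GeometryError, match=match):
        GeometryConfig(**kwargs).validate()


def test_electrode_layout_28():
    cfg = GeometryConfig(n_electrodes=28, n_rings=4)
    fps = place_surface_electrodes(cfg)
    assert len(fps) == 28
    ring0 = [fp for fp in fps if fp.ring == 0]
    assert len(ring0) == 7
    angles = sorted(fp.theta for fp in ring0)
    assert np.allclose(np.diff(angles), 2 * math.pi / 7)
    # brute-force pairwise surface distances >= 2 mm for r_t = 1 mm
    R = cfg.vein_outer_radius
    dmin = math.inf
    for i in range(len(fps)):
        for j in range(i + 1, len(fps)):
            dth = abs(fps[i].theta - fps[j].theta)
            dth = min(dth, 2 * math.pi - dth)
            dmin = min(dmin, math.hypot(R * dth, fps[i].z - fps[j].z))
    assert dmin >= 2e-3


def test_dense_large_electrodes_overlap():
    # 12 per ring on a 44 mm circumference: pitch 3.67 mm < 2*2.5 mm
    cfg = GeometryConfig(n_electrodes=48, r_terminal=2.5e-3)
    with pytest.raises(LayoutError, match="feasible radius"):
        place_surface_electrodes(cfg)


def test_electrode_masks_simultaneous(default_grid):
    cfg = GeometryConfig()
    fps = place_surface_electrodes(cfg)
    exc = electrode_masks(default_grid, cfg, fps, mode="simultaneous")
    assert len(exc.terminal_masks) == 28
    assert exc.inactive == ()
    assert exc.ground_mask.any()
    # pairwise disjoint and disjoint from ground
    union = np.zeros(exc.grid.shape, dtype=int)
    for m in exc.terminal_masks.values():
        assert m.any()
        union += m
    assert union.max() == 1
    assert not (union.astype(bool) & exc.ground_mask).any()
    # Dirichlet values: terminals at 1 V, ground at 0 V
    fixed, values = exc.fixed_and_values()
    assert np.all(values[union.astype(bool).ravel()] == 1.0)
    assert np.all(values[exc.ground_mask.ravel()] == 0.0)
    assert fixed.sum() == union.sum() + exc.ground_mask.sum()


def test_electrode_masks_single(default_grid):
    cfg = GeometryConfig()
    fps = place_surface_electrodes(cfg)
    exc = electrode_masks(default_grid, cfg, fps, mode=("single", 13))
    assert set(exc.terminal_masks) == {13}
    assert len(exc.inactive) == 27
    # inactive electrodes are electrically absent: their cells stay quartz
    quartz = exc.grid.region_id("quartz_substrate")
    gold = exc.grid.region_id("gold_electrode")
    active_cells = exc.terminal_masks[13]
    assert np.all(exc.grid.labels[active_cells] == gold)
    exc_float = electrode_masks(default_grid, cfg, fps, mode=("single", 13), inactive="floating")
    n_gold_absent = (exc.grid.labels == gold).sum()
    n_gold_float = (exc_float.grid.labels == gold).sum()
    assert n_gold_float > n_gold_absent  # floating bodies stay gold


def test_footprint_areas_close_to_disk(default_grid):
    cfg = GeometryConfig()
    fps = place_surface_electrodes(cfg)
    exc = electrode_masks(default_grid, cfg, fps, mode="simultaneous")
    R = cfg.vein_outer_radius
    e1, e2 = exc.grid.edges[1], exc.grid.edges[2]
    disk = math.pi * cfg.r_terminal**2
    for m in exc.terminal_masks.values():
        i, j, k = np.nonzero(m)
        area = float(np.sum(R * np.diff(e1)[j] * np.diff(e2)[k]))
        assert area == pytest.approx(disk, rel=0.10)


def test_footprint_area_error_shrinks_with_resolution():
    cfg = GeometryConfig()
    fps = place_surface_electrodes(cfg)
    disk = math.pi * cfg.r_terminal**2
    errs = []
    for res in [(16, 64, 128), (16, 128, 256), (16, 256, 512)]:
        grid = build_grid(cfg, res)
        exc = electrode_masks(grid, cfg, fps, mode="simultaneous")
        R = cfg.vein_outer_radius
        e1, e2 = exc.grid.edges[1], exc.grid.edges[2]
        rel = []
        for m in exc.terminal_masks.values():
            i, j, k = np.nonzero(m)
            area = float(np.sum(R * np.diff(e1)[j] * np.diff(e2)[k]))
            rel.append(abs(area - disk) / disk)
        errs.append(np.mean(rel))
    assert errs[-1] < errs[0]
    assert errs[-1] < 0.02


def test_tiny_footprint_raises_resolution_error(default_grid):
    cfg = GeometryConfig(r_terminal=0.2e-3)
    fps = place_surface_electrodes(cfg)
    with pytest.raises(ResolutionError, match="pitch"):
        electrode_masks(default_grid, cfg, fps, mode="simultaneous")
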