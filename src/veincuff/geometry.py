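"""Parametric geometry of the saline-perfused vein with a cuff electrode.

The model is a cylindrical chamber (PMMA) filled with saline, two glass
tubes entering through the end walls, a venous segment mounted between the
tubes, a quartz cuff substrate wrapped around the vein carrying gold surface
electrodes on its inner face, and a gold ground wire running along the axis
through tubes and vein.

The domain is voxelized on a cylindrical structured grid whose radial and
axial cell boundaries are aligned with the material interfaces, so thin
layers (vein wall, cuff substrate) are resolved exactly in the radial
direction and every region's voxelized volume converges rapidly to the
analytic one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .grid import GridError, LabeledGrid
from .materials import REGION_NAMES


class GeometryError(ValueError):
    """Invalid geometry configuration."""


class LayoutError(GeometryError):
    """Electrode footprints cannot be placed without overlap."""


class ResolutionError(GridError):
    """The requested grid cannot resolve a geometric feature."""


#: Maximum local refinement of the radial/axial grid relative to the uniform
#: spacing; a layer thinner than 2 * (extent/n)/GRADING_CAP cannot be resolved
#: without excessively graded cells and raises ResolutionError instead.
GRADING_CAP = 20.0


@dataclass(frozen=True)
class GeometryConfig:
    """Dimensions (meters) and electrode layout of the vein model.

    Defaults give the study geometry: a 6 cm long, 1.4 cm diameter venous
    segment, 28 surface electrodes of radius 1 mm in 4 rings, and a 0.5 mm
    radius axial ground wire running the full length of the chamber.
    """

    vein_length: float = 0.06
    vein_outer_diameter: float = 0.014
    vein_wall_thickness: float = 5.0e-4
    cuff_substrate_thickness: float = 5.0e-4
    chamber_radius: float = 0.025
    chamber_length: float = 0.12
    chamber_wall_thickness: float = 2.0e-3
    tube_inner_radius: float = 0.007
    tube_wall_thickness: float = 1.0e-3
    n_electrodes: int = 28
    n_rings: int = 4
    r_terminal: float = 1.0e-3
    r_ground: float = 0.5e-3
    ground_length: float = 0.12

    # ------------------------------------------------------------- derived
    @property
    def vein_outer_radius(self) -> float:
        return 0.5 * self.vein_outer_diameter

    @property
    def vein_inner_radius(self) -> float:
        return self.vein_outer_radius - self.vein_wall_thickness

    @property
    def substrate_outer_radius(self) -> float:
        return self.vein_outer_radius + self.cuff_substrate_thickness

    @property
    def tube_outer_radius(self) -> float:
        return self.tube_inner_radius + self.tube_wall_thickness

    @property
    def vein_span(self) -> tuple[float, float]:
        zc = 0.5 * self.chamber_length
        return (zc - 0.5 * self.vein_length, zc + 0.5 * self.vein_length)

    @property
    def ground_span(self) -> tuple[float, float]:
        zc = 0.5 * self.chamber_length
        lo = max(0.0, zc - 0.5 * self.ground_length)
        hi = min(self.chamber_length, zc + 0.5 * self.ground_length)
        return (lo, hi)

    def validate(self) -> None:
        errors: list[str] = []
        if self.vein_wall_thickness <= 0 or self.vein_inner_radius <= 0:
            errors.append("vein wall thickness must be positive and thinner than the radius")
        if self.r_ground >= self.vein_inner_radius:
            errors.append(
                f"r_ground={self.r_ground} must be smaller than the vein inner "
                f"radius {self.vein_inner_radius}"
            )
        if self.n_rings < 1 or self.n_electrodes < 1:
            errors.append("n_electrodes and n_rings must be positive")
        elif self.n_electrodes % self.n_rings != 0:
            errors.append(
                f"n_electrodes={self.n_electrodes} not divisible by n_rings={self.n_rings}"
            )
        if self.n_rings >= 1 and self.r_terminal >= self.vein_length / (2 * self.n_rings):
            errors.append(
                f"r_terminal={self.r_terminal} must be < vein_length/(2*n_rings)="
                f"{self.vein_length / (2 * self.n_rings)}"
            )
        if self.vein_length > self.chamber_length:
            errors.append("vein longer than chamber")
        # cuff wraps the vein only (substrate axial extent == vein extent here)
        if self.cuff_substrate_thickness <= 0:
            errors.append("cuff substrate thickness must be positive")
        if self.ground_length < self.chamber_length:
            errors.append(
                "ground wire must run the full chamber length (through both "
                f"glass tubes): ground_length={self.ground_length} < "
                f"chamber_length={self.chamber_length}"
            )
        v0, v1 = self.vein_span
        g0, g1 = self.ground_span
        if not (g0 < v0 and g1 > v1):
            errors.append("ground electrode must strictly contain the vein axially")
        if abs(self.tube_inner_radius - self.vein_outer_radius) > 1e-9:
            errors.append(
                "glass tube inner radius must match the vein outer radius "
                "(the vein is mounted between the tubes)"
            )
        if self.chamber_radius - self.chamber_wall_thickness <= self.tube_outer_radius:
            errors.append("chamber too small for the tube construct")
        if errors:
            raise GeometryError("; ".join(errors))


# --------------------------------------------------------------------------
# grid construction
# --------------------------------------------------------------------------

def _subdivide(breakpoints: Sequence[float], n: int, layer_names: Sequence[str]) -> np.ndarray:
    """Distribute ``n`` cells over the intervals between ``breakpoints``.

    Every interval receives at least 2 cells; the remainder is apportioned
    proportionally to interval width (largest-remainder rule, deterministic).
    An interval so thin that resolving it would exceed the grading cap
    relative to uniform spacing raises ResolutionError naming the layer.
    """
    bp = np.asarray(breakpoints, dtype=float)
    widths = np.diff(bp)
    m = widths.size
    if np.any(widths <= 0):
        raise GeometryError("breakpoints must be strictly increasing")
    total = bp[-1] - bp[0]
    uniform = total / n
    for w, name in zip(widths, layer_names):
        if 0.5 * w < uniform / GRADING_CAP:
            raise ResolutionError(
                f"layer {name!r} (thickness {w:.3g} m) cannot be resolved with 2 "
                f"cells at this resolution (uniform spacing {uniform:.3g} m, "
                f"grading cap {GRADING_CAP:g}); increase the resolution"
            )
    if n < 2 * m:
        raise ResolutionError(
            f"need at least {2 * m} cells to give every layer 2 cells, got {n}"
        )
    counts = np.full(m, 2, dtype=int)
    spare = n - 2 * m
    quota = widths / total * spare
    counts += quota.astype(int)
    frac = quota - quota.astype(int)
    left = n - counts.sum()
    for i in np.argsort(-frac, kind="stable")[:left]:
        counts[i] += 1
    edges = [bp[0]]
    for lo, hi, c in zip(bp[:-1], bp[1:], counts):
        edges.extend(np.linspace(lo, hi, c + 1)[1:])
    return np.asarray(edges)


def build_grid(cfg: GeometryConfig, resolution: tuple[int, int, int] = (32, 64, 128)) -> LabeledGrid:
    """Voxelize the vein model into a region-labeled cylindrical grid.

    ``resolution`` is (n_r, n_theta, n_z).  Radial and axial cell boundaries
    conform to the material interfaces; the vein wall is guaranteed at least
    two radial cells (ResolutionError otherwise).  Labels are assigned by
    cell-center membership with priority electrode > substrate > vein >
    glass > saline > chamber (the ground wire is labeled gold at build time;
    surface-electrode cells are labeled by :func:`electrode_masks`).
    """
    cfg.validate()
    n_r, n_th, n_z = resolution
    if min(resolution) < 8:
        raise ResolutionError(f"resolution components must be >= 8, got {resolution}")

    radial_bp = [
        (0.0, "axis"),
        (cfg.r_ground, "ground_wire"),
        (cfg.vein_inner_radius, "lumen"),
        (cfg.vein_outer_radius, "vein_wall"),
        (cfg.substrate_outer_radius, "cuff_substrate"),
        (cfg.tube_outer_radius, "tube_wall"),
        (cfg.chamber_radius - cfg.chamber_wall_thickness, "saline_bulk"),
        (cfg.chamber_radius, "chamber_wall"),
    ]
    radial_bp.sort(key=lambda t: t[0])
    rvals = [t[0] for t in radial_bp]
    if len(set(rvals)) != len(rvals):
        raise GeometryError("coincident radial interfaces; adjust dimensions")
    r_edges = _subdivide(rvals, n_r, [t[1] for t in radial_bp[1:]])

    v0, v1 = cfg.vein_span
    z_bp = sorted({0.0, v0, v1, cfg.chamber_length})
    z_names = ["tube_inlet", "vein_section", "tube_outlet"][: len(z_bp) - 1]
    z_edges = _subdivide(z_bp, n_z, z_names)

    th_edges = np.linspace(0.0, 2.0 * math.pi, n_th + 1)

    rc = 0.5 * (r_edges[:-1] + r_edges[1:])
    zc = 0.5 * (z_edges[:-1] + z_edges[1:])

    names = REGION_NAMES
    rid = {n: i for i, n in enumerate(names)}
    labels = np.full((n_r, n_th, n_z), rid["saline"], dtype=np.int16)

    in_vein_z = (zc > v0) & (zc < v1)
    in_tube_z = ~in_vein_z

    # chamber wall (lowest priority after saline default)
    labels[rc > cfg.chamber_radius - cfg.chamber_wall_thickness, :, :] = rid["pmma_chamber"]
    # glass tubes outside the vein section
    glass_r = (rc > cfg.tube_inner_radius) & (rc < cfg.tube_outer_radius)
    labels[np.ix_(glass_r, np.ones(n_th, bool), in_tube_z)] = rid["glass_tube"]
    # vein wall
    wall_r = (rc > cfg.vein_inner_radius) & (rc < cfg.vein_outer_radius)
    labels[np.ix_(wall_r, np.ones(n_th, bool), in_vein_z)] = rid["vein_wall"]
    # cuff substrate
    sub_r = (rc > cfg.vein_outer_radius) & (rc < cfg.substrate_outer_radius)
    labels[np.ix_(sub_r, np.ones(n_th, bool), in_vein_z)] = rid["quartz_substrate"]
    # ground wire (gold) along the axis
    g0, g1 = cfg.ground_span
    in_ground_z = (zc > g0 - 1e-15) & (zc < g1 + 1e-15)
    labels[np.ix_(rc < cfg.r_ground, np.ones(n_th, bool), in_ground_z)] = rid["gold_electrode"]

    grid = LabeledGrid(
        metric="cylindrical",
        edges=(r_edges, th_edges, z_edges),
        labels=labels,
        region_names=names,
    )

    wall_cells = np.count_nonzero(wall_r)
    if wall_cells < 2:
        raise ResolutionError(
            f"vein wall resolved by only {wall_cells} radial cell(s); "
            "increase n_r"
        )
    return grid


# --------------------------------------------------------------------------
# electrodes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ElectrodeFootprint:
    """Circular electrode footprint on the vein outer surface."""

    theta: float  # center angle, rad
    z: float  # center axial position, m
    radius: float  # footprint radius, m
    ring: int  # ring index (0 = nearest z=0, the ground-wire output end)
    index: int  # global electrode index


def place_surface_electrodes(cfg: GeometryConfig) -> list[ElectrodeFootprint]:
    """Arrange the surface electrodes on equispaced rings around the vein.

    ``n_rings`` equispaced axial rings centered on the vein, each carrying
    ``n_electrodes / n_rings`` electrodes equispaced in angle (all rings
    aligned in angle).  Raises LayoutError if footprints would overlap on the
    cylinder surface, reporting the largest feasible radius.
    """
    cfg.validate()
    per_ring = cfg.n_electrodes // cfg.n_rings
    R = cfg.vein_outer_radius
    zc = 0.5 * cfg.chamber_length
    pitch = cfg.vein_length / cfg.n_rings
    footprints: list[ElectrodeFootprint] = []
    k = 0
    for ring in range(cfg.n_rings):
        z = zc + (ring - (cfg.n_rings - 1) / 2.0) * pitch
        for m in range(per_ring):
            theta = 2.0 * math.pi * m / per_ring
            footprints.append(
                ElectrodeFootprint(theta=theta, z=z, radius=cfg.r_terminal, ring=ring, index=k)
            )
            k += 1

    # brute-force pairwise overlap check on the unrolled cylinder surface
    min_dist = math.inf
    for i in range(len(footprints)):
        for j in range(i + 1, len(footprints)):
            a, b = footprints[i], footprints[j]
            dth = abs(a.theta - b.theta)
            dth = min(dth, 2.0 * math.pi - dth)
            d = math.hypot(R * dth, a.z - b.z)
            min_dist = min(min_dist, d)
    if footprints and len(footprints) > 1 and min_dist < 2.0 * cfg.r_terminal:
        raise LayoutError(
            f"electrode footprints overlap: minimum center distance "
            f"{min_dist * 1e3:.3f} mm < 2*r_terminal = {2e3 * cfg.r_terminal:.3f} mm; "
            f"largest feasible radius is {0.5e3 * min_dist:.3f} mm"
        )
    return footprints


@dataclass
class Excitation:
    """Dirichlet masks of one excitation: driven terminals at U volts, ground at 0."""

    grid: LabeledGrid
    terminal_masks: dict[int, np.ndarray]
    ground_mask: np.ndarray
    inactive: tuple[int, ...] = ()
    U: float = 1.0
    mode: str = "simultaneous"

    def fixed_and_values(self) -> tuple[np.ndarray, np.ndarray]:
        """Flat boolean fixed-cell mask and flat complex potential values."""
        shape = self.grid.shape
        fixed = np.zeros(shape, dtype=bool)
        values = np.zeros(shape, dtype=complex)
        for m in self.terminal_masks.values():
            fixed |= m
            values[m] = self.U
        overlap = fixed & self.ground_mask
        if overlap.any():
            raise GeometryError("terminal and ground masks overlap")
        fixed |= self.ground_mask
        return fixed.ravel(), values.ravel()

    @property
    def terminal_union(self) -> np.ndarray:
        out = np.zeros(self.grid.shape, dtype=bool)
        for m in self.terminal_masks.values():
            out |= m
        return out


def _snap(value: float, centers: np.ndarray) -> float:
    return float(centers[np.argmin(np.abs(centers - value))])


def electrode_masks(
    grid: LabeledGrid,
    cfg: GeometryConfig,
    footprints: Sequence[ElectrodeFootprint],
    mode: str | tuple[str, int] = "simultaneous",
    inactive: str = "substrate",
) -> Excitation:
    """Voxelize electrode footprints into Dirichlet masks for one excitation.

    ``mode`` is ``"simultaneous"`` (all footprints driven at 1 V) or
    ``("single", k)`` (footprint ``k`` driven, the rest inactive).  Inactive
    electrodes are either electrically absent (``inactive="substrate"``, the
    default) or left as floating gold bodies (``inactive="floating"``).

    Footprint centers are snapped to the nearest cell center in (theta, z)
    so that voxelized footprints are congruent across rings; cells of the
    innermost substrate layer whose centers lie within the footprint radius
    (surface arc metric) form the mask.  A footprint finer than the grid
    raises ResolutionError.

    Returns a fresh Excitation whose grid copy has active (and floating)
    electrode cells relabeled gold.
    """
    if mode == "simultaneous":
        active = set(range(len(footprints)))
        mode_name = "simultaneous"
    elif isinstance(mode, tuple) and len(mode) == 2 and mode[0] == "single":
        k = int(mode[1])
        if not (0 <= k < len(footprints)):
            raise GeometryError(f"single-terminal index {k} out of range")
        active = {k}
        mode_name = f"single({k})"
    else:
        raise GeometryError(f"unknown excitation mode {mode!r}")
    if inactive not in ("substrate", "floating"):
        raise GeometryError(f"unknown inactive-electrode policy {inactive!r}")

    g = grid.copy()
    rc, thc, zc = g.centers
    R = cfg.vein_outer_radius
    gold = g.region_id("gold_electrode")
    quartz = g.region_id("quartz_substrate")

    # innermost radial cell layer inside the substrate band
    sub_layers = np.nonzero(
        (rc > cfg.vein_outer_radius) & (rc < cfg.substrate_outer_radius)
    )[0]
    if sub_layers.size == 0:
        raise ResolutionError("no radial cell layer inside the cuff substrate")
    i_surf = int(sub_layers[0])

    # a footprint narrower than the surface cell pitch cannot be voxelized
    dz_vein = np.diff(g.edges[2])
    v0, v1 = cfg.vein_span
    in_vein = (zc > v0) & (zc < v1)
    pitch = max(float(dz_vein[in_vein].max()), float(R * np.diff(g.edges[1]).max()))
    if footprints and footprints[0].radius < 0.5 * pitch:
        raise ResolutionError(
            f"electrode footprint radius {footprints[0].radius:.3g} m is finer "
            f"than the surface cell pitch {pitch:.3g} m; increase the "
            "angular/axial resolution"
        )

    masks: dict[int, np.ndarray] = {}
    union = np.zeros(g.shape, dtype=bool)
    for fp in footprints:
        th0 = _snap(fp.theta if fp.theta < 2 * math.pi else 0.0, thc)
        z0 = _snap(fp.z, zc)
        dth = np.abs(thc - th0)
        dth = np.minimum(dth, 2.0 * math.pi - dth)
        dist2 = (R * dth[:, None]) ** 2 + (zc[None, :] - z0) ** 2
        sel = dist2 <= fp.radius**2
        if not sel.any():
            raise ResolutionError(
                f"electrode footprint {fp.index} (radius {fp.radius:.3g} m) is "
                "finer than the grid; increase the angular/axial resolution"
            )
        m = np.zeros(g.shape, dtype=bool)
        m[i_surf, :, :] = sel
        if (m & union).any():
            raise LayoutError(
                f"voxelized footprint {fp.index} overlaps another electrode"
            )
        if fp.index in active:
            union |= m
            masks[fp.index] = m
            g.labels[m] = gold
        else:
            if inactive == "floating":
                g.labels[m] = gold
            # "substrate": leave the cells as quartz (electrically absent)

    ground_mask = np.zeros(g.shape, dtype=bool)
    g0, g1 = cfg.ground_span
    in_ground_z = (zc > g0 - 1e-15) & (zc < g1 + 1e-15)
    ground_mask[np.ix_(rc < cfg.r_ground, np.ones(g.shape[1], bool), in_ground_z)] = True
    if not ground_mask.any():
        raise ResolutionError("ground wire not resolved by the radial grid")

    return Excitation(
        grid=g,
        terminal_masks=masks,
        ground_mask=ground_mask,
        inactive=tuple(sorted(set(range(len(footprints))) - active)),
        U=1.0,
        mode=mode_name,
    )
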