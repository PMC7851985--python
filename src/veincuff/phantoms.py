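"""Analytic phantoms with closed-form impedances for solver validation.

Each phantom builds a labeled grid, Dirichlet masks and a material table
directly consumable by the field solver, plus a closed-form complex
impedance (single parallel-RC form per region):

* ``slab``: a rectangular bar of one material between full-face electrodes,
  Z = L / (sigma* A);
* ``series_bilayer``: two materials stacked along z, Z = sum of layer slabs,
  with closed-form region contributions (series-resistor ratios);
* ``coaxial``: saline annulus between an inner wire (radius a) and an outer
  shell (radius b), Z = ln(b/a) / (2 pi sigma* L);
* ``homogeneous_cylinder``: full cylinder between end-face electrodes,
  Z = L / (sigma* pi R^2).

Electrode bodies are one cell layer of gold held at fixed potential; gold's
conductivity makes their internal drop negligible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import Excitation
from .grid import LabeledGrid
from .materials import (
    EPS0,
    MaterialSpec,
    MaterialTable,
    admittivity,
    uniform_table,
)


class PhantomError(ValueError):
    pass


@dataclass(frozen=True)
class PhantomSpec:
    """Specification of one analytic phantom.

    ``kind`` selects the geometry; the relevant dimensions (meters) and
    per-region properties are taken from the fields below.
    """

    kind: str  # slab | series_bilayer | coaxial | homogeneous_cylinder
    length: float = 0.01  # axial length of the conducting body, m
    area: float = 1.0e-4  # cross-section of slab phantoms, m^2
    radius_inner: float = 1.0e-3  # coaxial inner radius a, m
    radius_outer: float = 2.0e-3  # coaxial outer radius b / cylinder R, m
    sigma: float = 1.0
    eps_r: float = 1.0
    sigma2: float = 2.0  # second layer of the bilayer
    eps_r2: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("slab", "series_bilayer", "coaxial", "homogeneous_cylinder"):
            raise PhantomError(f"unknown phantom kind {self.kind!r}")
        if self.length <= 0:
            raise PhantomError("length must be positive")
        if self.kind == "coaxial" and not (0 < self.radius_inner <= self.radius_outer):
            raise PhantomError("coaxial phantom needs 0 < a <= b")


def _bilayer_table(spec: PhantomSpec) -> MaterialTable:
    t = uniform_table(spec.sigma, spec.eps_r)
    return t.replace(
        vein_wall=MaterialSpec("vein_wall", sigma=spec.sigma2, eps_r=spec.eps_r2)
    )


def make_phantom(
    spec: PhantomSpec, resolution: tuple[int, int, int] = (16, 16, 32)
) -> tuple[LabeledGrid, Excitation, MaterialTable]:
    """Build grid, excitation masks and materials for a phantom.

    ``resolution`` counts cells of the conducting body; electrode layers are
    added on top of it.  Deterministic for fixed inputs.
    """
    n0, n1, n2 = resolution
    if min(resolution) < 2:
        raise PhantomError("resolution components must be >= 2")

    if spec.kind in ("slab", "series_bilayer"):
        side = math.sqrt(spec.area)
        dz = spec.length / n2
        x = np.linspace(0.0, side, n0 + 1)
        y = np.linspace(0.0, side, n1 + 1)
        z = np.concatenate([[-dz], np.linspace(0.0, spec.length, n2 + 1), [spec.length + dz]])
        labels = np.zeros((n0, n1, n2 + 2), dtype=np.int16)
        grid = LabeledGrid(metric="cartesian", edges=(x, y, z), labels=labels)
        gold = grid.region_id("gold_electrode")
        labels[:, :, 0] = gold
        labels[:, :, -1] = gold
        if spec.kind == "series_bilayer":
            zc = 0.5 * (z[:-1] + z[1:])
            second = (zc > 0.5 * spec.length) & (zc < spec.length)
            labels[:, :, second] = grid.region_id("vein_wall")
            table = _bilayer_table(spec)
        else:
            table = uniform_table(spec.sigma, spec.eps_r)
        ground = np.zeros_like(labels, dtype=bool)
        term = np.zeros_like(labels, dtype=bool)
        ground[:, :, 0] = True
        term[:, :, -1] = True
    elif spec.kind == "coaxial":
        a, b = spec.radius_inner, spec.radius_outer
        if a == b:
            raise PhantomError("degenerate coaxial annulus (a == b) has Z = 0")
        dr = (b - a) / n0
        r = np.concatenate(
            [np.linspace(0.0, a, 3), np.linspace(a, b, n0 + 1)[1:], [b + dr, b + 2 * dr]]
        )
        th = np.linspace(0.0, 2.0 * math.pi, n1 + 1)
        z = np.linspace(0.0, spec.length, n2 + 1)
        nr = r.size - 1
        labels = np.zeros((nr, n1, n2), dtype=np.int16)
        grid = LabeledGrid(metric="cylindrical", edges=(r, th, z), labels=labels)
        gold = grid.region_id("gold_electrode")
        rc = grid.centers[0]
        labels[rc < a] = gold
        labels[rc > b] = gold
        table = uniform_table(spec.sigma, spec.eps_r)
        term = np.zeros_like(labels, dtype=bool)
        ground = np.zeros_like(labels, dtype=bool)
        term[rc < a] = True  # inner wire driven at 1 V
        ground[rc > b] = True
    else:  # homogeneous_cylinder
        R = spec.radius_outer
        dz = spec.length / n2
        r = np.linspace(0.0, R, n0 + 1)
        th = np.linspace(0.0, 2.0 * math.pi, n1 + 1)
        z = np.concatenate([[-dz], np.linspace(0.0, spec.length, n2 + 1), [spec.length + dz]])
        labels = np.zeros((n0, n1, n2 + 2), dtype=np.int16)
        grid = LabeledGrid(metric="cylindrical", edges=(r, th, z), labels=labels)
        gold = grid.region_id("gold_electrode")
        labels[:, :, 0] = gold
        labels[:, :, -1] = gold
        table = uniform_table(spec.sigma, spec.eps_r)
        term = np.zeros_like(labels, dtype=bool)
        ground = np.zeros_like(labels, dtype=bool)
        term[:, :, -1] = True
        ground[:, :, 0] = True

    exc = Excitation(
        grid=grid,
        terminal_masks={0: term},
        ground_mask=ground,
        U=1.0,
        mode="phantom",
    )
    return grid, exc, table


def analytic_impedance(spec: PhantomSpec, f: float = 0.0) -> complex:
    """Closed-form complex impedance of a phantom at frequency ``f`` (Hz)."""
    s1 = complex(spec.sigma, 2.0 * math.pi * f * EPS0 * spec.eps_r)
    if spec.kind == "slab":
        return spec.length / (s1 * spec.area)
    if spec.kind == "series_bilayer":
        s2 = complex(spec.sigma2, 2.0 * math.pi * f * EPS0 * spec.eps_r2)
        half = 0.5 * spec.length
        return half / (s1 * spec.area) + half / (s2 * spec.area)
    if spec.kind == "coaxial":
        if spec.radius_inner == spec.radius_outer:
            return 0.0 + 0.0j
        return math.log(spec.radius_outer / spec.radius_inner) / (
            2.0 * math.pi * s1 * spec.length
        )
    if spec.kind == "homogeneous_cylinder":
        return spec.length / (s1 * math.pi * spec.radius_outer**2)
    raise PhantomError(f"no closed form for phantom kind {spec.kind!r}")


def analytic_contributions(spec: PhantomSpec, f: float = 0.0) -> dict[str, float]:
    """Closed-form region contribution percentages (series-resistor ratios)."""
    if spec.kind != "series_bilayer":
        raise PhantomError("closed-form contributions exist only for series_bilayer")
    s1 = complex(spec.sigma, 2.0 * math.pi * f * EPS0 * spec.eps_r)
    s2 = complex(spec.sigma2, 2.0 * math.pi * f * EPS0 * spec.eps_r2)
    r1 = (0.5 * spec.length / (s1 * spec.area)).real
    r2 = (0.5 * spec.length / (s2 * spec.area)).real
    tot = r1 + r2
    return {"saline": 100.0 * r1 / tot, "vein_wall": 100.0 * r2 / tot}
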