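"""Region-labeled structured grids (cylindrical or Cartesian).

The solver is metric-agnostic: a grid exposes cell volumes and, per axis,
the face areas and the center-to-face half-distances needed to form
two-point flux conductances.  Cylindrical grids are (r, theta, z) with theta
periodic; Cartesian grids are (x, y, z).  Cell boundaries along the first
(radial) axis of a cylindrical grid may be non-uniform so that material
interfaces coincide with cell faces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .materials import REGION_NAMES


class GridError(ValueError):
    """Inconsistent grid construction or lookup."""


@dataclass
class FaceGeometry:
    """Two-point flux geometry for all faces along one axis.

    ``lo``/``hi`` are flat cell indices on either side of each face; ``area``
    the face area; ``d_lo``/``d_hi`` the distances from the adjacent cell
    centers to the face (along the flux path).
    """

    lo: np.ndarray
    hi: np.ndarray
    area: np.ndarray
    d_lo: np.ndarray
    d_hi: np.ndarray


@dataclass
class LabeledGrid:
    """Structured grid with one region label per cell and Dirichlet masks.

    Attributes
    ----------
    metric : {"cylindrical", "cartesian"}
    edges : tuple of 3 arrays
        Cell boundary coordinates per axis (lengths n+1).  For cylindrical
        grids the axes are (r, theta, z); theta edges must span [0, 2*pi].
    labels : int array, shape (n0, n1, n2)
        Index into ``region_names`` per cell.
    region_names : tuple of str
    """

    metric: str
    edges: tuple[np.ndarray, np.ndarray, np.ndarray]
    labels: np.ndarray
    region_names: tuple[str, ...] = REGION_NAMES

    def __post_init__(self) -> None:
        if self.metric not in ("cylindrical", "cartesian"):
            raise GridError(f"unknown metric {self.metric!r}")
        self.edges = tuple(np.asarray(e, dtype=float) for e in self.edges)
        for e in self.edges:
            if e.ndim != 1 or e.size < 2 or np.any(np.diff(e) <= 0):
                raise GridError("edges must be strictly increasing 1D arrays")
        if self.labels.shape != self.shape:
            raise GridError(
                f"labels shape {self.labels.shape} does not match grid {self.shape}"
            )
        if self.metric == "cylindrical":
            th = self.edges[1]
            if not (abs(th[0]) < 1e-12 and abs(th[-1] - 2 * np.pi) < 1e-9):
                raise GridError("cylindrical theta edges must span [0, 2*pi]")
            if self.edges[0][0] < 0:
                raise GridError("radial edges must be non-negative")

    # ------------------------------------------------------------------ basic
    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(e.size - 1 for e in self.edges)

    @property
    def n_cells(self) -> int:
        n0, n1, n2 = self.shape
        return n0 * n1 * n2

    @property
    def periodic(self) -> tuple[bool, bool, bool]:
        return (False, self.metric == "cylindrical", False)

    @property
    def centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(0.5 * (e[:-1] + e[1:]) for e in self.edges)

    @property
    def widths(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(np.diff(e) for e in self.edges)

    def cell_volumes(self) -> np.ndarray:
        """Cell volumes, shape (n0, n1, n2)."""
        e0, e1, e2 = self.edges
        d1 = np.diff(e1)
        d2 = np.diff(e2)
        if self.metric == "cylindrical":
            radial = 0.5 * (e0[1:] ** 2 - e0[:-1] ** 2)
        else:
            radial = np.diff(e0)
        return radial[:, None, None] * d1[None, :, None] * d2[None, None, :]

    def flat_index(self) -> np.ndarray:
        return np.arange(self.n_cells).reshape(self.shape)

    def region_id(self, name: str) -> int:
        try:
            return self.region_names.index(name)
        except ValueError:
            raise GridError(f"unknown region {name!r}") from None

    def region_mask(self, name: str) -> np.ndarray:
        return self.labels == self.region_id(name)

    def region_volume(self, name: str) -> float:
        return float(self.cell_volumes()[self.region_mask(name)].sum())

    def copy(self) -> "LabeledGrid":
        return LabeledGrid(
            metric=self.metric,
            edges=tuple(e.copy() for e in self.edges),
            labels=self.labels.copy(),
            region_names=self.region_names,
        )

    # ------------------------------------------------------------------ faces
    def face_geometry(self) -> Iterator[FaceGeometry]:
        """Yield the face geometry of each axis (wrap face included for theta)."""
        n0, n1, n2 = self.shape
        idx = self.flat_index()
        e0, e1, e2 = self.edges
        c0, c1, c2 = self.centers
        d1 = np.diff(e1)
        d2 = np.diff(e2)
        cyl = self.metric == "cylindrical"

        # --- axis 0 (r or x): faces between i and i+1
        if n0 > 1:
            if cyl:
                area = (
                    e0[1:-1][:, None, None]
                    * d1[None, :, None]
                    * d2[None, None, :]
                )
            else:
                area = np.broadcast_to(
                    d1[None, :, None] * d2[None, None, :], (n0 - 1, n1, n2)
                )
            dlo = (e0[1:-1] - c0[:-1])[:, None, None]
            dhi = (c0[1:] - e0[1:-1])[:, None, None]
            yield FaceGeometry(
                lo=idx[:-1].ravel(),
                hi=idx[1:].ravel(),
                area=np.ascontiguousarray(area).ravel(),
                d_lo=np.broadcast_to(dlo, (n0 - 1, n1, n2)).ravel(),
                d_hi=np.broadcast_to(dhi, (n0 - 1, n1, n2)).ravel(),
            )

        # --- axis 1 (theta or y)
        if n1 > 1 or (cyl and n1 == 1):
            if cyl:
                dr = np.diff(e0)
                area = dr[:, None, None] * d2[None, None, :]  # (n0, 1, n2)
                # arc half-lengths use each cell's own center radius
                arc = c0[:, None, None]
                if n1 > 1:
                    lo = idx[:, :-1].ravel()
                    hi = idx[:, 1:].ravel()
                    a = np.broadcast_to(area, (n0, n1 - 1, n2)).ravel()
                    dlo = np.broadcast_to(
                        arc * (0.5 * d1[None, :-1, None]), (n0, n1 - 1, n2)
                    ).ravel()
                    dhi = np.broadcast_to(
                        arc * (0.5 * d1[None, 1:, None]), (n0, n1 - 1, n2)
                    ).ravel()
                    # wrap face between last and first theta cell
                    lo = np.concatenate([lo, idx[:, -1].ravel()])
                    hi = np.concatenate([hi, idx[:, 0].ravel()])
                    a = np.concatenate(
                        [a, np.broadcast_to(area, (n0, 1, n2)).ravel()]
                    )
                    dlo = np.concatenate(
                        [
                            dlo,
                            np.broadcast_to(
                                arc * (0.5 * d1[None, -1:, None]), (n0, 1, n2)
                            ).ravel(),
                        ]
                    )
                    dhi = np.concatenate(
                        [
                            dhi,
                            np.broadcast_to(
                                arc * (0.5 * d1[None, :1, None]), (n0, 1, n2)
                            ).ravel(),
                        ]
                    )
                    yield FaceGeometry(lo=lo, hi=hi, area=a, d_lo=dlo, d_hi=dhi)
            else:
                if n1 > 1:
                    dr = np.diff(e0)
                    area = np.broadcast_to(
                        dr[:, None, None] * d2[None, None, :], (n0, n1 - 1, n2)
                    )
                    dlo = np.broadcast_to(
                        0.5 * d1[None, :-1, None], (n0, n1 - 1, n2)
                    )
                    dhi = np.broadcast_to(
                        0.5 * d1[None, 1:, None], (n0, n1 - 1, n2)
                    )
                    yield FaceGeometry(
                        lo=idx[:, :-1].ravel(),
                        hi=idx[:, 1:].ravel(),
                        area=np.ascontiguousarray(area).ravel(),
                        d_lo=np.ascontiguousarray(dlo).ravel(),
                        d_hi=np.ascontiguousarray(dhi).ravel(),
                    )

        # --- axis 2 (z)
        if n2 > 1:
            if cyl:
                radial = 0.5 * (e0[1:] ** 2 - e0[:-1] ** 2)
                area = radial[:, None, None] * d1[None, :, None]  # (n0, n1, 1)
            else:
                dr = np.diff(e0)
                area = dr[:, None, None] * d1[None, :, None]
            a = np.broadcast_to(area, (n0, n1, n2 - 1)).ravel()
            dlo = np.broadcast_to(
                0.5 * d2[None, None, :-1], (n0, n1, n2 - 1)
            ).ravel()
            dhi = np.broadcast_to(
                0.5 * d2[None, None, 1:], (n0, n1, n2 - 1)
            ).ravel()
            yield FaceGeometry(
                lo=idx[:, :, :-1].ravel(),
                hi=idx[:, :, 1:].ravel(),
                area=a,
                d_lo=dlo,
                d_hi=dhi,
            )

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Cell-center coordinates broadcast to the full 3D shape."""
        c0, c1, c2 = self.centers
        return np.meshgrid(c0, c1, c2, indexing="ij")
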