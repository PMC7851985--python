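"""Quasi-static complex conduction solver on labeled structured grids.

Solves div(sigma*(f) grad V) = 0 with Dirichlet electrodes (driven terminals
at U volts, ground at 0 V) and insulating (zero normal current) outer
boundaries, by a cell-centered finite-volume discretization.  Face
conductances are formed from the series composition of the two half-cell
resistances, so layered interfaces are exact in the 1D limit (equivalent to
harmonic averaging of the admittivity on uniform grids).

The linear system is complex symmetric with non-negative real part; it is
solved either directly (small problems) or by ILU-preconditioned BiCGSTAB
after symmetric diagonal scaling (large problems).  Both paths are fully
deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property
from typing import Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import Excitation
from .grid import LabeledGrid
from .materials import MaterialTable

DEFAULT_TOL = 1e-8
_DIRECT_LIMIT = 15_000  # unknowns below which a direct sparse solve is used
# ILU escalation ladder: (drop_tol, fill_factor), cheapest first
_ILU_LADDER = ((1e-2, 3.0), (1e-4, 6.0), (1e-5, 10.0))


class SolverError(RuntimeError):
    """The linear solve failed or did not reach the requested residual."""


class SingularityError(SolverError):
    """No conducting path between terminal and ground (singular system)."""


@dataclass
class _Faces:
    """Flattened two-point flux data for all faces of the grid."""

    lo: np.ndarray  # flat cell index on the low side
    hi: np.ndarray
    g: np.ndarray  # complex face conductance, S
    r_lo: np.ndarray  # half resistance on the lo side, Ohm
    r_hi: np.ndarray
    axis: np.ndarray  # axis id of each face (0, 1, 2)


def _cell_admittivity(grid: LabeledGrid, materials: MaterialTable, f: float) -> np.ndarray:
    sig = np.empty(grid.shape, dtype=complex)
    for rid, name in enumerate(grid.region_names):
        m = grid.labels == rid
        if m.any():
            sig[m] = materials.admittivity(name, f)
    return sig


def _build_faces(grid: LabeledGrid, sigma_star: np.ndarray) -> _Faces:
    sig = sigma_star.ravel()
    lo_l, hi_l, g_l, rlo_l, rhi_l, ax_l = [], [], [], [], [], []
    for axis, fg in enumerate(grid.face_geometry()):
        r_lo = fg.d_lo / (sig[fg.lo] * fg.area)
        r_hi = fg.d_hi / (sig[fg.hi] * fg.area)
        lo_l.append(fg.lo)
        hi_l.append(fg.hi)
        g_l.append(1.0 / (r_lo + r_hi))
        rlo_l.append(r_lo)
        rhi_l.append(r_hi)
        ax_l.append(np.full(fg.lo.size, axis, dtype=np.int8))
    return _Faces(
        lo=np.concatenate(lo_l),
        hi=np.concatenate(hi_l),
        g=np.concatenate(g_l),
        r_lo=np.concatenate(rlo_l),
        r_hi=np.concatenate(rhi_l),
        axis=np.concatenate(ax_l),
    )


def _laplacian(n: int, faces: _Faces) -> sp.csr_matrix:
    rows = np.concatenate([faces.lo, faces.hi, faces.lo, faces.hi])
    cols = np.concatenate([faces.hi, faces.lo, faces.lo, faces.hi])
    vals = np.concatenate([-faces.g, -faces.g, faces.g, faces.g])
    return sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


@dataclass
class FieldSolution:
    """Complex potential and derived fields for one frequency and excitation."""

    grid: LabeledGrid
    excitation: Excitation
    frequency: float
    V: np.ndarray  # complex potential per cell, shape grid.shape
    sigma_star: np.ndarray  # complex admittivity per cell
    U: float
    residual: float
    _faces: _Faces = field(repr=False)

    @cached_property
    def face_current(self) -> np.ndarray:
        """Complex current through each face, positive from lo to hi cell."""
        v = self.V.ravel()
        return self._faces.g * (v[self._faces.lo] - v[self._faces.hi])

    @cached_property
    def I(self) -> complex:
        """Total complex current collected by the ground electrode (A)."""
        return -electrode_current(self, self.excitation.ground_mask)

    @cached_property
    def E(self) -> np.ndarray:
        """Cell-centered electric field (3, n0, n1, n2), V/m.

        Components are reconstructed from the per-axis half-face potential
        drops (the drop across each half-cell of the two-point flux path),
        which is exact for piecewise-linear 1D profiles including those
        through ideal-conductor electrode cells.
        """
        shape = self.grid.shape
        n = self.grid.n_cells
        drop = np.zeros((3, n), dtype=complex)
        f = self._faces
        If = self.face_current
        for axis in range(3):
            m = f.axis == axis
            # drop on the lo cell's plus side and the hi cell's minus side
            np.add.at(drop[axis], f.lo[m], If[m] * f.r_lo[m])
            np.add.at(drop[axis], f.hi[m], If[m] * f.r_hi[m])
        e0, e1, e2 = self.grid.edges
        c0 = 0.5 * (e0[:-1] + e0[1:])
        w0 = np.diff(e0)[:, None, None]
        if self.grid.metric == "cylindrical":
            w1 = (c0[:, None] * np.diff(e1)[None, :])[:, :, None]
        else:
            w1 = np.diff(e1)[None, :, None]
        w2 = np.diff(e2)[None, None, :]
        E = drop.reshape((3,) + shape)
        out = np.empty_like(E)
        out[0] = E[0] / np.broadcast_to(w0, shape)
        out[1] = E[1] / np.broadcast_to(w1, shape)
        out[2] = E[2] / np.broadcast_to(w2, shape)
        return out

    @cached_property
    def J(self) -> np.ndarray:
        """Cell-centered current density J = sigma* E, (3, n0, n1, n2), A/m^2."""
        return self.sigma_star[None, ...] * self.E


def assemble_and_solve(
    grid: LabeledGrid,
    materials: MaterialTable,
    excitation: Excitation,
    f: float,
    tol: float = DEFAULT_TOL,
    method: str = "auto",
) -> FieldSolution:
    """Assemble and solve the conduction problem at frequency ``f`` (Hz).

    ``tol`` is the relative residual bound of the discrete conservation law,
    measured per interior cell against the local conductance scale.
    ``method`` is "auto" (direct below a size threshold, else iterative),
    "direct", or "iterative".

    Raises
    ------
    SingularityError
        If terminal and ground are not connected by a conducting path.
    SolverError
        On non-convergence (carries the achieved residual).
    """
    if not (0.0 < tol <= 1e-3):
        raise ValueError(f"tol must be in (0, 1e-3], got {tol}")
    g2 = excitation.grid
    if g2.shape != grid.shape:
        raise SolverError("excitation grid does not match the labeled grid")
    grid = g2  # the excitation's grid carries electrode relabeling

    fixed, vfix = excitation.fixed_and_values()
    if not fixed.any():
        raise SingularityError("no Dirichlet cells: empty excitation masks")
    if not any(m.any() for m in excitation.terminal_masks.values()):
        raise SingularityError("no active terminal cells")

    sigma_star = _cell_admittivity(grid, materials, f)
    faces = _build_faces(grid, sigma_star)
    n = grid.n_cells
    L = _laplacian(n, faces)

    free = ~fixed
    A = L[free][:, free].tocsc()
    b = -(L[free][:, fixed] @ vfix[fixed])

    nfree = int(free.sum())
    v = vfix.copy()
    if nfree:
        d = A.diagonal()
        if np.any(d == 0):
            raise SingularityError(
                "isolated cells with zero conductance; check the material table"
            )
        if method == "direct" or (method == "auto" and nfree <= _DIRECT_LIMIT):
            x = spla.spsolve(A, b)
        elif method in ("iterative", "auto"):
            x = _iterative_solve(A, b, d, tol)
        else:
            raise ValueError(f"unknown method {method!r}")
        if not np.all(np.isfinite(x)):
            raise SingularityError(
                "singular system: terminal and ground are not connected"
            )
        v[free] = x

    # per-cell conservation residual, relative to the local conductance scale
    scale = np.asarray(np.abs(L).sum(axis=1)).ravel()
    res = np.abs(L @ v)[free]
    rel = float(np.max(res / (scale[free] * max(abs(excitation.U), 1e-300))))
    if rel > tol:
        raise SolverError(
            f"solver residual {rel:.3e} exceeds tolerance {tol:.1e} at f={f} Hz"
        )

    return FieldSolution(
        grid=grid,
        excitation=excitation,
        frequency=f,
        V=v.reshape(grid.shape),
        sigma_star=sigma_star,
        U=excitation.U,
        residual=rel,
        _faces=faces,
    )


def _iterative_solve(A: sp.csc_matrix, b: np.ndarray, diag: np.ndarray, tol: float) -> np.ndarray:
    """Symmetric diagonal scaling + ILU-preconditioned BiCGSTAB.

    Starts with a cheap incomplete factorization and escalates to stronger
    ones if the Krylov iteration stalls.  Fully deterministic.
    """
    s = 1.0 / np.sqrt(np.abs(diag))
    D = sp.diags(s)
    As = (D @ A @ D).tocsc()
    bs = s * b
    bnorm = np.linalg.norm(bs)
    if bnorm == 0:
        return np.zeros_like(b)
    rtol = min(tol * 1e-2, 1e-10)
    achieved = math.inf
    for drop_tol, fill_factor in _ILU_LADDER:
        try:
            ilu = spla.spilu(As, drop_tol=drop_tol, fill_factor=fill_factor)
        except RuntimeError:
            continue
        M = spla.LinearOperator(As.shape, ilu.solve)
        x, info = spla.bicgstab(As, bs, rtol=rtol, atol=0.0, M=M, maxiter=2000)
        if info == 0:
            return s * x
        achieved = np.linalg.norm(As @ x - bs) / bnorm
    raise SolverError(
        f"iterative solver did not converge (achieved relative residual {achieved:.3e})"
    )


def electrode_current(sol: FieldSolution, mask: np.ndarray) -> complex:
    """Complex current leaving the masked electrode into the domain (A).

    The sign convention makes the current from a driven 1 V terminal
    positive and the current "leaving" the collecting ground negative, so
    that the currents of all electrodes of one solution sum to zero.
    """
    if mask.shape != sol.grid.shape:
        raise SolverError("mask shape does not match the solved grid")
    m = mask.ravel()
    f = sol._faces
    lo_in = m[f.lo]
    hi_in = m[f.hi]
    boundary = lo_in ^ hi_in
    If = sol.face_current[boundary]
    sign = np.where(lo_in[boundary], 1.0, -1.0)
    return complex(np.sum(sign * If))


# --------------------------------------------------------------------------
# impedance spectra
# --------------------------------------------------------------------------

@dataclass
class ImpedanceResult:
    """Impedance spectrum of one configuration.

    All arrays are aligned with ``frequencies``.  Z = 1/Y where Y = I/U is
    the admittance between the driven terminals and ground; R = Re Z,
    X = Im Z, |Z| = sqrt(R^2 + X^2), phi = arctan(X/R); Y = G + i*omega*C.
    """

    frequencies: np.ndarray
    Z: np.ndarray
    U: float = 1.0

    @property
    def Y(self) -> np.ndarray:
        return 1.0 / self.Z

    @property
    def R(self) -> np.ndarray:
        return self.Z.real

    @property
    def X(self) -> np.ndarray:
        return self.Z.imag

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.Z)

    @property
    def phase_rad(self) -> np.ndarray:
        return np.arctan2(self.X, self.R)

    @property
    def phase_deg(self) -> np.ndarray:
        return np.degrees(self.phase_rad)

    @property
    def G(self) -> np.ndarray:
        return self.Y.real

    @property
    def C(self) -> np.ndarray:
        w = 2.0 * np.pi * self.frequencies
        with np.errstate(divide="ignore", invalid="ignore"):
            c = np.where(w > 0, self.Y.imag / np.where(w > 0, w, 1.0), 0.0)
        return c

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "f_Hz": self.frequencies,
                "ReZ": self.R,
                "ImZ": self.X,
                "absZ": self.magnitude,
                "phase_deg": self.phase_deg,
                "G_S": self.G,
                "C_F": self.C,
            }
        )


def decompose_admittance(Y: complex, f: float) -> tuple[float, float]:
    """Split an admittance into conductance G (S) and capacitance C (F).

    Y = G + i*omega*C with omega = 2*pi*f; requires f > 0 unless Y is purely
    real (DC limit, C = 0).
    """
    if f < 0:
        raise ValueError(f"negative frequency {f}")
    if f == 0:
        if Y.imag != 0:
            raise ValueError("f = 0 with a reactive admittance: C is undefined")
        return (Y.real, 0.0)
    return (Y.real, Y.imag / (2.0 * math.pi * f))


def impedance_spectrum(
    grid: LabeledGrid,
    materials: MaterialTable,
    excitation: Excitation,
    freqs: Sequence[float],
    tol: float = DEFAULT_TOL,
    method: str = "auto",
) -> ImpedanceResult:
    """Solve once per frequency and collect the impedance spectrum."""
    freqs = np.asarray(list(freqs), dtype=float)
    if freqs.size == 0:
        raise ValueError("empty frequency list")
    if np.any(np.diff(freqs) <= 0):
        raise ValueError("frequencies must be strictly increasing")
    Z = np.empty(freqs.size, dtype=complex)
    for i, f in enumerate(freqs):
        try:
            sol = assemble_and_solve(grid, materials, excitation, f, tol=tol, method=method)
        except SolverError as exc:
            raise SolverError(f"at f={f} Hz: {exc}") from exc
        if sol.I == 0:
            raise SingularityError(f"zero total current at f={f} Hz")
        Z[i] = excitation.U / sol.I
    return ImpedanceResult(frequencies=freqs, Z=Z, U=excitation.U)
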