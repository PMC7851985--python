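"""Configuration sweeps and excitation-mode comparisons of the vein model.

Drives the electrode-configuration study: for each configuration (number of
surface electrodes, terminal radius, ground radius) and excitation mode
(all terminals simultaneously, or a single terminal at a chosen position)
the quasi-static problem is solved and the venous segment's percentage
contribution to the measured impedance is reported, by volume-impedance-
density integration and by dissipated-power integration.

Contribution tables are reported at 1 MHz by default (the frequency of the
slice-plot comparisons); full spectra use an exponential 10 Hz - 1 MHz grid.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .geometry import (
    Excitation,
    GeometryConfig,
    GeometryError,
    build_grid,
    electrode_masks,
    place_surface_electrodes,
)
from .grid import LabeledGrid
from .materials import MaterialTable, default_material_table
from .sensitivity import ContributionReport, region_contributions, sensitivity_field
from .solver import (
    DEFAULT_TOL,
    FieldSolution,
    ImpedanceResult,
    assemble_and_solve,
    impedance_spectrum,
)

POSITIONS = ("middle", "first_end", "second_end")
DEFAULT_RESOLUTION = (32, 64, 128)
REPORT_FREQUENCY = 1.0e6


def frequency_grid(f_min: float, f_max: float, points_per_decade: int = 5) -> np.ndarray:
    """Logarithmically equispaced frequencies, endpoints included.

    The default of 5 points/decade over 10 Hz - 1 MHz gives 26 points.
    """
    if f_min <= 0 or f_max <= 0:
        raise ValueError("frequency bounds must be positive")
    if f_min >= f_max:
        raise ValueError(f"f_min={f_min} must be < f_max={f_max}")
    if points_per_decade < 1:
        raise ValueError("points_per_decade must be >= 1")
    decades = math.log10(f_max / f_min)
    n = int(round(decades * points_per_decade)) + 1
    g = np.geomspace(f_min, f_max, n)
    g[0], g[-1] = f_min, f_max
    return g


def position_to_electrode(cfg: GeometryConfig, position: str) -> int:
    """Map a named terminal position to an electrode index.

    Rings are numbered by increasing z; ring 0 is the end nearest z=0, the
    side where the ground wire exits ("first end close to the ground
    electrode output").  "middle" is the ring nearest the vein center on the
    far side, "second_end" the last ring.  The electrode at angle 0 of the
    ring is used.
    """
    per_ring = cfg.n_electrodes // cfg.n_rings
    rings = {
        "first_end": 0,
        "middle": cfg.n_rings // 2,
        "second_end": cfg.n_rings - 1,
    }
    if position not in rings:
        raise ValueError(f"unknown position {position!r}; expected one of {POSITIONS}")
    return rings[position] * per_ring


@dataclass(frozen=True)
class RunSpec:
    """One solve of the sweep: a configuration plus an excitation mode."""

    config: GeometryConfig
    mode: str = "simultaneous"  # "simultaneous" or "single"
    position: str = "middle"  # used when mode == "single"
    with_vein: bool = True

    def label(self) -> dict:
        return {
            "n_electrodes": self.config.n_electrodes,
            "r_terminal_mm": self.config.r_terminal * 1e3,
            "r_ground_mm": self.config.r_ground * 1e3,
            "mode": self.mode,
            "position": self.position if self.mode == "single" else "",
            "with_vein": self.with_vein,
        }


@dataclass
class ExperimentPlan:
    """A list of runs plus the shared numerical settings."""

    runs: list[RunSpec]
    materials: MaterialTable = field(default_factory=default_material_table)
    resolution: tuple[int, int, int] = DEFAULT_RESOLUTION
    frequencies: tuple[float, ...] = (REPORT_FREQUENCY,)
    tol: float = DEFAULT_TOL

    def validate(self) -> None:
        """Fail fast: validate every configuration, reporting all failures."""
        failures = []
        for i, run in enumerate(self.runs):
            try:
                run.config.validate()
                place_surface_electrodes(run.config)
            except (GeometryError, ValueError) as exc:
                failures.append(f"run {i} ({run.label()}): {exc}")
        if failures:
            raise GeometryError(
                "invalid configurations:\n" + "\n".join(failures)
            )


def build_vein_excitation(
    cfg: GeometryConfig,
    resolution: tuple[int, int, int] = DEFAULT_RESOLUTION,
    mode: str = "simultaneous",
    position: str = "middle",
    with_vein: bool = True,
    inactive: str = "substrate",
) -> Excitation:
    """Build the labeled grid and Dirichlet masks for one vein-model run.

    ``with_vein=False`` relabels the vein wall as saline (the "without the
    vein" variant of the slice-plot comparisons).
    """
    grid = build_grid(cfg, resolution)
    if not with_vein:
        grid.labels[grid.region_mask("vein_wall")] = grid.region_id("saline")
    footprints = place_surface_electrodes(cfg)
    if mode == "simultaneous":
        m: str | tuple[str, int] = "simultaneous"
    elif mode == "single":
        m = ("single", position_to_electrode(cfg, position))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return electrode_masks(grid, cfg, footprints, mode=m, inactive=inactive)


def solve_run(
    run: RunSpec,
    materials: MaterialTable,
    resolution: tuple[int, int, int],
    f: float = REPORT_FREQUENCY,
    tol: float = DEFAULT_TOL,
) -> tuple[FieldSolution, ContributionReport]:
    """Solve one run at one frequency and compute its contribution report."""
    exc = build_vein_excitation(
        run.config, resolution, mode=run.mode, position=run.position, with_vein=run.with_vein
    )
    sol = assemble_and_solve(exc.grid, materials, exc, f, tol=tol)
    fld = sensitivity_field(sol)
    report = region_contributions(fld, descriptor=run.label())
    return sol, report


@dataclass
class SweepResult:
    """Outcome of a configuration sweep."""

    table: pd.DataFrame
    reports: list[ContributionReport]
    spectra: list[ImpedanceResult]
    provenance: dict

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def run_configuration_sweep(plan: ExperimentPlan) -> SweepResult:
    """Solve every run of the plan and tabulate vein contributions.

    One contribution report per (configuration, mode) at each plan
    frequency; the returned table mirrors the study's summary tables with
    per-region contribution columns appended.
    """
    plan.validate()
    rows = []
    reports: list[ContributionReport] = []
    spectra: list[ImpedanceResult] = []
    for run in plan.runs:
        exc = build_vein_excitation(
            run.config, plan.resolution, mode=run.mode, position=run.position,
            with_vein=run.with_vein,
        )
        freqs = np.asarray(plan.frequencies, dtype=float)
        Z = np.empty(freqs.size, dtype=complex)
        for i, f in enumerate(freqs):
            sol = assemble_and_solve(exc.grid, plan.materials, exc, f, tol=plan.tol)
            fld = sensitivity_field(sol)
            report = region_contributions(fld, descriptor=run.label())
            reports.append(report)
            Z[i] = fld.Z
            row = dict(run.label())
            row.update(
                {
                    "f_Hz": f,
                    "power_loss_vein_pct": report.vein_power_pct,
                    "z_density_vein_pct": report.vein_z_pct,
                    "ReZ": Z[i].real,
                    "ImZ": Z[i].imag,
                    "absZ": abs(Z[i]),
                    "phase_deg": math.degrees(math.atan2(Z[i].imag, Z[i].real)),
                }
            )
            for name in exc.grid.region_names:
                row[f"z_pct_{name}"] = report.z_pct[name]
                row[f"power_pct_{name}"] = report.power_pct[name]
            rows.append(row)
        spectra.append(ImpedanceResult(frequencies=freqs, Z=Z))
    table = pd.DataFrame(rows)
    mat_hash = hashlib.sha256(plan.materials.to_yaml().encode()).hexdigest()[:16]
    provenance = {
        "resolution": tuple(plan.resolution),
        "tolerance": plan.tol,
        "material_table_sha256": mat_hash,
        "code_version": __version__,
    }
    return SweepResult(table=table, reports=reports, spectra=spectra, provenance=provenance)


def table1_plan(resolution=DEFAULT_RESOLUTION, **kwargs) -> ExperimentPlan:
    """All-terminal excitation, r_t = 1 mm, r_g = 0.5 mm, N in {28,32,44,48}."""
    runs = [
        RunSpec(GeometryConfig(n_electrodes=n, r_terminal=1e-3, r_ground=0.5e-3))
        for n in (28, 32, 44, 48)
    ]
    return ExperimentPlan(runs=runs, resolution=resolution, **kwargs)


def table2_plan(resolution=DEFAULT_RESOLUTION, **kwargs) -> ExperimentPlan:
    """All-terminal excitation, r_t = 1 mm, r_g = 1 mm, N in {28,32,44,48}."""
    runs = [
        RunSpec(GeometryConfig(n_electrodes=n, r_terminal=1e-3, r_ground=1e-3))
        for n in (28, 32, 44, 48)
    ]
    return ExperimentPlan(runs=runs, resolution=resolution, **kwargs)


def table3_plan(resolution=DEFAULT_RESOLUTION, **kwargs) -> ExperimentPlan:
    """Single-terminal excitation at three positions, r_t in {1, 2.5} mm."""
    runs = [
        RunSpec(
            GeometryConfig(r_terminal=rt, r_ground=0.5e-3),
            mode="single",
            position=pos,
        )
        for rt in (1e-3, 2.5e-3)
        for pos in POSITIONS
    ]
    return ExperimentPlan(runs=runs, resolution=resolution, **kwargs)


@dataclass
class ScanResult:
    """Single-terminal position scan outcome."""

    reports: dict[str, ContributionReport]
    max_pairwise_diff_pp: float


def single_terminal_scan(
    cfg: GeometryConfig,
    materials: MaterialTable | None = None,
    positions: Sequence[str] = POSITIONS,
    resolution: tuple[int, int, int] = DEFAULT_RESOLUTION,
    f: float = REPORT_FREQUENCY,
    tol: float = DEFAULT_TOL,
) -> ScanResult:
    """Move the single driven terminal between named positions.

    Solves once per position and reports the maximum pairwise absolute
    difference of the vein's volume-impedance-density percentage, in
    percentage points.
    """
    materials = materials or default_material_table()
    idx = {p: position_to_electrode(cfg, p) for p in positions}
    if len(set(idx.values())) < 3:
        raise GeometryError(
            f"positions {positions} resolve to fewer than 3 distinct electrodes: {idx}"
        )
    reports: dict[str, ContributionReport] = {}
    for pos in positions:
        run = RunSpec(cfg, mode="single", position=pos)
        _, report = solve_run(run, materials, resolution, f=f, tol=tol)
        reports[pos] = report
    vals = [r.vein_z_pct for r in reports.values()]
    diff = max(abs(a - b) for a in vals for b in vals)
    return ScanResult(reports=reports, max_pairwise_diff_pp=diff)


# --------------------------------------------------------------------------
# slice export
# --------------------------------------------------------------------------

def export_slice(obj, quantity: str, plane: str = "yz") -> tuple[np.ndarray, dict]:
    """Sample a field on the y-z midplane as a 2D array plus axis metadata.

    ``obj`` is a FieldSolution or SensitivityField; ``quantity`` one of
    ``potential``, ``J``, ``S``, ``z`` (magnitudes are exported for the
    vector/complex quantities, matching how slice plots are drawn).
    """
    if plane != "yz":
        raise ValueError(f"unsupported plane {plane!r}; only the y-z midplane is exported")
    from .sensitivity import SensitivityField

    if isinstance(obj, SensitivityField):
        grid = obj.grid
        freq = obj.frequency
        fields = {
            "S": (np.abs(obj.S), "1/m^4"),
            "z": (np.abs(obj.z), "Ohm/m^2"),
        }
    else:
        grid = obj.grid
        freq = obj.frequency
        J = obj.J
        fields = {
            "potential": (np.abs(obj.V), "V"),
            "J": (np.sqrt(np.abs(J[0]) ** 2 + np.abs(J[1]) ** 2 + np.abs(J[2]) ** 2), "A/m^2"),
        }
    if quantity not in fields:
        raise ValueError(
            f"quantity {quantity!r} not available on {type(obj).__name__}; "
            f"choose from {sorted(fields)}"
        )
    data, units = fields[quantity]

    if grid.metric == "cylindrical":
        thc = grid.centers[1]
        j_pos = int(np.argmin(np.abs(thc - 0.5 * np.pi)))
        j_neg = int(np.argmin(np.abs(thc - 1.5 * np.pi)))
        rc = grid.centers[0]
        top = data[:, j_pos, :]
        bottom = data[::-1, j_neg, :]
        arr = np.vstack([bottom, top])
        yaxis = np.concatenate([-rc[::-1], rc])
    else:
        nx = grid.shape[0]
        arr = data[nx // 2, :, :]
        yaxis = grid.centers[1]
    meta = {
        "quantity": quantity,
        "units": units,
        "frequency_Hz": freq,
        "y_m": yaxis,
        "z_m": grid.centers[2],
    }
    return arr, meta
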