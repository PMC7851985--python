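# Methods

## Physical model

`veincuff` simulates two-electrode impedance measurement of a saline-perfused
venous segment held in a cylindrical measurement chamber, with a cuff of
small gold surface electrodes wrapped around the vessel and a thin axial
gold ground wire running through the lumen.

At the frequencies of interest (10 Hz – 1 MHz) the geometry is far smaller
than the electromagnetic wavelength, so the quasi-static approximation
applies: the potential obeys the complex conduction equation

    div( sigma* grad V ) = 0,        sigma* = sigma + i 2 pi f eps0 eps_r,

with Dirichlet conditions of 1 V on the driven terminal electrodes and 0 V
on the ground wire, and natural (insulating) conditions on the outer chamber
wall. The measured impedance is Z = U / I with U = 1 V and I the total
complex current collected by the ground electrode.

### Sensitivity and regional contributions

For a two-electrode lead the sensitivity field is S = (J · J) / I²
(unconjugated), and the volume impedance density z = rho · S with
rho = 1 / sigma*. Its volume integral reproduces the measured impedance
(the lead-field identity), and regional integrals decompose Z into
per-material contributions. A second, independent measure is the regional
share of the dissipated power, proportional to Re(sigma*) |E|². Contribution
reports carry both; on every solved case the two agree within a tenth of a
percentage point.

Two discretizations of the identity are carried side by side:

* cell-centered fields S, z and p reconstructed from cell-centered J and E —
  used for slice exports;
* an operator-consistent per-cell contribution obtained by splitting each
  face's dissipation g (ΔV)² between its two cells in proportion to their
  half-cell series resistances. Summed over all cells this reproduces the
  solver's Z to machine precision, so regional tables are exact partitions
  of the measured impedance.

## Geometry and defaults

The model is parameterised by `GeometryConfig`. Defaults (all overridable):

| Parameter | Default | Rationale |
|---|---|---|
| vein length / diameter | 60 mm / 14 mm | large superficial vein segment |
| vein wall thickness | 0.5 mm | typical large-vein wall scale |
| chamber radius / length | 25 mm / 120 mm | PMMA chamber with 2 mm wall |
| inlet/outlet glass tubes | 7 mm inner radius, 1 mm wall | match the vein outer radius |
| electrodes | 28 in 4 rings | smallest studied cuff |
| terminal radius r_t | 1 mm | smallest studied contact |
| ground wire radius r_g | 0.5 mm | thin axial return electrode |
| substrate thickness | 0.5 mm | flexible quartz cuff substrate |

Materials are order-of-magnitude laboratory values, fully declared and
overridable via YAML: saline 1.6 S/m, eps_r 80; vein wall 0.3 S/m with a
dispersive permittivity (power-law fall from 1e5 at 10 Hz to 2e3 at 1 MHz,
i.e. linear on log-log axes, emulating beta-dispersion; with this form the
capacitive susceptance omega·eps_r rises monotonically with frequency, as
it must for a relaxing dielectric); glass 1e-12 S/m / 4.2; quartz
1e-12 S/m / 3.75; PMMA 1e-14 S/m / 3.0; gold 4.1e7 S/m / 1. Because the
scientific conclusions are orderings and invariances rather than absolute
percentages, exact material values are not load-bearing.

## Discretization

A cell-centered finite-volume scheme on a structured cylindrical grid
(r, theta, z; theta periodic). Radial and axial grid lines are placed
exactly on every material interface and each layer receives at least two
cells, with remaining cells distributed proportionally (largest-remainder
rounding) under a grading cap of 20x the uniform spacing — a layer that
would need finer grading raises a `ResolutionError` naming the layer.
Because every interface is face-aligned, voxelized region volumes are
analytically exact and the series face conductance

    g = A / (d_lo / sigma*_lo + d_hi / sigma*_hi)

is exact for layered one-dimensional media.

Electrode footprints are disks on the cuff's inner surface. Footprint
centers are snapped to the nearest surface cell center so that footprints
are congruent across rings; this congruence is what makes the
terminal-position invariance measurable on a coarse grid. A footprint
smaller than the local surface cell pitch raises a `ResolutionError`.
Inactive electrodes in single-terminal mode are electrically absent by
default (substrate material), or can be kept as floating gold bodies.

## Linear solver

The reduced system (free cells only) is complex, sparse and structurally
symmetric. Systems below 15,000 unknowns are solved directly (sparse LU);
larger systems use symmetric diagonal scaling, an incomplete-LU
preconditioner and BiCGSTAB with an escalation ladder of ILU strengths
(drop tolerance 1e-2/1e-4/1e-5 with growing fill). A direct factorization
at the study resolution (262k cells) exceeds an 8 GiB memory budget, which
is why the iterative path is the default there. Every solve is verified a
posteriori: the per-cell residual of the full (unreduced) operator, scaled
by the local conductance and the applied voltage, must not exceed the
requested tolerance (default 1e-8) or a `SolverError` is raised. All steps
are deterministic.

## Problem sizes

Chosen to balance fidelity against a single-CPU budget:

* (32, 64, 128) ≈ 262k cells — the study's coarse grid for contribution
  tables and the position scan (~35 s per solve);
* (24, 48, 96) ≈ 110k cells — ordering comparisons (~10 s per solve);
* (16, 32, 64) ≈ 33k cells — frequency sweeps and variants (~4 s per solve).

The reported orderings and invariances are stable across these grids.

## Validation phantoms

Analytic phantoms exercised by the test suite and `veincuff validate`:

* **slab** — rectangular bar between full-face electrodes, Z = L/(sigma* A);
  also the capacitor limit C = eps0 eps_r A / L;
* **series_bilayer** — two materials stacked axially; closed-form impedance
  and closed-form regional contributions (series-resistor ratios);
* **coaxial** — annulus between an inner wire and an outer shell,
  Z = ln(b/a)/(2 pi sigma* L), exercising the cylindrical metric with a
  genuinely non-uniform field (second-order convergence observed);
* **homogeneous_cylinder** — full cylinder between end caps,
  Z = L/(sigma* pi R²).

A finite-difference perturbation oracle additionally checks that the
regional z-density integrals equal the derivative of Z with respect to a
regional resistivity scaling.

## Conventions and limitations

* "middle" terminal position: with an even number of rings no ring sits
  exactly at the vein center; the ring at index `n_rings // 2` is used.
* The power-density fields omit the time-average factor 1/2 throughout; it
  cancels in every fraction.
* Electrode contacts are ideal Dirichlet patches: no contact impedance or
  double-layer model (a two-electrode measurement at these areas is
  dominated by the bulk above ~kHz).
* Blood is replaced by saline (perfused-segment setup), and the vessel is a
  straight circular cylinder; no flow, pulsation or wall compliance.
* Absolute contribution percentages depend on the declared material table;
  with these defaults the vein share at 1 MHz is in the 60–75 % range. The
  scientific claims validated by the test suite are orderings, invariances
  and identities, which are insensitive to the exact material values.
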