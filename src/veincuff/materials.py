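"""Frequency-dependent electrical material properties.

Every region of the model is described by its conductivity ``sigma`` (S/m)
and relative permittivity ``eps_r`` (dimensionless), either as constants or
as tables of ``(frequency_Hz, value)`` knots interpolated as a power law
(linearly on log-log axes) in frequency.  The quantity the field solver consumes is the complex
admittivity

    sigma* = sigma(f) + i * 2*pi*f * eps0 * eps_r(f)     [S/m]

whose reciprocal is the complex resistivity rho = 1/sigma* (Ohm*m).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np
import yaml

#: Vacuum permittivity, F/m (5 significant figures).
EPS0 = 8.8542e-12

#: The six region names of the cuff-electrode vein model.
REGION_NAMES = (
    "saline",
    "vein_wall",
    "glass_tube",
    "quartz_substrate",
    "pmma_chamber",
    "gold_electrode",
)

PropertyValue = Union[float, Sequence[tuple[float, float]]]


class MaterialError(ValueError):
    """Invalid material definition or lookup."""


def _as_table(value: PropertyValue, what: str, minimum: float) -> tuple[np.ndarray, np.ndarray] | float:
    """Normalize a property to either a scalar or (freqs, values) arrays."""
    if isinstance(value, (int, float)):
        v = float(value)
        if v < minimum:
            raise MaterialError(f"{what}={v} below physical minimum {minimum}")
        return v
    pairs = [(float(f), float(v)) for f, v in value]
    if not pairs:
        raise MaterialError(f"empty table for {what}")
    freqs = np.array([p[0] for p in pairs])
    vals = np.array([p[1] for p in pairs])
    if np.any(freqs <= 0):
        raise MaterialError(f"{what}: tabulated frequencies must be positive")
    if np.any(np.diff(freqs) <= 0):
        raise MaterialError(f"{what}: tabulated frequencies must be strictly increasing")
    if np.any(vals < minimum):
        raise MaterialError(f"{what}: value below physical minimum {minimum}")
    if np.any(vals <= 0):
        raise MaterialError(f"{what}: tabulated values must be positive (log-log interpolation)")
    return freqs, vals


@dataclass(frozen=True)
class MaterialSpec:
    """Electrical properties of one material.

    Parameters
    ----------
    name
        Identifier used in error messages and serialization.
    sigma
        Conductivity in S/m; a constant or a list of (Hz, S/m) pairs.
    eps_r
        Relative permittivity; a constant or a list of (Hz, value) pairs.

    Tabulated properties are interpolated as power laws (linearly on
    log-log axes) and clamped to the end knots outside the tabulated range
    (including f=0).
    """

    name: str
    sigma: PropertyValue
    eps_r: PropertyValue

    def __post_init__(self) -> None:
        _as_table(self.sigma, f"{self.name}.sigma", 0.0)
        _as_table(self.eps_r, f"{self.name}.eps_r", 1.0)

    def _eval(self, value: PropertyValue, f: float, minimum: float, what: str) -> float:
        table = _as_table(value, what, minimum)
        if isinstance(table, float):
            return table
        freqs, vals = table
        if f <= freqs[0]:
            return float(vals[0])
        if f >= freqs[-1]:
            return float(vals[-1])
        # power-law (log-log) interpolation: a dispersive fall between two
        # knots behaves as value ~ f^-s, so omega*eps stays monotone in f
        return float(
            10.0 ** np.interp(math.log10(f), np.log10(freqs), np.log10(vals))
        )

    def sigma_at(self, f: float) -> float:
        """Conductivity (S/m) at frequency ``f`` (Hz)."""
        if f < 0:
            raise MaterialError(f"negative frequency {f}")
        return self._eval(self.sigma, f, 0.0, f"{self.name}.sigma")

    def eps_r_at(self, f: float) -> float:
        """Relative permittivity at frequency ``f`` (Hz)."""
        if f < 0:
            raise MaterialError(f"negative frequency {f}")
        return self._eval(self.eps_r, f, 1.0, f"{self.name}.eps_r")

    def to_dict(self) -> dict:
        def conv(v: PropertyValue):
            if isinstance(v, (int, float)):
                return float(v)
            return [[float(f), float(x)] for f, x in v]

        return {"sigma": conv(self.sigma), "eps_r": conv(self.eps_r)}

    @classmethod
    def from_dict(cls, name: str, d: Mapping) -> "MaterialSpec":
        def conv(v):
            if isinstance(v, (int, float)):
                return float(v)
            return tuple((float(f), float(x)) for f, x in v)

        return cls(name=name, sigma=conv(d["sigma"]), eps_r=conv(d["eps_r"]))


def admittivity(spec: MaterialSpec, f: float) -> complex:
    """Complex admittivity sigma* = sigma(f) + i*2*pi*f*eps0*eps_r(f), in S/m.

    Raises
    ------
    MaterialError
        If ``f`` is negative.
    """
    if f < 0:
        raise MaterialError(f"negative frequency {f} for material {spec.name!r}")
    return complex(spec.sigma_at(f), 2.0 * math.pi * f * EPS0 * spec.eps_r_at(f))


def complex_resistivity(spec: MaterialSpec, f: float) -> complex:
    """Complex resistivity rho = 1/sigma* in Ohm*m.

    Raises
    ------
    MaterialError
        If the admittivity vanishes (perfect insulator at DC).
    """
    s = admittivity(spec, f)
    if s == 0:
        raise MaterialError(
            f"material {spec.name!r} has zero admittivity at f={f} Hz; "
            "resistivity is undefined"
        )
    return 1.0 / s


@dataclass(frozen=True)
class MaterialTable:
    """Mapping from the six model region names to material specs."""

    specs: Mapping[str, MaterialSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [r for r in REGION_NAMES if r not in self.specs]
        if missing:
            raise MaterialError(f"material table missing regions: {missing}")

    def __getitem__(self, region: str) -> MaterialSpec:
        try:
            return self.specs[region]
        except KeyError:
            raise MaterialError(
                f"unknown region {region!r}; known regions: {sorted(self.specs)}"
            ) from None

    def admittivity(self, region: str, f: float) -> complex:
        return admittivity(self[region], f)

    def resistivity(self, region: str, f: float) -> complex:
        return complex_resistivity(self[region], f)

    def to_dict(self) -> dict:
        return {name: spec.to_dict() for name, spec in self.specs.items()}

    @classmethod
    def from_dict(cls, d: Mapping) -> "MaterialTable":
        return cls({name: MaterialSpec.from_dict(name, sub) for name, sub in d.items()})

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "MaterialTable":
        return cls.from_dict(yaml.safe_load(text))

    def replace(self, **overrides: MaterialSpec) -> "MaterialTable":
        """Return a copy with some regions replaced."""
        specs = dict(self.specs)
        for region, spec in overrides.items():
            if region not in specs:
                raise MaterialError(f"unknown region {region!r}")
            specs[region] = spec
        return MaterialTable(specs)


def uniform_table(sigma: float, eps_r: float = 1.0) -> MaterialTable:
    """A table where every region shares the same constant properties.

    Convenient for single-material phantoms; the electrode region is still
    assigned gold so ideal-conductor assumptions hold.
    """
    specs = {
        name: MaterialSpec(name=name, sigma=sigma, eps_r=eps_r)
        for name in REGION_NAMES
        if name != "gold_electrode"
    }
    specs["gold_electrode"] = MaterialSpec("gold_electrode", sigma=4.1e7, eps_r=1.0)
    return MaterialTable(specs)


def default_material_table() -> MaterialTable:
    """The documented default material table of the vein model.

    The defaults are declared, order-of-magnitude-correct values (overridable
    through the config file):

    * saline: sigma = 1.6 S/m, eps_r = 80 (frequency independent);
    * vein wall: sigma = 0.3 S/m; eps_r dispersive, falling log-linearly from
      1e5 at 10 Hz to 2e3 at 1 MHz, emulating the beta dispersion of soft
      tissue (cell-membrane capacitance charging);
    * glass tube (silica): sigma = 1e-12 S/m, eps_r = 4.2;
    * quartz cuff substrate: sigma = 1e-12 S/m, eps_r = 3.75;
    * PMMA chamber: sigma = 1e-14 S/m, eps_r = 3.0;
    * gold electrodes: sigma = 4.1e7 S/m, eps_r = 1.
    """
    return MaterialTable(
        {
            "saline": MaterialSpec("saline", sigma=1.6, eps_r=80.0),
            "vein_wall": MaterialSpec(
                "vein_wall",
                sigma=0.3,
                eps_r=((10.0, 1.0e5), (1.0e6, 2.0e3)),
            ),
            "glass_tube": MaterialSpec("glass_tube", sigma=1.0e-12, eps_r=4.2),
            "quartz_substrate": MaterialSpec("quartz_substrate", sigma=1.0e-12, eps_r=3.75),
            "pmma_chamber": MaterialSpec("pmma_chamber", sigma=1.0e-14, eps_r=3.0),
            "gold_electrode": MaterialSpec("gold_electrode", sigma=4.1e7, eps_r=1.0),
        }
    )
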