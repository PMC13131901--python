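"""Species physiology database.

Whole-body physiological system parameters (organ volumes, regional blood
flows, extracellular space, GFR, cardiac output) for the four species used in
the middle-out workflow: mouse, rat, cynomolgus monkey and a 13-year-old,
50 kg male human. Values are bundled structured-text data files with their
literature sources annotated inline; any field can be overridden at load
time.

Internal unit conventions (used throughout the package): volumes in mL,
flows and clearances in mL/h, body weight in kg, time in h.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

import yaml

SUPPORTED_SPECIES = ("mouse", "rat", "monkey", "human")

#: Tissues drained by the portal vein; their venous outflow enters the liver.
PORTAL_TISSUES = ("gut", "spleen")

#: Fraction of total blood volume assigned to the venous pool (the remainder
#: is arterial). A standard ~2:1 venous:arterial split.
VENOUS_BLOOD_FRACTION = 2.0 / 3.0


class UnknownSpeciesError(KeyError):
    """Raised when a species label has no bundled physiology."""


@dataclass(frozen=True)
class TissueSpec:
    """One perfused tissue compartment.

    Attributes
    ----------
    name:
        Tissue identifier (``lung``, ``liver``, ..., ``rest``).
    blood_flow:
        Arterial inflow, mL/h. For the lung this is the entire cardiac
        output (pulmonary circulation in series).
    total_volume:
        Tissue volume, mL (density taken as 1 g/mL).
    extracellular_fraction:
        Fraction of ``total_volume`` that is extracellular (vascular +
        interstitial) space; the rest is intracellular.
    """

    name: str
    blood_flow: float
    total_volume: float
    extracellular_fraction: float

    def __post_init__(self) -> None:
        if self.blood_flow <= 0 or self.total_volume <= 0:
            raise ValueError(
                f"tissue {self.name!r}: flow and volume must be positive"
            )
        if not 0.0 < self.extracellular_fraction < 1.0:
            raise ValueError(
                f"tissue {self.name!r}: extracellular fraction must be in (0, 1)"
            )

    @property
    def extracellular_volume(self) -> float:
        return self.total_volume * self.extracellular_fraction

    @property
    def intracellular_volume(self) -> float:
        return self.total_volume * (1.0 - self.extracellular_fraction)


@dataclass(frozen=True)
class SpeciesPhysiology:
    """Fully populated physiology for one species."""

    species: str
    body_weight: float  # kg
    gfr: float  # mL/h
    cardiac_output: float  # mL/h
    blood_volume: float  # mL
    tissues: tuple[TissueSpec, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.body_weight <= 0 or self.gfr <= 0:
            raise ValueError("body weight and GFR must be positive")
        if self.cardiac_output <= 0 or self.blood_volume <= 0:
            raise ValueError("cardiac output and blood volume must be positive")
        names = [t.name for t in self.tissues]
        if len(set(names)) != len(names):
            raise ValueError("duplicate tissue names")
        flows = sum(t.blood_flow for t in self.tissues if t.name != "lung")
        if abs(flows / self.cardiac_output - 1.0) > 0.01:
            raise ValueError(
                "non-lung tissue flows must balance cardiac output within 1% "
                f"(got {flows:.4g} vs CO {self.cardiac_output:.4g})"
            )

    @property
    def tissue_names(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.tissues)

    def tissue(self, name: str) -> TissueSpec:
        for t in self.tissues:
            if t.name == name:
                return t
        raise KeyError(f"no tissue {name!r} in {self.species} physiology")

    @property
    def venous_blood_volume(self) -> float:
        return self.blood_volume * VENOUS_BLOOD_FRACTION

    @property
    def arterial_blood_volume(self) -> float:
        return self.blood_volume * (1.0 - VENOUS_BLOOD_FRACTION)


def _data_text(relative: str) -> str:
    return (
        resources.files("mithrapbpk").joinpath("data").joinpath(relative).read_text()
    )


def _deep_update(base: dict, overrides: Mapping) -> dict:
    out = dict(base)
    for key, value in overrides.items():
        if isinstance(value, Mapping) and isinstance(out.get(key), dict):
            out[key] = _deep_update(out[key], value)
        else:
            out[key] = value
    return out


def get_physiology(
    species: str,
    body_weight: float | None = None,
    overrides: Mapping | None = None,
) -> SpeciesPhysiology:
    """Load the bundled physiology for ``species``.

    Parameters
    ----------
    species:
        One of ``mouse``, ``rat``, ``monkey``, ``human``.
    body_weight:
        Optional body weight (kg) replacing the bundled default. Organ
        volumes, flows, blood volume and cardiac output are stored as
        fractions/absolute rates; volumes scale with body weight while
        cardiac output and GFR keep their bundled absolute values unless
        overridden explicitly.
    overrides:
        Nested mapping merged over the raw data file (e.g.
        ``{"gfr_mL_per_h": 5400.0}`` or
        ``{"tissues": {"liver": {"volume_frac_bw": 0.03}}}``).
    """
    if species not in SUPPORTED_SPECIES:
        raise UnknownSpeciesError(
            f"unknown species {species!r}; supported: {', '.join(SUPPORTED_SPECIES)}"
        )
    raw = yaml.safe_load(_data_text(f"physiology/{species}.yaml"))
    if overrides:
        raw = _deep_update(raw, overrides)
    bw = float(body_weight if body_weight is not None else raw["body_weight_kg"])
    co = float(raw["cardiac_output_mL_per_h"])
    tissues = []
    for name, spec in raw["tissues"].items():
        flow = co if name == "lung" else float(spec["flow_frac_co"]) * co
        tissues.append(
            TissueSpec(
                name=name,
                blood_flow=flow,
                total_volume=float(spec["volume_frac_bw"]) * bw * 1000.0,
                extracellular_fraction=float(spec["extracellular_fraction"]),
            )
        )
    return SpeciesPhysiology(
        species=species,
        body_weight=bw,
        gfr=float(raw["gfr_mL_per_h"]),
        cardiac_output=co,
        blood_volume=float(raw["blood_volume_frac_bw"]) * bw * 1000.0,
        tissues=tuple(tissues),
    )


def with_gfr(physiology: SpeciesPhysiology, gfr: float) -> SpeciesPhysiology:
    """Return a copy of ``physiology`` with a replaced GFR (mL/h)."""
    if gfr <= 0:
        raise ValueError("GFR must be positive")
    return replace(physiology, gfr=gfr)
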