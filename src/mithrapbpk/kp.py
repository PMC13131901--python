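"""Tissue:plasma partition coefficients by the Poulin & Theil method.

For each non-adipose tissue t the partition coefficient at distribution
equilibrium is predicted from tissue composition and lipophilicity:

    Kp_t = [P*f_nl,t + (0.3P + 0.7)*f_ph,t + f_w,t]
           ---------------------------------------- * (fup / fut)
           [P*f_nl,p + (0.3P + 0.7)*f_ph,p + f_w,p]

with P = 10^logP, f_nl / f_ph / f_w the neutral-lipid, phospholipid and
water volume fractions of tissue (t) or plasma (p), and fut the unbound
fraction in tissue derived from the plasma unbound fraction through the
extracellular-protein ratio RA (tissue:plasma interstitial protein):

    fut = 1 / (1 + ((1 - fup)/fup) * RA)

Adipose uses the method's adipose variant: interstitial binding in fat is
taken as negligible (fut = 1), so the binding correction reduces to fup.
Ionization is not modelled (the method uses logP, not logD); pKa values are
carried as provenance only.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import yaml

from .compounds import CompoundParams
from .physiology import SpeciesPhysiology


@dataclass(frozen=True)
class KpSet:
    """Per-tissue partition coefficients plus the tissue unbound fractions used."""

    values: Mapping[str, float]
    fut: Mapping[str, float]
    method: str = "poulin-theil-extracellular"

    def __post_init__(self) -> None:
        for name, kp in self.values.items():
            if not (kp > 0 and kp < float("inf")):
                raise ValueError(f"Kp[{name}]={kp} must be positive and finite")

    def __getitem__(self, tissue: str) -> float:
        return self.values[tissue]


def _composition_tables() -> tuple[dict, dict]:
    raw = yaml.safe_load(
        resources.files("mithrapbpk")
        .joinpath("data/tissue_composition.yaml")
        .read_text()
    )
    return raw["plasma"], raw["tissues"]


def _lipid_term(p: float, comp: Mapping[str, float]) -> float:
    return p * comp["f_nl"] + (0.3 * p + 0.7) * comp["f_ph"] + comp["f_w"]


def unbound_fraction_tissue(fup: float, ra: float) -> float:
    """Tissue unbound fraction from plasma fup and extracellular protein ratio."""
    if not 0.0 < fup <= 1.0:
        raise ValueError(f"fup={fup} must be in (0, 1]")
    return 1.0 / (1.0 + (1.0 - fup) / fup * ra)


def predict_kp(
    compound: CompoundParams,
    physiology: SpeciesPhysiology,
    species: str | None = None,
    logp: float | None = None,
    fup: float | None = None,
) -> KpSet:
    """Predict Kp for every tissue of ``physiology``.

    ``species`` defaults to the physiology's own label and selects the fup
    entry; ``logp`` and ``fup`` allow explicit overrides (used by the
    sensitivity scans without mutating the compound).
    """
    species = species or physiology.species
    fup_val = fup if fup is not None else compound.fup_for(species)
    logp_val = logp if logp is not None else compound.logp
    if not 0.0 < fup_val <= 1.0:
        raise ValueError(f"fup={fup_val} must be in (0, 1] for Kp prediction")
    p = 10.0 ** logp_val
    plasma, tissues = _composition_tables()
    denom = _lipid_term(p, plasma)
    values: dict[str, float] = {}
    futs: dict[str, float] = {}
    for tissue in physiology.tissue_names:
        if tissue not in tissues:
            raise KeyError(f"no bundled composition for tissue {tissue!r}")
        comp = tissues[tissue]
        if tissue == "adipose":
            fut = 1.0
        else:
            fut = unbound_fraction_tissue(fup_val, float(comp["ra"]))
        values[tissue] = _lipid_term(p, comp) / denom * (fup_val / fut)
        futs[tissue] = fut
    return KpSet(values=values, fut=futs)
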