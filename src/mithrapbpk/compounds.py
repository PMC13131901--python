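"""Drug-specific model inputs and their validation.

A :class:`CompoundParams` bundles the physicochemical, binding and
permeability inputs of one compound: molecular weight, logP, aqueous
solubility (metadata only in this IV-only model), pKa values (retained for
provenance, unused in partitioning), per-species plasma unbound fraction
(fup) and blood:plasma ratio (BPR), and the mouse-calibrated specific
permeability-surface-area product (SpecPStc, mL/s per mL cell volume).

Parameters are read from human-editable YAML configs; the two study
compounds (mithramycin and MTMSA-Trp) ship with the package.
"""

from __future__ import annotations

import dataclasses
import io
import os
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import yaml

#: fup assigned when the measured value is below the quantification limit
#: (<1%): entered as 0.1%.
FUP_BELOW_LOQ = 0.001


class CompoundValidationError(ValueError):
    """Raised when a compound config fails validation; lists the offending fields."""


@dataclass(frozen=True)
class CompoundParams:
    name: str
    mw: float  # g/mol
    logp: float
    solubility: float  # mg/mL at solubility_ph
    solubility_ph: float | None
    pka: tuple[float, ...]
    fup: Mapping[str, float] = field(default_factory=dict)  # fraction in (0, 1]
    bpr: Mapping[str, float] = field(default_factory=dict)  # dimensionless > 0
    spec_pstc: float = 0.0  # mL/s per mL cell volume

    def __post_init__(self) -> None:
        problems = []
        if self.mw <= 0:
            problems.append(f"mw={self.mw} (must be > 0)")
        if self.solubility is not None and self.solubility <= 0:
            problems.append(f"solubility={self.solubility} (must be > 0)")
        if self.spec_pstc <= 0:
            problems.append(f"spec_pstc={self.spec_pstc} (must be > 0)")
        for sp, v in self.fup.items():
            if not 0.0 < v <= 1.0:
                problems.append(f"fup[{sp}]={v} (must be in (0, 1])")
        for sp, v in self.bpr.items():
            if v <= 0:
                problems.append(f"bpr[{sp}]={v} (must be > 0)")
        if problems:
            raise CompoundValidationError(
                f"invalid parameters for {self.name!r}: " + "; ".join(problems)
            )

    def fup_for(self, species: str) -> float:
        try:
            return self.fup[species]
        except KeyError:
            raise KeyError(
                f"{self.name}: no fup entry for species {species!r}"
            ) from None

    def bpr_for(self, species: str) -> float:
        try:
            return self.bpr[species]
        except KeyError:
            raise KeyError(
                f"{self.name}: no BPR entry for species {species!r}"
            ) from None

    def with_updates(self, **kwargs) -> "CompoundParams":
        """Return a modified copy (used by sensitivity scans and calibration)."""
        return dataclasses.replace(self, **kwargs)


_REQUIRED = ("name", "mw_g_per_mol", "logp", "fup", "bpr", "spec_pstc_ml_per_s_per_ml")

#: Short names of the bundled compound configs.
BUNDLED_COMPOUNDS = {"MTM": "mtm.yaml", "MTMSA-Trp": "mtmsa_trp.yaml"}


def _params_from_mapping(raw: Mapping) -> CompoundParams:
    missing = [k for k in _REQUIRED if k not in raw]
    if missing:
        raise CompoundValidationError(
            "compound config missing required fields: " + ", ".join(missing)
        )
    pka = raw.get("pka", [])
    return CompoundParams(
        name=str(raw["name"]),
        mw=float(raw["mw_g_per_mol"]),
        logp=float(raw["logp"]),
        solubility=float(raw["solubility_mg_per_ml"])
        if raw.get("solubility_mg_per_ml") is not None
        else None,
        solubility_ph=float(raw["solubility_ph"])
        if raw.get("solubility_ph") is not None
        else None,
        pka=tuple(float(v) for v in pka),
        fup={str(k): float(v) for k, v in dict(raw["fup"]).items()},
        bpr={str(k): float(v) for k, v in dict(raw["bpr"]).items()},
        spec_pstc=float(raw["spec_pstc_ml_per_s_per_ml"]),
    )


def load_compound(source: str | os.PathLike) -> CompoundParams:
    """Load and validate compound parameters.

    ``source`` is either the short name of a bundled compound (``"MTM"``,
    ``"MTMSA-Trp"``) or a path to a YAML config with the same schema.
    """
    name = str(source)
    if name in BUNDLED_COMPOUNDS:
        text = (
            resources.files("mithrapbpk")
            .joinpath("data/compounds")
            .joinpath(BUNDLED_COMPOUNDS[name])
            .read_text()
        )
    else:
        with open(source) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    if not isinstance(raw, Mapping):
        raise CompoundValidationError(f"compound config {source!r} did not parse to a mapping")
    return _params_from_mapping(raw)


def save_compound(params: CompoundParams, path: str | os.PathLike) -> None:
    """Write ``params`` back to a YAML config (round-trips with load_compound)."""
    raw = {
        "name": params.name,
        "mw_g_per_mol": params.mw,
        "logp": params.logp,
        "solubility_mg_per_ml": params.solubility,
        "solubility_ph": params.solubility_ph,
        "pka": list(params.pka),
        "fup": dict(params.fup),
        "bpr": dict(params.bpr),
        "spec_pstc_ml_per_s_per_ml": params.spec_pstc,
    }
    buf = io.StringIO()
    yaml.safe_dump(raw, buf, sort_keys=False)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
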