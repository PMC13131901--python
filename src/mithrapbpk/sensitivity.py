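"""One-at-a-time parameter sensitivity analysis (PSA) of the human model.

Each scanned parameter (BPR, fup or logP) is varied over a physiologically
plausible set while everything else — including the clearance input — is
held constant; Kp values are re-derived whenever logP or fup changes. The
study-condition scan sets are:

* BPR: {0.02, base, 1.0} — the monkey-adjusted lower value and a generally
  accepted upper-range assumption;
* fup: {base/10, base, base*10} — a 10-fold spread (capped at 1);
* logP: {base - log10(3), base, base + log10(3)} — a 3-fold change in the
  partition ratio P = 10^logP (the alternative reading, +/-3 logP units, is
  available via ``logp_mode="absolute"``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

from .compounds import CompoundParams
from .engine import ConcProfile, Regimen, build_model
from .kp import predict_kp
from .nca import auc_loglinear
from .physiology import SpeciesPhysiology

SCAN_PARAMETERS = ("bpr", "fup", "logp")


@dataclass(frozen=True)
class PsaPoint:
    parameter: str
    value: float
    profile: ConcProfile
    auc: float  # plasma AUC over the scan window, ng/mL*h


def default_scan_values(
    compound: CompoundParams,
    parameter: str,
    species: str = "human",
    logp_mode: str = "fold",
) -> list[float]:
    if parameter == "bpr":
        base = compound.bpr_for(species)
        return sorted({0.02, base, 1.0})
    if parameter == "fup":
        base = compound.fup_for(species)
        return sorted({base / 10.0, base, min(base * 10.0, 1.0)})
    if parameter == "logp":
        delta = math.log10(3.0) if logp_mode == "fold" else 3.0
        return [compound.logp - delta, compound.logp, compound.logp + delta]
    raise ValueError(f"unknown PSA parameter {parameter!r}; use one of {SCAN_PARAMETERS}")


def psa(
    compound: CompoundParams,
    parameter: str,
    values: Sequence[float],
    regimen: Regimen,
    physiology: SpeciesPhysiology,
    cl_input: float,
    species: str = "human",
    duration: float = 24.0,
    output_interval: float = 0.5,
    clearance_method: str = "allometric",
) -> list[PsaPoint]:
    """Run the scan; invalid values are skipped with a warning.

    ``cl_input`` is the human plasma clearance (mL/h) predicted by
    ``clearance_method`` (metadata only; the numeric value is what matters).
    """
    if parameter not in SCAN_PARAMETERS:
        raise ValueError(f"unknown PSA parameter {parameter!r}; use one of {SCAN_PARAMETERS}")
    points: list[PsaPoint] = []
    for value in values:
        try:
            candidate = compound
            kp_kwargs = {}
            if parameter == "bpr":
                if value <= 0:
                    raise ValueError("BPR must be > 0")
                candidate = compound.with_updates(bpr={**compound.bpr, species: value})
            elif parameter == "fup":
                if not 0.0 < value <= 1.0:
                    raise ValueError("fup must be in (0, 1]")
                candidate = compound.with_updates(fup={**compound.fup, species: value})
                kp_kwargs = {"fup": value}
            else:  # logp
                candidate = compound.with_updates(logp=value)
                kp_kwargs = {"logp": value}
            kp = predict_kp(candidate, physiology, species, **kp_kwargs)
            model = build_model(candidate, physiology, species, cl_input, kp)
            result = model.simulate(regimen, duration, output_interval=output_interval)
            profile = result.plasma_profile()
            points.append(
                PsaPoint(parameter=parameter, value=float(value), profile=profile,
                         auc=auc_loglinear(profile))
            )
        except ValueError as err:
            warnings.warn(f"PSA {parameter}={value!r} skipped: {err}", stacklevel=2)
    return points


def auc_range_ratio(points: Sequence[PsaPoint]) -> float:
    """Sensitivity summary for one scan: max AUC / min AUC across values."""
    if not points:
        raise ValueError("no PSA points")
    aucs = [p.auc for p in points]
    return max(aucs) / min(aucs)


def rank_parameters(scans: dict[str, Sequence[PsaPoint]]) -> list[tuple[str, float]]:
    """Parameters ordered from most to least influential by AUC range ratio."""
    return sorted(
        ((name, auc_range_ratio(points)) for name, points in scans.items()),
        key=lambda item: item[1],
        reverse=True,
    )
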