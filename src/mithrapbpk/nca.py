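"""Non-compartmental analysis of concentration-time profiles.

AUC to the last time point uses the log-linear trapezoidal rule: on each
interval where the concentration declines between two positive values the
log-trapezoid (C1 - C2) * dt / ln(C1/C2) is used (exact for
mono-exponential decay); rising, flat or zero-touching intervals use the
linear trapezoid. Observed systemic clearance is the model-free
CL = Dose / AUC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import ConcProfile


@dataclass(frozen=True)
class PKSummary:
    """NCA outputs for one profile."""

    auc_last: float  # ng/mL * h
    cl_per_kg: float | None = None  # mL/h/kg
    cl_absolute: float | None = None  # mL/h
    auc_inf: float | None = None
    lambda_z: float | None = None  # 1/h
    compound: str = ""
    species: str = ""
    dose: str = ""


def _interval_auc(t1: float, t2: float, c1: float, c2: float) -> float:
    dt = t2 - t1
    if c1 > 0 and 0 < c2 < c1:
        return (c1 - c2) * dt / np.log(c1 / c2)
    return 0.5 * (c1 + c2) * dt


def auc_loglinear(profile: ConcProfile, t_end: float | None = None) -> float:
    """AUC from the first sample to ``t_end`` (default: last sample)."""
    times = profile.times
    conc = profile.concentrations
    if t_end is not None:
        mask = times <= t_end + 1e-12
        times, conc = times[mask], conc[mask]
    if len(times) < 2:
        raise ValueError("need at least 2 samples at or before t_end for AUC")
    if np.any(np.diff(times) == 0):
        raise ValueError("duplicated timestamps are not allowed")
    total = 0.0
    for i in range(len(times) - 1):
        total += _interval_auc(times[i], times[i + 1], conc[i], conc[i + 1])
    return total


def terminal_rate_constant(profile: ConcProfile, n_points: int = 3) -> float:
    """Terminal log-linear slope from the last ``n_points`` positive samples."""
    mask = profile.concentrations > 0
    t = profile.times[mask][-n_points:]
    c = profile.concentrations[mask][-n_points:]
    if len(t) < 2:
        raise ValueError("need at least 2 positive samples for lambda_z")
    slope = np.polyfit(t, np.log(c), 1)[0]
    if slope >= 0:
        raise ValueError("terminal phase is not declining; lambda_z undefined")
    return -slope


def observed_clearance(dose_per_kg: float, auc: float, dose_unit: str = "ng/kg") -> float:
    """CL_obs = Dose / AUC, in mL/h/kg.

    ``dose_per_kg`` in ``dose_unit`` (ng/kg, ug/kg or mg/kg); ``auc`` in
    ng/mL * h.
    """
    scale = {"ng/kg": 1.0, "ug/kg": 1.0e3, "mg/kg": 1.0e6}
    if dose_unit not in scale:
        raise ValueError(f"unknown dose unit {dose_unit!r}")
    if dose_per_kg <= 0:
        raise ValueError("dose must be positive")
    if auc <= 0:
        raise ValueError("AUC must be positive")
    return dose_per_kg * scale[dose_unit] / auc


def summarize(
    profile: ConcProfile,
    dose_per_kg: float,
    body_weight: float,
    dose_unit: str = "ng/kg",
    t_end: float | None = None,
    extrapolate: bool = False,
) -> PKSummary:
    """NCA summary of one profile: AUC_last, CL, optional AUC_inf."""
    auc = auc_loglinear(profile, t_end=t_end)
    cl_kg = observed_clearance(dose_per_kg, auc, dose_unit=dose_unit)
    auc_inf = lz = None
    if extrapolate:
        lz = terminal_rate_constant(profile)
        c_last = profile.concentrations[profile.concentrations > 0][-1]
        auc_inf = auc + c_last / lz
    return PKSummary(
        auc_last=auc,
        cl_per_kg=cl_kg,
        cl_absolute=cl_kg * body_weight,
        auc_inf=auc_inf,
        lambda_z=lz,
        compound=profile.compound,
        species=profile.species,
        dose=profile.dose,
    )
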