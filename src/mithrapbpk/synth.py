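"""Synthetic "observed" concentration-time studies.

The raw preclinical/clinical profiles behind the printed AUC summaries are
not public, so every pipeline stage is exercised against synthetic studies:
the engine simulates the stated regimen with the compound's own parameters,
optionally with the clearance solved so that the noise-free log-trapezoid
AUC over the sampling window hits a stated target AUC, and multiplicative
log-normal noise (the standard LC-MS/MS bioanalytical error model) is
applied with a seeded generator. Samples below the LLOQ are censored to 0.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .compounds import CompoundParams
from .engine import ConcProfile, Regimen, build_model
from .kp import predict_kp
from .nca import auc_loglinear
from .physiology import SpeciesPhysiology, get_physiology

#: Default serial-sampling design (h) for preclinical IV PK studies.
DEFAULT_SAMPLING_H = (0.083, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 24.0)

#: Default bioanalytical coefficient of variation.
DEFAULT_NOISE_CV = 0.15

_CL_BOUNDS_ML_H = (1e-4, 1e9)


def _noise_free_profile(
    compound: CompoundParams,
    physiology: SpeciesPhysiology,
    species: str,
    regimen: Regimen,
    sampling_times: np.ndarray,
    cl_input: float,
) -> ConcProfile:
    kp = predict_kp(compound, physiology, species)
    model = build_model(compound, physiology, species, cl_input, kp)
    result = model.simulate(regimen, duration=float(sampling_times[-1]), times=sampling_times)
    return result.plasma_profile()


def solve_clearance_for_auc(
    compound: CompoundParams,
    physiology: SpeciesPhysiology,
    species: str,
    regimen: Regimen,
    sampling_times: Sequence[float],
    target_auc: float,
    rtol: float = 1e-4,
) -> float:
    """Plasma clearance (mL/h) whose noise-free profile hits ``target_auc``.

    The AUC over a fixed window decreases monotonically with clearance, so
    the root is bracketed on log10(CL) and found by Brent's method.
    """
    times = np.asarray(sampling_times, dtype=float)

    def auc_gap(log10_cl: float) -> float:
        profile = _noise_free_profile(compound, physiology, species, regimen,
                                      times, 10.0 ** log10_cl)
        return auc_loglinear(profile) - target_auc

    lo, hi = np.log10(_CL_BOUNDS_ML_H)
    if auc_gap(lo) < 0 or auc_gap(hi) > 0:
        raise ValueError(
            f"target AUC {target_auc:g} unreachable within clearance bounds "
            f"{_CL_BOUNDS_ML_H}"
        )
    root = brentq(auc_gap, lo, hi, xtol=1e-10, rtol=1e-12)
    cl = float(10.0 ** root)
    achieved = target_auc + auc_gap(root)
    if abs(achieved / target_auc - 1.0) > 5e-3:
        raise ValueError(
            f"clearance solve landed at AUC {achieved:g}, outside 0.5% of "
            f"target {target_auc:g}"
        )
    return cl


def make_study(
    compound: CompoundParams,
    species: str,
    regimen: Regimen,
    sampling_times: Sequence[float] = DEFAULT_SAMPLING_H,
    noise_cv: float = DEFAULT_NOISE_CV,
    seed: int = 0,
    target_auc: float | None = None,
    cl_input: float | None = None,
    lloq: float = 0.0,
    physiology: SpeciesPhysiology | None = None,
) -> tuple[ConcProfile, float]:
    """Generate one synthetic observed study.

    Returns ``(profile, cl_input)`` — the noisy profile and the clearance
    actually used (solved when ``target_auc`` is given, else ``cl_input``).
    Noise is multiplicative log-normal with coefficient of variation
    ``noise_cv`` (median-preserving: sigma = sqrt(ln(1 + cv^2))).
    """
    times = np.asarray(sampling_times, dtype=float)
    if times.ndim != 1 or len(times) == 0 or times[0] <= 0 or np.any(np.diff(times) <= 0):
        raise ValueError("sampling times must be positive and strictly increasing")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    if (target_auc is None) == (cl_input is None):
        raise ValueError("provide exactly one of target_auc or cl_input")
    physiology = physiology or get_physiology(species)
    if target_auc is not None:
        cl_input = solve_clearance_for_auc(
            compound, physiology, species, regimen, times, target_auc
        )
    profile = _noise_free_profile(compound, physiology, species, regimen, times, cl_input)
    conc = profile.concentrations.copy()
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(noise_cv ** 2))
        conc = conc * np.exp(sigma * rng.standard_normal(conc.shape))
    conc[conc < lloq] = 0.0
    noisy = ConcProfile(
        times=times,
        concentrations=conc,
        matrix="plasma",
        compound=compound.name,
        species=species,
        dose=profile.dose,
    )
    return noisy, float(cl_input)
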