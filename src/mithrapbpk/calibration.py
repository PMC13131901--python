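"""SpecPStc calibration against mouse plasma PK (the middle-out step).

The single permeability parameter is optimized on a log10 scale by bounded
scalar minimization of the relative-weighted least squares objective

    SS = sum_i (C_obs,i - C_pred,i)^2 / C_pred,i^2

(1/Y-hat^2 weighting), with clearance held fixed at its NCA value. The two
study compounds' optima differ by two orders of magnitude, which is why the
search runs in log space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .compounds import CompoundParams
from .engine import ConcProfile, Regimen, build_model
from .kp import predict_kp
from .physiology import SpeciesPhysiology


@dataclass(frozen=True)
class FitReport:
    """Outcome of a SpecPStc fit."""

    spec_pstc: float  # mL/s per mL cell volume
    objective: float
    at_bound: bool
    bounds: tuple[float, float]
    table: pd.DataFrame  # time_h, observed, predicted

    @property
    def converged(self) -> bool:
        return not self.at_bound


def _objective(c_obs: np.ndarray, c_pred: np.ndarray) -> float:
    pred = np.where(c_pred > 0, c_pred, np.nan)
    resid = (c_obs - pred) ** 2 / pred ** 2
    val = float(np.nansum(resid))
    if not np.isfinite(val) or np.all(np.isnan(resid)):
        return np.inf
    return val


def fit_spec_pstc(
    observed: ConcProfile,
    compound: CompoundParams,
    physiology: SpeciesPhysiology,
    regimen: Regimen,
    cl_input: float,
    species: str = "mouse",
    bounds: tuple[float, float] = (1e-6, 1.0),
    xatol: float = 1e-4,
) -> FitReport:
    """Fit SpecPStc to an observed plasma profile.

    ``cl_input`` is the (fixed) plasma clearance in mL/h, normally the NCA
    value Dose/AUC_obs. ``bounds`` bracket SpecPStc in mL/s/mL; the search
    runs on log10(SpecPStc) with absolute tolerance ``xatol`` log10 units.
    """
    if len(observed) < 4:
        raise ValueError("need at least 4 observed samples to fit SpecPStc")
    if bounds[0] <= 0 or bounds[1] <= bounds[0]:
        raise ValueError("bounds must be positive and increasing")
    kp = predict_kp(compound, physiology, species)
    t_obs = observed.times
    c_obs = observed.concentrations
    duration = float(t_obs[-1])

    def predict(log10_pstc: float) -> np.ndarray:
        candidate = compound.with_updates(spec_pstc=10.0 ** log10_pstc)
        model = build_model(candidate, physiology, species, cl_input, kp)
        result = model.simulate(regimen, duration=duration, times=t_obs)
        return result.plasma_profile().concentrations

    def objective(log10_pstc: float) -> float:
        return _objective(c_obs, predict(log10_pstc))

    lo, hi = np.log10(bounds[0]), np.log10(bounds[1])
    if not np.isfinite(objective(0.5 * (lo + hi))):
        raise RuntimeError(
            "objective non-finite across the search bracket; check observed data "
            "and clearance input"
        )
    res = minimize_scalar(objective, bounds=(lo, hi), method="bounded",
                          options={"xatol": xatol})
    best = float(10.0 ** res.x)
    at_bound = (res.x - lo) < 2 * xatol or (hi - res.x) < 2 * xatol
    table = pd.DataFrame(
        {"time_h": t_obs, "observed": c_obs, "predicted": predict(res.x)}
    )
    return FitReport(
        spec_pstc=best,
        objective=float(res.fun),
        at_bound=bool(at_bound),
        bounds=bounds,
        table=table,
    )
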