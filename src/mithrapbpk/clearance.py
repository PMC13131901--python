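"""Human clearance projection by three interspecies methods.

Method 1 — additional clearance: in each preclinical species the observed
systemic clearance is split into renal-filtration clearance CL_R = fup * GFR
and a residual CL_add = CL_obs - CL_R; the percentage %CL_add =
CL_add / CL_obs * 100 is geometric-averaged across mouse, rat and monkey and
applied in reverse to the predicted human renal-filtration clearance:
CL_human = CL_R,human / (100 - avg %CL_add) * 100.

Method 2 — allometric scaling: fit CL = a * BW^b on log-log absolute
clearances across species and extrapolate to 50 kg.

Method 3 — single-species scaling from monkey with a fixed exponent of
0.75: CL_human = CL_monkey * (BW_human / BW_monkey)^0.75.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm

#: Floor applied to %CL_add values of exactly zero so the geometric mean
#: remains defined.
PCT_CL_ADD_FLOOR = 0.1


@dataclass(frozen=True)
class ClearanceRecord:
    """Observed clearance decomposition for one preclinical species."""

    species: str
    cl_obs: float  # mL/h/kg (or any unit, used consistently)
    cl_renal: float  # same unit
    cl_add: float
    pct_cl_add: float

    @classmethod
    def from_observed(cls, species: str, cl_obs: float, fup: float, gfr: float) -> "ClearanceRecord":
        """Decompose CL_obs given fup and GFR (same units as cl_obs).

        If renal filtration alone exceeds the observed clearance the
        additional component is clamped to zero with a warning.
        """
        cl_r = renal_filtration_cl(fup, gfr)
        cl_add = cl_obs - cl_r
        if cl_add < 0:
            warnings.warn(
                f"{species}: CL_obs ({cl_obs:.4g}) below renal filtration "
                f"({cl_r:.4g}); clamping CL_add to 0",
                stacklevel=2,
            )
            cl_add = 0.0
        pct = cl_add / cl_obs * 100.0
        return cls(species=species, cl_obs=cl_obs, cl_renal=cl_r, cl_add=cl_add, pct_cl_add=pct)


@dataclass(frozen=True)
class AllometricFit:
    """Power-law clearance fit CL = a * BW^b with log-scale diagnostics."""

    a: float
    b: float
    r_squared: float
    points: tuple[tuple[float, float], ...]

    def predict(self, bw: float) -> float:
        if bw <= 0:
            raise ValueError("body weight must be positive")
        return self.a * bw ** self.b


def renal_filtration_cl(fup: float, gfr: float) -> float:
    """Renal-filtration clearance CL_R = fup * GFR."""
    if not 0.0 < fup <= 1.0:
        raise ValueError(f"fup={fup} must be in (0, 1]")
    if gfr <= 0:
        raise ValueError("GFR must be positive")
    return fup * gfr


def geometric_mean(values: Sequence[float]) -> float:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0 or np.any(arr <= 0):
        raise ValueError("geometric mean requires positive values")
    return float(np.exp(np.mean(np.log(arr))))


def additional_clearance_human(
    records: Sequence[ClearanceRecord],
    fup_human: float,
    gfr_human: float,
) -> float:
    """Method-1 human clearance from preclinical %CL_add records.

    Returns CL_human in the units of ``gfr_human`` (mL/h when GFR is mL/h).
    """
    if not records:
        raise ValueError("need at least one preclinical clearance record")
    cl_r_human = renal_filtration_cl(fup_human, gfr_human)
    if all(r.pct_cl_add == 0.0 for r in records):
        # filtration-only limit: no additional clearance anywhere
        return cl_r_human
    pcts = []
    for r in records:
        if not 0.0 <= r.pct_cl_add < 100.0:
            raise ValueError(
                f"{r.species}: %CL_add={r.pct_cl_add:.4g} outside [0, 100)"
            )
        pct = r.pct_cl_add
        if pct == 0.0:
            warnings.warn(
                f"{r.species}: %CL_add is 0; flooring at {PCT_CL_ADD_FLOOR}% for the "
                "geometric mean",
                stacklevel=2,
            )
            pct = PCT_CL_ADD_FLOOR
        pcts.append(pct)
    avg = geometric_mean(pcts)
    if avg >= 100.0:
        raise ValueError(f"geometric-mean %CL_add = {avg:.4g} >= 100; method undefined")
    return cl_r_human / (100.0 - avg) * 100.0


def allometric_fit(points: Sequence[tuple[float, float]]) -> AllometricFit:
    """OLS fit of ln CL on ln BW over (BW kg, absolute CL) points."""
    if len(points) < 2:
        raise ValueError("need at least 2 (BW, CL) points")
    bw = np.asarray([p[0] for p in points], dtype=float)
    cl = np.asarray([p[1] for p in points], dtype=float)
    if np.any(bw <= 0) or np.any(cl <= 0):
        raise ValueError("body weights and clearances must be positive")
    if len(np.unique(bw)) < 2:
        raise ValueError("allometric fit is singular: all body weights identical")
    X = sm.add_constant(np.log(bw))
    fit = sm.OLS(np.log(cl), X).fit()
    r2 = 1.0 if len(points) == 2 else float(fit.rsquared)
    return AllometricFit(
        a=float(np.exp(fit.params[0])),
        b=float(fit.params[1]),
        r_squared=r2,
        points=tuple((float(b_), float(c_)) for b_, c_ in zip(bw, cl)),
    )


def allometric_predict(fit: AllometricFit, bw: float) -> float:
    """Extrapolate the fitted power law to ``bw`` kg."""
    return fit.predict(bw)


def single_species_scale(
    cl_monkey: float,
    bw_monkey: float,
    bw_human: float,
    exponent: float = 0.75,
) -> float:
    """Fixed-exponent scaling of monkey absolute clearance to human."""
    if cl_monkey <= 0 or bw_monkey <= 0 or bw_human <= 0:
        raise ValueError("clearance and body weights must be positive")
    return cl_monkey * (bw_human / bw_monkey) ** exponent
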