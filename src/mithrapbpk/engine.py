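"""Whole-body permeability-limited PBPK simulator for IV regimens.

Model structure
---------------
Venous blood -> lung -> arterial blood -> tissues -> venous blood, with the
liver receiving the hepatic artery plus the portal outflow of gut and
spleen. Every tissue is split into an extracellular sub-compartment
(vascular + interstitial, flow-connected to arterial blood) and an
intracellular sub-compartment reached through a permeability term:

    dA_ec,t/dt = Q_t*(C_art - C_ec,t) - fup * PS_t*(C_ec,t - C_ic,t / Kp_t)
    dA_ic,t/dt =                        fup * PS_t*(C_ec,t - C_ic,t / Kp_t)

with PS_t = SpecPStc * V_ic,t (the specific permeability-surface-area
product scaled by intracellular volume) and Kp_t the tissue:plasma partition
coefficient that sets the intracellular:extracellular ratio at equilibrium.
Passive transmembrane flux is carried by unbound drug, so the exchange rate
scales with the plasma unbound fraction fup (``permeability_driver=
"unbound"``, the default); this leaves the equilibrium ratio untouched but
makes cellular uptake of highly protein-bound compounds slow — the
behaviour that distinguishes MTMSA-Trp (fup 0.1%) from MTM. Setting
``permeability_driver="total"`` drops the fup factor.
Flow terms carry blood concentrations; the plasma concentration at the
sampling site is C_plasma = C_venous_blood / BPR (sign convention
C_blood = BPR * C_plasma). Systemic clearance is applied to venous plasma:
elimination rate = CL_input * C_plasma. Doses are IV: boluses are
instantaneous inputs into venous blood, infusions zero-order inputs over
the stated duration.

Because every term is linear and time-invariant, the system is propagated
exactly (to machine precision) with matrix exponentials over the
piecewise-constant dosing segments rather than with an adaptive ODE
stepper; the amount vector therefore conserves mass exactly and stays
non-negative (the rate matrix is Metzler and column-conservative once the
cleared-amount state is included).

Units: time h, volume mL, amount ng, concentration ng/mL, flow and
clearance mL/h.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .compounds import CompoundParams
from .kp import KpSet
from .physiology import PORTAL_TISSUES, SpeciesPhysiology

_DOSE_UNIT_NG_PER_KG = {"ng/kg": 1.0, "ug/kg": 1.0e3, "mg/kg": 1.0e6}


class SimulationError(RuntimeError):
    """Raised when state propagation produces non-finite amounts."""


@dataclass(frozen=True)
class DoseEvent:
    """One IV dose: ``duration == 0`` is a bolus, otherwise a zero-order infusion."""

    start: float  # h
    amount_per_kg: float  # ng/kg
    duration: float = 0.0  # h

    def __post_init__(self) -> None:
        if self.amount_per_kg <= 0:
            raise ValueError("dose amount must be positive")
        if self.start < 0 or self.duration < 0:
            raise ValueError("dose start and duration must be non-negative")

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass(frozen=True)
class Regimen:
    events: tuple[DoseEvent, ...]

    def __post_init__(self) -> None:
        events = tuple(sorted(self.events, key=lambda e: e.start))
        object.__setattr__(self, "events", events)
        for a, b in zip(events, events[1:]):
            if a.duration > 0 and b.start < a.end:
                raise ValueError("infusion windows must not overlap later doses")

    @classmethod
    def bolus(
        cls,
        amount: float,
        unit: str = "mg/kg",
        n_doses: int = 1,
        interval_h: float = 24.0,
        start: float = 0.0,
    ) -> "Regimen":
        return cls.infusion(amount, unit, duration_h=0.0, n_doses=n_doses,
                            interval_h=interval_h, start=start)

    @classmethod
    def infusion(
        cls,
        amount: float,
        unit: str = "ug/kg",
        duration_h: float = 1.0,
        n_doses: int = 1,
        interval_h: float = 24.0,
        start: float = 0.0,
    ) -> "Regimen":
        try:
            scale = _DOSE_UNIT_NG_PER_KG[unit]
        except KeyError:
            raise ValueError(
                f"unknown dose unit {unit!r}; use one of {sorted(_DOSE_UNIT_NG_PER_KG)}"
            ) from None
        events = tuple(
            DoseEvent(start=start + i * interval_h, amount_per_kg=amount * scale,
                      duration=duration_h)
            for i in range(n_doses)
        )
        return cls(events=events)

    def total_amount_per_kg(self) -> float:
        return sum(e.amount_per_kg for e in self.events)

    def scaled(self, factor: float) -> "Regimen":
        return Regimen(tuple(
            DoseEvent(e.start, e.amount_per_kg * factor, e.duration) for e in self.events
        ))


@dataclass(frozen=True)
class ConcProfile:
    """A time-stamped concentration profile for one matrix (plasma/blood/tissue)."""

    times: np.ndarray  # h, strictly increasing
    concentrations: np.ndarray  # ng/mL, >= 0
    matrix: str = "plasma"
    compound: str = ""
    species: str = ""
    dose: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        conc = np.asarray(self.concentrations, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "concentrations", conc)
        if times.ndim != 1 or times.shape != conc.shape:
            raise ValueError("times and concentrations must be 1-D and equal length")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(conc < 0):
            raise ValueError("concentrations must be non-negative")

    def __len__(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.times,
                "conc_ng_per_mL": self.concentrations,
                "matrix": self.matrix,
                "compound": self.compound,
                "species": self.species,
                "dose": self.dose,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ConcProfile":
        first = frame.iloc[0]
        return cls(
            times=frame["time_h"].to_numpy(dtype=float),
            concentrations=frame["conc_ng_per_mL"].to_numpy(dtype=float),
            matrix=str(first.get("matrix", "plasma")),
            compound=str(first.get("compound", "")),
            species=str(first.get("species", "")),
            dose=str(first.get("dose", "")),
        )

    @classmethod
    def read_csv(cls, path) -> "ConcProfile":
        return cls.from_frame(pd.read_csv(path))


class PBPKModel:
    """Assembled linear PBPK system for one compound/species/clearance."""

    def __init__(
        self,
        compound: CompoundParams,
        physiology: SpeciesPhysiology,
        species: str,
        cl_input: float,
        kp: KpSet,
        ps_reference: str = "intracellular",
        permeability_driver: str = "unbound",
    ) -> None:
        if cl_input < 0:
            raise ValueError("clearance must be non-negative")
        if ps_reference not in ("intracellular", "total"):
            raise ValueError("ps_reference must be 'intracellular' or 'total'")
        if permeability_driver not in ("unbound", "total"):
            raise ValueError("permeability_driver must be 'unbound' or 'total'")
        for t in physiology.tissue_names:
            if t not in kp.values:
                raise KeyError(f"missing Kp for tissue {t!r}")
        self.compound = compound
        self.physiology = physiology
        self.species = species
        self.cl_input = float(cl_input)  # plasma clearance, mL/h
        self.kp = kp
        self.bpr = compound.bpr_for(species)

        tissues = physiology.tissues
        self.tissue_names = physiology.tissue_names
        n = 3 + 2 * len(tissues)
        self.i_ven, self.i_art, self.i_clr = 0, 1, 2
        self.i_ec = {t.name: 3 + 2 * k for k, t in enumerate(tissues)}
        self.i_ic = {t.name: 4 + 2 * k for k, t in enumerate(tissues)}

        vol = np.zeros(n)
        vol[self.i_ven] = physiology.venous_blood_volume
        vol[self.i_art] = physiology.arterial_blood_volume
        vol[self.i_clr] = 1.0  # unused; cleared state is an amount sink
        for t in tissues:
            vol[self.i_ec[t.name]] = t.extracellular_volume
            vol[self.i_ic[t.name]] = t.intracellular_volume
        self.volumes = vol

        A = np.zeros((n, n))
        co = physiology.cardiac_output

        def add_flow(src: int, dst: int, q: float) -> None:
            A[src, src] -= q / vol[src]
            A[dst, src] += q / vol[src]

        # venous -> lung -> arterial
        add_flow(self.i_ven, self.i_ec["lung"], co)
        add_flow(self.i_ec["lung"], self.i_art, co)
        # arterial -> tissues -> venous (portal tissues drain into the liver
        # when one is present; reduced physiologies without a liver drain
        # everything straight to venous blood)
        has_liver = "liver" in self.i_ec
        liver_out = 0.0
        for t in tissues:
            if t.name == "lung":
                continue
            add_flow(self.i_art, self.i_ec[t.name], t.blood_flow)
            if has_liver and t.name in PORTAL_TISSUES:
                add_flow(self.i_ec[t.name], self.i_ec["liver"], t.blood_flow)
                liver_out += t.blood_flow
            elif t.name == "liver":
                liver_out += t.blood_flow
            else:
                add_flow(self.i_ec[t.name], self.i_ven, t.blood_flow)
        if has_liver:
            add_flow(self.i_ec["liver"], self.i_ven, liver_out)
        # extracellular <-> intracellular permeability exchange; flux carried
        # by unbound drug unless permeability_driver == "total"
        fup_scale = compound.fup_for(species) if permeability_driver == "unbound" else 1.0
        ps_per_ml = compound.spec_pstc * 3600.0  # mL/h per mL reference volume
        self.permeability_driver = permeability_driver
        self.ps = {}
        for t in tissues:
            ref = t.intracellular_volume if ps_reference == "intracellular" else t.total_volume
            ps = ps_per_ml * ref * fup_scale
            self.ps[t.name] = ps
            kp_t = kp[t.name]
            iec, iic = self.i_ec[t.name], self.i_ic[t.name]
            A[iec, iec] -= ps / vol[iec]
            A[iic, iec] += ps / vol[iec]
            A[iic, iic] -= ps / (kp_t * vol[iic])
            A[iec, iic] += ps / (kp_t * vol[iic])
        # systemic clearance from venous plasma (C_plasma = C_ven / BPR)
        cl_blood = self.cl_input / self.bpr
        A[self.i_ven, self.i_ven] -= cl_blood / vol[self.i_ven]
        A[self.i_clr, self.i_ven] += cl_blood / vol[self.i_ven]

        self.A = A
        self.n_state = n
        self._input = np.zeros(n)
        self._input[self.i_ven] = 1.0

    # -- simulation -------------------------------------------------------

    def simulate(
        self,
        regimen: Regimen,
        duration: float,
        output_interval: float = 0.5,
        times: Iterable[float] | None = None,
    ) -> "SimulationResult":
        """Simulate ``regimen`` and sample the state on an output grid.

        ``times`` overrides the regular grid (used to evaluate predictions
        exactly at observed sampling times). The grid spans 0..duration at
        ``output_interval`` spacing otherwise.
        """
        if duration <= 0:
            raise ValueError("duration must be positive")
        if times is None:
            n_steps = int(round(duration / output_interval))
            grid = np.linspace(0.0, n_steps * output_interval, n_steps + 1)
        else:
            grid = np.asarray(sorted(set(float(t) for t in times)))
            if grid.size == 0 or grid[0] < 0:
                raise ValueError("output times must be non-negative")
        bw = self.physiology.body_weight
        boluses: dict[float, float] = {}
        windows: list[tuple[float, float, float]] = []  # (start, end, ng/h)
        for e in regimen.events:
            amount = e.amount_per_kg * bw
            if e.duration == 0:
                boluses[e.start] = boluses.get(e.start, 0.0) + amount
            else:
                windows.append((e.start, e.end, amount / e.duration))

        breaks = {0.0, float(grid[-1])}
        breaks.update(grid.tolist())
        breaks.update(boluses)
        for s, end, _ in windows:
            breaks.update((s, end))
        breaks = sorted(b for b in breaks if b <= grid[-1] + 1e-12)

        x = np.zeros(self.n_state)
        administered = 0.0
        cache: dict[tuple[float, float], np.ndarray] = {}
        grid_set = {round(t, 10) for t in grid.tolist()}
        states, admin_series, out_times = [], [], []

        def record(t: float) -> None:
            if round(t, 10) in grid_set:
                out_times.append(t)
                states.append(x.copy())
                admin_series.append(administered)

        t_prev = breaks[0]
        if t_prev in boluses:
            x[self.i_ven] += boluses[t_prev]
            administered += boluses[t_prev]
        record(t_prev)
        naug = self.n_state + 1
        for t_next in breaks[1:]:
            h = t_next - t_prev
            if h > 1e-13:
                rate = sum(r for s, end, r in windows if s <= t_prev + 1e-12 and t_next <= end + 1e-12
                           and t_prev + 1e-12 < end)
                key = (round(h, 12), rate)
                if key not in cache:
                    M = np.zeros((naug, naug))
                    M[: self.n_state, : self.n_state] = self.A * h
                    M[: self.n_state, -1] = self._input * rate * h
                    cache[key] = expm(M)
                E = cache[key]
                x = E[: self.n_state, : self.n_state] @ x + E[: self.n_state, -1]
                administered += rate * h
            if t_next in boluses and t_next > breaks[0]:
                x[self.i_ven] += boluses[t_next]
                administered += boluses[t_next]
            if not np.all(np.isfinite(x)):
                raise SimulationError(
                    f"non-finite state at t={t_next} h (segment length {h} h)"
                )
            record(t_next)
            t_prev = t_next
        return SimulationResult(
            model=self,
            times=np.asarray(out_times),
            states=np.vstack(states),
            administered=np.asarray(admin_series),
            regimen=regimen,
        )


@dataclass(frozen=True)
class SimulationResult:
    """Sampled state trajectories plus convenience concentration accessors."""

    model: PBPKModel
    times: np.ndarray  # h
    states: np.ndarray  # (n_times, n_state) amounts in ng
    administered: np.ndarray  # cumulative input, ng
    regimen: Regimen = field(repr=False, default=None)

    def _meta(self) -> dict:
        dose = ""
        if self.regimen is not None and self.regimen.events:
            e = self.regimen.events[0]
            dose = f"{e.amount_per_kg:g} ng/kg" + (
                f" {e.duration:g}h-infusion" if e.duration else " bolus"
            )
        return {
            "compound": self.model.compound.name,
            "species": self.model.species,
            "dose": dose,
        }

    @property
    def cleared(self) -> np.ndarray:
        return self.states[:, self.model.i_clr]

    @property
    def body_burden(self) -> np.ndarray:
        burden = self.states.sum(axis=1) - self.cleared
        return burden

    def plasma_profile(self) -> ConcProfile:
        c_blood = self.states[:, self.model.i_ven] / self.model.volumes[self.model.i_ven]
        return ConcProfile(
            times=self.times,
            concentrations=c_blood / self.model.bpr,
            matrix="plasma",
            **self._meta(),
        )

    def blood_profile(self) -> ConcProfile:
        c_blood = self.states[:, self.model.i_ven] / self.model.volumes[self.model.i_ven]
        return ConcProfile(times=self.times, concentrations=c_blood,
                           matrix="blood", **self._meta())

    def tissue_profile(self, tissue: str) -> ConcProfile:
        m = self.model
        if tissue not in m.i_ec:
            raise KeyError(f"no tissue {tissue!r} in model")
        spec = m.physiology.tissue(tissue)
        amounts = self.states[:, m.i_ec[tissue]] + self.states[:, m.i_ic[tissue]]
        return ConcProfile(times=self.times, concentrations=amounts / spec.total_volume,
                           matrix=tissue, **self._meta())

    def tissue_profiles(self) -> Mapping[str, ConcProfile]:
        return {t: self.tissue_profile(t) for t in self.model.tissue_names}


def build_model(
    compound: CompoundParams,
    physiology: SpeciesPhysiology,
    species: str,
    cl_input: float,
    kp: KpSet,
    ps_reference: str = "intracellular",
    permeability_driver: str = "unbound",
) -> PBPKModel:
    """Assemble the linear PBPK system (see module docstring for structure)."""
    return PBPKModel(compound, physiology, species, cl_input, kp,
                     ps_reference, permeability_driver)


def simulate(
    model: PBPKModel,
    regimen: Regimen,
    duration: float,
    output_interval: float = 0.5,
    times: Iterable[float] | None = None,
) -> SimulationResult:
    return model.simulate(regimen, duration, output_interval=output_interval, times=times)
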