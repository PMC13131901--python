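import numpy as np
import pytest

from mithrapbpk.compounds import CompoundParams
from mithrapbpk.engine import ConcProfile, DoseEvent, Regimen, build_model
from mithrapbpk.kp import KpSet, predict_kp
from mithrapbpk.nca import auc_loglinear
from mithrapbpk.physiology import SpeciesPhysiology, TissueSpec, get_physiology


def _dense_times(t_end, n=400):
    """Output grid resolving the post-bolus mixing transient (log-spaced)."""
    return np.unique(np.concatenate([[0.0], np.geomspace(1e-4, t_end, n)]))


def _random_compound(rng):
    return CompoundParams(
        name="rand",
        mw=1000.0,
        logp=float(rng.uniform(-1, 3)),
        solubility=1.0,
        solubility_ph=7.0,
        pka=(),
        fup={s: float(rng.uniform(0.001, 1.0)) for s in ("mouse", "rat", "monkey", "human")},
        bpr={s: float(rng.uniform(0.1, 1.5)) for s in ("mouse", "rat", "monkey", "human")},
        spec_pstc=float(10 ** rng.uniform(-5, -1)),
    )


def test_mass_balance_random_draws():
    """Administered dose equals body burden plus cleared amount (<0.1%) at
    every output time, across 20 random parameter draws."""
    rng = np.random.default_rng(42)
    species_cycle = ("mouse", "rat", "monkey", "human")
    for i in range(20):
        species = species_cycle[i % 4]
        phys = get_physiology(species)
        compound = _random_compound(rng)
        kp = predict_kp(compound, phys, species)
        cl = float(rng.uniform(0, 5)) * phys.body_weight * 60.0
        model = build_model(compound, phys, species, cl, kp)
        res = model.simulate(Regimen.bolus(1.0, "mg/kg"), 24.0, 0.5)
        balance = res.body_burden + res.cleared
        assert np.allclose(balance, res.administered, rtol=1e-3)
        assert np.all(res.states >= -1e-9 * res.administered[-1])


def test_zero_clearance_conserves_mass(mtm, mouse):
    kp = predict_kp(mtm, mouse, "mouse")
    model = build_model(mtm, mouse, "mouse", 0.0, kp)
    res = model.simulate(Regimen.bolus(2.0, "mg/kg"), 48.0, 1.0)
    assert np.allclose(res.body_burden, res.administered, rtol=1e-9)
    assert np.allclose(res.cleared, 0.0)


def test_dose_linearity(mtm, human):
    kp = predict_kp(mtm, human, "human")
    cl = 5000.0
    model = build_model(mtm, human, "human", cl, kp)
    reg = Regimen.infusion(13.0, "ug/kg", duration_h=6.0)
    lo = model.simulate(reg, 24.0, 0.5).plasma_profile()
    hi = model.simulate(reg.scaled(2.0), 24.0, 0.5).plasma_profile()
    assert np.allclose(hi.concentrations, 2.0 * lo.concentrations, rtol=1e-9)


def test_high_permeability_reaches_kp_equilibrium(mtm, mouse):
    """PS -> large, CL = 0: intracellular:extracellular ratio approaches Kp."""
    fast = mtm.with_updates(spec_pstc=10.0)
    kp = predict_kp(fast, mouse, "mouse")
    model = build_model(fast, mouse, "mouse", 0.0, kp, permeability_driver="total")
    res = model.simulate(Regimen.bolus(2.0, "mg/kg"), 48.0, 1.0)
    for name in ("liver", "muscle", "adipose"):
        iec, iic = model.i_ec[name], model.i_ic[name]
        c_ec = res.states[-1, iec] / model.volumes[iec]
        c_ic = res.states[-1, iic] / model.volumes[iic]
        assert c_ic / c_ec == pytest.approx(kp[name], rel=1e-3)


def test_degenerate_model_matches_one_compartment_closed_form():
    """Single rest-of-body tissue with negligible volume and no permeability:
    plasma follows C_p(t) = Dose/(BPR*V_blood) * exp(-CL*t/(BPR*V_blood))."""
    bw = 1.0
    phys = SpeciesPhysiology(
        species="human",
        body_weight=bw,
        gfr=100.0,
        cardiac_output=10000.0,
        blood_volume=100.0,
        tissues=(
            TissueSpec("lung", 10000.0, 1e-3, 0.5),
            TissueSpec("rest", 10000.0, 1e-3, 0.5),
        ),
    )
    bpr = 0.7
    compound = CompoundParams(
        name="onecomp", mw=500.0, logp=0.0, solubility=1.0, solubility_ph=7.0,
        pka=(), fup={"human": 0.5}, bpr={"human": bpr}, spec_pstc=1e-12,
    )
    cl = 20.0  # mL/h plasma clearance
    kp = KpSet(values={"lung": 1.0, "rest": 1.0}, fut={"lung": 1.0, "rest": 1.0})
    model = build_model(compound, phys, "human", cl, kp)
    res = model.simulate(Regimen.bolus(1.0, "mg/kg"), 10.0, 0.25)
    dose_ng = 1.0e6 * bw
    v_app = bpr * phys.blood_volume  # apparent plasma volume, mL
    expected = dose_ng / v_app * np.exp(-cl * res.times / v_app)
    # skip t=0: the bolus enters the venous pool and mixes with arterial
    # blood within the (fast) circulation; the closed form assumes
    # instantaneous whole-blood mixing
    assert np.allclose(res.plasma_profile().concentrations[1:], expected[1:],
                       rtol=1e-3)


@pytest.mark.parametrize("species,compound_fixture", [
    ("mouse", "mtm"), ("rat", "mtm"), ("monkey", "mtm"), ("human", "mtm"),
    ("mouse", "mtmsa"), ("rat", "mtmsa"), ("monkey", "mtmsa"), ("human", "mtmsa"),
])
def test_auc_inf_equals_dose_over_clearance(species, compound_fixture, request):
    """The distribution-free clearance oracle: AUC(0-inf) = Dose / CL within
    1%, for every species/compound pair, independent of Kp and PS."""
    compound = request.getfixturevalue(compound_fixture)
    phys = get_physiology(species)
    kp = predict_kp(compound, phys, species)
    cl = 2.0 * phys.body_weight * 60.0  # 2 mL/min/kg
    model = build_model(compound, phys, species, cl, kp)
    dose_ng = 1.0e6 * phys.body_weight  # 1 mg/kg
    # simulate >= 20 half-lives of the slowest kinetic phase (eigenvalue-based)
    rates = np.abs(np.linalg.eigvals(model.A).real)
    slowest = rates[rates > 1e-12 * rates.max()].min()
    t_end = 20 * 0.693 / slowest
    times = _dense_times(t_end)
    res = model.simulate(Regimen.bolus(1.0, "mg/kg"), t_end, times=times)
    auc = auc_loglinear(res.plasma_profile())
    assert auc == pytest.approx(dose_ng / cl, rel=0.01)
    assert res.cleared[-1] == pytest.approx(dose_ng, rel=0.01)


def test_output_grid_arithmetic(mtm, human):
    kp = predict_kp(mtm, human, "human")
    model = build_model(mtm, human, "human", 5000.0, kp)
    res = model.simulate(Regimen.infusion(13.0, "ug/kg", duration_h=6.0), 24.0, 0.5)
    assert len(res.times) == 49
    assert res.times[0] == 0.0 and res.times[-1] == 24.0


def test_multidose_infusion_accumulates(mtmsa, human):
    kp = predict_kp(mtmsa, human, "human")
    model = build_model(mtmsa, human, "human", 200.0, kp)
    reg = Regimen.infusion(13.0, "ug/kg", duration_h=6.0, n_doses=3, interval_h=24.0)
    res = model.simulate(reg, 72.0, 0.5)
    p = res.plasma_profile().concentrations
    t = res.times
    # trough before each later dose exceeds the previous trough (accumulation)
    c24, c48, c72 = (p[np.searchsorted(t, h)] for h in (24.0, 48.0, 72.0))
    assert c48 > c24 and c72 > c48
    assert res.administered[-1] == pytest.approx(3 * 13e3 * 50.0)


def test_invalid_inputs_raise(mtm, human):
    kp = predict_kp(mtm, human, "human")
    with pytest.raises(ValueError, match="clearance"):
        build_model(mtm, human, "human", -1.0, kp)
    bad_kp = KpSet(values={"liver": 1.0}, fut={"liver": 1.0})
    with pytest.raises(KeyError, match="lung"):
        build_model(mtm, human, "human", 100.0, bad_kp)
    model = build_model(mtm, human, "human", 100.0, kp)
    with pytest.raises(ValueError, match="duration"):
        model.simulate(Regimen.bolus(1.0, "mg/kg"), -5.0)


def test_regimen_validation():
    with pytest.raises(ValueError, match="positive"):
        DoseEvent(start=0.0, amount_per_kg=-1.0)
    with pytest.raises(ValueError, match="overlap"):
        Regimen((DoseEvent(0.0, 100.0, duration=6.0), DoseEvent(3.0, 100.0)))


def test_conc_profile_roundtrip(tmp_path, mtm, human):
    kp = predict_kp(mtm, human, "human")
    model = build_model(mtm, human, "human", 5000.0, kp)
    profile = model.simulate(Regimen.bolus(13.0, "ug/kg"), 24.0, 0.5).plasma_profile()
    path = tmp_path / "profile.csv"
    profile.to_csv(path)
    again = ConcProfile.read_csv(path)
    assert np.allclose(again.times, profile.times)
    assert np.allclose(again.concentrations, profile.concentrations)
    assert again.matrix == "plasma" and again.compound == "MTM"
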