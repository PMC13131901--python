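import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mithrapbpk.clearance import (
    AllometricFit,
    ClearanceRecord,
    additional_clearance_human,
    allometric_fit,
    allometric_predict,
    geometric_mean,
    renal_filtration_cl,
    single_species_scale,
)


def _record(species, pct):
    cl_obs = 100.0
    return ClearanceRecord(species=species, cl_obs=cl_obs,
                           cl_renal=cl_obs * (100 - pct) / 100,
                           cl_add=cl_obs * pct / 100, pct_cl_add=pct)


def test_renal_filtration_identity_and_errors():
    assert renal_filtration_cl(1.0, 6000.0) == 6000.0
    assert renal_filtration_cl(0.1826, 6000.0) == pytest.approx(1095.6)
    with pytest.raises(ValueError, match="fup"):
        renal_filtration_cl(0.0, 6000.0)
    with pytest.raises(ValueError, match="GFR"):
        renal_filtration_cl(0.5, -1.0)


def test_filtration_only_limit_is_exact():
    """All %CL_add = 0 => CL_human = fup_human * GFR_human exactly."""
    records = [_record(s, 0.0) for s in ("mouse", "rat", "monkey")]
    cl = additional_clearance_human(records, fup_human=0.1826, gfr_human=6000.0)
    assert cl == 0.1826 * 6000.0


def test_fifty_percent_everywhere_doubles_renal():
    records = [_record(s, 50.0) for s in ("mouse", "rat", "monkey")]
    # CL_R,human = 1 L/h -> CL_human = 2 L/h
    cl = additional_clearance_human(records, fup_human=0.5, gfr_human=2000.0)
    assert cl == pytest.approx(2000.0)


def test_geometric_average_matches_brute_force():
    pcts = [25.0, 100 * (1 - 1 / np.e ** 2), 60.0]
    records = [_record(s, p) for s, p in zip(("mouse", "rat", "monkey"), pcts)]
    cl = additional_clearance_human(records, fup_human=0.2, gfr_human=5000.0)
    brute = np.exp(np.mean([np.log(p) for p in pcts]))
    assert cl == pytest.approx(0.2 * 5000.0 / (100 - brute) * 100)


def test_clamping_and_bad_percentages():
    with pytest.warns(UserWarning, match="clamping"):
        rec = ClearanceRecord.from_observed("rat", cl_obs=10.0, fup=1.0, gfr=100.0)
    assert rec.cl_add == 0.0 and rec.pct_cl_add == 0.0
    bad = _record("mouse", 100.0)
    with pytest.raises(ValueError, match="outside"):
        additional_clearance_human([bad], 0.1, 1000.0)


def test_zero_mixed_with_nonzero_floored_with_warning():
    records = [_record("mouse", 0.0), _record("rat", 50.0)]
    with pytest.warns(UserWarning, match="flooring"):
        cl = additional_clearance_human(records, 0.5, 1000.0)
    geo = np.exp(0.5 * (np.log(0.1) + np.log(50.0)))
    assert cl == pytest.approx(500.0 / (100 - geo) * 100)


@settings(deadline=None, max_examples=60)
@given(st.lists(st.floats(0.1, 99.0), min_size=1, max_size=6))
def test_geometric_mean_below_arithmetic(pcts):
    assert geometric_mean(pcts) <= np.mean(pcts) + 1e-9


def test_allometric_exact_recovery():
    """Noise-free CL = 2 * BW^0.75 points are recovered exactly."""
    points = [(bw, 2.0 * bw ** 0.75) for bw in (0.025, 0.25, 5.0)]
    fit = allometric_fit(points)
    assert fit.a == pytest.approx(2.0, rel=1e-10)
    assert fit.b == pytest.approx(0.75, rel=1e-10)
    assert fit.r_squared == pytest.approx(1.0)
    assert allometric_predict(fit, 50.0) == pytest.approx(2.0 * 50.0 ** 0.75, rel=1e-10)


def test_two_points_interpolate():
    fit = allometric_fit([(1.0, 3.0), (10.0, 30.0)])
    assert fit.b == pytest.approx(1.0)
    assert fit.predict(1.0) == pytest.approx(3.0)


def test_singular_fit_rejected():
    with pytest.raises(ValueError, match="singular"):
        allometric_fit([(1.0, 2.0), (1.0, 4.0)])


def test_noisy_exponent_recovery():
    """Multiplicative-noise points recover the exponent within the noise band."""
    rng = np.random.default_rng(11)
    bw = np.geomspace(0.02, 70, 12)
    cl = 3.0 * bw ** 0.75 * np.exp(rng.normal(0, 0.1, bw.size))
    fit = allometric_fit(list(zip(bw, cl)))
    # sd of the slope ~ sigma / (sqrt(n) * sd(ln BW)) ~ 0.012; allow 4 sd
    assert fit.b == pytest.approx(0.75, abs=0.05)
    assert fit.r_squared > 0.95


def test_single_species_scaling_closed_forms():
    assert single_species_scale(1000.0, 5.0, 50.0) == pytest.approx(
        1000.0 * 10 ** 0.75
    )
    assert single_species_scale(1.0, 5.0, 50.0, exponent=1.0) == pytest.approx(10.0)
    assert single_species_scale(7.0, 5.0, 5.0) == pytest.approx(7.0)


def test_allometric_fit_validation():
    with pytest.raises(ValueError, match="2"):
        allometric_fit([(1.0, 1.0)])
    with pytest.raises(ValueError, match="positive"):
        allometric_fit([(1.0, -1.0), (2.0, 1.0)])
    with pytest.raises(ValueError, match="positive"):
        AllometricFit(a=1.0, b=0.75, r_squared=1.0, points=()).predict(-5.0)
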