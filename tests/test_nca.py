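import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mithrapbpk.engine import ConcProfile
from mithrapbpk.nca import (
    auc_loglinear,
    observed_clearance,
    summarize,
    terminal_rate_constant,
)


def _profile(times, conc):
    return ConcProfile(times=np.asarray(times, float), concentrations=np.asarray(conc, float))


@pytest.mark.parametrize(
    "times,conc,expected",
    [
        ([0.0, 1.0], [100.0, 100.0], 100.0),  # flat: linear rule
        ([0.0, 1.0], [50.0, 100.0], 75.0),  # rising: arithmetic mean
        ([0.0, 1.0], [100.0, 0.0], 50.0),  # zero endpoint forces linear rule
    ],
)
def test_interval_rules(times, conc, expected):
    assert auc_loglinear(_profile(times, conc)) == pytest.approx(expected)


@settings(deadline=None, max_examples=100)
@given(
    k=st.floats(0.05, 5.0),
    c0=st.floats(1.0, 1e5),
    times=st.lists(st.floats(0.0, 30.0), min_size=2, max_size=12, unique=True),
)
def test_exact_on_monoexponential(k, c0, times):
    """Log-trapezoid integrates mono-exponential decay exactly: the AUC over
    [t1, tn] equals c0/k * (e^(-k t1) - e^(-k tn)) to machine precision."""
    from hypothesis import assume

    t = np.sort(np.asarray(times))
    assume(np.all(np.diff(t) > 1e-3))  # avoid cancellation in ln(C1/C2)
    conc = c0 * np.exp(-k * t)
    auc = auc_loglinear(_profile(t, conc))
    expected = c0 / k * (np.exp(-k * t[0]) - np.exp(-k * t[-1]))
    assert auc == pytest.approx(expected, rel=1e-12, abs=1e-12)


def test_additivity_over_contiguous_intervals():
    rng = np.random.default_rng(7)
    t = np.sort(rng.uniform(0, 24, 15))
    c = np.exp(rng.normal(2, 1, 15))
    full = auc_loglinear(_profile(t, c))
    left = auc_loglinear(_profile(t[:8], c[:8]))
    right = auc_loglinear(_profile(t[7:], c[7:]))
    assert full == pytest.approx(left + right, rel=1e-12)


def test_t_end_truncates():
    p = _profile([0, 1, 2, 4], [100, 100, 100, 100])
    assert auc_loglinear(p, t_end=2.0) == pytest.approx(200.0)


def test_errors():
    with pytest.raises(ValueError, match="2 samples"):
        auc_loglinear(_profile([1.0], [5.0]))
    with pytest.raises(ValueError, match="increasing"):
        _profile([0.0, 0.0, 1.0], [1.0, 1.0, 1.0])
    with pytest.raises(ValueError, match="positive"):
        observed_clearance(0.0, 100.0)
    with pytest.raises(ValueError, match="AUC"):
        observed_clearance(1.0, 0.0)


def test_observed_clearance_from_printed_summaries():
    """Dose/AUC from the observed monkey and rat study summaries."""
    assert observed_clearance(13.18, 255.0, "ug/kg") == pytest.approx(51.7, rel=2e-3)
    assert observed_clearance(0.5, 173.0, "mg/kg") == pytest.approx(2890.0, rel=2e-3)


def test_summarize_with_extrapolation():
    t = np.array([0.5, 1, 2, 4, 8, 12.0])
    c = 100 * np.exp(-0.3 * t)
    summary = summarize(_profile(t, c), dose_per_kg=1.0, body_weight=0.25,
                        dose_unit="mg/kg", extrapolate=True)
    assert summary.lambda_z == pytest.approx(0.3, rel=1e-6)
    # for exact mono-exponential data AUC_inf = C(t1)/k ... full integral from t1
    assert summary.auc_inf == pytest.approx(100 * np.exp(-0.15) / 0.3, rel=1e-6)
    assert summary.auc_inf >= summary.auc_last
    assert summary.cl_absolute == pytest.approx(summary.cl_per_kg * 0.25)


def test_lambda_z_requires_decline():
    with pytest.raises(ValueError, match="declining"):
        terminal_rate_constant(_profile([1, 2, 3], [1.0, 2.0, 3.0]))
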