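import numpy as np
import pytest
from scipy.integrate import solve_ivp

import anls_ltp as al
from anls_ltp import plasticity
from anls_ltp.errors import CoverageError


def test_bistability_two_stable_one_unstable(params):
    fp = al.fixed_points(params)
    assert len(fp["stable"]) == 2
    assert len(fp["unstable"]) == 1
    lo, hi = fp["stable"]
    assert lo == pytest.approx(params.w_baseline, abs=1e-6)
    assert hi == pytest.approx(params.w_potentiated, abs=1e-6)
    assert lo < fp["unstable"][0] < hi


def test_derivative_zero_at_fixed_point_with_gates_closed(params):
    ca_low = params.ca_rest
    atp_high = 4.2
    for w in (params.w_baseline, params.w_potentiated):
        # the smooth gates leave a ~1e-8 residual drive far from threshold
        assert al.weight_derivative(w, ca_low, atp_high, params) == pytest.approx(
            0.0, abs=1e-6
        )


def test_potentiation_gate_drives_weight_up(params):
    dw = al.weight_derivative(
        params.w_baseline, params.ltp_start * 2.0, 4.2, params
    )
    assert dw > 0


def test_nonfinite_inputs_rejected(params):
    with pytest.raises(ValueError):
        al.weight_derivative(float("nan"), 0.1, 4.0, params)


def test_phase_line_convergence_from_above_unstable_point(params):
    """With gates closed, a weight just above the middle fixed point flows
    to the potentiated state; just below, back to baseline."""
    wu = params.w_unstable

    def integrate(w0):
        # escape from the neighbourhood of the unstable point is slow:
        # allow many weight time constants
        sol = solve_ivp(
            lambda t, w: [plasticity.weight_drift(w[0], 0.0, 4.2, params)],
            (0, 100 * params.tau_w),
            [w0],
            rtol=1e-9,
        )
        return sol.y[0, -1]

    assert integrate(wu + 0.01) == pytest.approx(params.w_potentiated, abs=1e-3)
    assert integrate(wu - 0.01) == pytest.approx(params.w_baseline, abs=1e-3)


def test_low_atp_erases_potentiation(params):
    """Clamping ATP below threshold after potentiation returns the weight
    to baseline (ATP-gated depotentiation)."""
    low_atp = params.atp_thr - 0.2
    sol = solve_ivp(
        lambda t, w: [plasticity.weight_drift(w[0], 0.0, low_atp, params)],
        (0, 600.0),
        [params.w_potentiated],
        rtol=1e-9,
    )
    assert sol.y[0, -1] < params.w_unstable
    # depotentiation is proportional to (W - baseline): it cannot push the
    # weight below baseline on its own
    assert sol.y[0, -1] >= params.w_baseline - 1e-6


def test_classify_constant_baseline():
    t = np.linspace(0, 5000.0, 200)
    out = al.classify_outcome(t, np.ones_like(t), protocol_end_time=100.0)
    assert out.label == "no_plasticity"
    assert out.magnitude_pct == pytest.approx(100.0)


def test_classify_requires_full_window():
    t = np.linspace(0, 1000.0, 50)
    with pytest.raises(CoverageError):
        al.classify_outcome(t, np.ones_like(t), protocol_end_time=100.0)


@pytest.mark.parametrize(
    "level,label",
    [(1.85, "LTP"), (1.05, "no_plasticity"), (0.85, "LTD")],
)
def test_classification_bands(level, label):
    t = np.linspace(0, 5000.0, 500)
    out = al.classify_outcome(t, np.full_like(t, level), protocol_end_time=100.0)
    assert out.label == label
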