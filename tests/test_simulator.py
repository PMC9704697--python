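import numpy as np
import pytest

import anls_ltp as al
from anls_ltp import electro
from anls_ltp.state import IX
from conftest import run


def test_unstimulated_run_stays_flat(params):
    """With no protocol, every trajectory stays at rest (within 0.1 %)."""
    res = al.run(None, None, params, followup_s=4200.0)
    for i in range(int(IX.NA_A) + 1):
        ref = max(abs(res.rest[i]), 1e-6)
        drift = np.max(np.abs(res.y[:, i] - res.rest[i])) / ref
        assert drift < 1e-3, al.state_names()[i]
    assert res.outcome.label == "no_plasticity"


def test_zero_amplitude_events_change_nothing(params):
    """Spike events with all amplitudes zeroed reproduce the unstimulated
    trajectories (event handling itself is exact)."""
    silent = params.with_overrides(
        {
            "na_ampa_jump": 0.0,
            "k_na_vgsc": 0.0,
            "glu_jump": 0.0,
            "dep_epsp": 0.0,
            "dep_bap": 0.0,
            "na_eaat_jump": 0.0,
        }
    )
    res = al.run(al.stdp(10, 1.0, 1), None, silent)
    ref = al.run(None, None, silent)
    t_cmp = np.linspace(-500.0, 3500.0, 200)
    for ix in (IX.NA_N, IX.CA, IX.ATP_N, IX.W):
        a = np.interp(t_cmp, res.t, res.y[:, ix])
        b = np.interp(t_cmp, ref.t, ref.y[:, ix])
        assert np.max(np.abs(a - b)) < 1e-6 * max(1.0, abs(res.rest[ix]))


def test_control_protocols_express_ltp(params):
    assert run(al.get_preset("tbs5")).outcome.label == "LTP"
    assert run(al.get_preset("stdp_50_0.5Hz")).outcome.label == "LTP"


def test_oxamate_separates_tbs_from_stdp(params):
    """Under LDH block, theta-burst ATP crosses the depotentiation
    threshold while 50-pairing STDP stays above it."""
    tbs = run(al.get_preset("tbs5"), "oxamate")
    stdp = run(al.get_preset("stdp_50_0.5Hz"), "oxamate")
    assert tbs.min_atp_neuron < params.atp_thr < stdp.min_atp_neuron
    assert tbs.outcome.label == "no_plasticity"
    assert stdp.outcome.label == "LTP"


def test_summaries_match_recomputation(params):
    res = run(al.get_preset("stdp_50_0.5Hz"))
    assert res.peak_delta_na == pytest.approx(
        np.max(res.y[:, IX.NA_N]) - res.rest[IX.NA_N]
    )
    assert res.peak_ca == pytest.approx(np.max(res.y[:, IX.CA]))
    _, recomputed = electro.pump_ATP_demand(res, params)
    assert recomputed == pytest.approx(res.cumulative_pump_atp, rel=0.03)


def test_solver_tolerance_convergence(params):
    """Halving solver tolerances changes the outcome magnitude by < 0.5 %."""
    proto = al.tbs(1)
    a = al.run(proto, None, params, solver=al.SolverSettings(rtol=1e-6, atol=1e-9))
    b = al.run(proto, None, params, solver=al.SolverSettings(rtol=5e-7, atol=5e-10))
    ma, mb = a.outcome.magnitude_pct, b.outcome.magnitude_pct
    assert abs(ma - mb) / ma < 5e-3


def test_trajectory_table_roundtrip(params, tmp_path):
    res = run(al.get_preset("stdp_50_0.5Hz"))
    path = tmp_path / "traj.csv"
    res.save_trajectory(path)
    import pandas as pd

    df = pd.read_csv(path)
    assert len(df) == len(res.t)
    assert "ATP_neuron (mM)" in df.columns
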