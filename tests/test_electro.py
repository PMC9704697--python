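import numpy as np
import pytest

import anls_ltp as al
from anls_ltp import electro
from anls_ltp.errors import EventOrderError
from anls_ltp.protocols import SpikeEvent


def _events(*specs):
    return [SpikeEvent(t, site, kind) for t, site, kind in specs]


def test_empty_train_stays_at_rest(params):
    tr = electro.ion_response([], params, t_end=30.0)
    assert np.ptp(tr.Na_neuron) < 1e-6
    assert np.ptp(tr.Ca_post) < 1e-6
    assert abs(tr.pump_ATP_cumulative[-1]) < 1e-3


def test_unsorted_events_rejected(params):
    ev = _events((1.0, "presynaptic", "stimulation"), (0.5, "postsynaptic", "bAP"))
    with pytest.raises(EventOrderError):
        electro.ion_response(ev, params)


def test_single_responses_superpose_when_far_apart(params):
    """Far-separated identical events produce near-identical transients."""
    one = electro.ion_response(
        _events((0.5, "presynaptic", "stimulation")), params, t_end=40.0
    )
    two = electro.ion_response(
        _events(
            (0.5, "presynaptic", "stimulation"),
            (20.5, "presynaptic", "stimulation"),
        ),
        params,
        t_end=40.0,
    )
    rest = one.Ca_post[0]
    peak1 = one.peak_Ca - rest
    # peak of the second response, measured in its own window
    sel = two.t > 20.0
    peak2 = np.max(two.Ca_post[sel]) - rest
    assert peak2 == pytest.approx(peak1, rel=0.01)


def test_pairing_calcium_is_supralinear(params):
    """NMDAR coincidence: pre+bAP pairing exceeds the sum of isolated
    responses."""
    rest = params.ca_rest

    def delta(events):
        tr = electro.ion_response(events, params, t_end=5.0)
        return np.trapezoid(tr.Ca_post - rest, tr.t)

    pre = delta(_events((0.1, "presynaptic", "stimulation")))
    post = delta(_events((0.1, "postsynaptic", "bAP")))
    paired = delta(
        _events(
            (0.1, "presynaptic", "stimulation"), (0.11, "postsynaptic", "bAP")
        )
    )
    assert paired > 1.2 * (pre + post)


def test_two_bap_calcium_transient_roughly_doubles(params):
    """Two bAPs 10 ms apart give about twice the Ca transient of one."""
    rest = params.ca_rest
    one = electro.ion_response(
        _events((0.05, "postsynaptic", "bAP")), params, t_end=3.0
    )
    two = electro.ion_response(
        _events((0.05, "postsynaptic", "bAP"), (0.06, "postsynaptic", "bAP")),
        params,
        t_end=3.0,
    )
    ratio = (two.peak_Ca - rest) / (one.peak_Ca - rest)
    assert ratio == pytest.approx(2.0, rel=0.15)


def test_mk801_abolishes_nmda_calcium(params):
    """With the NMDAR blocked, the theta-burst Ca transient stays below the
    potentiation threshold."""
    ev = al.get_preset("tbs5").compile()
    tr = electro.ion_response(ev, params, condition="mk801", t_end=25.0)
    assert tr.peak_Ca < params.ltp_start


def test_pump_demand_monotone_in_influx(params):
    """Doubling every Na influx amplitude strictly increases cumulative
    pump ATP consumption."""
    ev = al.stdp(10, 1.0, 1).compile()
    base = electro.ion_response(ev, params, t_end=120.0)
    doubled_params = params.scaled({"na_ampa_jump": 2.0, "k_na_vgsc": 2.0})
    doubled = electro.ion_response(ev, doubled_params, t_end=120.0)
    assert doubled.pump_ATP_cumulative[-1] > base.pump_ATP_cumulative[-1]


def test_cumulative_demand_matches_recomputation(params):
    """The integrator's accumulator agrees with trapezoidal recomputation
    from the saved Na/ATP trajectories."""
    ev = al.stdp(15, 1.0, 1).compile()
    tr = electro.ion_response(ev, params, t_end=200.0, dt_out=0.005)
    _, recomputed = electro.pump_ATP_demand(tr, params)
    assert recomputed == pytest.approx(tr.pump_ATP_cumulative[-1], rel=0.02)


def test_accumulator_is_nondecreasing(params):
    ev = al.stdp(5, 1.0, 1).compile()
    tr = electro.ion_response(ev, params, t_end=60.0)
    assert np.all(np.diff(tr.pump_ATP_cumulative) > -1e-9)
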