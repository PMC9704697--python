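import numpy as np
import pytest

import anls_ltp as al
from anls_ltp.calibrate import _ParamView
from anls_ltp.errors import FitProtocolError


@pytest.fixture(scope="module")
def stdp_model(params):
    return al.WeightModel.build(al.get_preset("stdp_50_0.5Hz"), None, params)


@pytest.fixture(scope="module")
def tbs_model(params):
    return al.WeightModel.build(al.get_preset("tbs5"), None, params)


def _series(model, proto, params, true, noise_cv=0.0, rng=None):
    t_obs = al.observation_times(model.protocol_end)
    w = model.sample(_ParamView(params, true), t_obs)
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        w = w * rng.lognormal(-0.5 * sigma**2, sigma, len(w))
    return al.FitSeries(proto, None, t_obs, w)


def test_zero_free_parameters_returns_residuals_only(params, stdp_model):
    t_obs = al.observation_times(stdp_model.protocol_end)
    w_obs = stdp_model.sample(_ParamView(params, {}), t_obs)
    fr = al.fit(
        [al.FitSeries(al.get_preset("stdp_50_0.5Hz"), None, t_obs, w_obs)],
        free=[],
        params=params,
    )
    assert fr.free == {}
    assert fr.cost == pytest.approx(0.0, abs=1e-20)


def test_noise_free_recovery_within_5_percent(params, stdp_model, tbs_model):
    """Self-consistency: fitting to model-generated data recovers the
    generating parameters."""
    true = {
        "gain_potentiation": params["gain_potentiation"] * 1.3,
        "tau_w": params["tau_w"] * 0.75,
    }
    series = [
        _series(stdp_model, al.get_preset("stdp_50_0.5Hz"), params, true),
        _series(tbs_model, al.get_preset("tbs5"), params, true),
    ]
    fr = al.fit(series, list(true), params=params, n_starts=3, seed=7)
    for name, v in true.items():
        assert abs(fr.free[name] - v) / v < 0.05, name


def test_monte_carlo_recovery_under_noise(params, stdp_model, tbs_model):
    """20 replicates at 5 % multiplicative noise: median relative error of
    the fitted plasticity gains stays below 15 %."""
    true = {
        "gain_potentiation": params["gain_potentiation"] * 1.2,
        "tau_w": params["tau_w"] * 0.85,
    }
    errors = {k: [] for k in true}
    for rep in range(20):
        rng = np.random.default_rng(1000 + rep)
        series = [
            _series(stdp_model, al.get_preset("stdp_50_0.5Hz"), params, true,
                    0.05, rng),
            _series(tbs_model, al.get_preset("tbs5"), params, true, 0.05, rng),
        ]
        fr = al.fit(series, list(true), params=params, n_starts=2, seed=rep)
        for k, v in true.items():
            errors[k].append(abs(fr.free[k] - v) / v)
    for k, errs in errors.items():
        assert np.median(errs) < 0.15, (k, np.median(errs))


def test_recovery_error_grows_with_noise(params, stdp_model):
    """Median recovery error increases with the injected noise level."""
    true = {"gain_potentiation": params["gain_potentiation"] * 1.25}
    med = {}
    for cv in (0.02, 0.15):
        errs = []
        for rep in range(8):
            rng = np.random.default_rng(500 + rep)
            s = _series(stdp_model, al.get_preset("stdp_50_0.5Hz"), params,
                        true, cv, rng)
            fr = al.fit([s], list(true), params=params, n_starts=1, seed=rep)
            errs.append(abs(fr.free["gain_potentiation"] - true["gain_potentiation"])
                        / true["gain_potentiation"])
        med[cv] = np.median(errs)
    assert med[0.15] > med[0.02]


def test_objective_history_is_monotone(params, stdp_model):
    true = {"gain_potentiation": params["gain_potentiation"] * 1.4}
    rng = np.random.default_rng(3)
    s = _series(stdp_model, al.get_preset("stdp_50_0.5Hz"), params, true,
                0.05, rng)
    fr = al.fit([s], list(true), params=params, n_starts=2, seed=3)
    hist = fr.cost_history
    assert all(b <= a for a, b in zip(hist, hist[1:]))


def test_metabolic_free_parameters_rejected(params, stdp_model):
    t_obs = al.observation_times(stdp_model.protocol_end)
    s = al.FitSeries(al.get_preset("stdp_50_0.5Hz"), None, t_obs,
                     np.ones_like(t_obs))
    with pytest.raises(FitProtocolError):
        al.fit([s], ["vmax_hk_neuron"], params=params)


def test_validation_scores_truth_table_and_rejects_overlap(params):
    """Held-out validation scores 1.0 on rows the calibrated model
    reproduces, and a permuted label set scores below 1."""
    rows = [
        (al.tbs(1), "oxamate"),
        (al.stdp(100, 1.0, 1), "oxamate"),
        (al.stdp(50, 1.0, 2), "oxamate"),
        (al.stdp(25, 1.0, 2), "oxamate"),
    ]
    labels = ["LTP", "LTP", "no_plasticity", "LTP"]
    score = al.validate(params, rows, labels)
    assert score == 1.0
    permuted = ["no_plasticity", "LTP", "LTP", "LTP"]
    assert al.validate(params, rows, permuted) < 1.0
    # overlap between fit and validation sets is a protocol error
    t = np.linspace(-600, 4000, 20)
    fr = al.FitResult(
        params=params, free={}, cost=0.0, residuals=np.zeros(1),
        start_costs=[0.0], cost_history=[0.0], unidentifiable=[],
        fit_keys=[("tbs1", "oxamate")],
    )
    with pytest.raises(FitProtocolError):
        al.validate(fr, rows, labels)
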