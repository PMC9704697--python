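import numpy as np
import pytest

import anls_ltp as al


def test_zero_noise_equals_ground_truth(params):
    df = al.generate_timecourse(params, al.get_preset("stdp_50_0.5Hz"),
                                noise_cv=0.0, seed=0)
    assert np.allclose(df.w_observed_pct, df.w_true_pct)


def test_fixed_seed_is_bitwise_reproducible(params):
    a = al.generate_timecourse(params, al.get_preset("stdp_50_0.5Hz"), seed=42)
    b = al.generate_timecourse(params, al.get_preset("stdp_50_0.5Hz"), seed=42)
    assert (a.w_observed_pct.values == b.w_observed_pct.values).all()
    c = al.generate_timecourse(params, al.get_preset("stdp_50_0.5Hz"), seed=43)
    assert not (a.w_observed_pct.values == c.w_observed_pct.values).all()


def test_baseline_sampling_layout(params):
    df = al.generate_timecourse(params, al.get_preset("stdp_50_0.5Hz"), seed=1)
    baseline = df[df.time_min < 0]
    assert len(baseline) == 10
    assert len(df) == 70  # 10 baseline + 60 follow-up minutes
    assert baseline.w_true_pct.max() == pytest.approx(100.0, abs=0.5)


def test_noise_cv_is_calibrated(params):
    """The sample CV of the baseline segment matches the requested CV."""
    rng_draws = []
    for seed in range(100):
        df = al.generate_timecourse(
            params, al.get_preset("stdp_50_0.5Hz"), noise_cv=0.05, seed=seed
        )
        rng_draws.extend(df[df.time_min < 0].w_observed_pct.values)
    draws = np.asarray(rng_draws)  # 1000 baseline samples
    cv = draws.std() / draws.mean()
    assert 0.04 < cv < 0.06


def test_cohort_zero_dispersion_identical_truth(params):
    obs, truth = al.generate_cohort(
        4, dispersion=0.0, protocol=al.get_preset("stdp_50_0.5Hz"),
        params=params, seed=0,
    )
    pivot = obs.pivot_table(index="time_min", columns="cell",
                            values="w_true_pct")
    assert np.allclose(pivot.std(axis=1), 0.0)
    assert truth.label.nunique() == 1


def test_cohort_mean_tracks_ground_truth(params):
    """With the experimental n (14 cells), the cohort mean stays inside the
    noise envelope of the generating trajectory."""
    obs, truth = al.generate_cohort(
        14, dispersion=0.0, protocol=al.get_preset("tbs5"), params=params,
        noise_cv=0.05, seed=5,
    )
    g = obs.groupby("time_min")
    mean = g.w_observed_pct.mean()
    true = g.w_true_pct.first()
    # standard error of a 5 % CV over 14 cells ~ 1.4 %
    assert np.all(np.abs(mean - true) / true < 0.05)


def test_oxamate_tbs_cohort_is_self_labelled_blocked(params):
    obs, truth = al.generate_cohort(
        3, dispersion=0.02, protocol=al.get_preset("tbs5"),
        condition="oxamate", params=params, seed=2,
    )
    assert (truth.label == "no_plasticity").all()


def test_cohort_argument_validation(params):
    with pytest.raises(ValueError):
        al.generate_cohort(0, protocol=al.get_preset("tbs5"), params=params)
    with pytest.raises(ValueError):
        al.generate_cohort(
            2, dispersed_params=("vmax_hk_neuron",),
            protocol=al.get_preset("tbs5"), params=params,
        )
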