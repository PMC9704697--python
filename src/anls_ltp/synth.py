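"""Synthetic experiment records with the statistical structure of the real
recordings: normalized EPSC amplitude sampled once per minute, a 10-min
baseline at 100 %, a 60-min post-protocol follow-up, multiplicative
log-normal measurement noise and optional cell-level parameter dispersion.

Every dataset is self-labelling: the noise-free ground truth is stored
alongside the observations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import pharmacology, simulate
from .calibrate import WeightModel, _ParamView, PLASTICITY_PARAMS
from .params import Params, load_default_params

__all__ = ["observation_times", "generate_timecourse", "generate_cohort"]


def observation_times(protocol_end: float) -> np.ndarray:
    """One sample per minute: 10 baseline minutes, 60 follow-up minutes.

    Times are on the simulator clock (0 = protocol start); follow-up
    sampling restarts one minute after the protocol ends.
    """
    baseline = np.arange(-10.0, 0.0) * 60.0 + 30.0  # centre of each minute
    followup = protocol_end + np.arange(1.0, 61.0) * 60.0
    return np.concatenate([baseline, followup])


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def generate_timecourse(
    params: Params | None = None,
    protocol=None,
    condition=None,
    noise_cv: float = 0.05,
    seed: int = 0,
    cell_scale_sd: float = 0.0,
) -> pd.DataFrame:
    """One synthetic cell: tidy frame with observed and true weights (%).

    Deterministic for a fixed seed. ``cell_scale_sd`` adds a single
    log-normal cell-level scaling factor to all observations.
    """
    params = params or load_default_params()
    if protocol is None:
        from .protocols import get_preset

        protocol = get_preset("stdp_50_0.5Hz")
    rng = np.random.default_rng(seed)
    res = simulate.run_cached(protocol, condition, params)
    t_obs = observation_times(res.protocol_end)
    from .state import IX

    w_true = np.interp(t_obs, res.t, res.y[:, IX.W]) * 100.0
    noise = _lognormal_factor(rng, noise_cv, len(t_obs))
    scale = _lognormal_factor(rng, cell_scale_sd, 1)[0] if cell_scale_sd > 0 else 1.0
    return pd.DataFrame(
        {
            "time_min": t_obs / 60.0,
            "w_observed_pct": w_true * noise * scale,
            "w_true_pct": w_true,
            "protocol": protocol.label(),
            "condition": pharmacology.condition_names(condition),
        }
    )


def generate_cohort(
    n_cells: int,
    dispersion: float = 0.0,
    protocol=None,
    condition=None,
    params: Params | None = None,
    noise_cv: float = 0.05,
    seed: int = 0,
    dispersed_params: tuple[str, ...] = ("gain_potentiation", "tau_w"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort of cells with log-normal per-cell parameter jitter.

    Returns ``(observations, ground_truth)``: a tidy per-minute table and a
    per-cell table carrying the generating parameter values and the
    noise-free outcome label. Only plasticity-level parameters may be
    dispersed (the weight rule is re-integrated per cell over one shared
    metabolic/ionic simulation).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    bad = set(dispersed_params) - PLASTICITY_PARAMS
    if bad:
        raise ValueError(f"non-plasticity parameters cannot be dispersed: {sorted(bad)}")
    params = params or load_default_params()
    if protocol is None:
        from .protocols import get_preset

        protocol = get_preset("stdp_50_0.5Hz")
    rng = np.random.default_rng(seed)
    model = WeightModel.build(protocol, condition, params)
    t_obs = observation_times(model.protocol_end)

    obs_rows, truth_rows = [], []
    for cell in range(n_cells):
        factors = {
            name: params[name] * _lognormal_factor(rng, dispersion, 1)[0]
            if dispersion > 0
            else params[name]
            for name in dispersed_params
        }
        view = _ParamView(params, factors)
        w = model.weights(view)
        w_true = np.interp(t_obs, model.t, w) * 100.0
        noise = _lognormal_factor(rng, noise_cv, len(t_obs))
        obs_rows.append(
            pd.DataFrame(
                {
                    "cell": cell,
                    "time_min": t_obs / 60.0,
                    "w_observed_pct": w_true * noise,
                    "w_true_pct": w_true,
                }
            )
        )
        from .plasticity import classify_outcome

        out = classify_outcome(model.t, w, model.protocol_end)
        truth_rows.append(
            {
                "cell": cell,
                **factors,
                "label": out.label,
                "magnitude_pct": out.magnitude_pct,
            }
        )
    observations = pd.concat(obs_rows, ignore_index=True)
    observations["protocol"] = protocol.label()
    observations["condition"] = pharmacology.condition_names(condition)
    return observations, pd.DataFrame(truth_rows)
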