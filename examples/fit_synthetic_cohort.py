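"""Calibrate the plasticity rule on synthetic recordings and validate on
held-out pharmacology.

Generates a noisy synthetic cohort (the normalized-EPSC layout of a slice
experiment: 10-min baseline, 60-min follow-up, one point per minute),
refits the potentiation gain and weight time constant, and scores the
refitted model on protocol x condition rows that were not used for fitting.
"""

import numpy as np

import anls_ltp as al

params = al.load_default_params()
rng_seed = 11

# --- synthesize observed time courses (ground truth known) -----------------
proto = al.get_preset("stdp_50_0.5Hz")
obs, truth = al.generate_cohort(
    8, dispersion=0.05, protocol=proto, params=params, noise_cv=0.05,
    seed=rng_seed,
)
mean = obs.groupby("time_min").w_observed_pct.mean()
print(f"cohort of 8 cells, ground-truth labels: {sorted(set(truth.label))}")
print(f"baseline mean {mean[mean.index < 0].mean():.1f}%  "
      f"last-10-min mean {mean[mean.index > 50].mean():.1f}%")

# --- refit the plasticity parameters to the averaged time course -----------
t_obs = al.observation_times(proto.span)
series = al.FitSeries(proto, None, t_obs, mean.values / 100.0)
fr = al.fit([series], ["gain_potentiation", "tau_w"], params=params,
            n_starts=4, seed=rng_seed)
print("\nrefitted parameters (table value in brackets):")
for k, v in fr.free.items():
    print(f"  {k:18s} {v:.4g}  [{params[k]:.4g}]")
print(f"  residual cost {fr.cost:.2e}, start-point dispersion {fr.start_dispersion:.2e}")

# --- validate on held-out pharmacology --------------------------------------
heldout = [
    (al.tbs(1), "oxamate"),
    (al.stdp(100, 1.0, 1), "oxamate"),
    (al.stdp(50, 1.0, 2), "oxamate"),
    (al.stdp(25, 1.0, 2), "oxamate"),
]
expected = ["LTP", "LTP", "no_plasticity", "LTP"]
score = al.validate(fr, heldout, expected)
print(f"\nheld-out truth-table score: {score:.2f} "
      f"({len(heldout)} protocol x condition rows)")
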