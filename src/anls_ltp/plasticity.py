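"""Bistable synaptic-weight rule gated by postsynaptic Ca and neuronal ATP.

The weight W (1.0 = baseline EPSC amplitude) follows a cubic bistable drift
with stable fixed points at baseline and at a potentiated value, plus two
gated drives:

* potentiation, active while postsynaptic calcium exceeds the ``ltp_start``
  threshold, saturating as W approaches ``w_sat`` (synaptic resource
  ceiling);
* depotentiation, active while neuronal ATP falls below ``atp_thr``,
  proportional to (W - baseline) so that on its own it can only erase
  potentiation, never drive the synapse below baseline.

Outcomes are classified from the weight trajectory 50-60 min after the end
of the stimulation protocol, as a percentage of baseline: >= 110 % is LTP,
<= 90 % is LTD, anything between is no plasticity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import CoverageError

__all__ = [
    "gate",
    "weight_drift",
    "weight_derivative",
    "fixed_points",
    "classify_outcome",
    "Outcome",
    "LTP_THRESHOLD_PCT",
    "LTD_THRESHOLD_PCT",
]

LTP_THRESHOLD_PCT = 110.0
LTD_THRESHOLD_PCT = 90.0

# classification window, seconds after protocol end
CLASSIFY_START_S = 50.0 * 60.0
CLASSIFY_END_S = 60.0 * 60.0


def gate(x: float, width: float) -> float:
    """Smooth non-negative sigmoidal gate: ~0 below threshold, ~1 above.

    ``x`` is the signed distance from the threshold; ``width`` controls
    sharpness (the gate rises over a few widths).
    """
    z = x / width
    if z > 40.0:
        return 1.0
    if z < -40.0:
        return 0.0
    return 1.0 / (1.0 + math.exp(-z))


def weight_drift(w: float, ca: float, atp: float, p) -> float:
    """dW/dt for the bistable rule; ``p`` is a parameter struct/table."""
    drift = (
        -(w - p.w_baseline) * (w - p.w_unstable) * (w - p.w_potentiated) / p.tau_w
    )
    pot = (
        p.gain_potentiation
        * gate(ca - p.ltp_start, p.gate_width_ca)
        * max(0.0, 1.0 - w / p.w_sat)
    )
    dep = (
        p.gain_depression
        * gate(p.atp_thr - atp, p.gate_width_atp)
        * (w - p.w_baseline)
    )
    return drift + pot - dep


def weight_derivative(w: float, ca_post: float, atp_neuron: float, params) -> float:
    """Public alias taking a Params table (same formula as the ODE core)."""
    for v in (w, ca_post, atp_neuron):
        if not math.isfinite(v):
            raise ValueError("weight_derivative requires finite inputs")
    return weight_drift(w, ca_post, atp_neuron, params)


def fixed_points(params) -> dict[str, list[float]]:
    """Stable and unstable fixed points of the drift with both gates closed.

    Found by root-finding on the cubic; with the default parameterisation
    there are exactly two stable points (baseline, potentiated) separated by
    one unstable point.
    """
    from scipy.optimize import brentq

    ca_closed = 0.0  # far below ltp_start
    atp_closed = params.atp_thr * 10.0  # far above atp_thr

    def drift(w):
        return weight_drift(w, ca_closed, atp_closed, params)

    grid = np.linspace(0.0, params.w_sat * 1.5, 2001)
    vals = np.array([drift(w) for w in grid])
    stable, unstable = [], []
    for i in range(len(grid) - 1):
        if vals[i] == 0.0 or vals[i] * vals[i + 1] >= 0.0:
            continue
        r = brentq(drift, grid[i], grid[i + 1], xtol=1e-12)
        eps = 1e-6
        slope = (drift(r + eps) - drift(r - eps)) / (2 * eps)
        (stable if slope < 0 else unstable).append(float(r))
    return {"stable": sorted(stable), "unstable": sorted(unstable)}


@dataclass(frozen=True)
class Outcome:
    """Plasticity classification of one simulation."""

    label: str  # "LTP" | "no_plasticity" | "LTD"
    magnitude_pct: float  # mean W in the 50-60 min window, % of baseline

    def __iter__(self):
        return iter((self.label, self.magnitude_pct))


def classify_outcome(
    t: np.ndarray,
    w: np.ndarray,
    protocol_end_time: float,
    baseline: float = 1.0,
) -> Outcome:
    """Classify a weight trajectory at 50-60 min after the protocol.

    ``t`` is in seconds on the same clock as ``protocol_end_time``.
    """
    t = np.asarray(t, dtype=float)
    w = np.asarray(w, dtype=float)
    t0 = protocol_end_time + CLASSIFY_START_S
    t1 = protocol_end_time + CLASSIFY_END_S
    if t[-1] + 1e-9 < t1:
        raise CoverageError(
            f"trajectory ends at {t[-1]:.0f} s but classification needs "
            f"coverage to {t1:.0f} s (60 min post-protocol)"
        )
    sel = (t >= t0) & (t <= t1)
    if not np.any(sel):
        raise CoverageError("no samples inside the 50-60 min window")
    magnitude = float(np.mean(w[sel]) / baseline * 100.0)
    if magnitude >= LTP_THRESHOLD_PCT:
        label = "LTP"
    elif magnitude <= LTD_THRESHOLD_PCT:
        label = "LTD"
    else:
        label = "no_plasticity"
    return Outcome(label, magnitude)
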