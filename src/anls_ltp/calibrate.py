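"""Fitting the plasticity rule to synaptic-weight time courses.

The procedure mirrors how such models are calibrated experimentally: free
parameters are fitted by weighted least squares between simulated and
observed normalized synaptic weights (EPSC amplitude, 1.0 = baseline),
using multi-start local optimization from Latin-hypercube initial points;
validation then checks the qualitative outcome (LTP / no plasticity) on
held-out protocol x condition pairs.

Because the synaptic weight does not feed back onto metabolism or ion
dynamics, refitting plasticity-level parameters only requires re-integrating
the scalar weight ODE over stored Ca/ATP trajectories — one full simulation
per protocol/condition, then thousands of cheap weight integrations. Freeing
a metabolic or electrogenic parameter falls back to full re-simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from . import pharmacology, plasticity, simulate
from .errors import FitProtocolError
from .params import Params, load_default_params
from .state import IX

__all__ = ["WeightModel", "FitSeries", "FitResult", "fit", "validate", "PLASTICITY_PARAMS"]

#: parameters that only enter the weight ODE (fast refit path)
PLASTICITY_PARAMS = frozenset(
    {
        "gain_potentiation",
        "gain_depression",
        "tau_w",
        "ltp_start",
        "atp_thr",
        "gate_width_ca",
        "gate_width_atp",
        "w_unstable",
        "w_potentiated",
        "w_sat",
        "w_baseline",
    }
)


def _weights_python(t, ca, atp, w0, wu, wp, tau_w, gp, ltp_start, wca, w_sat,
                    gd, atp_thr, watp):
    """Midpoint-rule integration of the weight ODE over a stored grid."""
    import math

    def drift(w, c, a):
        d = -(w - w0) * (w - wu) * (w - wp) / tau_w
        zc = (c - ltp_start) / wca
        gate_c = 1.0 / (1.0 + math.exp(-zc)) if abs(zc) < 40 else (zc > 0) * 1.0
        d += gp * gate_c * max(0.0, 1.0 - w / w_sat)
        za = (atp_thr - a) / watp
        gate_a = 1.0 / (1.0 + math.exp(-za)) if abs(za) < 40 else (za > 0) * 1.0
        d -= gd * gate_a * (w - w0)
        return d

    w = np.empty_like(t)
    wi = w0
    w[0] = wi
    for i in range(len(t) - 1):
        dt = t[i + 1] - t[i]
        k1 = drift(wi, ca[i], atp[i], )
        k2 = drift(
            wi + 0.5 * dt * k1,
            0.5 * (ca[i] + ca[i + 1]),
            0.5 * (atp[i] + atp[i + 1]),
        )
        wi = wi + dt * k2
        w[i + 1] = wi
    return w


try:  # optional JIT acceleration for the refit loops
    import numba as _numba

    @_numba.njit(cache=False)
    def _weights_kernel(t, ca, atp, w0, wu, wp, tau_w, gp, ltp_start, wca,
                        w_sat, gd, atp_thr, watp):  # pragma: no cover
        n = t.shape[0]
        w = np.empty(n)
        wi = w0
        w[0] = wi
        k1 = 0.0
        for i in range(n - 1):
            dt = t[i + 1] - t[i]
            for stage in range(2):
                if stage == 0:
                    ww = wi
                    c = ca[i]
                    a = atp[i]
                else:
                    ww = wi + 0.5 * dt * k1
                    c = 0.5 * (ca[i] + ca[i + 1])
                    a = 0.5 * (atp[i] + atp[i + 1])
                d = -(ww - w0) * (ww - wu) * (ww - wp) / tau_w
                zc = (c - ltp_start) / wca
                if zc > 40.0:
                    gate_c = 1.0
                elif zc < -40.0:
                    gate_c = 0.0
                else:
                    gate_c = 1.0 / (1.0 + np.exp(-zc))
                sat = 1.0 - ww / w_sat
                if sat < 0.0:
                    sat = 0.0
                d += gp * gate_c * sat
                za = (atp_thr - a) / watp
                if za > 40.0:
                    gate_a = 1.0
                elif za < -40.0:
                    gate_a = 0.0
                else:
                    gate_a = 1.0 / (1.0 + np.exp(-za))
                d -= gd * gate_a * (ww - w0)
                if stage == 0:
                    k1 = d
                else:
                    wi = wi + dt * d
            w[i + 1] = wi
        return w

except Exception:  # pragma: no cover
    _weights_kernel = None


class WeightModel:
    """Integrates the weight ODE over a stored Ca/ATP trajectory."""

    def __init__(self, result: simulate.SimulationResult):
        self.t = result.t
        self.ca = result.y[:, IX.CA]
        self.atp = result.y[:, IX.ATP_N]
        self.protocol_end = result.protocol_end
        self.key = (
            result.protocol.label() if result.protocol else "none",
            result.conditions,
        )

    @classmethod
    def build(cls, protocol, condition, params: Params) -> "WeightModel":
        return cls(simulate.run_cached(protocol, condition, params))

    def weights(self, params) -> np.ndarray:
        """Weight trajectory on the native grid (midpoint rule)."""
        t, ca, atp = self.t, self.ca, self.atp
        args = (
            params.w_baseline,
            params.w_unstable,
            params.w_potentiated,
            params.tau_w,
            params.gain_potentiation,
            params.ltp_start,
            params.gate_width_ca,
            params.w_sat,
            params.gain_depression,
            params.atp_thr,
            params.gate_width_atp,
        )
        if _weights_kernel is not None:
            return _weights_kernel(t, ca, atp, *args)
        return _weights_python(t, ca, atp, *args)

    def sample(self, params, t_obs: np.ndarray) -> np.ndarray:
        return np.interp(t_obs, self.t, self.weights(params))

    def outcome(self, params) -> plasticity.Outcome:
        return plasticity.classify_outcome(
            self.t, self.weights(params), self.protocol_end
        )


@dataclass
class FitSeries:
    """One observed normalized-weight time course."""

    protocol: object
    condition: object
    t_obs: np.ndarray  # s, same clock as the simulator (0 = protocol start)
    w_obs: np.ndarray  # fraction of baseline
    sigma: np.ndarray | None = None  # optional per-point SEM weights

    def key(self):
        return (
            self.protocol.label() if self.protocol is not None else "none",
            pharmacology.condition_names(self.condition),
        )


@dataclass
class FitResult:
    params: Params
    free: dict[str, float]
    cost: float
    residuals: np.ndarray
    start_costs: list[float]  # best cost reached from each start point
    cost_history: list[float]  # accepted (monotone) objective values, best start
    unidentifiable: list[str]
    fit_keys: list[tuple]

    @property
    def start_dispersion(self) -> float:
        return float(np.std(self.start_costs))


class _ParamView:
    """Attribute view merging a base table with free-parameter overrides."""

    __slots__ = ("_base", "_over")

    def __init__(self, base: Params, over: dict[str, float]):
        self._base = base
        self._over = over

    def __getattr__(self, name):
        over = object.__getattribute__(self, "_over")
        if name in over:
            return over[name]
        return object.__getattribute__(self, "_base")[name]


def fit(
    timecourses: list[FitSeries],
    free: list[str],
    bounds: dict[str, tuple[float, float]] | None = None,
    params: Params | None = None,
    n_starts: int = 4,
    seed: int = 0,
) -> FitResult:
    """Weighted least squares with multi-start Latin-hypercube initials.

    With zero free parameters this reduces to a pure residual evaluation at
    the input table.
    """
    if len(timecourses) < 1:
        raise FitProtocolError("at least one time course is required")
    params = params or load_default_params()
    for name in free:
        if name not in params:
            raise FitProtocolError(f"free parameter {name!r} not in the table")
    fast = set(free) <= PLASTICITY_PARAMS
    if not fast:
        raise FitProtocolError(
            "only plasticity-level parameters are supported as free "
            f"parameters (got {sorted(set(free) - PLASTICITY_PARAMS)}); "
            "metabolic parameters stay at table values"
        )

    models = [WeightModel.build(s.protocol, s.condition, params) for s in timecourses]

    def residual_vec(x: np.ndarray) -> np.ndarray:
        view = _ParamView(params, dict(zip(free, x)))
        out = []
        for s, m in zip(timecourses, models):
            pred = m.sample(view, s.t_obs)
            r = pred - s.w_obs
            if s.sigma is not None:
                r = r / s.sigma
            out.append(r)
        return np.concatenate(out)

    if not free:
        r = residual_vec(np.array([]))
        return FitResult(
            params=params,
            free={},
            cost=0.5 * float(r @ r),
            residuals=r,
            start_costs=[0.5 * float(r @ r)],
            cost_history=[0.5 * float(r @ r)],
            unidentifiable=[],
            fit_keys=[s.key() for s in timecourses],
        )

    bounds = bounds or {}
    lo = np.array([bounds.get(n, (params[n] * 0.2, params[n] * 5.0))[0] for n in free])
    hi = np.array([bounds.get(n, (params[n] * 0.2, params[n] * 5.0))[1] for n in free])

    sampler = qmc.LatinHypercube(d=len(free), seed=seed)
    starts = lo + sampler.random(n_starts) * (hi - lo)
    starts[0] = np.clip([params[n] for n in free], lo, hi)  # include table values

    best = None
    start_costs = []
    best_history: list[float] = []
    for x0 in starts:
        history: list[float] = []

        def tracked(x):
            r = residual_vec(x)
            c = 0.5 * float(r @ r)
            if not history or c < history[-1]:
                history.append(c)  # accepted (improving) objective values
            return r

        res = least_squares(
            tracked, x0, bounds=(lo, hi), method="trf",
            diff_step=0.05, max_nfev=60 * len(free),
        )
        start_costs.append(float(res.cost))
        if best is None or res.cost < best.cost:
            best = res
            best_history = history

    x = best.x
    # identifiability: near-zero jacobian column => flat profile
    J = best.jac
    col = np.linalg.norm(J, axis=0)
    scale = np.max(col) if np.max(col) > 0 else 1.0
    unident = [n for n, c in zip(free, col) if c < 1e-6 * scale]

    fitted = params.with_overrides(dict(zip(free, x)), provenance="recalibrated")
    return FitResult(
        params=fitted,
        free=dict(zip(free, x)),
        cost=float(best.cost),
        residuals=best.fun,
        start_costs=start_costs,
        cost_history=best_history,
        unidentifiable=unident,
        fit_keys=[s.key() for s in timecourses],
    )


def validate(
    fitted: Params | FitResult,
    heldout: list[tuple],
    expected: list[str],
    fit_keys: list[tuple] | None = None,
) -> float:
    """Truth-table score on held-out (protocol, condition) pairs.

    ``heldout`` is a list of (protocol, condition); ``expected`` the
    corresponding outcome labels. Raises if a held-out pair was used for
    fitting.
    """
    if isinstance(fitted, FitResult):
        fit_keys = fitted.fit_keys
        params = fitted.params
    else:
        params = fitted
    keys = {
        (
            p.label() if p is not None else "none",
            pharmacology.condition_names(c),
        )
        for p, c in heldout
    }
    if fit_keys and keys & set(fit_keys):
        raise FitProtocolError(
            f"held-out set overlaps the fitting set: {keys & set(fit_keys)}"
        )
    hits = 0
    for (proto, cond), want in zip(heldout, expected):
        res = simulate.run_cached(proto, cond, params)
        hits += res.outcome.label == want
    return hits / len(heldout)
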