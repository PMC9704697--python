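"""Full-experiment orchestration.

A run mirrors the slice-electrophysiology timeline: the model is initialised
at its pharmacology-dependent resting state, held for a 10-min baseline,
the stimulation protocol is delivered with exact event handling (the stiff
integrator restarts at every spike time), and the follow-up covers 60+ min
so plasticity can be classified in the 50-60 min post-protocol window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import dynamics, metabolism, pharmacology, plasticity
from .errors import IntegrationError
from .params import Params, load_default_params
from .protocols import SpikeEvent, StimulationProtocol, check_sorted
from .state import IX, N_STATES, state_names

__all__ = ["SolverSettings", "SimulationResult", "run"]

BASELINE_S = 600.0  # 10 min pre-protocol baseline
FOLLOWUP_S = 3660.0  # > 60 min post-protocol follow-up


@dataclass(frozen=True)
class SolverSettings:
    rtol: float = 1e-6
    atol: float = 1e-9
    method: str = "LSODA"
    dt_out_protocol: float = 0.005  # s, output grid during the protocol
    dt_out_slow: float = 2.0  # s, output grid outside the protocol
    max_step_protocol: float = np.inf


@dataclass
class SimulationResult:
    """Time-stamped trajectories plus derived summaries and provenance."""

    t: np.ndarray  # s, 0 = protocol start
    y: np.ndarray  # (n_time, n_states)
    protocol: StimulationProtocol | None
    conditions: str
    params_hash: str
    solver: SolverSettings
    protocol_end: float
    rest: np.ndarray  # resting state vector

    # -- summaries (recomputable from the trajectories) -----------------------
    @property
    def peak_delta_na(self) -> float:
        """Peak neuronal Na increase over rest (mM)."""
        return float(np.max(self.y[:, IX.NA_N]) - self.rest[IX.NA_N])

    @property
    def peak_ca(self) -> float:
        """Peak postsynaptic Ca (uM)."""
        return float(np.max(self.y[:, IX.CA]))

    @property
    def cumulative_pump_atp(self) -> float:
        """Total activity-evoked Na,K-ATPase ATP consumption (uM)."""
        return float(self.y[-1, IX.PUMP_ATP_CUM])

    @property
    def min_atp_neuron(self) -> float:
        return float(np.min(self.y[:, IX.ATP_N]))

    @property
    def outcome(self) -> plasticity.Outcome:
        return plasticity.classify_outcome(
            self.t, self.y[:, IX.W], self.protocol_end
        )

    def series(self, ix: IX) -> np.ndarray:
        return self.y[:, ix]

    # trajectory views (shared interface with electro.IonTrajectory)
    @property
    def Na_neuron(self) -> np.ndarray:
        return self.y[:, IX.NA_N]

    @property
    def ATP_neuron(self) -> np.ndarray:
        return self.y[:, IX.ATP_N]

    @property
    def pump_ATP_cumulative(self) -> np.ndarray:
        return self.y[:, IX.PUMP_ATP_CUM]

    def summary(self) -> dict:
        out = self.outcome
        return {
            "protocol": self.protocol.label() if self.protocol else "none",
            "condition": self.conditions,
            "peak_delta_na_mM": self.peak_delta_na,
            "peak_ca_uM": self.peak_ca,
            "cumulative_pump_atp_uM": self.cumulative_pump_atp,
            "min_atp_neuron_mM": self.min_atp_neuron,
            "outcome": out.label,
            "magnitude_pct": out.magnitude_pct,
            "params_hash": self.params_hash,
        }

    def to_frame(self) -> pd.DataFrame:
        """Tidy trajectory table, one row per time point."""
        df = pd.DataFrame(self.y, columns=state_names(with_units=True))
        df.insert(0, "time (s)", self.t)
        return df

    def save_trajectory(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def run(
    protocol: StimulationProtocol | None,
    condition=None,
    params: Params | None = None,
    solver: SolverSettings | None = None,
    baseline_s: float = BASELINE_S,
    followup_s: float = FOLLOWUP_S,
) -> SimulationResult:
    """Simulate one full experiment; fully deterministic.

    ``protocol=None`` runs an unstimulated control of the same duration.
    """
    params = params or load_default_params()
    solver = solver or SolverSettings()
    cond_params = pharmacology.apply(condition, params) if condition else params
    cond_label = pharmacology.condition_names(condition)
    p = dynamics.param_struct(cond_params)

    y0 = metabolism.steady_state(params, condition)
    rest = y0.copy()
    rest_pump_atp = dynamics.evaluate_fluxes(y0, p).pump_atp_neuron

    if protocol is not None:
        events = protocol.compile()
        check_sorted(events)
        span = protocol.span
    else:
        events, span = [], 0.0

    def f(t, y):
        return dynamics.rhs(t, y, p, rest_pump_atp=rest_pump_atp)

    t_final = span + followup_s
    # segment boundaries: baseline start, each distinct event time, end
    ev_times = sorted({e.time for e in events})
    boundaries = [-baseline_s] + ev_times + [t_final]

    ts: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    y = y0.copy()
    t_now = boundaries[0]
    ts.append(np.array([t_now]))
    ys.append(y[None, :].copy())

    ev_iter = iter(events)
    pending = next(ev_iter, None)
    in_protocol_window = lambda a, b: (b > -1.0) and (a < span + 30.0)

    for t_next in boundaries[1:]:
        if t_next > t_now + 1e-12:
            fine = in_protocol_window(t_now, t_next)
            dt = solver.dt_out_protocol if fine else solver.dt_out_slow
            n = int(np.ceil((t_next - t_now) / dt))
            n = min(max(n, 1), 4000)
            t_eval = np.linspace(t_now, t_next, n + 1)
            sol = solve_ivp(
                f,
                (t_now, t_next),
                y,
                method=solver.method,
                t_eval=t_eval,
                rtol=solver.rtol,
                atol=solver.atol,
                max_step=solver.max_step_protocol if fine else np.inf,
            )
            if not sol.success:
                raise IntegrationError(
                    f"integrator failed at t={sol.t[-1]:.3f}s: {sol.message}",
                    t=sol.t[-1],
                    y=sol.y[:, -1],
                )
            ts.append(sol.t[1:])
            ys.append(sol.y[:, 1:].T)
            y = sol.y[:, -1].copy()
            t_now = t_next
        while pending is not None and pending.time <= t_next + 1e-12:
            from .electro import apply_event

            apply_event(y, pending, p)
            pending = next(ev_iter, None)

    t_arr = np.concatenate(ts)
    y_arr = np.vstack(ys)
    return SimulationResult(
        t=t_arr,
        y=y_arr,
        protocol=protocol,
        conditions=cond_label,
        params_hash=cond_params.hash(),
        solver=solver,
        protocol_end=span,
        rest=rest,
    )


# ---------------------------------------------------------------------------
# memoised runner for sweeps / test suites (results are deterministic)
# ---------------------------------------------------------------------------
_RUN_CACHE: dict[tuple, SimulationResult] = {}


def run_cached(protocol, condition=None, params: Params | None = None) -> SimulationResult:
    params = params or load_default_params()
    cond_params = pharmacology.apply(condition, params) if condition else params
    key = (
        protocol.label() if protocol is not None else "none",
        repr(protocol),
        cond_params.hash(),
    )
    if key not in _RUN_CACHE:
        _RUN_CACHE[key] = run(protocol, condition, params)
    return _RUN_CACHE[key]
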