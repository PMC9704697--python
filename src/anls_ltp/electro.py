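"""Event-driven electrophysiology: spikes -> ion loads -> pump ATP demand.

Spikes are instantaneous events triggering stereotyped transients (no
membrane-voltage solver):

* a presynaptic stimulation increments a glutamate trace G (NMDAR binding),
  a depolarization trace V (EPSP), injects AMPAR Na into the neuron and
  co-transports Na into the astrocyte (EAAT stoichiometry, 3 Na per
  glutamate);
* a back-propagating action potential (bAP) increments V strongly and
  injects VGSC Na.

Between events, NMDAR Ca/Na flux is proportional to G x V (the coincidence
term: glutamate bound while depolarized), VGCC Ca flux is proportional to V,
and Na decays through the Na,K-ATPase (3 Na : 1 ATP), which is what couples
electrical activity to the metabolic model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from . import dynamics
from .errors import EventOrderError
from .params import Params
from .protocols import SpikeEvent, check_sorted
from .state import IX, N_STATES

__all__ = ["apply_event", "ion_response", "pump_ATP_demand", "IonTrajectory"]


def apply_event(y: np.ndarray, event: SpikeEvent, p) -> None:
    """Apply the instantaneous state jumps of one spike event (in place)."""
    # depolarization jumps are amplified regeneratively when the membrane is
    # already depolarized (temporal summation recruiting dendritic spikes),
    # and saturate at dep_max
    def dep_add(jump):
        amplified = jump * (1.0 + p.dep_regen * y[IX.DEP])
        y[IX.DEP] = min(y[IX.DEP] + amplified, p.dep_max)

    if event.site == "presynaptic":
        # NMDAR glutamate binding saturates during high-frequency bursts
        y[IX.GLU] += p.glu_jump * max(0.0, 1.0 - y[IX.GLU] / p.glu_sat)
        dep_add(p.dep_epsp)
        y[IX.NA_N] += p.na_ampa_jump
        y[IX.NA_A] += p.na_eaat_jump
    else:  # postsynaptic bAP
        dep_add(p.dep_bap)
        y[IX.NA_N] += p.na_vgsc_jump


@dataclass
class IonTrajectory:
    """Time-stamped Na/Ca trajectories with pump bookkeeping."""

    t: np.ndarray
    Na_neuron: np.ndarray
    Na_astrocyte: np.ndarray
    Ca_post: np.ndarray
    pump_ATP_cumulative: np.ndarray  # uM, activity-evoked, above rest
    ATP_neuron: np.ndarray

    @property
    def peak_delta_Na(self) -> float:
        return float(np.max(self.Na_neuron) - self.Na_neuron[0])

    @property
    def peak_Ca(self) -> float:
        return float(np.max(self.Ca_post))


def _validate_params(p) -> None:
    for name in ("tau_glu", "tau_dep", "tau_ca", "tau_w"):
        if getattr(p, name) <= 0:
            raise ValueError(f"decay constant {name} must be positive")


def ion_response(
    events: list[SpikeEvent],
    params: Params,
    condition=None,
    t_end: float | None = None,
    clamp_atp: float | None = None,
    dt_out: float = 0.002,
) -> IonTrajectory:
    """Integrate the ion/trace subsystem for a spike train.

    Metabolite concentrations are clamped at their resting values (``clamp_atp``
    overrides the resting neuronal ATP), which isolates the electrogenic
    response; the full coupled behaviour is available through
    :func:`anls_ltp.simulate.run`.
    """
    from . import metabolism, pharmacology

    cond_params = pharmacology.apply(condition, params) if condition else params
    p = dynamics.param_struct(cond_params)
    _validate_params(p)
    check_sorted(events)

    y0 = metabolism.steady_state(params, condition)
    if clamp_atp is not None:
        y0[IX.ATP_N] = clamp_atp
    rest = dynamics.evaluate_fluxes(y0, p)
    rest_pump_atp = rest.pump_atp_neuron

    ion_ix = np.array([IX.NA_N, IX.NA_A, IX.CA, IX.GLU, IX.DEP, IX.PUMP_ATP_CUM])

    def ion_rhs(t, x):
        z = y0.copy()
        z[ion_ix] = x
        dz = dynamics.rhs(t, z, p, rest_pump_atp=rest_pump_atp)
        return dz[ion_ix]

    times = [e.time for e in events]
    t_stop = (times[-1] if times else 0.0) + (t_end or 120.0)
    breakpoints = sorted(set(times)) + [t_stop]

    x = y0[ion_ix].copy()
    t_now = 0.0
    ts = [0.0]
    xs = [x.copy()]
    ev_iter = iter(events)
    pending = next(ev_iter, None)
    for t_next in breakpoints:
        if t_next > t_now:
            n_pts = max(2, int(np.ceil((t_next - t_now) / dt_out)) + 1)
            t_eval = np.linspace(t_now, t_next, min(n_pts, 2000))
            sol = solve_ivp(
                ion_rhs,
                (t_now, t_next),
                x,
                method="LSODA",
                t_eval=t_eval,
                rtol=1e-7,
                atol=1e-10,
            )
            ts.extend(sol.t[1:].tolist())
            xs.extend(sol.y[:, 1:].T)
            x = sol.y[:, -1].copy()
            t_now = t_next
        # apply all events scheduled exactly at t_next
        z = y0.copy()
        z[ion_ix] = x
        while pending is not None and pending.time <= t_next + 1e-12:
            apply_event(z, pending, p)
            pending = next(ev_iter, None)
        x = z[ion_ix].copy()

    arr = np.array(xs)
    t_arr = np.array(ts)
    return IonTrajectory(
        t=t_arr,
        Na_neuron=arr[:, 0],
        Na_astrocyte=arr[:, 1],
        Ca_post=arr[:, 2],
        pump_ATP_cumulative=arr[:, 5],
        ATP_neuron=np.full_like(t_arr, y0[IX.ATP_N]),
    )


def pump_ATP_demand(
    traj,
    params: Params,
) -> tuple[np.ndarray, float]:
    """Recompute the Na,K-ATPase ATP demand from an ion trajectory.

    Returns the instantaneous activity-evoked consumption rate (uM/s of
    cytosolic ATP, above rest) and its cumulative total (uM) by trapezoidal
    integration. Independent of the integrator's own accumulator, so it
    doubles as a consistency oracle.
    """
    p = dynamics.param_struct(params)
    na = np.asarray(traj.Na_neuron, dtype=float)
    atp = np.asarray(traj.ATP_neuron, dtype=float)
    t = np.asarray(traj.t, dtype=float)
    h = p.hill_pump_na
    ha = p.hill_pump_atp
    pump = (
        p.vmax_pump_neuron
        * (na**h / (na**h + p.km_pump_na**h))
        * (atp**ha / (atp**ha + p.km_pump_atp**ha))
    )
    rate_atp = pump * p.na_volume_fraction / 3.0 * 1000.0  # uM/s
    rate_above_rest = rate_atp - rate_atp[0]
    cumulative = float(np.trapezoid(rate_above_rest, t))
    return rate_above_rest, cumulative
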