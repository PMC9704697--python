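"""Three-compartment kinetic model of energy metabolism (public surface).

Implements the astrocyte-neuron lactate shuttle: glycolysis and LDH in glia
and postsynaptic neuron, astrocytic glycogenolysis, glucose/lactate exchange
through the extracellular space, phenomenological mitochondrial ATP
production and ATP consumption by ion pumps and housekeeping load.

The flux formulas themselves live in :mod:`anls_ltp.dynamics`; this module
exposes the typed operations: :func:`compute_fluxes` and
:func:`steady_state`.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from . import dynamics
from .errors import InvalidStateError, NoSteadyStateError
from .params import Params
from .state import IX, N_STATES, MetabolicState, IonState

__all__ = ["compute_fluxes", "steady_state", "resting_vector", "default_guess"]

# states solved for at rest (metabolites + ions; traces/accumulators/W fixed)
_DYNAMIC = np.arange(int(IX.GLC_N), int(IX.NA_A) + 1)

_SS_CACHE: dict[str, np.ndarray] = {}


def compute_fluxes(state, ions=None, params: Params | None = None):
    """Evaluate all reaction/transport rates at one instant.

    ``state`` may be a :class:`MetabolicState` (with ``ions`` an
    :class:`IonState`) or a full flat state vector.
    """
    if params is None:
        raise ValueError("params is required")
    if isinstance(state, MetabolicState):
        state.validate(params)
        y = state.to_vector()
        if ions is not None:
            y[IX.NA_N] = ions.Na_neuron
            y[IX.NA_A] = ions.Na_astrocyte
            y[IX.CA] = ions.Ca_post
        else:
            y[IX.NA_N] = params.na_rest_neuron
            y[IX.NA_A] = params.na_rest_astro
            y[IX.CA] = params.ca_rest
        y[IX.W] = 1.0
    else:
        y = np.asarray(state, dtype=float)
        if not np.all(np.isfinite(y)):
            raise InvalidStateError("state vector contains non-finite entries")
        MetabolicState.from_vector(y).validate(params)
    p = dynamics.param_struct(params)
    return dynamics.evaluate_fluxes(y, p)


def default_guess(params: Params) -> np.ndarray:
    """Generic physiological starting point for the resting-state solve."""
    y = np.zeros(N_STATES)
    y[IX.GLC_N] = 2.0
    y[IX.PYR_N] = 0.04
    y[IX.LAC_N] = 0.8
    y[IX.NADH_N] = 0.45 * params.nad_tot_neuron
    y[IX.ATP_N] = 0.92 * params.adenine_pool_neuron
    y[IX.PCR_N] = 0.78 * params.pcr_pool_neuron
    y[IX.O2_N] = params.bath_o2
    y[IX.GLC_A] = 1.2
    y[IX.PYR_A] = 0.15
    y[IX.LAC_A] = 2.2
    y[IX.NADH_A] = 0.65 * params.nad_tot_astro
    y[IX.ATP_A] = 0.95 * params.adenine_pool_astro
    y[IX.GLYG_A] = 0.75 * params.glycogen_cap
    y[IX.O2_A] = params.bath_o2
    y[IX.GLC_E] = max(0.5, 0.75 * params.bath_glucose)
    y[IX.LAC_E] = 1.2
    y[IX.NA_N] = params.na_rest_neuron
    y[IX.NA_A] = params.na_rest_astro
    y[IX.CA] = params.ca_rest
    y[IX.W] = 1.0
    return y


def steady_state(
    params: Params,
    condition=None,
    tol: float = 1e-10,
    relax_time: float = 2.0e5,
    use_cache: bool = True,
) -> np.ndarray:
    """Solve for the resting state (all time derivatives vanish, no spikes).

    Returns a full state vector with traces and accumulators at zero and
    W = 1. Deterministic for fixed parameters. Raises
    :class:`NoSteadyStateError` (reporting the final residual) if the
    relax-then-polish scheme fails to reach ``tol`` (mM/s, per species).
    """
    from . import pharmacology

    base_params = params
    if condition is not None:
        params = pharmacology.apply(condition, params)
    key = params.hash()
    if use_cache and key in _SS_CACHE:
        return _SS_CACHE[key].copy()

    # For a pharmacological condition, follow the resting branch by
    # homotopy from the drug-free root: interpolate the changed parameters
    # in steps, polishing the root at each step. If the branch folds (the
    # healthy state genuinely disappears under the manipulation), fall back
    # to forward relaxation, which finds the state the tissue would reach.
    if condition is not None and params.diff(base_params):
        try:
            y = _continue_branch(base_params, params, tol)
        except NoSteadyStateError:
            y = None
        if y is not None:
            if use_cache:
                _SS_CACHE[key] = y.copy()
            return y.copy()

    p = dynamics.param_struct(params)

    def rest_rhs(t, y):
        return dynamics.rhs(t, y, p)

    # 0) cheap path: polish directly from the physiological guess; accept
    # only a converged *stable* root (guards against landing on the unstable
    # middle branch of a bistable metabolic regime)
    y = default_guess(params)
    cand, resid = _polish_root(y, p, tol, max_rel_step=2.0)
    if resid < tol and _is_stable(cand, p):
        cand[IX.CA] = params.ca_rest
        if use_cache:
            _SS_CACHE[key] = cand.copy()
        return cand.copy()

    # 1) relax by long forward integration from a generic guess
    sol = solve_ivp(
        rest_rhs,
        (0.0, relax_time),
        y,
        method="LSODA",
        rtol=1e-8,
        atol=1e-10,
    )
    y = sol.y[:, -1]
    # traces, accumulators and W are not part of the rest problem
    y[IX.GLU] = y[IX.DEP] = 0.0
    y[IX.PUMP_ATP_CUM] = y[IX.OX_CARBON_CUM] = 0.0
    y[IX.W] = 1.0
    y[IX.CA] = params.ca_rest

    # 2) polish with a root solve on the dynamic subset
    def residual(x):
        z = y.copy()
        z[_DYNAMIC] = x
        return dynamics.rhs(0.0, z, p)[_DYNAMIC]

    def _polish(anchor: np.ndarray) -> tuple[np.ndarray, float]:
        """Root-polish near ``anchor``; reject roots far from it (the
        steady state is defined as the limit of forward relaxation, and the
        polish must not jump to a different branch)."""
        out = anchor
        out_resid = np.max(np.abs(residual(anchor[_DYNAMIC])))
        scale = np.maximum(np.abs(anchor[_DYNAMIC]), 0.05)
        for method in ("hybr", "lm"):
            res = root(residual, anchor[_DYNAMIC], method=method, tol=1e-13)
            cand = anchor.copy()
            cand[_DYNAMIC] = res.x
            near = np.all(np.abs(res.x - anchor[_DYNAMIC]) / scale < 0.5)
            if near and np.all(cand[_DYNAMIC] >= -1e-9):
                cand[_DYNAMIC] = np.maximum(cand[_DYNAMIC], 0.0)
                r = np.max(np.abs(residual(cand[_DYNAMIC])))
                if r < out_resid:
                    out, out_resid = cand, r
        return out, out_resid

    y, resid = _polish(y)
    for attempt in range(3):
        if resid < tol:
            break
        sol = solve_ivp(
            rest_rhs, (0.0, relax_time * (2.0**attempt)), y, method="LSODA",
            rtol=1e-9, atol=1e-11,
        )
        y = sol.y[:, -1]
        y[IX.GLU] = y[IX.DEP] = 0.0
        y[IX.PUMP_ATP_CUM] = y[IX.OX_CARBON_CUM] = 0.0
        y[IX.W] = 1.0
        y[IX.CA] = params.ca_rest
        y, resid = _polish(y)
    if resid > tol:
        raise NoSteadyStateError(
            f"resting-state solve did not converge (residual {resid:.3e} mM/s)",
            residual=resid,
        )
    y[IX.CA] = params.ca_rest
    if use_cache:
        _SS_CACHE[key] = y.copy()
    return y.copy()


def _is_stable(y: np.ndarray, p, eps_eig: float = 1e-7) -> bool:
    """Numerical linear stability of a resting state (dynamic subset)."""
    n = len(_DYNAMIC)
    J = np.zeros((n, n))
    f0 = dynamics.rhs(0.0, y, p)[_DYNAMIC]
    for j, ix in enumerate(_DYNAMIC):
        h = max(1e-7, 1e-6 * abs(y[ix]))
        z = y.copy()
        z[ix] += h
        J[:, j] = (dynamics.rhs(0.0, z, p)[_DYNAMIC] - f0) / h
    return bool(np.max(np.linalg.eigvals(J).real) < eps_eig)


def _polish_root(y: np.ndarray, p, tol: float, max_rel_step: float = 0.6):
    """Root-polish near ``y``; returns (state, residual) or (y, inf) if the
    root jumps to a distant branch."""
    def residual(x):
        z = y.copy()
        z[_DYNAMIC] = x
        return dynamics.rhs(0.0, z, p)[_DYNAMIC]

    scale = np.maximum(np.abs(y[_DYNAMIC]), 0.05)
    best, best_resid = y, np.max(np.abs(residual(y[_DYNAMIC])))
    for method in ("hybr", "lm"):
        res = root(residual, y[_DYNAMIC], method=method, tol=1e-13)
        if np.any(np.abs(res.x - y[_DYNAMIC]) / scale > max_rel_step):
            continue
        if np.any(res.x < -1e-9):
            continue
        cand = y.copy()
        cand[_DYNAMIC] = np.maximum(res.x, 0.0)
        r = np.max(np.abs(residual(cand[_DYNAMIC])))
        if r < best_resid:
            best, best_resid = cand, r
    return best, best_resid


def _continue_branch(base_params: Params, cond_params: Params, tol: float) -> np.ndarray:
    """Track the resting branch from drug-free to condition parameters."""
    changed = cond_params.diff(base_params)
    y = steady_state(base_params)  # drug-free root (cached)
    n_steps = 8
    for k in range(1, n_steps + 1):
        lam = k / n_steps
        mix = base_params.with_overrides(
            {
                name: (1 - lam) * base_params[name] + lam * cond_params[name]
                for name in changed
            }
        )
        p = dynamics.param_struct(mix)
        y, resid = _polish_root(y, p, tol)
        if resid > tol:
            # give the intermediate system a little time, then re-polish
            sol = solve_ivp(
                lambda t, z: dynamics.rhs(t, z, p), (0.0, 2e4), y,
                method="LSODA", rtol=1e-9, atol=1e-11,
            )
            y = sol.y[:, -1]
            y, resid = _polish_root(y, p, tol)
        if resid > tol or not _is_stable(y, p):
            raise NoSteadyStateError(
                f"branch tracking failed at homotopy step {lam:.2f}",
                residual=resid,
            )
    y[IX.GLU] = y[IX.DEP] = 0.0
    y[IX.PUMP_ATP_CUM] = y[IX.OX_CARBON_CUM] = 0.0
    y[IX.W] = 1.0
    y[IX.CA] = cond_params.ca_rest
    return y


def resting_vector(params: Params, condition=None) -> MetabolicState:
    """Convenience: resting :class:`MetabolicState` under a condition."""
    return MetabolicState.from_vector(steady_state(params, condition))
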