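"""Pharmacological / substrate manipulations as parameter overrides.

Each condition is a named, composable set of overrides with an application
route: ``intracellular_neuron`` (pipette dialysis into the recorded neuron;
may only touch neuronal parameters) or ``bath`` (boundary conditions and
astrocytic / extracellular parameters). Inhibitors are treated as complete
blocks (rate x 0); substrate supplements are clamped supply terms or bath
boundary changes.

Built-in conditions:

================  ==============  ================================================
name              route           effect
================  ==============  ================================================
control           bath            identity
oxamate           intracellular   neuronal LDH rates -> 0
dab               bath            glycogen phosphorylase -> 0
mannoheptulose    intracellular   neuronal hexokinase -> 0
mk801             intracellular   NMDAR Ca/Na flux -> 0
lactate           bath            bath lactate clamp 10 mM
glucose_25        bath            bath glucose 25 mM
nadh              intracellular   slow clamp of neuronal NADH toward 4 mM
pyruvate          intracellular   slow clamp of neuronal pyruvate toward 10 mM
low_energy        intracellular   reduced pipette ATP / phosphocreatine pools
================  ==============  ================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from .errors import ConditionError
from .params import Params

__all__ = ["Override", "PharmacologyCondition", "CONDITIONS", "get_condition", "apply"]

# parameters that an intracellular (single-neuron) condition may modify
_NEURONAL_PREFIXES = (
    "ldh_vf_neuron",
    "ldh_vr_neuron",
    "vmax_hk_neuron",
    "nmda_scale",
    "k_nmda_ca",
    "k_nmda_na",
    "pyr_clamp_rate_neuron",
    "pyr_clamp_level_neuron",
    "nadh_clamp_rate_neuron",
    "nadh_clamp_level_neuron",
    "adenine_pool_neuron",
    "pcr_pool_neuron",
)


@dataclass(frozen=True)
class Override:
    """One parameter override: multiplicative ``scale`` or absolute ``set``."""

    path: str
    op: Literal["scale", "set"]
    value: float


@dataclass(frozen=True)
class PharmacologyCondition:
    """A named drug / substrate manipulation."""

    name: str
    overrides: tuple[Override, ...] = ()
    route: Literal["intracellular_neuron", "bath"] = "bath"

    def apply(self, params: Params) -> Params:
        return apply([self], params)


_DIALYSIS_RATE = 0.002  # 1/s, slow pipette equilibration


def _cond(name, route, *ovr):
    return PharmacologyCondition(name, tuple(Override(*o) for o in ovr), route)


CONDITIONS: dict[str, PharmacologyCondition] = {
    "control": _cond("control", "bath"),
    "oxamate": _cond(
        "oxamate",
        "intracellular_neuron",
        ("ldh_vf_neuron", "scale", 0.0),
        ("ldh_vr_neuron", "scale", 0.0),
    ),
    "dab": _cond("dab", "bath", ("vmax_gp", "scale", 0.0)),
    "mannoheptulose": _cond(
        "mannoheptulose", "intracellular_neuron", ("vmax_hk_neuron", "scale", 0.0)
    ),
    "mk801": _cond("mk801", "intracellular_neuron", ("nmda_scale", "scale", 0.0)),
    "lactate": _cond("lactate", "bath", ("bath_lactate", "set", 10.0)),
    "glucose_25": _cond("glucose_25", "bath", ("bath_glucose", "set", 25.0)),
    "nadh": _cond(
        "nadh",
        "intracellular_neuron",
        ("nadh_clamp_rate_neuron", "set", _DIALYSIS_RATE),
        ("nadh_clamp_level_neuron", "set", 4.0),
    ),
    "pyruvate": _cond(
        "pyruvate",
        "intracellular_neuron",
        ("pyr_clamp_rate_neuron", "set", _DIALYSIS_RATE),
        ("pyr_clamp_level_neuron", "set", 10.0),
    ),
    "low_energy": _cond(
        "low_energy",
        "intracellular_neuron",
        ("adenine_pool_neuron", "set", 2.5),
        ("pcr_pool_neuron", "set", 1.5),
    ),
}


def get_condition(name: str) -> PharmacologyCondition:
    key = name.strip().lower().replace("-", "_")
    aliases = {"glucose25": "glucose_25", "manno": "mannoheptulose"}
    key = aliases.get(key, key)
    if key not in CONDITIONS:
        raise ConditionError(
            f"unknown condition {name!r}; available: {sorted(CONDITIONS)}"
        )
    return CONDITIONS[key]


def _as_conditions(
    conditions: PharmacologyCondition | str | Iterable | None,
) -> list[PharmacologyCondition]:
    if conditions is None:
        return []
    if isinstance(conditions, (PharmacologyCondition, str)):
        conditions = [conditions]
    out = []
    for c in conditions:
        out.append(get_condition(c) if isinstance(c, str) else c)
    return out


def apply(conditions, params: Params) -> Params:
    """Apply one or several conditions, order-independently.

    Scale overrides on the same parameter compose multiplicatively; two
    ``set`` overrides (or a set and a scale) on the same parameter conflict
    unless they agree, and raise :class:`ConditionError`.
    """
    conds = _as_conditions(conditions)
    scales: dict[str, float] = {}
    sets: dict[str, float] = {}
    for cond in conds:
        for ovr in cond.overrides:
            if ovr.path not in params:
                raise ConditionError(
                    f"condition {cond.name!r} overrides unknown parameter "
                    f"{ovr.path!r}"
                )
            if cond.route == "intracellular_neuron" and ovr.path not in _NEURONAL_PREFIXES:
                raise ConditionError(
                    f"intracellular condition {cond.name!r} may not modify "
                    f"non-neuronal parameter {ovr.path!r}"
                )
            if ovr.op == "scale":
                if ovr.path in sets:
                    raise ConditionError(
                        f"conflicting overrides for {ovr.path!r} (set and scale)"
                    )
                scales[ovr.path] = scales.get(ovr.path, 1.0) * ovr.value
            else:
                if ovr.path in scales:
                    raise ConditionError(
                        f"conflicting overrides for {ovr.path!r} (set and scale)"
                    )
                if ovr.path in sets and sets[ovr.path] != ovr.value:
                    raise ConditionError(
                        f"conflicting set overrides for {ovr.path!r}"
                    )
                sets[ovr.path] = ovr.value
    out = params
    if scales:
        out = out.scaled(scales)
    if sets:
        out = out.with_overrides(sets)
    return out


def condition_names(conditions) -> str:
    conds = _as_conditions(conditions)
    return "+".join(c.name for c in conds) if conds else "control"
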