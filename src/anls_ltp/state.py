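"""State containers and the flat ODE state-vector layout.

The simulator integrates a single flat vector; this module owns the index
map and the typed views (:class:`MetabolicState`, :class:`IonState`) used by
the public API. NAD and ADP are not state variables: they are derived from
the fixed redox / adenine pools, which enforces both conservation laws
algebraically.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

__all__ = ["IX", "N_STATES", "MetabolicState", "IonState", "state_names"]


class IX(IntEnum):
    """Indices into the flat state vector."""

    # neuron metabolic
    GLC_N = 0
    PYR_N = 1
    LAC_N = 2
    NADH_N = 3
    ATP_N = 4
    PCR_N = 5
    O2_N = 6
    # astrocyte metabolic
    GLC_A = 7
    PYR_A = 8
    LAC_A = 9
    NADH_A = 10
    ATP_A = 11
    GLYG_A = 12
    O2_A = 13
    # extracellular (transport species only)
    GLC_E = 14
    LAC_E = 15
    # ions
    NA_N = 16
    NA_A = 17
    CA = 18  # uM, postsynaptic
    # synaptic drive traces
    GLU = 19
    DEP = 20
    # diagnostic accumulators
    PUMP_ATP_CUM = 21  # uM, activity-evoked Na,K-ATPase ATP, above rest
    OX_CARBON_CUM = 22  # mM glucosyl equivalents, tissue volume
    # synaptic weight
    W = 23


N_STATES = len(IX)

_NAMES = {
    IX.GLC_N: ("glucose_neuron", "mM"),
    IX.PYR_N: ("pyruvate_neuron", "mM"),
    IX.LAC_N: ("lactate_neuron", "mM"),
    IX.NADH_N: ("NADH_neuron", "mM"),
    IX.ATP_N: ("ATP_neuron", "mM"),
    IX.PCR_N: ("phosphocreatine_neuron", "mM"),
    IX.O2_N: ("oxygen_neuron", "mM"),
    IX.GLC_A: ("glucose_astrocyte", "mM"),
    IX.PYR_A: ("pyruvate_astrocyte", "mM"),
    IX.LAC_A: ("lactate_astrocyte", "mM"),
    IX.NADH_A: ("NADH_astrocyte", "mM"),
    IX.ATP_A: ("ATP_astrocyte", "mM"),
    IX.GLYG_A: ("glycogen_astrocyte", "mM"),
    IX.O2_A: ("oxygen_astrocyte", "mM"),
    IX.GLC_E: ("glucose_extracellular", "mM"),
    IX.LAC_E: ("lactate_extracellular", "mM"),
    IX.NA_N: ("Na_neuron", "mM"),
    IX.NA_A: ("Na_astrocyte", "mM"),
    IX.CA: ("Ca_post", "uM"),
    IX.GLU: ("glutamate_trace", "a.u."),
    IX.DEP: ("depolarization_trace", "a.u."),
    IX.PUMP_ATP_CUM: ("pump_ATP_cumulative", "uM"),
    IX.OX_CARBON_CUM: ("oxidized_carbon_cumulative", "mM"),
    IX.W: ("synaptic_weight", ""),
}


def state_names(with_units: bool = False) -> list[str]:
    """Ordered column names for trajectory tables."""
    if with_units:
        return [f"{n} ({u})" if u else n for n, u in (_NAMES[i] for i in IX)]
    return [_NAMES[i][0] for i in IX]


_METABOLIC_FIELDS = {
    "glucose_neuron": IX.GLC_N,
    "pyruvate_neuron": IX.PYR_N,
    "lactate_neuron": IX.LAC_N,
    "NADH_neuron": IX.NADH_N,
    "ATP_neuron": IX.ATP_N,
    "phosphocreatine_neuron": IX.PCR_N,
    "oxygen_neuron": IX.O2_N,
    "glucose_astrocyte": IX.GLC_A,
    "pyruvate_astrocyte": IX.PYR_A,
    "lactate_astrocyte": IX.LAC_A,
    "NADH_astrocyte": IX.NADH_A,
    "ATP_astrocyte": IX.ATP_A,
    "glycogen_astrocyte": IX.GLYG_A,
    "oxygen_astrocyte": IX.O2_A,
    "glucose_extracellular": IX.GLC_E,
    "lactate_extracellular": IX.LAC_E,
}


@dataclass
class MetabolicState:
    """Concentrations of energy metabolites per compartment at one instant.

    Glycogen exists only in the astrocyte; the extracellular space carries
    transport species (glucose, lactate) only.
    """

    glucose_neuron: float
    pyruvate_neuron: float
    lactate_neuron: float
    NADH_neuron: float
    ATP_neuron: float
    phosphocreatine_neuron: float
    oxygen_neuron: float
    glucose_astrocyte: float
    pyruvate_astrocyte: float
    lactate_astrocyte: float
    NADH_astrocyte: float
    ATP_astrocyte: float
    glycogen_astrocyte: float
    oxygen_astrocyte: float
    glucose_extracellular: float
    lactate_extracellular: float

    @classmethod
    def from_vector(cls, y: np.ndarray) -> "MetabolicState":
        return cls(**{f: float(y[i]) for f, i in _METABOLIC_FIELDS.items()})

    def to_vector(self, y: np.ndarray | None = None) -> np.ndarray:
        """Write the metabolic fields into (a copy of) a full state vector."""
        out = np.zeros(N_STATES) if y is None else np.array(y, dtype=float)
        for f, i in _METABOLIC_FIELDS.items():
            out[i] = getattr(self, f)
        return out

    def validate(self, params) -> None:
        """Raise ``InvalidStateError`` on negative or non-finite entries or
        pool violations."""
        from .errors import InvalidStateError

        for f in _METABOLIC_FIELDS:
            v = getattr(self, f)
            if not np.isfinite(v):
                raise InvalidStateError(f"{f} is not finite")
            if v < 0:
                raise InvalidStateError(f"{f} is negative ({v})")
        if self.NADH_neuron > params.nad_tot_neuron + 1e-12:
            raise InvalidStateError("neuronal NADH exceeds the redox pool")
        if self.NADH_astrocyte > params.nad_tot_astro + 1e-12:
            raise InvalidStateError("astrocytic NADH exceeds the redox pool")
        if self.ATP_neuron > params.adenine_pool_neuron + 1e-12:
            raise InvalidStateError("neuronal ATP exceeds the adenine pool")
        if self.ATP_astrocyte > params.adenine_pool_astro + 1e-12:
            raise InvalidStateError("astrocytic ATP exceeds the adenine pool")

    # Derived species (pool conservation is enforced here, not integrated).
    def NAD_neuron(self, params) -> float:
        return params.nad_tot_neuron - self.NADH_neuron

    def NAD_astrocyte(self, params) -> float:
        return params.nad_tot_astro - self.NADH_astrocyte

    def ADP_neuron(self, params) -> float:
        return params.adenine_pool_neuron - self.ATP_neuron

    def ADP_astrocyte(self, params) -> float:
        return params.adenine_pool_astro - self.ATP_astrocyte


@dataclass
class IonState:
    """Neuronal/astrocytic Na and postsynaptic Ca plus pump bookkeeping."""

    Na_neuron: float
    Na_astrocyte: float
    Ca_post: float  # uM
    cumulative_ATP_for_Na_extrusion: float  # uM

    @classmethod
    def from_vector(cls, y: np.ndarray) -> "IonState":
        return cls(
            Na_neuron=float(y[IX.NA_N]),
            Na_astrocyte=float(y[IX.NA_A]),
            Ca_post=float(y[IX.CA]),
            cumulative_ATP_for_Na_extrusion=float(y[IX.PUMP_ATP_CUM]),
        )
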