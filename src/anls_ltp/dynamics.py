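"""Numeric core: rate laws, flux evaluation and the full ODE right-hand side.

All rate laws follow the conventions of kinetic neuro-glia metabolic models:
reversible Michaelis-Menten for transporters, Michaelis-Menten or mass
action for enzymes, and a phenomenological mitochondrial ATP production
driven by pyruvate, cytosolic NADH (malate-aspartate shuttle, lumped), ADP
availability and oxygen. Glycolytic intermediates between hexokinase and
pyruvate are lumped into a single flux; glucose-1-phosphate is folded into
the glycogen phosphorylase flux.

Units: mM and seconds (postsynaptic Ca in uM). Transmembrane fluxes are
expressed in mM/s of the cellular compartment; the extracellular derivative
is volume-corrected.
"""

from __future__ import annotations

from types import SimpleNamespace
from typing import NamedTuple

import numpy as np

from .state import IX, N_STATES

__all__ = ["FluxVector", "evaluate_fluxes", "rhs", "param_struct"]


def param_struct(params) -> SimpleNamespace:
    """Flatten a Params table into a plain attribute struct for fast access."""
    return SimpleNamespace(**params.to_dict())


def _mm(x: float, k: float) -> float:
    x = x if x > 0.0 else 0.0
    return x / (x + k)


def _pos(x: float) -> float:
    return x if x > 0.0 else 0.0


class FluxVector(NamedTuple):
    """Signed rates for every reaction/transport arrow of the model.

    Sign conventions: transporters positive into the named cell compartment
    (MCT astro positive = export to ECS); LDH positive in the
    pyruvate+NADH -> lactate+NAD direction; pump fluxes are Na extrusion
    rates (mM Na/s in their compartment).
    """

    # transport
    glc_bath_ecs: float
    glc_uptake_neuron: float
    glc_uptake_astro: float
    lac_bath_ecs: float
    lac_uptake_neuron: float
    lac_export_astro: float
    # neuron metabolism
    glycolysis_neuron: float  # glucose units
    ldh_neuron: float
    mito_neuron: float  # pyruvate oxidation, pyruvate units
    shuttle_neuron: float  # cytosolic NADH oxidation via shuttle, NADH units
    creatine_kinase: float
    housekeeping_neuron: float
    pump_na_neuron: float  # Na extrusion, mM Na/s
    pump_atp_neuron: float  # cytosolic ATP cost of Na extrusion, mM/s
    # astrocyte metabolism
    glycolysis_astro: float  # glucose units
    glycogenolysis: float  # glucosyl units
    glycogen_synthesis: float  # glucosyl units
    ldh_astro: float
    mito_astro: float
    shuttle_astro: float
    housekeeping_astro: float
    pump_na_astro: float
    pump_atp_astro: float
    # oxygen
    o2_supply_neuron: float
    o2_supply_astro: float
    # pipette dialysis
    pyr_dialysis_neuron: float
    nadh_dialysis_neuron: float


def evaluate_fluxes(y: np.ndarray, p: SimpleNamespace) -> FluxVector:
    """Evaluate every flux at state ``y`` under parameter struct ``p``."""
    glc_n = y[IX.GLC_N]
    pyr_n = _pos(y[IX.PYR_N])
    lac_n = _pos(y[IX.LAC_N])
    nadh_n = _pos(y[IX.NADH_N])
    atp_n = _pos(y[IX.ATP_N])
    pcr_n = _pos(y[IX.PCR_N])
    o2_n = y[IX.O2_N]
    glc_a = y[IX.GLC_A]
    pyr_a = _pos(y[IX.PYR_A])
    lac_a = _pos(y[IX.LAC_A])
    nadh_a = _pos(y[IX.NADH_A])
    atp_a = _pos(y[IX.ATP_A])
    glyg = _pos(y[IX.GLYG_A])
    o2_a = y[IX.O2_A]
    glc_e = y[IX.GLC_E]
    lac_e = _pos(y[IX.LAC_E])
    na_n = y[IX.NA_N]
    na_a = y[IX.NA_A]

    nad_n = _pos(p.nad_tot_neuron - nadh_n)
    nad_a = _pos(p.nad_tot_astro - nadh_a)
    adp_n = _pos(p.adenine_pool_neuron - atp_n)
    adp_a = _pos(p.adenine_pool_astro - atp_a)
    cr_n = _pos(p.pcr_pool_neuron - pcr_n)

    # glucose transport (reversible MM)
    glc_bath = p.tmax_glc_bath * (_mm(p.bath_glucose, p.km_glut) - _mm(glc_e, p.km_glut))
    glut_n = p.tmax_glut_neuron * (_mm(glc_e, p.km_glut) - _mm(glc_n, p.km_glut))
    glut_a = p.tmax_glut_astro * (_mm(glc_e, p.km_glut) - _mm(glc_a, p.km_glut))

    # lactate transport (perfusion exchange is linear in concentration)
    lac_bath = p.k_bath_lac * (p.bath_lactate - lac_e)
    mct_n = p.tmax_mct_neuron * (_mm(lac_e, p.km_mct_neuron) - _mm(lac_n, p.km_mct_neuron))
    mct_a = p.tmax_mct_astro * (_mm(lac_a, p.km_mct_astro) - _mm(lac_e, p.km_mct_astro))

    # lumped glycolysis (hexokinase-limited, pyruvate product-inhibited),
    # glucose units
    # neuronal glycolysis: broad ADP activation (sets the glycolytic resting
    # regime under LDH block) combined with a narrow ultrasensitive switch
    # around the working point (steep but hard-capped spare capacity,
    # zero-order ultrasensitive energy sensing)
    z = (adp_n - p.gly_adp_switch) / p.gly_adp_width
    if z > 40.0:
        sw = 1.0
    elif z < -40.0:
        sw = 0.0
    else:
        sw = 1.0 / (1.0 + np.exp(-z))
    broad = adp_n * adp_n / (adp_n * adp_n + p.km_gly_adp_neuron**2)
    adp_act_n = broad * (1.0 + p.gly_adp_boost * sw)
    hk_n = (
        p.vmax_hk_neuron
        * _mm(glc_n, p.km_hk_glc)
        * adp_act_n
        * _mm(nad_n, p.km_gly_nad)
        * (p.ki_pyr_gly / (p.ki_pyr_gly + pyr_n))
    )
    hk_a = (
        p.vmax_hk_astro
        * _mm(glc_a, p.km_hk_glc)
        * _mm(adp_a, p.km_gly_adp_astro)
        * _mm(nad_a, p.km_gly_nad)
        * (p.ki_pyr_gly / (p.ki_pyr_gly + pyr_a))
    )

    # astrocytic glycogen turnover (glucosyl units)
    gp = (
        p.vmax_gp
        * _mm(glyg, p.km_glyg)
        * (1.0 + p.gp_adp_gain * _mm(adp_a, p.km_gp_adp))
        * _mm(nad_a, p.km_gly_nad)
        * (p.ki_pyr_gly / (p.ki_pyr_gly + pyr_a))
    )
    gs = (
        p.vmax_gs
        * _mm(glc_a, p.km_gs_glc)
        * _mm(atp_a, p.km_gs_atp)
        * _pos(1.0 - glyg / p.glycogen_cap)
    )

    # LDH, reversible saturable kinetics, pyr + NADH -> lac + NAD positive
    ldh_n = p.ldh_vf_neuron * _mm(pyr_n, p.km_ldh_pyr) * _mm(nadh_n, p.km_ldh_nadh) - (
        p.ldh_vr_neuron * _mm(lac_n, p.km_ldh_lac) * _mm(nad_n, p.km_ldh_nad)
    )
    ldh_a = p.ldh_vf_astro * _mm(pyr_a, p.km_ldh_pyr) * _mm(nadh_a, p.km_ldh_nadh) - (
        p.ldh_vr_astro * _mm(lac_a, p.km_ldh_lac) * _mm(nad_a, p.km_ldh_nad)
    )

    # mitochondrial pyruvate oxidation (pyruvate units); the cytosolic NADH
    # term is regulatory with cooperativity: an oxidized cytosol throttles
    # oxidative ATP output
    hm = p.hill_mito_nadh
    nadh_gate_n = nadh_n**hm / (nadh_n**hm + p.km_mito_nadh**hm)
    # the astrocyte, robustly glycolytic, is only weakly redox-gated
    nadh_gate_a = _mm(nadh_a, p.km_mito_nadh_astro)
    # the neuronal oxidative machinery shares the ultrasensitive ADP switch
    # (fast, hard-capped output boost drawn from standing pyruvate/NADH) and
    # is further stimulated by postsynaptic calcium (Ca-activated
    # dehydrogenases)
    ca_above = _pos(y[IX.CA] - p.ca_rest)
    hca = p.hill_mito_ca
    ca_act = ca_above**hca / (ca_above**hca + p.km_mito_ca**hca)
    fast_boost = (1.0 + p.mito_adp_boost * sw) * (1.0 + p.mito_ca_boost * ca_act)
    mito_n = (
        p.vmax_mito_neuron
        * _mm(pyr_n, p.km_mito_pyr)
        * nadh_gate_n
        * _mm(adp_n, p.km_mito_adp)
        * _mm(o2_n, p.km_mito_o2)
        * fast_boost
    )
    mito_a = (
        p.vmax_mito_astro
        * _mm(pyr_a, p.km_mito_pyr)
        * nadh_gate_a
        * _mm(adp_a, p.km_mito_adp)
        * _mm(o2_a, p.km_mito_o2)
    )
    # malate-aspartate shuttle (lumped): oxidizes cytosolic NADH for ATP
    sh_n = (
        p.vmax_shuttle_neuron
        * _mm(nadh_n, p.km_shuttle_nadh)
        * _mm(adp_n, p.km_mito_adp)
        * _mm(o2_n, p.km_mito_o2)
        * fast_boost
    )
    sh_a = (
        p.vmax_shuttle_astro
        * _mm(nadh_a, p.km_shuttle_nadh)
        * _mm(adp_a, p.km_mito_adp)
        * _mm(o2_a, p.km_mito_o2)
    )

    # creatine kinase: PCr + ADP -> Cr + ATP positive
    ck = p.k_ck * (pcr_n * adp_n - cr_n * atp_n / p.keq_ck)

    # ATP consumption
    house_n = p.k_house_neuron * _mm(atp_n, p.km_house_atp) + p.k_house_lin_neuron * atp_n
    house_a = p.k_house_astro * _mm(atp_a, p.km_house_atp) + p.k_house_lin_astro * atp_a

    # Na,K-ATPase (Na extrusion in mM Na/s of the Na compartment)
    na_pos = _pos(na_n)
    h = p.hill_pump_na
    pump_n = (
        p.vmax_pump_neuron
        * (na_pos**h / (na_pos**h + p.km_pump_na**h))
        * (atp_n ** p.hill_pump_atp / (atp_n ** p.hill_pump_atp + p.km_pump_atp ** p.hill_pump_atp))
    )
    pump_a = (
        p.vmax_pump_astro
        * _mm(_pos(na_a), p.km_pump_na_astro)
        * _mm(atp_a, p.km_pump_atp_astro)
    )
    # 3 Na per ATP; neuronal Na transients live in a dendritic sub-volume
    pump_atp_n = pump_n * p.na_volume_fraction / 3.0
    pump_atp_a = pump_a / 3.0

    o2_sup_n = p.k_o2_supply * (p.bath_o2 - o2_n)
    o2_sup_a = p.k_o2_supply * (p.bath_o2 - o2_a)

    pyr_dial = p.pyr_clamp_rate_neuron * (p.pyr_clamp_level_neuron - pyr_n)
    nadh_dial = p.nadh_clamp_rate_neuron * (p.nadh_clamp_level_neuron - nadh_n)

    return FluxVector(
        glc_bath_ecs=glc_bath,
        glc_uptake_neuron=glut_n,
        glc_uptake_astro=glut_a,
        lac_bath_ecs=lac_bath,
        lac_uptake_neuron=mct_n,
        lac_export_astro=mct_a,
        glycolysis_neuron=hk_n,
        ldh_neuron=ldh_n,
        mito_neuron=mito_n,
        shuttle_neuron=sh_n,
        creatine_kinase=ck,
        housekeeping_neuron=house_n,
        pump_na_neuron=pump_n,
        pump_atp_neuron=pump_atp_n,
        glycolysis_astro=hk_a,
        glycogenolysis=gp,
        glycogen_synthesis=gs,
        ldh_astro=ldh_a,
        mito_astro=mito_a,
        shuttle_astro=sh_a,
        housekeeping_astro=house_a,
        pump_na_astro=pump_a,
        pump_atp_astro=pump_atp_a,
        o2_supply_neuron=o2_sup_n,
        o2_supply_astro=o2_sup_a,
        pyr_dialysis_neuron=pyr_dial,
        nadh_dialysis_neuron=nadh_dial,
    )


def rhs(t: float, y: np.ndarray, p: SimpleNamespace, rest_pump_atp: float = 0.0) -> np.ndarray:
    """Time derivative of the full state vector.

    ``rest_pump_atp`` is the resting neuronal pump ATP rate (mM/s) used as
    the baseline for the activity-evoked consumption accumulator.
    """
    from .plasticity import weight_drift  # local import to avoid a cycle

    f = evaluate_fluxes(y, p)
    dy = np.zeros(N_STATES)

    vn, va, ve = p.vol_neuron, p.vol_astro, p.vol_ecs

    # --- neuron ---
    dy[IX.GLC_N] = f.glc_uptake_neuron - f.glycolysis_neuron
    dy[IX.PYR_N] = (
        2.0 * f.glycolysis_neuron - f.ldh_neuron - f.mito_neuron + f.pyr_dialysis_neuron
    )
    dy[IX.LAC_N] = f.ldh_neuron + f.lac_uptake_neuron
    dy[IX.NADH_N] = (
        2.0 * f.glycolysis_neuron
        - f.ldh_neuron
        - f.shuttle_neuron
        + f.nadh_dialysis_neuron
    )
    dy[IX.ATP_N] = (
        2.0 * f.glycolysis_neuron
        + p.atp_per_pyruvate * f.mito_neuron
        + p.atp_per_nadh * f.shuttle_neuron
        + f.creatine_kinase
        - f.housekeeping_neuron
        - f.pump_atp_neuron
    )
    dy[IX.PCR_N] = -f.creatine_kinase
    dy[IX.O2_N] = (
        f.o2_supply_neuron
        - p.o2_per_pyruvate * f.mito_neuron
        - 0.5 * f.shuttle_neuron
    )

    # --- astrocyte ---
    dy[IX.GLC_A] = (
        f.glc_uptake_astro
        - f.glycolysis_astro
        - f.glycogen_synthesis
        + p.k_glyg_leak * y[IX.GLYG_A]  # basal glycogen turnover (debranching)
    )
    dy[IX.PYR_A] = (
        2.0 * f.glycolysis_astro + 2.0 * f.glycogenolysis - f.ldh_astro - f.mito_astro
    )
    dy[IX.LAC_A] = f.ldh_astro - f.lac_export_astro
    dy[IX.NADH_A] = (
        2.0 * f.glycolysis_astro
        + 2.0 * f.glycogenolysis
        - f.ldh_astro
        - f.shuttle_astro
    )
    dy[IX.ATP_A] = (
        2.0 * f.glycolysis_astro
        + 3.0 * f.glycogenolysis
        - 2.0 * f.glycogen_synthesis
        + p.atp_per_pyruvate * f.mito_astro
        + p.atp_per_nadh * f.shuttle_astro
        - f.housekeeping_astro
        - f.pump_atp_astro
    )
    # basal glycogen turnover keeps the pool determinate when the
    # phosphorylase flux is pharmacologically blocked
    dy[IX.GLYG_A] = (
        f.glycogen_synthesis - f.glycogenolysis - p.k_glyg_leak * y[IX.GLYG_A]
    )
    dy[IX.O2_A] = (
        f.o2_supply_astro
        - p.o2_per_pyruvate * f.mito_astro
        - 0.5 * f.shuttle_astro
    )

    # --- extracellular ---
    dy[IX.GLC_E] = (
        f.glc_bath_ecs
        - (vn / ve) * f.glc_uptake_neuron
        - (va / ve) * f.glc_uptake_astro
    )
    dy[IX.LAC_E] = (
        f.lac_bath_ecs
        + (va / ve) * f.lac_export_astro
        - (vn / ve) * f.lac_uptake_neuron
    )

    # --- ions and synaptic drive traces ---
    glu = y[IX.GLU]
    dep = y[IX.DEP]
    # NMDAR Mg-unblock and VGCC activation both saturate with depolarization
    unblock = dep * dep / (dep * dep + p.v50_nmda * p.v50_nmda) if dep > 0 else 0.0
    vgcc_act = dep / (dep + p.v50_vgcc) if dep > 0 else 0.0
    gv = glu * unblock * p.nmda_scale
    # regenerative VGSC Na influx recruited by suprathreshold depolarization
    # (bAPs and burst-summated EPSPs; single EPSPs stay subthreshold)
    vgsc = p.k_na_vgsc * max(0.0, dep - p.vgsc_threshold)
    dy[IX.NA_N] = (
        p.na_leak_neuron
        - f.pump_na_neuron
        - p.k_ncx_neuron * (y[IX.NA_N] - p.na_floor_neuron)
        + p.k_nmda_na * gv
        + vgsc
    )
    dy[IX.NA_A] = (
        p.na_leak_astro
        - f.pump_na_astro
        - p.k_ncx_astro * (y[IX.NA_A] - p.na_floor_astro)
    )
    dy[IX.CA] = (
        (p.ca_rest - y[IX.CA]) / p.tau_ca
        + p.k_nmda_ca * gv
        + p.k_vgcc_ca * vgcc_act
    )
    dy[IX.GLU] = -glu / p.tau_glu
    dy[IX.DEP] = -dep / p.tau_dep

    # --- accumulators ---
    dy[IX.PUMP_ATP_CUM] = 1000.0 * (f.pump_atp_neuron - rest_pump_atp)
    dy[IX.OX_CARBON_CUM] = 0.5 * (vn * f.mito_neuron + va * f.mito_astro)

    # --- synaptic weight ---
    dy[IX.W] = weight_drift(y[IX.W], y[IX.CA], y[IX.ATP_N], p)

    return dy
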