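# Model description and methods

`anls_ltp` simulates a single CA1 postsynaptic compartment, an adjacent
astrocyte and the extracellular space between them, coupled to an
event-driven synapse and a bistable synaptic-weight rule. This note
documents the model equations and assumptions, the parameters that matter
and why they hold their default values, what the synthetic-data generator
does and does not emulate, the numerical choices, and the limitations we
know about.

## 1. Scope and state

The state vector has 24 entries: per-compartment energy metabolites
(glucose, pyruvate, lactate, NADH, ATP; phosphocreatine and O₂ in the cells;
glycogen in the astrocyte; glucose and lactate in the extracellular space),
neuronal and astrocytic Na⁺, postsynaptic Ca²⁺ (µM), two synaptic drive
traces (bound glutamate and depolarization), two diagnostic accumulators
(activity-evoked pump ATP; oxidized carbon) and the synaptic weight W.
NAD⁺ and ADP are not integrated: they are derived from fixed redox and
adenine pools, which enforces both conservation laws exactly. Units are mM
and seconds throughout (Ca in µM); compartment volume fractions
(0.45/0.25/0.20) convert transmembrane fluxes.

## 2. Metabolic core

Rate-law conventions follow the kinetic neuro–glia modelling literature:
reversible Michaelis–Menten transporters (GLUT, MCT), saturable reversible
LDH, lumped glycolysis, and phenomenological mitochondria. Glycolytic
intermediates are folded into a single hexokinase-limited flux
(glucose + 2 NAD⁺ → 2 pyruvate + 2 NADH, net 2 ATP); glucose-1-phosphate is
folded into the glycogen-phosphorylase flux.

Design choices that carry the model's behaviour:

* **Two oxidative fluxes.** Pyruvate oxidation (12.5 ATP per pyruvate)
  carries most of the ATP but is *gated by cytosolic NADH* with
  cooperativity (Hill 2, K 0.5 mM): an oxidized cytosol throttles oxidative
  output. A separate lumped malate–aspartate-shuttle flux oxidizes
  cytosolic NADH directly (2.5 ATP per NADH). This split is the minimal
  structure under which supplementing NADH restores ATP production when LDH
  is blocked, while supplementing pyruvate does not — the redox product of
  the LDH reaction, not its carbon product, is what the blocked neuron is
  missing.
* **Saturable LDH.** Pure mass-action LDH admits an unphysical runaway in
  which accumulating pyruvate drains the entire NADH pool; saturable
  kinetics (Km: pyruvate 0.3, lactate 3.0, NAD(H) 0.5 mM) bound the flux
  and remove that attractor while keeping the enzyme close to equilibrium
  at rest.
* **Glycogen shunt.** Astrocytic glucose is routed predominantly through
  glycogen (synthesis, then phosphorylase-limited glycogenolysis with mild
  ADP activation); direct astrocytic glycolysis is small. Consequently the
  astrocyte's lactate export — the neuron's lactate supply — collapses when
  glycogen phosphorylase is blocked, as the pharmacology requires. A basal
  glycogen turnover (2·10⁻⁶ s⁻¹, returned to the glucose pool so carbon is
  conserved) keeps the pool determinate when the phosphorylase flux is
  zero.
* **The LDH valve.** Resting neuronal pyruvate sits well above the
  mitochondrial pyruvate Km (0.6 mM). When extracellular lactate is scarce
  (glycogenolysis blocked), neuronal LDH runs forward, regenerating lactate
  that leaks out through the MCT: the neuron bleeds carbon and reducing
  equivalents and its resting ATP falls below the depotentiation threshold.
  This is how a *bath* manipulation of the astrocyte reaches the neuron.
* **Ultrasensitive energy sensing.** Neuronal glycolysis and the oxidative
  fluxes share a narrow sigmoidal ADP switch (centre 2.40 mM ADP, width
  0.03 mM) on top of a broad Hill-2 ADP activation. The broad term sets
  where the LDH-blocked neuron comes to rest (≈ 2.1 mM ATP, about half of
  control); the narrow switch provides a steep but hard-capped spare
  capacity (~2–3 µM ATP/s) around that working point. Zero-order
  ultrasensitivity of this kind is standard in covalent-modification
  energy-sensing cascades; here it is the feature that lets a sustained
  1-bAP pairing load (≈ 1.7 µM/s) be covered indefinitely while a 2-bAP
  load (≈ 4 µM/s) overruns the cap and digs into the buffer.
* **Ca²⁺-activated mitochondria.** Oxidative output is further stimulated
  by postsynaptic Ca²⁺ (Hill 4, K 1.1 µM) — the classic Ca activation of
  mitochondrial dehydrogenases. Only large (theta-burst-scale) calcium
  transients engage it, which buys the burst protocols extra oxidative
  capacity relative to pairing protocols of similar total load.
* **Phosphocreatine.** A creatine-kinase equilibrium buffers neuronal ATP.
  The effective CK-accessible pool is 3 mM: large enough to smooth
  transients, small enough that second-scale energy deficits remain visible
  in ATP.
* **Oxygen** is supplied first-order from a clamped bath and is never
  limiting at default settings; no oxygen-limitation claim is modelled.

The resting state is solved per pharmacological condition by parameter
homotopy: the drug-free root is polished first, then the changed parameters
are interpolated in eight steps with a stability-checked root polish at
each. If the branch genuinely folds (e.g. hexokinase + LDH both blocked),
the solver falls back to forward relaxation and reports the collapsed state
the tissue would actually reach.

## 3. Electrophysiology

Spikes are instantaneous events with stereotyped consequences — there is no
membrane-potential solver. A presynaptic stimulation increments a saturating
glutamate trace (τ = 0.1 s) and a depolarization trace (EPSP, 0.35 a.u.);
a bAP increments depolarization by 1.0. Depolarization jumps are amplified
regeneratively by existing depolarization (gain 1.2, capped at 4): temporal
summation within 100-Hz bursts, or a second bAP 10 ms after the first,
recruits dendritic spikes. Continuous fluxes then follow the traces:

* NMDAR Ca²⁺ ∝ glutamate × Mg-unblock(V) (sigmoidal, V₅₀ 0.35) — the
  coincidence detector; zeroed by the open-channel blocker condition.
* VGCC Ca²⁺ ∝ saturating V.
* VGSC Na⁺ ∝ max(0, V − 0.42): single EPSPs stay subthreshold; bursts and
  bAPs do not. AMPAR Na⁺ is a fixed jump per presynaptic event.
* Astrocytic EAAT Na⁺: 3 Na⁺ co-transported per glutamate event.

Na⁺ is removed by the Na,K-ATPase (Hill 8 in Na, Km 12.8 mM; ATP-dependent
with Hill 4, Km 1.8 mM — pump efficacy degrades steeply exactly in the
ATP range where the LDH-blocked neuron operates) plus a small
ATP-independent linear exchanger. Pump ATP consumption is scaled by the
dendritic sub-volume fraction (0.115) in which the activity-evoked Na lives,
and integrated above its resting rate into the `pump_ATP_cumulative`
accumulator (µM) — the model's read-out of the energetic cost of a
protocol.

The event amplitudes and gains were calibrated jointly so that, under
control conditions, the 50-pairing STDP protocol and the 5-train theta
burst reproduce the model's headline transient predictions: peak Na rise
0.6 vs 3.2 mM, peak Ca 0.75 vs 1.5 µM, pump ATP 90 vs 300 µM, and a two-bAP
calcium transient roughly twice the single-bAP one.

## 4. Plasticity rule

W follows a cubic bistable drift with stable points at baseline (1.0) and
potentiated (1.8) separated by an unstable point (1.3), weight time
constant 240 s. Two smooth gated drives act on it: potentiation
(gain 0.25 s⁻¹, saturating as W → 3) while Ca > LTPStart = 0.5 µM
(gate width 0.025 µM), and depotentiation (gain 0.08 s⁻¹, proportional to
W − 1, hence unable to push W below baseline) while ATP < ATPThr = 2.049 mM.
The ATP gate is deliberately sharp (width 1 µM): the ATP dips that separate
passing from failing protocols differ by only tens of µM, so a percent-wide
gate would blur the phenotype. The depotentiation drive is reversible; an
outcome becomes irreversible only through the bistable dynamics (once W has
been pulled below the unstable point, it relaxes to baseline even after ATP
recovers). Outcomes are classified from mean W at 50–60 min post-protocol:
LTP ≥ 110 %, LTD ≤ 90 % (configurable).

Because W does not feed back onto metabolism or ion dynamics, plasticity
parameters can be refitted by re-integrating the scalar W equation over
stored Ca/ATP trajectories (midpoint rule on the solver's output grid, with
an optional numba kernel). The calibration module exploits this: weighted
least squares, multi-start from Latin-hypercube initials, identifiability
flagged via degenerate Jacobian columns, and held-out truth-table
validation with an explicit overlap check.

## 5. Stimulation protocols

Theta burst: 4 pulses at 100 Hz per burst, 10 bursts at 5 Hz per train,
trains at 0.1 Hz — "5-TBS" delivers exactly 200 stimulations. The
pulses-per-burst count is fixed by that printed total. STDP: pre-then-post
pairings at +10 ms, one or two bAPs (10 ms apart) per pairing, at 0.5 or
1 Hz; only positive spike-timing delays are in scope. Compilation to event
trains is deterministic, order-stable (presynaptic first on ties) and
validated against overlapping schedules.

## 6. Simulator

A run mirrors the experimental timeline: condition-specific steady state,
10-min baseline, protocol with the stiff integrator (LSODA, rtol 10⁻⁶,
atol 10⁻⁹) restarted at every spike time, and a 61-min follow-up. Output is
sampled at 5 ms during the protocol and 2 s elsewhere. Summaries (peak ΔNa,
peak Ca, cumulative pump ATP, minimum ATP, outcome) are recomputable from
the stored trajectories and tested against independent recomputation.
Halving the solver tolerances changes outcome magnitudes by far less than
0.5 %. The model is fully deterministic; nothing in the simulator consumes
random numbers.

## 7. Synthetic data

`synth.generate_timecourse` / `generate_cohort` emulate normalized-EPSC
recordings: one sample per minute, a 10-min baseline at 100 %, a 60-min
follow-up starting after the protocol, multiplicative log-normal noise
(default CV 5 %), optional log-normal cell-level scaling and per-cell
dispersion of plasticity parameters. Ground truth is always stored beside
the observations. The generator does **not** emulate raw electrophysiology:
no EPSC waveforms, no synaptic failures or short-term plasticity, no
recording drift, no inter-animal structure. Passing recovery tests on these
data therefore demonstrates self-consistency of the fitting machinery at
realistic noise levels, not robustness to every artefact of real slices.

## 8. Numerical choices and degenerate inputs

Steady states are accepted below a 10⁻¹⁰ mM/s residual with a linear
stability check; root polishes that jump far from the relaxation endpoint
are rejected (the steady state is defined as the limit of forward
relaxation). Concentrations are clamped non-negative inside rate laws to
tolerate integrator micro-undershoots. Simultaneous events are applied in
timestamp order with presynaptic before postsynaptic. Sweep grids must be
sorted and finite; non-monotone outcome maps report all change points
rather than silently choosing one. Phase-map results are cached by
(protocol, condition, parameter-hash).

## 9. Parameter provenance and problem sizes

Every parameter in `data/default_params.yaml` carries a provenance tag:
`base` (structural defaults from the neuro–glia modelling conventions) or
`recalibrated` (tuned against the model's own quantitative predictions and
weight time courses, as the parameter-estimation strategy prescribes —
calibration used only the 5-TBS and 50-pairing control protocols plus the
resting-state targets; all other protocol × condition phenotypes are
predictions of the calibrated model). Test and acceptance runs use the full
protocol sizes (200-pulse theta bursts, up to 500 pairings); a complete
suite runs in about a minute on one CPU because each 71-minute experiment
integrates in well under a second.

## 10. Known limitations

* Compartments are well mixed; there are no spatial gradients, no
  neurovascular coupling and no pentose-phosphate branch.
* Inhibitors are all-or-none (rate × 0); no dose–response.
* The depression observed in vivo after behaviour is outside the model:
  depotentiation here can only return W to baseline.
* Under combined hexokinase + LDH block, or pyruvate dialysis with LDH
  blocked, the model neuron settles into a deeply energy-depleted state —
  adequate for "no plasticity", but the absolute Na/ATP values in that
  regime should not be over-interpreted.
* The reduced-pipette-energy condition (`low_energy`) is provided but its
  plasticity phenotype has not been calibrated.
* The astrocyte's own energy state degrades when glycogenolysis is blocked;
  no claim about astrocytic viability is intended.
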