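# anls-ltp

**Energy-constrained synaptic plasticity in a neuro–glia unit.**

Hippocampal long-term potentiation (LTP) is metabolically expensive, and the
fuel it runs on depends on how it is induced. Rate-coded induction (theta-burst
stimulation, hundreds of pulses) requires astrocyte-derived lactate — glycogen
is mobilised in the astrocyte, converted to lactate, shuttled to the neuron
through monocarboxylate transporters and oxidised after conversion to pyruvate
by lactate dehydrogenase (LDH). Time-coded induction (spike-timing-dependent
plasticity, a few dozen pre/post pairings) is satisfied by neuronal glycolysis
alone. `anls_ltp` is a kinetic model of this division of labour, built for
simulating in-silico pharmacology: which stimulation patterns still express
LTP when glycogenolysis, LDH, hexokinase or the NMDA receptor is blocked, or
when lactate, pyruvate, NADH or extra glucose is supplied.

The model couples three layers in one stiff ODE system:

* **Metabolism** — a three-compartment (neuron / astrocyte / extracellular)
  model of the astrocyte–neuron lactate shuttle: glucose and lactate
  transport (reversible Michaelis–Menten), lumped glycolysis, an astrocytic
  glycogen shunt, reversible LDH in both cells, phenomenological
  mitochondrial ATP production gated by cytosolic NADH, a
  malate–aspartate-shuttle flux, creatine-kinase buffering and Na,K-ATPase /
  housekeeping ATP consumption. Conserved NAD(H) and adenine pools are
  enforced algebraically.
* **Electrophysiology** — spikes are timed events: presynaptic stimulations
  release glutamate (NMDAR binding, AMPAR Na⁺, astrocytic EAAT Na⁺ load) and
  depolarize; back-propagating action potentials (bAPs) depolarize strongly.
  NMDAR Ca²⁺ requires glutamate *and* depolarization (Mg²⁺ unblock);
  suprathreshold depolarization recruits regenerative VGSC Na⁺. Sodium
  extrusion by the Na,K-ATPase (3 Na⁺ : 1 ATP) is what couples activity to
  metabolism.
* **Plasticity** — the synaptic weight W follows a bistable ODE, gated by
  calcium and ATP:

  ```
  dW/dt = −(W−1)(W−Wu)(W−Wp)/τw  +  γP · g(Ca − LTPStart) · (1 − W/Wsat)
                                  −  γD · g(ATPThr − ATP) · (W − 1)
  ```

  Calcium above `LTPStart` drives potentiation; neuronal ATP below `ATPThr`
  drives depotentiation. LTP is scored as mean W at 50–60 min after the
  protocol, ≥ 110 % of baseline.

## A worked example

```python
import anls_ltp as al

params = al.load_default_params()

# control theta burst: 5 trains x 10 bursts x 4 pulses at 100 Hz
res = al.run(al.get_preset("tbs5"), None, params)
print(res.summary())
```

prints (abridged):

```
peak_delta_na_mM        : 3.20      # peak neuronal Na rise, mM
peak_ca_uM              : 1.52      # peak postsynaptic Ca, uM
cumulative_pump_atp_uM  : 302       # ATP spent on Na extrusion, uM
min_atp_neuron_mM       : 4.15      # ATP never approaches the threshold
outcome                 : LTP       # 180% of baseline at 50-60 min
```

The same protocol with neuronal LDH blocked fails — resting ATP halves to
2.10 mM and the theta-burst load pushes it under the depotentiation
threshold — while 50 STDP pairings at 0.5 Hz under the same block still
potentiate:

```python
al.run(al.get_preset("tbs5"), "oxamate", params).outcome
# Outcome(label='no_plasticity', magnitude_pct=100.0)
al.run(al.get_preset("stdp_50_0.5Hz"), "oxamate", params).outcome
# Outcome(label='LTP', magnitude_pct=180.0)
```

Phase boundaries come from sweeps:

```python
al.tbs_train_axis(range(1, 6), "oxamate").failure_threshold()   # 4 trains
al.stdp_pairing_axis([20, 25, 30, 35, 50], 1.0, 2, "oxamate").failure_threshold()  # 30
```

The `examples/` directory holds short narrative scripts, one per
capability: transient comparison, LDH-block dissociation and rescues, phase
boundaries, and calibration on synthetic cohorts. A thin CLI mirrors the
API (`anls-ltp simulate --protocol tbs5 --condition oxamate`,
`anls-ltp sweep --axis tbs-trains --condition oxamate`).

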