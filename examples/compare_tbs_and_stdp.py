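"""Rate coding versus time coding: the energetic footprint of two LTP
protocols.

Runs the two canonical induction paradigms under control conditions — a
5-train theta-burst stimulation (200 presynaptic pulses) and a 50-pairing
STDP protocol at 0.5 Hz — and prints the sodium and calcium transients,
the Na,K-ATPase ATP budget and the plasticity outcome of each.
"""

import anls_ltp as al

params = al.load_default_params()

for name in ("tbs5", "stdp_50_0.5Hz"):
    res = al.run(al.get_preset(name), None, params)
    s = res.summary()
    print(f"\n{name}  ({res.protocol.n_events} events over {res.protocol.span:.0f} s)")
    print(f"  peak neuronal Na rise : {s['peak_delta_na_mM']:.2f} mM")
    print(f"  peak postsynaptic Ca  : {s['peak_ca_uM']:.2f} uM")
    print(f"  pump ATP for Na efflux: {s['cumulative_pump_atp_uM']:.0f} uM")
    print(f"  outcome at 50-60 min  : {s['outcome']} ({s['magnitude_pct']:.0f}% of baseline)")

print(
    "\nBoth patterns drive calcium past the potentiation threshold, but the"
    "\ntheta-burst paradigm moves roughly three times more sodium and ATP:"
    "\nthe rate-coded protocol carries a much larger energetic load."
)
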