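"""Where does LTP start to need astrocytic lactate?

Sweeps stimulation intensity under LDH inhibition along three axes and
prints each phase boundary: theta-burst train count, 2-bAP pairing count,
and 1-bAP pairing count (which never becomes lactate-dependent).
"""

import anls_ltp as al

params = al.load_default_params()

tbs = al.tbs_train_axis(range(1, 6), "oxamate", params)
print("theta-burst trains under LDH block:")
print(tbs.to_frame().to_string(index=False))
print(f"-> LTP fails from {tbs.failure_threshold():.0f} trains\n")

two = al.stdp_pairing_axis([20, 25, 30, 35, 50], 1.0, 2, "oxamate", params)
print("STDP pairings (two bAPs, 1 Hz) under LDH block:")
print(two.to_frame().to_string(index=False))
print(f"-> LTP fails from {two.failure_threshold():.0f} pairings\n")

one = al.stdp_pairing_axis([20, 100, 500], 1.0, 1, "oxamate", params)
print("STDP pairings (one bAP, 1 Hz) under LDH block:")
print(one.to_frame().to_string(index=False))
print(f"-> LTP persists up to {one.largest_ltp():.0f} pairings")
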