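import numpy as np
import pytest

import anls_ltp as al


@pytest.fixture(scope="session")
def params():
    return al.load_default_params()


@pytest.fixture(scope="session")
def control_rest(params):
    return al.steady_state(params)


def run(proto, cond=None):
    """Session-cached full simulation (results are deterministic)."""
    return al.run_cached(proto, cond)


def proto_by_name(name: str):
    if name.startswith("tbs"):
        return al.tbs(int(name[3:]))
    q = name.split("_")
    return al.stdp(int(q[1]), float(q[2][:-2]), 2 if "2bAP" in name else 1)


#: protocol x condition -> expected outcome, assembled from the reported
#: slice-experiment phenotypes (LTP vs no plasticity at 50-60 min)
TRUTH_TABLE = [
    ("tbs5", None, "LTP"),
    ("stdp_50_0.5Hz", None, "LTP"),
    ("tbs5", "mk801", "no_plasticity"),
    ("stdp_50_0.5Hz", "mk801", "no_plasticity"),
    ("tbs5", "dab", "no_plasticity"),
    ("stdp_50_0.5Hz", "dab", "no_plasticity"),
    ("tbs5", ("dab", "lactate"), "LTP"),
    ("stdp_50_0.5Hz", ("dab", "lactate"), "LTP"),
    ("tbs5", "oxamate", "no_plasticity"),
    ("stdp_50_0.5Hz", "oxamate", "LTP"),
    ("tbs5", ("oxamate", "nadh"), "LTP"),
    ("tbs5", ("oxamate", "pyruvate"), "no_plasticity"),
    ("tbs5", "glucose_25", "LTP"),
    ("tbs5", ("glucose_25", "oxamate"), "LTP"),
    ("tbs5", "mannoheptulose", "LTP"),
    ("stdp_50_0.5Hz", "mannoheptulose", "LTP"),
    ("stdp_100_1Hz", "mannoheptulose", "LTP"),
    ("stdp_100_1Hz", ("mannoheptulose", "oxamate"), "no_plasticity"),
    ("tbs1", "oxamate", "LTP"),
    ("stdp_100_1Hz", None, "LTP"),
    ("stdp_100_1Hz", "oxamate", "LTP"),
    ("stdp_50_1Hz_2bAP", "oxamate", "no_plasticity"),
    ("stdp_25_1Hz_2bAP", "oxamate", "LTP"),
    ("stdp_50_1Hz_2bAP", ("oxamate", "nadh"), "LTP"),
    ("stdp_25_0.5Hz_2bAP", None, "LTP"),
    ("stdp_25_0.5Hz_2bAP", "oxamate", "LTP"),
]
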