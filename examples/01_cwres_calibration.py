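"""Simulate a correct-model run and check that CWRES are standard normal.

A dataset is simulated from the bundled one-compartment IVGTT scenario and
CWRES are computed under the same model.  For a correctly specified model
they should have mean ~0 and variance ~1.
"""

import numpy as np

from cwresqa import compute_cwres, make_ivgtt_protocol, one_compartment_model, simulate_dataset

model = one_compartment_model()
dataset = simulate_dataset(model, make_ivgtt_protocol().to_design(), 100, seed=1)
result = compute_cwres(model, dataset)
r = result.table["CWRES"].to_numpy()

print(f"{r.size} CWRES values from 100 subjects")
print(f"mean     = {r.mean():+.4f}   (expected ~0 for a correct model)")
print(f"variance = {r.var(ddof=1):.4f}   (expected ~1 for a correct model)")
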