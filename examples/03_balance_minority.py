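"""Correct the seizure / non-seizure imbalance with SMOTE and ADASYN.

Both interpolate between a minority sample and one of its k nearest
minority neighbours; ADASYN additionally allocates more synthetics to
minority points whose neighbourhoods are dominated by the majority class
(the decision-boundary region).
"""

import numpy as np

from capseeg.balancing import OversampleConfig, adasyn, smote
from capseeg.data import SynthConfig, synth_generate, to_binary

data = to_binary(synth_generate(SynthConfig(n_per_class=60, seed=2)))
print(f"before: {data.class_counts()}")

cfg = OversampleConfig(k_neighbors=5, target_ratio=1.0, seed=0)
for name, method in (("SMOTE", smote), ("ADASYN", adasyn)):
    out = method(data, cfg)
    n_synth = out.n_segments - data.n_segments
    print(f"{name:6s} after: {out.class_counts()}  "
          f"(+{n_synth} synthetic seizure segments)")
    assert np.array_equal(out.signals[:data.n_segments], data.signals)

print("originals are preserved unchanged; synthetics are appended.")
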