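"""Generate synthetic EEG, restructure raw recordings, relabel for the
binary task.

The corpus convention: 23.5-second recordings of 4097 samples are cut into
23 one-second segments of 178 samples each (the 3-sample remainder is
dropped); class 1 (ictal) becomes the seizure class and classes 2-5
collapse to non-seizure.
"""

import numpy as np

from capseeg.data import (RecordingSet, SynthConfig, segment_recordings,
                          synth_generate, to_binary)

# five-class synthetic segments, 100 per class
segments = synth_generate(SynthConfig(n_per_class=100, seed=0))
print(f"synthetic set: {segments.n_segments} segments of "
      f"{segments.segment_len} samples, classes {segments.class_counts()}")

# restructuring arithmetic on raw recordings
rng = np.random.default_rng(0)
recordings = RecordingSet(recordings=rng.normal(size=(500, 4097)),
                          labels=np.repeat([1, 2, 3, 4, 5], 100))
chunks = segment_recordings(recordings, chunk_len=178)
print(f"500 recordings x 4097 samples -> {chunks.n_segments} segments "
      f"({chunks.n_segments // 500} per recording)")

binary = to_binary(chunks)
counts = binary.class_counts()
print(f"binary relabelling: {counts[1]} seizure vs {counts[0]} non-seizure")
# The 2300 / 9200 imbalance is what the oversamplers in
# examples/03_balance_minority.py correct.
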