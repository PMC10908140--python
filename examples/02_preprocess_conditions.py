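"""The four dataset conditions: any, scaling, pca, scaling_pca.

All parameters are fit on the training partition only.  PCA reduces the
178 per-segment samples to 40 principal components, which is why the
convolutional models accept either input length.
"""

from capseeg.data import SynthConfig, stratified_split, synth_generate
from capseeg.preprocessing import condition_pipeline

data = synth_generate(SynthConfig(n_per_class=80, seed=1))
train, test = stratified_split(data, test_frac=0.2, seed=0)

for name in ("any", "scaling", "pca", "scaling_pca"):
    (tr, te), params = condition_pipeline(name, train, test)
    fitted = ", ".join(params) or "nothing fitted"
    print(f"{name:12s} -> train {tr.signals.shape}, test {te.signals.shape}"
          f"  ({fitted})")

# standardization makes each of the 178 positions zero-mean/unit-sd on the
# training set; PCA keeps the 40 highest-variance directions of that space.
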