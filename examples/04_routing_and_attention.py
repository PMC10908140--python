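"""The network primitives in isolation: squash, routing-by-agreement,
scaled dot-product attention.

squash maps a vector to the same direction with norm ||s||^2/(1+||s||^2);
routing iteratively couples input capsules to the output capsules their
predictions agree with; attention is softmax(QK^T/sqrt(d_k)) V.
"""

import numpy as np

from capseeg.nn import functional as F

print(f"SELU(1) = {F.selu(1.0):.4f}   (the scale constant lambda)")
print(f"squash((1,0)) = {F.squash(np.array([1.0, 0.0]))}")

# routing: four inputs agree on output capsule 1
rng = np.random.default_rng(0)
u_hat = rng.normal(size=(4, 3, 4)) * 0.01
u_hat[:, 1, :] = [3.0, 0.0, 0.0, 0.0]  # strong agreed prediction
for r in (1, 2, 3):
    _, state = F.dynamic_routing(u_hat, r)
    print(f"r={r}: mean coupling onto agreed capsule = "
          f"{state.c[:, 1].mean():.3f}")
# the coupling mass concentrates on the agreed-upon capsule as r grows.

q = rng.normal(size=(3, 4))
k = rng.normal(size=(3, 4))
v = rng.normal(size=(3, 4))
out = F.attention(q, k, v)
print(f"attention output shape {out.shape}; one token returns V exactly: "
      f"{np.allclose(F.attention(q[:1], k[:1], v[:1]), v[:1])}")
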