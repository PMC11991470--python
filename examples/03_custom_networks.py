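"""The two custom multichannel architectures.

Cres embeds a four-branch inception transform in residual macroblocks
(channels double, spatial halves); Catt runs a 3-D convolutional stack
over the band/depth axis into a Transformer encoder.  Both accept any
number of input bands.
"""

import numpy as np

from bandfuse import CattSpec, NetworkConfig, build_catt, build_cres
from bandfuse.nn import Tensor

rng = np.random.default_rng(0)

cres = build_cres(None, NetworkConfig("cres", 13, 10, (64, 64)), 1)
x = Tensor(rng.normal(size=(2, 13, 64, 64)).astype(np.float32))
feat = cres.forward_features(x)
print(f"Cres: {cres.n_parameters():,} parameters; "
      f"pre-flatten feature map {feat.shape[1:]} for a 13x64x64 input")

catt = build_catt(CattSpec(), NetworkConfig("catt", 10, 17, (32, 32)), 1)
xb = Tensor(rng.normal(size=(2, 10, 32, 32)).astype(np.float32))
pooled = catt.forward_pooled(xb)
out = catt(xb)
print(f"Catt: pooled map {pooled.shape[1:]} -> 64 tokens -> "
      f"{len(catt.encoders)} encoder layers -> logits {out.shape}")
attn = catt.encoders[0].attn.last_attn
print(f"first-layer attention rows sum to 1: "
      f"{np.allclose(attn.sum(-1), 1.0, atol=1e-5)}")
print("the 1x8x8 adaptive pooling makes the encoder blind to input size:")
catt64 = build_catt(CattSpec(), NetworkConfig("catt", 10, 17, (64, 64)), 1)
print(f"  head shape at 32x32: {catt.head.weight.shape}, "
      f"at 64x64: {catt64.head.weight.shape}")
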