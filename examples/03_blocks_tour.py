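"""Tour of the three bespoke blocks on tiny feature maps.

Shows the factorized large-kernel parameter budget, the context-attention
block's shape contract and softmax structure, and the nodule-adaptive
convolution's input-dependent branch weights.
"""

import numpy as np

from lcanet import (
    AttentionConfig,
    branch_weights,
    context_attention_forward,
    effective_kernel_extent,
    init_context_attention,
    init_nac_block,
    param_reduction_percent,
)
from lcanet.blocks import init_backbone_block
from lcanet.ops import count_parameters

rng = np.random.default_rng(0)

# backbone: spatially factorized 7x7
p = init_backbone_block(rng, 16)
print(f"7x1 + 1x7 pair at 16 channels: {count_parameters(p['fk'])} weights "
      f"(one 7x7 would use {49 * 16 * 16}); "
      f"reduction {param_reduction_percent(7):.1f}%")

# context attention: same-shape residual block
ap = init_context_attention(rng, 8)
x = rng.normal(size=(1, 8, 16, 16))
y = context_attention_forward(ap, x, cfg=AttentionConfig(mode="global"))
print(f"attention block: input {x.shape} -> output {np.asarray(y).shape} "
      "(8x8 query windows over overlapping 10x10 key-value windows)")

# NAC: convex mixture over branches with receptive fields 1/5/7/11
np_ = init_nac_block(rng, 8)
extents = [effective_kernel_extent(k, d)
           for k, d in [(1, 1), (3, 2), (3, 3), (3, 5)]]
a = np.asarray(branch_weights(np_, rng.normal(size=(3, 8, 12, 12))))
print(f"NAC branch extents: {extents} pixels")
for i, row in enumerate(a):
    print(f"  input {i}: branch weights {np.round(row, 3)} (sum {row.sum():.6f})")
# the weights are input-conditioned and lie on the probability simplex, so
# the block interpolates between small- and large-receptive-field behaviour.
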