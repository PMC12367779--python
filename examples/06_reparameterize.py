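"""Structural reparameterization: fuse MobileOne branches for deployment.

Builds the detector, runs a forward pass in its multi-branch training
structure, fuses every block into single convolutions, and shows that the
outputs agree to numerical precision while the parameter count drops.
"""

import numpy as np

from rotphenex import build_wheat_rynet, reparameterize
from rotphenex.model import ModelConfig

cfg = ModelConfig(input_size=64, width_mult=0.25)
net = build_wheat_rynet(cfg)
net.train()
x = np.random.default_rng(0).random((1, 3, 64, 64))
for _ in range(3):
    net(x)  # populate normalization statistics
net.eval()
before = net(x)[0].raw.data
n_before = net.num_parameters()

reparameterize(net)
after = net(x)[0].raw.data
print(f"max |deployed - train-structure| = {np.abs(after - before).max():.2e}")
print(f"parameters: {n_before} (train structure, all branches counted)")
# after fusion each block applies exactly one convolution at inference time,
# which is what makes the MobileOne design fast on edge hardware
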