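"""Adam optimizer with decoupled weight decay."""

from __future__ import annotations

import numpy as np


class Adam:
    """Adaptive moment estimation over flat parameter/gradient lists.

    Weight decay is applied multiplicatively to the parameters before the
    Adam step (decoupled, AdamW-style); a decay of 0.005 corresponds to the
    conventional "0.5%" setting.
    """

    def __init__(self, params, grads, lr=1e-4, betas=(0.9, 0.999),
                 eps=1e-8, weight_decay=0.0):
        self.params = params
        self.grads = grads
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            if self.weight_decay and p.ndim > 1:
                p *= 1.0 - self.lr * self.weight_decay
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for g in self.grads:
            g[...] = 0
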