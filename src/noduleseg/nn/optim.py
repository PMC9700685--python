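"""Adam optimiser with decoupled weight decay.

Defaults follow the training recipe used throughout this package:
beta1 = 0.99 (deliberately higher than the conventional 0.9), beta2 =
0.999, learning rate 1e-3 and decoupled weight decay 5e-4.  Setting
``decoupled=False`` folds the decay into the gradient instead (classic L2
regularisation); biases are never decayed.
"""

from __future__ import annotations

import numpy as np


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.99, beta2=0.999, eps=1e-7,
                 weight_decay=5e-4, decoupled=True):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.decoupled = decoupled
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            decay = self.weight_decay if p.data.ndim > 1 else 0.0
            if decay and not self.decoupled:
                g = g + decay * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            update = (m / bias1) / (np.sqrt(v / bias2) + self.eps)
            if decay and self.decoupled:
                update = update + decay * p.data
            p.data -= self.lr * update
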