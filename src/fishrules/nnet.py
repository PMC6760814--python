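"""Minimal dense-network engine (float32 forward/backward + Adam).

The turning-side models are small fully-connected stacks (a few layers of
128 rectified-linear units), so a hand-rolled engine on top of BLAS matmuls
is all that is needed; everything is deterministic given the RNG used for
initialization and minibatch shuffling.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP", "Adam"]


class MLP:
    """Fully-connected stack with ReLU after each hidden layer, linear readout."""

    def __init__(self, sizes: list[int], rng: np.random.Generator):
        # sizes = [in, hidden..., out]
        self.sizes = list(sizes)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            std = np.sqrt(2.0 / fan_in)  # He init for ReLU stacks
            self.weights.append(
                (rng.standard_normal((fan_in, fan_out)) * std).astype(np.float32)
            )
            self.biases.append(np.zeros(fan_out, dtype=np.float32))

    @property
    def params(self) -> list[np.ndarray]:
        return self.weights + self.biases

    def set_params(self, params: list[np.ndarray]) -> None:
        k = len(self.weights)
        self.weights = [p.copy() for p in params[:k]]
        self.biases = [p.copy() for p in params[k:]]

    def n_params(self) -> int:
        return sum(p.size for p in self.params)

    def forward(self, x: np.ndarray, cache: list | None = None) -> np.ndarray:
        """Forward pass; if ``cache`` is a list, store activations for backward."""
        h = x.astype(np.float32, copy=False)
        if cache is not None:
            cache.append(h)
        last = len(self.weights) - 1
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ w + b
            if i < last:
                np.maximum(h, 0.0, out=h)
            if cache is not None:
                cache.append(h)
        return h

    def backward(
        self, cache: list, d_out: np.ndarray, need_dx: bool = False
    ) -> tuple[list[np.ndarray], np.ndarray | None]:
        """Gradients of a scalar loss given d(loss)/d(output).

        ``cache`` is the activation list filled by :meth:`forward`.  Returns
        gradients aligned with :attr:`params` and optionally the gradient
        with respect to the input.
        """
        g = d_out.astype(np.float32, copy=False)
        dw = [None] * len(self.weights)
        db = [None] * len(self.biases)
        last = len(self.weights) - 1
        for i in range(last, -1, -1):
            if i < last:  # undo ReLU of layer i (cache[i+1] is its output)
                g = g * (cache[i + 1] > 0)
            dw[i] = cache[i].T @ g
            db[i] = g.sum(axis=0)
            if i > 0 or need_dx:
                g = g @ self.weights[i].T
        return dw + db, (g if need_dx else None)


class Adam:
    """Adam optimizer over a flat list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], beta1=0.9, beta2=0.999, eps=1e-8):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray], lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * np.square(g)
            p -= lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
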