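"""Minimal dense neural-network numerics.

Explicit numpy forward/backward passes for the two architectures the
predictor needs — a ReLU multilayer perceptron with a linear scalar head,
and a graph-convolution stack H_{k+1} = relu(A H_k W_k) with a linear last
layer — plus an Adam optimizer.  Everything is deterministic given the
seed; there is no threading or fused-kernel nondeterminism to control.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Adam", "MLP", "GcnStack", "gcn_forward_cached", "init_weights"]


def init_weights(sizes: list[int], rng: np.random.Generator) -> list[np.ndarray]:
    """He-scaled Gaussian init for a chain of dense layers."""
    return [
        rng.normal(0.0, np.sqrt(2.0 / sizes[i]), size=(sizes[i], sizes[i + 1]))
        for i in range(len(sizes) - 1)
    ]


class Adam:
    """Adam with bias correction; state per parameter tensor."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class MLP:
    """Dense ReLU network, linear scalar (or vector) output layer.

    ``weights[k]`` has shape (d_k, d_{k+1}); biases are separate vectors.
    ReLU follows every layer except the last.
    """

    def __init__(self, weights: list[np.ndarray], biases: list[np.ndarray]):
        self.weights = weights
        self.biases = biases

    @classmethod
    def create(cls, sizes: list[int], rng: np.random.Generator) -> "MLP":
        w = init_weights(sizes, rng)
        b = [np.zeros(s) for s in sizes[1:]]
        return cls(w, b)

    @property
    def params(self) -> list[np.ndarray]:
        return [*self.weights, *self.biases]

    def forward(self, x: np.ndarray):
        """Return (output, cache) for a batch (n, d_in)."""
        acts = [x]
        pre = []
        h = x
        last = len(self.weights) - 1
        for k, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = h @ w + b
            pre.append(z)
            h = z if k == last else np.maximum(z, 0.0)
            acts.append(h)
        return h, (acts, pre)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)[0]

    def backward(self, cache, dout: np.ndarray):
        """Return (grads aligned with ``params``, d_input)."""
        acts, pre = cache
        last = len(self.weights) - 1
        dw = [None] * len(self.weights)
        db = [None] * len(self.biases)
        delta = dout
        for k in range(last, -1, -1):
            if k != last:
                delta = delta * (pre[k] > 0)
            dw[k] = acts[k].T @ delta
            db[k] = delta.sum(axis=0)
            delta = delta @ self.weights[k].T
        return [*dw, *db], delta


def gcn_forward_cached(adj: np.ndarray, weights: list[np.ndarray]):
    """Graph-convolution stack on identity input features.

    H_0 = I; H_{k+1} = relu(adj @ H_k @ W_k) for all but the final layer,
    which is linear.  Returns (node embeddings, cache).
    """
    n = adj.shape[0]
    if weights[0].shape[0] != n:
        raise ValueError(
            f"first GCN layer expects input width {weights[0].shape[0]}, adjacency has {n} nodes")
    h = np.eye(n)
    acts = [h]
    pre = []
    last = len(weights) - 1
    for k, w in enumerate(weights):
        z = adj @ h @ w
        pre.append(z)
        h = z if k == last else np.maximum(z, 0.0)
        acts.append(h)
    return h, (adj, acts, pre)


class GcnStack:
    """GCN weights + forward/backward, mirroring MLP's interface."""

    def __init__(self, weights: list[np.ndarray]):
        self.weights = weights

    @classmethod
    def create(cls, n_nodes: int, sizes: list[int], rng: np.random.Generator) -> "GcnStack":
        return cls(init_weights([n_nodes, *sizes], rng))

    @property
    def params(self) -> list[np.ndarray]:
        return self.weights

    def forward(self, adj: np.ndarray):
        return gcn_forward_cached(adj, self.weights)

    def backward(self, cache, dout: np.ndarray) -> list[np.ndarray]:
        adj, acts, pre = cache
        n_layers = len(pre)
        grads = [None] * n_layers
        delta = dout
        for k in range(n_layers - 1, -1, -1):
            if k != n_layers - 1:
                delta = delta * (pre[k] > 0)
            ah = adj @ acts[k]
            grads[k] = ah.T @ delta
            if k > 0:
                delta = (adj.T @ delta) @ self.weights[k].T
        return grads
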