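"""Minimal dense-network machinery for the two constitutive blocks.

The constitutive network outputs a strain energy whose *derivatives* with
respect to two of its inputs enter the loss, so training needs the exact
gradient of an input-tangent quantity with respect to the weights.  This
module therefore implements, besides the usual forward/backward pass:

* ``forward_tangent`` -- forward-mode propagation of directional
  derivatives (tangents) alongside activations, giving exact
  ``d output / d input_k`` for selected input directions;
* ``backward_tangent`` -- the adjoint of that joint computation, i.e.
  second-order backpropagation producing ``dL/dW`` when the loss depends
  on both activations and tangents.

Everything is plain NumPy; the networks involved have a few thousand
parameters, so clarity and exactness beat framework overhead here.
Correctness is pinned against finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Activation", "ACTIVATIONS", "MLP", "Adam", "forward_tangent", "backward_tangent"]


@dataclass(frozen=True)
class Activation:
    """Scalar activation with first and second derivatives.

    ``d_from``/``dd_from`` compute the derivatives from already-computed
    forward values (x = f(z), s1 = f'(z)), avoiding redundant transcendental
    evaluations in the training hot path.
    """

    name: str
    f: callable
    d: callable
    dd: callable
    d_from: callable
    dd_from: callable


def _tanh_d(z):
    t = np.tanh(z)
    return 1.0 - t * t


def _tanh_dd(z):
    t = np.tanh(z)
    return -2.0 * t * (1.0 - t * t)


def _elu(z):
    return np.where(z > 0.0, z, np.expm1(np.minimum(z, 0.0)))


def _elu_d(z):
    return np.where(z > 0.0, 1.0, np.exp(np.minimum(z, 0.0)))


def _elu_dd(z):
    return np.where(z > 0.0, 0.0, np.exp(np.minimum(z, 0.0)))


def _sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def _sigmoid_d(z):
    s = _sigmoid(z)
    return s * (1.0 - s)


def _sigmoid_dd(z):
    s = _sigmoid(z)
    return s * (1.0 - s) * (1.0 - 2.0 * s)


ACTIVATIONS = {
    "tanh": Activation(
        "tanh", np.tanh, _tanh_d, _tanh_dd,
        d_from=lambda z, x: 1.0 - x * x,
        dd_from=lambda z, x, s1: -2.0 * x * s1,
    ),
    "elu": Activation(
        "elu", _elu, _elu_d, _elu_dd,
        d_from=lambda z, x: np.where(z > 0.0, 1.0, x + 1.0),
        dd_from=lambda z, x, s1: np.where(z > 0.0, 0.0, s1),
    ),
    "sigmoid": Activation(
        "sigmoid", _sigmoid, _sigmoid_d, _sigmoid_dd,
        d_from=lambda z, x: x * (1.0 - x),
        dd_from=lambda z, x, s1: s1 * (1.0 - 2.0 * x),
    ),
    "linear": Activation(
        "linear", lambda z: z, lambda z: np.ones_like(z), np.zeros_like,
        d_from=lambda z, x: np.ones_like(z),
        dd_from=lambda z, x, s1: np.zeros_like(z),
    ),
}


class MLP:
    """Fully-connected network with Glorot-uniform initialization.

    Parameters
    ----------
    sizes : sequence of int
        Layer widths including input and output, e.g. ``(13, 32, 32, 48, 1)``.
    activations : sequence of str
        One activation name per weight layer.
    rng : numpy.random.Generator
        Source for the Glorot draws; pass a seeded generator for
        reproducible initialization.
    dropout_layer : int or None
        Index of the weight layer after whose activation inverted dropout
        is applied during training (None disables).
    dropout_rate : float
        Probability of dropping a unit when a mask is requested.
    """

    def __init__(self, sizes, activations, rng, *, dropout_layer=None, dropout_rate=0.5):
        if len(activations) != len(sizes) - 1:
            raise ValueError("need one activation per weight layer")
        self.sizes = tuple(int(s) for s in sizes)
        self.activation_names = tuple(activations)
        self.acts = [ACTIVATIONS[a] for a in activations]
        self.dropout_layer = dropout_layer
        self.dropout_rate = float(dropout_rate)
        self.W = []
        self.b = []
        for fan_in, fan_out in zip(self.sizes[:-1], self.sizes[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            self.W.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))

    @property
    def n_layers(self) -> int:
        return len(self.W)

    # -- parameter bookkeeping -------------------------------------------

    def parameters(self):
        return self.W + self.b

    def copy_parameters(self):
        return [p.copy() for p in self.parameters()]

    def set_parameters(self, params):
        for dst, src in zip(self.parameters(), params):
            np.copyto(dst, src)

    def dropout_mask(self, rng):
        """Inverted-dropout mask for the configured layer (training only).

        One mask per optimization step, shared across the whole time
        series in the batch (recurrent-dropout semantics): a batch here is
        one specimen's ordered stress history feeding a recursion, and
        per-sample masks would inject artificial high-frequency noise into
        the stress increments that drive the history integrals.
        """
        if self.dropout_layer is None:
            return None
        width = self.sizes[self.dropout_layer + 1]
        keep = 1.0 - self.dropout_rate
        return (rng.random(width) < keep).astype(float) / keep

    # -- passes ----------------------------------------------------------

    def forward(self, X, mask=None):
        """Plain forward pass; returns (xs, zs) with xs[0] = X.

        ``xs[l+1]`` is the (post-dropout) output of weight layer ``l``.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        xs, zs = [X], []
        for l in range(self.n_layers):
            z = xs[-1] @ self.W[l] + self.b[l]
            x = self.acts[l].f(z)
            if mask is not None and l == self.dropout_layer:
                x = x * mask
            zs.append(z)
            xs.append(x)
        return xs, zs

    def __call__(self, X):
        return self.forward(X)[0][-1]

    def backward(self, xs, zs, out_bar, mask=None):
        """First-order backprop; returns (dW, db, dX)."""
        dW = [None] * self.n_layers
        db = [None] * self.n_layers
        xbar = np.asarray(out_bar, dtype=float)
        for l in range(self.n_layers - 1, -1, -1):
            if mask is not None and l == self.dropout_layer:
                xbar = xbar * mask
            zbar = xbar * self.acts[l].d(zs[l])
            dW[l] = xs[l].T @ zbar
            db[l] = zbar.sum(axis=0)
            xbar = zbar @ self.W[l].T
        return dW, db, xbar


def forward_tangent(mlp: MLP, X, seeds, mask=None):
    """Joint forward pass of activations and input tangents.

    ``seeds`` is a list of (batch, n_in) tangent seed matrices (one per
    differentiation direction).  Returns a cache dict consumed by
    ``backward_tangent``; outputs live in ``cache['xs'][-1]`` and
    ``cache['ts'][k][-1]``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    K = len(seeds)
    xs, zs, s1s, xraw = [X], [], [], []
    ts = [[np.atleast_2d(np.asarray(s, dtype=float))] for s in seeds]
    pre = [[] for _ in range(K)]  # pre-activation tangents a = t_prev @ W
    for l in range(mlp.n_layers):
        z = xs[-1] @ mlp.W[l] + mlp.b[l]
        x = mlp.acts[l].f(z)
        s1 = mlp.acts[l].d_from(z, x)
        xraw.append(x)
        drop = mask if (mask is not None and l == mlp.dropout_layer) else None
        if drop is not None:
            x = x * drop
        zs.append(z)
        xs.append(x)
        s1s.append(s1)
        for k in range(K):
            a = ts[k][-1] @ mlp.W[l]
            tk = a * s1
            if drop is not None:
                tk = tk * drop
            pre[k].append(a)
            ts[k].append(tk)
    return {"xs": xs, "zs": zs, "s1s": s1s, "xraw": xraw, "ts": ts, "pre": pre, "mask": mask}


def backward_tangent(mlp: MLP, cache, out_bar, tangent_bars):
    """Adjoint of ``forward_tangent``: exact dL/dW, dL/db.

    ``out_bar`` is the adjoint of the network output (may be zeros) and
    ``tangent_bars[k]`` the adjoint of the k-th tangent output.  Returns
    ``(dW, db)`` lists matching ``mlp.W`` / ``mlp.b``.
    """
    xs, zs, ts, pre, mask = cache["xs"], cache["zs"], cache["ts"], cache["pre"], cache["mask"]
    s1s, xraw = cache["s1s"], cache["xraw"]
    K = len(ts)
    dW = [np.zeros_like(w) for w in mlp.W]
    db = [np.zeros_like(b) for b in mlp.b]
    xbar = np.asarray(out_bar, dtype=float)
    tbars = [np.asarray(tb, dtype=float) for tb in tangent_bars]
    for l in range(mlp.n_layers - 1, -1, -1):
        act = mlp.acts[l]
        z = zs[l]
        s1 = s1s[l]
        s2 = act.dd_from(z, xraw[l], s1)
        if mask is not None and l == mlp.dropout_layer:
            xbar = xbar * mask
            tbars = [tb * mask for tb in tbars]
        zbar = xbar * s1
        new_tbars = []
        for k in range(K):
            a = pre[k][l]
            abar = tbars[k] * s1
            zbar = zbar + tbars[k] * a * s2
            dW[l] += ts[k][l].T @ abar
            new_tbars.append(abar @ mlp.W[l].T)
        dW[l] += xs[l].T @ zbar
        db[l] += zbar.sum(axis=0)
        xbar = zbar @ mlp.W[l].T
        tbars = new_tbars
    return dW, db


class Adam:
    """Adam optimizer over a flat list of parameter arrays (in-place updates)."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
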