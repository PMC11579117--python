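"""Minimal feed-forward network core used by the DANN and LSPIN estimators.

Plain-numpy multilayer perceptrons with explicit forward caches and
hand-written backpropagation.  Keeping the autodiff surface this small makes
the adversarial update rule and the stochastic-gate gradients directly
inspectable and lets the test suite verify every gradient against central
finite differences.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "MLP",
    "softmax",
    "cross_entropy",
    "cross_entropy_grad",
    "make_optimizer",
]

_SELU_ALPHA = 1.6732632423543772
_SELU_SCALE = 1.0507009873554805


def _relu(a):
    return np.maximum(a, 0.0)


def _relu_grad(a, h):
    return (a > 0.0).astype(a.dtype)


def _tanh(a):
    return np.tanh(a)


def _tanh_grad(a, h):
    return 1.0 - h * h


def _selu(a):
    return _SELU_SCALE * np.where(a > 0.0, a, _SELU_ALPHA * np.expm1(a))


def _selu_grad(a, h):
    return _SELU_SCALE * np.where(a > 0.0, 1.0, _SELU_ALPHA * np.exp(a))


def _swish(a):
    return a / (1.0 + np.exp(-a))


def _swish_grad(a, h):
    s = 1.0 / (1.0 + np.exp(-a))
    return s + a * s * (1.0 - s)


def _linear(a):
    return a


def _linear_grad(a, h):
    return np.ones_like(a)


_ACTIVATIONS = {
    "relu": (_relu, _relu_grad),
    "tanh": (_tanh, _tanh_grad),
    "selu": (_selu, _selu_grad),
    "swish": (_swish, _swish_grad),
    "linear": (_linear, _linear_grad),
}


class MLP:
    """Fully connected network with per-layer activations and inverted dropout.

    Parameters are stored as flat lists ``weights`` / ``biases`` so optimizers
    and finite-difference probes can address them uniformly.
    """

    def __init__(self, layer_sizes, activations, rng, dropout=0.0):
        if len(activations) != len(layer_sizes) - 1:
            raise ValueError(
                f"need {len(layer_sizes) - 1} activations, got {len(activations)}"
            )
        for act in activations:
            if act not in _ACTIVATIONS:
                raise ValueError(f"unknown activation {act!r}")
        self.layer_sizes = tuple(int(s) for s in layer_sizes)
        self.activations = tuple(activations)
        self.dropout = float(dropout)
        self.weights = []
        self.biases = []
        for fan_in, fan_out in zip(layer_sizes[:-1], layer_sizes[1:]):
            bound = 1.0 / np.sqrt(fan_in)
            self.weights.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))

    @property
    def n_params(self):
        return sum(w.size for w in self.weights) + sum(b.size for b in self.biases)

    def parameters(self):
        return self.weights + self.biases

    def copy_parameters(self):
        return [p.copy() for p in self.parameters()]

    def set_parameters(self, params):
        n = len(self.weights)
        for w, new in zip(self.weights, params[:n]):
            w[...] = new
        for b, new in zip(self.biases, params[n:]):
            b[...] = new

    def forward(self, X, train=False, rng=None):
        """Return (output, cache); cache replays the pass for backward()."""
        h = np.asarray(X, dtype=float)
        pre, post, clean, masks = [], [h], [], []
        n_layers = len(self.weights)
        for k, (W, b) in enumerate(zip(self.weights, self.biases)):
            a = h @ W + b
            fn, _ = _ACTIVATIONS[self.activations[k]]
            h = fn(a)
            clean.append(h)
            mask = None
            # dropout on hidden activations only, never on the output layer
            if train and self.dropout > 0.0 and k < n_layers - 1:
                if rng is None:
                    raise ValueError("dropout requires an rng in train mode")
                keep = 1.0 - self.dropout
                mask = (rng.random(h.shape) < keep) / keep
                h = h * mask
            pre.append(a)
            post.append(h)
            masks.append(mask)
        return h, (pre, post, clean, masks)

    def backward(self, cache, d_out):
        """Backpropagate d_out; returns (grads aligned with parameters(), dX)."""
        pre, post, clean, masks = cache
        dW_list = [None] * len(self.weights)
        db_list = [None] * len(self.biases)
        grad = np.asarray(d_out, dtype=float)
        for k in range(len(self.weights) - 1, -1, -1):
            if masks[k] is not None:
                grad = grad * masks[k]
            _, dfn = _ACTIVATIONS[self.activations[k]]
            grad = grad * dfn(pre[k], clean[k])
            dW_list[k] = post[k].T @ grad
            db_list[k] = grad.sum(axis=0)
            grad = grad @ self.weights[k].T
        return dW_list + db_list, grad


def softmax(logits):
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits, y, sample_weight=None):
    """Mean softmax cross-entropy; y is an int vector of class indices."""
    if logits.shape[0] == 0:
        raise ValueError("empty batch")
    p = softmax(logits)
    nll = -np.log(np.clip(p[np.arange(len(y)), y], 1e-12, None))
    if sample_weight is not None:
        return float(np.sum(nll * sample_weight) / np.sum(sample_weight))
    return float(nll.mean())


def cross_entropy_grad(logits, y, sample_weight=None):
    """d(mean CE)/d(logits); rows sum to zero."""
    n = logits.shape[0]
    g = softmax(logits)
    g[np.arange(n), y] -= 1.0
    if sample_weight is not None:
        w = np.asarray(sample_weight, dtype=float)
        return g * (w / w.sum())[:, None]
    return g / n


class _SGD:
    def __init__(self, params, lr):
        self.params = params
        self.lr = lr

    def step(self, grads):
        for p, g in zip(self.params, grads):
            p -= self.lr * g


class _RMSProp:
    def __init__(self, params, lr, rho=0.9, eps=1e-8):
        self.params = params
        self.lr = lr
        self.rho = rho
        self.eps = eps
        self.sq = [np.zeros_like(p) for p in params]

    def step(self, grads):
        for p, g, s in zip(self.params, grads, self.sq):
            s *= self.rho
            s += (1.0 - self.rho) * g * g
            p -= self.lr * g / (np.sqrt(s) + self.eps)


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


_OPTIMIZERS = {"sgd": _SGD, "rmsprop": _RMSProp, "adam": _Adam}


def make_optimizer(name, params, lr):
    key = name.lower()
    if key not in _OPTIMIZERS:
        raise ValueError(f"unknown optimizer {name!r}; choose from {sorted(_OPTIMIZERS)}")
    return _OPTIMIZERS[key](params, lr)
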