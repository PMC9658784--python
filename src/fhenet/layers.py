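"""FHE-compatible graph nodes and their functional building blocks.

Everything here runs identically on plain numpy arrays and on
:class:`~fhenet.ckks.CyphertextMeta` objects, because both expose the same
element-wise ``+``/``*`` call surface.  The constraints of levelled CKKS shape
the designs:

* **Kernel masquerading** — a convolution kernel merged with a zero mask into
  a single input-shaped sparse tensor, so one whole-cyphertext Hadamard
  product realises one window.  A biased cross-correlation therefore costs a
  single multiplicative level regardless of kernel size.
* **Commuted bias** — the bias ``b`` is distributed as ``b/N`` into each of
  the ``N`` products of a window, so the later fold-sum (a key rotation)
  reproduces ``Σ x_i w_i + b`` exactly without a separate post-sum addition.
* **Polynomial activations** — ReLU and sigmoid are replaced by low-degree
  polynomial approximations evaluable in two multiplicative levels; the exact
  functions remain available as plaintext reference oracles.
* **Plaintext-only circuit elements** — softmax, categorical cross-entropy,
  argmax and MSE involve division, exponentials or order comparisons, none of
  which are abelian-compatible; they live behind the decryption boundary and
  raise :class:`~fhenet.errors.FHEIncompatibilityError` when handed a
  cyphertext.

Weights are plaintext throughout: training happens on the plaintext shadow of
the network while inference runs on either representation.
"""

from __future__ import annotations

import warnings
from itertools import product
from typing import Any, Sequence

import numpy as np

from . import ckks
from .autofhe import FHEParams
from .ckks import CyphertextMeta, is_encrypted
from .errors import (FHEIncompatibilityError, ShapeError, StateError)
from .graph import Node

__all__ = [
    "masquerade",
    "relu", "relu_approx", "relu_approx_derivative", "relu_range_update",
    "sigmoid", "sigmoid_approx", "sigmoid_approx_derivative",
    "softmax", "cce_loss", "mse_loss",
    "argmax_onehot", "onehot_encode", "onehot_decode",
    "InputNode", "GenericNode", "EncryptNode", "DecryptNode", "RotationNode",
    "CrossCorrelationNode", "DenseNode", "ReluApproxNode", "SigmoidApproxNode",
    "SoftmaxNode", "CCENode", "ArgmaxNode", "OneHotEncodeNode",
    "OneHotDecodeNode", "MSENode",
    "NODE_TYPES", "register_node",
]

#: registry of serialisable node types
NODE_TYPES: dict[str, type] = {}


def register_node(cls: type) -> type:
    NODE_TYPES[cls.__name__] = cls
    return cls


# ---------------------------------------------------------------------------
# Functional operations
# ---------------------------------------------------------------------------

def masquerade(kernel: np.ndarray, input_shape: Sequence[int],
               window_offset: Sequence[int]) -> np.ndarray:
    """Merge a kernel and its zero mask into one input-shaped sparse tensor.

    The returned tensor holds the kernel values at ``window_offset`` and zeros
    elsewhere; flattened to slot order it multiplies a whole cyphertext in a
    single Hadamard product while zeroing everything outside the window.
    """
    kernel = np.asarray(kernel, dtype=np.float64)
    input_shape = tuple(int(d) for d in input_shape)
    offset = tuple(int(o) for o in window_offset)
    if kernel.ndim != len(input_shape) or len(offset) != len(input_shape):
        raise ShapeError(
            f"kernel ({kernel.ndim}d), input shape {input_shape} and offset "
            f"{offset} must share dimensionality")
    for o, k, d in zip(offset, kernel.shape, input_shape):
        if o < 0 or o + k > d:
            raise ShapeError(
                f"window of shape {kernel.shape} at offset {offset} does not "
                f"fit inside input of shape {input_shape}")
    mask = np.zeros(input_shape, dtype=np.float64)
    mask[tuple(slice(o, o + k) for o, k in zip(offset, kernel.shape))] = kernel
    return mask


def _require_plain(x: Any, context: str) -> None:
    if is_encrypted(x) or (isinstance(x, (list, tuple))
                           and any(is_encrypted(v) for v in x)):
        raise FHEIncompatibilityError(
            f"{context} is not an FHE-compatible operation: it requires "
            "context across slots (division, exponentials or comparisons) "
            "and must run on the plaintext side of a decryption boundary")


def relu(x):
    """Exact rectifier max(0, x) — plaintext reference oracle."""
    _require_plain(x, "exact ReLU")
    return np.maximum(0.0, np.asarray(x, dtype=np.float64))


def relu_approx(x, q: float):
    """Degree-2 ReLU approximation (4/(3πq))x² + x/2 + q/(3π).

    Valid over the dynamic range [-q, q]; evaluates in two multiplicative
    levels on a cyphertext and identically on plaintext.
    """
    if q <= 0:
        raise ValueError(f"approximation range q must be positive, got {q}")
    x2 = x * x
    term2 = x2 * (4.0 / (3.0 * np.pi * q))
    term1 = x * 0.5
    return term2 + term1 + q / (3.0 * np.pi)


def relu_approx_derivative(x, q: float):
    """Analytic derivative (8/(3πq))x + 1/2 of the ReLU approximation."""
    if q <= 0:
        raise ValueError(f"approximation range q must be positive, got {q}")
    return x * (8.0 / (3.0 * np.pi * q)) + 0.5


def relu_range_update(node: "ReluApproxNode", batch_inputs) -> float:
    """Exponential-moving-average update of the dynamic range q.

    ``q <- (1 - alpha) q + alpha max|batch|`` — the fixed point under
    constant-magnitude inputs is that magnitude.
    """
    vals = batch_inputs if isinstance(batch_inputs, (list, tuple)) \
        else [batch_inputs]
    if not vals:
        raise ValueError("batch_inputs must be non-empty")
    m = max(float(np.max(np.abs(np.asarray(v, dtype=np.float64))))
            for v in vals)
    node.q = max((1.0 - node.alpha) * node.q + node.alpha * m, node.q_min)
    return node.q


def sigmoid(x):
    """Exact logistic 1/(1+e^-x) — plaintext reference oracle."""
    _require_plain(x, "exact sigmoid")
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=np.float64)))


def sigmoid_approx(x):
    """Static cubic sigmoid approximation 0.5 + 0.197x - 0.004x³.

    Tracks the logistic closely over roughly [-5, 5]; two multiplicative
    levels on a cyphertext (x² then x²·(coef·x)).
    """
    x2 = x * x
    t = x * (-0.004)
    term3 = x2 * t
    term1 = x * 0.197
    return term3 + term1 + 0.5


def sigmoid_approx_derivative(x):
    """Analytic derivative 0.197 - 0.012x² of the cubic approximation."""
    x2 = x * x
    return x2 * (-0.012) + 0.197


def softmax(a):
    """Normalised exponentials e^{a_i}/Σ_j e^{a_j} (plaintext only)."""
    _require_plain(a, "softmax")
    a = np.asarray(a, dtype=np.float64)
    shifted = a - np.max(a)  # numerical stabilisation; softmax is shift-invariant
    e = np.exp(shifted)
    return e / e.sum()


def cce_loss(p, y_onehot, eps: float = 1e-12):
    """Categorical cross-entropy -Σ y log p and combined gradient p - y.

    The returned gradient is the softmax+CCE product already folded together,
    which distributes the error over every class neuron rather than only the
    argmax winner.
    """
    _require_plain(p, "categorical cross-entropy")
    p = np.asarray(p, dtype=np.float64)
    y = np.asarray(y_onehot, dtype=np.float64)
    if p.shape != y.shape:
        raise ShapeError(f"shape mismatch: p {p.shape} vs y {y.shape}")
    if not np.isclose(p.sum(), 1.0, atol=1e-6):
        warnings.warn("probability vector does not sum to 1; was softmax "
                      "applied?", UserWarning, stacklevel=2)
    loss = float(-(y * np.log(np.clip(p, eps, None))).sum())
    return loss, p - y


def mse_loss(yhat, y):
    """Mean squared error and its gradient 2(yhat - y)/n."""
    _require_plain(yhat, "mean squared error")
    yhat = np.atleast_1d(np.asarray(yhat, dtype=np.float64))
    y = np.atleast_1d(np.asarray(y, dtype=np.float64))
    if yhat.shape != y.shape:
        raise ShapeError(f"shape mismatch: yhat {yhat.shape} vs y {y.shape}")
    diff = yhat - y
    return float(np.mean(diff ** 2)), 2.0 * diff / diff.size


def argmax_onehot(a) -> np.ndarray:
    """One-hot of the maximal entry; ties break toward the lowest index."""
    _require_plain(a, "argmax")
    a = np.asarray(a, dtype=np.float64)
    out = np.zeros_like(a)
    out[int(np.argmax(a))] = 1.0
    return out


def onehot_encode(y: int, K: int) -> np.ndarray:
    y = int(y)
    if not 0 <= y < K:
        raise ValueError(f"class {y} outside [0, {K})")
    v = np.zeros(K, dtype=np.float64)
    v[y] = 1.0
    return v


def onehot_decode(v) -> int:
    return int(np.argmax(np.asarray(v)))


# ---------------------------------------------------------------------------
# Shared node helpers
# ---------------------------------------------------------------------------

def _sum_edge_grads(g):
    """Merge gradients arriving from several outbound edges."""
    if isinstance(g, list):
        total = np.asarray(g[0], dtype=np.float64)
        for item in g[1:]:
            total = total + np.asarray(item, dtype=np.float64)
        return total
    return np.asarray(g, dtype=np.float64)


def _plain_array(x, context: str) -> np.ndarray:
    if is_encrypted(x):
        raise StateError(
            f"{context}: gradients require the plaintext shadow of the "
            "forward pass; run training with plaintext signals")
    return np.asarray(x, dtype=np.float64)


# ---------------------------------------------------------------------------
# Plumbing nodes
# ---------------------------------------------------------------------------

@register_node
class InputNode(Node):
    """Graph ingress: optionally flattens array signals, else passes through."""

    def __init__(self, mode: str = "raw"):
        if mode not in ("raw", "flatten"):
            raise ValueError(f"unknown input mode {mode!r}")
        self.mode = mode

    def forward(self, s):
        if self.mode == "flatten" and not is_encrypted(s):
            return np.asarray(s, dtype=np.float64).ravel()
        return s

    def backward(self, g):
        return None  # ingress terminates gradient flow

    def get_config(self):
        return {"mode": self.mode}, {}


@register_node
class GenericNode(Node):
    """Identity computation object with a configurable depth cost.

    Used for hand-written parameterisation fixtures where only the topology
    and per-node costs matter.
    """

    def __init__(self, cost: int = 0):
        self._cost = int(cost)

    def cost(self) -> int:
        return self._cost

    def forward(self, s):
        return s

    def backward(self, g):
        return g

    def get_config(self):
        return {"cost": self._cost}, {}


@register_node
class EncryptNode(Node):
    """Boundary where data becomes a cyphertext (when enabled).

    ``configure_fhe`` is called by parameter assignment with the node's group
    parameters and shared key id.  With encryption disabled the node passes
    the flattened plaintext through, which is how the plaintext shadow of the
    network runs.
    """

    def __init__(self, enabled: bool = False):
        self.enabled = enabled
        self.params: FHEParams | None = None
        self.key_id: str | None = None
        self.backend = None

    def configure_fhe(self, params: FHEParams, key_id: str) -> None:
        self.params = params
        self.key_id = key_id

    def forward(self, s):
        if is_encrypted(s):
            return s
        arr = np.asarray(s, dtype=np.float64).ravel()
        if not self.enabled:
            return arr
        if self.params is None:
            raise StateError("encrypt node fired before parameter assignment")
        return ckks.encrypt(arr, self.params, self.key_id or "default",
                            backend=self.backend)

    def backward(self, g):
        return g

    def get_config(self):
        cfg = {"enabled": self.enabled}
        if self.params is not None:
            cfg["params"] = self.params.to_dict()
            cfg["key_id"] = self.key_id
        return cfg, {}

    @classmethod
    def from_config(cls, config, arrays):
        node = cls(enabled=config.get("enabled", False))
        if "params" in config:
            node.configure_fhe(FHEParams.from_dict(config["params"]),
                               config.get("key_id", "default"))
        return node


@register_node
class DecryptNode(Node):
    """Boundary where cyphertexts become plaintexts again."""

    def __init__(self):
        self.backend = None

    def forward(self, s):
        if is_encrypted(s):
            return ckks.decrypt(s, backend=self.backend)
        if isinstance(s, list):
            return [ckks.decrypt(v, backend=self.backend)
                    if is_encrypted(v) else v for v in s]
        return s

    def backward(self, g):
        return g

    def get_config(self):
        return {}, {}


@register_node
class RotationNode(Node):
    """Key rotation stage: refresh, fold-sum or split a cyphertext.

    Fold is the workhorse: it realises the commuted sum of a masqueraded
    window by re-encrypting the slot-sum as a single value.  The plaintext
    shadow performs the matching plain summation.
    """

    def __init__(self, mode: str = "fold"):
        if mode not in ("refresh", "fold", "split"):
            raise ValueError(f"unknown rotation mode {mode!r}")
        self.mode = mode
        self.params: FHEParams | None = None
        self.key_id: str | None = None
        self.backend = None

    def configure_fhe(self, params: FHEParams, key_id: str) -> None:
        self.params = params
        self.key_id = key_id

    def forward(self, s):
        if is_encrypted(s):
            return ckks.rotate(s, self.params, self.key_id, mode=self.mode,
                               backend=self.backend)
        arr = np.asarray(s, dtype=np.float64).ravel()
        if self.mode == "refresh":
            return arr
        if self.mode == "fold":
            return np.asarray([arr.sum()])
        return [arr[i:i + 1] for i in range(arr.size)]

    def backward(self, g):
        # d(Σx)/dx_i = 1: the scalar gradient passes through unchanged
        return g

    def get_config(self):
        cfg = {"mode": self.mode}
        if self.params is not None:
            cfg["params"] = self.params.to_dict()
            cfg["key_id"] = self.key_id
        return cfg, {}

    @classmethod
    def from_config(cls, config, arrays):
        node = cls(mode=config.get("mode", "fold"))
        if "params" in config:
            node.configure_fhe(FHEParams.from_dict(config["params"]),
                               config.get("key_id", "default"))
        return node


# ---------------------------------------------------------------------------
# Learnable nodes
# ---------------------------------------------------------------------------

@register_node
class CrossCorrelationNode(Node):
    """Biased cross-correlation via kernel masquerading.

    The forward receptor yields one un-summed cyphertext per valid window:
    ``mask_t ⊙ x + (b/N)·support_t`` where ``support_t`` indicates the window
    footprint and ``N`` is the window element count.  A downstream fold-sum
    then reproduces ``Σ x_i w_i + b`` exactly.  Only one multiplicative level
    of the input is consumed, whatever the kernel size.

    Windows follow valid (no padding) placement with per-axis strides on the
    row-major flattened input.
    """

    def __init__(self, input_shape: Sequence[int],
                 kernel_shape: Sequence[int],
                 stride: int | Sequence[int] = 1,
                 bias: float = 0.0, seed: int | None = None,
                 weight_scale: float = 0.1,
                 kernel: np.ndarray | None = None):
        self.input_shape = tuple(int(d) for d in input_shape)
        self.kernel_shape = tuple(int(d) for d in kernel_shape)
        ndim = len(self.input_shape)
        if len(self.kernel_shape) != ndim:
            raise ShapeError("kernel and input dimensionalities differ")
        if isinstance(stride, int):
            stride = (stride,) * ndim
        self.stride = tuple(int(s) for s in stride)
        if any(s < 1 for s in self.stride):
            raise ShapeError("strides must be >= 1")
        if any(k > d for k, d in zip(self.kernel_shape, self.input_shape)):
            raise ShapeError(
                f"kernel {self.kernel_shape} larger than input "
                f"{self.input_shape}")
        if kernel is not None:
            self.kernel = np.asarray(kernel, dtype=np.float64).copy()
            if self.kernel.shape != self.kernel_shape:
                raise ShapeError("explicit kernel has the wrong shape")
        else:
            rng = np.random.default_rng(seed)
            self.kernel = rng.normal(0.0, weight_scale, self.kernel_shape)
        self.bias = float(bias)
        self.offsets = [
            offs for offs in product(*(
                range(0, d - k + 1, st) for d, k, st in
                zip(self.input_shape, self.kernel_shape, self.stride)))
        ]
        self.window_slices = [
            tuple(slice(o, o + k) for o, k in zip(offs, self.kernel_shape))
            for offs in self.offsets
        ]
        size = int(np.prod(self.input_shape))
        self.support = np.zeros((len(self.offsets), size))
        for t, sl in enumerate(self.window_slices):
            ind = np.zeros(self.input_shape)
            ind[sl] = 1.0
            self.support[t] = ind.ravel()
        self._cache = None
        self._gk = np.zeros_like(self.kernel)
        self._gb = 0.0

    @property
    def N(self) -> int:
        """Window element count (the commuted-bias divisor)."""
        return int(np.prod(self.kernel_shape))

    @property
    def window_count(self) -> int:
        return len(self.offsets)

    def cost(self) -> int:
        return 1  # one ct x pt Hadamard product per window

    def forward(self, x):
        self._cache = x
        masks = [masquerade(self.kernel, self.input_shape, offs).ravel()
                 for offs in self.offsets]
        bias_terms = [(self.bias / self.N) * sup for sup in self.support]

        def windows():
            for mask, bias_t in zip(masks, bias_terms):
                yield x * mask + bias_t

        return windows()

    def backward(self, grads):
        if self._cache is None:
            raise StateError("backward before forward: no cached input")
        x = _plain_array(self._cache, "cross-correlation backward"
                         ).reshape(self.input_shape)
        gs = grads if isinstance(grads, list) else [grads]
        if len(gs) != self.window_count:
            raise ShapeError(
                f"expected {self.window_count} window gradients, "
                f"got {len(gs)}")
        gx = np.zeros(self.input_shape)
        for sl, g in zip(self.window_slices, gs):
            gt = float(np.sum(np.asarray(g, dtype=np.float64)))
            self._gk += gt * x[sl]
            self._gb += gt  # each window contributes N * (1/N) = 1
            gx[sl] += gt * self.kernel
        return gx.ravel()

    def apply_gradients(self, lr: float) -> None:
        self.kernel -= lr * self._gk
        self.bias -= lr * self._gb
        self.zero_gradients()

    def zero_gradients(self) -> None:
        self._gk = np.zeros_like(self.kernel)
        self._gb = 0.0

    def get_config(self):
        cfg = {"input_shape": list(self.input_shape),
               "kernel_shape": list(self.kernel_shape),
               "stride": list(self.stride),
               "bias": self.bias}
        return cfg, {"kernel": self.kernel.copy()}

    @classmethod
    def from_config(cls, config, arrays):
        return cls(input_shape=config["input_shape"],
                   kernel_shape=config["kernel_shape"],
                   stride=tuple(config["stride"]),
                   bias=config["bias"],
                   kernel=arrays["kernel"])


@register_node
class DenseNode(Node):
    """Fully connected neuron merging divergent branches back together.

    Accepts the ordered sequence of branch values on its single inbound edge
    and computes ``z = Σ_i (x_i w_i + b/N)`` — the commuted-bias form of the
    affine map, one multiplicative level per branch cyphertext.
    """

    def __init__(self, n_inputs: int, bias: float = 0.0,
                 seed: int | None = None, weight_scale: float = 0.1,
                 weights: np.ndarray | None = None):
        self.n_inputs = int(n_inputs)
        if self.n_inputs < 1:
            raise ShapeError("dense node needs at least one input branch")
        if weights is not None:
            self.w = np.asarray(weights, dtype=np.float64).copy()
            if self.w.shape != (self.n_inputs,):
                raise ShapeError("explicit weights have the wrong shape")
        else:
            rng = np.random.default_rng(seed)
            self.w = rng.normal(0.0, weight_scale, self.n_inputs)
        self.bias = float(bias)
        self._cache = None
        self._gw = np.zeros_like(self.w)
        self._gb = 0.0

    def cost(self) -> int:
        return 1

    def forward(self, xs):
        if isinstance(xs, (list, tuple)):
            xs = list(xs)
        elif isinstance(xs, np.ndarray):
            xs = [np.atleast_1d(row) for row in np.atleast_2d(xs)] \
                if xs.ndim > 1 else [np.asarray([v]) for v in xs]
        else:
            xs = [xs]
        if len(xs) != self.n_inputs:
            raise ShapeError(
                f"dense node expects {self.n_inputs} inputs, got {len(xs)}")
        self._cache = xs
        N = self.n_inputs
        z = xs[0] * self.w[0] + self.bias / N
        for i in range(1, N):
            z = z + (xs[i] * self.w[i] + self.bias / N)
        return z

    def backward(self, g):
        if self._cache is None:
            raise StateError("backward before forward: no cached input")
        g = _sum_edge_grads(g)
        xs = [_plain_array(x, "dense backward") for x in self._cache]
        for i, x in enumerate(xs):
            self._gw[i] += float(np.sum(g * x))
        self._gb += float(np.sum(g))
        return [g * self.w[i] for i in range(self.n_inputs)]

    def apply_gradients(self, lr: float) -> None:
        self.w -= lr * self._gw
        self.bias -= lr * self._gb
        self.zero_gradients()

    def zero_gradients(self) -> None:
        self._gw = np.zeros_like(self.w)
        self._gb = 0.0

    def get_config(self):
        return ({"n_inputs": self.n_inputs, "bias": self.bias},
                {"weights": self.w.copy()})

    @classmethod
    def from_config(cls, config, arrays):
        return cls(n_inputs=config["n_inputs"], bias=config["bias"],
                   weights=arrays["weights"])


class _ActivationBase(Node):
    """Element-wise activation applied to a value or a sequence of values.

    Sequences are activated element-by-element and returned as a list that is
    broadcast downstream; the backward receptor splits the merged gradient
    back per inbound edge via a generator.
    """

    def cost(self) -> int:
        return 2

    def _f(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def _df(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def _pre_forward(self, s):
        pass

    def forward(self, s):
        self._pre_forward(s)
        if isinstance(s, (list, tuple)):
            self._cache = list(s)
            return [self._f(x) for x in s]
        self._cache = s
        return self._f(s)

    def backward(self, g):
        cached = getattr(self, "_cache", None)
        if cached is None:
            raise StateError("backward before forward: no cached input")
        if isinstance(cached, list):
            plain = [_plain_array(x, "activation backward") for x in cached]
            if isinstance(g, list) and g and isinstance(g[0], (list, tuple)):
                # gradients from several outbound edges: sum element-wise
                merged = [
                    sum(np.asarray(edge[i], dtype=np.float64)
                        for edge in g)
                    for i in range(len(plain))
                ]
            elif isinstance(g, list):
                merged = [np.asarray(gi, dtype=np.float64) for gi in g]
            else:
                raise ShapeError(
                    "activation over a sequence expects per-element "
                    "gradients")
            if len(merged) != len(plain):
                raise ShapeError("gradient/input sequence length mismatch")
            out = [gi * self._df(xi) for gi, xi in zip(merged, plain)]
            return (o for o in out)
        x = _plain_array(cached, "activation backward")
        g = _sum_edge_grads(g)
        self._post_backward(g, x)
        return g * self._df(x)

    def _post_backward(self, g, x):
        pass


@register_node
class ReluApproxNode(_ActivationBase):
    """ReLU approximation with a dynamically tracked range q.

    While training, q follows an exponential moving average of the batch
    maximum magnitude (default policy), keeping the polynomial's valid window
    matched to the activations it actually sees.  A gradient-based update
    using dRa/dq = -4x²/(3πq²) + 1/(3π) is available as ``q_policy="grad"``.
    """

    def __init__(self, q: float = 1.0, alpha: float = 0.1,
                 q_policy: str = "ema", q_min: float = 1e-3,
                 q_lr: float = 0.01):
        if q <= 0:
            raise ValueError("q must be positive")
        if q_policy not in ("ema", "grad", "none"):
            raise ValueError(f"unknown q policy {q_policy!r}")
        self.q = float(q)
        self.alpha = float(alpha)
        self.q_policy = q_policy
        self.q_min = float(q_min)
        self.q_lr = float(q_lr)
        self.training = False
        self._cache = None
        self._gq = 0.0

    def _f(self, x):
        return relu_approx(x, self.q)

    def _df(self, x):
        return relu_approx_derivative(x, self.q)

    def _pre_forward(self, s):
        if self.training and self.q_policy == "ema":
            batch = list(s) if isinstance(s, (list, tuple)) else [s]
            if not any(is_encrypted(v) for v in batch):
                relu_range_update(self, batch)

    def _dq(self, x):
        return -4.0 * x * x / (3.0 * np.pi * self.q ** 2) + 1.0 / (3.0 * np.pi)

    def backward(self, g):
        if self.q_policy == "grad" and self.training:
            cached = self._cache
            xs = cached if isinstance(cached, list) else [cached]
            gs = g if isinstance(g, list) else [g]
            try:
                for gi, xi in zip(gs, xs):
                    xi = _plain_array(xi, "relu range gradient")
                    self._gq += float(np.sum(
                        np.asarray(gi, dtype=np.float64) * self._dq(xi)))
            except (ShapeError, StateError):
                pass
        return super().backward(g)

    def apply_gradients(self, lr: float) -> None:
        if self.q_policy == "grad" and self._gq:
            self.q = max(self.q - self.q_lr * self._gq, self.q_min)
        self._gq = 0.0

    def get_config(self):
        return ({"q": self.q, "alpha": self.alpha, "q_policy": self.q_policy,
                 "q_min": self.q_min, "q_lr": self.q_lr}, {})


@register_node
class SigmoidApproxNode(_ActivationBase):
    """Static cubic sigmoid approximation node (coefficients 0.5, 0.197, -0.004)."""

    def __init__(self):
        self._cache = None
        self.training = False

    def _f(self, x):
        return sigmoid_approx(x)

    def _df(self, x):
        return sigmoid_approx_derivative(x)

    def get_config(self):
        return {}, {}


# ---------------------------------------------------------------------------
# Plaintext loss / prediction circuit
# ---------------------------------------------------------------------------

def _stack_scalars(s) -> np.ndarray:
    if isinstance(s, (list, tuple)):
        _require_plain(list(s), "plaintext circuit input")
        return np.concatenate(
            [np.atleast_1d(np.asarray(v, dtype=np.float64)) for v in s])
    _require_plain(s, "plaintext circuit input")
    return np.atleast_1d(np.asarray(s, dtype=np.float64))


@register_node
class SoftmaxNode(Node):
    """Plaintext softmax over the stacked per-class activations.

    The backward receptor receives the combined softmax+CCE gradient p - y
    from the loss node and splits it per class back onto its inbound edges.
    """

    def __init__(self):
        self._p = None
        self._k = 0

    def forward(self, s):
        a = _stack_scalars(s)
        self._k = a.size
        self._p = softmax(a)
        return self._p

    def backward(self, g):
        g = np.asarray(_sum_edge_grads(g), dtype=np.float64).ravel()
        if g.size != self._k:
            raise ShapeError("gradient size does not match class count")
        return (np.asarray([g[i]]) for i in range(self._k))

    def get_config(self):
        return {}, {}


@register_node
class CCENode(Node):
    """Categorical cross-entropy fed by the softmax and the one-hot label."""

    def __init__(self, eps: float = 1e-12):
        self.eps = eps
        self._p = None
        self._y = None
        self.last_loss: float | None = None

    def forward(self, s):
        if not (isinstance(s, list) and len(s) == 2):
            raise ShapeError(
                "CCE expects exactly two inbound signals: probabilities "
                "and the one-hot label")
        p, y = s
        loss, _ = cce_loss(p, y, eps=self.eps)
        self._p = np.asarray(p, dtype=np.float64)
        self._y = np.asarray(y, dtype=np.float64)
        self.last_loss = loss
        return loss

    def backward(self, seed):
        if self._p is None:
            raise StateError("backward before forward: no cached prediction")
        return (self._p - self._y) * float(np.asarray(seed))

    def get_config(self):
        return {"eps": self.eps}, {}


@register_node
class ArgmaxNode(Node):
    """Plaintext argmax -> one-hot; an output-only branch with no gradient."""

    def forward(self, s):
        return argmax_onehot(_stack_scalars(s))

    def backward(self, g):
        return None

    def get_config(self):
        return {}, {}


@register_node
class OneHotEncodeNode(Node):
    def __init__(self, K: int):
        self.K = int(K)

    def forward(self, s):
        return onehot_encode(int(np.asarray(s)), self.K)

    def backward(self, g):
        return None

    def get_config(self):
        return {"K": self.K}, {}


@register_node
class OneHotDecodeNode(Node):
    def forward(self, s):
        return onehot_decode(s)

    def backward(self, g):
        return None

    def get_config(self):
        return {}, {}


@register_node
class MSENode(Node):
    """Mean-squared-error loss for the regression networks."""

    def __init__(self):
        self._grad = None
        self.last_loss: float | None = None

    def forward(self, s):
        if not (isinstance(s, list) and len(s) == 2):
            raise ShapeError(
                "MSE expects exactly two inbound signals: prediction and "
                "target")
        yhat, y = s
        loss, grad = mse_loss(yhat, y)
        self._grad = grad
        self.last_loss = loss
        return loss

    def backward(self, seed):
        if self._grad is None:
            raise StateError("backward before forward: no cached residual")
        return self._grad * float(np.asarray(seed))

    def get_config(self):
        return {}, {}
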