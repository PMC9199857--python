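"""Per-atlas MLP subnetworks: forward pass, loss, and analytic gradients.

Each retained atlas feeds one small fully connected network ending in a
3-way softmax head.  Atlases with more than 100 ROIs get three linear
layers (linear -> ReLU, linear -> dropout, linear -> softmax); coarser
atlases get two (linear -> dropout, linear -> softmax).  The pre-activation
of a layer is ``z^l = a^(l-1) W^l + b^l``; the hidden activation is a noisy
rectifier ``max(0, z + eps)`` with ``eps ~ N(0, 1)`` drawn independently per
element during training (plain ReLU at evaluation, so inference is
deterministic).  Training minimises the cross-entropy ``-log p_y`` by
mini-batch SGD; the backward pass here is hand-derived and is validated
against central finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

N_CLASSES = 3
_EPS = 1e-12  # cross-entropy probability clip


@dataclass(frozen=True)
class SubnetSpec:
    """Architecture of one atlas subnetwork."""

    atlas_name: str
    input_dim: int
    depth: int  # number of linear layers, 2 or 3
    hidden_dims: tuple[int, ...]
    dropout_rate: float = 0.5
    noisy_activation: bool = True
    output_dim: int = N_CLASSES

    def __post_init__(self):
        if self.depth not in (2, 3):
            raise ValueError(f"depth must be 2 or 3, got {self.depth}")
        if len(self.hidden_dims) != self.depth - 1:
            raise ValueError(
                f"{self.atlas_name}: depth {self.depth} needs "
                f"{self.depth - 1} hidden width(s), got {self.hidden_dims}"
            )
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")

    @property
    def layer_dims(self) -> list[int]:
        return [self.input_dim, *self.hidden_dims, self.output_dim]


@dataclass
class SubnetParams:
    """Weight matrices and bias vectors, one pair per linear layer."""

    weights: list[np.ndarray] = field(default_factory=list)
    biases: list[np.ndarray] = field(default_factory=list)

    def copy(self) -> "SubnetParams":
        return SubnetParams([w.copy() for w in self.weights],
                            [b.copy() for b in self.biases])


def init_params(spec: SubnetSpec, rng: np.random.Generator) -> SubnetParams:
    """Scaled uniform fan-in initialisation, U(-1/sqrt(fan_in), +1/sqrt(fan_in))."""
    dims = spec.layer_dims
    weights, biases = [], []
    for fan_in, fan_out in zip(dims, dims[1:]):
        bound = 1.0 / np.sqrt(fan_in)
        weights.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
        biases.append(rng.uniform(-bound, bound, size=fan_out))
    return SubnetParams(weights, biases)


def softmax(z: np.ndarray) -> np.ndarray:
    """Row-wise softmax with max-shift for overflow safety."""
    z = np.asarray(z, dtype=float)
    shifted = z - z.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def activation(z: np.ndarray, noisy: bool = False,
               rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Rectifier ``max(0, z)``; with ``noisy`` a standard-normal perturbation
    is added inside the rectifier (training-time regulariser)."""
    z = np.asarray(z, dtype=float)
    if noisy:
        if rng is None:
            raise ValueError("noisy activation requires an rng")
        z = z + rng.standard_normal(z.shape)
    return np.maximum(0.0, z)


def cross_entropy(prob: np.ndarray, label) -> float | np.ndarray:
    """Cross-entropy ``-log p_label`` with probabilities clipped to [1e-12, 1].

    Accepts a single probability vector with an integer label, or a batch
    (rows) with a label array; the batch form returns the per-sample vector.
    """
    prob = np.asarray(prob, dtype=float)
    if prob.ndim == 1:
        return float(-np.log(np.clip(prob[int(label)], _EPS, 1.0)))
    picked = prob[np.arange(prob.shape[0]), np.asarray(label, dtype=int)]
    return -np.log(np.clip(picked, _EPS, 1.0))


class ShapeError(ValueError):
    pass


def subnet_forward(x: np.ndarray, spec: SubnetSpec, params: SubnetParams,
                   mode: str = "eval",
                   rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Run one subnetwork; returns softmax probabilities.

    ``mode="train"`` activates dropout and (if the spec says so) the noisy
    rectifier; ``mode="eval"`` is deterministic.  Accepts a single feature
    vector or a batch.
    """
    probs, _ = _forward(x, spec, params, mode=mode, rng=rng)
    return probs


def _forward(x, spec, params, mode="eval", rng=None):
    """Forward pass returning (probs, cache) for backprop."""
    if mode not in ("train", "eval"):
        raise ValueError(f"mode must be 'train' or 'eval', got {mode!r}")
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    a = x[None, :] if single else x
    if a.shape[1] != spec.input_dim:
        raise ShapeError(
            f"subnet {spec.atlas_name!r} expects input width "
            f"{spec.input_dim}, got {a.shape[1]}"
        )
    train = mode == "train"
    if train and rng is None and (spec.dropout_rate > 0 or spec.noisy_activation):
        raise ValueError("train mode with dropout/noise requires an rng")
    W, b = params.weights, params.biases
    cache = {"a0": a}
    if spec.depth == 3:
        z1 = a @ W[0] + b[0]
        pre = z1 + rng.standard_normal(z1.shape) if (train and spec.noisy_activation) else z1
        a1 = np.maximum(0.0, pre)
        cache["relu_pre"] = pre
        z2 = a1 @ W[1] + b[1]
        a2, mask = _dropout(z2, spec.dropout_rate, train, rng)
        cache.update(a1=a1, drop_mask=mask, a2=a2)
        z3 = a2 @ W[2] + b[2]
        probs = softmax(z3)
    else:
        z1 = a @ W[0] + b[0]
        a1, mask = _dropout(z1, spec.dropout_rate, train, rng)
        cache.update(drop_mask=mask, a1=a1)
        z2 = a1 @ W[1] + b[1]
        probs = softmax(z2)
    cache["probs"] = probs
    return (probs[0] if single else probs), cache


def _dropout(z, rate, train, rng):
    """Inverted dropout: surviving units scaled by 1/(1-rate)."""
    if not train or rate <= 0.0:
        return z, None
    mask = (rng.random(z.shape) >= rate) / (1.0 - rate)
    return z * mask, mask


def subnet_loss_grad(x, y, spec: SubnetSpec, params: SubnetParams,
                     mode: str = "train",
                     rng: Optional[np.random.Generator] = None):
    """Mean cross-entropy over the batch and its analytic parameter gradients.

    Returns ``(loss, grad)`` where ``grad`` is a :class:`SubnetParams` of the
    same shapes.  Gradients are of the batch-mean loss.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=int))
    n = x.shape[0]
    probs, cache = _forward(x, spec, params, mode=mode, rng=rng)
    loss = float(np.mean(cross_entropy(probs, y)))

    onehot = np.zeros((n, spec.output_dim))
    onehot[np.arange(n), y] = 1.0
    # d(mean CE)/d(logits) through softmax
    dz_out = (cache["probs"] - onehot) / n

    W = params.weights
    gW = [None] * len(W)
    gb = [None] * len(W)
    if spec.depth == 3:
        gW[2] = cache["a2"].T @ dz_out
        gb[2] = dz_out.sum(axis=0)
        da2 = dz_out @ W[2].T
        dz2 = da2 if cache["drop_mask"] is None else da2 * cache["drop_mask"]
        gW[1] = cache["a1"].T @ dz2
        gb[1] = dz2.sum(axis=0)
        da1 = dz2 @ W[1].T
        dz1 = da1 * (cache["relu_pre"] > 0)
        gW[0] = cache["a0"].T @ dz1
        gb[0] = dz1.sum(axis=0)
    else:
        gW[1] = cache["a1"].T @ dz_out
        gb[1] = dz_out.sum(axis=0)
        da1 = dz_out @ W[1].T
        dz1 = da1 if cache["drop_mask"] is None else da1 * cache["drop_mask"]
        gW[0] = cache["a0"].T @ dz1
        gb[0] = dz1.sum(axis=0)
    return loss, SubnetParams(gW, gb)


def sgd_step(params: SubnetParams, grad: SubnetParams, lr: float) -> None:
    """In-place plain SGD update (no momentum, no weight decay)."""
    for w, gw in zip(params.weights, grad.weights):
        w -= lr * gw
    for b, gb in zip(params.biases, grad.biases):
        b -= lr * gb
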