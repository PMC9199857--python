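"""Multi-atlas MLP ensemble classifier (scikit-learn estimator).

One subnetwork per retained atlas sees only that atlas's column slice; the
ensemble decision is softmax-sum voting: the per-subnet softmax vectors are
summed elementwise and the predicted class is the argmax of the sum,
``O = argmax_k sum_j softmax(M_j)_k``.  Subnetworks are trained
independently, each by mini-batch SGD on its own cross-entropy loss against
the shared labels (a joint mode that backpropagates through the averaged
vote exists behind ``joint_training=True``).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import nn
from .io import CLASS_NAMES, FeatureMatrix
from .metrics import confusion, macro_f1
from .registry import (AtlasRegistry, assign_depth, default_registry,
                       load_registry)


class SplitError(ValueError):
    """A class has too few samples for the requested balanced test set."""


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""


def split_dataset(labels: np.ndarray, per_class_test: int = 100,
                  seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Label-balanced train/test split.

    The test set holds exactly ``per_class_test`` uniformly sampled (seeded)
    samples of each class; everything else is train.  With the emulated
    cohort (NC 781 / MCI 1,148 / AD 671 = 2,600 samples) and the default
    ``per_class_test=100`` this reproduces the 2,300:300 protocol split.
    """
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    test_parts = []
    for k, name in enumerate(CLASS_NAMES):
        idx = np.flatnonzero(labels == k)
        if idx.size < per_class_test:
            raise SplitError(
                f"class {name} has {idx.size} samples, fewer than the "
                f"requested {per_class_test} test samples"
            )
        test_parts.append(rng.choice(idx, size=per_class_test, replace=False))
    test_idx = np.sort(np.concatenate(test_parts)) if test_parts else np.array([], int)
    mask = np.ones(labels.size, dtype=bool)
    mask[test_idx] = False
    return np.flatnonzero(mask), test_idx


class MAMLPClassifier(ClassifierMixin, BaseEstimator):
    """Per-atlas MLP ensemble with softmax-sum voting.

    Parameters
    ----------
    registry : AtlasRegistry or None
        Filtered atlas layout; each version's span selects that subnet's
        input columns.  ``None`` uses the packaged 13-atlas registry.
    hidden_dims_deep : tuple of int, default (128, 32)
        Hidden widths of three-layer subnets (atlases with > 100 ROIs).
    hidden_dims_shallow : tuple of int, default (32,)
        Hidden width of two-layer subnets.
    learning_rate : float, default 0.001
    dropout_rate : float, default 0.5
    batch_size : int, default 32
    epochs : int, default 100
    noisy_activation : bool, default True
        Add N(0, 1) noise inside hidden rectifiers during training.
    joint_training : bool, default False
        Backpropagate the shared cross-entropy of the averaged vote through
        every subnet instead of training subnets independently.
    eval_every : int, default 1
        Log accuracy / macro F1 every this many epochs (loss every epoch).
    random_state : int, default 0

    Attributes
    ----------
    classes_ : ndarray, [0, 1, 2] (NC, MCI, AD)
    subnets_ : list of (AtlasVersion, SubnetSpec, SubnetParams)
    history_ : pandas.DataFrame
        Columns epoch, split, loss, accuracy, macro_f1.
    """

    def __init__(self, registry: Optional[AtlasRegistry] = None,
                 hidden_dims_deep: tuple = (128, 32),
                 hidden_dims_shallow: tuple = (32,),
                 learning_rate: float = 0.001, dropout_rate: float = 0.5,
                 batch_size: int = 32, epochs: int = 100,
                 noisy_activation: bool = True, joint_training: bool = False,
                 eval_every: int = 1, random_state: int = 0):
        self.registry = registry
        self.hidden_dims_deep = hidden_dims_deep
        self.hidden_dims_shallow = hidden_dims_shallow
        self.learning_rate = learning_rate
        self.dropout_rate = dropout_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.noisy_activation = noisy_activation
        self.joint_training = joint_training
        self.eval_every = eval_every
        self.random_state = random_state

    # -- construction -----------------------------------------------------

    def _registry(self) -> AtlasRegistry:
        reg = self.registry if self.registry is not None else default_registry(filtered=True)
        if len(reg) == 0:
            raise ValueError("registry is empty; nothing to build subnets for")
        return reg

    def _build(self, rng: np.random.Generator):
        reg = self._registry()
        subnets = []
        for version in reg:
            depth = assign_depth(version.roi_count)
            hidden = (tuple(self.hidden_dims_deep) if depth == 3
                      else tuple(self.hidden_dims_shallow))
            spec = nn.SubnetSpec(
                atlas_name=version.name, input_dim=version.n_features,
                depth=depth, hidden_dims=hidden,
                dropout_rate=self.dropout_rate,
                noisy_activation=self.noisy_activation,
            )
            subnets.append([version, spec, nn.init_params(spec, rng)])
        return reg, subnets

    # -- training ---------------------------------------------------------

    def fit(self, X, y, eval_set: Optional[tuple] = None):
        """Train every subnetwork by mini-batch SGD.

        ``eval_set=(X_test, y_test)`` adds held-out loss/accuracy/macro-F1
        tracking to ``history_``; it never influences the fit itself.
        """
        X, y = self._check_Xy(X, y)
        seed_root = np.random.SeedSequence(self.random_state)
        init_rng = np.random.default_rng(seed_root.spawn(1)[0])
        self.registry_, self.subnets_ = self._build(init_rng)
        if X.shape[1] != self.registry_.total_features:
            raise nn.ShapeError(
                f"X has {X.shape[1]} columns but the registry lays out "
                f"{self.registry_.total_features} features"
            )
        self.classes_ = np.arange(nn.N_CLASSES)
        train_rng = np.random.default_rng(seed_root.spawn(2)[1])

        slices = [slice(*v.span) for v, _, _ in self.subnets_]
        n = X.shape[0]
        log_rows = []
        for epoch in range(1, self.epochs + 1):
            order = train_rng.permutation(n)
            epoch_loss = 0.0
            n_batches = 0
            for start in range(0, n, self.batch_size):
                batch = order[start:start + self.batch_size]
                xb, yb = X[batch], y[batch]
                if self.joint_training:
                    loss = self._joint_step(xb, yb, slices, train_rng)
                else:
                    loss = self._independent_step(xb, yb, slices, train_rng)
                if not np.isfinite(loss):
                    raise DivergenceError(
                        f"non-finite loss at epoch {epoch}"
                    )
                epoch_loss += loss
                n_batches += 1
            row = {"epoch": epoch, "split": "train",
                   "loss": epoch_loss / n_batches}
            if epoch % self.eval_every == 0 or epoch == self.epochs:
                row.update(self._eval_metrics(X, y))
                log_rows.append(row)
                if eval_set is not None:
                    Xt, yt = self._check_Xy(*eval_set)
                    trow = {"epoch": epoch, "split": "test",
                            "loss": float(np.mean(nn.cross_entropy(
                                self.predict_proba(Xt), yt)))}
                    trow.update(self._eval_metrics(Xt, yt))
                    log_rows.append(trow)
            else:
                log_rows.append(row)
        self.history_ = pd.DataFrame(log_rows)
        return self

    def _independent_step(self, xb, yb, slices, rng):
        """One SGD step per subnet on its own cross-entropy; returns the
        mean subnet loss."""
        total = 0.0
        for (version, spec, params), sl in zip(self.subnets_, slices):
            loss, grad = nn.subnet_loss_grad(
                xb[:, sl], yb, spec, params, mode="train", rng=rng)
            if not np.isfinite(loss):
                raise DivergenceError(
                    f"non-finite loss in subnet {version.name!r}"
                )
            nn.sgd_step(params, grad, self.learning_rate)
            total += loss
        return total / len(self.subnets_)

    def _joint_step(self, xb, yb, slices, rng):
        """One SGD step on the cross-entropy of the averaged vote."""
        nsub = len(self.subnets_)
        nb = xb.shape[0]
        caches, probs = [], []
        for (_, spec, params), sl in zip(self.subnets_, slices):
            p, cache = nn._forward(xb[:, sl], spec, params, mode="train", rng=rng)
            caches.append(cache)
            probs.append(cache["probs"])
        pbar = np.mean(probs, axis=0)
        loss = float(np.mean(nn.cross_entropy(pbar, yb)))
        # dL/d p_j = -(1/(N n)) * onehot / pbar; through each softmax jacobian
        g = np.zeros_like(pbar)
        g[np.arange(nb), yb] = -1.0 / np.clip(pbar[np.arange(nb), yb], nn._EPS, 1.0)
        g /= nsub * nb
        for (_, spec, params), sl, cache, pj in zip(
                self.subnets_, slices, caches, probs):
            dz_out = pj * (g - (g * pj).sum(axis=1, keepdims=True))
            grad = self._backprop_from_logits(xb[:, sl], spec, params, cache, dz_out)
            nn.sgd_step(params, grad, self.learning_rate)
        return loss

    @staticmethod
    def _backprop_from_logits(xb, spec, params, cache, dz_out):
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
        return nn.SubnetParams(gW, gb)

    def _eval_metrics(self, X, y):
        pred = self.predict(X)
        cm = confusion(y, pred)
        return {"accuracy": float(np.mean(pred == y)),
                "macro_f1": macro_f1(cm)}

    # -- inference --------------------------------------------------------

    def decision_function(self, X) -> np.ndarray:
        """Summed softmax scores S with ``sum_k S_k = n_subnets``."""
        check_is_fitted(self, "subnets_")
        X = self._check_X(X)
        total = np.zeros((X.shape[0], nn.N_CLASSES))
        for version, spec, params in self.subnets_:
            sl = slice(*version.span)
            total += nn.subnet_forward(X[:, sl], spec, params, mode="eval")
        return total

    def predict_proba(self, X) -> np.ndarray:
        """Summed softmax scores divided by the number of subnets."""
        return self.decision_function(X) / len(self.subnets_)

    def predict(self, X) -> np.ndarray:
        """Argmax of the summed vote; ties break toward the lowest class
        index (NC before MCI before AD)."""
        return np.argmax(self.decision_function(X), axis=1)

    # -- validation -------------------------------------------------------

    @staticmethod
    def _check_X(X) -> np.ndarray:
        if isinstance(X, FeatureMatrix):
            X = X.values
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if not np.isfinite(X).all():
            raise ValueError("X contains non-finite entries; preprocess first")
        return X

    def _check_Xy(self, X, y=None):
        if isinstance(X, FeatureMatrix):
            if y is None:
                y = X.labels
            X = X.values
        if y is None:
            raise ValueError("labels are required")
        X = self._check_X(X)
        y = np.asarray(y, dtype=int)
        if np.any((y < 0) | (y >= nn.N_CLASSES)):
            raise ValueError("labels must be class codes 0 (NC), 1 (MCI), 2 (AD)")
        return X, y

    # -- persistence ------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Persist to a directory: registry + spec metadata (JSON) and
        per-subnet parameter arrays (NPZ); round-trips bit-exactly."""
        check_is_fitted(self, "subnets_")
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "class_names": list(CLASS_NAMES),
            "params": {k: v for k, v in self.get_params().items()
                       if k != "registry"},
            "registry": self.registry_.to_manifest(),
            "subnets": [
                {"atlas": v.name, "depth": s.depth,
                 "hidden_dims": list(s.hidden_dims),
                 "dropout_rate": s.dropout_rate,
                 "noisy_activation": s.noisy_activation}
                for v, s, _ in self.subnets_
            ],
        }
        with open(directory / "model.json", "w") as fh:
            json.dump(meta, fh, indent=1)
        arrays = {}
        for i, (_, _, params) in enumerate(self.subnets_):
            for l, (w, b) in enumerate(zip(params.weights, params.biases)):
                arrays[f"subnet{i}_W{l}"] = w
                arrays[f"subnet{i}_b{l}"] = b
        np.savez(directory / "params.npz", **arrays)

    @classmethod
    def load(cls, directory: str | Path) -> "MAMLPClassifier":
        directory = Path(directory)
        with open(directory / "model.json") as fh:
            meta = json.load(fh)
        registry = load_registry(meta["registry"])
        clf = cls(registry=registry, **meta["params"])
        clf.registry_ = registry
        clf.classes_ = np.arange(nn.N_CLASSES)
        npz = np.load(directory / "params.npz")
        subnets = []
        for i, (version, sub) in enumerate(zip(registry, meta["subnets"])):
            spec = nn.SubnetSpec(
                atlas_name=version.name, input_dim=version.n_features,
                depth=sub["depth"], hidden_dims=tuple(sub["hidden_dims"]),
                dropout_rate=sub["dropout_rate"],
                noisy_activation=sub["noisy_activation"],
            )
            weights, biases = [], []
            for l in range(sub["depth"]):
                weights.append(npz[f"subnet{i}_W{l}"])
                biases.append(npz[f"subnet{i}_b{l}"])
            subnets.append([version, spec, nn.SubnetParams(weights, biases)])
        clf.subnets_ = subnets
        clf.history_ = pd.DataFrame()
        return clf


# -- functional wrappers ---------------------------------------------------

def build_ensemble(registry: AtlasRegistry, config: Optional[dict] = None,
                   seed: int = 0) -> MAMLPClassifier:
    """Construct an (untrained-but-initialised) ensemble over ``registry``."""
    clf = MAMLPClassifier(registry=registry, random_state=seed,
                          **(config or {}))
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    clf.registry_, clf.subnets_ = clf._build(rng)
    clf.classes_ = np.arange(nn.N_CLASSES)
    return clf


def ensemble_probs(x, model: MAMLPClassifier,
                   registry: Optional[AtlasRegistry] = None) -> np.ndarray:
    """Summed softmax vote for one feature vector (length-3, sums to the
    number of subnets)."""
    scores = model.decision_function(np.atleast_2d(x))
    return scores[0] if np.asarray(x).ndim == 1 else scores


def ensemble_predict(x, model: MAMLPClassifier,
                     registry: Optional[AtlasRegistry] = None):
    """Argmax of :func:`ensemble_probs` (lowest index wins ties)."""
    pred = model.predict(np.atleast_2d(x))
    return int(pred[0]) if np.asarray(x).ndim == 1 else pred


def train_ensemble(matrix: FeatureMatrix, registry: AtlasRegistry,
                   config: Optional[dict] = None,
                   eval_set: Optional[tuple] = None
                   ) -> tuple[MAMLPClassifier, pd.DataFrame]:
    """Fit an ensemble on a labelled feature matrix; returns (model, log)."""
    clf = MAMLPClassifier(registry=registry, **(config or {}))
    clf.fit(matrix, matrix.labels, eval_set=eval_set)
    return clf, clf.history_
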