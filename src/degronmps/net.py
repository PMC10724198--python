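"""Fully connected stability classifier.

Architecture (fixed by design): input -> 50 -> 12 -> 5 -> 2-class softmax.
Each hidden layer uses ReLU and dropout 0.3 during training; the 50-node and
5-node layers carry L1 and L2 weight penalties of 0.001 (the published
description indexes the regularized layers over the five-layer count, which
is ambiguous against "3 internal layers"; the first and last hidden layers
are used here). Training is plain mini-batch Adam on categorical
cross-entropy over the two softmax outputs (equivalent to binary
cross-entropy), batch size 500, 30 epochs, no early stopping.

Implemented directly in numpy: the network is tiny, training takes seconds,
and every arithmetic step is seeded and reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

UNSTABLE, STABLE = 1, 0  # class indices; column 1 of the softmax = unstable


@dataclass
class NetConfig:
    hidden_sizes: tuple[int, int, int] = (50, 12, 5)
    dropout: float = 0.3
    l1: float = 1e-3
    l2: float = 1e-3
    regularized_layers: tuple[int, ...] = (0, 2)  # indices into hidden_sizes
    learning_rate: float = 1e-3
    batch_size: int = 500
    epochs: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.hidden_sizes) != 3 or any(h < 1 for h in self.hidden_sizes):
            raise ValueError("hidden_sizes must be three positive layer widths")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        for v in (self.l1, self.l2, self.learning_rate):
            if v < 0:
                raise ValueError("hyperparameters must be non-negative")
        if self.batch_size < 1 or self.epochs < 0:
            raise ValueError("batch_size must be positive and epochs >= 0")


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class DegronClassifier:
    """The stability network plus its input standardization statistics.

    ``fit`` standardizes features with statistics of the training set only
    and stores them; ``predict_proba`` applies the same transform, so test
    data never leak into the scaler.
    """

    def __init__(self, n_features: int, config: NetConfig | None = None):
        self.config = config or NetConfig()
        self.n_features = n_features
        self.scaler_mean_: np.ndarray | None = None
        self.scaler_scale_: np.ndarray | None = None
        self.scaler_source: str | None = None  # provenance tag ("train")
        rng = np.random.default_rng(self.config.seed)
        sizes = [n_features, *self.config.hidden_sizes, 2]
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))  # Glorot uniform
            self.weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))

    # -- plumbing -------------------------------------------------------------

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        if self.scaler_mean_ is None:
            raise RuntimeError("model is not fitted (no scaler statistics)")
        return (X - self.scaler_mean_) / self.scaler_scale_

    def _forward(self, Xs: np.ndarray, rng: np.random.Generator | None = None):
        """Forward pass on standardized input; dropout only when rng given."""
        cfg = self.config
        acts = [Xs]
        masks = []
        h = Xs
        for li in range(3):
            z = h @ self.weights[li] + self.biases[li]
            h = np.maximum(z, 0.0)
            if rng is not None and cfg.dropout > 0:
                mask = (rng.random(h.shape) >= cfg.dropout) / (1.0 - cfg.dropout)
                h = h * mask
            else:
                mask = None
            masks.append(mask)
            acts.append(h)
        probs = _softmax(h @ self.weights[3] + self.biases[3])
        return probs, acts, masks

    # -- API ------------------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> "DegronClassifier":
        """Train on features X (raw) and binary labels y (1 = unstable)."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.shape[1] != self.n_features:
            raise ValueError(f"feature length {X.shape[1]} != model input {self.n_features}")
        cfg = self.config
        self.scaler_mean_ = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
        self.scaler_scale_ = scale
        self.scaler_source = "train"
        Xs = self._standardize(X)
        Y = np.eye(2)[y]
        rng = np.random.default_rng(cfg.seed + 1)

        # Adam state
        m_w = [np.zeros_like(w) for w in self.weights]
        v_w = [np.zeros_like(w) for w in self.weights]
        m_b = [np.zeros_like(b) for b in self.biases]
        v_b = [np.zeros_like(b) for b in self.biases]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        n = len(Xs)
        n_batches = int(np.ceil(n / cfg.batch_size))
        for _epoch in range(cfg.epochs):
            order = rng.permutation(n)
            for bi in range(n_batches):
                idx = order[bi * cfg.batch_size : (bi + 1) * cfg.batch_size]
                xb, yb = Xs[idx], Y[idx]
                probs, acts, masks = self._forward(xb, rng=rng)
                grads_w = [None] * 4
                grads_b = [None] * 4
                delta = (probs - yb) / len(xb)  # dL/dz at softmax
                for li in range(3, -1, -1):
                    grads_w[li] = acts[li].T @ delta
                    grads_b[li] = delta.sum(axis=0)
                    if li > 0:
                        delta = delta @ self.weights[li].T
                        if masks[li - 1] is not None:
                            delta = delta * masks[li - 1]
                        delta = delta * (acts[li] > 0)
                for li in cfg.regularized_layers:
                    grads_w[li] = grads_w[li] + cfg.l1 * np.sign(self.weights[li]) + 2 * cfg.l2 * self.weights[li]
                t += 1
                for li in range(4):
                    m_w[li] = beta1 * m_w[li] + (1 - beta1) * grads_w[li]
                    v_w[li] = beta2 * v_w[li] + (1 - beta2) * grads_w[li] ** 2
                    m_b[li] = beta1 * m_b[li] + (1 - beta1) * grads_b[li]
                    v_b[li] = beta2 * v_b[li] + (1 - beta2) * grads_b[li] ** 2
                    mw_hat = m_w[li] / (1 - beta1**t)
                    vw_hat = v_w[li] / (1 - beta2**t)
                    mb_hat = m_b[li] / (1 - beta1**t)
                    vb_hat = v_b[li] / (1 - beta2**t)
                    self.weights[li] -= cfg.learning_rate * mw_hat / (np.sqrt(vw_hat) + eps)
                    self.biases[li] -= cfg.learning_rate * mb_hat / (np.sqrt(vb_hat) + eps)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """(n, 2) softmax probabilities; column 1 = unstable class."""
        Xs = self._standardize(np.asarray(X, dtype=float))
        probs, _, _ = self._forward(Xs, rng=None)
        return probs

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def unstable_probability(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X)[:, UNSTABLE]

    # -- persistence ----------------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {f"w{i}": w for i, w in enumerate(self.weights)}
        arrays |= {f"b{i}": b for i, b in enumerate(self.biases)}
        arrays["scaler_mean"] = self.scaler_mean_
        arrays["scaler_scale"] = self.scaler_scale_
        np.savez(path.with_suffix(".npz"), **arrays)
        meta = {"config": asdict(self.config), "n_features": self.n_features,
                "scaler_source": self.scaler_source}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "DegronClassifier":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        cfgd = meta["config"]
        cfgd["hidden_sizes"] = tuple(cfgd["hidden_sizes"])
        cfgd["regularized_layers"] = tuple(cfgd["regularized_layers"])
        model = cls(meta["n_features"], NetConfig(**cfgd))
        data = np.load(path.with_suffix(".npz"))
        model.weights = [data[f"w{i}"] for i in range(4)]
        model.biases = [data[f"b{i}"] for i in range(4)]
        model.scaler_mean_ = data["scaler_mean"]
        model.scaler_scale_ = data["scaler_scale"]
        model.scaler_source = meta["scaler_source"]
        return model


# -- dataset splitting --------------------------------------------------------


@dataclass
class SplitSpec:
    n_per_class: int = 3750
    validation_fraction: float = 0.2
    n_test_sets: int = 3
    seed: int = 0


def split_dataset(labels: pd.Series, spec: SplitSpec) -> dict[str, list[str]]:
    """Balanced train / validation / disjoint test splits of labeled peptides.

    ``labels``: index = peptide, value in {"stable", "unstable"}. The train
    set samples ``n_per_class`` per class; the validation set is a random
    fraction of the train set (held out of fitting, used for monitoring);
    all remaining peptides are partitioned uniformly into ``n_test_sets``
    disjoint test sets whose union is also returned (``test_4`` by default).
    """
    rng = np.random.default_rng(spec.seed)
    peps = labels.index.to_numpy()
    classes = {"unstable", "stable"}
    if not set(labels.unique()) <= classes:
        raise ValueError("labels must be 'stable' or 'unstable'")
    chosen = []
    for cls in sorted(classes):
        members = peps[(labels == cls).to_numpy()]
        if len(members) < spec.n_per_class:
            raise ValueError(
                f"class {cls!r} has {len(members)} members; {spec.n_per_class} required"
            )
        chosen.append(rng.choice(members, size=spec.n_per_class, replace=False))
    train = np.concatenate(chosen)
    train = train[rng.permutation(len(train))]
    n_val = int(round(spec.validation_fraction * len(train)))
    validation = train[:n_val]
    train_fit = train[n_val:]
    leftover = np.array(sorted(set(peps) - set(train)))
    leftover = leftover[rng.permutation(len(leftover))]
    tests = np.array_split(leftover, spec.n_test_sets)
    splits = {
        "train": list(train),
        "train_fit": list(train_fit),
        "validation": list(validation),
    }
    for i, tset in enumerate(tests, start=1):
        splits[f"test_{i}"] = list(tset)
    splits[f"test_{spec.n_test_sets + 1}"] = list(leftover)
    return splits


def train_model(
    X: np.ndarray, y: np.ndarray, config: NetConfig | None = None
) -> DegronClassifier:
    model = DegronClassifier(n_features=X.shape[1], config=config)
    return model.fit(X, y)


def evaluate_model(model: DegronClassifier, X: np.ndarray, y: np.ndarray) -> dict:
    """loss / accuracy / AUC / precision / recall / MSE on a labeled set.

    AUC is over the unstable-class probability; precision and recall are for
    the unstable class; MSE compares softmax outputs with one-hot labels.
    AUC is None when only one class is present.
    """
    y = np.asarray(y, dtype=int)
    if len(y) == 0:
        raise ValueError("empty evaluation set")
    probs = model.predict_proba(X)
    pred = probs.argmax(axis=1)
    onehot = np.eye(2)[y]
    eps = 1e-12
    loss = float(-np.mean(np.sum(onehot * np.log(probs + eps), axis=1)))
    accuracy = float(np.mean(pred == y))
    tp = int(np.sum((pred == UNSTABLE) & (y == UNSTABLE)))
    fp = int(np.sum((pred == UNSTABLE) & (y != UNSTABLE)))
    fn = int(np.sum((pred != UNSTABLE) & (y == UNSTABLE)))
    precision = tp / (tp + fp) if (tp + fp) else np.nan
    recall = tp / (tp + fn) if (tp + fn) else np.nan
    auc = float(roc_auc_score(y, probs[:, UNSTABLE])) if len(set(y)) == 2 else None
    mse = float(np.mean((probs - onehot) ** 2))
    return {"loss": loss, "accuracy": accuracy, "auc": auc,
            "precision": precision, "recall": recall, "mse": mse}
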