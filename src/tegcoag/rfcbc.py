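"""Residual Fully Connected Binary Classifier (RFCBC).

A small fully connected network for tabular coagulation features with two
concatenation (skip) junctions:

    FC1: in -> 64
    FC2: 64 -> 128
    FC3: 128 -> 256
    FC4: 256 -> 512
    FC5: 512 -> 256
    concat1 = [FC1 out, FC5 out]        -> 320
    FC3': 320 -> 256
    FC4': 256 -> 512
    concat2 = [FC2 out, FC4' out]       -> 640
    FC6: 640 -> 2 (softmax)

ReLU follows every hidden layer; nothing precedes the final softmax.  The
published narrative reuses "FC3 and FC4" for the post-concatenation stage and
says FC6 maps 512 -> 2; neither is dimensionally consistent with the stated
concatenations, so the canonical resolution here uses fresh dimension-matched
layers FC3'/FC4' and FC6: 640 -> 2.  A weight-sharing variant (learned
320 -> 128 projection feeding the original FC3/FC4) and an alternative
640 -> 512 -> 2 head are available behind flags.

Implemented directly in numpy (forward, backprop, Adam, dropout, early
stopping); at these layer widths and cohort sizes, batched matrix products
are all that is required, and single-threaded runs are exactly reproducible
from the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RfcbcArchitecture",
    "TrainConfig",
    "TrainedModel",
    "build_rfcbc",
    "train",
    "forward",
    "RfcbcClassifier",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class RfcbcArchitecture:
    """Resolved layer plan; widths beyond FC1 are input-independent."""

    input_dim: int
    layer_dims: dict
    concat_plan: list  # (name, sources, width)
    activation: str = "relu"
    dropout_rate: float = 0.1
    shared_reprocessing: bool = False
    wide_head: bool = False  # FC6 as 640 -> 512 -> 2 instead of 640 -> 2

    def layer_shapes(self) -> list:
        """(name, in_width, out_width) for every weight matrix, in order."""
        d = self.layer_dims
        shapes = [
            ("fc1", self.input_dim, d["fc1"]),
            ("fc2", d["fc1"], d["fc2"]),
            ("fc3", d["fc2"], d["fc3"]),
            ("fc4", d["fc3"], d["fc4"]),
            ("fc5", d["fc4"], d["fc5"]),
        ]
        if self.shared_reprocessing:
            shapes.append(("proj", d["concat1"], d["fc2"]))
        else:
            shapes += [
                ("fc3p", d["concat1"], d["fc3p"]),
                ("fc4p", d["fc3p"], d["fc4p"]),
            ]
        if self.wide_head:
            shapes += [("fc6a", d["concat2"], 512), ("fc6", 512, 2)]
        else:
            shapes.append(("fc6", d["concat2"], 2))
        return shapes

    def parameter_count(self) -> int:
        return sum((i + 1) * o for _, i, o in self.layer_shapes())

    def summary(self) -> str:
        lines = [f"RFCBC(input_dim={self.input_dim})"]
        for name, i, o in self.layer_shapes():
            lines.append(f"  {name}: {i} -> {o}")
        for name, sources, width in self.concat_plan:
            lines.append(f"  {name}: concat{sources} -> {width}")
        lines.append(f"  parameters: {self.parameter_count()}")
        return "\n".join(lines)


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 200
    early_stop_patience: int = 20
    validation_fraction: float = 0.2
    seed: int = 0
    standardize: bool = True
    weight_decay: float = 0.0

    def __post_init__(self):
        if self.learning_rate <= 0 or self.batch_size <= 0 or self.max_epochs <= 0:
            raise ValueError("learning_rate, batch_size, max_epochs must be positive")
        if not 0.0 <= self.validation_fraction <= 0.5:
            raise ValueError("validation_fraction must lie in [0, 0.5]")


@dataclass
class TrainedModel:
    architecture: RfcbcArchitecture
    weights: dict  # name -> (W, b)
    scaler: tuple  # (mean vector, sd vector)
    history: list = field(default_factory=list)  # per-epoch dicts

    def predict_proba(self, X) -> np.ndarray:
        return forward(self, X)

    def predict(self, X) -> np.ndarray:
        return forward(self, X).argmax(axis=1)


def build_rfcbc(input_dim: int, dropout_rate: float = 0.1,
                shared_reprocessing: bool = False,
                wide_head: bool = False) -> RfcbcArchitecture:
    """Resolve the canonical RFCBC layer plan for ``input_dim`` features."""
    if input_dim < 1:
        raise ValueError("input_dim must be >= 1")
    dims = {
        "fc1": 64, "fc2": 128, "fc3": 256, "fc4": 512, "fc5": 256,
        "concat1": 64 + 256, "fc3p": 256, "fc4p": 512,
        "concat2": 128 + 512, "output": 2,
    }
    concat_plan = [
        ("concat1", ["fc1", "fc5"], dims["concat1"]),
        ("concat2", ["fc2", "fc4p" if not shared_reprocessing else "fc4_shared"],
         dims["concat2"]),
    ]
    return RfcbcArchitecture(
        input_dim=int(input_dim), layer_dims=dims, concat_plan=concat_plan,
        dropout_rate=dropout_rate, shared_reprocessing=shared_reprocessing,
        wide_head=wide_head,
    )


# ---------------------------------------------------------------------------
# Forward / backward
# ---------------------------------------------------------------------------


def _relu(x):
    return np.maximum(x, 0.0)


def _softmax(logits):
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward_pass(arch, weights, X, dropout_rng=None):
    """Run the network; returns (probs, cache) with pre-activations cached."""
    rate = arch.dropout_rate if dropout_rng is not None else 0.0

    def drop(h):
        if rate <= 0:
            return h, None
        mask = (dropout_rng.random(h.shape) >= rate) / (1 - rate)
        return h * mask, mask

    cache = {"X": X, "masks": {}}

    def dense(name, inp, activate=True):
        W, b = weights[name]
        z = inp @ W + b
        h = _relu(z) if activate else z
        cache[name] = (inp, z, h)
        if activate and dropout_rng is not None:
            h, mask = drop(h)
            cache["masks"][name] = mask
        return h

    h1 = dense("fc1", X)
    h2 = dense("fc2", h1)
    h3 = dense("fc3", h2)
    h4 = dense("fc4", h3)
    h5 = dense("fc5", h4)
    c1 = np.concatenate([h1, h5], axis=1)
    if arch.shared_reprocessing:
        hp = dense("proj", c1)
        h3p = dense("fc3_shared", hp)  # reuses fc3/fc4 weights
        h4p = dense("fc4_shared", h3p)
    else:
        h3p = dense("fc3p", c1)
        h4p = dense("fc4p", h3p)
    c2 = np.concatenate([h2, h4p], axis=1)
    if arch.wide_head:
        h6a = dense("fc6a", c2)
        logits = dense("fc6", h6a, activate=False)
    else:
        logits = dense("fc6", c2, activate=False)
    return _softmax(logits), cache


class _SharedView(dict):
    """Weight lookup that aliases fc3_shared/fc4_shared to fc3/fc4."""

    def __getitem__(self, key):
        if key in ("fc3_shared", "fc4_shared"):
            key = key.replace("_shared", "")
        return super().__getitem__(key)


def _backward_pass(arch, weights, cache, probs, y_onehot):
    """Cross-entropy gradient through the skip-concatenation graph."""
    grads = {}
    n = len(y_onehot)

    def back_dense(name, dh, weight_key=None):
        weight_key = weight_key or name
        inp, z, _ = cache[name]
        mask = cache["masks"].get(name)
        if mask is not None:
            dh = dh * mask
        dz = dh * (z > 0)  # hidden layers only; the output layer is handled below
        W, _ = weights[weight_key]
        gW = inp.T @ dz / n
        gb = dz.mean(axis=0)
        if weight_key in grads:
            grads[weight_key] = (grads[weight_key][0] + gW, grads[weight_key][1] + gb)
        else:
            grads[weight_key] = (gW, gb)
        return dz @ W.T

    dlogits = probs - y_onehot
    if arch.wide_head:
        # fc6 here is a linear output layer on top of the hidden fc6a
        inp, z, _ = cache["fc6"]
        W, _ = weights["fc6"]
        grads["fc6"] = (inp.T @ dlogits / n, dlogits.mean(axis=0))
        dh6a = dlogits @ W.T
        dc2 = back_dense("fc6a", dh6a)
    else:
        inp, z, _ = cache["fc6"]
        W, _ = weights["fc6"]
        grads["fc6"] = (inp.T @ dlogits / n, dlogits.mean(axis=0))
        dc2 = dlogits @ W.T

    d2 = arch.layer_dims["fc2"]
    dh2_skip, dh4p = dc2[:, :d2], dc2[:, d2:]
    if arch.shared_reprocessing:
        dh3p = back_dense("fc4_shared", dh4p, weight_key="fc4")
        dhp = back_dense("fc3_shared", dh3p, weight_key="fc3")
        dc1 = back_dense("proj", dhp)
    else:
        dh3p = back_dense("fc4p", dh4p)
        dc1 = back_dense("fc3p", dh3p)
    d1 = arch.layer_dims["fc1"]
    dh1_skip, dh5 = dc1[:, :d1], dc1[:, d1:]
    dh4 = back_dense("fc5", dh5)
    dh3 = back_dense("fc4", dh4)
    dh2 = back_dense("fc3", dh3)
    dh1 = back_dense("fc2", dh2 + dh2_skip)
    back_dense("fc1", dh1 + dh1_skip)
    return grads


def _init_weights(arch, rng):
    weights = {}
    for name, fan_in, fan_out in arch.layer_shapes():
        scale = np.sqrt(2.0 / fan_in)
        weights[name] = (
            rng.normal(0.0, scale, size=(fan_in, fan_out)),
            np.zeros(fan_out),
        )
    return _SharedView(weights) if arch.shared_reprocessing else weights


def forward(model: TrainedModel, X) -> np.ndarray:
    """Class-probability matrix for ``X``; rows sum to 1."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.architecture.input_dim:
        raise ValueError(
            f"expected {model.architecture.input_dim} features, got {X.shape[1]}"
        )
    mean, sd = model.scaler
    Xs = (X - mean) / sd
    probs, _ = _forward_pass(model.architecture, model.weights, Xs)
    return probs


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def _cross_entropy(probs, y):
    return float(-np.log(np.clip(probs[np.arange(len(y)), y], 1e-12, None)).mean())


def train(arch: RfcbcArchitecture, X, y, config: TrainConfig | None = None
          ) -> TrainedModel:
    """Train with Adam on the cross-entropy, early stopping on validation loss.

    Fully reproducible given ``(X, y, config.seed)`` on a single thread; the
    best-validation weights are restored at the end.  Raises on non-finite
    loss.
    """
    config = config or TrainConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) != 2:
        raise ValueError("both classes must be present")
    if len(X) < config.batch_size and config.validation_fraction > 0:
        raise ValueError("need at least one full batch of training rows")

    rng = np.random.default_rng(config.seed)
    if config.standardize:
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
    else:
        mean = np.zeros(X.shape[1])
        sd = np.ones(X.shape[1])
    Xs = (X - mean) / sd

    # stratified validation split
    if config.validation_fraction > 0:
        val_idx = []
        for cls in (0, 1):
            idx = np.where(y == cls)[0]
            idx = rng.permutation(idx)
            k = max(1, int(round(len(idx) * config.validation_fraction)))
            val_idx.extend(idx[:k])
        val_mask = np.zeros(len(y), dtype=bool)
        val_mask[val_idx] = True
        X_tr, y_tr = Xs[~val_mask], y[~val_mask]
        X_val, y_val = Xs[val_mask], y[val_mask]
    else:
        X_tr, y_tr = Xs, y
        X_val, y_val = None, None

    weights = _init_weights(arch, rng)
    adam_m = {k: (np.zeros_like(w), np.zeros_like(b)) for k, (w, b) in weights.items()}
    adam_v = {k: (np.zeros_like(w), np.zeros_like(b)) for k, (w, b) in weights.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t_step = 0

    y_tr_onehot = np.eye(2)[y_tr]
    history = []
    best = (np.inf, None, -1)
    patience_left = config.early_stop_patience
    dropout_rng = np.random.default_rng(rng.integers(2**31))

    for epoch in range(config.max_epochs):
        order = rng.permutation(len(X_tr))
        for start in range(0, len(X_tr), config.batch_size):
            idx = order[start:start + config.batch_size]
            if len(idx) == 0:
                continue
            probs, cache = _forward_pass(arch, weights, X_tr[idx],
                                         dropout_rng=dropout_rng)
            grads = _backward_pass(arch, weights, cache, probs, y_tr_onehot[idx])
            t_step += 1
            for k, (gW, gb) in grads.items():
                if config.weight_decay:
                    gW = gW + config.weight_decay * weights[k][0]
                mW, mb = adam_m[k]
                vW, vb = adam_v[k]
                mW = beta1 * mW + (1 - beta1) * gW
                mb = beta1 * mb + (1 - beta1) * gb
                vW = beta2 * vW + (1 - beta2) * gW**2
                vb = beta2 * vb + (1 - beta2) * gb**2
                adam_m[k] = (mW, mb)
                adam_v[k] = (vW, vb)
                bc1 = 1 - beta1**t_step
                bc2 = 1 - beta2**t_step
                W, b = weights[k]
                weights[k] = (
                    W - config.learning_rate * (mW / bc1) / (np.sqrt(vW / bc2) + eps),
                    b - config.learning_rate * (mb / bc1) / (np.sqrt(vb / bc2) + eps),
                )

        tr_probs, _ = _forward_pass(arch, weights, X_tr)
        tr_loss = _cross_entropy(tr_probs, y_tr)
        if not np.isfinite(tr_loss):
            raise FloatingPointError(
                f"non-finite training loss at epoch {epoch}"
            )
        entry = {
            "epoch": epoch,
            "train_loss": tr_loss,
            "train_accuracy": float((tr_probs.argmax(axis=1) == y_tr).mean()),
        }
        if X_val is not None:
            val_probs, _ = _forward_pass(arch, weights, X_val)
            val_loss = _cross_entropy(val_probs, y_val)
            entry["val_loss"] = val_loss
            entry["val_accuracy"] = float(
                (val_probs.argmax(axis=1) == y_val).mean()
            )
            monitor = val_loss
        else:
            monitor = tr_loss
        history.append(entry)

        if monitor < best[0] - 1e-6:
            best = (monitor, {k: (W.copy(), b.copy())
                              for k, (W, b) in weights.items()}, epoch)
            patience_left = config.early_stop_patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                break

    final_weights = best[1] if best[1] is not None else weights
    if arch.shared_reprocessing and not isinstance(final_weights, _SharedView):
        final_weights = _SharedView(final_weights)
    return TrainedModel(
        architecture=arch, weights=final_weights, scaler=(mean, sd),
        history=history,
    )


# ---------------------------------------------------------------------------
# Persistence and sklearn-style wrapper
# ---------------------------------------------------------------------------


def save_model(model: TrainedModel, npz_path, sidecar_path=None) -> None:
    """Serialize weights to npz with a JSON sidecar (architecture + scaler)."""
    arrays = {}
    for k, (W, b) in dict(model.weights).items():
        arrays[f"{k}__W"] = W
        arrays[f"{k}__b"] = b
    np.savez(npz_path, **arrays)
    sidecar = {
        "input_dim": model.architecture.input_dim,
        "dropout_rate": model.architecture.dropout_rate,
        "shared_reprocessing": model.architecture.shared_reprocessing,
        "wide_head": model.architecture.wide_head,
        "scaler_mean": np.asarray(model.scaler[0]).tolist(),
        "scaler_sd": np.asarray(model.scaler[1]).tolist(),
    }
    sidecar_path = sidecar_path or str(npz_path) + ".json"
    with open(sidecar_path, "w") as fh:
        json.dump(sidecar, fh, indent=1)


def load_model(npz_path, sidecar_path=None) -> TrainedModel:
    sidecar_path = sidecar_path or str(npz_path) + ".json"
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    arch = build_rfcbc(
        meta["input_dim"], dropout_rate=meta["dropout_rate"],
        shared_reprocessing=meta["shared_reprocessing"],
        wide_head=meta["wide_head"],
    )
    data = np.load(npz_path)
    names = {k.rsplit("__", 1)[0] for k in data.files}
    weights = {k: (data[f"{k}__W"], data[f"{k}__b"]) for k in names}
    if arch.shared_reprocessing:
        weights = _SharedView(weights)
    return TrainedModel(
        architecture=arch, weights=weights,
        scaler=(np.asarray(meta["scaler_mean"]), np.asarray(meta["scaler_sd"])),
    )


class RfcbcClassifier:
    """Minimal sklearn-style estimator wrapping build/train/forward."""

    def __init__(self, dropout_rate: float = 0.1, learning_rate: float = 1e-3,
                 batch_size: int = 32, max_epochs: int = 200,
                 early_stop_patience: int = 20,
                 validation_fraction: float = 0.2, seed: int = 0,
                 standardize: bool = True):
        self.dropout_rate = dropout_rate
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.early_stop_patience = early_stop_patience
        self.validation_fraction = validation_fraction
        self.seed = seed
        self.standardize = standardize
        self.model_ = None

    def get_params(self, deep=True):
        return {
            "dropout_rate": self.dropout_rate,
            "learning_rate": self.learning_rate,
            "batch_size": self.batch_size,
            "max_epochs": self.max_epochs,
            "early_stop_patience": self.early_stop_patience,
            "validation_fraction": self.validation_fraction,
            "seed": self.seed,
            "standardize": self.standardize,
        }

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        arch = build_rfcbc(X.shape[1], dropout_rate=self.dropout_rate)
        vf = self.validation_fraction
        if len(X) < 4 * self.batch_size:
            vf = 0.0  # tiny folds: train on everything
        config = TrainConfig(
            learning_rate=self.learning_rate,
            batch_size=min(self.batch_size, len(X)),
            max_epochs=self.max_epochs,
            early_stop_patience=self.early_stop_patience,
            validation_fraction=vf, seed=self.seed,
            standardize=self.standardize,
        )
        self.model_ = train(arch, X, np.asarray(y, dtype=int), config)
        return self

    def predict_proba(self, X):
        return forward(self.model_, X)

    def predict(self, X):
        return self.predict_proba(X).argmax(axis=1)
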