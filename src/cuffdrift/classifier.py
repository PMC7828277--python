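"""Three-pathway signature classifiers with calibrated softmax probabilities.

Two interchangeable model specs are provided:

``linear_baseline``
    Multinomial softmax regression on the flattened 56 x 100 signature.
    Fast enough for CPU-scale strategy sweeps; used as the default desk-scale
    classifier.

``dual_cnn``
    A dual-branch convolutional network: the same signature is fed once in
    ring-major ("spatial emphasis") and once in slot-major ("temporal
    emphasis") row order through two identical-topology convolutional
    branches (untied weights), concatenated into a single dense softmax(3)
    layer.  Convolution, pooling and backpropagation are implemented in
    numpy; filter counts and the training schedule are config-exposed.

Both specs share the state/train/predict contract, so everything downstream
(strategy engine, orchestration) treats them identically.  Training is
plain minibatch SGD with momentum, warm-starting from the passed-in
parameters; ``epochs=0`` is an exact no-op, which the update strategies rely
on for their warm-start chains.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .dataset_builder import CLASS_LABELS, SignatureDataset, reorder

__all__ = [
    "ClassifierState",
    "PredictionResult",
    "build_classifier",
    "train",
    "train_on_arrays",
    "predict_proba",
    "macro_f1",
    "count_parameters",
]

_DEFAULT_CONFIG = {
    "linear_baseline": {
        "learning_rate": 0.05,
        "momentum": 0.9,
        "batch_size": 128,
        "epochs": 15,
        "init_scale": 0.01,
    },
    "dual_cnn": {
        "learning_rate": 0.01,
        "momentum": 0.9,
        "batch_size": 64,
        "epochs": 8,
        "filters1": 8,
        "filters2": 16,
    },
}


@dataclass
class ClassifierState:
    """Opaque parameter collection plus architecture/config metadata."""

    spec: str
    params: dict[str, np.ndarray]
    config: dict
    classes: tuple[str, ...] = CLASS_LABELS
    history: list = field(default_factory=list)
    seed: int = 0

    def copy(self) -> "ClassifierState":
        return ClassifierState(
            spec=self.spec,
            params={k: v.copy() for k, v in self.params.items()},
            config=dict(self.config),
            classes=self.classes,
            history=copy.deepcopy(self.history),
            seed=self.seed,
        )


@dataclass
class PredictionResult:
    """Per-sample predicted labels and 3-class probability vectors."""

    labels: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self):
        if self.probabilities.shape[0] != self.labels.shape[0]:
            raise ValueError("labels and probabilities must align")

    @property
    def confidences(self) -> np.ndarray:
        return self.probabilities.max(axis=1)


def build_classifier(spec: str, seed: int, input_shape=(56, 100), **overrides) -> ClassifierState:
    """Create a seeded, untrained classifier state for a named spec."""
    if spec not in _DEFAULT_CONFIG:
        raise ValueError(f"unknown classifier spec {spec!r}")
    config = {**_DEFAULT_CONFIG[spec], **overrides, "input_shape": tuple(input_shape)}
    rng = np.random.default_rng(seed)
    C, T = input_shape
    n_classes = len(CLASS_LABELS)
    if spec == "linear_baseline":
        d = C * T
        params = {
            "W": rng.normal(0.0, config["init_scale"], (n_classes, d)),
            "b": np.zeros(n_classes),
        }
    else:
        f1, f2 = config["filters1"], config["filters2"]
        d_branch = f2 * (C // 4) * (T // 4)
        params = {}
        for br in ("spat", "temp"):
            params[f"{br}_w1"] = rng.normal(0.0, np.sqrt(2.0 / 9.0), (f1, 1, 3, 3))
            params[f"{br}_b1"] = np.zeros(f1)
            params[f"{br}_w2"] = rng.normal(0.0, np.sqrt(2.0 / (9.0 * f1)), (f2, f1, 3, 3))
            params[f"{br}_b2"] = np.zeros(f2)
        params["W"] = rng.normal(0.0, np.sqrt(1.0 / (2 * d_branch)), (n_classes, 2 * d_branch))
        params["b"] = np.zeros(n_classes)
    return ClassifierState(spec=spec, params=params, config=config, seed=seed)


def count_parameters(state: ClassifierState) -> int:
    return int(sum(v.size for v in state.params.values()))


# ---------------------------------------------------------------------------
# numpy conv/pool primitives


def _conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """3x3 same-padding correlation.  Returns (y, cached windows)."""
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (N, C, H, W, 3, 3)
    y = np.tensordot(win, w, axes=([1, 4, 5], [1, 2, 3]))  # (N, H, W, F)
    y = np.moveaxis(y, 3, 1) + b[None, :, None, None]
    return y, win


def _conv2d_grads(win, dy, w, need_dx: bool):
    """Gradients of a 3x3 same-padding correlation."""
    dw = np.tensordot(dy, win, axes=([0, 2, 3], [0, 2, 3]))  # (F, C, 3, 3)
    db = dy.sum(axis=(0, 2, 3))
    dx = None
    if need_dx:
        dyp = np.pad(dy, ((0, 0), (0, 0), (1, 1), (1, 1)))
        dwin = sliding_window_view(dyp, (3, 3), axis=(2, 3))  # (N, F, H, W, 3, 3)
        wf = w[:, :, ::-1, ::-1]
        dx = np.tensordot(dwin, wf, axes=([1, 4, 5], [0, 2, 3]))  # (N, H, W, C)
        dx = np.moveaxis(dx, 3, 1)
    return dw, db, dx


def _maxpool2(x: np.ndarray):
    N, F, H, W = x.shape
    xr = x.reshape(N, F, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
        N, F, H // 2, W // 2, 4
    )
    idx = xr.argmax(axis=-1)
    y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return y, idx


def _maxpool2_grad(dy: np.ndarray, idx: np.ndarray, in_shape):
    N, F, H, W = in_shape
    dxr = np.zeros((N, F, H // 2, W // 2, 4), dtype=dy.dtype)
    np.put_along_axis(dxr, idx[..., None], dy[..., None], axis=-1)
    return dxr.reshape(N, F, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
        N, F, H, W
    )


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# forward / backward


def _branch_forward(p, prefix, x):
    c1, win1 = _conv2d(x, p[f"{prefix}_w1"], p[f"{prefix}_b1"])
    r1 = np.maximum(c1, 0.0)
    p1, idx1 = _maxpool2(r1)
    c2, win2 = _conv2d(p1, p[f"{prefix}_w2"], p[f"{prefix}_b2"])
    r2 = np.maximum(c2, 0.0)
    p2, idx2 = _maxpool2(r2)
    feats = p2.reshape(x.shape[0], -1)
    cache = (win1, c1, idx1, r1.shape, win2, c2, idx2, r2.shape, p2.shape)
    return feats, cache


def _branch_backward(p, prefix, dfeats, cache, grads):
    win1, c1, idx1, r1_shape, win2, c2, idx2, r2_shape, p2_shape = cache
    dp2 = dfeats.reshape(p2_shape)
    dr2 = _maxpool2_grad(dp2, idx2, r2_shape)
    dc2 = dr2 * (c2 > 0)
    dw2, db2, dp1 = _conv2d_grads(win2, dc2, p[f"{prefix}_w2"], need_dx=True)
    dr1 = _maxpool2_grad(dp1, idx1, r1_shape)
    dc1 = dr1 * (c1 > 0)
    dw1, db1, _ = _conv2d_grads(win1, dc1, p[f"{prefix}_w1"], need_dx=False)
    grads[f"{prefix}_w1"] = dw1
    grads[f"{prefix}_b1"] = db1
    grads[f"{prefix}_w2"] = dw2
    grads[f"{prefix}_b2"] = db2


def _forward(state: ClassifierState, X: np.ndarray, with_cache: bool = False):
    p = state.params
    if state.spec == "linear_baseline":
        flat = X.reshape(X.shape[0], -1)
        logits = flat @ p["W"].T + p["b"]
        probs = _softmax(logits)
        return (probs, {"flat": flat}) if with_cache else probs
    xs = reorder(X, "spatial")[:, None, :, :]
    xt = reorder(X, "temporal")[:, None, :, :]
    fs, cs = _branch_forward(p, "spat", xs)
    ft, ct = _branch_forward(p, "temp", xt)
    feats = np.concatenate([fs, ft], axis=1)
    probs = _softmax(feats @ p["W"].T + p["b"])
    return (probs, {"feats": feats, "cache_s": cs, "cache_t": ct}) if with_cache else probs


def _backward(state: ClassifierState, probs, y_onehot, cache):
    p = state.params
    n = probs.shape[0]
    dlogits = (probs - y_onehot) / n
    grads: dict[str, np.ndarray] = {"b": dlogits.sum(axis=0)}
    if state.spec == "linear_baseline":
        grads["W"] = dlogits.T @ cache["flat"]
        return grads
    feats = cache["feats"]
    grads["W"] = dlogits.T @ feats
    dfeats = dlogits @ p["W"]
    half = feats.shape[1] // 2
    _branch_backward(p, "spat", dfeats[:, :half], cache["cache_s"], grads)
    _branch_backward(p, "temp", dfeats[:, half:], cache["cache_t"], grads)
    return grads


def predict_proba(state: ClassifierState, X: np.ndarray, batch_size: int = 512) -> PredictionResult:
    """Deterministic class probabilities; label = argmax (ties to the lowest
    class index)."""
    X = np.asarray(X)
    if X.ndim == 2:
        X = X[None]
    if X.shape[1:] != tuple(state.config["input_shape"]):
        raise ValueError(
            f"signature shape {X.shape[1:]} does not match {state.config['input_shape']}"
        )
    chunks = [
        _forward(state, X[i : i + batch_size]) for i in range(0, X.shape[0], batch_size)
    ]
    probs = np.concatenate(chunks, axis=0)
    return PredictionResult(labels=probs.argmax(axis=1), probabilities=probs)


def train_on_arrays(
    state: ClassifierState,
    X: np.ndarray,
    y: np.ndarray,
    epochs: int | None = None,
    seed: int = 0,
    require_all_classes: bool = True,
    **overrides,
) -> ClassifierState:
    """Warm-start minibatch SGD on raw arrays; returns a new state.

    ``epochs=0`` returns a copy with identical parameters.  Training always
    continues from the passed-in parameters.
    """
    if X.shape[0] == 0:
        raise ValueError("empty training set")
    y = np.asarray(y, dtype=int)
    if require_all_classes and np.any(np.bincount(y, minlength=len(state.classes)) == 0):
        raise ValueError("at least one class has no training samples")
    new = state.copy()
    cfg = {**new.config, **overrides}
    if epochs is None:
        epochs = cfg["epochs"]
    if epochs == 0:
        return new
    lr, mom, bs = cfg["learning_rate"], cfg["momentum"], cfg["batch_size"]
    rng = np.random.default_rng(seed)
    vel = {k: np.zeros_like(v) for k, v in new.params.items()}
    onehot = np.eye(len(new.classes))[y]
    for epoch in range(epochs):
        order = rng.permutation(X.shape[0])
        losses = []
        for start in range(0, X.shape[0], bs):
            idx = order[start : start + bs]
            probs, cache = _forward(new, X[idx], with_cache=True)
            grads = _backward(new, probs, onehot[idx], cache)
            eps = 1e-12
            losses.append(-np.mean(np.log(probs[np.arange(len(idx)), y[idx]] + eps)))
            for k, g in grads.items():
                vel[k] = mom * vel[k] - lr * g
                new.params[k] += vel[k]
        new.history.append({"epoch": len(new.history), "loss": float(np.mean(losses))})
    return new


def train(
    state: ClassifierState,
    dataset: SignatureDataset,
    train_folds,
    epochs: int | None = None,
    seed: int = 0,
    **overrides,
) -> ClassifierState:
    """Train on the signatures of the given folds with their true labels."""
    mask = dataset.fold_mask(train_folds)
    if not mask.any():
        raise ValueError("train_folds select no samples")
    return train_on_arrays(
        state, dataset.matrices[mask], dataset.labels[mask], epochs=epochs, seed=seed, **overrides
    )


def macro_f1(predictions, true_labels) -> float:
    """Macro-averaged F1: per-class F1 = 2PR/(P+R) (0 when P+R = 0), averaged
    over the three pathway classes."""
    pred = predictions.labels if isinstance(predictions, PredictionResult) else np.asarray(predictions)
    true = np.asarray(true_labels)
    if pred.size == 0 or pred.shape != true.shape:
        raise ValueError("predictions and labels must be non-empty and aligned")
    scores = []
    for c in range(len(CLASS_LABELS)):
        tp = np.sum((pred == c) & (true == c))
        fp = np.sum((pred == c) & (true != c))
        fn = np.sum((pred != c) & (true == c))
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        scores.append(2 * precision * recall / (precision + recall) if precision + recall else 0.0)
    return float(np.mean(scores))
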