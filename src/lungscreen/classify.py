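"""PResNet: a small residual network with parametric ReLU, plus the risk screen.

The classifier consumes the selected feature vector of an image and outputs
Normal/Abnormal with an abnormal probability. Topology (feature-vector mode):

    input (1 channel, d features)
      -> 1-D convolution stem (width channels, kernel 3, same padding) -> p-ReLU
      -> n_blocks residual blocks: [conv -> p-ReLU -> conv] + identity skip
      -> non-overlapping max pooling with stride kappa
      -> fully connected head -> 2 logits -> softmax

The parametric rectifier mu(x) = x for x > 0 and J*x otherwise; the negative
slope J is a learnable scalar per activation site (one for the stem, one per
block). Training minimises softmax cross-entropy with Adam; everything is
implemented in NumPy with explicit backward passes (gradient-checked in the
test suite) and float64 parameters, so runs are bit-reproducible for a fixed
seed and a saved checkpoint reloads to identical predictions.

"Transfer learning" is realised as an optional warm start: ``train`` accepts
a model restored from a checkpoint (e.g. pre-trained on a larger phantom
corpus) and continues optimisation on the new data.

Risk screening follows the classification: a Normal prediction carries risk
"none"; an Abnormal one is screened on the on-rib evidence of its most
salient quadrant — the quadrant with the largest candidate-lesion blob — and
marked high risk when that quadrant's on-rib flag is set or its blob radius
reaches ``tau_risk`` (default 8 px).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .features import QUADRANT_TAGS, feature_names

__all__ = [
    "PresnetConfig",
    "Prediction",
    "PresnetModel",
    "prelu",
    "build_presnet",
    "train",
    "predict",
    "predict_batch",
    "risk_screen",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class PresnetConfig:
    """Architecture and training knobs of the PResNet classifier."""

    n_blocks: int = 3
    width: int = 32
    j_init: float = 0.25  # negative-slope initialisation
    learnable_j: bool = True
    kappa: int = 2  # max-pooling stride
    epochs: int = 50
    batch_size: int = 32
    lr: float = 0.01
    weight_decay: float = 0.0
    seed: int = 0
    mode: str = "feature_vector"

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if not (0 <= self.j_init < 1):
            raise ValueError("j_init must be in [0, 1)")
        if self.kappa < 1:
            raise ValueError("kappa must be >= 1")
        if self.mode != "feature_vector":
            raise NotImplementedError(
                "only mode='feature_vector' is implemented; image mode is not "
                "available in this build"
            )


@dataclass(frozen=True)
class Prediction:
    """Classifier output for one image."""

    class_label: str  # "Normal" | "Abnormal"
    abnormal_score: float  # softmax probability of Abnormal, in [0, 1]
    risk_label: str = "none"  # "none" | "low" | "high"

    def __post_init__(self) -> None:
        if (self.risk_label == "none") != (self.class_label == "Normal"):
            raise ValueError("risk_label must be 'none' iff class_label is Normal")


def prelu(x, j: float):
    """Parametric rectifier: x for x > 0, J*x otherwise (elementwise)."""
    if not np.isfinite(j):
        raise ValueError("J must be finite")
    x = np.asarray(x, dtype=float)
    return np.where(x > 0, x, j * x)


# ----------------------------------------------------------- layer algebra


def _conv1d(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Same-padded 1-D convolution; x (n, C, L), w (O, C, 3) -> (n, O, L)."""
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1)))
    n, c, lp = xp.shape
    length = x.shape[2]
    out = np.zeros((n, w.shape[0], length))
    for j in range(3):
        out += np.einsum("ncl,oc->nol", xp[:, :, j: j + length], w[:, :, j])
    return out + b[None, :, None]


def _conv1d_backward(dout, x, w):
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1)))
    length = x.shape[2]
    dw = np.zeros_like(w)
    dxp = np.zeros_like(xp)
    for j in range(3):
        dw[:, :, j] = np.einsum("nol,ncl->oc", dout, xp[:, :, j: j + length])
        dxp[:, :, j: j + length] += np.einsum("nol,oc->ncl", dout, w[:, :, j])
    db = dout.sum(axis=(0, 2))
    return dxp[:, :, 1:-1], dw, db


def _prelu_forward(x, j):
    return np.where(x > 0, x, j * x)


def _prelu_backward(dout, x, j):
    dx = dout * np.where(x > 0, 1.0, j)
    dj = float(np.sum(dout * np.where(x > 0, 0.0, x)))
    return dx, dj


def _maxpool(x: np.ndarray, kappa: int):
    n, c, length = x.shape
    lo = length // kappa
    view = x[:, :, : lo * kappa].reshape(n, c, lo, kappa)
    arg = view.argmax(axis=3)
    return view.max(axis=3), arg


def _maxpool_backward(dout, x_shape, arg, kappa):
    n, c, lo = dout.shape
    dview = np.zeros((n, c, lo, kappa))
    ii, jj, kk = np.ogrid[:n, :c, :lo]
    dview[ii, jj, kk, arg] = dout
    dx = np.zeros(x_shape)
    dx[:, :, : lo * kappa] = dview.reshape(n, c, lo * kappa)
    return dx


# ----------------------------------------------------------------- model


class PresnetModel:
    """Parameter container with forward/backward passes.

    Parameters live in ``self.params`` (name -> float64 array); the p-ReLU
    slopes are the 0-d arrays ``j_stem`` and ``j_block{i}``.
    """

    def __init__(self, config: PresnetConfig, input_dim: int):
        if input_dim < config.kappa:
            raise ValueError(
                f"input_dim={input_dim} is smaller than the pooling footprint "
                f"kappa={config.kappa}"
            )
        self.config = config
        self.input_dim = int(input_dim)
        rng = np.random.default_rng(config.seed)
        width = config.width
        p: dict[str, np.ndarray] = {}
        p["w_stem"] = rng.normal(0.0, np.sqrt(2.0 / 3.0), (width, 1, 3))
        p["b_stem"] = np.zeros(width)
        p["j_stem"] = np.array(config.j_init)
        for i in range(config.n_blocks):
            std = np.sqrt(2.0 / (width * 3))
            p[f"w_a{i}"] = rng.normal(0.0, std, (width, width, 3))
            p[f"b_a{i}"] = np.zeros(width)
            p[f"j_block{i}"] = np.array(config.j_init)
            p[f"w_b{i}"] = rng.normal(0.0, std, (width, width, 3))
            p[f"b_b{i}"] = np.zeros(width)
        pooled = input_dim // config.kappa
        if pooled < 1:
            raise ValueError("pooling footprint leaves no features")
        p["w_fc"] = rng.normal(0.0, np.sqrt(2.0 / (width * pooled)), (2, width * pooled))
        p["b_fc"] = np.zeros(2)
        self.params = p

    # -- forward ----------------------------------------------------------

    def forward(self, x: np.ndarray, cache: dict | None = None) -> np.ndarray:
        """Logits for x of shape (n, input_dim)."""
        x = np.asarray(x, dtype=float)
        if x.ndim != 2 or x.shape[1] != self.input_dim:
            raise ValueError(f"expected (n, {self.input_dim}) input, got {x.shape}")
        p = self.params
        h = x[:, None, :]
        if cache is not None:
            cache["x0"] = h
        z = _conv1d(h, p["w_stem"], p["b_stem"])
        if cache is not None:
            cache["z_stem"] = z
        h = _prelu_forward(z, float(p["j_stem"]))
        for i in range(self.config.n_blocks):
            if cache is not None:
                cache[f"in{i}"] = h
            za = _conv1d(h, p[f"w_a{i}"], p[f"b_a{i}"])
            ha = _prelu_forward(za, float(p[f"j_block{i}"]))
            zb = _conv1d(ha, p[f"w_b{i}"], p[f"b_b{i}"])
            if cache is not None:
                cache[f"za{i}"], cache[f"ha{i}"] = za, ha
            h = zb + h  # identity skip
        pooled, arg = _maxpool(h, self.config.kappa)
        if cache is not None:
            cache["pre_pool"], cache["arg"] = h, arg
        flat = pooled.reshape(pooled.shape[0], -1)
        if cache is not None:
            cache["flat"] = flat
        return flat @ p["w_fc"].T + p["b_fc"]

    # -- loss and gradients ----------------------------------------------

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray):
        """Mean cross-entropy loss and gradients for integer labels y."""
        cache: dict = {}
        logits = self.forward(x, cache)
        n = logits.shape[0]
        shifted = logits - logits.max(axis=1, keepdims=True)
        expv = np.exp(shifted)
        probs = expv / expv.sum(axis=1, keepdims=True)
        loss = float(-np.mean(np.log(probs[np.arange(n), y] + 1e-300)))

        p = self.params
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        grads["w_fc"] = dlogits.T @ cache["flat"]
        grads["b_fc"] = dlogits.sum(axis=0)
        dflat = dlogits @ p["w_fc"]
        npool = cache["pre_pool"].shape
        dpool = dflat.reshape(npool[0], npool[1], -1)
        dh = _maxpool_backward(dpool, npool, cache["arg"], self.config.kappa)
        for i in reversed(range(self.config.n_blocks)):
            dzb = dh  # skip branch passes dh through unchanged
            dha, dwb, dbb = _conv1d_backward(dzb, cache[f"ha{i}"], p[f"w_b{i}"])
            grads[f"w_b{i}"], grads[f"b_b{i}"] = dwb, dbb
            dza, dj = _prelu_backward(dha, cache[f"za{i}"], float(p[f"j_block{i}"]))
            grads[f"j_block{i}"] = np.array(dj)
            dxa, dwa, dba = _conv1d_backward(dza, cache[f"in{i}"], p[f"w_a{i}"])
            grads[f"w_a{i}"], grads[f"b_a{i}"] = dwa, dba
            dh = dxa + dh  # gradient through the identity skip
        dz, dj = _prelu_backward(dh, cache["z_stem"], float(p["j_stem"]))
        grads["j_stem"] = np.array(dj)
        _, dws, dbs = _conv1d_backward(dz, cache["x0"], p["w_stem"])
        grads["w_stem"], grads["b_stem"] = dws, dbs

        if self.config.weight_decay > 0:
            for k in p:
                if k.startswith("w_"):
                    loss += 0.5 * self.config.weight_decay * float(np.sum(p[k] ** 2))
                    grads[k] = grads[k] + self.config.weight_decay * p[k]
        if not self.config.learnable_j:
            for k in grads:
                if k.startswith("j_"):
                    grads[k] = np.zeros_like(grads[k])
        return loss, grads


def build_presnet(config: PresnetConfig | None = None, input_dim: int = 84) -> PresnetModel:
    """Construct a PResNet with seeded parameter initialisation."""
    return PresnetModel(config or PresnetConfig(), input_dim)


# --------------------------------------------------------------- training


def train(
    model: PresnetModel,
    features: np.ndarray,
    labels: np.ndarray,
    config: PresnetConfig | None = None,
) -> tuple[PresnetModel, dict]:
    """Adam training on (n, d) features with labels 0=Normal / 1=Abnormal.

    Fully seeded (shuffling comes from the config seed); history records
    per-epoch mean loss and training accuracy. A warm-started model (loaded
    from a checkpoint) is simply trained further — the transfer-learning
    hook. Raises on non-finite loss.
    """
    config = config or model.config
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if x.ndim != 2 or x.shape[0] != y.shape[0]:
        raise ValueError("features and labels disagree in length")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present for training")

    rng = np.random.default_rng(config.seed + 1)
    m_state = {k: np.zeros_like(v) for k, v in model.params.items()}
    v_state = {k: np.zeros_like(v) for k, v in model.params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    history = {"loss": [], "accuracy": []}
    n = x.shape[0]
    for _ in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start: start + config.batch_size]
            loss, grads = model.loss_and_grads(x[idx], y[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss ({loss}) at step {t}; "
                    "reduce the learning rate or rescale the features"
                )
            losses.append(loss)
            t += 1
            for k, g in grads.items():
                m_state[k] = beta1 * m_state[k] + (1 - beta1) * g
                v_state[k] = beta2 * v_state[k] + (1 - beta2) * g * g
                mhat = m_state[k] / (1 - beta1**t)
                vhat = v_state[k] / (1 - beta2**t)
                model.params[k] = model.params[k] - config.lr * mhat / (np.sqrt(vhat) + eps)
        preds = model.forward(x).argmax(axis=1)
        history["loss"].append(float(np.mean(losses)))
        history["accuracy"].append(float(np.mean(preds == y)))
    return model, history


# -------------------------------------------------------------- inference


def _softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=1, keepdims=True)
    expv = np.exp(shifted)
    return expv / expv.sum(axis=1, keepdims=True)


def predict(model: PresnetModel, feature_vector: np.ndarray) -> Prediction:
    """Classify one feature vector; risk_label is the 'none' placeholder
    (fill it with :func:`risk_screen`). Ties (score exactly 0.5) resolve to
    Normal."""
    v = np.asarray(feature_vector, dtype=float).ravel()
    if v.size != model.input_dim:
        raise ValueError(f"expected {model.input_dim} features, got {v.size}")
    probs = _softmax(model.forward(v[None, :]))[0]
    score = float(probs[1])
    label = "Abnormal" if score > 0.5 else "Normal"
    return Prediction(class_label=label, abnormal_score=score,
                      risk_label="none" if label == "Normal" else "low")


def predict_batch(model: PresnetModel, features: np.ndarray) -> list[Prediction]:
    """Vectorised :func:`predict` over rows of (n, d) features."""
    x = np.asarray(features, dtype=float)
    probs = _softmax(model.forward(x))
    out = []
    for score in probs[:, 1]:
        label = "Abnormal" if score > 0.5 else "Normal"
        out.append(Prediction(label, float(score), "none" if label == "Normal" else "low"))
    return out


def risk_screen(
    prediction: Prediction,
    feature_vector: np.ndarray,
    names: tuple[str, ...] | None = None,
    tau_risk: float = 8.0,
) -> Prediction:
    """Attach the high/low risk label to an Abnormal prediction.

    Normal predictions keep risk "none". For Abnormal ones, the quadrant
    with the largest candidate-lesion blob radius is the salient quadrant;
    risk is high when its on-rib flag is set or its blob radius reaches
    ``tau_risk`` (px), else low. Raises if the feature layout lacks the
    on-rib block.
    """
    if prediction.class_label == "Normal":
        return Prediction("Normal", prediction.abnormal_score, "none")
    v = np.asarray(feature_vector, dtype=float).ravel()
    names = tuple(names) if names is not None else tuple(feature_names())
    if v.size != len(names):
        raise ValueError("feature vector and name layout disagree")
    try:
        flags = [v[names.index(f"{q}_on_rib_flag")] for q in QUADRANT_TAGS]
        radii = [v[names.index(f"{q}_nodule_blob_radius")] for q in QUADRANT_TAGS]
    except ValueError as exc:
        raise ValueError("feature layout is missing the on-rib block") from exc
    q = int(np.argmax(radii))
    high = flags[q] >= 0.5 or radii[q] >= tau_risk
    return Prediction("Abnormal", prediction.abnormal_score, "high" if high else "low")


# ------------------------------------------------------------ persistence


def save_model(model: PresnetModel, path: str | Path) -> None:
    """Save parameters + config to an .npz checkpoint (exact float64)."""
    payload = dict(model.params)
    payload["__config__"] = np.frombuffer(
        json.dumps({"config": asdict(model.config), "input_dim": model.input_dim}).encode(),
        dtype=np.uint8,
    )
    np.savez(path, **payload)


def load_model(path: str | Path) -> PresnetModel:
    """Restore a checkpoint; predictions bit-match the saved model."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__config__"]).decode())
        model = PresnetModel(PresnetConfig(**meta["config"]), meta["input_dim"])
        for k in model.params:
            model.params[k] = data[k].copy()
    return model

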