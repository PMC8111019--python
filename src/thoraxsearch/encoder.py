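"""Two-step feature compressor: autoencoder pre-training, class-weighted
supervised fine-tuning, then encoder extraction; with a PCA baseline.

The compressor reduces a concatenated multi-view descriptor (3,072 values by
default) to a 256-value code for image search, in two steps:

* **Step 1 — unsupervised pre-training.** A symmetric autoencoder (decoder
  mirrors the encoder widths) is trained to reconstruct its input under mean
  squared error, Adam, batch size 128, 10 epochs, with inverted dropout
  (rate 0.2) after every non-final layer.

* **Step 2 — supervised fine-tuning.** The decoder is dropped and a single
  sigmoid unit is attached after the bottleneck (with dropout between code
  and head). The whole encoder plus head is trained with class-weighted
  binary cross-entropy, same optimiser settings. Class weights follow
  ``W_c = S / (C * S_c)`` (S samples, C classes, S_c per class), which makes
  every class contribute the same total loss mass ``S / C``.

After fine-tuning the head is removed; the remaining encoder is a pure
deterministic map (dropout inactive at inference) used to code both archive
and query descriptors.

The network is plain dense linear algebra implemented on NumPy: ReLU on
intermediate layers, a linear bottleneck (codes are unrestricted reals) and a
linear reconstruction output. The weights reached at the final epoch are
used; there is no early stopping. A seeded 10% validation split is held out
only to record a validation loss curve.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
from sklearn.decomposition import PCA

from .store import FeatureStore


# --------------------------------------------------------------------------
# specs and class weights

@dataclass(frozen=True)
class EncoderSpec:
    """Architecture and training parameters of the compressor.

    ``layer_widths`` runs from the input dimension down to the bottleneck and
    must be strictly decreasing; the decoder mirrors it. ``hidden_activation``
    applies to intermediate layers only (the bottleneck and the decoder
    output are linear); ``"linear"`` yields a fully linear autoencoder, whose
    optimum coincides with PCA at the same bottleneck.
    """

    layer_widths: tuple[int, ...] = (3072, 1024, 512, 256)
    dropout_rate: float = 0.2
    epochs: int = 10
    batch_size: int = 128
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    hidden_activation: str = "relu"
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        w = tuple(int(v) for v in self.layer_widths)
        object.__setattr__(self, "layer_widths", w)
        if len(w) < 2:
            raise ValueError("layer_widths needs at least input and bottleneck")
        if any(a <= b for a, b in zip(w, w[1:])):
            raise ValueError("layer_widths must be strictly decreasing")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.hidden_activation not in ("relu", "linear"):
            raise ValueError("hidden_activation must be 'relu' or 'linear'")
        if not 0.0 <= self.val_fraction < 1.0:
            raise ValueError("val_fraction must lie in [0, 1)")

    @property
    def bottleneck(self) -> int:
        return self.layer_widths[-1]


@dataclass(frozen=True)
class ClassWeightTable:
    """Per-class loss multipliers ``W_c = S / (C * S_c)``.

    Conservation holds by construction: ``sum_c W_c * S_c = S`` exactly.
    """

    classes: tuple[int, ...]
    counts: tuple[int, ...]
    weights: tuple[float, ...]

    @property
    def total(self) -> int:
        return sum(self.counts)

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def weight_of(self, cls: int) -> float:
        return self.weights[self.classes.index(cls)]

    def sample_weights(self, labels: np.ndarray) -> np.ndarray:
        labels = np.asarray(labels)
        lut = dict(zip(self.classes, self.weights))
        unknown = set(np.unique(labels)) - set(self.classes)
        if unknown:
            raise ValueError(f"labels {sorted(unknown)} missing from weight table")
        return np.array([lut[int(v)] for v in labels], dtype=np.float64)


def compute_class_weights(counts, classes: Sequence[int] | None = None
                          ) -> ClassWeightTable:
    """Balanced class weights from per-class sample counts.

    ``counts`` may be a mapping class -> count or a sequence (classes then
    default to 0..C-1). Every count must be positive. Weights are computed in
    exact rational arithmetic before conversion to float.
    """
    if isinstance(counts, dict):
        classes = tuple(sorted(counts))
        cvals = tuple(int(counts[c]) for c in classes)
    else:
        cvals = tuple(int(v) for v in counts)
        classes = tuple(classes) if classes is not None else tuple(range(len(cvals)))
    if len(cvals) < 2:
        raise ValueError("need at least two classes")
    if any(v <= 0 for v in cvals):
        raise ValueError("every class count must be positive")
    s, c = sum(cvals), len(cvals)
    weights = tuple(float(Fraction(s, c * sc)) for sc in cvals)
    return ClassWeightTable(classes=classes, counts=cvals, weights=weights)


# --------------------------------------------------------------------------
# dense network plumbing

@dataclass
class _Dense:
    W: np.ndarray
    b: np.ndarray


def _init_layer(rng: np.random.Generator, n_in: int, n_out: int) -> _Dense:
    # He-style scaling; adequate for both relu and linear stacks here
    w = rng.standard_normal((n_in, n_out)).astype(np.float32)
    return _Dense(W=w * np.float32(np.sqrt(2.0 / n_in)),
                  b=np.zeros(n_out, dtype=np.float32))


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2 ** self.t) / (1 - self.b1 ** self.t)
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)


def _relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


@dataclass
class EncoderModel:
    """Encoder (and, depending on phase, decoder or sigmoid head) weights."""

    spec: EncoderSpec
    enc: list[_Dense]
    dec: list[_Dense] | None
    head: _Dense | None
    phase: str  # pretrained | finetuned | encoder_only
    history: list[dict] = field(default_factory=list)

    @property
    def bottleneck(self) -> int:
        return self.spec.bottleneck

    def encode(self, x: np.ndarray) -> np.ndarray:
        """Deterministic code: dropout is inactive at inference."""
        a = np.asarray(x, dtype=np.float32)
        if a.ndim != 2 or a.shape[1] != self.spec.layer_widths[0]:
            raise ValueError(
                f"expected (n, {self.spec.layer_widths[0]}) input, got {a.shape}")
        hidden_relu = self.spec.hidden_activation == "relu"
        for i, layer in enumerate(self.enc):
            a = a @ layer.W + layer.b
            if hidden_relu and i < len(self.enc) - 1:  # bottleneck stays linear
                a = _relu(a)
        return a

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        if self.dec is None:
            raise ValueError("model has no decoder (phase %r)" % self.phase)
        a = self.encode(x)
        hidden_relu = self.spec.hidden_activation == "relu"
        for i, layer in enumerate(self.dec):
            a = a @ layer.W + layer.b
            if hidden_relu and i < len(self.dec) - 1:  # output stays linear
                a = _relu(a)
        return a

    def head_scores(self, x: np.ndarray) -> np.ndarray:
        if self.head is None:
            raise ValueError("model has no classification head")
        z = self.encode(x) @ self.head.W + self.head.b
        return 1.0 / (1.0 + np.exp(-z[:, 0]))


def _as_matrix(features) -> np.ndarray:
    x = features.features if isinstance(features, FeatureStore) else features
    return np.asarray(x, dtype=np.float32)


def _forward_train(layers: list[_Dense], relu_mask: list[bool],
                   drop_mask_on: list[bool], x: np.ndarray, rate: float,
                   rng: np.random.Generator):
    """Forward pass with inverted dropout; returns output and per-layer caches
    (input, pre-activation, dropout mask)."""
    a = x
    caches = []
    for layer, use_relu, use_drop in zip(layers, relu_mask, drop_mask_on):
        z = a @ layer.W + layer.b
        h = _relu(z) if use_relu else z
        mask = None
        if use_drop and rate > 0.0:
            mask = (rng.random(h.shape, dtype=np.float32) >= rate).astype(
                np.float32) / np.float32(1.0 - rate)
            h = h * mask
        caches.append((a, z, mask))
        a = h
    return a, caches


def _backward(layers: list[_Dense], relu_mask: list[bool], caches,
              delta: np.ndarray, delta_is_preact_last: bool = False):
    """Backpropagate ``delta`` (dL/d output, or dL/d pre-activation of the
    last layer when flagged); returns grads aligned with layers."""
    grads: list[tuple[np.ndarray, np.ndarray]] = [None] * len(layers)  # type: ignore
    for i in range(len(layers) - 1, -1, -1):
        a_prev, z, mask = caches[i]
        if i == len(layers) - 1 and delta_is_preact_last:
            dz = delta
        else:
            if mask is not None:
                delta = delta * mask
            dz = delta * (z > 0) if relu_mask[i] else delta
        grads[i] = (a_prev.T @ dz, dz.sum(axis=0))
        if i > 0:
            delta = dz @ layers[i].W.T
    return grads


def _val_split(n: int, fraction: float, rng: np.random.Generator):
    n_val = int(round(n * fraction))
    if n - n_val < 1:
        n_val = 0
    perm = rng.permutation(n)
    return perm[n_val:], perm[:n_val]


# --------------------------------------------------------------------------
# step 1: unsupervised pre-training

def pretrain_autoencoder(features, spec: EncoderSpec) -> EncoderModel:
    """Train the symmetric autoencoder to reconstruct its input (MSE, Adam).

    Records per-epoch training and validation loss; the weights after the
    final epoch are kept.
    """
    x = _as_matrix(features)
    if x.ndim != 2 or x.shape[1] != spec.layer_widths[0]:
        raise ValueError(f"store dimension {x.shape[1] if x.ndim == 2 else '?'} "
                         f"does not match spec input {spec.layer_widths[0]}")
    if x.shape[0] < 2:
        raise ValueError("need at least 2 samples to pretrain")

    init_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    widths = spec.layer_widths
    enc = [_init_layer(init_rng, a, b) for a, b in zip(widths, widths[1:])]
    dec_widths = widths[::-1]
    dec = [_init_layer(init_rng, a, b) for a, b in zip(dec_widths, dec_widths[1:])]
    model = EncoderModel(spec=spec, enc=enc, dec=dec, head=None,
                         phase="pretrained")

    layers = enc + dec
    n_enc, n_dec = len(enc), len(dec)
    relu_hidden = spec.hidden_activation == "relu"
    # intermediate layers relu; bottleneck (last enc) and output (last dec) linear
    relu_mask = [relu_hidden and i < n_enc - 1 for i in range(n_enc)] + \
                [relu_hidden and i < n_dec - 1 for i in range(n_dec)]
    drop_on = [True] * (len(layers) - 1) + [False]  # no dropout after output

    params = [p for layer in layers for p in (layer.W, layer.b)]
    opt = _Adam(params, spec.learning_rate)
    run_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    train_idx, val_idx = _val_split(x.shape[0], spec.val_fraction, run_rng)
    x_train, x_val = x[train_idx], x[val_idx]

    for epoch in range(spec.epochs):
        order = run_rng.permutation(x_train.shape[0])
        losses, weights_n = [], []
        for start in range(0, len(order), spec.batch_size):
            xb = x_train[order[start:start + spec.batch_size]]
            out, caches = _forward_train(layers, relu_mask, drop_on, xb,
                                         spec.dropout_rate, run_rng)
            resid = out - xb
            loss = float(np.mean(resid ** 2))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite reconstruction loss at epoch {epoch + 1}")
            delta = (2.0 / resid.size) * resid
            grads = _backward(layers, relu_mask, caches, delta)
            opt.step(params, [g for pair in grads for g in pair])
            losses.append(loss)
            weights_n.append(xb.shape[0])
        train_loss = float(np.average(losses, weights=weights_n))
        val_loss = (float(np.mean((model.reconstruct(x_val) - x_val) ** 2))
                    if len(x_val) else float("nan"))
        model.history.append({"phase": "pretrain", "epoch": epoch + 1,
                              "train_loss": train_loss, "val_loss": val_loss})
    return model


# --------------------------------------------------------------------------
# step 2: supervised fine-tuning

def finetune_with_labels(model: EncoderModel, features, labels,
                         weights: ClassWeightTable | None = None,
                         spec: EncoderSpec | None = None) -> EncoderModel:
    """Drop the decoder, attach a 1-unit sigmoid head, and fine-tune the whole
    encoder with class-weighted binary cross-entropy.

    Returns a new model (``phase="finetuned"``); the input model is untouched.
    Class weights default to the balanced formula on the given labels.
    """
    if model.phase != "pretrained":
        raise ValueError(f"fine-tuning requires a pretrained model, got phase "
                         f"{model.phase!r}")
    spec = spec or model.spec
    x = _as_matrix(features)
    y = np.asarray(labels).astype(np.float32)
    uniq = set(np.unique(y).tolist())
    if not uniq <= {0.0, 1.0} or len(uniq) != 2:
        raise ValueError("fine-tuning needs binary 0/1 labels with both classes")
    if x.shape[0] != y.shape[0]:
        raise ValueError("features and labels length mismatch")
    if weights is None:
        weights = compute_class_weights(
            {0: int((y == 0).sum()), 1: int((y == 1).sum())})
    sw_all = weights.sample_weights(y.astype(int))

    new = EncoderModel(spec=spec, enc=copy.deepcopy(model.enc), dec=None,
                       head=None, phase="finetuned",
                       history=list(model.history))
    init_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    new.head = _init_layer(init_rng, spec.bottleneck, 1)

    layers = new.enc + [new.head]
    n_enc = len(new.enc)
    relu_hidden = spec.hidden_activation == "relu"
    relu_mask = [relu_hidden and i < n_enc - 1 for i in range(n_enc)] + [False]
    drop_on = [True] * n_enc + [False]  # incl. dropout between code and head

    params = [p for layer in layers for p in (layer.W, layer.b)]
    opt = _Adam(params, spec.learning_rate)
    run_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 3]))
    train_idx, val_idx = _val_split(x.shape[0], spec.val_fraction, run_rng)
    eps = np.float32(1e-7)

    def _bce(xs, ys, ws) -> float:
        p = np.clip(new.head_scores(xs), eps, 1 - eps)
        return float(np.mean(ws * -(ys * np.log(p) + (1 - ys) * np.log(1 - p))))

    for epoch in range(spec.epochs):
        order = run_rng.permutation(len(train_idx))
        losses, weights_n = [], []
        for start in range(0, len(order), spec.batch_size):
            sel = train_idx[order[start:start + spec.batch_size]]
            xb, yb, wb = x[sel], y[sel], sw_all[sel]
            zout, caches = _forward_train(layers, relu_mask, drop_on, xb,
                                          spec.dropout_rate, run_rng)
            p = 1.0 / (1.0 + np.exp(-zout[:, 0]))
            pc = np.clip(p, eps, 1 - eps)
            loss = float(np.mean(
                wb * -(yb * np.log(pc) + (1 - yb) * np.log(1 - pc))))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite cross-entropy at epoch {epoch + 1}")
            # d(BCE)/dz of the sigmoid head, weighted, mean over batch
            dz = (wb * (p - yb) / xb.shape[0]).astype(np.float32)[:, None]
            grads = _backward(layers, relu_mask, caches, dz,
                              delta_is_preact_last=True)
            opt.step(params, [g for pair in grads for g in pair])
            losses.append(loss)
            weights_n.append(xb.shape[0])
        train_loss = float(np.average(losses, weights=weights_n))
        val_loss = (_bce(x[val_idx], y[val_idx], sw_all[val_idx])
                    if len(val_idx) else float("nan"))
        new.history.append({"phase": "finetune", "epoch": epoch + 1,
                            "train_loss": train_loss, "val_loss": val_loss})
    return new


def strip_head(model: EncoderModel) -> EncoderModel:
    """Remove the sigmoid head, leaving the bare deterministic encoder."""
    if model.phase != "finetuned":
        raise ValueError(f"strip_head requires phase 'finetuned', got "
                         f"{model.phase!r}")
    return EncoderModel(spec=model.spec, enc=copy.deepcopy(model.enc),
                        dec=None, head=None, phase="encoder_only",
                        history=list(model.history))


def train_encoder(features, labels, spec: EncoderSpec,
                  weights: ClassWeightTable | None = None) -> EncoderModel:
    """Convenience: pretrain, fine-tune, strip — the full two-step recipe."""
    model = pretrain_autoencoder(features, spec)
    model = finetune_with_labels(model, features, labels, weights, spec)
    return strip_head(model)


def encode_store(encoder: EncoderModel, features: FeatureStore) -> FeatureStore:
    """Code a whole store, preserving ids, labels and row order."""
    if encoder.phase != "encoder_only":
        raise ValueError("encode_store requires an encoder_only model")
    codes = encoder.encode(features.features) if len(features) else \
        np.zeros((0, encoder.bottleneck), dtype=np.float32)
    return FeatureStore(features=codes, ids=features.ids, labels=features.labels,
                        config="codes", backbone=features.backbone,
                        descriptor_length=encoder.bottleneck)


# --------------------------------------------------------------------------
# PCA baseline

@dataclass
class PcaProjection:
    """Mean-centred orthogonal projection onto the top principal axes."""

    mean: np.ndarray
    components: np.ndarray  # (dim_out, dim_in)

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=np.float32) - self.mean) @ self.components.T


def pca_compress(features: FeatureStore, dim: int,
                 seed: int = 0) -> tuple[PcaProjection, FeatureStore]:
    """Fit PCA on the store and return (projection, coded store)."""
    x = features.features
    max_dim = min(len(features) - 1, features.dim)
    if not 1 <= dim <= max_dim:
        raise ValueError(f"dim must lie in [1, {max_dim}], got {dim}")
    pca = PCA(n_components=dim, random_state=seed)
    codes = pca.fit_transform(x).astype(np.float32)
    proj = PcaProjection(mean=pca.mean_.astype(np.float32),
                         components=pca.components_.astype(np.float32))
    return proj, FeatureStore(features=codes, ids=features.ids,
                              labels=features.labels, config="codes",
                              backbone=f"{features.backbone}+pca{dim}",
                              descriptor_length=dim)


# --------------------------------------------------------------------------
# serialization

def save_encoder(model: EncoderModel, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["phase"] = model.phase
        f.attrs["layer_widths"] = np.asarray(model.spec.layer_widths)
        f.attrs["dropout_rate"] = model.spec.dropout_rate
        f.attrs["epochs"] = model.spec.epochs
        f.attrs["batch_size"] = model.spec.batch_size
        f.attrs["learning_rate"] = model.spec.learning_rate
        f.attrs["hidden_activation"] = model.spec.hidden_activation
        f.attrs["val_fraction"] = model.spec.val_fraction
        f.attrs["seed"] = model.spec.seed
        for tag, stack in (("enc", model.enc), ("dec", model.dec or []),
                           ("head", [model.head] if model.head else [])):
            for i, layer in enumerate(stack):
                f.create_dataset(f"{tag}/{i}/W", data=layer.W)
                f.create_dataset(f"{tag}/{i}/b", data=layer.b)
        if model.history:
            keys = ("train_loss", "val_loss")
            f.create_dataset("history/phase", data=np.array(
                [h["phase"] for h in model.history], dtype=object),
                dtype=h5py.string_dtype())
            f.create_dataset("history/epoch", data=np.array(
                [h["epoch"] for h in model.history]))
            for k in keys:
                f.create_dataset(f"history/{k}", data=np.array(
                    [h[k] for h in model.history]))


def load_encoder(path: str | Path) -> EncoderModel:
    with h5py.File(path, "r") as f:
        spec = EncoderSpec(
            layer_widths=tuple(int(v) for v in f.attrs["layer_widths"]),
            dropout_rate=float(f.attrs["dropout_rate"]),
            epochs=int(f.attrs["epochs"]),
            batch_size=int(f.attrs["batch_size"]),
            learning_rate=float(f.attrs["learning_rate"]),
            hidden_activation=str(f.attrs["hidden_activation"]),
            val_fraction=float(f.attrs["val_fraction"]),
            seed=int(f.attrs["seed"]),
        )

        def _stack(tag: str) -> list[_Dense]:
            if tag not in f:
                return []
            idx = sorted(int(i) for i in f[tag])
            return [_Dense(W=f[f"{tag}/{i}/W"][...], b=f[f"{tag}/{i}/b"][...])
                    for i in idx]

        enc, dec, head = _stack("enc"), _stack("dec"), _stack("head")
        history = []
        if "history" in f:
            phases = f["history/phase"].asstr()[...]
            epochs = f["history/epoch"][...]
            tl = f["history/train_loss"][...]
            vl = f["history/val_loss"][...]
            history = [{"phase": p, "epoch": int(e), "train_loss": float(t),
                        "val_loss": float(v)}
                       for p, e, t, v in zip(phases, epochs, tl, vl)]
        return EncoderModel(spec=spec, enc=enc, dec=dec or None,
                            head=head[0] if head else None,
                            phase=str(f.attrs["phase"]), history=history)
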