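"""Descriptor extraction: tag every image with a fixed-length deep feature.

The extractor is a frozen, pluggable backbone mapping a 224 x 224 x 3 image to
a constant-length real vector (1,024 by convention, the global-average-pooled
final convolutional output of a DenseNet-121-class network). The pipeline
never trains the backbone, so any deterministic callable satisfying
:class:`Backbone` plugs in.

Three view configurations build the per-image descriptor:

* config 1 — the whole radiograph: one 1,024-d vector;
* config 2 — left half and flipped right half: ``[left, right_flipped]``,
  2,048 values;
* config 3 — both halves plus the whole image:
  ``[left, right_flipped, whole]``, 3,072 values.

The default :class:`StubBackbone` is pure arithmetic — per-channel mean
pooling over 32 x 32 blocks followed by a fixed seeded Gaussian projection —
so every downstream stage is exactly reproducible without pretrained weights.
Raw descriptors are stored unnormalised; matching is plain Euclidean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Protocol, runtime_checkable

import numpy as np

from .store import FeatureStore
from .views import INPUT_SIDE, ImageRecord, ViewSet, make_views

#: segment order per configuration, fixed and part of the store contract
CONFIG_VIEW_ORDER = {
    1: ("whole",),
    2: ("left", "right_flipped"),
    3: ("left", "right_flipped", "whole"),
}


@runtime_checkable
class Backbone(Protocol):
    """Frozen feature extractor contract: deterministic, constant length."""

    name: str
    descriptor_length: int

    def apply(self, image: np.ndarray) -> np.ndarray:
        """Map one (side, side, 3) image in [0, 1] to a descriptor vector."""
        ...


@dataclass
class StubBackbone:
    """Deterministic arithmetic backbone for weight-free pipelines.

    Per-channel mean pooling over ``block x block`` tiles (7 x 7 x 3 = 147
    values at the 224 input side), flattened and passed through a fixed
    Gaussian projection seeded once at construction. Pure linear algebra:
    identical across runs and platforms.
    """

    descriptor_length: int = 1024
    block: int = 32
    seed: int = 0
    name: str = field(init=False)
    _projection: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.name = f"stub-{self.block}x{self.block}-{self.descriptor_length}"
        tiles = (INPUT_SIDE // self.block) ** 2 * 3
        rng = np.random.default_rng(np.random.SeedSequence([self.seed]))
        self._projection = rng.standard_normal(
            (tiles, self.descriptor_length)).astype(np.float32) / np.sqrt(tiles)

    def pool(self, image: np.ndarray) -> np.ndarray:
        """Per-channel block means, shape (side/block, side/block, 3)."""
        s, b = image.shape[0], self.block
        if image.shape != (s, s, 3) or s % b:
            raise ValueError(f"expected (n*{b}, n*{b}, 3) image, got {image.shape}")
        t = s // b
        return image.reshape(t, b, t, b, 3).mean(axis=(1, 3))

    def apply(self, image: np.ndarray) -> np.ndarray:
        pooled = self.pool(np.asarray(image, dtype=np.float32))
        return pooled.reshape(-1) @ self._projection


@dataclass
class FeatureRecord:
    """One image's descriptor under one configuration."""

    id: str
    config: int
    vector: np.ndarray
    label: int


def extract_view_descriptor(view: np.ndarray, backbone: Backbone) -> np.ndarray:
    """Run one grayscale view through the backbone.

    The single channel is replicated to three (frozen classification
    backbones expect RGB); any backbone-specific input normalisation is owned
    by the backbone itself.
    """
    view = np.asarray(view, dtype=np.float32)
    if view.ndim != 2 or view.shape[0] != view.shape[1]:
        raise ValueError(f"view must be a square 2-d matrix, got {view.shape}")
    rgb = np.repeat(view[:, :, None], 3, axis=2)
    vec = np.asarray(backbone.apply(rgb), dtype=np.float32).reshape(-1)
    if vec.shape[0] != backbone.descriptor_length:
        raise ValueError(
            f"backbone {backbone.name} returned length {vec.shape[0]}, "
            f"declared {backbone.descriptor_length}")
    if not np.all(np.isfinite(vec)):
        raise ValueError(f"backbone {backbone.name} produced non-finite output")
    return vec


def build_feature(views: ViewSet, config: int, backbone: Backbone,
                  image_id: str = "", label: int = -1) -> FeatureRecord:
    """Concatenate view descriptors in the fixed per-configuration order."""
    if config not in CONFIG_VIEW_ORDER:
        raise ValueError(f"unknown configuration {config!r}; expected 1, 2 or 3")
    parts = [extract_view_descriptor(getattr(views, name), backbone)
             for name in CONFIG_VIEW_ORDER[config]]
    return FeatureRecord(id=image_id, config=config,
                         vector=np.concatenate(parts), label=label)


def tag_archive(images: Iterable, config: int, backbone: Backbone,
                skip_errors: bool = False) -> FeatureStore:
    """Tag a collection of images, producing one store row per image in order.

    ``images`` may be :class:`ImageRecord` or phantom records (anything with
    ``id``, ``pixels`` and ``label``). A failing image aborts with its id
    unless ``skip_errors`` is set, in which case it is dropped.
    """
    rows, ids, labels = [], [], []
    n_seen = 0
    for im in images:
        n_seen += 1
        try:
            rec = build_feature(make_views(im.pixels), config, backbone,
                                image_id=im.id, label=im.label)
        except Exception as exc:
            if skip_errors:
                continue
            raise RuntimeError(f"feature extraction failed for image "
                               f"{im.id!r}: {exc}") from exc
        rows.append(rec.vector)
        ids.append(rec.id)
        labels.append(rec.label)
    if n_seen == 0:
        raise ValueError("tag_archive needs a non-empty image collection")
    if not rows:
        raise ValueError("all images failed feature extraction")
    return FeatureStore(
        features=np.stack(rows), ids=np.array(ids), labels=np.array(labels),
        config=str(config), backbone=backbone.name,
        descriptor_length=backbone.descriptor_length)
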