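"""Synthetic fixtures: thorax phantom radiographs and Gaussian feature clusters.

The retrieval pipeline exploits two statistical facts about frontal chest
radiographs: a healthy thorax is approximately mirror-symmetric about the
mediastinum, and a pneumothorax breaks that symmetry on one side, typically as
a lucent pleural margin. The phantom generator makes both facts literally
true: negatives are built as functions of ``|x - cx|`` (hence exactly
symmetric before noise), and positives additionally carry a darkened pleural
crescent along the lateral lung edge on one randomly chosen side.

``generate_feature_clusters`` emulates the other end of the pipeline: long
concatenated deep-feature vectors whose class signal lives in a small
coordinate subspace, the regime a 256-d bottleneck is meant to preserve. The
two class means differ by a vector of norm ``separation`` supported on the
first ``informative_dim`` coordinates, with unit isotropic noise everywhere;
the Bayes-optimal AUC is the closed form ``Phi(separation / sqrt(2))``
(the projected scores of the two classes are unit-variance Gaussians whose
difference has variance 2).

All randomness is counter-based: image ``i`` draws from
``SeedSequence([seed, i])`` so output is reproducible under reordering.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .store import FeatureStore, LABEL_NEGATIVE, LABEL_POSITIVE


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic radiograph collection.

    positive_fraction defaults to the 6% pneumothorax prevalence typical of
    large public chest X-ray archives. lesion_contrast is the multiplicative
    darkening of the pleural crescent; lesion_width_frac its width as a
    fraction of the image side.
    """

    n_images: int
    image_side: int = 224
    positive_fraction: float = 0.06
    lesion_contrast: float = 0.5
    lesion_width_frac: float = 0.12
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_images < 2:
            raise ValueError("n_images must be >= 2")
        if not 0.0 < self.positive_fraction < 1.0:
            raise ValueError("positive_fraction must lie in (0, 1)")
        if not 0.0 < self.lesion_contrast <= 1.0:
            raise ValueError("lesion_contrast must lie in (0, 1]")
        if not 0.0 < self.lesion_width_frac <= 0.5:
            raise ValueError("lesion_width_frac must lie in (0, 0.5]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.image_side < 8:
            raise ValueError("image_side must be >= 8")


@dataclass
class PhantomImage:
    """One synthetic radiograph with its image-level label."""

    id: str
    pixels: np.ndarray  # (side, side) float32 in [0, 1]
    label: int  # LABEL_POSITIVE / LABEL_NEGATIVE
    lesion_side: str | None  # "left" | "right" | None


def _render_phantom(spec: PhantomSpec, lesion_side: str | None,
                    rng: np.random.Generator) -> np.ndarray:
    """Render one phantom. Everything except the lesion and the additive noise
    is a function of the folded coordinate |x - cx|, so the lesion-free,
    noise-free image equals its own horizontal mirror exactly."""
    s = spec.image_side
    y, x = np.mgrid[0:s, 0:s].astype(np.float32)
    cx = (s - 1) / 2.0
    dx = np.abs(x - cx) / s  # folded lateral coordinate, 0 at midline
    yn = y / s

    # per-image jitter (shared by both sides: symmetry is preserved)
    j_ax, j_ay, j_cy, j_gain = rng.uniform(-1.0, 1.0, size=4)
    lung_cx = 0.22
    lung_cy = 0.46 + 0.02 * j_cy
    lung_ax = 0.15 * (1.0 + 0.05 * j_ax)
    lung_ay = 0.30 * (1.0 + 0.05 * j_ay)

    img = np.full((s, s), 0.08, dtype=np.float32)
    body = (dx / 0.42) ** 2 + ((yn - 0.52) / 0.46) ** 2 <= 1.0
    img[body] = 0.30

    lung_e = ((dx - lung_cx) / lung_ax) ** 2 + ((yn - lung_cy) / lung_ay) ** 2
    lung = lung_e <= 1.0
    # rib-like sinusoidal banding inside the lung fields
    ribs = (0.80 * (1.0 + 0.08 * np.sin(2.0 * np.pi * yn / 0.08))).astype(np.float32)
    img[lung] = ribs[lung]

    img[dx <= 0.06] = 0.42  # mediastinal band straddling the midline

    img *= np.float32(1.0 + 0.03 * j_gain)
    np.clip(img, 0.0, 1.0, out=img)

    if lesion_side is not None:
        w = np.float32(spec.lesion_width_frac)
        in_ax = max(lung_ax - w, 1e-3)
        in_ay = max(lung_ay - w, 1e-3)
        inner = ((dx - lung_cx) / in_ax) ** 2 + ((yn - lung_cy) / in_ay) ** 2
        crescent = lung & (inner > 1.0) & (dx > lung_cx)
        side_mask = x > cx if lesion_side == "right" else x < cx
        lesion = crescent & side_mask
        img[lesion] *= np.float32(1.0 - spec.lesion_contrast)

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape).astype(np.float32)
        np.clip(img, 0.0, 1.0, out=img)
    return img.astype(np.float32)


def generate_phantoms(spec: PhantomSpec) -> list[PhantomImage]:
    """Generate ``spec.n_images`` labelled phantoms.

    Exactly ``round(n_images * positive_fraction)`` images are positive; which
    ones, and each positive's lesion side, are drawn from the seeded stream.
    """
    n = spec.n_images
    n_pos = int(round(n * spec.positive_fraction))
    master = np.random.default_rng(np.random.SeedSequence([spec.seed]))
    positive = np.zeros(n, dtype=bool)
    positive[master.permutation(n)[:n_pos]] = True

    out: list[PhantomImage] = []
    for i in range(n):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, i]))
        side = str(rng.choice(["left", "right"])) if positive[i] else None
        pixels = _render_phantom(spec, side, rng)
        out.append(PhantomImage(
            id=f"phantom-{i:05d}",
            pixels=pixels,
            label=LABEL_POSITIVE if positive[i] else LABEL_NEGATIVE,
            lesion_side=side,
        ))
    return out


def save_phantoms(images: list[PhantomImage], out_dir: str | Path,
                  seed: int | None = None) -> Path:
    """Write phantoms as 8-bit PNGs plus a manifest CSV; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for im in images:
        fname = f"{im.id}.png"
        arr = np.clip(np.round(im.pixels * 255.0), 0, 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(out_dir / fname)
        rows.append({
            "id": im.id,
            "filename": fname,
            "label": im.label,
            "side_of_lesion": im.lesion_side or "none",
            "seed": seed if seed is not None else "",
        })
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


@dataclass(frozen=True)
class FeatureSimSpec:
    """Two-class Gaussian feature collection with a low-dimensional signal."""

    n_samples: int
    dim: int = 3072
    informative_dim: int = 256
    separation: float = 6.0
    positive_fraction: float = 0.06
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.dim < 1 or self.informative_dim < 1:
            raise ValueError("dim and informative_dim must be positive")
        if self.informative_dim > self.dim:
            raise ValueError("informative_dim must not exceed dim")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        if not 0.0 < self.positive_fraction < 1.0:
            raise ValueError("positive_fraction must lie in (0, 1)")


def class_mean_shift(spec: FeatureSimSpec) -> np.ndarray:
    """The fixed between-class mean difference: norm ``separation``, supported
    on the first ``informative_dim`` coordinates (equal components)."""
    delta = np.zeros(spec.dim, dtype=np.float32)
    delta[: spec.informative_dim] = spec.separation / np.sqrt(spec.informative_dim)
    return delta


def generate_feature_clusters(spec: FeatureSimSpec) -> FeatureStore:
    """Sample the labelled two-class Gaussian collection as a FeatureStore."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed]))
    n = spec.n_samples
    n_pos = int(round(n * spec.positive_fraction))
    labels = np.zeros(n, dtype=np.int8)
    labels[rng.permutation(n)[:n_pos]] = LABEL_POSITIVE

    x = rng.standard_normal((n, spec.dim), dtype=np.float32)
    x[labels == LABEL_POSITIVE] += class_mean_shift(spec)
    ids = np.array([f"sim-{i:05d}" for i in range(n)])
    return FeatureStore(features=x, ids=ids, labels=labels,
                        config="sim", backbone="simulated",
                        descriptor_length=spec.dim)
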