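"""Feature stores: the archive container binding descriptors to ids and labels.

A :class:`FeatureStore` is a dense ``n x d`` float32 matrix plus aligned image
ids and binary labels, with metadata recording which view configuration and
backbone produced it. Stores persist to HDF5 (datasets ``/features``, ``/ids``,
``/labels``; attrs ``config``, ``backbone``, ``descriptor_length``) or, for
small collections, to a flat CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

#: image-level label codes
LABEL_POSITIVE = 1
LABEL_NEGATIVE = 0
LABEL_OTHER = -1

#: largest store exported to CSV (wider collections belong in HDF5)
CSV_MAX_ROWS = 10_000


@dataclass
class FeatureStore:
    """Aligned descriptors, ids and labels for one view configuration."""

    features: np.ndarray
    ids: np.ndarray
    labels: np.ndarray
    config: str = "1"
    backbone: str = "stub"
    descriptor_length: int | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float32)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-d (n, dim) matrix")
        self.ids = np.asarray(self.ids, dtype=str)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        n = self.features.shape[0]
        if len(self.ids) != n or len(self.labels) != n:
            raise ValueError(
                f"misaligned store: {n} feature rows, {len(self.ids)} ids, "
                f"{len(self.labels)} labels"
            )
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features contain non-finite entries")

    def __len__(self) -> int:
        return self.features.shape[0]

    @property
    def dim(self) -> int:
        return self.features.shape[1]

    def subset(self, index: np.ndarray) -> "FeatureStore":
        """Row subset (boolean mask or integer index), order-preserving."""
        return replace(
            self,
            features=self.features[index],
            ids=self.ids[index],
            labels=self.labels[index],
        )

    # ------------------------------------------------------------------ I/O

    def save_h5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("features", data=self.features)
            f.create_dataset("ids", data=self.ids.astype(object),
                             dtype=h5py.string_dtype())
            f.create_dataset("labels", data=self.labels.astype(np.int8))
            f.attrs["config"] = str(self.config)
            f.attrs["backbone"] = self.backbone
            if self.descriptor_length is not None:
                f.attrs["descriptor_length"] = int(self.descriptor_length)

    @classmethod
    def load_h5(cls, path: str | Path) -> "FeatureStore":
        with h5py.File(path, "r") as f:
            dl = f.attrs.get("descriptor_length")
            return cls(
                features=f["features"][...],
                ids=f["ids"].asstr()[...],
                labels=f["labels"][...],
                config=str(f.attrs.get("config", "1")),
                backbone=str(f.attrs.get("backbone", "stub")),
                descriptor_length=None if dl is None else int(dl),
            )

    def to_csv(self, path: str | Path) -> None:
        if len(self) > CSV_MAX_ROWS:
            raise ValueError(
                f"CSV export limited to {CSV_MAX_ROWS} rows; use save_h5"
            )
        df = pd.DataFrame(self.features,
                          columns=[f"f{j}" for j in range(self.dim)])
        df.insert(0, "label", self.labels)
        df.insert(0, "id", self.ids)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, config: str = "1",
                 backbone: str = "stub") -> "FeatureStore":
        df = pd.read_csv(path)
        feat_cols = [c for c in df.columns if c not in ("id", "label")]
        return cls(
            features=df[feat_cols].to_numpy(dtype=np.float32),
            ids=df["id"].astype(str).to_numpy(),
            labels=df["label"].to_numpy(),
            config=config,
            backbone=backbone,
        )

    def save(self, path: str | Path) -> None:
        """Dispatch on extension: ``.csv`` for flat text, anything else HDF5."""
        if str(path).endswith(".csv"):
            self.to_csv(path)
        else:
            self.save_h5(path)

    @classmethod
    def load(cls, path: str | Path) -> "FeatureStore":
        if str(path).endswith(".csv"):
            return cls.from_csv(path)
        return cls.load_h5(path)
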