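"""Manifest, report and configuration I/O.

Manifests are CSVs with at least ``id``, ``path`` (or ``filename``) and
``label`` columns; unknown columns are preserved on round-trip. Reports are
JSON stamped with the tool version and a hash of the configuration that
produced them, so any artifact can be traced back to its run.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import __version__
from .views import ImageRecord

MANIFEST_REQUIRED = ("id", "label")


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read and validate a manifest CSV; raises on schema violations."""
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"manifest {path} is empty")
    missing = [c for c in MANIFEST_REQUIRED if c not in df.columns]
    if "path" not in df.columns and "filename" not in df.columns:
        missing.append("path|filename")
    if missing:
        raise ValueError(f"manifest {path} missing columns: {missing}")
    dup = df["id"][df["id"].duplicated()].astype(str).tolist()
    if dup:
        raise ValueError(f"manifest {path} has duplicate ids: {sorted(set(dup))}")
    bad = df.index[~df["label"].isin([0, 1, -1])].tolist()
    if bad:
        raise ValueError(f"manifest {path} has non-binary labels at rows {bad}")
    return df


def load_images(manifest: pd.DataFrame, root: str | Path) -> list[ImageRecord]:
    """Load the grayscale images listed in a manifest as ImageRecords."""
    root = Path(root)
    col = "path" if "path" in manifest.columns else "filename"
    records = []
    for _, row in manifest.iterrows():
        arr = np.asarray(Image.open(root / str(row[col])).convert("L"),
                         dtype=np.float32) / 255.0
        records.append(ImageRecord(id=str(row["id"]), pixels=arr,
                                   label=int(row["label"]),
                                   source=str(row[col])))
    return records


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_report(path: str | Path, results: dict, config: dict) -> dict:
    """Write a version- and config-stamped JSON report; returns the payload."""
    payload = {
        "tool": "thoraxsearch",
        "version": __version__,
        "config": config,
        "config_hash": config_hash(config),
        "results": results,
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as f:
        json.dump(payload, f, indent=2, sort_keys=True)
        f.write("\n")
    return payload


def load_config(path: str | Path) -> dict:
    with open(path) as f:
        cfg = yaml.safe_load(f)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return cfg


def save_config(config: dict, path: str | Path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(config, f, sort_keys=True)
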