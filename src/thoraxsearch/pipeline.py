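"""End-to-end orchestration: simulate/load -> tag -> (compress) -> search -> CV.

A :class:`RunConfig` captures every knob of one experiment, including the
single seed that fans out (via named substreams) to phantom rendering, fold
assignment, encoder initialisation and PCA. Two runs with identical configs
produce identical reports.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

from .encoder import EncoderSpec
from .evaluate import run_cv
from .features import StubBackbone, tag_archive
from .io import load_images, read_manifest, write_report
from .phantoms import FeatureSimSpec, PhantomSpec, generate_feature_clusters, \
    generate_phantoms
from .store import FeatureStore


@dataclass(frozen=True)
class RunConfig:
    """One reproducible experiment.

    source: "phantoms" renders synthetic radiographs; "clusters" samples the
    Gaussian feature collection; "manifest"/"store" load user data.
    method: "raw" | "encoded" | "pca" (how archive codes are produced).
    feature_config: view configuration 1/2/3 for image sources.
    """

    source: str = "phantoms"
    method: str = "raw"
    feature_config: int = 3
    n_samples: int = 300
    ks: tuple[int, ...] = (11, 51)
    n_folds: int = 10
    seed: int = 0
    input_path: str | None = None  # manifest CSV or feature store
    phantom: dict = field(default_factory=dict)  # PhantomSpec overrides
    clusters: dict = field(default_factory=dict)  # FeatureSimSpec overrides
    encoder_widths: tuple[int, ...] | None = None
    encoder_epochs: int = 10
    encoder_batch_size: int = 128
    encoder_dropout: float = 0.2
    pca_dim: int = 256

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ks"] = list(self.ks)
        if self.encoder_widths is not None:
            d["encoder_widths"] = list(self.encoder_widths)
        return d


def build_store(config: RunConfig) -> FeatureStore:
    """Stage 1-2: obtain descriptors for the configured source."""
    if config.source == "clusters":
        spec = FeatureSimSpec(n_samples=config.n_samples, seed=config.seed,
                              **config.clusters)
        return generate_feature_clusters(spec)
    if config.source == "store":
        if not config.input_path or not Path(config.input_path).exists():
            raise FileNotFoundError(
                f"stage load-store: missing store {config.input_path!r}")
        return FeatureStore.load(config.input_path)
    backbone = StubBackbone(seed=config.seed)
    if config.source == "phantoms":
        spec = PhantomSpec(n_images=config.n_samples, seed=config.seed,
                           **config.phantom)
        images = generate_phantoms(spec)
    elif config.source == "manifest":
        if not config.input_path or not Path(config.input_path).exists():
            raise FileNotFoundError(
                f"stage read-manifest: missing manifest {config.input_path!r}")
        manifest = read_manifest(config.input_path)
        images = load_images(manifest, Path(config.input_path).parent)
    else:
        raise ValueError(f"unknown source {config.source!r}")
    return tag_archive(images, config.feature_config, backbone)


def run_pipeline(config: RunConfig, out: str | Path | None = None) -> dict:
    """Execute the full pipeline and return (optionally write) the report."""
    store = build_store(config)
    enc_spec = None
    if config.method == "encoded":
        widths = config.encoder_widths or _benchmark_widths(store.dim)
        enc_spec = EncoderSpec(layer_widths=widths,
                               epochs=config.encoder_epochs,
                               batch_size=config.encoder_batch_size,
                               dropout_rate=config.encoder_dropout,
                               seed=config.seed)
    reports = run_cv(store, mode=config.method, ks=config.ks,
                     n_folds=config.n_folds, seed=config.seed,
                     encoder_spec=enc_spec, pca_dim=config.pca_dim)
    results = {str(k): rep.to_dict() for k, rep in sorted(reports.items())}
    if out is not None:
        return write_report(out, results, config.to_dict())
    return {"results": results, "config": config.to_dict()}


def _benchmark_widths(dim: int) -> tuple[int, ...]:
    """Slim single-hidden-layer stack to a 256-d (or smaller) bottleneck."""
    bottleneck = min(256, max(2, dim // 4))
    mid = min(512, max(bottleneck * 2, dim // 2))
    return tuple(dict.fromkeys((dim, mid, bottleneck)))
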