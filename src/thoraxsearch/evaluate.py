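"""Evaluation: ROC/AUC, Youden operating point, tenfold CV, paired testing.

The vote likelihood ``m/k`` is a score on a coarse grid; the ROC curve is
built at every unique score (descending, plus a predict-none sentinel) under
the ``>=`` decision rule. AUC is the trapezoidal area over
(1 - specificity, sensitivity), identical to the Mann-Whitney concordance
probability with ties credited 1/2. The operating point maximises Youden's
J = sensitivity + specificity - 1, ties resolved toward the smallest
threshold (higher sensitivity).

Cross-validation mirrors the retrieval protocol: images are split into
stratified folds; each fold in turn is the query/validation set while the
remainder is the searchable archive. In ``encoded`` mode a fresh compressor
is trained per fold on that fold's archive only, then used to code both
sides, so no query information leaks into training.

``wilcoxon_paired`` is the two-sided Wilcoxon signed-rank test on paired
per-fold metrics: mid-ranks for tied absolute differences, zero differences
dropped, exact p by sign-assignment enumeration (dynamic programming) up to
n = 25 and a normal approximation with tie correction above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as _dc_replace

import numpy as np
from scipy.stats import norm as _norm
from scipy.stats import rankdata

from .encoder import EncoderSpec, compute_class_weights, encode_store, \
    pca_compress, train_encoder
from .search import build_index, knn_batch
from .store import FeatureStore

DEFAULT_K_GRID = (11, 51, 101, 251, 501, 1001)


# --------------------------------------------------------------------------
# ROC / Youden / confusion

@dataclass
class RocCurve:
    thresholds: np.ndarray  # descending; thresholds[0] is the +inf sentinel
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    youden_threshold: float
    youden_j: float


def roc(likelihoods, labels) -> RocCurve:
    """ROC over all unique score thresholds with the ``>=`` decision rule."""
    s = np.asarray(likelihoods, dtype=float)
    y = np.asarray(labels).astype(int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("likelihoods and labels must be equal-length vectors")
    pos, neg = int((y == 1).sum()), int((y == 0).sum())
    if pos == 0 or neg == 0:
        raise ValueError("ROC needs both classes present")

    uniq = np.unique(s)[::-1]  # descending
    # counts of positives/negatives at each unique score
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    boundaries = np.searchsorted(-s_sorted, -uniq, side="right")
    tp_cum = np.cumsum(y_sorted)
    tp = tp_cum[boundaries - 1]
    fp = boundaries - tp

    sens = np.concatenate([[0.0], tp / pos])
    fpr = np.concatenate([[0.0], fp / neg])
    thresholds = np.concatenate([[np.inf], uniq])
    spec = 1.0 - fpr

    auc = float(np.trapezoid(sens, fpr))
    j = sens + spec - 1.0
    # ties toward the smallest threshold (thresholds are descending)
    best = len(j) - 1 - int(np.argmax(j[::-1]))
    return RocCurve(thresholds=thresholds, sensitivity=sens, specificity=spec,
                    auc=auc, youden_threshold=float(thresholds[best]),
                    youden_j=float(j[best]))


def youden(curve: RocCurve) -> float:
    """The threshold maximising J = sensitivity + specificity - 1."""
    return curve.youden_threshold


def confusion(labels, predictions) -> dict[str, int]:
    """2x2 counts {tp, fp, fn, tn}."""
    y = np.asarray(labels).astype(int)
    p = np.asarray(predictions).astype(int)
    if y.shape != p.shape:
        raise ValueError("labels and predictions length mismatch")
    return {
        "tp": int(((y == 1) & (p == 1)).sum()),
        "fp": int(((y == 0) & (p == 1)).sum()),
        "fn": int(((y == 1) & (p == 0)).sum()),
        "tn": int(((y == 0) & (p == 0)).sum()),
    }


# --------------------------------------------------------------------------
# folds

@dataclass
class FoldAssignment:
    """Map of each item to exactly one validation fold (0-based)."""

    fold_of: np.ndarray  # fold index per item, aligned with ids
    ids: np.ndarray
    n_folds: int
    seed: int

    def validation_mask(self, fold: int) -> np.ndarray:
        return self.fold_of == fold


def make_folds(ids, n_folds: int = 10, seed: int = 0,
               labels=None) -> FoldAssignment:
    """Seeded near-equal partition, stratified by label when given.

    Each class is shuffled and dealt round-robin, the second class starting
    where the first stopped, so per-class and total fold sizes both differ by
    at most one.
    """
    ids = np.asarray(ids, dtype=str)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if len(np.unique(ids)) != len(ids):
        raise ValueError("ids must be distinct")
    if len(ids) < n_folds:
        raise ValueError(f"{len(ids)} ids cannot fill {n_folds} folds")
    rng = np.random.default_rng(np.random.SeedSequence([seed]))
    fold_of = np.empty(len(ids), dtype=np.int64)
    groups = ([np.arange(len(ids))] if labels is None else
              [np.flatnonzero(np.asarray(labels) == v)
               for v in np.unique(labels)])
    cursor = 0
    for g in groups:
        g = rng.permutation(g)
        fold_of[g] = (cursor + np.arange(len(g))) % n_folds
        cursor = (cursor + len(g)) % n_folds
    return FoldAssignment(fold_of=fold_of, ids=ids, n_folds=n_folds, seed=seed)


# --------------------------------------------------------------------------
# cross-validated retrieval evaluation

@dataclass
class EvalReport:
    """Per-fold retrieval-classifier metrics for one (mode, k) setting."""

    mode: str
    k: int
    fold_sensitivity: list[float] = field(default_factory=list)
    fold_specificity: list[float] = field(default_factory=list)
    fold_auc: list[float] = field(default_factory=list)
    confusion: dict[str, int] = field(
        default_factory=lambda: {"tp": 0, "fp": 0, "fn": 0, "tn": 0})

    @property
    def mean_sensitivity(self) -> float:
        return float(np.mean(self.fold_sensitivity))

    @property
    def mean_specificity(self) -> float:
        return float(np.mean(self.fold_specificity))

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_auc))

    def to_dict(self) -> dict:
        sd = lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
        return {
            "mode": self.mode, "k": self.k,
            "n_folds": len(self.fold_auc),
            "sensitivity": self.mean_sensitivity,
            "specificity": self.mean_specificity,
            "auc": self.mean_auc,
            "sd_sensitivity": sd(self.fold_sensitivity),
            "sd_specificity": sd(self.fold_specificity),
            "sd_auc": sd(self.fold_auc),
            "fold_sensitivity": list(self.fold_sensitivity),
            "fold_specificity": list(self.fold_specificity),
            "fold_auc": list(self.fold_auc),
            "confusion": dict(self.confusion),
        }


def _default_encoder_spec(dim: int, seed: int) -> EncoderSpec:
    bottleneck = min(256, max(2, dim // 4))
    mid = min(512, max(bottleneck * 2, dim // 2))
    widths = tuple(dict.fromkeys((dim, mid, bottleneck)))  # dedupe, keep order
    if len(widths) < 2:
        widths = (dim, max(dim // 2, 1))
    return EncoderSpec(layer_widths=widths, seed=seed)


def run_cv(store: FeatureStore, mode: str = "raw", ks=(11, 51),
           n_folds: int = 10, seed: int = 0,
           encoder_spec: EncoderSpec | None = None,
           pca_dim: int = 256) -> dict[int, EvalReport]:
    """Cross-validated image-search classification.

    modes: ``raw`` searches the stored descriptors directly; ``encoded``
    trains the two-step compressor per fold on the archive portion and
    searches the codes; ``pca`` does the same with a PCA projection.
    Per fold and per k: vote likelihoods for every validation query, the
    fold ROC, and sensitivity/specificity at that fold's Youden threshold.
    Returns one report per k. Folds, encoder init and PCA all derive from
    ``seed``.
    """
    if mode not in ("raw", "encoded", "pca"):
        raise ValueError(f"unknown mode {mode!r}")
    ks = sorted(set(int(k) for k in ks))
    if ks[0] < 1:
        raise ValueError("k must be >= 1")
    y = store.labels
    if set(np.unique(y).tolist()) != {0, 1}:
        raise ValueError("evaluation needs binary 0/1 labels with both classes")

    folds = make_folds(store.ids, n_folds=n_folds, seed=seed, labels=y)
    reports = {k: EvalReport(mode=mode, k=k) for k in ks}

    for fold in range(n_folds):
        val_mask = folds.validation_mask(fold)
        archive, queries = store.subset(~val_mask), store.subset(val_mask)
        ya, yq = archive.labels, queries.labels
        if len(set(ya.tolist())) < 2 or len(set(yq.tolist())) < 2:
            raise ValueError(f"fold {fold} is missing a class; "
                             "use stratified folds with enough positives")

        fold_seed = int(np.random.SeedSequence([seed, fold]).generate_state(1)[0]
                        % (2 ** 31))
        if mode == "encoded":
            spec = (_dc_replace(encoder_spec, seed=fold_seed)
                    if encoder_spec is not None
                    else _default_encoder_spec(store.dim, fold_seed))
            weights = compute_class_weights(
                {0: int((ya == 0).sum()), 1: int((ya == 1).sum())})
            enc = train_encoder(archive.features, ya, spec, weights)
            arch_codes = encode_store(enc, archive)
            query_codes = enc.encode(queries.features)
        elif mode == "pca":
            proj, arch_codes = pca_compress(archive, min(pca_dim, len(archive) - 1,
                                                         archive.dim),
                                            seed=fold_seed)
            query_codes = proj.transform(queries.features)
        else:
            arch_codes, query_codes = archive, queries.features

        index = build_index(arch_codes)
        _, order = knn_batch(index, query_codes, max(ks))
        hit_labels = (index.labels[order] == 1)

        for k in ks:
            k_eff = min(k, index.n)
            lik = hit_labels[:, :k_eff].mean(axis=1)
            curve = roc(lik, yq)
            thr = curve.youden_threshold
            preds = (lik >= thr).astype(int)
            cm = confusion(yq, preds)
            rep = reports[k]
            rep.fold_auc.append(curve.auc)
            rep.fold_sensitivity.append(cm["tp"] / (cm["tp"] + cm["fn"]))
            rep.fold_specificity.append(cm["tn"] / (cm["tn"] + cm["fp"]))
            for key in cm:
                rep.confusion[key] += cm[key]
    return reports


# --------------------------------------------------------------------------
# paired significance testing

def wilcoxon_paired(per_fold_a, per_fold_b) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired per-fold metrics.

    Returns ``(statistic, p)`` with statistic ``min(W+, W-)``. Zero
    differences are dropped; tied absolute differences get mid-ranks. The
    p-value is exact (enumeration over sign assignments) for up to 25
    nonzero differences, normal approximation with tie correction beyond.
    """
    a = np.asarray(per_fold_a, dtype=float)
    b = np.asarray(per_fold_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length vectors")
    if len(a) < 5:
        raise ValueError("need at least 5 pairs")
    d = a - b
    d = d[d != 0.0]
    if len(d) == 0:
        raise ValueError("all paired differences are zero")
    n = len(d)
    r = rankdata(np.abs(d))  # mid-ranks for ties
    w_pos = float(r[d > 0].sum())
    w_neg = float(r[d < 0].sum())
    stat = min(w_pos, w_neg)

    if n <= 25:
        # distribution of 2*W+ over all 2^n sign assignments (doubled ranks
        # are integers even with .5 mid-ranks)
        r2 = np.rint(2 * r).astype(int)
        total = int(r2.sum())
        counts = np.zeros(total + 1, dtype=float)
        counts[0] = 1.0
        for ri in r2:
            counts[ri:] += counts[: counts.size - ri].copy()
        lo = int(round(2 * stat))
        hi = total - lo
        p = (counts[: lo + 1].sum() + counts[hi:].sum()) / (2.0 ** n)
        if lo >= hi:  # the two tails overlap
            p = 1.0
        return stat, float(min(p, 1.0))

    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(r, return_counts=True)
    tie_corr = float(((tie_counts ** 3 - tie_counts) / 48.0).sum())
    sigma = math.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_corr)
    z = (w_pos - mu) / sigma
    return stat, float(min(1.0, 2.0 * _norm.sf(abs(z))))
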