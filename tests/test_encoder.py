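"""Compressor: class weights (exact arithmetic), the two training phases,
phase contracts, encoder determinism, and the PCA baseline/optimum."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from thoraxsearch import (EncoderSpec, FeatureSimSpec, FeatureStore,
                          compute_class_weights, encode_store,
                          finetune_with_labels, generate_feature_clusters,
                          pca_compress, pretrain_autoencoder, strip_head,
                          train_encoder)
from thoraxsearch.encoder import load_encoder, save_encoder


class TestClassWeights:
    def test_balanced_classes_get_unit_weights(self):
        t = compute_class_weights({0: 50, 1: 50})
        assert t.weights == (1.0, 1.0)

    def test_imbalanced_example(self):
        t = compute_class_weights({0: 20, 1: 100})
        assert t.weights == (3.0, 0.6)

    def test_archive_scale_counts(self):
        # 6%-prevalence archive: 34,605 positives vs 516,778 negatives
        t = compute_class_weights({1: 34_605, 0: 516_778})
        assert t.weight_of(1) == pytest.approx(float(Fraction(551_383, 69_210)),
                                               abs=1e-12)
        assert t.weight_of(0) == pytest.approx(float(Fraction(551_383, 1_033_556)),
                                               abs=1e-12)

    @given(st.lists(st.integers(min_value=1, max_value=10 ** 6),
                    min_size=2, max_size=6))
    def test_conservation_sum_wc_sc_equals_s(self, counts):
        # exact in rationals: sum_c W_c * S_c = S
        s, c = sum(counts), len(counts)
        exact = sum(Fraction(s, c * sc) * sc for sc in counts)
        assert exact == s
        t = compute_class_weights(counts)
        assert sum(w * n for w, n in zip(t.weights, t.counts)) == \
            pytest.approx(s, rel=1e-9)

    def test_per_class_total_loss_mass_equal(self):
        # an 83%/17% split with weights {0.6, 3.0}: each class sums to S/C
        labels = np.array([0] * 100 + [1] * 20)
        t = compute_class_weights({0: 100, 1: 20})
        sw = t.sample_weights(labels)
        assert abs(sw[labels == 0].sum() - sw[labels == 1].sum()) < 1e-6

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError):
            compute_class_weights({0: 10, 1: 0})


@pytest.fixture(scope="module")
def subspace_data():
    """Inputs drawn exactly from an 4-d linear subspace of 32-d space."""
    rng = np.random.default_rng(42)
    basis = np.linalg.qr(rng.standard_normal((32, 4)))[0]
    z = rng.standard_normal((256, 4))
    return (z @ basis.T).astype(np.float32)


class TestPretraining:
    def test_subspace_data_reconstructed(self, subspace_data):
        # a rank-4 linear map achieves zero error; PCA confirms attainability
        spec = EncoderSpec(layer_widths=(32, 16, 4), dropout_rate=0.0,
                           epochs=300, batch_size=64, learning_rate=3e-3,
                           val_fraction=0.0, seed=0)
        model = pretrain_autoencoder(subspace_data, spec)
        mse = float(np.mean((model.reconstruct(subspace_data)
                             - subspace_data) ** 2))
        assert mse < 1e-3 * float(subspace_data.var())

    def test_constant_inputs_reconstructed(self):
        x = np.full((64, 16), 0.7, dtype=np.float32)
        spec = EncoderSpec(layer_widths=(16, 8, 4), dropout_rate=0.0,
                           epochs=200, batch_size=32, learning_rate=1e-2,
                           val_fraction=0.0, seed=1)
        model = pretrain_autoencoder(x, spec)
        assert float(np.mean((model.reconstruct(x) - x) ** 2)) < 1e-6

    @pytest.mark.parametrize("seed", range(5))
    def test_training_loss_decreases(self, seed, small_cluster_store):
        spec = EncoderSpec(layer_widths=(32, 16, 8), epochs=10, batch_size=64,
                           seed=seed)
        model = pretrain_autoencoder(small_cluster_store, spec)
        hist = [h for h in model.history if h["phase"] == "pretrain"]
        assert hist[-1]["train_loss"] < hist[0]["train_loss"]

    def test_seeded_runs_identical(self, small_cluster_store):
        spec = EncoderSpec(layer_widths=(32, 16, 8), epochs=3, seed=7)
        a = pretrain_autoencoder(small_cluster_store, spec)
        b = pretrain_autoencoder(small_cluster_store, spec)
        assert a.history == b.history
        for la, lb in zip(a.enc, b.enc):
            assert np.array_equal(la.W, lb.W)

    def test_dimension_mismatch_rejected(self, small_cluster_store):
        spec = EncoderSpec(layer_widths=(16, 8), seed=0)
        with pytest.raises(ValueError):
            pretrain_autoencoder(small_cluster_store, spec)


class TestFinetuning:
    def test_separable_clusters_head_accuracy(self):
        store = generate_feature_clusters(FeatureSimSpec(
            n_samples=600, dim=32, informative_dim=8, separation=8.0,
            positive_fraction=0.3, seed=10))
        spec = EncoderSpec(layer_widths=(32, 16, 8), epochs=10, batch_size=32,
                           val_fraction=0.0, seed=0)
        model = finetune_with_labels(pretrain_autoencoder(store, spec),
                                     store.features, store.labels, spec=spec)
        acc = ((model.head_scores(store.features) >= 0.5)
               == (store.labels == 1)).mean()
        # logistic-regression oracle on the same data is near-perfect
        lr = LogisticRegression(max_iter=1000).fit(store.features, store.labels)
        assert lr.score(store.features, store.labels) >= 0.99
        assert acc > 0.95

    def test_random_labels_give_chance_auc(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((2000, 16)).astype(np.float32)
        y = (rng.random(2000) < 0.5).astype(np.int8)
        spec = EncoderSpec(layer_widths=(16, 8, 4), epochs=5, batch_size=128,
                           val_fraction=0.0, seed=3)
        model = finetune_with_labels(pretrain_autoencoder(x, spec),
                                     x[:1000], y[:1000], spec=spec)
        auc = roc_auc_score(y[1000:], model.head_scores(x[1000:]))
        assert 0.4 <= auc <= 0.6

    def test_requires_pretrained_phase(self, small_cluster_store):
        spec = EncoderSpec(layer_widths=(32, 8), epochs=1, seed=0)
        model = pretrain_autoencoder(small_cluster_store, spec)
        tuned = finetune_with_labels(model, small_cluster_store.features,
                                     small_cluster_store.labels, spec=spec)
        with pytest.raises(ValueError):
            finetune_with_labels(tuned, small_cluster_store.features,
                                 small_cluster_store.labels, spec=spec)

    def test_non_binary_labels_rejected(self, small_cluster_store):
        spec = EncoderSpec(layer_widths=(32, 8), epochs=1, seed=0)
        model = pretrain_autoencoder(small_cluster_store, spec)
        bad = np.zeros(len(small_cluster_store), dtype=int)
        bad[0] = 2
        with pytest.raises(ValueError):
            finetune_with_labels(model, small_cluster_store.features, bad,
                                 spec=spec)


@pytest.fixture(scope="module")
def trained(small_cluster_store):
    spec = EncoderSpec(layer_widths=(32, 16, 8), epochs=3, seed=0)
    return train_encoder(small_cluster_store.features,
                         small_cluster_store.labels, spec)


class TestEncoderContract:
    def test_output_dimension_is_bottleneck(self, trained, small_cluster_store):
        codes = trained.encode(small_cluster_store.features)
        assert codes.shape == (len(small_cluster_store), 8)

    def test_encode_is_pure(self, trained, small_cluster_store):
        a = trained.encode(small_cluster_store.features)
        b = trained.encode(small_cluster_store.features)
        assert np.array_equal(a, b)

    def test_strip_twice_rejected(self, trained):
        with pytest.raises(ValueError):
            strip_head(trained)

    def test_encode_store_preserves_alignment(self, trained,
                                              small_cluster_store):
        codes = encode_store(trained, small_cluster_store)
        assert np.array_equal(codes.ids, small_cluster_store.ids)
        assert np.array_equal(codes.labels, small_cluster_store.labels)
        assert codes.dim == 8

    def test_serialization_roundtrip(self, trained, small_cluster_store,
                                     tmp_path):
        path = tmp_path / "encoder.h5"
        save_encoder(trained, path)
        loaded = load_encoder(path)
        assert loaded.phase == "encoder_only"
        assert np.array_equal(loaded.encode(small_cluster_store.features),
                              trained.encode(small_cluster_store.features))
        assert loaded.history == trained.history


class TestPcaBaseline:
    def test_exact_subspace_recovered(self):
        rng = np.random.default_rng(5)
        basis = np.linalg.qr(rng.standard_normal((10, 2)))[0]
        x = (rng.standard_normal((50, 2)) @ basis.T).astype(np.float32)
        store = FeatureStore(features=x, ids=[str(i) for i in range(50)],
                             labels=np.zeros(50))
        proj, codes = pca_compress(store, 2)
        recon = codes.features @ proj.components + proj.mean
        assert float(np.mean((recon - x) ** 2)) < 1e-10

    def test_components_match_covariance_eigendecomposition(self):
        x = np.array([[1.0, 2.0, 0.5], [0.2, 0.1, 0.9], [1.5, 2.2, 0.3],
                      [0.4, 0.5, 1.1], [0.9, 1.4, 0.7]], dtype=np.float32)
        store = FeatureStore(features=x, ids=list("abcde"),
                             labels=np.zeros(5))
        proj, _ = pca_compress(store, 2)
        cov = np.cov((x - x.mean(0)).T)
        evals, evecs = np.linalg.eigh(cov)
        top = evecs[:, np.argsort(evals)[::-1][:2]].T
        for comp, ev in zip(proj.components, top):
            assert min(np.abs(comp - ev).max(), np.abs(comp + ev).max()) < 1e-4

    def test_full_dimension_is_lossless(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal((20, 4)).astype(np.float32)
        store = FeatureStore(features=x, ids=[str(i) for i in range(20)],
                             labels=np.zeros(20))
        proj, codes = pca_compress(store, 4)
        recon = codes.features @ proj.components + proj.mean
        assert float(np.mean((recon - x) ** 2)) < 1e-9

    def test_dim_too_large_rejected(self, small_cluster_store):
        with pytest.raises(ValueError):
            pca_compress(small_cluster_store, 33)

    def test_linear_autoencoder_approaches_pca_optimum(self):
        # PCA is the linear-reconstruction optimum; a converged linear
        # autoencoder must come within a few percent, never below it
        rng = np.random.default_rng(13)
        scales = np.array([3.0, 2.0, 1.5, 1.0, 0.5, 0.3, 0.2, 0.1])
        x = (rng.standard_normal((300, 8)) * scales).astype(np.float32)
        store = FeatureStore(features=x, ids=[str(i) for i in range(300)],
                             labels=np.zeros(300))
        proj, codes = pca_compress(store, 3)
        recon = codes.features @ proj.components + proj.mean
        pca_mse = float(np.mean((recon - x) ** 2))

        spec = EncoderSpec(layer_widths=(8, 3), dropout_rate=0.0, epochs=800,
                           batch_size=64, learning_rate=1e-2,
                           hidden_activation="linear", val_fraction=0.0, seed=2)
        model = pretrain_autoencoder(x, spec)
        ae_mse = float(np.mean((model.reconstruct(x) - x) ** 2))
        assert ae_mse >= pca_mse * (1.0 - 1e-6)
        assert ae_mse <= pca_mse * 1.05
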