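# thoraxsearch

Image search as a classifier for pneumothorax screening on frontal chest
radiographs.

Pneumothorax — air in the pleural space collapsing a lung — is an emergency
finding that radiologists must flag within minutes, yet small collapses are
easy to miss under routine workload. Rather than training yet another
end-to-end classifier, `thoraxsearch` turns an archive of already-diagnosed
radiographs into the decision engine: a query image is matched against the
archive and inherits the diagnosis of its nearest neighbours, together with
the matched cases themselves as supporting evidence — a "virtual second
opinion" rather than an opaque probability.

## Method

For a query radiograph *q* and an archive tagged with descriptors:

1. **Tagging.** Each image is rendered as three aligned 224 × 224 views —
   the whole image, the left half, and the horizontally *flipped* right half
   (a coarse registration exploiting thoracic symmetry) — and a frozen
   backbone maps each view to a 1,024-d feature. Configuration 1 uses the
   whole-image feature (1,024 values), configuration 2 concatenates the two
   half features (2,048), configuration 3 concatenates all three (3,072).
2. **Compression.** A two-step autoencoder squeezes the 3,072-d vector into
   256 values (12× smaller): unsupervised reconstruction pre-training
   (MSE, Adam, 10 epochs, batch 128, dropout 0.2), then supervised
   fine-tuning through a single sigmoid unit with class-weighted binary
   cross-entropy, where class *c* with *S_c* of *S* samples over *C* classes
   gets weight

   W_c = S / (C · S_c),

   so each class contributes equal total loss mass despite the ~6%
   prevalence of pneumothorax. The sigmoid head is then discarded and the
   bare encoder codes both archive and queries.
3. **Search.** Exhaustive Euclidean k-nearest-neighbour retrieval; of the
   *k* nearest archived images, *m* carry the pneumothorax label, and
   *m/k* is the query's class likelihood.
4. **Decision.** The operating threshold maximises Youden's index
   J = sensitivity + specificity − 1 on the ROC of vote likelihoods;
   performance is reported as sensitivity, specificity and AUC under
   tenfold cross-validation, with a fresh encoder trained per fold on that
   fold's archive only.

No pretrained weights ship with the package: the backbone is a pluggable
contract, and the default `StubBackbone` (block-mean pooling plus a fixed
seeded projection) is pure arithmetic, so the entire pipeline is exactly
reproducible from synthetic data. Two generators provide test beds: thorax
phantoms with exact bilateral symmetry (broken one-sidedly by a pleural
crescent in positives) and Gaussian feature clusters whose class signal
lives in a 256-d subspace of 3,072 dimensions.

## Worked example

Evaluate raw descriptor search against compressed-code search on the
synthetic benchmark (2,000 descriptors, 6% positive, tenfold CV):

```python
import thoraxsearch as ts

store = ts.generate_feature_clusters(ts.FeatureSimSpec(
    n_samples=2000, dim=3072, informative_dim=256, separation=6.0,
    positive_fraction=0.06, seed=0))

raw = ts.run_cv(store, mode="raw", ks=(11, 51), n_folds=10, seed=0)
enc = ts.run_cv(store, mode="encoded", ks=(11, 51), n_folds=10, seed=0,
                encoder_spec=ts.EncoderSpec(layer_widths=(3072, 512, 256),
                                            seed=0))
for k in (11, 51):
    print(f"k={k}: raw AUC={raw[k].mean_auc:.3f}  "
          f"encoded AUC={enc[k].mean_auc:.3f}")
```

prints

```
k=11: raw AUC=0.775  encoded AUC=0.913
k=51: raw AUC=0.917  encoded AUC=0.974
```

Raw 3,072-d matching is weak at small k — with only ~120 positives in an
1,800-item archive the distance signal is diluted across thousands of noise
dimensions and an 11-neighbour vote takes just 12 distinct values — while
the 256-d codes, pre-trained to reconstruct and fine-tuned to discriminate,
recover most of the attainable ranking quality at both k. The same
comparison against PCA at the same bottleneck (`mode="pca"`) shows the
learned encoder ahead (0.73/0.94), most visibly at small k.

The same experiment from the shell:

```bash
thoraxsearch simulate features --n 2000 --seed 0 --out store.h5
thoraxsearch evaluate --store store.h5 --mode raw     --k 11,51 --folds 10 --seed 0 --out raw.json
thoraxsearch evaluate --store store.h5 --mode encoded --k 11,51 --folds 10 --seed 0 --widths 3072,512,256 --out enc.json
```

Further subcommands: `simulate images` (phantom radiographs + manifest),
`extract` (manifest → descriptor store), `train-encoder` / `encode`,
`search` / `classify` (hit tables and thresholded votes), `run` (end to
end), and `compare` (encoder vs PCA with a paired two-sided Wilcoxon
signed-rank test across folds).

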