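# sparseae

Supervised autoencoder with structured-sparsity feature selection for tabular
omics data — in particular LC-MS metabolomics feature tables, where a clinician
or analyst needs three things at once from a classifier: an accurate
prediction, a **confidence score** for each individual patient, and a short,
interpretable list of the **features (metabolites)** that drive the decision.

## The model

Given an `m × d` intensity matrix `X` with class labels `y ∈ {0..k−1}`, the
network is a small autoencoder whose latent space doubles as the classifier's
logit space:

```
encoder:  d  → 96 (ReLU) → k        latent code Z  (k = number of classes)
softmax:  Z  → class probabilities  (confidence = max probability)
decoder:  k  → 96 (ReLU) → d        reconstruction X̂
```

Training minimises the composite criterion

```
loss(W) = CE(softmax(Z), y) + λ · Huber(X̂ − X)      s.t.  ‖W₁‖₁,₁ ≤ η
```

where `CE` is the cross-entropy, the Huber (smooth ℓ1) reconstruction loss is
robust to outlier samples, and the constraint bounds the **ℓ1,1 norm** (sum of
row-wise ℓ1 norms) of the first encoder layer `W₁`. The constraint is enforced
by a two-stage projection — distribute the budget η over rows, then project
each row — which zeroes *whole rows* of `W₁`. Since each row corresponds to
one input feature, training performs feature selection: features with a zero
row are disconnected from the entire network. Optimisation is a projected
ADAM loop with a double-descent (prune-and-retrain) schedule: after a first
training phase the eliminated rows are frozen and the surviving weights are
retrained.

The budget η is chosen by cross-validated accuracy (`select_eta`). For
benchmarking, the package ships a 4-fold × 3-seed cross-validation harness
(12 train/test splits) comparing the SAE (Huber and squared-error variants)
against PLS-DA, Random Forest, a linear-kernel SVM with grid-searched C, and a
plain neural network with the same encoder architecture.

A synthetic-data module generates metabolomics-like tables with known ground
truth: log-normal intensities, planted class-informative features, correlated
adduct/isotope blocks and heavy-tailed outlier samples — so the whole pipeline
is testable without any external dataset.

## Worked example

```bash
$ sparseae simulate --preset tiny --out demo.csv --seed 0
wrote 60 x 40 table to demo.csv

$ sparseae train --input demo.csv --out demo_run --eta 8 --seed 0
trained SAE: 5/40 features selected; artifacts in demo_run

$ sparseae holdout-sim --input demo.csv --out demo_sim --seed 1
S0025: predicted class 0 (true 0) with confidence 0.86
S0036: predicted class 1 (true 1) with confidence 0.93
```

The tiny preset plants 5 informative features among 40; with η = 8 the ℓ1,1
constraint keeps exactly 5 nonzero rows. `demo_run/feature_ranking.tsv` ranks
features by the ℓ1 norm of their weight row, and `holdout-sim` retrains with
one patient per class withheld, then reports each withheld patient's predicted
class and softmax confidence together with the latent coordinates of the
training cohort (`latent_coordinates.csv`) for plotting.

The same pipeline from Python:

```python
import sparseae as s

table, planted = s.generate(s.preset("tiny"))
model = s.train_sae(table, s.SAEConfig(eta=8.0, seed=0))
ranking = s.rank_features_sae(model, table)
ranking.top(5)
# ['MZ 185.21', 'MZ 634.53', 'MZ 217.89', 'MZ 203.35', 'MZ 424.54']
# — four of the five are planted ground-truth features
```

Other commands: `sparseae benchmark` (the 12-split comparison, writes
`cv_splits.csv` / `cv_aggregates.json`), `sparseae select-eta`, and
`sparseae rank-features`. Every command writes a `manifest.json` with the
config echo, seed and library versions that reproduce the run exactly.

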