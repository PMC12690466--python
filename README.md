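# esssubgraph

Inductive essential-gene prediction from protein–protein interaction (PPI)
networks and gene-expression-derived node features.

A gene is *essential* when its loss of function compromises cell viability;
*common essential* genes produce a growth defect in most cell lines screened.
Knockout screens (CRISPR, RNAi) identify them experimentally, but screens are
expensive and never cover every gene, cell type, or species.  This package
frames the problem as node classification on a PPI graph and solves it with a
subgraph-sampling graph neural network that is **inductive**: a trained model
can score genes that were entirely absent — edges, features, and labels —
from the training graph, which matters because interaction networks grow
continuously.

## The model

Each layer k updates a node's representation from a *sampled* fixed-size
neighbor set (default sizes [30, 25, 10] for hops 1–3):

```
h_N(v)^k = mean{ h_u^(k-1) : u ∈ sampled N(v) }
h_v^k    = ReLU( W^k · concat(h_v^(k-1), h_N(v)^k) )
```

After K = 3 steps a learnable linear projection maps h_v^K to a logit;
σ(logit) is the probability that gene v is essential.  Node features h^0 are
the top 50 principal components of a log-transformed expression matrix,
min–max scaled on the genes used for fitting.  Training minimizes
class-weighted binary cross-entropy (weight 4 on the rare essential class)
with Adam (lr 0.01, ≤200 epochs, early stopping on validation loss).
Because a prediction touches only a sampled K-hop neighborhood, memory is
bounded regardless of network size.

Around the classifier the package provides:

- **Label construction** (`esssubgraph.labeling`): per-cell-line percentile
  ranks of viability effect, a per-gene 0.90-quantile summary, a Gaussian-KDE
  valley threshold separating the bimodal summary distribution, screen
  intersection, and conditional-essential exclusion.
- **Graph I/O** (`esssubgraph.graph`): STRING/CPDB-style edge lists,
  confidence filtering, canonicalization, dataset alignment.
- **Evaluation** (`esssubgraph.evaluation`): 4:1 negative subsampling
  (AUPRC baseline 0.2), repeated stratified 5-fold CV, AUPRC/AUROC, Youden-J
  cutoff selection, and four unseen-gene exposure scenarios.
- **Perturbation** (`esssubgraph.perturb`): edge replacement and feature
  swapping with a degradation scan harness.
- **Synthetic data** (`esssubgraph.synthetic`): scale-free graphs, planted
  labels, expression with class signal, bimodal screen matrices.

## Worked example

```python
import numpy as np
from esssubgraph import (EssSubgraph, auprc, make_reference_dataset,
                         subsample_negatives, make_cv_splits)

ds = make_reference_dataset(seed=1)          # 2,000 genes, 10,000 interactions
rng = np.random.default_rng(0)
pool = subsample_negatives(ds.labels, rng=rng)        # 200 essential + 800
y = np.array([g in ds.labels.essential for g in pool], dtype=int)
train, val, test = make_cv_splits(pool, y, rng=rng).folds[0]

result = EssSubgraph(ds).fit(train, val, seed=7)
print(result.summary())
p = result.predict_scores(test, seed=7)
y_test = [g in ds.labels.essential for g in test]
print("test AUPRC:", round(auprc(p, y_test), 3))
```

Output:

```
EssSubgraph Results
======================================================
Depth (K)                     3
Sample sizes (hop 1..K)       [30, 25, 10]
Hidden dims                   [64, 64, 64]
Input dim                     50
Learnable parameters          22849
Learning rate (Adam)          0.01
Class weights (ess/noness)    4/1
Epochs run                    54/200
Best epoch (val loss)         44
Final train loss              0.0001
Best val loss                 0.0002
======================================================

test AUPRC: 1.0
```

The synthetic reference experiment plants a strong class signal (essential
genes shifted by 1.5 noise-sd in expression, enriched among hubs), so the
held-out AUPRC of 1.0 against the 0.2 chance baseline says the pipeline
recovers exactly the structure it was given — see `docs/methods.md` for what
that does and does not imply about real screens.

A command-line interface mirrors the library
(`esssubgraph simulate | label | featurize | train | predict | evaluate |
unseen | perturb-scan`); every run writes a manifest sufficient to reproduce
it.

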