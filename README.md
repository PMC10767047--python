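# spatglia

Spatiotemporal analysis of glial-cell activation in spot-based spatial
transcriptomics, built for studies of amyloid-pathology ("AD") mouse
models profiled with Visium-style slides at several ages. The package is
aimed at computational biologists who want the whole spot-level pipeline
— region clustering, region-wise differential expression, activation
signature scoring, fluorescence-image integration, and pseudotime — as
reusable, tested library code rather than a one-off notebook.

The scientific question it serves: where in the brain does glial
activation start, and how does it spread as pathology progresses? The
pipeline is designed to detect the characteristic pattern in which
disease-associated microglia (DAM) and astrocyte (DAA) signatures rise
first in white matter (WM) at an early age and spread into gray matter
(GM) later, and to resolve that progression into spatially distinct
activation trajectories.

## What is implemented

- **Synthetic study generator** (`spatglia.syndata`): seeded Visium-like
  datasets with the full 2 genotypes x 2 ages x 2 replicates design —
  hex-lattice spots, anatomical regions (cortex layers, hippocampus,
  striatum, thalamus, a WM band, border), negative-binomial counts
  `mean = baseline * fold^activation`, a WM-early/GM-late activation
  field, and a paired plaque-like grayscale image driven by a designated
  gene. Every downstream stage is testable without downloads.
- **Data model and I/O** (`spatglia.io`): sparse gene x spot datasets,
  10x-style MTX triplets with a tissue-positions CSV, GMT gene sets,
  multi-sample merging with gene-universe union.
- **Clustering** (`spatglia.preprocess`): log-normalization (scale
  10,000), vst highly-variable genes (n = 2,000), covariate regression
  and scaling, 30-component PCA, SNN-graph Louvain clustering at
  resolution 0.2, one-vs-rest Wilcoxon markers, replicate-correlation QC.
- **Differential expression** (`spatglia.diffexpr`): two-part hurdle test
  (logistic detection + Gaussian positive components, combined LRT with
  2 df), logFC on de-logged means, BH adjustment, per-cluster AD-vs-WT
  contrasts (adjusted p < 0.05, logFC > 0.25), cross-cluster
  intersections, and a pseudobulk label-shuffle robustness check.
- **Signature scores** (`spatglia.signatures`): binned-control module
  scores (24 bins, 100 controls per gene) for the printed DAM set (Lpl,
  Cst7, Axl, Itgax, Spp1, Cd9, Ccl6, Csf1), the DAA set (Ggta1, Gsn,
  Osmr, Vim, Serpina3n, Ctsb, Gfap), or any GMT set, with per-cluster
  genotype comparisons and spatial export.
- **Image integration** (`spatglia.imglink`): rigid -> affine (->
  demons) registration of a fluorescence image to the spot frame, 32x32
  patches at spots, a training-free feature bank, PCA image latents
  ("ImageLatent_1"), and per-gene regression on a latent with top-100
  selection.
- **Pseudotime** (`spatglia.trajectory`): PCA on a 28-gene microglial
  panel, an elastic principal tree (k-means + SimplePPT-style refinement
  + MST), root selection by late-disease-group depletion, per-spot
  geodesic pseudotime, branch decomposition, spatial pseudotime maps and
  expression-vs-pseudotime curves.
- **Over-representation** (`spatglia.enrich`): exact hypergeometric
  upper-tail tests of gene lists against GMT sets.

## Worked example

```python
import numpy as np
from sklearn.metrics import adjusted_rand_score
from spatglia import syndata, signatures, diffexpr
from spatglia.preprocess import (cluster_pipeline, annotate_clusters,
                                 log_normalize)

study = syndata.simulate_study(seed=1, n_rows=20, n_cols=25,
                               n_genes=800, n_region_markers=40)
data = study.data

clusters, emb, norm = cluster_pipeline(data, n_hvg=600, seed=1)
ari = adjusted_rand_score(data.meta["region"], clusters.labels)
annotation = annotate_clusters(clusters.labels,
                               data.meta["region"].to_numpy())

dam, _ = signatures.module_score(norm, signatures.DAM_SIGNATURE, seed=1)
by_group = signatures.score_by_group(dam, data.meta["region"].to_numpy(),
                                     data.meta["genotype"].to_numpy(),
                                     data.meta["age"].to_numpy())

threeM = data.subset_spots((data.meta["age"] == "3M").to_numpy())
de = diffexpr.deg_per_cluster(log_normalize(threeM),
                              threeM.meta["region"].to_numpy(),
                              threeM.meta["genotype"].to_numpy())
up = de["WM"].up(alpha=0.05, min_logfc=0.25)
```

Output:

```
800 genes x 4000 spots, 8 samples
7 clusters, ARI vs true regions = 1.000
cluster -> region: {0: 'striatum', 1: 'thalamus', 2: 'cortex_outer',
                    3: 'cortex_inner', 4: 'border', 5: 'WM',
                    6: 'hippocampus'}
DAM score, WM at 3M: AD-WT diff = 0.543 (Wilcoxon p = 4.82e-14)
DAM score, inner cortex: 3M diff = 0.012, 7M diff = 0.603
AD-vs-WT upregulated in WM at 3M: ['Apoe', 'Axl', 'B2m', 'Ccl6', 'Cd9',
                                   'Csf1', 'Ctsl', 'Fth1'] ... (22 genes)
```

Reading the numbers: the Louvain clusters reproduce the ground-truth
anatomy exactly (ARI 1.0) and are annotated by majority region. The DAM
module score separates AD from WT in white matter already at 3 months
(+0.54, p ~ 5e-14) while the inner cortex shows essentially no shift at
3 months (+0.01) and a strong one at 7 months (+0.60) — the
WM-early/GM-late progression the pipeline is built to detect. The hurdle
test recovers the activation program genes (DAM, DAA, and the auxiliary
panel genes) as upregulated in WM at 3 months.

A command-line interface mirrors the main stages:

```
spatglia simulate --config cfg.yaml --seed 1 --out data/
spatglia cluster  --in data/ --resolution 0.2 --out results/
spatglia score    --in data/ --gmt sets.gmt --seed 1 --out scores.csv
spatglia de       --in data/ --clusters results/clusters.csv --contrast AD:WT --out de.tsv
spatglia traj     --in data/ --late AD:7M --seed 1 --out traj/
spatglia imglink  --image data/plaque.tif --in data/ --out img/
spatglia ora      --query up.txt --gmt sets.gmt --out ora.tsv
```

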