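# bcmnet

Dense-component mining of tumor–stroma co-expression networks with a
provable density guarantee.

## The problem

The tumor microenvironment — mostly stromal tissue — interacts with the
tumor itself, and those interactions leave a footprint in gene expression:
groups of tumor genes and stroma genes whose profiles co-vary across
matched specimens. Given two expression matrices (genes × samples, log
intensities) measured on the *same* patients in the two compartments,
bcmnet models their relationship as a weighted bipartite graph: tumor
genes on one side, stroma genes on the other, and an edge of weight
ρ<sub>ij</sub> wherever the Pearson correlation between tumor gene *i* and
stroma gene *j* reaches a threshold. Densely connected bipartite
sub-networks (**BiNets**) of this graph are candidate cross-tissue
programs, and their gene sets can be tested as prognostic biomarkers.

## The algorithm

**BCM** (Bipartite Component Mining) grows a BiNet *B* = (V′_X, V′_Y) from
each unselected heavy seed edge (weight ≥ β·w_max). The density of *B* is
the average weight over all a·b vertex pairs,

    d(B) = Σ_{e ∈ E(B)} w(e) / (a·b),    a = |V′_X|, b = |V′_Y|,

absent edges counting 0, and a candidate vertex v's contribution is its
mean edge weight into the opposite member set. At each step the
best-contributing candidate on each side is found and the overall winner
is admitted only if its contribution is at least α·d(B), with the
size-dependent schedule

    α = 1 − 1/(λ·(size + τ + 1)),   λ = max{1, C/(size + τ + 1)²}.

This schedule buys a guarantee: every mined BiNet satisfies

    d(B) / w(seed) ≥ F(C, τ) = ((2C−τ−2)/(2C))^{2k} · ((√C−τ−1)/(√C−τ))²,

where k counts the sizes i ≥ 1 with (i+τ+1)² < C. For C = 100, τ = 1 the
bound is ≈ 0.64; for C = 10000, τ = 0 it exceeds 0.96. The defaults
C = 36, τ = 2, β = 0.7 give F ≈ 0.448.

Downstream, BiNets with ≥ 10 distinct genes are kept, merged
agglomeratively into macro networks while merged density stays ≥ 0.3, and
each BiNet's union gene set is evaluated as a survival biomarker: patients
are split in two by K-means (K = 2, city-block distance, median centroid
update, best of 100 restarts) on the BiNet's features, and the two groups
are compared with a log-rank test.

Because the original microarray cohorts are external downloads, the
package ships a synthetic-data module that plants cross-tissue correlated
modules via a shared latent factor (expected member-pair correlation
ρ\* = loading²/(loading²+σ²)) and ties survival hazard to module activity,
so the entire pipeline is testable end to end.

## Worked example

```sh
bcmnet simulate --outdir demo --n-samples 200 --n-tumor-genes 60 \
    --n-stroma-genes 60 --module 15,15,0.8 --prognostic-module 0 \
    --hazard-ratio 3.0 --censoring 0.2 --seed 7
bcmnet build-net demo/tumor.tsv demo/stroma.tsv --min-weight 0.5 -o demo/edges.tsv
bcmnet mine demo/edges.tsv -o demo/binets.json
bcmnet filter demo/binets.json --min-genes 10 -o demo/kept.json
bcmnet merge demo/kept.json demo/edges.tsv -o demo/macros.json --newick demo/dendro.nwk
bcmnet evaluate demo/kept.json --survival-csv demo/survival.csv \
    --tumor-tsv demo/tumor.tsv --stroma-tsv demo/stroma.tsv -o demo/eval.csv
bcmnet verify demo/kept.json demo/edges.tsv
```

prints

```
simulate: wrote 60+60 genes, 200 samples to demo
build-net: 15x15 vertices, 225 edges
mine: 1 BiNets, w_max=0.8114, bound F=0.4475
filter: kept 1/1 BiNets
merge: 1 macro networks at threshold 0.3
evaluate: 1/1 BiNets significant (p<0.05) in >=1 cohort
binet0	ratio=0.938456	pass
bound F=0.447536	overall=pass
```

Reading: after variance filtering, only the 15+15 planted module genes
survive, and all 225 cross-pairs clear the 0.5 correlation threshold. BCM
recovers the module as a single BiNet of density 0.761 — 0.938 of its
seed-edge weight 0.811, comfortably above the guaranteed F = 0.448. The
K-means split of its features separates the cohort 110/90, and the
log-rank test gives χ² = 21.0, p ≈ 5·10⁻⁶: the planted prognostic signal
(hazard ratio 3) is detected.

The same machinery is available as a library, including sklearn-style
estimators:

```python
import numpy as np
from bcmnet import BCMMiner

W = np.array([[1.0, 0.9], [0.95, 0.9]])   # weight matrix, 0 = no edge
miner = BCMMiner(C=36, tau=2, beta=0.7).fit(W)
miner.binets_[0].density                   # 0.9375
```

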