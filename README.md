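# rootpheno

Seedling root-system-architecture (RSA) phenomics for diversity panels:
from 2-D root photographs to trait tables, genotype BLUPs and heritability,
root-ideotype rankings, population structure, and a mixed-model GWAS — with
a synthetic-data layer that generates every input the pipeline needs,
complete with ground truth.

It is written for plant-genetics and phenomics groups who screen hundreds
of accessions as seedlings on germination paper in growth chambers (one
image per seedling per day), and for methods work that needs an RSA
pipeline whose every stage can be validated against a simulator oracle.

## What it computes

**Image traits.** A photograph is thresholded, thinned to a skeleton graph,
and measured: total and primary root length (TRL, PRL), depth and width,
diameter, lateral branch count (LRB), convex area and solidity (SOL),
rhizosphere area, surface area and volume of the primary, the upper-third
length fraction (TRL_Upper, LED = TRL_Upper/TRL_Lower), and the median
lateral root angle from the vertical axis (LRA).

**Mixed model and heritability.** Per trait,

    y_ijkl = mu + Chamber_i + (Chamber:Block)_ij + (Chamber:Block:Sub-block)_ijk
             + Genotype_l + e_ijkl

with chamber fixed and the rest random; variance components by REML,
genotype BLUPs and their prediction-error covariances from Henderson's
equations, and Cullis broad-sense heritability

    H^2 = 1 - Vdelta_BLUP / (2 * sigma_g^2),

where `Vdelta_BLUP` is the mean variance of a difference of two genotypic
BLUPs — valid for unbalanced chamber data.

**Ideotypes.** Sum-of-ranks "iRoot" scoring: rank genotypes per component
trait, sum, rank the sums. Topsoil foraging = {TRL_GR, WID, TRL_Upper}
(higher is better); steep-cheap-deep = {TRL_GR up, steep LRA, low SOL2}.

**Population structure.** PCA and complete-linkage clustering of trait or
SNP matrices, cluster-count selection by an internal-index vote, and
pairwise Weir–Cockerham (1984) Fst, `theta = sum(a) / sum(a+b+c)`.

**GWAS.** Site filters (missingness > 15%, MAF < 0.01), VanRaden kinship,
a P3D mixed linear model `y = X beta + u + e` with `u ~ N(0, sigma_g^2 K)`
and PC covariates, per-marker GLS tests, and Bonferroni thresholds.

**Synthetic data.** Chamber/block/sub-block randomized designs (376
genotypes per chamber replicate), forward-simulated root systems rendered
to PNG with controllable noise, phenotypes drawn from the variance-component
model, and Balding–Nichols SNP panels with planted QTL — all seeded and
with recorded truth.

## Worked example

`examples/01_simulate_and_extract_traits.py` simulates a day-15 seedling,
renders it at 20 px/cm, and measures it back:

```
rendered image: 850 x 97 px at 20 px/cm
trait       measured     truth
TRL            76.06     77.40
PRL            41.49     42.00
DEP            41.90     41.94
WID             4.25      4.27
LRB             9.00      9.00
LRA            19.54     21.09
TRL_Upper      22.98     23.30
LED             0.43      0.43
```

The pixel pipeline reproduces the polyline ground truth: root lengths to
~2%, the lateral count exactly, and the median lateral angle to ~1.5
degrees. `examples/04_population_structure.py` runs the genotypic side on
a two-subpopulation Balding–Nichols panel simulated at Fst = 0.05:

```
PC1 and PC2 explain 5.3% and 0.7% of the variation
index panel votes for k = 2 clusters (votes: [2, 2, 2])
complete-linkage clusters of size [100, 100]; 100% match the true subpopulations
pairwise Weir-Cockerham Fst between the clusters: 0.048 (simulated truth 0.05)
```

The remaining examples cover the heritability pipeline (design →
phenotypes → Tukey filter → REML → Cullis H), ideotype ranking, and a GWAS
scan that recovers a planted QTL at the Bonferroni threshold.

## Layout

```
src/rootpheno/
  sim/          designs, root systems, renders, phenotypes, SNP panels
  imaging/      segmentation, skeleton graphs, trait extraction
  phenostats.py Tukey filter, REML/BLUP, Cullis H, descriptives, correlations
  ideotype.py   sum-of-ranks iRoot scoring
  popgen.py     PCA, hierarchical clustering, k selection, WC84 Fst
  gwas.py       site filters, kinship, P3D MLM scan, Bonferroni
  genotypes.py  dosage matrices and VCF I/O
examples/       one narrative script per capability
docs/methods.md models, conventions, numerical choices, limitations
```
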