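# genoanat

Computational genetic neuroanatomy for voxel-level spatial gene expression.

Developing-brain atlases provide, for each voxel of a 3-D reference grid,
an *expression energy* per gene and an anatomical annotation drawn from a
rooted, level-numbered ontology (level 1: the primary brain vesicles;
level 3: transversal segments; level 5: segments × longitudinal zones of
the prosomeric model). `genoanat` asks how well the anatomy is encoded in
the expression data alone: it embeds the n × d voxel-by-gene matrix into
2 or 10 dimensions, clusters voxels, and measures how consistent the
clusters are with the anatomy at several ontology levels. It is written
for computational biologists who want a fully-tested, dependency-light
reference implementation of this pipeline, including a ground-truthed
synthetic atlas so nothing requires a download.

## What is inside

* **Exact t-SNE, from the defining equations.** Gaussian conditional
  affinities `p_{j|i} = exp(−‖x_i−x_j‖²/2σ_i²) / Σ_{k≠i} exp(−‖x_i−x_k‖²/2σ_i²)`
  with each σ_i tuned by binary search to a fixed perplexity (default 30);
  symmetrization `p_ij = (p_{j|i}+p_{i|j})/2` normalized to a distribution;
  Student-t map kernel `q_ij ∝ (1+‖y_i−y_j‖²)^{−1}`; momentum gradient
  descent on `KL(P‖Q)` with early exaggeration. Plus a centered-PCA
  baseline.
* **k-means with the min-WCSS restart protocol**, k tied to the number of
  anatomical structures present at the ontology level under study.
* **Concordance measures** between a clustering and the annotation: NMI,
  adjusted Rand index, purity, and a voxel-weighted containment S-index
  that penalizes clusters straddling anatomical boundaries.
* **Atlas model**: ontology trees (JSON), annotation/expression volumes
  (NRRD or CSV), voxel filtering (background, excluded subtrees such as
  the spinal cord, annotations coarser than level 5) and up-propagation of
  labels to levels 1/3/5.
* **Synthetic atlas generator**: a seeded ontology + grid-like annotation
  (transversal × longitudinal domains) + expression model (hierarchical
  latent walk, marker genes, per-voxel brightness, observation noise) with
  full ground truth.
* A `genoanat` CLI (`simulate`, `embed`, `cluster`, `evaluate`, `run`).

## Worked example

Generate a small synthetic atlas (720 labeled voxels, 60 genes, 3 level-1
blocks), then compare k-means in raw expression space against k-means on
the t-SNE 2-D map:

```python
from genoanat import ExperimentConfig, SyntheticSpec, TsneConfig, run_experiment

cfg = ExperimentConfig(
    atlas_spec=SyntheticSpec(dims=(14, 12, 8), n_genes=60),
    methods=("raw", "tsne"), dims=(2,), levels=(1, 5),
    tsne=TsneConfig(perplexity=30, n_iter=300), kmeans_restarts=10, seed=0,
)
report = run_experiment(cfg)
print(report[["method", "dim", "level", "k", "n",
              "nmi", "s_index", "ari", "purity"]].to_string(index=False))
```

```
method  dim  level  k   n    nmi  s_index    ari  purity
   raw   60      1  3 720 0.2209   0.6667 0.0673  0.4694
   raw   60      5 36 720 0.5060   0.2816 0.1331  0.3014
  tsne    2      1  3 720 0.7202   0.8992 0.7520  0.9125
  tsne    2      5 36 720 0.5435   0.3030 0.1730  0.3278
```

Reading the table: at level 1 (three brain vesicles, k = 3), clustering
the raw 60-dimensional expression vectors agrees only weakly with anatomy
(NMI 0.22) — per-voxel intensity variation dominates raw Euclidean
distances — while clustering the 2-D t-SNE map recovers the vesicles well
(NMI 0.72, purity 0.91). At level 5 (36 segment × zone domains) both
representations do similarly (NMI 0.51 vs 0.54): the fine structure is
already prominent in raw space, so the low-dimensional map helps most at
the coarsest anatomy. The same directional pattern holds on the default
full-size atlas across master seeds.

The same pipeline runs from the shell:

```bash
genoanat simulate --spec spec.yaml --out atlas/          # atlas + dataset.tsv
genoanat embed --input atlas/dataset.tsv --method tsne --dim 2 --out emb.tsv
genoanat cluster --input emb.tsv --k 3 --out labels.tsv
genoanat evaluate --truth atlas/dataset.tsv --clusters labels.tsv --out scores.tsv
genoanat run --config experiment.yaml                    # the full grid
```

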