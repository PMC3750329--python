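"""End-to-end experiment runner: methods x dimensions x ontology levels.

One experiment reproduces the full comparison grid: for each representation
(raw expression space, PCA to 2/10-D, t-SNE to 2/10-D) the voxels are
k-means-clustered with k equal to the number of structures present at each
studied ontology level, and the partition is scored against the up-propagated
anatomical labels with NMI, S-index, ARI and purity. The result is a tidy
report table (a pandas DataFrame; written as TSV with 4 decimal places) with
one row per (method, dim, level) combination.

Seeding: every stochastic stage draws its own sub-seed from the master seed
through a fixed per-stage code (``_sub_seed``), so adding or removing a
method never shifts the random streams of the others, and a rerun with the
same master seed reproduces the report byte for byte. When the experiment
generates its own synthetic atlas, the atlas seed is likewise derived from
the master seed.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cluster import choose_k, kmeans
from .concordance import score_all
from .dataset import VoxelDataset
from .embedding import Embedding, TsneConfig, run_pca, run_tsne
from .exceptions import DomainError, GenoanatError, SpecError, ValidationError
from .ontology import OntologyTree
from .synthetic import SyntheticSpec, generate_atlas, longitudinal_zone_map

__all__ = [
    "ExperimentConfig",
    "run_experiment",
    "export_scatter",
    "export_zone_scatter",
]

logger = logging.getLogger("genoanat")

METHODS = ("raw", "pca", "tsne")
_STAGE_CODES = {"atlas": 1, ("tsne", 2): 102, ("tsne", 10): 110}


def _sub_seed(master: int, code: int) -> int:
    """Deterministic per-stage sub-seed, stable across config changes."""
    ss = np.random.SeedSequence([int(master), int(code)])
    return int(ss.generate_state(1)[0] % 2**31)


def _kmeans_code(method: str, dim: int, level: int) -> int:
    return 1000 + METHODS.index(method) * 100 + dim * 10 + level


@dataclass
class ExperimentConfig:
    """Settings of one full comparison grid.

    Exactly one of ``atlas_spec`` (generate a synthetic atlas; its seed is
    re-derived from ``seed``) or ``dataset_path`` (a filtered dataset TSV)
    supplies the input.
    """

    atlas_spec: SyntheticSpec | None = None
    dataset_path: str | None = None
    methods: tuple[str, ...] = ("raw", "pca", "tsne")
    dims: tuple[int, ...] = (2, 10)
    levels: tuple[int, ...] = (1, 3, 5)
    tsne: TsneConfig = field(default_factory=TsneConfig)
    kmeans_restarts: int = 10
    seed: int = 0
    out_dir: str | None = None
    dataset_name: str = "synthetic"

    def __post_init__(self) -> None:
        if not self.methods or not self.levels:
            raise SpecError("methods and levels must be non-empty")
        bad = [m for m in self.methods if m not in METHODS]
        if bad:
            raise SpecError(f"unknown methods {bad}; choose from {METHODS}")
        if any(m in ("pca", "tsne") for m in self.methods) and not self.dims:
            raise SpecError("dims required unless the only method is 'raw'")
        if any(l not in (1, 3, 5) for l in self.levels):
            raise SpecError(f"levels must be among (1, 3, 5), got {self.levels}")
        if any(d not in (2, 10) for d in self.dims):
            raise SpecError(f"dims must be among (2, 10), got {self.dims}")
        if (self.atlas_spec is None) == (self.dataset_path is None):
            raise SpecError("provide exactly one of atlas_spec or dataset_path")


def _combinations(cfg: ExperimentConfig) -> list[tuple[str, int]]:
    out: list[tuple[str, int]] = []
    for m in cfg.methods:
        if m == "raw":
            out.append((m, 0))  # dim 0 = original space
        else:
            out.extend((m, d) for d in cfg.dims)
    return out


def run_experiment(cfg: ExperimentConfig) -> pd.DataFrame:
    """Run the grid and return the concordance report.

    Embeddings are computed once per (method, dim) and reused across levels.
    A failing combination contributes an error row (scores NaN, message in
    the ``error`` column) and the run continues; if every combination fails,
    a :class:`GenoanatError` is raised.
    """
    t0 = time.time()
    out_dir = Path(cfg.out_dir) if cfg.out_dir else None
    log_handler = None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        log_handler = logging.FileHandler(out_dir / "genoanat.log", mode="w")
        log_handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
        log_handler.setLevel(logging.INFO)
        logger.addHandler(log_handler)
        prev_level = logger.level
        logger.setLevel(logging.INFO)

    atlas = None
    try:
        if cfg.atlas_spec is not None:
            atlas_seed = _sub_seed(cfg.seed, _STAGE_CODES["atlas"])
            logger.info("master seed %d; atlas sub-seed %d", cfg.seed, atlas_seed)
            atlas = generate_atlas(replace(cfg.atlas_spec, seed=atlas_seed))
            ds = atlas.build_dataset()
        else:
            ds = VoxelDataset.from_tsv(cfg.dataset_path)
        logger.info("dataset ready: n=%d voxels, d=%d genes (%.1fs)",
                    ds.n_voxels, ds.n_genes, time.time() - t0)
        return _run_grid(cfg, ds, atlas, out_dir, t0)
    finally:
        if log_handler is not None:
            logger.removeHandler(log_handler)
            log_handler.close()
            logger.setLevel(prev_level)


def _run_grid(cfg: ExperimentConfig, ds: VoxelDataset, atlas, out_dir: Path | None,
              t0: float) -> pd.DataFrame:

    rows: list[dict] = []
    n_failed = 0
    for method, dim in _combinations(cfg):
        t1 = time.time()
        try:
            Y = _representation(ds.X, method, dim, cfg)
        except GenoanatError as exc:
            logger.warning("%s_%s failed: %s", method, dim, exc)
            for level in cfg.levels:
                rows.append(_error_row(cfg, method, dim, level, ds, str(exc)))
                n_failed += 1
            continue
        logger.info("representation %s dim=%s computed in %.1fs", method, dim,
                    time.time() - t1)
        if out_dir and method != "raw":
            _write_embedding_tsv(Y, out_dir / f"embedding_{method}{dim}.tsv")
        if out_dir and atlas is not None and dim == 2:
            emb2 = Embedding(Y=Y, m=2, method=method)  # type: ignore[arg-type]
            for level in cfg.levels:
                export_scatter(emb2, ds.labels_at_level(level), atlas.tree,
                               out_dir / f"scatter_{method}2_l{level}")
            export_zone_scatter(emb2, ds.label_l5, atlas.tree,
                                longitudinal_zone_map(atlas),
                                out_dir / f"scatter_{method}2_zones")
        for level in cfg.levels:
            truth = ds.labels_at_level(level)
            k = choose_k(truth)
            km_seed = _sub_seed(cfg.seed, _kmeans_code(method, dim, level))
            logger.info("kmeans %s dim=%s level=%d k=%d sub-seed %d",
                        method, dim, level, k, km_seed)
            try:
                res = kmeans(Y, k, restarts=cfg.kmeans_restarts, seed=km_seed)
            except GenoanatError as exc:
                rows.append(_error_row(cfg, method, dim, level, ds, str(exc)))
                n_failed += 1
                continue
            sc = score_all(truth, res.labels)
            rows.append({
                "dataset": cfg.dataset_name, "level": level, "method": method,
                "dim": dim if method != "raw" else ds.n_genes,
                "nmi": sc.nmi, "s_index": sc.s_index, "ari": sc.ari,
                "purity": sc.purity, "k": k, "n": ds.n_voxels,
                "seed": cfg.seed, "error": "",
            })
    if n_failed == len(rows):
        raise GenoanatError("every configured combination failed")
    report = pd.DataFrame(rows)
    if out_dir:
        write_report(report, out_dir / "report.tsv")
    logger.info("experiment finished in %.1fs", time.time() - t0)
    return report


def _representation(X: np.ndarray, method: str, dim: int,
                    cfg: ExperimentConfig) -> np.ndarray:
    if method == "raw":
        return np.asarray(X, dtype=float)
    if method == "pca":
        return run_pca(X, dim).Y
    tsne_cfg = replace(cfg.tsne, seed=_sub_seed(cfg.seed, _STAGE_CODES[("tsne", dim)]))
    return run_tsne(X, dim, tsne_cfg).Y


def _error_row(cfg: ExperimentConfig, method: str, dim: int, level: int,
               ds: VoxelDataset, msg: str) -> dict:
    return {
        "dataset": cfg.dataset_name, "level": level, "method": method,
        "dim": dim, "nmi": np.nan, "s_index": np.nan, "ari": np.nan,
        "purity": np.nan, "k": -1, "n": ds.n_voxels, "seed": cfg.seed,
        "error": msg,
    }


def write_report(report: pd.DataFrame, path: str | Path) -> None:
    """Write the report TSV with scores at 4 decimal places."""
    report.to_csv(path, sep="\t", index=False, float_format="%.4f")


def _write_embedding_tsv(Y: np.ndarray, path: Path) -> None:
    cols = {f"coordinate_{j + 1}": Y[:, j] for j in range(Y.shape[1])}
    pd.DataFrame({"voxel_index": np.arange(Y.shape[0]), **cols}).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# scatter exports


def export_scatter(emb: Embedding, labels: np.ndarray, tree: OntologyTree,
                   out_prefix: str | Path) -> tuple[Path, Path]:
    """Write a 2-D map as TSV (x, y, acronym, color_hex) and an SVG where
    each voxel is drawn as its structure acronym in its ontology color."""
    if emb.m != 2:
        raise DomainError(f"scatter export needs a 2-D embedding, got m={emb.m}")
    labels = np.asarray(labels)
    if labels.shape[0] != emb.n:
        raise ValidationError("labels length != number of map points")
    acr = np.array([tree[int(t)].acronym for t in labels])
    col = np.array([tree[int(t)].color for t in labels])
    out_prefix = Path(out_prefix)
    tsv_path = out_prefix.with_suffix(".tsv")
    pd.DataFrame({"x": emb.Y[:, 0], "y": emb.Y[:, 1],
                  "acronym": acr, "color_hex": col}).to_csv(
        tsv_path, sep="\t", index=False)
    svg_path = out_prefix.with_suffix(".svg")
    _draw_text_scatter(emb.Y, acr, col, svg_path)
    return tsv_path, svg_path


def export_zone_scatter(emb: Embedding, labels_l5: np.ndarray, tree: OntologyTree,
                        zone_map: Mapping[int, str],
                        out_prefix: str | Path) -> tuple[Path, Path]:
    """Like :func:`export_scatter`, but each point is drawn as its
    longitudinal-zone tag (e.g. F/B/A/R) rather than its structure acronym."""
    if emb.m != 2:
        raise DomainError(f"scatter export needs a 2-D embedding, got m={emb.m}")
    if not zone_map:
        raise ValidationError("zone_map is empty")
    labels_l5 = np.asarray(labels_l5)
    if labels_l5.shape[0] != emb.n:
        raise ValidationError("labels length != number of map points")
    missing = sorted({int(t) for t in labels_l5} - set(zone_map))
    if missing:
        raise ValidationError(f"level-5 terms missing from zone_map: {missing}")
    zones = np.array([zone_map[int(t)] for t in labels_l5])
    col = np.array([tree[int(t)].color for t in labels_l5])
    out_prefix = Path(out_prefix)
    tsv_path = out_prefix.with_suffix(".tsv")
    pd.DataFrame({"x": emb.Y[:, 0], "y": emb.Y[:, 1],
                  "zone": zones, "color_hex": col}).to_csv(
        tsv_path, sep="\t", index=False)
    svg_path = out_prefix.with_suffix(".svg")
    _draw_text_scatter(emb.Y, zones, col, svg_path)
    return tsv_path, svg_path


def _draw_text_scatter(Y: np.ndarray, texts: np.ndarray, colors: np.ndarray,
                       path: Path, max_points: int = 2000) -> None:
    """Render points as colored text markers. Down-samples deterministically
    when there are more points than an SVG can sensibly hold."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    idx = np.arange(Y.shape[0])
    if idx.size > max_points:
        idx = idx[:: int(np.ceil(idx.size / max_points))]
    fig, ax = plt.subplots(figsize=(8, 8))
    for i in idx:
        ax.text(Y[i, 0], Y[i, 1], str(texts[i]), color=colors[i],
                fontsize=5, ha="center", va="center")
    ax.set_xlim(Y[:, 0].min() - 1, Y[:, 0].max() + 1)
    ax.set_ylim(Y[:, 1].min() - 1, Y[:, 1].max() + 1)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(path, format="svg")
    plt.close(fig)
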