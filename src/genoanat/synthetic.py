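"""Seeded synthetic atlases: ontology + annotation + expression + truth.

The generator emulates the statistical structure the analysis assumes about
a developing-brain atlas, following the prosomeric picture of the neural
tube: a grid of transversal segments crossed with longitudinal zones.

* **Ontology** — a rooted tree subdivided level-wise: every term at level
  ``l`` has ``branching[l]`` children. Sibling colors share the parent's hue
  family, echoing atlas colormaps where related structures look alike.
* **Annotation** — the grid interior (inside a background margin) is
  partitioned recursively: levels 1–3 split contiguous blocks along x
  (transversal segments), levels 4–5 split along y (longitudinal zones,
  conventionally 4: roof/alar/basal/floor stacked superior→inferior), and
  deeper levels cycle through z, x, y. Every labeled voxel carries a term at
  the tree's maximum depth.
* **Expression** — each leaf structure gets a latent position from a
  hierarchical Gaussian walk down the tree (step sd ``signal_sd * 2**-level``),
  so structures sharing ancestors lie close on a ``latent_dim``-dimensional
  manifold. Non-marker genes respond to the latent position through a random
  linear map followed by a softplus (keeping energies nonnegative without
  truncation bias); marker genes are high in one randomly chosen structure's
  subtree and zero elsewhere, mimicking regionally restricted expression.
  Each voxel's expression vector is scaled by a lognormal brightness factor
  (sd ``voxel_scale_sd``) emulating the per-voxel signal-density variation
  of ISH expression energy — set it to 0 for noiseless structure means plus
  noise only. Gaussian observation noise (sd ``noise_sd``) is added last,
  with only the noise clipped at zero.

Identical specs (including the seed) produce bit-identical atlases.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass
from math import prod
from pathlib import Path
from typing import Sequence

import numpy as np

from .dataset import VoxelDataset, build_dataset
from .exceptions import SpecError
from .ontology import OntologyTerm, OntologyTree, ancestor_at_level
from .volumes import AnnotationVolume, ExpressionVolumeSet

__all__ = [
    "SyntheticSpec",
    "SyntheticAtlas",
    "generate_ontology",
    "generate_annotation",
    "generate_expression",
    "generate_atlas",
    "longitudinal_zone_map",
]

# default branching: 3 level-1 vesicles, 3x1 transversal segments each
# (9 segments total along x), 4x1 longitudinal zones along y, and a final
# left/right split so native annotations sit below level 5
DEFAULT_BRANCHING = (3, 3, 1, 4, 1, 2)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic atlas.

    Defaults mirror a scaled-down embryonic (E11.5-like) grid: a 24×20×12
    volume whose interior (~4000 voxels inside a 1-voxel background margin)
    is divided into 3 level-1 blocks × 9 transversal segments × 4
    longitudinal zones, with 200 genes.
    """

    dims: tuple[int, int, int] = (24, 20, 12)
    n_genes: int = 200
    branching: tuple[int, ...] = DEFAULT_BRANCHING
    n_transversal: int | None = None  # derived from branching[:3] if None
    n_longitudinal: int | None = None  # derived from branching[3:5] if None
    margin: int = 1
    signal_sd: float = 1.0
    noise_sd: float = 1.0
    marker_fraction: float = 0.15
    marker_mean: float = 4.0
    voxel_scale_sd: float = 0.6
    latent_dim: int = 10
    resolution_um: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or min(self.dims) < 1:
            raise SpecError(f"dims must be 3 positive ints, got {self.dims}")
        if not self.branching:
            raise SpecError("branching must be non-empty")
        if any(b < 1 for b in self.branching):
            raise SpecError(f"branching entries must be >= 1, got {self.branching}")
        if not 0.0 <= self.marker_fraction <= 1.0:
            raise SpecError(f"marker_fraction must be in [0, 1], got {self.marker_fraction}")
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be >= 0")
        if self.margin < 0:
            raise SpecError("margin must be >= 0")
        if self.n_genes < 1 or self.latent_dim < 1:
            raise SpecError("n_genes and latent_dim must be >= 1")
        tr = prod(self.branching[:3])
        lo = prod(self.branching[3:5]) if len(self.branching) > 3 else 1
        if self.n_transversal is not None and self.n_transversal != tr:
            raise SpecError(
                f"n_transversal={self.n_transversal} inconsistent with branching "
                f"(levels 1-3 give {tr} segments)"
            )
        if self.n_longitudinal is not None and (self.n_longitudinal < 1 or self.n_longitudinal != lo):
            raise SpecError(
                f"n_longitudinal={self.n_longitudinal} inconsistent with branching "
                f"(levels 4-5 give {lo} zones)"
            )

    @property
    def transversal_segments(self) -> int:
        return prod(self.branching[:3])

    @property
    def longitudinal_zones(self) -> int:
        return prod(self.branching[3:5]) if len(self.branching) > 3 else 1

    @property
    def max_level(self) -> int:
        return len(self.branching)


@dataclass
class SyntheticAtlas:
    """A generated atlas plus its per-level ground truth.

    ``truth[l]`` is a 3-D array of term ids at ontology level ``l`` (0 for
    background), for every level from 0 to the tree's max depth.
    """

    spec: SyntheticSpec
    tree: OntologyTree
    annotation: AnnotationVolume
    expression: ExpressionVolumeSet
    truth: dict[int, np.ndarray]

    def truth_labels(self, level: int) -> np.ndarray:
        """Ground-truth term ids at ``level`` for the labeled voxels, in the
        same row-major (z fastest) order that :func:`build_dataset` uses."""
        flat_leaf = self.annotation.labels.reshape(-1)
        return self.truth[level].reshape(-1)[flat_leaf != 0]

    def build_dataset(self, exclude_subtrees: Sequence[int] = (),
                      min_level: int = 5) -> VoxelDataset:
        return build_dataset(self.annotation, self.expression, self.tree,
                             exclude_subtrees=exclude_subtrees, min_level=min_level)

    def write_dir(self, out_dir: str | Path) -> None:
        """Write ontology JSON, annotation + expression NRRDs, truth TSV."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.tree.to_json(out / "ontology.json")
        self.annotation.to_nrrd(out / "annotation.nrrd")
        self.expression.to_nrrd_dir(out / "expression", self.spec.resolution_um)
        flat_leaf = self.annotation.labels.reshape(-1)
        keep = flat_leaf != 0
        xs, ys, zs = np.unravel_index(np.flatnonzero(keep), self.annotation.dims)
        with open(out / "truth.tsv", "w") as fh:
            fh.write("\t".join(["x", "y", "z"] + [f"level_{l}" for l in sorted(self.truth)]) + "\n")
            per_level = [self.truth[l].reshape(-1)[keep] for l in sorted(self.truth)]
            for i in range(keep.sum()):
                row = [str(xs[i]), str(ys[i]), str(zs[i])] + [str(int(v[i])) for v in per_level]
                fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# ontology


def _hex(h: float, s: float, v: float) -> str:
    r, g, b = colorsys.hsv_to_rgb(h % 1.0, s, v)
    return "#{:02x}{:02x}{:02x}".format(int(r * 255), int(g * 255), int(b * 255))


def generate_ontology(spec: SyntheticSpec) -> OntologyTree:
    """Build the level-wise subdivided tree defined by ``spec.branching``."""
    rng = np.random.default_rng([spec.seed, 0])
    terms: list[OntologyTerm] = [
        OntologyTerm(id=1, acronym="NP", name="neural plate (root)",
                     level=0, parent_id=None, color="#b0b0b0")
    ]
    hues = {1: 0.0}
    frontier = [1]
    next_id = 2
    for level, n_children in enumerate(spec.branching, start=1):
        new_frontier: list[int] = []
        for parent in frontier:
            for c in range(n_children):
                if level == 1:
                    # top-level vesicles get well-separated hues
                    hue = (len(new_frontier)) / max(spec.branching[0], 1)
                else:
                    hue = hues[parent] + rng.uniform(-0.5, 0.5) * 0.3 / 2**level
                tid = next_id
                next_id += 1
                hues[tid] = hue
                terms.append(
                    OntologyTerm(
                        id=tid,
                        acronym=f"S{level}.{len(new_frontier) + 1}",
                        name=f"structure level {level} #{len(new_frontier) + 1}",
                        level=level,
                        parent_id=parent,
                        color=_hex(hue, 0.55 + 0.3 * (level / len(spec.branching)),
                                   0.9 - 0.25 * rng.uniform()),
                    )
                )
                new_frontier.append(tid)
        frontier = new_frontier
    return OntologyTree(terms)


# ---------------------------------------------------------------------------
# annotation


def _axis_for_level(level: int) -> int:
    """Spatial axis split at each ontology level: x for transversal
    segments (levels 1-3), y for longitudinal zones (levels 4-5), then
    cycle z, x, y for finer subdivisions."""
    if level <= 3:
        return 0
    if level <= 5:
        return 1
    return (2, 0, 1)[(level - 6) % 3]


def _split_span(start: int, stop: int, parts: int) -> list[tuple[int, int]]:
    if stop - start < parts:
        raise SpecError(
            f"cannot split {stop - start} voxels into {parts} contiguous segments"
        )
    edges = np.linspace(start, stop, parts + 1).round().astype(int)
    return [(int(edges[i]), int(edges[i + 1])) for i in range(parts)]


def generate_annotation(spec: SyntheticSpec, tree: OntologyTree) -> AnnotationVolume:
    """Partition the grid interior into the tree's leaf structures."""
    labels = np.zeros(spec.dims, dtype=np.int64)
    m = spec.margin
    interior = tuple((m, d - m) for d in spec.dims)
    if any(hi - lo < 1 for lo, hi in interior):
        raise SpecError(f"margin {m} leaves no interior for dims {spec.dims}")

    # depth-first: each term owns a box; children split it along one axis
    stack: list[tuple[int, tuple[tuple[int, int], ...]]] = [(tree.root_id, interior)]
    while stack:
        tid, box = stack.pop()
        kids = tree.children(tid)
        if not kids:
            (x0, x1), (y0, y1), (z0, z1) = box
            labels[x0:x1, y0:y1, z0:z1] = tid
            continue
        axis = _axis_for_level(tree[tid].level + 1)
        spans = _split_span(box[axis][0], box[axis][1], len(kids))
        for kid, span in zip(sorted(kids), spans):
            kid_box = tuple(span if a == axis else box[a] for a in range(3))
            stack.append((kid, kid_box))
    return AnnotationVolume(labels=labels, resolution_um=spec.resolution_um)


# ---------------------------------------------------------------------------
# expression


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _latent_positions(spec: SyntheticSpec, tree: OntologyTree,
                      rng: np.random.Generator) -> dict[int, np.ndarray]:
    """Hierarchical Gaussian walk: child = parent + N(0, signal_sd * 2**-level)."""
    z: dict[int, np.ndarray] = {tree.root_id: np.zeros(spec.latent_dim)}
    for term in sorted(tree, key=lambda t: (t.level, t.id)):
        if term.parent_id is None:
            continue
        step = spec.signal_sd * 2.0 ** (-term.level)
        z[term.id] = z[term.parent_id] + rng.normal(0.0, step, spec.latent_dim)
    return z


def generate_expression(spec: SyntheticSpec, tree: OntologyTree,
                        ann: AnnotationVolume) -> ExpressionVolumeSet:
    """Draw per-gene expression-energy volumes over the annotated grid."""
    rng = np.random.default_rng([spec.seed, 2])
    leaves = sorted(tid for tid in (t.id for t in tree) if not tree.children(tid))
    leaf_index = {tid: i for i, tid in enumerate(leaves)}
    z = _latent_positions(spec, tree, rng)
    Z = np.stack([z[tid] for tid in leaves])  # (n_leaves, latent_dim)

    d = spec.n_genes
    n_markers = int(round(spec.marker_fraction * d))
    marker_genes = rng.choice(d, size=n_markers, replace=False) if n_markers else np.array([], dtype=int)
    is_marker = np.zeros(d, dtype=bool)
    is_marker[marker_genes] = True

    # structure-mean matrix (n_leaves, d)
    W = rng.normal(0.0, 1.0, (spec.latent_dim, d))
    b = rng.normal(0.0, 1.0, d)
    means = _softplus(Z @ W + b)

    non_root = sorted(t.id for t in tree if t.parent_id is not None)
    leaf_sets = {tid: _subtree_leaves(tree, tid, leaf_index) for tid in non_root}
    for g in marker_genes:
        target = int(rng.choice(non_root))
        col = np.zeros(len(leaves))
        col[leaf_sets[target]] = spec.marker_mean
        means[:, g] = col

    flat_leaf = ann.labels.reshape(-1)
    labeled = flat_leaf != 0
    rows = np.array([leaf_index[int(t)] for t in flat_leaf[labeled]])

    vols = np.zeros((d, flat_leaf.size))
    base = means[rows]  # (n_labeled, d)
    if spec.voxel_scale_sd > 0:
        # per-voxel multiplicative brightness (signal-density variation of
        # the assay); scales the whole expression vector, not the noise
        scale = np.exp(rng.normal(0.0, spec.voxel_scale_sd, base.shape[0]))
        base = base * scale[:, None]
    noise = rng.normal(0.0, spec.noise_sd, base.shape) if spec.noise_sd > 0 else 0.0
    vols[:, labeled] = np.maximum(base + noise, 0.0).T
    gene_ids = [f"gene_{j:04d}" for j in range(d)]
    return ExpressionVolumeSet(gene_ids=gene_ids,
                               volumes=vols.reshape((d,) + spec.dims))


def _subtree_leaves(tree: OntologyTree, root: int, leaf_index: dict[int, int]) -> list[int]:
    out: list[int] = []
    stack = [root]
    while stack:
        tid = stack.pop()
        kids = tree.children(tid)
        if kids:
            stack.extend(kids)
        else:
            out.append(leaf_index[tid])
    return out


ZONE_TAGS_4 = ("R", "A", "B", "F")  # roof, alar, basal, floor, superior->inferior


def longitudinal_zone_map(atlas: SyntheticAtlas) -> dict[int, str]:
    """Map every level-5 term to its longitudinal-zone tag.

    The zone of a level-5 band is its rank along y within its level-3
    transversal segment (bands were laid out superior->inferior at
    generation time). With the conventional four zones the tags are
    R/A/B/F (roof, alar, basal, floor); otherwise Z0..Z{n-1}.
    """
    tree = atlas.tree
    n_zones = atlas.spec.longitudinal_zones
    tags = ZONE_TAGS_4 if n_zones == 4 else tuple(f"Z{i}" for i in range(n_zones))
    out: dict[int, str] = {}
    for term in tree.terms_at_level(5):
        l3 = ancestor_at_level(tree, term.id, 3)
        siblings = sorted(
            t.id for t in tree.terms_at_level(5)
            if ancestor_at_level(tree, t.id, 3) == l3
        )
        out[term.id] = tags[siblings.index(term.id) % len(tags)]
    return out


# ---------------------------------------------------------------------------
# assembly


def generate_atlas(spec: SyntheticSpec) -> SyntheticAtlas:
    """Generate the full atlas and per-level ground truth for one spec."""
    tree = generate_ontology(spec)
    ann = generate_annotation(spec, tree)
    expr = generate_expression(spec, tree, ann)

    truth: dict[int, np.ndarray] = {}
    leaf_ids = np.unique(ann.labels)
    leaf_ids = leaf_ids[leaf_ids != 0]
    for level in range(tree.max_level + 1):
        lut = {0: 0}
        for tid in leaf_ids:
            lut[int(tid)] = ancestor_at_level(tree, int(tid), level)
        truth[level] = np.vectorize(lut.__getitem__, otypes=[np.int64])(ann.labels)
    return SyntheticAtlas(spec=spec, tree=tree, annotation=ann,
                          expression=expr, truth=truth)
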