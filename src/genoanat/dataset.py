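"""Assembly of the analysis-ready voxel × gene matrix.

Three filters turn raw atlas volumes into the matrix the embedding and
clustering stages consume:

1. background voxels (label 0) are dropped;
2. voxels whose annotation lies inside any excluded subtree (e.g. the
   spinal cord, when the goal is brain anatomy) are dropped;
3. voxels annotated more coarsely than a minimum ontology level (default 5)
   are dropped, so every retained voxel can be up-propagated to levels
   5, 3 and 1.

Surviving voxels are flattened in row-major (x, y, z) order — z fastest —
so ``coords`` lets any per-voxel quantity be painted back into the volume.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import DomainError, IntegrityError, ShapeError
from .ontology import OntologyTree, ancestor_at_level
from .volumes import AnnotationVolume, ExpressionVolumeSet

__all__ = ["VoxelDataset", "build_dataset"]


@dataclass
class VoxelDataset:
    """Filtered expression matrix with multi-level anatomical labels.

    Attributes
    ----------
    X : (n, d) float array
        Expression energies, finite and nonnegative.
    gene_ids : list of str
    coords : (n, 3) int array
        0-based (x, y, z) voxel indices into the source grid.
    label_native : (n,) int array
        The deepest (as-annotated) ontology term per voxel.
    label_l1, label_l3, label_l5 : (n,) int arrays
        Up-propagated term ids at ontology levels 1, 3 and 5.
    """

    X: np.ndarray
    gene_ids: list[str]
    coords: np.ndarray
    label_native: np.ndarray
    label_l1: np.ndarray
    label_l3: np.ndarray
    label_l5: np.ndarray

    def __post_init__(self) -> None:
        n = self.X.shape[0]
        for name in ("coords", "label_native", "label_l1", "label_l3", "label_l5"):
            if getattr(self, name).shape[0] != n:
                raise ShapeError(f"{name} has {getattr(self, name).shape[0]} rows, X has {n}")
        if self.X.ndim != 2 or self.X.shape[1] != len(self.gene_ids):
            raise ShapeError(
                f"X is {self.X.shape}, expected (n, {len(self.gene_ids)})"
            )

    @property
    def n_voxels(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]

    def labels_at_level(self, level: int) -> np.ndarray:
        try:
            return {1: self.label_l1, 3: self.label_l3, 5: self.label_l5}[level]
        except KeyError:
            raise DomainError(f"labels stored for levels 1/3/5 only, not {level}") from None

    # -- TSV interchange ----------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "x": self.coords[:, 0],
                "y": self.coords[:, 1],
                "z": self.coords[:, 2],
                "label_native": self.label_native,
                "label_l1": self.label_l1,
                "label_l3": self.label_l3,
                "label_l5": self.label_l5,
            }
        )
        for j, g in enumerate(self.gene_ids):
            df[g] = self.X[:, j]
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "VoxelDataset":
        df = pd.read_csv(path, sep="\t")
        meta = ["x", "y", "z", "label_native", "label_l1", "label_l3", "label_l5"]
        genes = [c for c in df.columns if c not in meta]
        return cls(
            X=df[genes].to_numpy(dtype=float),
            gene_ids=genes,
            coords=df[["x", "y", "z"]].to_numpy(dtype=np.int64),
            label_native=df["label_native"].to_numpy(dtype=np.int64),
            label_l1=df["label_l1"].to_numpy(dtype=np.int64),
            label_l3=df["label_l3"].to_numpy(dtype=np.int64),
            label_l5=df["label_l5"].to_numpy(dtype=np.int64),
        )


def _subtree_ids(tree: OntologyTree, roots: Sequence[int]) -> set[int]:
    out: set[int] = set()
    stack = list(roots)
    while stack:
        tid = stack.pop()
        if tid in out:
            continue
        out.add(tid)
        stack.extend(tree.children(tid))
    return out


def build_dataset(
    ann: AnnotationVolume,
    expr: ExpressionVolumeSet,
    tree: OntologyTree,
    exclude_subtrees: Sequence[int] = (),
    min_level: int = 5,
) -> VoxelDataset:
    """Filter voxels and assemble the n × d expression matrix.

    A voxel is retained iff its annotation is nonzero, resolves in ``tree``
    at level >= ``min_level``, and does not fall inside any subtree rooted at
    an id in ``exclude_subtrees``. Labels at levels 1/3/5 are filled by
    up-propagation along the unique root path.

    Raises
    ------
    ShapeError
        If annotation and expression grids disagree.
    IntegrityError
        If a nonzero annotation id is absent from the tree.
    """
    if ann.dims != expr.dims:
        raise ShapeError(f"annotation dims {ann.dims} != expression dims {expr.dims}")
    excluded = _subtree_ids(tree, list(exclude_subtrees))

    flat = ann.labels.reshape(-1)  # row-major: z fastest
    present = np.unique(flat)
    present = present[present != 0]
    missing = [int(t) for t in present if int(t) not in tree]
    if missing:
        raise IntegrityError(f"annotation ids not in ontology: {missing[:10]}")

    keep_term = {
        int(t): (tree[int(t)].level >= min_level and int(t) not in excluded)
        for t in present
    }
    keep = np.array([t != 0 and keep_term[int(t)] for t in flat], dtype=bool)
    idx = np.flatnonzero(keep)
    xs, ys, zs = np.unravel_index(idx, ann.dims)

    native = flat[idx].astype(np.int64)
    anc_cache: dict[tuple[int, int], int] = {}

    def anc(t: int, lvl: int) -> int:
        key = (t, lvl)
        if key not in anc_cache:
            anc_cache[key] = ancestor_at_level(tree, t, lvl)
        return anc_cache[key]

    l1 = np.array([anc(int(t), 1) for t in native], dtype=np.int64)
    l3 = np.array([anc(int(t), 3) for t in native], dtype=np.int64)
    l5 = np.array([anc(int(t), 5) for t in native], dtype=np.int64)

    X = expr.volumes.reshape(expr.n_genes, -1)[:, idx].T.astype(float)
    return VoxelDataset(
        X=np.ascontiguousarray(X),
        gene_ids=list(expr.gene_ids),
        coords=np.column_stack([xs, ys, zs]).astype(np.int64),
        label_native=native,
        label_l1=l1,
        label_l3=l3,
        label_l5=l5,
    )
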