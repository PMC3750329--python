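"""Annotation and expression volumes on the reference voxel grid.

Both volume types share one dense 3-D grid whose axes follow the reference
atlas convention: x = anterior→posterior, y = superior→inferior,
z = left→right. Arrays are indexed ``[x, y, z]`` with 0-based indices.

On-disk formats: NRRD (one file per gene plus one annotation volume; read
and written through SimpleITK) and a plain-text CSV fallback
(``voxel_x,voxel_y,voxel_z,value``) for small fixtures. SimpleITK stores
arrays with the fastest-varying axis first, so NRRD round-trips transpose
between its (z, y, x) numpy layout and our (x, y, z) layout.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .exceptions import ShapeError, ValidationError

__all__ = ["AnnotationVolume", "ExpressionVolumeSet"]


def _check_dims(arr: np.ndarray, name: str) -> None:
    if arr.ndim != 3:
        raise ShapeError(f"{name} must be 3-D, got shape {arr.shape}")
    if min(arr.shape) < 1:
        raise ShapeError(f"{name} dims must be positive, got {arr.shape}")


@dataclass
class AnnotationVolume:
    """Per-voxel ontology labels on the 3-D grid.

    ``labels[x, y, z]`` is an ontology term id, or 0 for background /
    unannotated voxels.
    """

    labels: np.ndarray
    resolution_um: float = 100.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        _check_dims(self.labels, "annotation labels")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValidationError(
                f"annotation labels must be integers, got dtype {self.labels.dtype}"
            )
        if (self.labels < 0).any():
            raise ValidationError("annotation labels must be >= 0")
        if self.resolution_um <= 0:
            raise ValidationError("resolution_um must be positive")

    @property
    def dims(self) -> tuple[int, int, int]:
        return tuple(self.labels.shape)  # type: ignore[return-value]

    # -- I/O ----------------------------------------------------------------
    def to_nrrd(self, path: str | Path) -> None:
        _write_nrrd(self.labels.astype(np.int32), self.resolution_um, path)

    @classmethod
    def from_nrrd(cls, path: str | Path) -> "AnnotationVolume":
        arr, res = _read_nrrd(path)
        return cls(labels=np.rint(arr).astype(np.int64), resolution_um=res)

    def to_csv(self, path: str | Path) -> None:
        _write_voxel_csv(self.labels, path, fmt="%d")

    @classmethod
    def from_csv(cls, path: str | Path, dims: tuple[int, int, int],
                 resolution_um: float = 100.0) -> "AnnotationVolume":
        arr = _read_voxel_csv(path, dims).astype(np.int64)
        return cls(labels=arr, resolution_um=resolution_um)


@dataclass
class ExpressionVolumeSet:
    """One nonnegative expression-energy volume per gene, on a shared grid."""

    gene_ids: list[str]
    volumes: np.ndarray  # (d, x, y, z)

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.volumes.ndim != 4:
            raise ShapeError(
                f"expression volumes must be (genes, x, y, z), got {self.volumes.shape}"
            )
        if len(self.gene_ids) != self.volumes.shape[0]:
            raise ShapeError(
                f"{len(self.gene_ids)} gene ids vs {self.volumes.shape[0]} volumes"
            )
        if not np.isfinite(self.volumes).all():
            raise ValidationError("expression energies must be finite")
        if (self.volumes < 0).any():
            raise ValidationError("expression energies must be >= 0")

    @property
    def n_genes(self) -> int:
        return self.volumes.shape[0]

    @property
    def dims(self) -> tuple[int, int, int]:
        return tuple(self.volumes.shape[1:])  # type: ignore[return-value]

    # -- I/O ----------------------------------------------------------------
    def to_nrrd_dir(self, out_dir: str | Path, resolution_um: float = 100.0) -> None:
        """Write one ``<gene>.nrrd`` per gene under ``out_dir``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for gene, vol in zip(self.gene_ids, self.volumes):
            _write_nrrd(vol.astype(np.float32), resolution_um, out / f"{gene}.nrrd")

    @classmethod
    def from_nrrd_dir(cls, in_dir: str | Path) -> "ExpressionVolumeSet":
        paths = sorted(Path(in_dir).glob("*.nrrd"))
        if not paths:
            raise ValidationError(f"no .nrrd files found in {in_dir}")
        vols = [_read_nrrd(p)[0] for p in paths]
        return cls(gene_ids=[p.stem for p in paths], volumes=np.stack(vols))


# ---------------------------------------------------------------------------
# low-level readers/writers


def _write_nrrd(arr_xyz: np.ndarray, resolution_um: float, path: str | Path) -> None:
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(np.ascontiguousarray(arr_xyz.transpose(2, 1, 0)))
    img.SetSpacing((resolution_um,) * 3)
    sitk.WriteImage(img, str(path))


def _read_nrrd(path: str | Path) -> tuple[np.ndarray, float]:
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return np.asarray(arr), float(img.GetSpacing()[0])


def _write_voxel_csv(arr: np.ndarray, path: str | Path, fmt: str = "%.6g") -> None:
    xs, ys, zs = np.unravel_index(np.arange(arr.size), arr.shape)
    with open(path, "w") as fh:
        fh.write("voxel_x,voxel_y,voxel_z,value\n")
        vals = arr.reshape(-1)
        for x, y, z, v in zip(xs, ys, zs, vals):
            fh.write(f"{x},{y},{z},{fmt % v}\n")


def _read_voxel_csv(path: str | Path, dims: tuple[int, int, int]) -> np.ndarray:
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    arr = np.zeros(dims, dtype=float)
    ix = data[:, 0].astype(int)
    iy = data[:, 1].astype(int)
    iz = data[:, 2].astype(int)
    if (ix >= dims[0]).any() or (iy >= dims[1]).any() or (iz >= dims[2]).any():
        raise ShapeError(f"CSV voxel indices exceed dims {dims}")
    arr[ix, iy, iz] = data[:, 3]
    return arr
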