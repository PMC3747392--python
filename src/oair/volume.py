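"""The 3D scalar volume container shared by every stage.

A :class:`Volume` is a 3D grid of real intensities together with the
physical voxel spacing (mm per axis) and the world coordinate of the
centre of voxel ``(0, 0, 0)``.  The coordinate convention, shared by the
whole package, is:

* 0-based voxel indices, samples located at voxel centres;
* continuous voxel coordinate ``x`` equals the index at grid points;
* world (mm) = origin + index * spacing, axes aligned with the array axes
  (x = axis 0, left-right; y = axis 1; z = axis 2, slice direction).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np


@dataclass
class Volume:
    """A 3D intensity grid with physical metadata.

    Parameters
    ----------
    data
        3D array of finite intensities (arbitrary units).
    spacing
        Per-axis voxel size in mm, all strictly positive.
    origin
        World coordinates (mm) of the centre of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got {self.data.ndim}D")
        if any(n < 2 for n in self.data.shape):
            raise ValueError(f"each axis needs length >= 2, got {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        if len(self.origin) != 3:
            raise ValueError("origin must have 3 components")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def world_center(self) -> np.ndarray:
        """World coordinate (mm) of the geometric centre of the grid."""
        idx = (np.asarray(self.shape, dtype=float) - 1.0) / 2.0
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map continuous voxel coordinates (..., 3) to world mm."""
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def world_to_voxel(self, pts: np.ndarray) -> np.ndarray:
        """Map world mm coordinates (..., 3) to continuous voxel coordinates."""
        pts = np.asarray(pts, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.spacing, self.origin)

    # ---------------------------------------------------------------- I/O

    def to_nifti(self, path: str | Path) -> None:
        """Write as NIfTI-1; spacing goes into the header pixdim."""
        import nibabel as nib

        affine = np.diag(list(self.spacing) + [1.0])
        affine[:3, 3] = self.origin
        img = nib.Nifti1Image(self.data.astype(np.float32), affine)
        img.header.set_zooms(self.spacing)
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "Volume":
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj, dtype=np.float64)
        zooms = img.header.get_zooms()[:3]
        origin = tuple(float(v) for v in img.affine[:3, 3])
        return cls(data, tuple(float(z) for z in zooms), origin)

    def to_raw(self, path: str | Path) -> None:
        """Raw float32 + JSON sidecar fallback (``path`` without suffix)."""
        path = Path(path)
        self.data.astype(np.float32).tofile(path.with_suffix(".raw"))
        meta = {"shape": list(self.shape), "spacing": list(self.spacing),
                "origin": list(self.origin), "dtype": "float32", "order": "C"}
        path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def from_raw(cls, path: str | Path) -> "Volume":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        data = np.fromfile(path.with_suffix(".raw"), dtype=np.float32)
        data = data.reshape(meta["shape"])
        return cls(data, tuple(meta["spacing"]), tuple(meta["origin"]))


def same_grid(a: Volume, b: Volume, tol: float = 1e-9) -> bool:
    """True when two volumes share shape, spacing and origin."""
    return (
        a.shape == b.shape
        and np.allclose(a.spacing, b.spacing, atol=tol)
        and np.allclose(a.origin, b.origin, atol=tol)
    )


def require_same_grid(a: Volume, b: Volume) -> None:
    if not same_grid(a, b):
        raise ValueError(
            f"volumes must share a grid: {a.shape}/{a.spacing} vs {b.shape}/{b.spacing}"
        )
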