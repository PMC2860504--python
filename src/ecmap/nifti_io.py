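"""NIfTI-1 input/output and mask geometry.

All other modules operate on flat per-voxel vectors/matrices; this module owns
the mapping between those flat vectors and the 3D grid.  In-mask voxels are
ordered by ascending Fortran-style linear index (x varies fastest), which is
stable across loads of the same mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

#: absolute per-entry tolerance when comparing affines of two grids
AFFINE_ATOL = 1e-4

#: minimum number of time points accepted for a 4D series
MIN_TIMEPOINTS = 8


class GridMismatchError(ValueError):
    """Raised when two volumes do not live on the same grid."""


class EmptyMaskError(ValueError):
    """Raised when a mask contains no usable voxels."""


@dataclass(frozen=True)
class MaskGeometry:
    """Binary 3D mask plus the bijection between grid coordinates and 0..n-1.

    Attributes
    ----------
    shape : tuple of int
        Grid dimensions (3 positive integers).
    voxel_size : tuple of float
        Voxel edge lengths in mm, derived from the affine.
    affine : (4, 4) ndarray
        Grid-to-world transform.
    inside : (i, j, k) bool ndarray
        True for in-mask voxels.
    coords : (n, 3) int ndarray
        Grid coordinates of in-mask voxels in the canonical order.
    """

    shape: tuple
    voxel_size: tuple
    affine: np.ndarray
    inside: np.ndarray
    coords: np.ndarray = field(repr=False)

    @property
    def n_voxels(self) -> int:
        return self.coords.shape[0]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    @classmethod
    def from_mask(cls, inside: np.ndarray, affine: np.ndarray) -> "MaskGeometry":
        inside = np.asarray(inside).astype(bool)
        if inside.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {inside.shape}")
        if not inside.any():
            raise EmptyMaskError("mask contains no voxels")
        affine = np.asarray(affine, dtype=float)
        voxel_size = tuple(np.sqrt((affine[:3, :3] ** 2).sum(axis=0)).tolist())
        coords = np.argwhere(inside)
        # canonical order: ascending linear index with x fastest (Fortran order)
        lin = np.ravel_multi_index((coords[:, 0], coords[:, 1], coords[:, 2]),
                                   inside.shape, order="F")
        coords = coords[np.argsort(lin)]
        return cls(shape=tuple(inside.shape), voxel_size=voxel_size,
                   affine=affine, inside=inside, coords=coords)

    def index_of(self, coord) -> int:
        """Map an in-mask grid coordinate to its flat index (bijection)."""
        hits = np.flatnonzero((self.coords == np.asarray(coord)).all(axis=1))
        if hits.size == 0:
            raise KeyError(f"coordinate {tuple(coord)} is not inside the mask")
        return int(hits[0])

    def coordinate_of(self, index: int):
        """Inverse of :meth:`index_of`."""
        return tuple(int(c) for c in self.coords[index])

    def subset(self, keep: np.ndarray) -> "MaskGeometry":
        """Return a geometry restricted to ``keep`` (bool over the n voxels)."""
        keep = np.asarray(keep, dtype=bool)
        if keep.shape != (self.n_voxels,):
            raise ValueError("keep must be a boolean n-vector")
        inside = np.zeros(self.shape, dtype=bool)
        kept = self.coords[keep]
        if kept.shape[0] == 0:
            raise EmptyMaskError("mask is empty after filtering")
        inside[kept[:, 0], kept[:, 1], kept[:, 2]] = True
        return MaskGeometry.from_mask(inside, self.affine)

    def embed(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Place an n-vector into a 3D array with `fill` outside the mask."""
        values = np.asarray(values)
        if values.shape != (self.n_voxels,):
            raise ValueError(
                f"expected {self.n_voxels} values, got {values.shape}")
        vol = np.full(self.shape, fill, dtype=float)
        vol[self.coords[:, 0], self.coords[:, 1], self.coords[:, 2]] = values
        return vol

    def extract(self, volume: np.ndarray) -> np.ndarray:
        """Read in-mask values from a 3D (or 3D+time) array in canonical order."""
        volume = np.asarray(volume)
        if volume.shape[:3] != self.shape:
            raise GridMismatchError(
                f"volume shape {volume.shape[:3]} does not match "
                f"mask shape {self.shape}")
        return volume[self.coords[:, 0], self.coords[:, 1], self.coords[:, 2]]


@dataclass
class MaskedSeries:
    """An n_voxels x T time-series matrix bound to a mask geometry."""

    geometry: MaskGeometry
    data: np.ndarray
    tr_seconds: float

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2D (n_voxels x T) matrix")
        if self.data.shape[0] != self.geometry.n_voxels:
            raise ValueError(
                f"data has {self.data.shape[0]} rows but geometry has "
                f"{self.geometry.n_voxels} voxels")
        if self.data.shape[1] < MIN_TIMEPOINTS:
            raise ValueError(
                f"need at least {MIN_TIMEPOINTS} time points, "
                f"got {self.data.shape[1]}")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


def _check_same_grid(shape_a, affine_a, shape_b, affine_b, what_a, what_b):
    if tuple(shape_a) != tuple(shape_b):
        raise GridMismatchError(
            f"{what_a} grid {tuple(shape_a)} does not match "
            f"{what_b} grid {tuple(shape_b)}")
    if not np.allclose(affine_a, affine_b, atol=AFFINE_ATOL, rtol=0):
        raise GridMismatchError(
            f"{what_a} and {what_b} affines differ by more than {AFFINE_ATOL}")


def filter_usable_voxels(series: MaskedSeries) -> MaskedSeries:
    """Drop voxels with non-finite values or zero temporal variance.

    Correlation is undefined for such voxels, so they are removed from the
    mask; the number removed is logged.  Idempotent.
    """
    finite = np.isfinite(series.data).all(axis=1)
    var = np.zeros(series.n_voxels)
    var[finite] = series.data[finite].var(axis=1)
    keep = finite & (var > 0)
    n_bad = int((~keep).sum())
    if n_bad == 0:
        return series
    logger.warning("removed %d voxel(s) with zero variance or non-finite "
                   "values from the mask", n_bad)
    if not keep.any():
        raise EmptyMaskError("no usable voxels remain after filtering")
    return MaskedSeries(geometry=series.geometry.subset(keep),
                        data=series.data[keep],
                        tr_seconds=series.tr_seconds)


def load_series(bold_path, mask_path, tr_seconds: float | None = None) -> MaskedSeries:
    """Load a 4D series and a 3D mask from NIfTI files.

    Rows are ordered by the mask bijection.  Voxels with zero variance or
    non-finite values are removed from the mask (with a logged count).  The
    repetition time is taken from the 4th header zoom unless overridden.
    """
    bold_img = nib.load(str(bold_path))
    mask_img = nib.load(str(mask_path))
    if bold_img.ndim != 4:
        raise ValueError(f"expected 4D series, got {bold_img.ndim}D")
    if mask_img.ndim != 3:
        raise ValueError(f"expected 3D mask, got {mask_img.ndim}D")
    _check_same_grid(bold_img.shape[:3], bold_img.affine,
                     mask_img.shape, mask_img.affine, "series", "mask")
    geometry = MaskGeometry.from_mask(mask_img.get_fdata() != 0, mask_img.affine)
    data = geometry.extract(np.asarray(bold_img.dataobj))
    if tr_seconds is None:
        zooms = bold_img.header.get_zooms()
        tr_seconds = float(zooms[3]) if len(zooms) > 3 else 0.0
        if tr_seconds <= 0:
            raise ValueError(
                "repetition time missing from header; pass tr_seconds")
    series = MaskedSeries(geometry=geometry, data=np.asarray(data, dtype=float),
                          tr_seconds=float(tr_seconds))
    return filter_usable_voxels(series)


def load_map(map_path, mask_path) -> tuple[np.ndarray, MaskGeometry]:
    """Load a 3D map as an n-vector in mask order."""
    map_img = nib.load(str(map_path))
    mask_img = nib.load(str(mask_path))
    _check_same_grid(map_img.shape[:3], map_img.affine,
                     mask_img.shape, mask_img.affine, "map", "mask")
    geometry = MaskGeometry.from_mask(mask_img.get_fdata() != 0, mask_img.affine)
    return geometry.extract(map_img.get_fdata()), geometry


def save_map(values: np.ndarray, geometry: MaskGeometry, path) -> None:
    """Write an n-vector as a 3D NIfTI (float32 on disk, zeros outside mask)."""
    values = np.asarray(values, dtype=np.float32)
    if values.shape != (geometry.n_voxels,):
        raise ValueError(
            f"expected {geometry.n_voxels} values, got shape {values.shape}")
    vol = np.zeros(geometry.shape, dtype=np.float32)
    vol[geometry.coords[:, 0], geometry.coords[:, 1], geometry.coords[:, 2]] = values
    img = nib.Nifti1Image(vol, geometry.affine)
    img.header["descrip"] = b"ecmap map; background=0"
    nib.save(img, str(path))


def save_mask(geometry: MaskGeometry, path) -> None:
    img = nib.Nifti1Image(geometry.inside.astype(np.uint8), geometry.affine)
    nib.save(img, str(path))


def save_series(series: MaskedSeries, path) -> None:
    """Write a MaskedSeries as a 4D NIfTI with zeros outside the mask."""
    g = series.geometry
    vol = np.zeros(g.shape + (series.n_timepoints,), dtype=np.float32)
    vol[g.coords[:, 0], g.coords[:, 1], g.coords[:, 2], :] = series.data
    img = nib.Nifti1Image(vol, g.affine)
    img.header.set_zooms(tuple(g.voxel_size) + (series.tr_seconds,))
    nib.save(img, str(path))
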