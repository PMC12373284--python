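"""Readers/writers and spatial sampling for the formats the pipeline touches.

Volumes are NIfTI-1 (via nibabel), streamlines are TRK/TCK (via
nibabel.streamlines), profiles go to a tidy long CSV.  All geometry is
expressed in world millimeters (RAS) after loading; the affine maps
0-based integer voxel indices to the world coordinates of voxel centers
(NIfTI convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates
from scipy.spatial import cKDTree

from .core_geometry import DegenerateStreamlineError, Tractogram, as_streamline

logger = logging.getLogger(__name__)

__all__ = [
    "ScalarVolume",
    "MaskVolume",
    "TIDY_COLUMNS",
    "read_scalar_volume",
    "read_mask_volume",
    "write_volume",
    "read_tractogram",
    "write_tractogram",
    "world_to_voxel",
    "nearest_voxel_indices",
    "sample_volume",
    "min_distance_to_mask",
    "write_tidy_csv",
    "read_tidy_csv",
]

TIDY_COLUMNS = ["subject_id", "tract_name", "node_id", "metric", "value"]


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError("affine must be 4x4")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine must be invertible")
    return affine


@dataclass
class ScalarVolume:
    """A 3-D scalar map (e.g. FA, MD, MK) with its voxel-to-world affine."""

    data: np.ndarray
    affine: np.ndarray
    name: str = "scalar"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3-D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"volume '{self.name}' contains non-finite values")
        self.affine = _check_affine(self.affine)


@dataclass
class MaskVolume:
    """A binary ROI ({0,1}) or probability map ([0,1]) on a 3-D grid.

    ROI masks (``kind='roi'``) are binarized nonzero -> 1 on construction;
    probability maps (``kind='prob'``) must lie in [0, 1].
    """

    data: np.ndarray
    affine: np.ndarray
    name: str = "mask"
    kind: str = "roi"
    # KD-tree over mask-voxel world centers, built lazily.
    _tree: cKDTree | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3:
            raise ValueError(f"mask must be 3-D, got shape {data.shape}")
        self.affine = _check_affine(self.affine)
        if self.kind == "roi":
            self.data = (data != 0).astype(np.uint8)
        elif self.kind == "prob":
            if data.min() < 0 or data.max() > 1:
                raise ValueError(
                    f"probability map '{self.name}' has values outside [0, 1]"
                )
            self.data = data
        else:
            raise ValueError(f"unknown mask kind: {self.kind!r}")

    def voxel_centers(self) -> np.ndarray:
        """World-mm coordinates of all nonzero voxel centers."""
        idx = np.argwhere(self.data != 0)
        if idx.size == 0:
            return np.empty((0, 3))
        return nib.affines.apply_affine(self.affine, idx)

    def center_tree(self) -> cKDTree:
        if self._tree is None:
            centers = self.voxel_centers()
            if centers.shape[0] == 0:
                raise ValueError(f"mask '{self.name}' is empty")
            self._tree = cKDTree(centers)
        return self._tree


# ---------------------------------------------------------------------------
# NIfTI volumes


def read_scalar_volume(path, name: str | None = None) -> ScalarVolume:
    img = nib.load(str(path))
    return ScalarVolume(
        data=np.asarray(img.dataobj, dtype=float),
        affine=img.affine,
        name=name or str(path),
    )


def read_mask_volume(path, name: str | None = None, kind: str = "roi") -> MaskVolume:
    img = nib.load(str(path))
    return MaskVolume(
        data=np.asarray(img.dataobj, dtype=float),
        affine=img.affine,
        name=name or str(path),
        kind=kind,
    )


def write_volume(vol: ScalarVolume | MaskVolume, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), vol.affine), str(path))


# ---------------------------------------------------------------------------
# Tractograms (TRK / TCK)


def read_tractogram(path, reference: ScalarVolume | None = None) -> Tractogram:
    """Load a TRK or TCK file into world-mm RAS streamlines.

    nibabel resolves the on-disk space from the TRK header; TCK files are
    already in world mm.  Degenerate streamlines (fewer than 2 points or
    zero length) are filtered out with a logged count.

    ``reference`` supplies the grid affine/shape for TCK files, which do
    not carry one; when omitted, an identity affine is recorded.
    """
    path = str(path)
    try:
        tfile = nib.streamlines.load(path)
    except Exception as exc:  # nibabel raises various header errors
        raise IOError(f"could not read tractogram {path}: {exc}") from exc
    raw = [np.asarray(s, dtype=float) for s in tfile.tractogram.streamlines]

    kept, n_dropped = [], 0
    for sl in raw:
        if sl.ndim != 2 or sl.shape[0] < 2:
            n_dropped += 1
            continue
        if np.linalg.norm(np.diff(sl, axis=0), axis=1).sum() == 0.0:
            n_dropped += 1
            continue
        kept.append(sl)
    if n_dropped:
        logger.warning(
            "dropped %d degenerate streamline(s) while reading %s", n_dropped, path
        )

    if reference is not None:
        affine, shape = reference.affine, reference.data.shape
    else:
        header = tfile.header
        affine = np.eye(4)
        shape = None
        if isinstance(header, dict):
            vox2ras = header.get("voxel_to_rasmm")
            if vox2ras is not None and np.isfinite(vox2ras).all() and abs(np.linalg.det(np.asarray(vox2ras)[:3, :3])) > 1e-12:
                affine = np.asarray(vox2ras, dtype=float)
            dims = header.get("dimensions")
            if dims is not None:
                shape = tuple(int(d) for d in dims)
    return Tractogram(streamlines=kept, affine=affine, shape=shape)


def write_tractogram(tractogram: Tractogram, path) -> None:
    """Write streamlines (world mm) to TRK or TCK, by file extension."""
    path = str(path)
    nib_tg = nib.streamlines.Tractogram(
        streamlines=[np.asarray(s, dtype=np.float32) for s in tractogram.streamlines],
        affine_to_rasmm=np.eye(4),
    )
    if path.endswith(".trk"):
        shape = tractogram.shape or (1, 1, 1)
        zooms = np.sqrt((tractogram.affine[:3, :3] ** 2).sum(axis=0))
        header = {
            nib.streamlines.trk.Field.VOXEL_TO_RASMM: tractogram.affine.astype(np.float32),
            nib.streamlines.trk.Field.VOXEL_SIZES: zooms.astype(np.float32),
            nib.streamlines.trk.Field.DIMENSIONS: np.asarray(shape, dtype=np.int16),
            nib.streamlines.trk.Field.VOXEL_ORDER: b"RAS",
        }
        nib.streamlines.save(nib_tg, path, header=header)
    elif path.endswith(".tck"):
        nib.streamlines.save(nib_tg, path)
    else:
        raise ValueError(f"unsupported tractogram extension: {path}")


# ---------------------------------------------------------------------------
# Spatial sampling


def world_to_voxel(affine: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Map world-mm points to continuous voxel coordinates."""
    inv = np.linalg.inv(_check_affine(affine))
    return nib.affines.apply_affine(inv, np.asarray(points, dtype=float))


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, halves away from zero (deterministic)."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def nearest_voxel_indices(affine: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Integer voxel index nearest to each world point (half away from zero)."""
    return _round_half_away(world_to_voxel(affine, points)).astype(int)


def point_in_mask(mask: MaskVolume, points: np.ndarray) -> np.ndarray:
    """Boolean per point: nearest voxel index lies inside the mask."""
    idx = nearest_voxel_indices(mask.affine, np.atleast_2d(points))
    shape = np.asarray(mask.data.shape)
    inside_grid = np.all((idx >= 0) & (idx < shape), axis=1)
    result = np.zeros(len(idx), dtype=bool)
    if inside_grid.any():
        ii = idx[inside_grid]
        result[inside_grid] = mask.data[ii[:, 0], ii[:, 1], ii[:, 2]] != 0
    return result


def sample_volume(vol: ScalarVolume | MaskVolume, points, mode: str = "trilinear") -> np.ndarray:
    """Sample a volume at world-mm points.

    ``mode='trilinear'`` interpolates linearly in voxel space;
    ``mode='nearest'`` takes the nearest voxel's value.  Points falling
    outside the voxel-center grid return 0 (the count is logged).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    vox = world_to_voxel(vol.affine, points)
    shape = np.asarray(vol.data.shape)
    inside = np.all((vox >= 0) & (vox <= shape - 1), axis=1)
    n_out = int((~inside).sum())
    if n_out:
        logger.debug("%d sample point(s) outside the grid of '%s'", n_out, vol.name)
    order = {"trilinear": 1, "nearest": 0}.get(mode)
    if order is None:
        raise ValueError(f"unknown sampling mode: {mode!r}")
    values = map_coordinates(
        np.asarray(vol.data, dtype=float), vox.T, order=order, mode="constant", cval=0.0
    )
    values[~inside] = 0.0
    return values


def min_distance_to_mask(points, mask: MaskVolume) -> float:
    """Minimum distance (mm) from any point to the nearest mask-voxel center.

    A point whose nearest integer voxel index is itself a mask voxel is
    treated as inside the ROI (distance 0).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if not np.any(mask.data != 0):
        raise ValueError(f"mask '{mask.name}' is empty")
    if point_in_mask(mask, points).any():
        return 0.0
    dists, _ = mask.center_tree().query(points)
    return float(np.min(dists))


# ---------------------------------------------------------------------------
# Tidy profile tables


def _validate_tidy(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TIDY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"tidy table missing columns: {missing}")
    keys = table[TIDY_COLUMNS[:4]]
    dup = keys.duplicated()
    if dup.any():
        first = keys[dup].iloc[0].tolist()
        raise ValueError(f"duplicate tidy key: {tuple(first)}")
    return table


def write_tidy_csv(table: pd.DataFrame, path, wide: bool = False) -> None:
    """Write a tidy long profile table to CSV.

    Header is exactly ``subject_id,tract_name,node_id,metric,value`` with
    rows sorted by (subject, tract, node, metric).  ``wide=True`` instead
    pivots metrics to columns (one row per subject/tract/node); the long
    form is the canonical output.
    """
    table = _validate_tidy(table)
    out = table[TIDY_COLUMNS].sort_values(TIDY_COLUMNS[:4], kind="mergesort")
    if wide:
        out = out.pivot_table(
            index=["subject_id", "tract_name", "node_id"],
            columns="metric",
            values="value",
        ).reset_index()
        out.columns.name = None
    out.to_csv(str(path), index=False)


def read_tidy_csv(path) -> pd.DataFrame:
    table = pd.read_csv(str(path))
    return _validate_tidy(table)
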