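"""Streamline geometry primitives.

A *streamline* is an ordered polyline in world millimeters (RAS: +x right,
+y anterior, +z superior), represented as a float64 array of shape (n, 3).
A *tractogram* bundles many streamlines together with the voxel-to-world
affine of the image grid they were traced on.

Everything downstream (recognition, cleaning, profiling) is built on the
handful of predicates and metrics defined here: arc-length resampling,
polyline length, the minimum-direct-flip (MDF) distance, midline crossing,
and the per-axis movement fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DegenerateStreamlineError",
    "Tractogram",
    "AXIS_LABELS",
    "as_streamline",
    "resample_streamline",
    "streamline_length",
    "mdf_distance",
    "crosses_midline",
    "primary_axis_fraction",
    "flip_streamline",
]

#: Map from anatomical axis label to world coordinate index.
AXIS_LABELS = {"L/R": 0, "P/A": 1, "I/S": 2}


class DegenerateStreamlineError(ValueError):
    """Raised for streamlines with fewer than 2 points or zero extent."""


def as_streamline(points) -> np.ndarray:
    """Validate and coerce ``points`` to a float64 (n, 3) streamline array.

    Raises
    ------
    DegenerateStreamlineError
        If the streamline has fewer than two points.
    ValueError
        If coordinates are not finite or not 3-D.
    """
    sl = np.asarray(points, dtype=float)
    if sl.ndim != 2 or sl.shape[1] != 3:
        raise ValueError(f"streamline must have shape (n, 3), got {sl.shape}")
    if sl.shape[0] < 2:
        raise DegenerateStreamlineError(
            f"streamline needs at least 2 points, got {sl.shape[0]}"
        )
    if not np.all(np.isfinite(sl)):
        raise ValueError("streamline coordinates must be finite")
    return sl


@dataclass
class Tractogram:
    """A set of streamlines in world mm plus the reference grid geometry.

    Parameters
    ----------
    streamlines : list of (n, 3) arrays
        Streamlines in world millimeters (RAS).
    affine : (4, 4) array
        Voxel-index to world-mm map of the reference image.
    shape : tuple of int, optional
        Reference image grid shape.
    """

    streamlines: list = field(default_factory=list)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    shape: tuple | None = None

    def __post_init__(self):
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be invertible")
        self.streamlines = [as_streamline(sl) for sl in self.streamlines]

    def __len__(self):
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)


def _cumulative_arclength(sl: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(sl, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_streamline(sl, n: int = 100) -> np.ndarray:
    """Resample a streamline to ``n`` points uniformly spaced in arc length.

    Output points lie on the piecewise-linear input curve at arc-length
    positions ``i * L / (n - 1)``; the endpoints are preserved exactly.
    """
    sl = as_streamline(sl)
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    cum = _cumulative_arclength(sl)
    total = cum[-1]
    if total == 0.0:
        raise DegenerateStreamlineError("streamline has zero length")
    targets = np.linspace(0.0, total, n)
    out = np.empty((n, 3))
    for d in range(3):
        out[:, d] = np.interp(targets, cum, sl[:, d])
    out[0] = sl[0]
    out[-1] = sl[-1]
    return out


def streamline_length(sl) -> float:
    """Polyline length in mm: sum of consecutive Euclidean distances."""
    sl = as_streamline(sl)
    return float(np.linalg.norm(np.diff(sl, axis=0), axis=1).sum())


def mdf_distance(a, b, n: int = 20) -> float:
    """Minimum-direct-flip distance between two streamlines, in mm.

    Both streamlines are resampled to ``n`` points; the distance is the
    smaller of the mean pointwise distance in direct order and in flipped
    order.  Symmetric, non-negative, and zero for identical curves up to a
    flip.
    """
    d_direct, d_flipped = _mdf_both(a, b, n)
    return min(d_direct, d_flipped)


def _mdf_both(a, b, n: int = 20) -> tuple[float, float]:
    """Direct and flipped mean pointwise distances after resampling."""
    ra = resample_streamline(a, n)
    rb = resample_streamline(b, n)
    d_direct = float(np.linalg.norm(ra - rb, axis=1).mean())
    d_flipped = float(np.linalg.norm(ra - rb[::-1], axis=1).mean())
    return d_direct, d_flipped


def crosses_midline(sl) -> bool:
    """True iff the x-coordinates include both strictly negative and
    strictly positive values (a sign change across the x = 0 plane).

    Touching the midline exactly (x == 0) does not count as crossing.
    """
    x = as_streamline(sl)[:, 0]
    return bool(np.any(x < 0) and np.any(x > 0))


def primary_axis_fraction(sl) -> np.ndarray:
    """Fraction of per-segment absolute movement along each world axis.

    Returns a length-3 array ``(f_x, f_y, f_z)`` summing to 1, where each
    component is the total absolute displacement along that axis over all
    consecutive segments, divided by the grand total.  Axis labels map via
    :data:`AXIS_LABELS` ('L/R' -> x, 'P/A' -> y, 'I/S' -> z).
    """
    sl = as_streamline(sl)
    moves = np.abs(np.diff(sl, axis=0)).sum(axis=0)
    total = moves.sum()
    if total == 0.0:
        raise DegenerateStreamlineError("streamline has zero movement")
    return moves / total


def flip_streamline(sl) -> np.ndarray:
    """Reverse the point order of a streamline (an involution)."""
    return as_streamline(sl)[::-1].copy()
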