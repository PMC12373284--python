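"""Set-level bundle cleaning.

Two complementary cleaners act on a recognized bundle as a whole, after
the per-streamline criteria:

* Mahalanobis cleaning iteratively removes streamlines that are unusually
  long (length z-score) or that run far from the core of the bundle
  (node-wise Mahalanobis distance to the bundle's node-wise mean).
* QuickBundles-threshold cleaning greedily clusters streamlines under the
  minimum-direct-flip distance and keeps the largest cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_geometry import resample_streamline, streamline_length

logger = logging.getLogger(__name__)

__all__ = ["CleaningParams", "mahalanobis_clean", "qb_threshold_clean", "align_bundle"]

# Relative ridge added to node covariances so rank-deficient node clouds
# (e.g. exactly collinear phantom bundles) stay invertible.
_RIDGE_REL = 1e-6
_RIDGE_ABS = 1e-12


@dataclass
class CleaningParams:
    """Parameters for Mahalanobis bundle cleaning.

    Defaults follow the established tractometry cleaning configuration:
    100 cleaning nodes, Mahalanobis distance threshold 3, length z-score
    threshold 4, at most 5 rounds, never dropping below 20 streamlines.
    """

    n_points: int = 100
    distance_threshold: float = 3.0
    length_threshold: float = 4.0
    clean_rounds: int = 5
    min_sl: int = 20

    def __post_init__(self):
        if self.n_points < 2 or self.distance_threshold <= 0 or \
                self.length_threshold <= 0 or self.clean_rounds < 1 or self.min_sl < 1:
            raise ValueError(f"invalid cleaning parameters: {self}")


def align_bundle(resampled: np.ndarray, reference: np.ndarray | None = None) -> np.ndarray:
    """Flip-align resampled streamlines (S, N, 3) to a reference streamline.

    Each streamline is reversed iff that lowers its mean pointwise distance
    to the reference (default: the first streamline).  Node statistics only
    make sense on a consistently oriented bundle.
    """
    resampled = np.asarray(resampled, dtype=float)
    ref = resampled[0] if reference is None else np.asarray(reference, dtype=float)
    out = resampled.copy()
    for i, sl in enumerate(resampled):
        direct = np.linalg.norm(sl - ref, axis=1).mean()
        flipped = np.linalg.norm(sl[::-1] - ref, axis=1).mean()
        if flipped < direct:
            out[i] = sl[::-1]
    return out


def _node_mahalanobis(coords: np.ndarray) -> np.ndarray:
    """Mean over nodes of each streamline's node-wise Mahalanobis distance.

    ``coords`` has shape (S, N, 3).  Per node, the 3x3 covariance across
    streamlines is ridge-regularized by ``1e-6 * spread^2 * I`` where
    ``spread^2`` is the mean node-cloud variance, so degenerate clouds
    remain invertible.
    """
    mu = coords.mean(axis=0)                      # (N, 3)
    diff = coords - mu                            # (S, N, 3)
    cov = np.einsum("snj,snk->njk", diff, diff) / coords.shape[0]  # (N, 3, 3)
    spread_sq = float(np.trace(cov, axis1=1, axis2=2).mean())
    ridge = _RIDGE_REL * spread_sq + _RIDGE_ABS
    cov = cov + ridge * np.eye(3)
    inv = np.linalg.inv(cov)                      # (N, 3, 3)
    d_sq = np.einsum("snj,njk,snk->sn", diff, inv, diff)
    d_sq = np.maximum(d_sq, 0.0)
    return np.sqrt(d_sq).mean(axis=1)             # (S,)


def mahalanobis_clean(bundle, params: CleaningParams | None = None) -> np.ndarray:
    """Iteratively remove length and trajectory outliers from a bundle.

    Per round, on the current survivors: (a) the absolute z-score of each
    streamline's length against the survivors' mean/std, and (b) the mean
    node-wise Mahalanobis distance of its resampled trajectory to the
    node-wise mean.  Streamlines exceeding either threshold are removed.
    Iteration stops when no streamline is removed, ``clean_rounds`` is
    reached, or a removal would drop the count below ``min_sl`` (that
    round is then skipped).

    Returns the kept indices in input order.
    """
    params = params or CleaningParams()
    bundle = list(bundle)
    if len(bundle) == 0:
        raise ValueError("cannot clean an empty bundle")
    lengths = np.array([streamline_length(sl) for sl in bundle])
    coords = align_bundle(
        np.stack([resample_streamline(sl, params.n_points) for sl in bundle])
    )

    keep = np.arange(len(bundle))
    for _ in range(params.clean_rounds):
        if len(keep) <= params.min_sl:
            logger.info(
                "bundle at or below min_sl=%d; cleaning skipped", params.min_sl
            )
            break
        sub_len = lengths[keep]
        std = sub_len.std()
        length_z = np.abs(sub_len - sub_len.mean()) / std if std > 0 else np.zeros_like(sub_len)
        mahal = _node_mahalanobis(coords[keep])
        bad = (mahal > params.distance_threshold) | (length_z > params.length_threshold)
        if not bad.any():
            break
        if len(keep) - int(bad.sum()) < params.min_sl:
            logger.info(
                "removal of %d streamline(s) would violate min_sl=%d; stopping",
                int(bad.sum()), params.min_sl,
            )
            break
        keep = keep[~bad]
    return keep


def qb_threshold_clean(bundle, thresh_mm: float, n_points: int = 12) -> np.ndarray:
    """Greedy QuickBundles-style cleaning: keep the largest MDF cluster.

    Streamlines are scanned in order; each joins the first existing cluster
    whose running centroid is within ``thresh_mm`` MDF (flip-aligned before
    updating the centroid mean), otherwise it opens a new cluster.  The
    indices of the largest cluster are returned (ties go to the earliest
    created cluster).
    """
    if thresh_mm <= 0:
        raise ValueError(f"thresh_mm must be positive, got {thresh_mm}")
    bundle = list(bundle)
    if len(bundle) == 0:
        raise ValueError("cannot clean an empty bundle")

    resampled = [resample_streamline(sl, n_points) for sl in bundle]
    clusters: list[dict] = []  # each: {"sum": (N,3), "members": [idx]}
    for i, sl in enumerate(resampled):
        assigned = False
        for cluster in clusters:
            centroid = cluster["sum"] / len(cluster["members"])
            direct = np.linalg.norm(sl - centroid, axis=1).mean()
            flipped = np.linalg.norm(sl[::-1] - centroid, axis=1).mean()
            if min(direct, flipped) <= thresh_mm:
                cluster["sum"] += sl if direct <= flipped else sl[::-1]
                cluster["members"].append(i)
                assigned = True
                break
        if not assigned:
            clusters.append({"sum": sl.copy(), "members": [i]})

    largest = max(clusters, key=lambda c: len(c["members"]))  # max() keeps first tie
    return np.asarray(largest["members"], dtype=int)
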