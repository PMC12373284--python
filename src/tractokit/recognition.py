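"""Bundle recognition: classify streamlines into named tracts.

A :class:`BundleDefinitionSet` is an ordered mapping from tract name to a
:class:`BundleCriteria` record.  Every criterion is optional.  Configured
criteria are applied in a fixed order:

    (1) prob_map, (2) cross_midline, (3) start, (4) end, (5) length,
    (6) primary_axis, (7) include, (8) exclude, (9) shape_prior,
    (10) qb_thresh, (11) mahal

The first eight (plus the shape prior) are per-streamline filters; the
last two are set-level cleaners run on the survivors.  A streamline that
passes all steps for several tracts is assigned to the first tract in the
mapping and a tie warning is recorded.  When both a start and an end ROI
are configured, streamlines satisfying the pair only after reversal are
flipped, so recognized bundles come out oriented from start to end.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .cleaning import CleaningParams, mahalanobis_clean, qb_threshold_clean
from .core_geometry import (
    AXIS_LABELS,
    Tractogram,
    crosses_midline,
    flip_streamline,
    mdf_distance,
    primary_axis_fraction,
    resample_streamline,
    streamline_length,
)
from .imaging_io import (
    MaskVolume,
    min_distance_to_mask,
    point_in_mask,
    read_mask_volume,
    read_tractogram,
    sample_volume,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CRITERION_ORDER",
    "BundleCriteria",
    "BundleDefinitionSet",
    "RecognitionResult",
    "passes_include",
    "passes_exclude",
    "passes_endpoints",
    "passes_prob_map",
    "passes_length",
    "passes_primary_axis",
    "passes_shape_prior",
    "recognize",
    "load_bundle_config",
]

#: Application order of the recognition criteria.
CRITERION_ORDER = (
    "prob_map",
    "cross_midline",
    "start",
    "end",
    "length",
    "primary_axis",
    "include",
    "exclude",
    "shape_prior",
    "qb_thresh",
    "mahal",
)


@dataclass
class BundleCriteria:
    """Recognition criteria for one tract; every field is optional.

    Fields
    ------
    include : list of (MaskVolume, tolerance mm)
        Waypoint ROIs the streamline must pass within tolerance of (all).
    exclude : list of (MaskVolume, tolerance mm)
        ROIs the streamline must stay farther than tolerance from (all).
    start, end : MaskVolume or None
        Endpoint ROIs (nearest-voxel membership, no tolerance).
    cross_midline : bool or None
        True: must cross x=0; False: must not; None: unconstrained.
    prob_map : (MaskVolume, threshold) or None
        Mean sampled probability along the streamline must exceed threshold.
    length : (min_len, max_len) mm or None
    primary_axis : (axis label, percentage) or None
        Axis in {'L/R', 'P/A', 'I/S'}; percentage of movement required.
    shape_prior : (list of reference streamlines, centroid threshold mm) or None
        Reduced shape criterion: min MDF to any reference must be under
        the threshold.
    qb_thresh : float mm or None
        QuickBundles set-level cleaning threshold.
    mahal : CleaningParams or None
        Mahalanobis set-level cleaning parameters.
    """

    include: list = field(default_factory=list)
    exclude: list = field(default_factory=list)
    start: MaskVolume | None = None
    end: MaskVolume | None = None
    cross_midline: bool | None = None
    prob_map: tuple | None = None
    length: tuple | None = None
    primary_axis: tuple | None = None
    shape_prior: tuple | None = None
    qb_thresh: float | None = None
    mahal: CleaningParams | None = None

    def __post_init__(self):
        for roi, tol in list(self.include) + list(self.exclude):
            if tol < 0:
                raise ValueError(f"ROI tolerance must be >= 0, got {tol}")
        if self.length is not None:
            lo, hi = self.length
            if lo > hi:
                raise ValueError(f"min_len {lo} > max_len {hi}")
        if self.primary_axis is not None:
            axis, pct = self.primary_axis
            if axis not in AXIS_LABELS:
                raise ValueError(f"unknown axis {axis!r}; use one of {sorted(AXIS_LABELS)}")
            if not 0 < pct <= 100:
                raise ValueError(f"primary-axis percentage must be in (0, 100], got {pct}")


class BundleDefinitionSet(dict):
    """Ordered mapping tract name -> BundleCriteria.

    Insertion order is semantically meaningful: a streamline matching
    several tracts is assigned to the first one.
    """

    def __setitem__(self, key, value):
        if not isinstance(value, BundleCriteria):
            raise TypeError("values must be BundleCriteria")
        super().__setitem__(key, value)


@dataclass
class RecognitionResult:
    """Outcome of :func:`recognize`.

    ``assignments[i]`` is the tract name for streamline ``i`` or None;
    ``bundles[tract]`` holds the assigned streamlines, flipped where the
    endpoint criterion required it; ``tallies[tract]`` counts, in criterion
    order, how many candidates each configured criterion rejected (plus an
    ``"accepted"`` entry); ``warnings`` collects tie messages.
    """

    assignments: list
    bundles: dict
    kept_indices: dict
    tallies: dict
    warnings: list


# ---------------------------------------------------------------------------
# Per-streamline criteria


def passes_include(sl, rois_with_tolerance) -> bool:
    """True iff the streamline passes within tolerance of EVERY inclusion ROI."""
    if not rois_with_tolerance:
        return True
    return all(
        min_distance_to_mask(sl, roi) <= tol for roi, tol in rois_with_tolerance
    )


def passes_exclude(sl, rois_with_tolerance) -> bool:
    """True iff the streamline stays beyond tolerance of every exclusion ROI."""
    return all(
        min_distance_to_mask(sl, roi) > tol for roi, tol in rois_with_tolerance
    )


def passes_endpoints(sl, start_roi: MaskVolume | None, end_roi: MaskVolume | None):
    """Check the start/end ROI pair, allowing a flip.

    Returns ``(ok, flipped, failed_criterion)``: the streamline passes if
    some orientation places its first point in the start ROI (if given)
    and its last point in the end ROI (if given).  ``failed_criterion`` is
    ``"start"`` or ``"end"``, naming the earliest criterion no orientation
    could satisfy, or None on success.
    """
    if start_roi is None and end_roi is None:
        return True, False, None
    first, last = np.asarray(sl)[0], np.asarray(sl)[-1]
    in_start = {
        "first": bool(point_in_mask(start_roi, first)[0]) if start_roi is not None else True,
        "last": bool(point_in_mask(start_roi, last)[0]) if start_roi is not None else True,
    }
    in_end = {
        "first": bool(point_in_mask(end_roi, first)[0]) if end_roi is not None else True,
        "last": bool(point_in_mask(end_roi, last)[0]) if end_roi is not None else True,
    }
    if in_start["first"] and in_end["last"]:
        return True, False, None
    if in_start["last"] and in_end["first"]:
        return True, True, None
    # Neither orientation works; attribute the failure to start first.
    if start_roi is not None and not (in_start["first"] or in_start["last"]):
        return False, False, "start"
    return False, False, "end" if end_roi is not None else "start"


def passes_prob_map(sl, prob_map: MaskVolume, threshold: float, n_points: int = 100) -> bool:
    """True iff the mean sampled probability along the resampled streamline
    is strictly greater than the threshold."""
    samples = sample_volume(prob_map, resample_streamline(sl, n_points), mode="trilinear")
    return float(samples.mean()) > threshold


def passes_length(sl, min_len: float, max_len: float) -> bool:
    """True iff min_len <= length <= max_len (inclusive bounds)."""
    return min_len <= streamline_length(sl) <= max_len


def passes_primary_axis(sl, axis: str, percentage: float) -> bool:
    """True iff at least ``percentage`` % of movement is along ``axis``."""
    frac = primary_axis_fraction(sl)[AXIS_LABELS[axis]]
    return frac * 100.0 >= percentage


def passes_shape_prior(sl, reference_streamlines, centroid_threshold_mm: float,
                       n_points: int = 20) -> bool:
    """True iff the min MDF to any reference streamline is within threshold."""
    refs = list(reference_streamlines)
    if not refs:
        raise ValueError("shape prior requires at least one reference streamline")
    return min(mdf_distance(sl, ref, n_points) for ref in refs) <= centroid_threshold_mm


# ---------------------------------------------------------------------------
# The recognition engine


def _first_failure(sl, criteria: BundleCriteria):
    """Apply the configured per-streamline criteria in order.

    Returns ``(failed_criterion_or_None, possibly_flipped_streamline)``.
    """
    if criteria.prob_map is not None:
        pmap, thr = criteria.prob_map
        if not passes_prob_map(sl, pmap, thr):
            return "prob_map", sl
    if criteria.cross_midline is not None:
        if crosses_midline(sl) != criteria.cross_midline:
            return "cross_midline", sl
    if criteria.start is not None or criteria.end is not None:
        ok, flipped, failed = passes_endpoints(sl, criteria.start, criteria.end)
        if not ok:
            return failed, sl
        if flipped:
            sl = flip_streamline(sl)
    if criteria.length is not None:
        if not passes_length(sl, *criteria.length):
            return "length", sl
    if criteria.primary_axis is not None:
        try:
            ok = passes_primary_axis(sl, *criteria.primary_axis)
        except Exception:
            ok = False  # zero-movement streamline
        if not ok:
            return "primary_axis", sl
    if criteria.include:
        if not passes_include(sl, criteria.include):
            return "include", sl
    if criteria.exclude:
        if not passes_exclude(sl, criteria.exclude):
            return "exclude", sl
    if criteria.shape_prior is not None:
        refs, thr = criteria.shape_prior
        if not passes_shape_prior(sl, refs, thr):
            return "shape_prior", sl
    return None, sl


def recognize(tractogram: Tractogram, defs: BundleDefinitionSet) -> RecognitionResult:
    """Classify each streamline of ``tractogram`` into at most one tract.

    For each tract (in mapping order) the full tractogram is filtered by
    the configured criteria in the canonical order; ``qb_thresh`` and
    ``mahal`` then clean the surviving set.  A streamline surviving for
    several tracts is assigned to the first and a tie warning recorded.
    """
    if not defs:
        raise ValueError("bundle definition set is empty")
    streamlines = list(tractogram.streamlines)
    warnings: list[str] = []
    if not streamlines:
        warnings.append("empty tractogram: nothing to recognize")

    survivors: dict[str, dict[int, np.ndarray]] = {}
    tallies: dict[str, dict[str, int]] = {}
    for tract, criteria in defs.items():
        tally = {c: 0 for c in CRITERION_ORDER}
        passed: dict[int, np.ndarray] = {}
        for i, sl in enumerate(streamlines):
            failed, oriented = _first_failure(sl, criteria)
            if failed is None:
                passed[i] = oriented
            else:
                tally[failed] += 1

        if criteria.qb_thresh is not None and passed:
            idx = list(passed)
            kept = qb_threshold_clean([passed[i] for i in idx], criteria.qb_thresh)
            kept_set = {idx[k] for k in kept}
            tally["qb_thresh"] += len(idx) - len(kept_set)
            passed = {i: passed[i] for i in idx if i in kept_set}
        if criteria.mahal is not None and passed:
            idx = list(passed)
            kept = mahalanobis_clean([passed[i] for i in idx], criteria.mahal)
            kept_set = {idx[k] for k in kept}
            tally["mahal"] += len(idx) - len(kept_set)
            passed = {i: passed[i] for i in idx if i in kept_set}

        tally["accepted"] = len(passed)
        survivors[tract] = passed
        tallies[tract] = tally

    assignments: list = [None] * len(streamlines)
    bundles: dict[str, list] = {t: [] for t in defs}
    kept_indices: dict[str, list] = {t: [] for t in defs}
    for tract in defs:
        for i, oriented in survivors[tract].items():
            if assignments[i] is None:
                assignments[i] = tract
                bundles[tract].append(oriented)
                kept_indices[tract].append(i)
            else:
                warnings.append(
                    f"streamline {i} matched both '{assignments[i]}' and "
                    f"'{tract}'; assigned to '{assignments[i]}' (first in the "
                    "bundle definition set)"
                )
    return RecognitionResult(
        assignments=assignments,
        bundles=bundles,
        kept_indices=kept_indices,
        tallies=tallies,
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# Configuration loading

_KNOWN_KEYS = {
    "include", "exclude", "start", "end", "cross_midline", "prob_map",
    "length", "primary_axis", "shape_prior", "qb_thresh", "mahal",
}


def load_bundle_config(path) -> BundleDefinitionSet:
    """Load a YAML/JSON bundle definition file.

    Schema (paths are resolved relative to the config file)::

        tracts:
          NAME:
            include: [{path: roi1.nii.gz, tol: 3.0}, ...]
            exclude: [{path: roi2.nii.gz, tol: 0.0}, ...]
            start: start.nii.gz
            end: end.nii.gz
            cross_midline: false
            prob_map: {path: pmap.nii.gz, threshold: 0.0}
            length: {min_len: 10, max_len: 200}
            primary_axis: {axis: "I/S", percentage: 60}
            shape_prior: {path: refs.trk, centroid: 5.0}
            qb_thresh: 10.0
            mahal: {distance_threshold: 3, length_threshold: 4}

    Unknown criterion keys raise an error naming the key.
    """
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(raw, dict) or "tracts" not in raw:
        raise ValueError(f"config {path} must contain a top-level 'tracts' mapping")
    base = path.parent

    defs = BundleDefinitionSet()
    for tract, spec in raw["tracts"].items():
        spec = dict(spec or {})
        unknown = set(spec) - _KNOWN_KEYS
        if unknown:
            raise ValueError(
                f"unknown criterion key(s) {sorted(unknown)} for tract '{tract}'"
            )
        crit = BundleCriteria()
        for field_name in ("include", "exclude"):
            for entry in spec.get(field_name, []):
                roi = read_mask_volume(base / entry["path"], kind="roi")
                getattr(crit, field_name).append((roi, float(entry.get("tol", 0.0))))
        if "start" in spec:
            crit.start = read_mask_volume(base / spec["start"], kind="roi")
        if "end" in spec:
            crit.end = read_mask_volume(base / spec["end"], kind="roi")
        if "cross_midline" in spec:
            crit.cross_midline = bool(spec["cross_midline"])
        if "prob_map" in spec:
            entry = spec["prob_map"]
            pmap = read_mask_volume(base / entry["path"], kind="prob")
            crit.prob_map = (pmap, float(entry.get("threshold", 0.0)))
        if "length" in spec:
            crit.length = (float(spec["length"]["min_len"]), float(spec["length"]["max_len"]))
        if "primary_axis" in spec:
            crit.primary_axis = (spec["primary_axis"]["axis"],
                                 float(spec["primary_axis"]["percentage"]))
        if "shape_prior" in spec:
            entry = spec["shape_prior"]
            refs = read_tractogram(base / entry["path"]).streamlines
            crit.shape_prior = (refs, float(entry["centroid"]))
        if "qb_thresh" in spec:
            crit.qb_thresh = float(spec["qb_thresh"])
        if "mahal" in spec:
            crit.mahal = CleaningParams(**(spec["mahal"] or {}))
        # re-run validation after field-by-field construction
        crit.__post_init__()
        defs[tract] = crit
    return defs
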