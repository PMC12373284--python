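"""Synthetic streamline phantoms with known ground truth.

Every input the pipeline consumes can be generated here: bundles of
streamlines sampled around parametric 3-D curves, scalar volumes with
planted along-tract profiles, waypoint/endpoint ROI masks, probability
maps, distractor streamlines, multi-subject group tables with planted
node-localized effects, and learning-curve data drawn from the
exponential model.  All generators are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, gaussian_filter1d
from scipy.spatial import cKDTree

from .core_geometry import Tractogram
from .imaging_io import MaskVolume, ScalarVolume, min_distance_to_mask
from .recognition import BundleCriteria, BundleDefinitionSet
from .stats_learning import learning_curve

__all__ = [
    "BundleSpec",
    "PhantomSpec",
    "GroundTruth",
    "PhantomResult",
    "arc_curve",
    "helix_curve",
    "make_bundle",
    "make_phantom",
    "default_phantom_spec",
    "make_group_dataset",
    "make_learning_data",
]


# ---------------------------------------------------------------------------
# Parametric curves


def arc_curve(center, radius: float, plane_axes=(1, 2), fixed_axis: int = 0,
              angles=(0.0, np.pi)):
    """Circular arc of ``radius`` mm in a coordinate plane.

    Returns a map t in [0, 1] -> (len(t), 3) world points.
    """
    center = np.asarray(center, dtype=float)

    def curve(t):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        theta = angles[0] + (angles[1] - angles[0]) * t
        pts = np.tile(center, (len(t), 1))
        pts[:, plane_axes[0]] += radius * np.cos(theta)
        pts[:, plane_axes[1]] += radius * np.sin(theta)
        return pts

    return curve


def helix_curve(center, radius: float, z_extent: float, turns: float = 1.0):
    """Helix around a vertical axis through ``center``, spanning z_extent mm."""
    center = np.asarray(center, dtype=float)

    def curve(t):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        theta = 2.0 * np.pi * turns * t
        pts = np.empty((len(t), 3))
        pts[:, 0] = center[0] + radius * np.cos(theta)
        pts[:, 1] = center[1] + radius * np.sin(theta)
        pts[:, 2] = center[2] - z_extent / 2.0 + z_extent * t
        return pts

    return curve


# ---------------------------------------------------------------------------
# Specs


@dataclass
class BundleSpec:
    """One planted bundle: a curve, its population, and its tissue profiles."""

    name: str
    curve: object                       # t in [0,1] -> (n, 3)
    n_streamlines: int = 60
    spread: float = 1.5                 # transverse displacement SD, mm
    noise: float = 0.2                  # per-point isotropic noise SD, mm
    profiles: dict = field(default_factory=dict)   # metric -> p(t)


@dataclass
class PhantomSpec:
    """Geometry and content of a synthetic phantom.

    The default grid is 60x60x60 voxels at 2 mm, centered on the world
    origin so the midline plane x = 0 bisects the FOV.
    """

    bundles: list = field(default_factory=list)
    n_distractors: int = 100
    shape: tuple = (60, 60, 60)
    voxel_size: float = 2.0
    background: float = 0.1
    seed: int = 0

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size
        # voxel centers symmetric about the world origin
        aff[:3, 3] = -self.voxel_size * (np.asarray(self.shape) - 1) / 2.0
        return aff

    @property
    def fov_mm(self) -> np.ndarray:
        half = self.voxel_size * (np.asarray(self.shape) - 1) / 2.0
        return np.stack([-half, half])


@dataclass
class GroundTruth:
    """Generator-side truth for a phantom: labels, profiles, and ROIs."""

    labels: list                        # per streamline: bundle name or "distractor"
    planted_profiles: dict              # bundle -> metric -> values at node grid
    node_grid: np.ndarray               # parameter values of the node grid
    rois: dict                          # bundle -> {"start","end","way_25","way_75": MaskVolume}


@dataclass
class PhantomResult:
    tractogram: Tractogram
    scalars: dict
    prob_maps: dict
    truth: GroundTruth
    definitions: BundleDefinitionSet


# ---------------------------------------------------------------------------
# Streamline generation


def _normal_frame(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-point orthonormal basis (N1, N2) of the curve's normal plane."""
    tang = np.gradient(points, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    ref = np.zeros(3)
    ref[np.argmin(np.abs(tang).mean(axis=0))] = 1.0   # least-aligned world axis
    n1 = np.cross(tang, ref)
    n1 /= np.linalg.norm(n1, axis=1, keepdims=True)
    n2 = np.cross(tang, n1)
    n2 /= np.linalg.norm(n2, axis=1, keepdims=True)
    return n1, n2


def make_bundle(curve, n_streamlines: int, spread: float, noise: float, seed,
                n_points: int = 100, flip_prob: float = 0.5) -> list:
    """Sample streamlines around a parametric curve.

    Each streamline is the curve at ``n_points`` parameters, displaced by a
    per-streamline constant offset drawn N(0, spread^2) per component in
    the curve's normal plane, plus per-point isotropic N(0, noise^2)
    jitter.  About half the streamlines are emitted reversed to exercise
    orientation handling downstream.
    """
    if spread < 0 or noise < 0:
        raise ValueError("spread and noise must be >= 0")
    if n_streamlines < 1:
        raise ValueError("need at least one streamline")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.linspace(0.0, 1.0, n_points)
    base = np.asarray(curve(t), dtype=float)
    n1, n2 = _normal_frame(base)

    streamlines = []
    for _ in range(n_streamlines):
        a, b = rng.normal(0.0, spread, size=2) if spread > 0 else (0.0, 0.0)
        sl = base + a * n1 + b * n2
        if noise > 0:
            sl = sl + rng.normal(0.0, noise, size=sl.shape)
        if rng.random() < flip_prob:
            sl = sl[::-1]
        streamlines.append(sl)
    return streamlines


def _make_distractor(rng: np.random.Generator, fov: np.ndarray,
                     n_points: int = 100, step: float = 1.0) -> np.ndarray:
    """A smoothed random walk inside the FOV."""
    lo, hi = fov[0] * 0.8, fov[1] * 0.8
    start = rng.uniform(lo, hi)
    steps = rng.normal(0.0, step, size=(n_points - 1, 3))
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    walk = np.vstack([[0, 0, 0], np.cumsum(steps + direction * step, axis=0)]) + start
    walk = gaussian_filter1d(walk, sigma=3.0, axis=0)
    return np.clip(walk, fov[0], fov[1])


# ---------------------------------------------------------------------------
# Phantom assembly


def _paint_sphere(shape, affine, center, radius: float) -> np.ndarray:
    idx = np.indices(shape).reshape(3, -1).T
    centers = idx @ affine[:3, :3].T + affine[:3, 3]
    data = (np.linalg.norm(centers - np.asarray(center), axis=1) <= radius)
    return data.reshape(shape).astype(np.uint8)


def make_phantom(spec: PhantomSpec) -> PhantomResult:
    """Generate a complete phantom: tractogram, volumes, ROIs, truth.

    Scalar volumes hold each bundle's planted profile p(t) inside a tube
    of radius 2 x spread around its curve (nearest-curve-parameter
    assignment), with a configurable background elsewhere.  Waypoint ROIs
    sit at t = 0.25 and 0.75 of each curve, endpoint ROIs at t = 0 and 1.
    Emitted bundle definitions use the waypoint/endpoint ROIs plus a
    length range, with inclusion tolerances wide enough for every planted
    streamline (derived from the generated data, so recognition of the
    phantom's own bundles is exact by construction).
    """
    rng = np.random.default_rng(spec.seed)
    affine = spec.affine
    shape = tuple(spec.shape)
    node_grid = np.linspace(0.0, 1.0, 100)

    # Warn about bundles drawn too close together for exact recovery.
    curves_dense = {b.name: np.asarray(b.curve(np.linspace(0, 1, 400)), dtype=float)
                    for b in spec.bundles}
    max_spread = max((b.spread for b in spec.bundles), default=0.0)
    names = [b.name for b in spec.bundles]
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            gap = cKDTree(curves_dense[names[i]]).query(curves_dense[names[j]])[0].min()
            if gap < 3.0 * max_spread:
                import warnings as _warnings
                _warnings.warn(
                    f"bundles '{names[i]}' and '{names[j]}' are closer than 3x "
                    "the maximum spread; exact recognition is not guaranteed",
                    stacklevel=2,
                )

    # Streamlines and labels (bundles first, then distractors, shuffled).
    streamlines, labels = [], []
    per_bundle: dict[str, list] = {}
    for b in spec.bundles:
        sls = make_bundle(b.curve, b.n_streamlines, b.spread, b.noise, rng)
        per_bundle[b.name] = sls
        streamlines.extend(sls)
        labels.extend([b.name] * len(sls))
    for _ in range(spec.n_distractors):
        streamlines.append(_make_distractor(rng, spec.fov_mm))
        labels.append("distractor")
    order = rng.permutation(len(streamlines))
    streamlines = [streamlines[i] for i in order]
    labels = [labels[i] for i in order]
    tractogram = Tractogram(streamlines=streamlines, affine=affine, shape=shape)

    # Scalar volumes with planted profiles.
    voxel_centers = (np.indices(shape).reshape(3, -1).T @ affine[:3, :3].T
                     + affine[:3, 3])
    metrics = sorted({m for b in spec.bundles for m in b.profiles})
    scalars = {}
    for metric in metrics:
        data = np.full(shape, spec.background, dtype=float)
        flat = data.reshape(-1)
        for b in spec.bundles:
            if metric not in b.profiles:
                continue
            t_dense = np.linspace(0.0, 1.0, 1000)
            dense = np.asarray(b.curve(t_dense), dtype=float)
            dist, nearest = cKDTree(dense).query(voxel_centers)
            # Tube radius: 2 x spread for the streamline population, plus
            # the trilinear support radius (sqrt(3) voxels) so that every
            # sample point inside the nominal tube interpolates painted
            # voxels only -- the planted profile is then the literal
            # ground truth for profile extraction.
            radius = 2.0 * b.spread + np.sqrt(3.0) * spec.voxel_size
            inside = dist <= radius
            flat[inside] = np.asarray(b.profiles[metric](t_dense[nearest[inside]]))
        scalars[metric] = ScalarVolume(data=data, affine=affine, name=metric)

    # ROIs, probability maps, definitions, planted profiles.
    rois: dict[str, dict] = {}
    prob_maps: dict[str, MaskVolume] = {}
    planted: dict[str, dict] = {}
    definitions = BundleDefinitionSet()
    for b in spec.bundles:
        ends = np.asarray(b.curve(np.array([0.0, 1.0])), dtype=float)
        ways = np.asarray(b.curve(np.array([0.25, 0.75])), dtype=float)
        sls = per_bundle[b.name]
        # Endpoint mask radius covers every planted streamline's endpoints
        # (allowing for the emitted flips) plus a one-voxel margin.
        end_dists = [
            min(np.linalg.norm(sl[0] - ends[k]), np.linalg.norm(sl[-1] - ends[k]))
            for sl in sls for k in (0, 1)
        ]
        r_end = max(end_dists) + spec.voxel_size
        r_way = 2.0 * b.spread + spec.voxel_size
        masks = {
            "start": MaskVolume(_paint_sphere(shape, affine, ends[0], r_end),
                                affine, name=f"{b.name}_start"),
            "end": MaskVolume(_paint_sphere(shape, affine, ends[1], r_end),
                              affine, name=f"{b.name}_end"),
            "way_25": MaskVolume(_paint_sphere(shape, affine, ways[0], r_way),
                                 affine, name=f"{b.name}_way25"),
            "way_75": MaskVolume(_paint_sphere(shape, affine, ways[1], r_way),
                                 affine, name=f"{b.name}_way75"),
        }
        rois[b.name] = masks

        occupancy = np.zeros(shape, dtype=float)
        pts = np.vstack(sls)
        inv = np.linalg.inv(affine)
        vox = np.round(pts @ inv[:3, :3].T + inv[:3, 3]).astype(int)
        ok = np.all((vox >= 0) & (vox < np.asarray(shape)), axis=1)
        np.add.at(occupancy, tuple(vox[ok].T), 1.0)
        smoothed = gaussian_filter(occupancy, sigma=1.0)
        if smoothed.max() > 0:
            smoothed /= smoothed.max()
        prob_maps[b.name] = MaskVolume(smoothed, affine, name=f"{b.name}_prob",
                                       kind="prob")

        tol = max(
            max(min_distance_to_mask(sl, masks[w]) for sl in sls)
            for w in ("way_25", "way_75")
        ) + 0.5
        sl_lengths = [np.linalg.norm(np.diff(sl, axis=0), axis=1).sum() for sl in sls]
        definitions[b.name] = BundleCriteria(
            include=[(masks["way_25"], tol), (masks["way_75"], tol)],
            start=masks["start"],
            end=masks["end"],
            length=(0.8 * min(sl_lengths), 1.2 * max(sl_lengths)),
        )
        planted[b.name] = {
            m: np.asarray(p(node_grid), dtype=float) for m, p in b.profiles.items()
        }

    truth = GroundTruth(labels=labels, planted_profiles=planted,
                        node_grid=node_grid, rois=rois)
    return PhantomResult(tractogram=tractogram, scalars=scalars,
                         prob_maps=prob_maps, truth=truth, definitions=definitions)


def default_phantom_spec(seed: int = 0, n_streamlines: int = 60,
                         n_distractors: int = 100) -> PhantomSpec:
    """The standard two-bundle phantom.

    A left-hemisphere arc (~79 mm) and a right-hemisphere helix (~71 mm),
    both with a planted FA profile ``p(t) = 0.3 + 0.2 sin(pi t)``, well
    separated relative to their 1.5 mm spread, plus smoothed-random-walk
    distractors.
    """
    fa = lambda t: 0.3 + 0.2 * np.sin(np.pi * np.asarray(t))
    return PhantomSpec(
        bundles=[
            BundleSpec(
                name="left_arc",
                curve=arc_curve(center=(-25.0, 0.0, 0.0), radius=25.0),
                n_streamlines=n_streamlines,
                profiles={"FA": fa},
            ),
            BundleSpec(
                name="right_helix",
                curve=helix_curve(center=(25.0, 0.0, 0.0), radius=6.0,
                                  z_extent=50.0),
                n_streamlines=n_streamlines,
                profiles={"FA": fa},
            ),
        ],
        n_distractors=n_distractors,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Group tables and learning-curve data


def make_group_dataset(
    n_per_group: int = 24,
    n_nodes: int = 100,
    effect_nodes=None,
    effect_size_sd: float = 0.0,
    noise_sd: float = 0.1,
    seed: int = 0,
    tract_name: str = "synthetic_tract",
    metric: str = "FA",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-group tidy profile table with an optional planted node effect.

    Each subject's profile is a shared smooth mean curve plus a low-order
    random cosine expansion (subject-level smooth variation, amplitude
    0.5 x noise_sd) plus iid node-wise N(0, noise_sd^2) noise.  Subjects
    in the second group are shifted by ``effect_size_sd * noise_sd`` at
    ``effect_nodes``; ``effect_size_sd = 0`` yields a global null.  Age
    and sex covariates are drawn independently of group and outcome.
    """
    if n_per_group < 2:
        raise ValueError("need at least 2 subjects per group")
    effect_nodes = np.asarray(
        [] if effect_nodes is None else list(effect_nodes), dtype=int
    )
    if effect_nodes.size and (effect_nodes.min() < 0 or effect_nodes.max() >= n_nodes):
        raise ValueError("effect_nodes must lie in [0, n_nodes)")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 1.0, n_nodes)
    mean_curve = 0.4 + 0.1 * np.sin(np.pi * t)
    basis = np.stack([np.cos(np.pi * (j + 1) * t) / (j + 1) for j in range(4)])

    n_total = 2 * n_per_group
    groups = np.array(["control"] * n_per_group + ["patient"] * n_per_group)
    rows = []
    for s in range(n_total):
        coef = rng.normal(0.0, 0.5 * noise_sd, size=4)
        profile = mean_curve + coef @ basis + rng.normal(0.0, noise_sd, size=n_nodes)
        if groups[s] == "patient" and effect_nodes.size:
            profile[effect_nodes] += effect_size_sd * noise_sd
        sid = f"sub-{s:03d}"
        rows.append(pd.DataFrame({
            "subject_id": sid,
            "tract_name": tract_name,
            "node_id": np.arange(n_nodes),
            "metric": metric,
            "value": profile,
        }))
    tidy = pd.concat(rows, ignore_index=True)
    covariates = pd.DataFrame({
        "subject_id": [f"sub-{s:03d}" for s in range(n_total)],
        "group": groups,
        "age": rng.uniform(20.0, 80.0, size=n_total),
        "sex": rng.choice(["F", "M"], size=n_total),
    })
    return tidy, covariates


def make_learning_data(alpha: float, beta: float, kappa: float, x_min: float,
                       sizes=(100, 175, 350, 700, 1000, 1453),
                       noise_sd: float = 0.0, seed: int = 0):
    """Scores drawn from the exponential learning curve plus Gaussian noise."""
    if not alpha > beta:
        raise ValueError("alpha must exceed beta")
    if kappa <= 0 or x_min <= 0:
        raise ValueError("kappa and x_min must be positive")
    sizes = np.asarray(sizes, dtype=float)
    if sizes.min() < x_min:
        raise ValueError("all sizes must be >= x_min")
    rng = np.random.default_rng(seed)
    scores = learning_curve(sizes, alpha, beta, kappa, x_min)
    if noise_sd > 0:
        scores = scores + rng.normal(0.0, noise_sd, size=sizes.shape)
    return sizes, scores
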