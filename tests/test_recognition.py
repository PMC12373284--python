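"""Bundle recognition: criteria semantics, order, tie-breaking, config."""

import numpy as np
import pytest
import yaml

from tractokit.core_geometry import Tractogram, flip_streamline
from tractokit.imaging_io import MaskVolume, write_volume
from tractokit.recognition import (
    BundleCriteria,
    BundleDefinitionSet,
    load_bundle_config,
    passes_endpoints,
    passes_exclude,
    passes_include,
    passes_length,
    passes_primary_axis,
    passes_prob_map,
    passes_shape_prior,
    recognize,
)


def sphere_mask(center, radius, shape=(40, 40, 40), voxel=2.0):
    affine = np.diag([voxel, voxel, voxel, 1.0])
    affine[:3, 3] = -voxel * (np.asarray(shape) - 1) / 2.0
    idx = np.indices(shape).reshape(3, -1).T
    centers = idx @ affine[:3, :3].T + affine[:3, 3]
    data = (np.linalg.norm(centers - np.asarray(center, float), axis=1) <= radius)
    return MaskVolume(data.reshape(shape).astype(float), affine)


def line(start, end, n=50):
    return np.linspace(np.asarray(start, float), np.asarray(end, float), n)


class TestIncludeExclude:
    def test_threading_both_waypoints(self):
        sl = line([-30, 0, 0], [30, 0, 0])
        rois = [(sphere_mask([-15, 0, 0], 4), 0.0), (sphere_mask([15, 0, 0], 4), 0.0)]
        assert passes_include(sl, rois)

    def test_tolerance_controls_a_miss(self):
        sl = line([-30, 8, 0], [30, 8, 0])   # passes ~3 mm above a small ROI
        roi = sphere_mask([1, 5, 1], 1.0)    # single voxel at a grid center
        from tractokit.imaging_io import min_distance_to_mask
        gap = min_distance_to_mask(sl, roi)
        assert gap > 0
        assert not passes_include(sl, [(roi, 0.0)])
        assert passes_include(sl, [(roi, gap + 0.5)])

    def test_vacuous_when_unconfigured(self):
        assert passes_include(line([0, 0, 0], [1, 1, 1]), [])

    def test_exclude(self):
        sl = line([-30, 0, 0], [30, 0, 0])
        far = sphere_mask([0, 30, 0], 3)
        hit = sphere_mask([0, 0, 0], 3)
        assert passes_exclude(sl, [(far, 0.0)])
        assert not passes_exclude(sl, [(hit, 0.0)])

    def test_exclude_grazing_within_tolerance(self):
        sl = line([-30, 5, 0], [30, 5, 0])
        roi = sphere_mask([0, 0, 0], 2)
        from tractokit.imaging_io import min_distance_to_mask
        gap = min_distance_to_mask(sl, roi)
        assert 0 < gap
        assert not passes_exclude(sl, [(roi, gap + 0.5)])
        assert passes_exclude(sl, [(roi, gap - 0.5)])


class TestEndpoints:
    def setup_method(self):
        self.start = sphere_mask([-20, 0, 0], 5)
        self.end = sphere_mask([20, 0, 0], 5)
        self.sl = line([-20, 0, 0], [20, 0, 0])

    def test_correct_orientation(self):
        ok, flipped, failed = passes_endpoints(self.sl, self.start, self.end)
        assert ok and not flipped and failed is None

    def test_reversed_is_flipped_and_accepted(self):
        ok, flipped, _ = passes_endpoints(flip_streamline(self.sl), self.start, self.end)
        assert ok and flipped

    def test_outside_both_orientations(self):
        stray = line([0, 30, 0], [20, 0, 0])
        ok, _, failed = passes_endpoints(stray, self.start, self.end)
        assert not ok and failed == "start"


class TestProbMap:
    def test_uniform_map(self):
        ones = MaskVolume(np.ones((20, 20, 20)), np.eye(4), kind="prob")
        sl = line([2, 2, 2], [15, 15, 15])
        assert passes_prob_map(sl, ones, 0.5)

    def test_strict_inequality_at_zero(self):
        zeros = MaskVolume(np.zeros((20, 20, 20)), np.eye(4), kind="prob")
        sl = line([2, 2, 2], [15, 15, 15])
        assert not passes_prob_map(sl, zeros, 0.0)

    def test_mean_statistic(self):
        # first half of the path over 0.8, second half over 0.0 -> mean 0.4
        data = np.zeros((21, 5, 5))
        data[:10] = 0.8
        pmap = MaskVolume(data, np.eye(4), kind="prob")
        sl = line([0, 2, 2], [19, 2, 2])
        assert not passes_prob_map(sl, pmap, 0.5)
        assert passes_prob_map(sl, pmap, 0.3)


class TestLengthAndAxis:
    def test_length_inclusive_bounds(self):
        sl = line([0, 0, 0], [50, 0, 0])
        assert passes_length(sl, 10, 200)
        assert passes_length(sl, 50, 200)      # exactly min_len
        assert not passes_length(line([0, 0, 0], [250, 0, 0]), 10, 200)

    def test_primary_axis(self):
        vertical = line([0, 0, 0], [0, 0, 60])
        assert passes_primary_axis(vertical, "I/S", 90)
        diagonal = line([0, 0, 0], [40, 0, 40])
        assert not passes_primary_axis(diagonal, "I/S", 60)
        assert passes_primary_axis(diagonal, "I/S", 50)


class TestShapePrior:
    def test_identical_and_reversed(self):
        ref = line([0, 0, 0], [40, 0, 0])
        assert passes_shape_prior(ref, [ref], 1.0)
        assert passes_shape_prior(flip_streamline(ref), [ref], 1.0)

    def test_parallel_offset_ten_mm(self):
        ref = line([0, 0, 0], [40, 0, 0])
        sl = ref + np.array([0, 10.0, 0])
        assert not passes_shape_prior(sl, [ref], 5.0)
        assert passes_shape_prior(sl, [ref], 10.0)

    def test_empty_reference(self):
        with pytest.raises(ValueError):
            passes_shape_prior(line([0, 0, 0], [1, 0, 0]), [], 5.0)


class TestRecognize:
    def test_phantom_exact_recovery(self, default_phantom):
        result = recognize(default_phantom.tractogram, default_phantom.definitions)
        labels = default_phantom.truth.labels
        for assigned, label in zip(result.assignments, labels):
            expected = label if label != "distractor" else None
            assert assigned == expected

    def test_tie_goes_to_first_tract_with_warning(self):
        sl = line([-20, 0, 0], [20, 0, 0])
        roi = sphere_mask([0, 0, 0], 5)
        defs = BundleDefinitionSet()
        defs["tract_a"] = BundleCriteria(include=[(roi, 0.0)])
        defs["tract_b"] = BundleCriteria(include=[(roi, 0.0)])
        result = recognize(Tractogram(streamlines=[sl]), defs)
        assert result.assignments == ["tract_a"]
        assert len(result.warnings) == 1
        assert "tract_a" in result.warnings[0] and "tract_b" in result.warnings[0]
        # reordering flips the tie exactly by the first-wins rule
        defs_rev = BundleDefinitionSet()
        defs_rev["tract_b"] = defs["tract_b"]
        defs_rev["tract_a"] = defs["tract_a"]
        assert recognize(Tractogram(streamlines=[sl]), defs_rev).assignments == ["tract_b"]

    def test_earlier_criterion_masks_later_tally(self):
        # streamline fails BOTH prob_map and include -> tallied only under prob_map
        sl = line([-20, 0, 0], [20, 0, 0])
        zeros = MaskVolume(np.zeros((40, 40, 40)),
                           sphere_mask([0, 0, 0], 1).affine, kind="prob")
        far_roi = sphere_mask([0, 30, 0], 2)
        defs = BundleDefinitionSet()
        defs["t"] = BundleCriteria(prob_map=(zeros, 0.0), include=[(far_roi, 0.0)])
        result = recognize(Tractogram(streamlines=[sl]), defs)
        assert result.tallies["t"]["prob_map"] == 1
        assert result.tallies["t"]["include"] == 0

    def test_tallies_partition_candidates(self, default_phantom):
        result = recognize(default_phantom.tractogram, default_phantom.definitions)
        n = len(default_phantom.tractogram)
        for tract, tally in result.tallies.items():
            assert sum(tally.values()) == n

    def test_removing_a_criterion_never_shrinks_a_tract(self, default_phantom):
        defs = default_phantom.definitions
        full = recognize(default_phantom.tractogram, defs)
        name = next(iter(defs))
        relaxed_defs = BundleDefinitionSet()
        relaxed = BundleCriteria(include=defs[name].include, length=defs[name].length)
        relaxed_defs[name] = relaxed  # start/end dropped
        loose = recognize(default_phantom.tractogram, relaxed_defs)
        assert loose.tallies[name]["accepted"] >= full.tallies[name]["accepted"]

    def test_cross_midline_tristate(self):
        crossing = line([-10, 0, 0], [10, 0, 0])
        left_only = line([-30, 0, 0], [-10, 0, 0])
        defs = BundleDefinitionSet()
        defs["must_cross"] = BundleCriteria(cross_midline=True)
        result = recognize(Tractogram(streamlines=[crossing, left_only]), defs)
        assert result.assignments == ["must_cross", None]
        defs2 = BundleDefinitionSet()
        defs2["no_cross"] = BundleCriteria(cross_midline=False)
        result2 = recognize(Tractogram(streamlines=[crossing, left_only]), defs2)
        assert result2.assignments == [None, "no_cross"]

    def test_empty_tractogram(self):
        defs = BundleDefinitionSet()
        defs["t"] = BundleCriteria(cross_midline=True)
        result = recognize(Tractogram(streamlines=[]), defs)
        assert result.assignments == []
        assert result.warnings

    def test_empty_definitions_rejected(self):
        with pytest.raises(ValueError):
            recognize(Tractogram(streamlines=[line([0, 0, 0], [1, 0, 0])]),
                      BundleDefinitionSet())


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        roi = sphere_mask([0, 0, 0], 4)
        write_volume(roi, tmp_path / "way.nii.gz")
        config = {
            "tracts": {
                "demo": {
                    "include": [{"path": "way.nii.gz", "tol": 3.0}],
                    "cross_midline": True,
                    "length": {"min_len": 10, "max_len": 200},
                    "qb_thresh": 10.0,
                }
            }
        }
        cfg = tmp_path / "bundles.yaml"
        cfg.write_text(yaml.safe_dump(config))
        defs = load_bundle_config(cfg)
        crit = defs["demo"]
        assert crit.cross_midline is True
        assert crit.length == (10.0, 200.0)
        assert crit.qb_thresh == 10.0
        assert len(crit.include) == 1 and crit.include[0][1] == 3.0

    def test_unknown_key_rejected(self, tmp_path):
        cfg = tmp_path / "bad.yaml"
        cfg.write_text(yaml.safe_dump({"tracts": {"t": {"includ": []}}}))
        with pytest.raises(ValueError, match="includ"):
            load_bundle_config(cfg)

    def test_invalid_criteria_values(self):
        with pytest.raises(ValueError):
            BundleCriteria(length=(200.0, 10.0))
        with pytest.raises(ValueError):
            BundleCriteria(primary_axis=("X/Y", 50))
        with pytest.raises(ValueError):
            BundleCriteria(include=[(sphere_mask([0, 0, 0], 2), -1.0)])
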