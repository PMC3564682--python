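"""Boundary inference: worked example, degenerate cases, region labels."""

import numpy as np
import pytest

from parscope.pab import (
    InconsistentAnnotationError,
    PABInferenceError,
    RegionLabel,
    classify_regions,
    infer_pab,
    infer_pab_array_only,
    par_size,
)
from parscope.ratios import clone_profiles
from parscope.regions import Region, build_track, call_regions
from parscope.simulate import annotate_from_truth
from parscope.tiling import CloneInterval, FishStatus, TilingPath, annotate


def two_clone_path(end_a, start_b, status_a=FishStatus.XY_HOMOLOGOUS,
                   status_b=FishStatus.X_ONLY):
    path = TilingPath(
        "X",
        [
            CloneInterval("A", "X", end_a - 170_000, end_a),
            CloneInterval("B", "X", start_b, start_b + 170_000),
        ],
    )
    return annotate(path, [status_a, status_b])


class TestInferPab:
    def test_flanking_bac_worked_example(self, boundary_flanking_path):
        call = infer_pab(boundary_flanking_path)
        assert call.last_par_clone == "CH242-236H7"
        assert call.first_xspecific_clone == "CH242-156O11"
        assert call.interval_start == 6_500_000
        assert call.interval_end == 6_910_000
        assert call.width == 410_000
        rep = call.report()
        assert rep["width_kb_rounded"] == 400
        assert rep["width_label"] == "~400 kb"
        assert rep["interval_mb"] == [6.50, 6.91]

    def test_adjacent_clones_give_zero_width_point_boundary(self):
        ann = two_clone_path(end_a=1_000_000, start_b=1_000_000)
        call = infer_pab(ann)
        assert call.width == 0
        assert call.interval_start == call.interval_end == 1_000_000

    def test_overlapping_flanking_clones_floor_width_at_zero(self):
        ann = two_clone_path(end_a=1_050_000, start_b=1_000_000)
        with pytest.warns(UserWarning, match="overlap"):
            call = infer_pab(ann)
        assert call.width == 0
        assert call.interval_start == call.interval_end

    def test_no_xy_clone_before_first_x_only_is_an_error(self):
        ann = two_clone_path(1_000_000, 2_000_000,
                             status_a=FishStatus.X_ONLY,
                             status_b=FishStatus.XY_HOMOLOGOUS)
        with pytest.raises(PABInferenceError, match="no PAR evidence"):
            infer_pab(ann)

    def test_no_x_only_clone_is_an_error(self):
        ann = two_clone_path(1_000_000, 2_000_000,
                             status_b=FishStatus.UNTESTED)
        with pytest.raises(PABInferenceError, match="no PAR evidence"):
            infer_pab(ann)

    def test_tight_interleave_is_an_error_listing_clones(self):
        path = TilingPath("X", [
            CloneInterval("A", "X", 0, 100),
            CloneInterval("B", "X", 100, 200),
            CloneInterval("C", "X", 200, 300),
        ])
        ann = annotate(path, [FishStatus.XY_HOMOLOGOUS, FishStatus.X_ONLY,
                              FishStatus.XY_HOMOLOGOUS])
        with pytest.raises(InconsistentAnnotationError, match="B.*C"):
            infer_pab(ann)

    def test_distal_homology_block_does_not_break_inference(self):
        # a well-separated XY block beyond an established X-only run is
        # legitimate (it is how the real chromosome looks)
        statuses = (
            [FishStatus.XY_HOMOLOGOUS] * 3
            + [FishStatus.X_ONLY] * 5
            + [FishStatus.XY_HOMOLOGOUS] * 2
            + [FishStatus.X_ONLY] * 2
        )
        path = TilingPath("X", [
            CloneInterval(f"c{i}", "X", i * 100, (i + 1) * 100)
            for i in range(len(statuses))
        ])
        call = infer_pab(annotate(path, statuses))
        assert call.last_par_clone == "c2"
        assert call.first_xspecific_clone == "c3"

    def test_untested_gap_clones_are_skipped(self):
        statuses = [FishStatus.XY_HOMOLOGOUS, FishStatus.UNTESTED, FishStatus.X_ONLY]
        path = TilingPath("X", [
            CloneInterval(f"c{i}", "X", i * 100, (i + 1) * 100) for i in range(3)
        ])
        call = infer_pab(annotate(path, statuses))
        assert call.interval_start == 100  # end of c0
        assert call.interval_end == 200  # start of c2

    def test_annotation_row_order_never_changes_call(self, boundary_flanking_path):
        from parscope.tiling import join_annotations

        path = boundary_flanking_path.path
        a = join_annotations(path, {"CH242-236H7": FishStatus.XY_HOMOLOGOUS,
                                    "CH242-156O11": FishStatus.X_ONLY})
        b = join_annotations(path, {"CH242-156O11": FishStatus.X_ONLY,
                                    "CH242-236H7": FishStatus.XY_HOMOLOGOUS})
        assert infer_pab(a) == infer_pab(b)

    def test_synthetic_interval_brackets_true_boundary(self, default_run):
        path, truth, _, _ = default_run
        call = infer_pab(annotate_from_truth(path, truth))
        assert call.brackets(truth.true_pab_position)


class TestParSize:
    def test_worked_example_size_report(self, boundary_flanking_path):
        call = infer_pab(boundary_flanking_path)
        size = par_size(call)
        assert size["point_estimate_bp"] == pytest.approx(6_705_000)
        assert size["point_estimate_mb"] == 6.7
        assert size["range_mb"] == [6.5, 6.9]

    def test_degenerate_zero_interval(self):
        ann = two_clone_path(0 + 170_000, 170_000)
        call = infer_pab(ann)
        assert par_size(call)["point_estimate_bp"] == 170_000

    def test_midpoint_matches_direct_arithmetic(self, rng):
        for _ in range(20):
            a = int(rng.integers(0, 10_000_000))
            b = a + int(rng.integers(0, 2_000_000))
            ann = two_clone_path(a, b)
            call = infer_pab(ann)
            assert call.par_size_point_estimate == (a + b) / 2


class TestArrayOnlyBoundary:
    def test_clone_resolution_interval_on_noise_free_data(self, noise_free_run):
        path, truth, tables, _ = noise_free_run
        track = build_track(path, clone_profiles(tables))
        call = infer_pab_array_only(track, path, threshold=0.2)
        assert call.evidence == "array_only"
        assert call.brackets(truth.true_pab_position)

    def test_track_not_starting_above_threshold_is_an_error(self):
        from parscope.regions import SmoothedTrack, moving_average

        values = np.array([0.0, 0.1, 1.0, 1.0])
        path = TilingPath("X", [
            CloneInterval(f"c{i}", "X", i * 100, (i + 1) * 100) for i in range(4)
        ])
        track = SmoothedTrack(
            clone_ids=tuple(path.clone_ids),
            mean_log2=values,
            smoothed_log2=moving_average(values, 3),
            window=3,
        )
        with pytest.raises(PABInferenceError, match="proximal end"):
            infer_pab_array_only(track, path)


class TestClassifyRegions:
    @staticmethod
    def region_of(path, lo, hi):
        members = [path[i] for i in range(lo, hi)]
        return Region(
            chrom="X",
            start=min(c.start for c in members),
            end=max(c.end for c in members),
            clone_ids=tuple(c.clone_id for c in members),
            peak_smoothed_log2=0.5,
            n_clones=hi - lo,
        )

    @pytest.fixture
    def labelled_path(self):
        statuses = [
            FishStatus.XY_HOMOLOGOUS,  # 0: proximal PAR evidence
            FishStatus.UNTESTED,       # 1
            FishStatus.X_ONLY,         # 2
            FishStatus.PANGENOMIC_REPETITIVE,  # 3
            FishStatus.UNTESTED,       # 4
            FishStatus.XY_HOMOLOGOUS,  # 5: distal block
            FishStatus.XY_HOMOLOGOUS,  # 6
            FishStatus.XY_HOMOLOGOUS,  # 7
        ]
        path = TilingPath("X", [
            CloneInterval(f"c{i}", "X", i * 100, (i + 1) * 100)
            for i in range(len(statuses))
        ])
        return annotate(path, statuses)

    def test_proximal_region_with_xy_member_is_par(self, labelled_path):
        region = self.region_of(labelled_path.path, 0, 2)
        assert classify_regions([region], labelled_path) == [RegionLabel.PAR]

    def test_distal_all_xy_region_is_xy_homology(self, labelled_path):
        region = self.region_of(labelled_path.path, 5, 8)
        assert classify_regions([region], labelled_path) == [RegionLabel.XY_HOMOLOGY]

    def test_mixed_xy_and_x_only_region_is_conflicting(self, labelled_path):
        region = self.region_of(labelled_path.path, 0, 3)  # includes X_ONLY c2
        assert classify_regions([region], labelled_path) == [RegionLabel.CONFLICTING]

    def test_repetitive_and_unconfirmed_labels(self, labelled_path):
        rep = self.region_of(labelled_path.path, 3, 4)
        untested = self.region_of(labelled_path.path, 4, 5)
        assert classify_regions([rep, untested], labelled_path) == [
            RegionLabel.REPETITIVE,
            RegionLabel.UNCONFIRMED,
        ]
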