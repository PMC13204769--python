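"""Figure-copy extraction, archetype fitting and criteria scoring."""

import numpy as np
import pytest

import neglectscore as ns
from neglectscore.copying import (extract_drawing, fit_archetype, score_star,
                                  score_diamond)
from conftest import make_ink_mask


def copy_run(run_pipeline, subtest, **kw):
    truth, norm, ink, score = run_pipeline(subtest, **kw)
    return truth, score.result


class TestExtractDrawing:
    def test_ideal_star_has_8_corners_4_outer(self, run_pipeline,
                                              templates, config):
        _, norm, ink, _ = run_pipeline("copy_star", seed=11)
        pts, corners = extract_drawing(
            ink, templates["copy_star"].drawing_region, "star", config)
        assert len(corners) == 8
        assert corners.classes.count("outer") == 4
        assert corners.classes.count("inner") == 4
        # corners ordered angularly around the centroid
        assert corners.angles_deg == sorted(corners.angles_deg)

    def test_corners_lie_on_true_geometry(self, run_pipeline, templates,
                                          config):
        truth, norm, ink, _ = run_pipeline("copy_star", seed=11)
        pts, corners = extract_drawing(
            ink, templates["copy_star"].drawing_region, "star", config)
        true_v = np.asarray(truth.copy_geometry["vertices"])
        for c in corners.corners:
            assert np.min(np.hypot(*(true_v - np.asarray(c)).T)) <= 6.0

    def test_deleted_tip_yields_fewer_corners(self, run_pipeline,
                                              templates, config):
        _, norm, ink, _ = run_pipeline("copy_star", seed=11, delete_tip=1)
        pts, corners = extract_drawing(
            ink, templates["copy_star"].drawing_region, "star", config)
        assert len(corners) < 8

    def test_empty_region_degenerates_quietly(self, templates, config):
        ink = make_ink_mask(np.zeros((1980, 1400), bool))
        pts, corners = extract_drawing(
            ink, templates["copy_star"].drawing_region, "star", config)
        assert len(corners) == 0
        arch = fit_archetype(corners, "star")
        assert arch.degenerate
        assert score_star(pts, corners, arch).net_sum == 0


class TestFitArchetype:
    def test_translation_equivariance(self, run_pipeline, templates,
                                      config):
        region = templates["copy_star"].drawing_region
        outs = []
        for off in ((0.0, 0.0), (60.0, -40.0)):
            _, norm, ink, _ = run_pipeline("copy_star", seed=11,
                                           copy_center_offset=off)
            pts, corners = extract_drawing(ink, region, "star", config)
            outs.append(np.asarray(fit_archetype(corners, "star").vertices))
        shift = outs[1] - outs[0]
        assert np.allclose(shift.mean(axis=0), (60.0, -40.0), atol=2.0)
        assert np.std(shift, axis=0).max() <= 2.0

    def test_scale_equivariance(self, run_pipeline, templates, config):
        region = templates["copy_star"].drawing_region
        rads = []
        for scale in (1.0, 0.5):
            _, norm, ink, _ = run_pipeline("copy_star", seed=11,
                                           copy_scale=scale)
            pts, corners = extract_drawing(ink, region, "star", config)
            v = np.asarray(fit_archetype(corners, "star").vertices)
            c = v.mean(axis=0)
            rads.append(np.hypot(*(v - c).T).mean())
        assert rads[1] / rads[0] == pytest.approx(0.5, abs=0.03)

    def test_degenerate_below_three_corners(self):
        cs = ns.CornerSet(corners=[(0, 0), (1, 1)], classes=["outer"] * 2,
                          centroid=(0.5, 0.5), angles_deg=[0.0, 180.0])
        assert fit_archetype(cs, "star").degenerate


class TestScoreStar:
    def test_ideal_star_full_marks(self, run_pipeline):
        _, r = copy_run(run_pipeline, "copy_star", seed=11)
        assert (r.shape, r.detail, r.arrangement) == (1, 1, 1)
        assert r.net_sum == 3 and r.bit_binary == 1

    def test_three_point_star_fails_detail_only(self, run_pipeline):
        # closed 6-corner outline: gestalt fine, eight corners required
        _, r = copy_run(run_pipeline, "copy_star", seed=11, star_n_tips=3,
                        star_tip_angle_deg=80.0)
        assert r.shape == 1 and r.detail == 0 and r.bit_binary == 0

    def test_all_angles_outside_strict_band_fail_arrangement(self,
                                                             run_pipeline):
        # four tips at 70°: each deviates 40° (allowed) but none is within
        # 30° of the expected 110°, so the two-angle rule fails
        _, r = copy_run(run_pipeline, "copy_star", seed=11,
                        star_tip_angle_deg=70.0)
        assert r.shape == 1 and r.detail == 1 and r.arrangement == 0

    def test_angle_beyond_max_deviation_fails(self, run_pipeline):
        _, r = copy_run(run_pipeline, "copy_star", seed=11,
                        star_tip_angle_deg=65.0)
        assert r.arrangement == 0

    def test_rotated_ideal_star_fails_arrangement(self, run_pipeline):
        # spans and opposing-tip alignment are axis-aligned: arrangement is
        # deliberately not rotation invariant
        _, r = copy_run(run_pipeline, "copy_star", seed=11,
                        star_rotation_deg=45.0)
        assert r.shape == 1 and r.detail == 1
        assert r.arrangement == 0
        assert r.diagnostics["tip_misalignment"] > 200.0

    def test_edge_gap_beyond_closure_tolerance_fails_shape(self,
                                                           run_pipeline):
        _, r = copy_run(run_pipeline, "copy_star", seed=11,
                        gap_probability=1.0, gap_width_px=30.0)
        assert r.shape == 0 and r.bit_binary == 0

    def test_small_gap_within_tolerance_passes(self, run_pipeline):
        _, r = copy_run(run_pipeline, "copy_star", seed=11,
                        gap_probability=1.0, gap_width_px=6.0)
        assert r.shape == 1

    def test_tremor_within_corridor_tolerated(self, run_pipeline):
        _, r = copy_run(run_pipeline, "copy_star", seed=11,
                        tremor_amplitude_px=3.0)
        assert r.net_sum == 3

    def test_gating_invariants(self, run_pipeline):
        for kw in ({}, {"delete_tip": 0}, {"star_tip_angle_deg": 70.0},
                   {"gap_probability": 1.0, "gap_width_px": 40.0}):
            _, r = copy_run(run_pipeline, "copy_star", seed=5, **kw)
            assert r.bit_binary == int(bool(r.shape and r.detail))
            assert r.detail <= r.shape          # star detail gated on shape
            assert r.net_hierarchical <= r.net_sum


class TestScoreDiamond:
    def test_perfect_diamond_full_marks(self, run_pipeline):
        _, r = copy_run(run_pipeline, "copy_diamond", seed=7)
        assert (r.shape, r.detail, r.arrangement) == (1, 1, 1)
        assert r.net_sum == 3 and r.net_hierarchical == 3
        assert r.bit_binary == 1

    def test_one_deviant_angle_tolerated_two_fail(self, run_pipeline):
        _, r1 = copy_run(run_pipeline, "copy_diamond", seed=7,
                         diamond_angles=(55.0, 45.0, 45.0, 45.0))
        assert r1.arrangement == 1
        _, r2 = copy_run(run_pipeline, "copy_diamond", seed=7,
                         diamond_angles=(55.0, 55.0, 45.0, 45.0))
        assert r2.arrangement == 0

    def test_missing_midline_fails_detail_and_gates(self, run_pipeline):
        _, r = copy_run(run_pipeline, "copy_diamond", seed=7,
                        draw_midline=False)
        assert r.shape == 1 and r.detail == 0
        assert r.bit_binary == 0
        # hierarchical arrangement forced to 0 without shape+detail
        assert r.net_hierarchical == 1

    def test_detached_midline_counts_as_absent(self, run_pipeline):
        # a gap between midline and corners beyond tolerance: no midline
        _, r = copy_run(run_pipeline, "copy_diamond", seed=7,
                        midline_gap_px=40.0)
        assert r.detail == 0

    def test_angle_sweep_flips_exactly_above_7_degrees(self, run_pipeline):
        flips = {}
        for delta in range(0, 15):
            _, r = copy_run(run_pipeline, "copy_diamond", seed=7,
                            diamond_angle_deltas=(float(delta), 0.0))
            flips[delta] = r.arrangement
        assert all(flips[d] == 1 for d in range(0, 8))
        assert all(flips[d] == 0 for d in range(8, 15))

    def test_translation_invariance_of_scores(self, run_pipeline):
        _, r0 = copy_run(run_pipeline, "copy_diamond", seed=7)
        _, r1 = copy_run(run_pipeline, "copy_diamond", seed=7,
                         copy_center_offset=(-70.0, 55.0))
        assert (r0.shape, r0.detail, r0.arrangement) == \
               (r1.shape, r1.detail, r1.arrangement)
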