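"""Geometry extraction and deformation-coefficient unit/property tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import meibomorph as mb
from meibomorph.morphometry import (
    MorphometryError,
    extract_geometry,
    label_glands,
    width_variation,
)
from meibomorph.synthetic import GlandShapeParams, generate_gland_mask

from conftest import dense_arc_oracle


class TestExtractGeometry:
    def test_axis_aligned_rectangle_is_measured_exactly(self, rect_mask):
        g = extract_geometry(rect_mask)
        assert g.pa == pytest.approx(99.0)
        assert g.pb == pytest.approx(99.0)
        assert g.L_central == pytest.approx(99.0)
        assert np.all(g.widths == 10.0)
        assert g.sigma_w == 0.0
        assert g.n == 100

    def test_rotated_rectangle_recovered_via_axis_alignment(self):
        from skimage.transform import rotate

        big = np.zeros((200, 200))
        big[50:150, 95:105] = 1
        rot = rotate(big, 30, order=0, resize=True) > 0.5
        g = extract_geometry(rot)
        for val in (g.pa, g.pb, g.L_central):
            assert val == pytest.approx(99.0, rel=0.02)

    def test_sinusoid_matches_dense_integration_oracle(self, sinusoid_gland):
        params, mask, _ = sinusoid_gland
        pa_o, pb_o, chord_o = dense_arc_oracle(params)
        g = extract_geometry(mask)
        assert g.pa == pytest.approx(pa_o, rel=0.02)
        assert g.pb == pytest.approx(pb_o, rel=0.02)
        assert g.L_central == pytest.approx(chord_o, rel=0.02)

    def test_too_short_and_fragmented_glands_raise(self):
        single = np.zeros((5, 5), dtype=bool)
        single[2, 2] = True
        with pytest.raises(MorphometryError, match="too short"):
            extract_geometry(single)
        with pytest.raises(MorphometryError, match="empty"):
            extract_geometry(np.zeros((5, 5), dtype=bool))
        frag = np.zeros((30, 9), dtype=bool)  # two blobs with an internal gap
        frag[0:10, 2:7] = True
        frag[15:25, 2:7] = True
        with pytest.raises(MorphometryError, match="fragmented"):
            extract_geometry(frag)


class TestLabelGlands:
    def test_orders_left_to_right_and_filters_small(self):
        mask = np.zeros((60, 100), dtype=bool)
        mask[10:50, 70:80] = True   # right gland
        mask[10:50, 10:20] = True   # left gland
        mask[5:7, 40:42] = True     # 4-px speck, below min_area
        comps = label_glands(mask, min_area=64)
        assert len(comps) == 2
        assert comps[0].centroid_col < comps[1].centroid_col

    def test_empty_mask_gives_empty_list(self):
        assert label_glands(np.zeros((10, 10), dtype=bool)) == []

    def test_equal_centroid_column_breaks_tie_by_topmost_row(self):
        mask = np.zeros((120, 30), dtype=bool)
        mask[5:45, 10:20] = True    # upper component
        mask[60:100, 10:20] = True  # lower component, same centroid column
        comps = label_glands(mask)
        assert len(comps) == 2
        assert comps[0].topmost_row < comps[1].topmost_row


class TestDeformationCoefficient:
    def test_straight_uniform_gland_attains_minimum_one(self, rect_mask):
        g = extract_geometry(rect_mask)
        assert mb.deformation_coefficient(g) == 1.0
        assert mb.deformation_coefficient(g, "normalized") == 0.0

    def test_literal_formula_vanishes_on_uniform_gland(self, rect_mask):
        # The literal product with raw sigma_w is 0, not the stated
        # minimum of 1 - the inconsistency the default variant repairs.
        g = extract_geometry(rect_mask)
        assert mb.deformation_coefficient(g, "as_printed") == 0.0

    def test_constant_width_sinusoid_reduces_to_arc_chord_factor(self, sinusoid_gland):
        params, mask, truth = sinusoid_gland
        pa_o, pb_o, chord_o = dense_arc_oracle(params)
        expected = pa_o * pb_o / chord_o**2
        assert truth.sigma_w == pytest.approx(0.0, abs=1e-9)
        assert mb.deformation_coefficient(truth) == pytest.approx(expected, rel=1e-4)
        assert mb.deformation_coefficient(extract_geometry(mask)) == pytest.approx(
            expected, rel=0.02
        )

    def test_unknown_variant_rejected(self, rect_mask):
        with pytest.raises(MorphometryError, match="variant"):
            mb.deformation_coefficient(extract_geometry(rect_mask), "bogus")

    def test_scale_invariance_across_rasterization_scales(self):
        # full periods keep the central chord axis-aligned at every scale
        base = dict(base_width_px=8.0, amplitude_px=8.0,
                    wavelength_px=60.0, width_slope=0.02, phase_rad=0.4)
        ds = []
        for s in (1, 2, 3):
            p = GlandShapeParams(
                length_px=120 * s + 1,
                base_width_px=base["base_width_px"] * s,
                amplitude_px=base["amplitude_px"] * s,
                wavelength_px=base["wavelength_px"] * s,
                width_slope=base["width_slope"],
                phase_rad=base["phase_rad"],
                axis_col=(base["amplitude_px"] + base["base_width_px"]) * s + 10.25,
            )
            mask, _ = generate_gland_mask(p, p.length_px + 20, int(p.axis_col * 2) + 20)
            ds.append(mb.deformation_coefficient(extract_geometry(mask)))
        assert max(ds) / min(ds) < 1.02

    def test_monotone_in_centerline_amplitude(self):
        ds = []
        for amp in range(0, 21, 2):
            p = GlandShapeParams(length_px=100, base_width_px=10.0, amplitude_px=amp,
                                 wavelength_px=100.0, axis_col=40.25)
            mask, _ = generate_gland_mask(p, 120, 100)
            ds.append(mb.deformation_coefficient(extract_geometry(mask)))
        assert all(b >= a - 1e-9 for a, b in zip(ds, ds[1:]))

    def test_arc_chord_factor_at_least_one_up_to_discretization(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            p = GlandShapeParams(
                length_px=int(rng.integers(80, 200)),
                base_width_px=float(rng.uniform(7, 14)),
                amplitude_px=float(rng.uniform(0, 20)),
                wavelength_px=float(rng.uniform(60, 150)),
                width_slope=float(rng.uniform(-0.02, 0.02)),
                phase_rad=float(rng.uniform(0, 2 * np.pi)),
                axis_col=60.25,
            )
            mask, _ = generate_gland_mask(p, p.length_px + 20, 160)
            g = extract_geometry(mask)
            assert g.pa * g.pb / g.L_central**2 >= 1.0 - 0.02


class TestWidthVariation:
    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=1.0, max_value=50.0), min_size=2, max_size=200))
    def test_matches_direct_summation_with_n_plus_1_denominator(self, widths):
        w = np.asarray(widths)
        direct = np.sqrt(sum((x - w.mean()) ** 2 for x in widths) / (len(widths) + 1))
        assert width_variation(widths) == pytest.approx(direct, rel=1e-9, abs=1e-12)

    def test_denominator_switch(self):
        w = [10.0, 12.0, 14.0]
        assert width_variation(w, "n_minus_1") == pytest.approx(np.std(w, ddof=1))


class TestAnalyzeEye:
    def test_fewer_than_ten_glands_is_an_error_naming_the_count(self):
        mask = np.zeros((140, 400), dtype=bool)
        for i in range(8):
            mask[20:120, 10 + i * 45 : 20 + i * 45] = True
        with pytest.raises(MorphometryError, match=r"insufficient glands \(8 < 10\)"):
            mb.analyze_eye(mask, "OD", "treatment")

    def test_round_trip_recovers_generated_deformation_targets(self):
        from meibomorph.synthetic import CohortSpec, generate_cohort, render_eye_scene

        subs = generate_cohort(CohortSpec(n_subjects=2, seed=0))
        for subj in subs:
            for eye in (subj.treatment, subj.control):
                scene = render_eye_scene(eye, noise_sd=0.0, seed=1)
                rec = mb.analyze_eye(scene.mask, eye.record.laterality, eye.record.group)
                assert len(rec.records) == 10
                for r in rec.records:
                    assert r.D == pytest.approx(eye.realized_d[r.gland_index], abs=0.05)

    def test_mirrored_scene_with_flipped_laterality_gives_identical_records(self):
        from meibomorph.synthetic import CohortSpec, generate_cohort, render_eye_scene

        eye = generate_cohort(CohortSpec(n_subjects=2, seed=5))[0].treatment
        scene = render_eye_scene(eye, noise_sd=0.0, seed=1)
        rec = mb.analyze_eye(scene.mask, eye.record.laterality, "treatment")
        flipped_lat = "OS" if eye.record.laterality == "OD" else "OD"
        rec_m = mb.analyze_eye(scene.mask[:, ::-1], flipped_lat, "treatment")
        d = {r.gland_index: r.D for r in rec.records}
        d_m = {r.gland_index: r.D for r in rec_m.records}
        for idx in d:
            assert d_m[idx] == pytest.approx(d[idx], abs=1e-9)
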