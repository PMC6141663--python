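import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vesiquant import (RegionOfInterest, align_and_average_profiles,
                       enrichment_fold, extract_line_profile,
                       manders_coefficients, nearest_soma_distance,
                       select_synapses, simulate_coloc_pair, synapse_density)
from vesiquant.coloc import LineProfile, build_synapse_map


class TestManders:
    def test_identical_images_give_unity(self, rng):
        a = rng.uniform(1, 10, (16, 16))
        res = manders_coefficients(a, a.copy())
        assert res.M1 == pytest.approx(1.0)
        assert res.M2 == pytest.approx(1.0)

    def test_disjoint_supports_give_zero(self):
        a = np.zeros((8, 8))
        b = np.zeros((8, 8))
        a[:4] = 5.0
        b[4:] = 5.0
        res = manders_coefficients(a, b)
        assert res.M1 == 0.0 and res.M2 == 0.0

    def test_two_by_two_worked_example(self):
        a = np.array([[2.0, 0.0], [0.0, 2.0]])
        b = np.array([[1.0, 1.0], [0.0, 0.0]])
        res = manders_coefficients(a, b)
        assert res.M1 == pytest.approx(0.5)
        assert res.M2 == pytest.approx(0.5)

    def test_matches_per_pixel_brute_force(self):
        for seed in range(20):
            r = np.random.default_rng(seed)
            a = r.integers(0, 10, (8, 8)).astype(float)
            b = r.integers(0, 10, (8, 8)).astype(float)
            res = manders_coefficients(a, b)
            m1 = a[b > 0].sum() / a[a > 0].sum()
            m2 = b[a > 0].sum() / b[b > 0].sum()
            assert res.M1 == m1 and res.M2 == m2  # exact equality

    def test_simulated_pair_truth_recovered(self):
        a, b, truth = simulate_coloc_pair(150, 0.37, seed=5)
        res = manders_coefficients(a, b)
        assert res.M1 == pytest.approx(truth.manders["M1"])
        assert res.M2 == pytest.approx(truth.manders["M2"])

    def test_empty_denominator_flagged_undefined(self):
        res = manders_coefficients(np.zeros((4, 4)), np.ones((4, 4)))
        assert res.M1 is None

    def test_roi_restriction(self):
        a = np.ones((8, 8))
        b = np.zeros((8, 8))
        b[:4] = 1.0
        mask = np.zeros((8, 8), dtype=bool)
        mask[:4] = True  # only the overlapping half
        roi = RegionOfInterest("label_mask", mask=mask)
        res = manders_coefficients(a, b, roi)
        assert res.M1 == pytest.approx(1.0)
        assert res.n_pixels == 32


class TestSelectSynapses:
    def _scene(self, delta_a, delta_b):
        a = np.full((64, 64), 100.0)
        b = np.full((64, 64), 150.0)
        a[30, 30] += delta_a
        b[30, 30] += delta_b
        mask = np.zeros((64, 64), dtype=bool)
        mask[25:36, 25:36] = True
        roi = RegionOfInterest("label_mask", mask=mask)
        return a, b, [(30.0, 30.0)], [roi]

    def test_bright_in_both_channels_selected(self):
        a, b, cand, rois = self._scene(1500.0, 1500.0)
        assert len(select_synapses(a, b, cand, rois)) == 1

    def test_one_channel_only_rejected(self):
        a, b, cand, rois = self._scene(1500.0, 0.0)
        assert len(select_synapses(a, b, cand, rois)) == 0

    def test_below_1000_au_rejected(self):
        a, b, cand, rois = self._scene(500.0, 500.0)
        assert len(select_synapses(a, b, cand, rois)) == 0


class TestLineProfiles:
    def test_constant_image_gives_constant_profile(self):
        img = np.full((40, 40), 7.0)
        p = extract_line_profile(img, [(20, 5), (20, 35)], width=3)
        np.testing.assert_allclose(p.intensities, 7.0)

    def test_bright_row_crossing_peaks_at_intersection(self):
        img = np.zeros((40, 40))
        img[20, :] = 99.0
        p = extract_line_profile(img, [(10, 20), (30, 20)], width=3)
        assert np.argmax(p.intensities) == 10
        assert p.intensities[10] == pytest.approx(99.0)
        assert p.intensities[0] == 0.0

    def test_width_one_reduces_to_direct_interpolation(self, rng):
        from scipy.ndimage import map_coordinates

        img = rng.uniform(0, 100, (40, 40))
        p = extract_line_profile(img, [(20.0, 5.0), (20.0, 30.0)], width=1)
        direct = map_coordinates(img, [np.full(26, 20.0),
                                       np.arange(5.0, 31.0)], order=1)
        np.testing.assert_allclose(p.intensities, direct)

    def test_path_exiting_image_rejected(self):
        img = np.zeros((20, 20))
        with pytest.raises(ValueError, match="exits"):
            extract_line_profile(img, [(10, -5), (10, 10)], width=3)

    def test_positions_scale_with_pixel_size(self):
        img = np.zeros((40, 40))
        p = extract_line_profile(img, [(20, 5), (20, 25)], width=1,
                                 pixel_size=0.2)
        assert p.positions_um[-1] == pytest.approx(4.0)


class TestAlignAndAverage:
    def _peak_profile(self, offset, n=21, amp=5.0):
        x = np.zeros(n)
        x[n // 2 + offset] = amp
        return LineProfile(np.arange(n, dtype=float) * 0.2, x)

    def test_shifted_peaks_align_to_undiminished_center(self):
        prof = {"ref": [self._peak_profile(2), self._peak_profile(-2)]}
        pos, mean, sem = align_and_average_profiles(prof, "ref")["ref"]
        assert mean[10] == pytest.approx(5.0)
        assert pos[10] == 0.0
        assert np.nansum(mean > 0.0) == 1  # a single central peak

    def test_averaging_copies_is_idempotent(self):
        p = self._peak_profile(0)
        prof = {"ref": [LineProfile(p.positions_um.copy(),
                                    p.intensities.copy()) for _ in range(5)]}
        _, mean, _ = align_and_average_profiles(prof, "ref")["ref"]
        np.testing.assert_allclose(mean, p.intensities)

    def test_single_profile_identity_up_to_centering(self):
        p = self._peak_profile(3)
        _, mean, _ = align_and_average_profiles({"ref": [p]}, "ref")["ref"]
        assert np.nanmax(mean) == pytest.approx(5.0)
        assert np.nanargmax(mean) == 10

    def test_flat_profiles_average_flat(self):
        prof = {"ref": [LineProfile(np.arange(9.0), np.full(9, 2.0))
                        for _ in range(3)]}
        _, mean, _ = align_and_average_profiles(prof, "ref")["ref"]
        valid = ~np.isnan(mean)
        np.testing.assert_allclose(mean[valid], 2.0)

    def test_secondary_channel_shifted_with_reference(self):
        ref = self._peak_profile(2)
        other = self._peak_profile(2, amp=3.0)
        out = align_and_average_profiles({"ref": [ref], "caps": [other]}, "ref")
        _, mean_caps, _ = out["caps"]
        assert np.nanargmax(mean_caps) == 10  # moved by the reference shift

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError):
            align_and_average_profiles({"a": [self._peak_profile(0)]}, "ref")


class TestEnrichmentFold:
    def _profile(self, center_val, flank_val):
        pos = np.linspace(-2.0, 2.0, 41)
        vals = np.where(np.abs(pos) <= 0.5, center_val, flank_val)
        return pos, vals

    def test_headline_ratio(self):
        pos, vals = self._profile(460.0, 100.0)
        assert enrichment_fold(pos, vals) == pytest.approx(4.6)

    def test_flat_profile_gives_unity(self):
        pos, vals = self._profile(3.0, 3.0)
        assert enrichment_fold(pos, vals) == pytest.approx(1.0)

    def test_zero_flanks_rejected(self):
        pos, vals = self._profile(10.0, 0.0)
        with pytest.raises(ValueError):
            enrichment_fold(pos, vals)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.floats(min_value=1e-6, max_value=1e6))
    def test_scale_invariance(self, scale):
        pos, vals = self._profile(460.0, 100.0)
        assert enrichment_fold(pos, vals * scale) == pytest.approx(4.6)


class TestSynapseMapping:
    def test_density_arithmetic(self):
        pts = np.zeros((50, 2))
        assert synapse_density(pts, 1000.0) == pytest.approx(0.05)
        assert synapse_density(np.empty((0, 2)), 10.0) == 0.0
        with pytest.raises(ValueError):
            synapse_density(pts, 0.0)

    def test_distance_to_square_edge(self):
        square = np.array([(10, 10), (10, 20), (20, 20), (20, 10)])
        assert nearest_soma_distance((15, 25), [square], 0.2) == pytest.approx(1.0)

    def test_boundary_and_interior_are_zero(self):
        square = np.array([(10, 10), (10, 20), (20, 20), (20, 10)])
        assert nearest_soma_distance((15, 20), [square], 0.2) == 0.0
        assert nearest_soma_distance((15, 15), [square], 0.2) == 0.0

    def test_empty_outline_list_rejected(self):
        with pytest.raises(ValueError):
            nearest_soma_distance((0, 0), [], 1.0)

    def test_build_map(self):
        square = np.array([(0, 0), (0, 10), (10, 10), (10, 0)])
        m = build_synapse_map(np.array([(5.0, 15.0)]), (100, 100), 0.1,
                              [square])
        assert m.image_area_um2 == pytest.approx(100.0)
        assert m.density_per_um2 == pytest.approx(0.01)
        assert m.distances_um[0] == pytest.approx(0.5)
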