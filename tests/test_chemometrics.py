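"""Chemometrics: band maps, teaching regions, SAM, LDA, edge response."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import erf

import mirhsi as M
from mirhsi.chemometrics import (
    GAUSSIAN_EDGE_FACTOR,
    RegionSamplingError,
    fisher_criterion,
    scatter_matrices,
)
from tests.conftest import teaching_from_truth


class TestAdditiveAveraging:
    def test_constant_cube_returns_constant(self):
        cube = np.full((4, 5, 10), 3.25)
        i_ave, mask = M.additive_averaging(cube, (2, 7))
        np.testing.assert_allclose(i_ave, 3.25)
        assert mask.all()

    def test_sum_over_n_arithmetic(self):
        cube = np.zeros((1, 1, 5))
        cube[0, 0] = [1.0, 2.0, 3.0, 4.0, 0.0]  # S = 10 over n = 5
        i_ave, _ = M.additive_averaging(cube, (0, 5))
        assert i_ave[0, 0] == 2.0

    def test_threshold_mask(self):
        cube = np.arange(8.0).reshape(2, 2, 2)
        i_ave, mask = M.additive_averaging(cube, (0, 2), (2.0, 5.0))
        np.testing.assert_array_equal(mask, (i_ave >= 2.0) & (i_ave <= 5.0))

    def test_empty_band_selection_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            M.additive_averaging(np.ones((2, 2, 4)), (3, 3))


class TestNdsi:
    def test_equal_bands_give_zero(self):
        cube = np.random.default_rng(0).uniform(1, 2, (3, 3, 4))
        cube[..., 1] = cube[..., 0]
        ndsi, _, _ = M.ndsi_map(cube, 0, 1)
        np.testing.assert_allclose(ndsi, 0.0)

    def test_three_one_gives_half(self):
        cube = np.zeros((1, 1, 2))
        cube[0, 0] = [3.0, 1.0]
        ndsi, _, _ = M.ndsi_map(cube, 0, 1)
        assert ndsi[0, 0] == 0.5

    def test_boundary_value_when_second_band_zero(self):
        cube = np.zeros((1, 1, 2))
        cube[0, 0] = [2.0, 0.0]
        ndsi, _, _ = M.ndsi_map(cube, 0, 1)
        assert ndsi[0, 0] == 1.0

    def test_range_and_antisymmetry(self):
        cube = np.random.default_rng(1).uniform(0, 5, (6, 6, 3))
        a, _, _ = M.ndsi_map(cube, 0, 2)
        b, _, _ = M.ndsi_map(cube, 2, 0)
        assert np.all(a >= -1) and np.all(a <= 1)
        np.testing.assert_allclose(a, -b)

    def test_zero_total_flagged(self):
        cube = np.zeros((2, 2, 2))
        ndsi, mask, degenerate = M.ndsi_map(cube, 0, 1)
        assert degenerate.all() and not mask.any()
        np.testing.assert_allclose(ndsi, 0.0)

    def test_identical_band_warning(self):
        with pytest.warns(UserWarning, match="identically zero"):
            M.ndsi_map(np.ones((2, 2, 3)), 1, 1)


class TestTeachingRegions:
    CONSTRAINT = M.RegionConstraint(x_min=4, x_max=35, y_min=3, y_max=55,
                                    area_min=20, area_max=720, n_regions=125)

    def test_large_frame_study_constraints(self):
        """125 disjoint rectangles on the full 640x480 frame, all inequalities strict."""
        ts = M.sample_teaching_regions((480, 640), self.CONSTRAINT, seed=1)
        regions = ts.classes["all"]
        assert len(regions) == 125
        for r in regions:
            assert 4 < r.width < 35
            assert 3 < r.height < 55
            assert 20 < r.width * r.height < 720
        for i, a in enumerate(regions):
            for b in regions[i + 1:]:
                assert not a.overlaps(b)

    def test_forced_single_region(self):
        c = M.RegionConstraint(1, 3, 1, 3, 0, 5, 1)
        ts = M.sample_teaching_regions((2, 2), c, seed=0)
        (r,) = ts.classes["all"]
        assert (r.width, r.height) == (2, 2)
        assert (r.row, r.col) == (0, 0)

    def test_same_seed_reproducible(self):
        c = M.RegionConstraint(4, 35, 3, 55, 20, 720, 20)
        a = M.sample_teaching_regions((100, 100), c, seed=9)
        b = M.sample_teaching_regions((100, 100), c, seed=9)
        assert a.classes == b.classes

    def test_infeasible_request_reports_achieved(self):
        c = M.RegionConstraint(4, 35, 3, 55, 20, 720, 1000)
        with pytest.raises(RegionSamplingError) as err:
            M.sample_teaching_regions((60, 60), c, seed=0, max_attempts=2000)
        assert err.value.achieved < 1000

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_constraints_always_satisfied(self, seed):
        c = M.RegionConstraint(2, 10, 2, 10, 5, 60, 10)
        ts = M.sample_teaching_regions((64, 64), c, seed=seed)
        for r in ts.classes["all"]:
            assert c.admits(r.width, r.height)


class TestSam:
    @staticmethod
    def _teaching(refs):
        ts = M.TeachingSet()
        for i, r in enumerate(refs):
            ts.classes[f"c{i}"] = []
            ts.spectra[f"c{i}"] = np.asarray([r], dtype=float)
        return ts

    def test_self_match(self):
        refs = np.eye(3) + 0.1
        ts = self._teaching(refs)
        cube = refs.reshape(1, 3, 3)
        cm = M.sam_classify(cube, ts)
        np.testing.assert_array_equal(cm.labels[0], [1, 2, 3])

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        refs = rng.uniform(0.1, 1, (4, 16))
        ts = self._teaching(refs)
        cube = (5.0 * refs).reshape(2, 2, 16)
        cm = M.sam_classify(cube, ts)
        np.testing.assert_array_equal(cm.labels.ravel(), [1, 2, 3, 4])

    def test_zero_norm_pixel_unclassified(self):
        ts = self._teaching(np.eye(2))
        cube = np.zeros((1, 1, 2))
        cm = M.sam_classify(cube, ts)
        assert cm.labels[0, 0] == 0

    def test_microchannel_noiseless_perfect(self, microchannel_noiseless):
        phantom, _, _, tcube = microchannel_noiseless
        ts = teaching_from_truth(tcube, phantom)
        cm = M.sam_classify(tcube.data, ts)
        in_channel = phantom.labels > 0
        assert cm.accuracy(phantom.labels, in_channel) == 1.0


class TestLda:
    @staticmethod
    def _gaussian_teaching(rng, means, n=40, scale=0.2):
        ts = M.TeachingSet()
        for i, mu in enumerate(means):
            ts.classes[f"c{i}"] = []
            ts.spectra[f"c{i}"] = mu + scale * rng.standard_normal((n, len(mu)))
        return ts

    def test_two_class_matches_closed_form(self):
        rng = np.random.default_rng(3)
        means = [np.zeros(5), np.ones(5)]
        ts = self._gaussian_teaching(rng, means)
        model = M.lda_train(ts)
        _, s_w, _, mus = scatter_matrices(ts)
        w_closed = np.linalg.solve(s_w, mus[0] - mus[1])
        cos = abs(w_closed @ model.w[:, 0]) / (
            np.linalg.norm(w_closed) * np.linalg.norm(model.w[:, 0])
        )
        assert cos == pytest.approx(1.0, abs=1e-8)

    def test_identical_means_zero_criterion(self):
        rng = np.random.default_rng(4)
        base = rng.standard_normal((30, 6))
        ts = M.TeachingSet()
        for name in ("a", "b"):
            ts.classes[name] = []
            # mirrored copies share the mean exactly
            ts.spectra[name] = np.vstack([base, 2 * base.mean(0) - base])
        model = M.lda_train(ts)
        assert model.fisher_j < 1e-10

    def test_beats_random_direction_search(self):
        rng = np.random.default_rng(5)
        means = [np.zeros(8), np.r_[np.ones(4), np.zeros(4)], np.full(8, -0.7)]
        ts = self._gaussian_teaching(rng, means, n=25)
        model = M.lda_train(ts)
        s_b, s_w, _, _ = scatter_matrices(ts)
        v = rng.standard_normal((100_000, 8))
        num = np.einsum("ij,jk,ik->i", v, s_b, v)
        den = np.einsum("ij,jk,ik->i", v, s_w, v)
        assert model.fisher_j >= (num / den).max()

    def test_criterion_scale_invariant(self):
        rng = np.random.default_rng(6)
        ts = self._gaussian_teaching(rng, [np.zeros(4), np.ones(4)])
        s_b, s_w, _, _ = scatter_matrices(ts)
        w = rng.standard_normal(4)
        assert fisher_criterion(3.7 * w, s_b, s_w) == pytest.approx(
            fisher_criterion(w, s_b, s_w), rel=1e-12
        )

    def test_single_class_rejected(self):
        ts = M.TeachingSet(classes={"a": []}, spectra={"a": np.ones((3, 4))})
        with pytest.raises(ValueError, match="two classes"):
            M.lda_train(ts)

    def test_singular_within_scatter_ridged(self):
        ts = M.TeachingSet()
        rng = np.random.default_rng(7)
        for i, name in enumerate(("a", "b")):
            ts.classes[name] = []
            ts.spectra[name] = np.tile(rng.standard_normal(10) + i, (3, 1))  # zero variance
        model = M.lda_train(ts)
        assert model.ridge > 0

    def test_centroid_pixel_classified_to_its_class(self):
        rng = np.random.default_rng(8)
        ts = self._gaussian_teaching(rng, [np.zeros(6), np.ones(6)])
        model = M.lda_train(ts)
        cube = np.stack([ts.spectra["c0"].mean(0), ts.spectra["c1"].mean(0)]).reshape(1, 2, 6)
        cm = M.lda_classify(cube, model)
        np.testing.assert_array_equal(cm.labels[0], [1, 2])

    def test_band_mismatch_rejected(self):
        rng = np.random.default_rng(9)
        ts = self._gaussian_teaching(rng, [np.zeros(6), np.ones(6)])
        model = M.lda_train(ts)
        with pytest.raises(ValueError, match="bands"):
            M.lda_classify(np.ones((2, 2, 4)), model)

    def test_microchannel_with_teaching_peaks(self, microchannel_noisy):
        """Classification on the diagnostic peak bands at real frame noise."""
        phantom, _, _, tcube = microchannel_noisy
        peaks = [p for ps in M.TEACHING_PEAKS.values() for p in ps]
        bands = [tcube.band_near(p) for p in peaks]
        ts = teaching_from_truth(tcube, phantom, seed=21)
        model = M.lda_train(ts, band_idx=bands)
        cm = M.lda_classify(tcube.data, model)
        in_channel = phantom.labels > 0
        assert cm.accuracy(phantom.labels, in_channel) >= 0.95


class TestEdgeResponse:
    def test_ideal_step_bounded_by_pixel_pitch(self):
        profile = np.r_[np.zeros(10), np.ones(10)]
        width = M.edge_response_resolution(profile, pixel_pitch_um=2.0)
        assert 0 < width <= 2.0

    def test_gaussian_edge_matches_closed_form(self):
        sigma_um = 6.0
        pitch = 0.5
        x = np.arange(400) * pitch
        profile = 0.5 * (1 + erf((x - 100.0) / (sigma_um * np.sqrt(2))))
        width = M.edge_response_resolution(profile, pitch)
        assert width == pytest.approx(GAUSSIAN_EDGE_FACTOR * sigma_um, rel=0.02)

    def test_non_monotone_profile_rejected(self):
        profile = np.r_[np.zeros(5), 1.0, 0.2, np.ones(5)]
        with pytest.raises(ValueError, match="monotone"):
            M.edge_response_resolution(profile, 1.0)

    def test_mesh_phantom_default_psf_near_fifteen_microns(self, library):
        mesh = M.make_phantom("mesh_grid")
        config = M.OpticalConfig(n_bands=16)
        cube, _ = M.simulate_cube(mesh, library, config, seed=0, noise=False)
        image = cube.data.astype(float).sum(axis=2)
        # bar centre (15 um) to open-area centre (75 um), row inside an open strip
        profile = M.extract_line_profile(image, (60, 12), (60, 60), n=97)
        pitch_eff = mesh.pixel_pitch_um * (60 - 12) / 96
        width = M.edge_response_resolution(profile, pitch_eff)
        assert width == pytest.approx(15.0, rel=0.1)
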