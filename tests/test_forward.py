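"""Forward model: pulses, sample interaction, detection, cubes, phantoms."""

import numpy as np
import pytest

import mirhsi as M
from mirhsi.constants import C_CM_FS, C_NM_FS
from mirhsi.forward import frame_factors, measure_pair, transmission_spectrum


class TestMirPulse:
    def test_envelope_fwhm_matches_configuration(self, cfg, mir):
        assert abs(mir.envelope_fwhm_fs() - cfg.mir_pulse_fwhm_fs) <= cfg.dt_fs

    def test_doubled_fwhm_scales_linearly(self, cfg):
        doubled = M.generate_mir_pulse(cfg.replace(mir_pulse_fwhm_fs=27.2))
        assert abs(doubled.envelope_fwhm_fs() - 27.2) <= cfg.dt_fs

    def test_sub_cycle_at_ten_micron(self, mir):
        # one optical cycle at 10 um, computed from the speed of light
        cycle_fs = 1.0e4 / C_NM_FS * 1.0e3 / 1.0e3  # 10e3 nm / (nm/fs)
        cycle_fs = 1.0e4 / C_NM_FS
        assert mir.envelope_fwhm_fs() < cycle_fs

    def test_spectral_support_covers_source_band(self, cfg, mir):
        f, s = mir.spectral_intensity()
        nu = f / C_CM_FS
        peak = s.max()
        for edge in (cfg.mir_band_lo_cm, cfg.mir_band_hi_cm):
            assert s[np.argmin(np.abs(nu - edge))] > 1e-6 * peak

    def test_too_coarse_grid_rejected(self):
        with pytest.raises(M.ConfigError):
            M.OpticalConfig(dt_fs=8.0)


class TestChirpedPulse:
    def test_duration_matches_configuration(self, cfg, chirped):
        cp, _ = chirped
        assert abs(cp.envelope_fwhm_fs() - cfg.cp_duration_fs) < 2 * cfg.dt_fs

    def test_zero_chirp_gives_transform_limit(self, cfg):
        c = cfg.replace(cp_duration_ps=cfg.cp_transform_limit_fs / 1000.0)
        cp, cal = M.generate_chirped_pulse(c)
        assert abs(cp.envelope_fwhm_fs() - cfg.cp_transform_limit_fs) < 2 * cfg.dt_fs
        assert cal.chirp_rate_rad_fs2 == 0.0

    def test_duration_below_transform_limit_rejected(self, cfg):
        with pytest.raises(M.ConfigError):
            M.generate_chirped_pulse(cfg.replace(cp_duration_ps=0.01))

    def test_chirp_rate_matches_cross_correlation_fit(self, cfg, mir, chirped):
        cp, cal = chirped
        delays = np.linspace(-900.0, 900.0, 61)
        f, d, cc = M.cross_correlation_map(mir, cp, delays, cfg)
        est = M.instantaneous_frequency(f, d, cc)
        assert est.chirp_rate_rad_fs2 == pytest.approx(cal.chirp_rate_rad_fs2, rel=0.01)


class TestApplySample:
    def test_empty_mixture_is_identity(self, mir, library):
        out = M.apply_sample(mir, {}, library)
        np.testing.assert_array_equal(out.field, mir.field)

    def test_center_transmittance_is_beer_lambert(self, mir, library):
        strength = 0.8
        lib = M.SpeciesLibrary({"x": [M.AbsorptionLine(1500.0, strength, 30.0)]})
        out = M.apply_sample(mir, {"x": 1.0}, lib)
        f, s_in = mir.spectral_intensity()
        _, s_out = out.spectral_intensity()
        i = np.argmin(np.abs(f / C_CM_FS - 1500.0))
        assert s_out[i] / s_in[i] == pytest.approx(np.exp(-strength), rel=1e-3)

    def test_unknown_species_error_names_it(self, mir, library):
        with pytest.raises(KeyError, match="unobtainium"):
            M.apply_sample(mir, {"unobtainium": 1.0}, library)

    def test_fid_decay_time_matches_lorentzian_width(self, mir):
        # field FID decays as exp(-pi c fwhm t): 1/e time = 1/(pi c fwhm).
        # A weak line keeps the response in the linear (single-scattering)
        # regime where this closed form holds.
        fwhm_cm = 10.0
        lib = M.SpeciesLibrary({"x": [M.AbsorptionLine(1500.0, 0.02, fwhm_cm)]})
        out = M.apply_sample(mir, {"x": 1.0}, lib)
        tail = np.abs(out.field - mir.field)  # isolate the ringing part
        t = out.t_fs
        sel = (t > 500.0) & (t < 4000.0)
        slope = np.polyfit(t[sel], np.log(tail[sel]), 1)[0]
        expected = -np.pi * C_CM_FS * fwhm_cm
        assert slope == pytest.approx(expected, rel=0.02)

    def test_beer_lambert_composition(self, mir, library):
        a = M.apply_sample(mir, {"glycerin": 1.0}, library)
        ab = M.apply_sample(a, {"water": 0.7}, library)
        direct = M.apply_sample(mir, {"glycerin": 1.0, "water": 0.7}, library)
        np.testing.assert_allclose(ab.field, direct.field, rtol=0, atol=1e-12 * np.abs(mir.field).max())

    def test_parseval_energy_conserved_through_sampling(self, mir, library):
        out = M.apply_sample(mir, {"glucose": 1.0}, library)
        for tr in (mir, out):
            assert tr.energy_time() == pytest.approx(tr.energy_freq(), rel=1e-9)


class TestMeasurement:
    def test_counts_quantized_within_bit_depth(self, cfg, mir, chirped):
        cp, _ = chirped
        ms = M.sfg_and_measure(mir, cp, None, cfg)
        assert ms.counts.dtype == np.uint16
        assert ms.counts.min() >= 0
        assert ms.counts.max() <= cfg.full_scale == 4095

    def test_detection_outside_grid_rejected(self, mir, chirped):
        cp, _ = chirped
        bad = M.OpticalConfig()  # valid; now forge an impossible window
        with pytest.raises(Exception):
            M.sfg_and_measure(mir, cp, None, bad.replace(detection_lo_nm=100.0,
                                                         detection_hi_nm=120.0))

    def test_co2_dip_appears_in_band(self, cfg, mir, chirped, library):
        cp, cal = chirped
        smp = M.apply_sample(mir, {"co2": 1.0}, library)
        ms, bg = measure_pair(smp, mir, cp, None, cfg)
        ratio = ms.counts.astype(float) / np.maximum(bg.counts.astype(float), 1.0)
        _, nu = M.sfg_to_mir_axis(ms.wavelength_nm, cfg.cp_center_wavelength_nm)
        dip_band = (nu > 2300) & (nu < 2400)
        assert ratio[dip_band].min() < 0.8
        assert ratio[(nu > 900) & (nu < 1800)].min() > 0.9

    def test_frame_factor_rms_recovery(self, cfg):
        rng = np.random.default_rng(7)
        n = 20000
        g = frame_factors(rng, n, cfg.frame_noise_rms)
        sample_rms = np.sqrt(np.mean((g - 1.0) ** 2))
        se = cfg.frame_noise_rms / np.sqrt(2 * n)
        assert abs(sample_rms - cfg.frame_noise_rms) < 3 * se


class TestCube:
    def test_same_seed_bit_identical(self, cfg, library):
        phantom = M.make_phantom("blobs", rows=16, cols=16, n_classes=2, seed=3)
        c1, b1 = M.simulate_cube(phantom, library, cfg, seed=42, noise=True)
        c2, b2 = M.simulate_cube(phantom, library, cfg, seed=42, noise=True)
        np.testing.assert_array_equal(c1.data, c2.data)
        np.testing.assert_array_equal(b1.data, b2.data)

    def test_uniform_empty_phantom_all_pixels_identical(self, cfg, library):
        empty = M.PhantomMap(species=[], scales=np.zeros((8, 8, 0)),
                             gray_od=np.zeros((8, 8)),
                             labels=np.zeros((8, 8), np.int32), legend={})
        cube, _ = M.simulate_cube(empty, library, cfg, seed=0, noise=False)
        assert np.all(cube.data == cube.data[0, 0])

    def test_channel_pixels_darker_than_walls_where_absorbing(
        self, microchannel_noiseless
    ):
        phantom, cube, background, tcube = microchannel_noiseless
        # glycerin channel: band-integrated transmittance at its peak dips
        band = tcube.band_near(1030.0)
        glyc = tcube.data[:, :, band][phantom.labels == 1].mean()
        direct = np.exp(-0.55)  # library strength of the 1030 line
        assert glyc == pytest.approx(direct, abs=0.08)
        # walls are gray absorbers: transmittance below channels off-resonance
        off = tcube.band_near(2600.0)
        wall = tcube.data[:, :, off][phantom.labels == 0].mean()
        assert wall < 0.6


class TestPhantoms:
    def test_microchannel_has_five_distinct_regions(self):
        ph = M.make_phantom("microchannel5")
        present = sorted(np.unique(ph.labels))
        assert present == [0, 1, 2, 3, 4, 5]
        assert len(ph.legend) == 5

    def test_flow_sequence_frame_spacing_matches_repetition_rate(self):
        frames = M.make_phantom("flow_sequence", n_frames=4)
        dt = np.diff([f.time_ms for f in frames])
        np.testing.assert_allclose(dt, 0.2)

    def test_flow_front_advances(self):
        frames = M.make_phantom("flow_sequence", n_frames=3, velocity_mm_s=2.5)
        filled = [f.scales.sum() for f in frames]
        assert filled[0] >= filled[1] >= filled[2]

    def test_mesh_zero_bar_width_is_transparent(self):
        ph = M.make_phantom("mesh_grid", bar_width_um=0.0)
        assert np.all(ph.gray_od == 0)
        assert np.all(ph.labels == 1)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown phantom kind"):
            M.make_phantom("pyramids")

    def test_size_limit_enforced(self):
        with pytest.raises(ValueError, match="sensor"):
            M.PhantomMap(species=[], scales=np.zeros((500, 700, 0)),
                         gray_od=np.zeros((500, 700)),
                         labels=np.zeros((500, 700), np.int32), legend={})
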