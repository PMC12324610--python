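"""Virtual microscope: screens, propagation, signal formation, phantoms."""

import itertools

import numpy as np
import pytest

from cfocus import (BinaryMask, OpticalConfig, Phantom, blank_mask,
                    generate_random_patterns, identity_medium,
                    make_phantom, make_phase_screen, make_pupil_screen,
                    memory_effect_correlation, pattern_signals, point_phantom,
                    propagate_to_focus, pupil_field, scan_image,
                    transfer_vector, two_photon_signal)
from cfocus.optics import _fftc


class TestPhaseScreens:
    def test_zero_strength_is_identity(self, small_cfg):
        med = make_phase_screen(small_cfg, 2.0, 0.0, 10.0, seed=1)
        assert not med.screens[0].phase.any()
        assert med.is_identity

    def test_deterministic(self, small_cfg):
        a = make_phase_screen(small_cfg, 3.0, 2.0, 10.0, seed=5)
        b = make_phase_screen(small_cfg, 3.0, 2.0, 10.0, seed=5)
        assert np.array_equal(a.screens[0].phase, b.screens[0].phase)

    def test_pointwise_std_on_dmd_scale_screen(self):
        # 800x800 pupil-grid screen, correlation four superpixel widths
        cfg = OpticalConfig.benchmark()
        med = make_pupil_screen(cfg, 4 * cfg.superpixel_size, 2.0, seed=3)
        assert med.screens[0].phase.shape == (800, 800)
        assert abs(med.screens[0].phase.std() - 2.0) < 0.1

    def test_unresolvable_correlation_rejected(self, small_cfg):
        with pytest.raises(ValueError, match="unresolvable"):
            make_phase_screen(small_cfg, 0.1 * small_cfg.focal_pixel_pitch,
                              1.0, 10.0)


class TestPropagation:
    def test_open_pupil_focus(self, small_cfg, small_blank):
        f = propagate_to_focus(small_blank, identity_medium(), small_cfg)
        n2 = small_cfg.field_grid // 2
        peak = np.unravel_index(np.argmax(f.intensity), f.intensity.shape)
        assert peak == (n2, n2)
        # equals the plain diffraction pattern of the open pupil
        direct = _fftc(pupil_field(small_blank, small_cfg))
        assert np.allclose(f.values, direct)

    @pytest.mark.parametrize("medium_kind", ["focal_screen", "pupil_screen",
                                             "two_screens"])
    def test_energy_conserved_through_phase_only_media(self, small_cfg,
                                                       small_blank,
                                                       medium_kind):
        from cfocus.media import ScatteringMedium

        corr = 3.0
        if medium_kind == "focal_screen":
            med = make_phase_screen(small_cfg, corr, 2.5, 12.0, seed=2)
        elif medium_kind == "pupil_screen":
            med = make_pupil_screen(small_cfg, 8.0, 2.5, seed=2)
        else:
            a = make_phase_screen(small_cfg, corr, 2.0, 15.0, seed=3)
            b = make_phase_screen(small_cfg, corr, 1.5, 5.0, seed=4)
            med = ScatteringMedium(a.screens + b.screens)
        p_in = float(np.sum(np.abs(pupil_field(small_blank, small_cfg)) ** 2))
        f = propagate_to_focus(small_blank, med, small_cfg)
        assert abs(f.total_power - p_in) / p_in < 1e-10

    def test_tilt_shifts_by_fourier_theorem(self, small_cfg, small_blank):
        f0 = propagate_to_focus(small_blank, identity_medium(),
                                small_cfg).intensity
        shift_px = 7
        d = shift_px * small_cfg.focal_pixel_pitch
        f1 = propagate_to_focus(small_blank, identity_medium(), small_cfg,
                                tilt=(d, 0.0)).intensity
        p0 = np.unravel_index(np.argmax(np.roll(f0, shift_px, axis=1)),
                              f0.shape)
        p1 = np.unravel_index(np.argmax(f1), f1.shape)
        assert abs(p0[0] - p1[0]) <= 1 and abs(p0[1] - p1[1]) <= 1

    def test_tilt_beyond_grid_rejected(self, small_cfg, small_blank):
        with pytest.raises(ValueError, match="tilt"):
            propagate_to_focus(small_blank, identity_medium(), small_cfg,
                               tilt=(small_cfg.fov, 0.0))


class TestTwoPhotonSignal:
    def test_quartic_amplitude_scaling(self, small_cfg, small_blank,
                                       small_medium):
        ph = point_phantom()
        s1 = two_photon_signal(small_blank, small_medium, ph, small_cfg)
        s2 = two_photon_signal(small_blank, small_medium, ph, small_cfg,
                               amplitude=2.0)
        assert s2 == pytest.approx(16.0 * s1, rel=1e-12)

    def test_empty_phantom_gives_zero(self, small_cfg, small_blank):
        ph = Phantom(np.zeros((1, 4, 4)), 0.2, np.zeros(1))
        assert two_photon_signal(small_blank, identity_medium(), ph,
                                 small_cfg) == 0.0

    def test_blank_beats_every_strict_submask_in_phase(self, tiny_cfg):
        # identity medium: all superpixel fields are in phase, so at equal
        # (un-normalized) input amplitude the open pupil maximises the signal
        # over all 2^9 masks on the 3x3 toy grid
        ph = point_phantom()
        signals = {}
        for bits in itertools.product((0, 1), repeat=9):
            m = np.array(bits, dtype=bool).reshape(3, 3)
            signals[bits] = two_photon_signal(
                BinaryMask(m, tiny_cfg.superpixel_size), identity_medium(),
                ph, tiny_cfg)
        full = signals[(1,) * 9]
        assert all(full > v for k, v in signals.items() if k != (1,) * 9)


class TestTransferVector:
    def test_identity_medium_constant_phase(self, small_cfg):
        u = transfer_vector(identity_medium(), small_cfg)
        phases = np.angle(u * np.conj(u.flat[0]))
        assert np.max(np.abs(phases)) < 1e-8

    def test_fast_path_matches_full_propagation(self, small_cfg, small_medium):
        u = transfer_vector(small_medium, small_cfg)
        ps = generate_random_patterns(50, small_cfg.superpixel_grid, 0.4,
                                      seed=21, superpixel_size=4)
        fast = pattern_signals(ps, u)
        n2 = small_cfg.field_grid // 2
        full = np.array([
            np.abs(propagate_to_focus(ps.mask(i), small_medium,
                                      small_cfg).values[n2, n2]) ** 4
            for i in range(50)])
        assert np.max(np.abs(fast - full) / full) < 1e-8

    def test_fast_path_matches_single_point_phantom(self, small_cfg,
                                                    small_medium):
        u = transfer_vector(small_medium, small_cfg)
        ps = generate_random_patterns(5, small_cfg.superpixel_grid, 0.4,
                                      seed=8, superpixel_size=4)
        fast = pattern_signals(ps, u)
        full = np.array([
            two_photon_signal(ps.mask(i), small_medium, point_phantom(),
                              small_cfg) for i in range(5)])
        assert np.max(np.abs(fast - full) / full) < 1e-8

    def test_amplitude_scaling_quartic(self, small_cfg, small_medium):
        u = transfer_vector(small_medium, small_cfg)
        ps = generate_random_patterns(3, small_cfg.superpixel_grid, 0.4,
                                      seed=1, superpixel_size=4)
        assert np.allclose(pattern_signals(ps, u, amplitude=3.0),
                           81.0 * pattern_signals(ps, u))

    def test_off_axis_target(self, small_cfg, small_medium):
        d = 6 * small_cfg.focal_pixel_pitch
        u = transfer_vector(small_medium, small_cfg, (d, 0.0, 0.0))
        ps = generate_random_patterns(5, small_cfg.superpixel_grid, 0.4,
                                      seed=5, superpixel_size=4)
        fast = pattern_signals(ps, u)
        n2 = small_cfg.field_grid // 2
        full = np.array([
            np.abs(propagate_to_focus(ps.mask(i), small_medium,
                                      small_cfg).values[n2, n2 + 6]) ** 4
            for i in range(5)])
        assert np.max(np.abs(fast - full) / full) < 1e-8


class TestMemoryEffect:
    def test_finite_screen_decorrelates_monotonically(self, small_cfg):
        shifts = [0.0, 1.5, 3.0, 6.0, 12.0]
        corr = np.zeros(len(shifts))
        for seed in range(10):
            med = make_phase_screen(small_cfg, 3.0, 2.0, 10.0, seed=seed)
            corr += memory_effect_correlation(med, small_cfg, shifts)
        corr /= 10
        assert corr[0] == pytest.approx(1.0)
        assert (np.diff(corr) < 0).all()

    def test_pupil_screen_is_tilt_invariant(self, small_cfg):
        med = make_pupil_screen(small_cfg, 8.0, 2.0, seed=11)
        corr = memory_effect_correlation(med, small_cfg, [0.0, 3.0, 12.0])
        assert np.allclose(corr, 1.0, atol=1e-9)


class TestScanImage:
    def test_bead_image_fwhm_matches_two_photon_psf(self):
        from cfocus.workflow import _fwhm_1d

        cfg = OpticalConfig(pupil_grid=64, superpixel_size=4, field_grid=256,
                            scan_pixel_pitch=0.12)
        # numeric unaberrated two-photon PSF width (the oracle)
        bm = blank_mask(cfg.superpixel_grid, cfg.superpixel_size)
        psf = np.abs(_fftc(pupil_field(bm, cfg))) ** 4
        n2 = cfg.field_grid // 2
        oracle = _fwhm_1d(psf[n2], cfg.focal_pixel_pitch, n2)
        # small bead so the object barely inflates the image width
        sigma = 0.15 / 2.3548
        ax = np.arange(-8, 9) * 0.05
        blob = np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2)
                      / (2 * sigma ** 2))
        ph = Phantom(blob[None], 0.05, np.zeros(1), kind="bead")
        img = scan_image([bm], None, identity_medium(), ph, cfg,
                         scan_shape=(25, 25))
        r, c = np.unravel_index(np.argmax(img), img.shape)
        assert (r, c) == (12, 12)
        fw = _fwhm_1d(img[r], cfg.scan_pixel_pitch, c)
        assert abs(fw - oracle) / oracle < 0.10

    def test_all_off_mask_pixels_exactly_zero(self, small_cfg, small_medium):
        off = BinaryMask(np.zeros(small_cfg.superpixel_grid, dtype=bool),
                         small_cfg.superpixel_size)
        on = blank_mask(small_cfg.superpixel_grid, small_cfg.superpixel_size)
        labels = np.zeros((6, 6), dtype=int)
        labels[:, 3:] = 1
        from cfocus.segmentation import SubregionMap

        sm = SubregionMap(labels, [(0, 0, 1.0), (0, 5, 1.0)], (1, 2),
                          np.array([[0, 1]]), 0.0, 0.0, 1.0)
        img = scan_image([off, on], sm, small_medium, point_phantom(),
                         small_cfg)
        assert (img[:, :3] == 0).all()
        assert img[:, 3:].max() > 0

    def test_identical_masks_equal_single_global_mask(self, small_cfg,
                                                      small_medium):
        from cfocus.segmentation import SubregionMap

        bm = blank_mask(small_cfg.superpixel_grid, small_cfg.superpixel_size)
        labels = np.zeros((5, 5), dtype=int)
        labels[2:, 2:] = 1
        sm = SubregionMap(labels, [(0, 0, 1.0), (4, 4, 1.0)], (1, 2),
                          np.array([[0, 1]]), 0.0, 0.0, 1.0)
        ph = point_phantom()
        split = scan_image([bm, bm], sm, small_medium, ph, small_cfg)
        whole = scan_image([bm], None, small_medium, ph, small_cfg,
                           scan_shape=(5, 5))
        assert np.array_equal(split, whole)

    def test_unassigned_pixel_rejected(self, small_cfg):
        bm = blank_mask(small_cfg.superpixel_grid, small_cfg.superpixel_size)
        from cfocus.segmentation import SubregionMap

        labels = np.array([[0, 2]])
        sm = SubregionMap(labels, [(0, 0, 1.0)], (1, 2), np.array([[0, 2]]),
                          0.0, 0.0, 1.0)
        with pytest.raises(ValueError, match="label"):
            scan_image([bm], sm, identity_medium(), point_phantom(),
                       small_cfg)


class TestPhantoms:
    def test_bead_total_matches_gaussian_integral(self):
        d = 0.71
        ph = make_phantom("bead", {"diameter": d, "xy_pitch": d / 10,
                                   "z_pitch": d / 10, "n_sigma": 5.0})
        sigma = d / 2.3548200450309493
        expected = (2 * np.pi) ** 1.5 * sigma ** 3 / (d / 10) ** 3
        assert ph.total == pytest.approx(expected, rel=0.01)

    def test_uniform_is_constant(self):
        ph = make_phantom("uniform", {"shape": (2, 8, 8), "value": 3.0})
        assert (ph.values == 3.0).all()

    def test_filament_cross_section_fwhm(self):
        from cfocus.workflow import _fwhm_1d

        d = 1.5
        pitch = d / 8
        ph = make_phantom("filament", {"diameter": d, "length": 20.0,
                                       "xy_pitch": pitch, "z_pitch": pitch,
                                       "wander": 1.0}, seed=4)
        nx = ph.values.shape[2]
        x0 = nx // 2
        plane = ph.values[:, :, x0]
        zi, yi = np.unravel_index(np.argmax(plane), plane.shape)
        fw = _fwhm_1d(plane[zi], pitch, yi)
        assert abs(fw - d) <= pitch + 1e-9

    def test_deterministic(self):
        a = make_phantom("filament", {"diameter": 1.0}, seed=3)
        b = make_phantom("filament", {"diameter": 1.0}, seed=3)
        assert np.array_equal(a.values, b.values)

    def test_negative_geometry_rejected(self):
        with pytest.raises(ValueError):
            make_phantom("bead", {"diameter": -1.0})

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            make_phantom("voronoi", {})
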