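import numpy as np
import pytest
from scipy import stats

from aoldv import (
    InvalidScenarioError,
    OpticalConfig,
    compute_power_spectrum,
    compute_vmax,
    delta_cutoff,
    detect_cutoff,
    detect_spot,
)
from aoldv.synthetic import (
    BifurcationScenario,
    ImageScenario,
    SpectrumScenario,
    draw_tone_frequencies,
    make_conserved_bifurcation,
    simulate_bifurcation,
    simulate_capillary_spectrum,
    simulate_detector_record,
    simulate_fundus_image,
)


class TestDetectorRecordSimulation:
    def test_determinism_bit_identical(self, cfg):
        sc = SpectrumScenario(vmax_true=8.0, snr=20, seed=99)
        r1 = simulate_detector_record(sc, cfg)
        r2 = simulate_detector_record(sc, cfg)
        np.testing.assert_array_equal(r1.channel_a, r2.channel_a)
        np.testing.assert_array_equal(r1.channel_b, r2.channel_b)

    def test_frequency_law_uniform(self, cfg):
        sc = SpectrumScenario(vmax_true=10.0, snr=20, seed=11, n_tones=10_000)
        f_cut = 4000.0
        freqs = draw_tone_frequencies(sc, f_cut, cfg)
        counts, _ = np.histogram(freqs, bins=20, range=(0, f_cut))
        chi2 = stats.chisquare(counts)
        assert chi2.pvalue > 0.01

    def test_zero_velocity_gives_noise_only(self, cfg):
        sc = SpectrumScenario(vmax_true=0.0, snr=20, seed=5)
        rec = simulate_detector_record(sc, cfg)
        sa, sb = compute_power_spectrum(rec, cfg)
        assert detect_cutoff(sa).quality_flag == "no_cutoff"
        assert detect_cutoff(sb).quality_flag == "no_cutoff"

    def test_cutoff_beyond_nyquist_rejected(self, cfg):
        sc = SpectrumScenario(vmax_true=500.0, snr=20, seed=1)  # ~ 80 kHz shift
        with pytest.raises(InvalidScenarioError):
            simulate_detector_record(sc, cfg)

    def test_end_to_end_velocity_recovery(self, cfg):
        sc = SpectrumScenario(vmax_true=10.0, snr=20, seed=1)
        rec = simulate_detector_record(sc, cfg)
        sa, sb = compute_power_spectrum(rec, cfg)
        df = delta_cutoff(detect_cutoff(sa), detect_cutoff(sb))
        vmax = compute_vmax(df, cfg).vmax_mm_s
        assert vmax == pytest.approx(10.0, rel=0.10)


class TestCapillarySpectrum:
    def test_same_cutoff_as_uniform_within_two_bins(self, cfg):
        # centre weighting reshapes the band but not its edge
        diffs = []
        for seed in range(6):
            un = SpectrumScenario(vmax_true=8.0, snr=1e6, seed=seed)
            cw = SpectrumScenario(vmax_true=8.0, snr=1e6, seed=seed,
                                  intensity_profile="center_weighted")
            _, sb_u = compute_power_spectrum(simulate_detector_record(un, cfg), cfg)
            _, sb_c = simulate_capillary_spectrum(cw, cfg)
            diffs.append(detect_cutoff(sb_c).cutoff_hz - detect_cutoff(sb_u).cutoff_hz)
        assert np.median(np.abs(diffs)) <= 2 * cfg.bin_width

    def test_total_power_constant_across_velocities(self, cfg):
        areas = []
        for v in (2.0, 6.0, 12.0):
            sc = SpectrumScenario(vmax_true=v, snr=1e9, seed=4,
                                  intensity_profile="center_weighted")
            sa, sb = simulate_capillary_spectrum(sc, cfg)
            areas.append(sa.power.sum() + sb.power.sum())
        areas = np.asarray(areas)
        assert areas.max() / areas.min() - 1 < 0.02

    def test_wide_beam_reduces_to_uniform(self, cfg):
        sc_wide = SpectrumScenario(vmax_true=8.0, snr=1e9, seed=2,
                                   intensity_profile="center_weighted",
                                   beam_sigma_fraction=1e4)
        sc_uni = SpectrumScenario(vmax_true=8.0, snr=1e9, seed=2)
        _, sb_w = simulate_capillary_spectrum(sc_wide, cfg)
        rec = simulate_detector_record(sc_uni, cfg)
        _, sb_u = compute_power_spectrum(rec, cfg)
        scale = max(sb_u.power.max(), 1e-300)
        assert np.max(np.abs(sb_w.power - sb_u.power)) / scale < 1e-3


class TestFundusPhantom:
    def test_determinism(self):
        sc = ImageScenario(diameter_px=73, seed=8, image_shape=(420, 420),
                           noise_sigma=300.0)
        np.testing.assert_array_equal(
            simulate_fundus_image(sc).pixels, simulate_fundus_image(sc).pixels
        )

    def test_spot_is_detected_not_vessel(self):
        sc = ImageScenario(diameter_px=73, spot_offset_px=20.0, seed=1,
                           image_shape=(420, 420))
        img = simulate_fundus_image(sc)
        spot = detect_spot(img)
        # spot sits 20 px perpendicular from the image-centre vessel line
        assert abs(spot.centroid_row - 209.5) < 25
        assert abs(spot.centroid_col - 209.5) < 25

    def test_seed_changes_image_not_diameter(self):
        from aoldv import measure_diameter

        d = []
        for seed in (21, 22):
            sc = ImageScenario(diameter_px=80, orientation_deg=15.0,
                               spot_offset_px=20.0, noise_sigma=400.0, seed=seed,
                               image_shape=(420, 420))
            d.append(measure_diameter(simulate_fundus_image(sc)).diameter_px)
        assert abs(d[0] - d[1]) < 2.0

    def test_oversized_band_rejected(self):
        with pytest.raises(InvalidScenarioError):
            ImageScenario(diameter_px=500, image_shape=(420, 420))


class TestBifurcationScenario:
    def test_conserved_closure_to_1e9(self):
        sc = make_conserved_bifurcation(104.0, 11.0, (90.0, 95.0), split_fraction=0.6)
        fp, f1, f2 = sc.flows_ul_min
        assert abs(fp - (f1 + f2)) <= 1e-9 * fp

    def test_reference_parent_flow(self):
        sc = make_conserved_bifurcation(104.0, 11.0, (90.0, 95.0))
        assert sc.flows_ul_min[0] == pytest.approx(2.80, abs=0.01)

    def test_inconsistent_conserved_flag_rejected(self):
        with pytest.raises(InvalidScenarioError):
            BifurcationScenario(parent=(104.0, 11.0),
                                daughters=((90.0, 1.0), (95.0, 1.0)), conserved=True)

    def test_simulated_acquisition_structure(self, small_cfg):
        sc = make_conserved_bifurcation(104.0, 11.0, (90.0, 95.0), seed=3)
        acqs = simulate_bifurcation(sc, small_cfg, image_shape=(420, 420))
        assert set(acqs) == {"PV", "DV1", "DV2"}
        for acq in acqs.values():
            assert len(acq.frames) == small_cfg.frames_per_acquisition
            img, rec = acq.frames[0]
            assert img.pixels.shape == (420, 420)
            assert rec.channel_a.size == small_cfg.window_samples
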