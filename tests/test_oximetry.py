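"""Lifetime oximetry: decay fitting, Stern-Volmer, Hill/OEF, tissue maps."""

import numpy as np
import pytest
from scipy import stats

from cortexflow import oximetry as ox
from cortexflow import synthetic_data as sd


class TestHill:
    def test_half_saturation_exactly_at_p50(self):
        assert ox.hill_so2(40.2) == 0.5

    def test_saturation_at_100_mmhg(self):
        # (100/40.2)^2.59 / (1 + (100/40.2)^2.59), direct evaluation
        x = (100.0 / 40.2) ** 2.59
        assert ox.hill_so2(100.0) == pytest.approx(x / (1 + x))

    def test_monotone_in_po2(self):
        po2 = np.linspace(0, 160, 300)
        so2 = ox.hill_so2(po2)
        assert np.all(np.diff(so2) > 0)
        assert so2[0] == 0.0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ox.HillParams(h=0.0, p50_mmhg=40.2)
        with pytest.raises(ValueError):
            ox.HillParams(h=2.59, p50_mmhg=-1.0)


class TestOef:
    def test_arteriovenous_extraction(self):
        so2_a = float(ox.hill_so2(100.0))
        so2_v = float(ox.hill_so2(40.0))
        want = (so2_a - so2_v) / so2_a
        assert ox.oef(so2_a, so2_v) == pytest.approx(want)

    def test_zero_when_no_desaturation(self):
        assert ox.oef(0.9, 0.9) == 0.0

    def test_oef_trace_applies_hill_pointwise(self):
        pa = np.array([100.0, 90.0])
        pv = np.array([40.0, 35.0])
        tr = ox.oef_trace(pa, pv)
        for i in range(2):
            assert tr[i] == pytest.approx(
                ox.oef(float(ox.hill_so2(pa[i])), float(ox.hill_so2(pv[i]))))


class TestSternVolmer:
    def test_round_trip_is_exact(self):
        calib = ox.OxyCalibration()
        po2 = np.array([0.0, 10.0, 40.2, 90.0, 160.0])
        assert np.allclose(ox.lifetime_to_po2(calib.tau(po2), calib), po2)

    def test_lifetime_decreases_with_po2(self):
        calib = ox.OxyCalibration()
        tau = calib.tau(np.linspace(0, 160, 50))
        assert np.all(np.diff(tau) < 0)

    def test_calibration_recovers_constants_from_synthetic_points(self):
        truth = ox.OxyCalibration(tau0_us=38.0, kq_per_us_mmhg=4.0e-4)
        po2 = np.array([5.0, 20.0, 60.0, 100.0, 150.0])
        fit = ox.calibrate(truth.tau(po2), po2)
        assert fit.tau0_us == pytest.approx(38.0, rel=1e-6)
        assert fit.kq_per_us_mmhg == pytest.approx(4.0e-4, rel=1e-6)

    def test_lifetime_above_tau0_clips_to_zero_with_warning(self):
        calib = ox.OxyCalibration(tau0_us=40.0)
        with pytest.warns(UserWarning):
            assert ox.lifetime_to_po2(45.0, calib) == 0.0


class TestDecayFitting:
    def test_noiseless_histogram_recovers_lifetime(self):
        calib = ox.OxyCalibration()
        cfg = sd.SimConfig(seed=1)
        ds, gt = sd.gen_decays(cfg, [60.0], calib,
                               photons_per_cycle=np.inf)
        fit = ox.fit_decay(ds.counts[0], ds.bin_width_us)
        assert fit["tau_us"] == pytest.approx(gt["tau_us"][0], rel=0.01)

    def test_poisson_noise_fit_unbiased_at_protocol_photon_budget(self):
        calib = ox.OxyCalibration()
        cfg = sd.SimConfig(seed=2)
        po2 = np.full(100, 40.0)
        ds, _ = sd.gen_decays(cfg, po2, calib, photons_per_cycle=50,
                              n_cycles=100)
        got = ox.fit_decay_set(ds, calib)
        assert got.mean() == pytest.approx(40.0, abs=1.5)

    def test_flat_histogram_is_a_fit_error(self):
        with pytest.raises(ox.DecayFitError):
            ox.fit_decay(np.full(290, 7.0), 1.0)

    def test_too_few_bins_rejected(self):
        with pytest.raises(ox.DecayFitError):
            ox.fit_decay(np.exp(-np.arange(5) / 2.0), 1.0)

    def test_constant_background_does_not_bias_lifetime(self):
        calib = ox.OxyCalibration()
        cfg = sd.SimConfig(seed=3)
        ds, gt = sd.gen_decays(cfg, [30.0], calib, photons_per_cycle=np.inf,
                               background_per_bin=0.5)
        fit = ox.fit_decay(ds.counts[0], ds.bin_width_us)
        assert fit["tau_us"] == pytest.approx(gt["tau_us"][0], rel=0.02)


class TestHypoxia:
    def test_threshold_is_strict(self):
        assert ox.hypoxic_fraction([18.0, 18.0]) == 0.0
        assert ox.hypoxic_fraction([17.99, 18.01]) == 0.5

    def test_matches_normal_cdf_for_gaussian_sample(self):
        rng = np.random.default_rng(4)
        x = rng.normal(22.1, 2.7, 200_000)
        want = stats.norm.cdf(18.0, 22.1, 2.7)
        assert ox.hypoxic_fraction(x) == pytest.approx(want, abs=0.005)

    def test_custom_threshold(self):
        assert ox.hypoxic_fraction([5.0, 25.0], threshold_mmhg=10.0) == 0.5


class TestDistanceClasses:
    def grid_masks(self, n=32):
        art = np.zeros((n, n), dtype=bool)
        ven = np.zeros((n, n), dtype=bool)
        art[8, 8] = True
        ven[24, 24] = True
        return art, ven

    def test_fifty_micron_radius_defines_the_classes(self):
        art, ven = self.grid_masks()
        classes, tie = ox.classify_distance(art, ven, pixel_size_um=16.0)
        assert classes[8, 9] == ox.NEAR_ARTERIOLE  # 16 um from arteriole
        assert classes[24, 23] == ox.NEAR_VENULE
        assert classes[0, 31] == ox.IN_BETWEEN  # far from both

    def test_equidistant_overlap_is_flagged_and_assigned_near_arteriole(self):
        n = 9
        art = np.zeros((n, n), dtype=bool)
        ven = np.zeros((n, n), dtype=bool)
        art[4, 2] = True
        ven[4, 6] = True
        classes, tie = ox.classify_distance(art, ven, pixel_size_um=16.0)
        assert tie[4, 4]
        assert classes[4, 4] == ox.NEAR_ARTERIOLE

    def test_classify_map_attaches_classes(self):
        cfg = sd.SimConfig(seed=5)
        tmap, _ = sd.gen_tissue_map(cfg, [(8, 8)], [(24, 24)])
        out = ox.classify_map(tmap)
        assert out.distance_class is not None
        assert out.distance_class.shape == tmap.po2.shape


class TestTissueMapGenerator:
    def test_map_mean_equals_group_draw(self):
        cfg = sd.SimConfig(seed=6)
        tmap, gt = sd.gen_tissue_map(cfg, [(8, 8)], [(24, 24)])
        assert tmap.po2.mean() == pytest.approx(gt["map_mean_mmhg"])

    def test_po2_decreases_away_from_arterioles(self):
        cfg = sd.SimConfig(seed=7)
        tmap, _ = sd.gen_tissue_map(cfg, [(8, 8)], [(24, 24)],
                                    group_sd_mmhg=0.0)
        ox.classify_map(tmap)
        near = tmap.po2[tmap.distance_class == ox.NEAR_ARTERIOLE].mean()
        far = tmap.po2[tmap.distance_class != ox.NEAR_ARTERIOLE].mean()
        assert near > far

    def test_infinite_gradient_scale_flattens_the_field(self):
        cfg = sd.SimConfig(seed=8)
        tmap, gt = sd.gen_tissue_map(cfg, [(8, 8)], [(24, 24)],
                                     gradient_um_scale=1e12)
        assert np.ptp(tmap.po2) < 1e-6


class TestStimulusPo2Metrics:
    def test_constructed_dip_peak_and_sustained_change(self, protocol):
        fs = 10.0
        t = np.arange(0, protocol.total_s, 1 / fs)
        x = np.full(t.size, 30.0)
        on = protocol.baseline_s
        x[(t >= on) & (t < on + 2)] -= 3.0          # initial dip
        x[(t >= on + 2) & (t < on + 4)] += 5.0      # initial peak
        x[(t >= on + 4) & (t < on + 30)] += 2.0     # sustained shallow change
        m = ox.stimulus_po2_metrics(t, x, protocol)
        assert m["initial_dip"] == pytest.approx(-3.0)
        assert m["initial_peak"] == pytest.approx(5.0)
        assert m["shallow_peak"] == pytest.approx(2.0)
        assert m["net_change"] == m["shallow_peak"]

    def test_short_stimulation_is_rejected(self):
        proto = sd.StimulusProtocol(baseline_s=15.0, stim_s=2.0,
                                    recovery_s=15.0)
        t = np.arange(0, proto.total_s, 0.1)
        with pytest.raises(ValueError):
            ox.stimulus_po2_metrics(t, np.full(t.size, 30.0), proto)


class TestScheduleAccounting:
    def test_intravascular_schedule_yields_seventy_timepoints(self):
        acc = ox.schedule_accounting(ox.AcquisitionSchedule())
        assert acc["n_timepoints_per_roi"] == 70

    def test_tissue_grid_yields_1024_rois(self):
        acc = ox.schedule_accounting(
            ox.AcquisitionSchedule(grid=(32, 32), n_repeats=10,
                                   cycles_per_roi=200, pair_average=True))
        assert acc["n_rois_total"] == 1024

    def test_odd_repeats_with_pair_averaging_rejected(self):
        with pytest.raises(ValueError):
            ox.AcquisitionSchedule(n_repeats=141, pair_average=True)


class TestRespirometry:
    def test_ratios_are_plain_quotients(self):
        out = ox.respirometry_ratios(state2_rate=10.0, state3_rate=45.0,
                                     adp_nmol=250.0, o_consumed_nmol=100.0)
        assert out["rcr"] == pytest.approx(4.5)
        assert out["adp_o"] == pytest.approx(2.5)

    def test_nonpositive_denominators_rejected(self):
        with pytest.raises(ValueError):
            ox.respirometry_ratios(0.0, 45.0, 250.0, 100.0)
        with pytest.raises(ValueError):
            ox.respirometry_ratios(10.0, 45.0, 250.0, 0.0)
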