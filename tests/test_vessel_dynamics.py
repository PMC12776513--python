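"""Diametry: FWHM, projection/Radon methods and stimulus-locked metrics."""

import numpy as np
import pytest

from cortexflow import synthetic_data as sd
from cortexflow import vessel_dynamics as vd


def gaussian_profile(n, center, sigma, amp=1.0, bg=0.1):
    x = np.arange(n, dtype=float)
    return bg + amp * np.exp(-0.5 * ((x - center) / sigma) ** 2)


def fwhm_oracle(profile, pixel_size_um, upsample=200):
    """Dense-grid half-max width: linear interpolation on a fine grid."""
    x = np.arange(profile.size, dtype=float)
    xf = np.linspace(0, profile.size - 1, profile.size * upsample)
    pf = np.interp(xf, x, profile)
    bg = np.sort(profile)[: max(1, profile.size // 4)].min()
    half = bg + 0.5 * (pf.max() - bg)
    above = np.flatnonzero(pf >= half)
    return (xf[above[-1]] - xf[above[0]]) * pixel_size_um


class TestFwhm:
    def test_gaussian_width_matches_analytic_fwhm(self):
        sigma = 2.0
        prof = gaussian_profile(64, 31.5, sigma, bg=0.0)
        w = vd.fwhm_diameter(prof, pixel_size_um=1.0)
        assert w == pytest.approx(2.3548 * sigma, rel=0.03)

    def test_matches_dense_grid_oracle_on_asymmetric_profile(self):
        x = np.arange(80, dtype=float)
        prof = 0.2 + np.exp(-0.5 * ((x - 40) / 3.0) ** 2) \
            + 0.4 * np.exp(-0.5 * ((x - 46) / 5.0) ** 2)
        w = vd.fwhm_diameter(prof, pixel_size_um=0.994)
        assert w == pytest.approx(fwhm_oracle(prof, 0.994), abs=0.1)

    def test_width_scales_with_pixel_size(self):
        prof = gaussian_profile(64, 32, 3.0)
        assert vd.fwhm_diameter(prof, 2.0) == pytest.approx(
            2 * vd.fwhm_diameter(prof, 1.0))

    def test_flat_profile_raises_vessel_not_found(self):
        with pytest.raises(vd.VesselNotFoundError):
            vd.fwhm_diameter(np.ones(50), 1.0)

    def test_edge_touching_lobe_raises(self):
        prof = gaussian_profile(40, 0.0, 5.0)  # no left crossing
        with pytest.raises(vd.VesselNotFoundError):
            vd.fwhm_diameter(prof, 1.0)


class TestTirs:
    def disk(self, d_px, n=64):
        frame, _ = sd.gen_vessel_movie(
            sd.SimConfig(seed=3, duration_s=1 / 3.8), "perpendicular",
            lambda t: d_px * 1.0, shape=(n, n))
        return frame[0]

    @pytest.mark.parametrize("d_px", [6, 10, 14, 20, 26])
    def test_disk_diameter_within_one_pixel(self, d_px):
        cfg = sd.SimConfig(seed=3, duration_s=1 / 3.8, pixel_size_um=1.0)
        frames, _ = sd.gen_vessel_movie(cfg, "perpendicular",
                                        lambda t: float(d_px))
        d = vd.tirs_diameter(frames[0], pixel_size_um=1.0)
        assert d == pytest.approx(d_px, abs=1.0)

    def test_agrees_with_fwhm_within_one_pixel_on_cross_section(self):
        cfg = sd.SimConfig(seed=4, duration_s=1 / 3.8, pixel_size_um=1.0)
        frames, _ = sd.gen_vessel_movie(cfg, "perpendicular", lambda t: 12.0)
        img = frames[0]
        d_tirs = vd.tirs_diameter(img, pixel_size_um=1.0)
        center_row = int(np.argmax(img.sum(axis=1)))
        d_fwhm = vd.fwhm_diameter(img[center_row], pixel_size_um=1.0)
        assert abs(d_tirs - d_fwhm) <= 1.0

    def test_two_vessels_in_frame_is_ambiguous(self):
        cfg = sd.SimConfig(seed=5, duration_s=1 / 3.8, pixel_size_um=1.0)
        a, _ = sd.gen_vessel_movie(cfg, "perpendicular", lambda t: 10.0,
                                   shape=(64, 64))
        img = a[0].copy()
        img[4:14, 4:14] += a[0][27:37, 27:37]  # second blob in the corner
        with pytest.raises(vd.AmbiguousVesselError):
            vd.tirs_diameter(img, pixel_size_um=1.0)

    def test_empty_frame_raises_vessel_not_found(self):
        with pytest.raises(vd.VesselNotFoundError):
            vd.tirs_diameter(np.zeros((64, 64)), pixel_size_um=1.0)


class TestProjectionDiametry:
    def test_recovers_sinusoidal_diameter_modulation(self):
        cfg = sd.SimConfig(seed=6, duration_s=4.0, pixel_size_um=1.0)
        fn = lambda t: 12.0 + 2.0 * np.sin(2 * np.pi * 0.5 * t)
        frames, gt = sd.gen_vessel_movie(cfg, "parallel", fn)
        tr = vd.radon_projection_diameter(frames, 1.0, cfg.frame_rate_hz)
        assert np.mean(tr.d_um) == pytest.approx(12.0, abs=0.6)
        assert np.ptp(tr.d_um) == pytest.approx(4.0, abs=1.0)

    def test_in_plane_rotation_does_not_change_width(self):
        cfg = sd.SimConfig(seed=8, duration_s=1.0, pixel_size_um=1.0)
        straight, _ = sd.gen_vessel_movie(cfg, "parallel", lambda t: 8.0)
        rotated, _ = sd.gen_vessel_movie(cfg, "parallel", lambda t: 8.0,
                                         angle_deg=30.0)
        d0 = vd.radon_projection_diameter(straight, 1.0, 3.8).d_um.mean()
        d30 = vd.radon_projection_diameter(rotated, 1.0, 3.8).d_um.mean()
        assert d30 == pytest.approx(d0, abs=0.5)

    def test_estimated_angle_matches_rendered_orientation(self):
        cfg = sd.SimConfig(seed=9, duration_s=1 / 3.8, pixel_size_um=1.0)
        frames, _ = sd.gen_vessel_movie(cfg, "parallel", lambda t: 8.0,
                                        angle_deg=20.0)
        ang = vd.estimate_vessel_angle(frames[0])
        assert ang == pytest.approx(20.0, abs=1.0)


class TestLowpass:
    def test_zero_phase_preserves_slow_sine_alignment(self):
        fs = 50.0
        t = np.arange(0, 20, 1 / fs)
        x = np.sin(2 * np.pi * 0.1 * t)
        y = vd.lowpass_zero_phase(x, fs, cutoff_hz=1.0)
        core = slice(100, -100)
        lag = np.argmax(np.correlate(y[core], x[core], "full")) \
            - (x[core].size - 1)
        assert lag == 0

    def test_attenuates_above_cutoff(self):
        fs = 50.0
        t = np.arange(0, 20, 1 / fs)
        fast = np.sin(2 * np.pi * 5.0 * t)
        y = vd.lowpass_zero_phase(fast, fs, cutoff_hz=1.0)
        assert np.std(y) < 0.05 * np.std(fast)

    def test_short_trace_does_not_crash(self):
        y = vd.lowpass_zero_phase(np.ones(8), fs_hz=10.0, cutoff_hz=1.0)
        assert y.shape == (8,)


class TestResponseMetrics:
    def make_trace(self, protocol, baseline=10.0, peak_pct=8.0,
                   latency=1.5, fs=3.8):
        n = int(round(protocol.total_s * fs))
        t = np.arange(n) / fs
        shape = np.clip((t - protocol.baseline_s) / (2 * latency), 0, 1)
        shape[t < protocol.baseline_s] = 0
        shape[t > protocol.baseline_s + protocol.stim_s] = 0
        d = baseline * (1 + peak_pct / 100.0 * shape)
        return vd.DiameterTrace(t=t, d_um=d, segment_class="penetrating",
                                protocol=protocol)

    def test_recovers_configured_baseline_peak_latency(self, protocol):
        tr = self.make_trace(protocol, baseline=10.0, peak_pct=8.0,
                             latency=1.5)
        m = vd.response_metrics(tr)
        assert m.baseline_um == pytest.approx(10.0)
        assert m.peak_pct == pytest.approx(8.0, rel=0.01)
        assert m.latency_s == pytest.approx(1.5, abs=0.05)
        # 30 s protocol: the sustained plateau equals the peak here
        assert m.shallow_peak_pct == pytest.approx(8.0, rel=0.01)

    def test_flat_trace_zero_peak_none_latency(self, protocol):
        n = int(round(protocol.total_s * 3.8))
        tr = vd.DiameterTrace(t=np.arange(n) / 3.8, d_um=np.full(n, 12.0),
                              segment_class="cap1", protocol=protocol)
        m = vd.response_metrics(tr)
        assert m.peak_pct == 0.0
        assert m.latency_s is None

    def test_short_protocol_omits_first_and_shallow_peaks(self):
        proto = sd.StimulusProtocol(baseline_s=15.0, stim_s=2.0,
                                    recovery_s=15.0)
        tr = self.make_trace(proto, latency=0.5)
        m = vd.response_metrics(tr)
        assert m.first_peak_pct is None
        assert m.shallow_peak_pct is None

    def test_missing_protocol_is_an_error(self):
        tr = vd.DiameterTrace(t=np.arange(10.0), d_um=np.full(10, 5.0),
                              segment_class="cap1", protocol=None)
        with pytest.raises(ValueError):
            vd.response_metrics(tr)


class TestOnsetOrder:
    def metrics(self, latencies):
        return {seg: vd.ResponseMetrics(baseline_um=10.0, peak_pct=5.0,
                                        latency_s=lat)
                for seg, lat in latencies.items()}

    def test_orders_segments_by_latency(self):
        order, tied = vd.segment_onset_order(self.metrics(
            {"pial>25": 2.4, "cap1": 1.1, "sphincter": 1.5}))
        assert order == ["cap1", "sphincter", "pial>25"]
        assert not tied

    def test_exact_tie_breaks_capillary_first_and_flags(self):
        order, tied = vd.segment_onset_order(self.metrics(
            {"penetrating": 1.0, "cap1": 1.0}))
        assert order == ["cap1", "penetrating"]
        assert tied

    def test_undefined_latency_is_excluded(self):
        mets = self.metrics({"cap1": 1.0, "pial<25": 2.0})
        mets["cap2"] = vd.ResponseMetrics(baseline_um=7.0, peak_pct=0.0,
                                          latency_s=None)
        order, _ = vd.segment_onset_order(mets)
        assert "cap2" not in order

    def test_fewer_than_two_defined_latencies_is_an_error(self):
        with pytest.raises(ValueError):
            vd.segment_onset_order(self.metrics({"cap1": 1.0}))


class TestDiameterTraceValidation:
    def test_unknown_segment_class_rejected(self):
        with pytest.raises(ValueError):
            vd.DiameterTrace(t=np.arange(5.0), d_um=np.full(5, 4.0),
                             segment_class="vein-of-galen")

    def test_negative_diameter_rejected(self):
        with pytest.raises(ValueError):
            vd.DiameterTrace(t=np.arange(5.0), d_um=np.array([1, 2, -3, 4, 5.0]),
                             segment_class="cap1")
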