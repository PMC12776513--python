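"""Synthetic neurovascular imaging data with known ground truth.

Every input the analysis pipeline consumes can be generated here with
the acquisition geometry of an awake-mouse two-photon experiment:
line-scan kymographs at 0.8-1.3 kHz with diagonal RBC streaks, vessel
movies with stimulus-locked dilation, correlated calcium populations at
3.8 Hz, mono-exponential phosphorescence decays with Poisson counting
noise, tissue pO2 fields with arteriole-to-venule gradients, and
NADH/SR101 trace pairs sharing a hemodynamic artifact.  Each generator
returns its artifact together with a ground-truth dictionary so that
analysis operations can be validated by parameter recovery.

Conventions: time in seconds, lengths in micrometers, speeds in mm/s,
pO2 in mmHg; frames are 0-based; windows are half-open [t0, t1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .calcium_ensemble import CalciumRecording
from .nadh_metabolism import NadhTracePair
from .oximetry import AcquisitionSchedule, DecaySet, OxyCalibration, TissuePO2Map
from .rbc_flow import Kymograph
from .vessel_dynamics import DiameterTrace

GroundTruth = dict

BEHAVIOR_STATES = ("rest", "whisk", "whisk+motion", "puff", "puff+motion")


@dataclass
class NoiseModel:
    """Additive Gaussian detector noise and Poisson photon-count scale."""

    gaussian_sd: float = 0.0
    poisson_scale: float = 0.0


@dataclass
class SimConfig:
    """Acquisition geometry and noise shared by the generators.

    Defaults mirror a typical awake-mouse two-photon configuration:
    1 kHz line scanning (instrument range 0.8-1.3 kHz), a 3.8 Hz
    resonant-scanner frame rate and 0.994 um pixels (1.0057 px/um).
    """

    seed: int = 0
    duration_s: float = 60.0
    line_rate_hz: float = 1000.0
    frame_rate_hz: float = 3.8
    pixel_size_um: float = 0.994
    noise: NoiseModel = field(default_factory=NoiseModel)

    def __post_init__(self) -> None:
        for name in ("duration_s", "line_rate_hz", "frame_rate_hz", "pixel_size_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def rng(self, stream: int = 0) -> np.random.Generator:
        """Deterministic per-stream generator derived from the seed."""
        return np.random.default_rng(np.random.SeedSequence((self.seed, stream)))


@dataclass
class StimulusProtocol:
    """Air-puff whisker-stimulation timing.

    The standard protocols are 15 s baseline / 30 s stimulation / 15 s
    recovery, or short 5 s puffs with a 15 s baseline.
    """

    baseline_s: float = 15.0
    stim_s: float = 30.0
    recovery_s: float = 15.0
    puff_times: Optional[list[float]] = None

    def __post_init__(self) -> None:
        if min(self.baseline_s, self.stim_s, self.recovery_s) < 0:
            raise ValueError("protocol windows must be non-negative")

    @property
    def onset_s(self) -> float:
        return self.baseline_s

    @property
    def total_s(self) -> float:
        return self.baseline_s + self.stim_s + self.recovery_s

    def stim_window(self) -> tuple[float, float]:
        return (self.baseline_s, self.baseline_s + self.stim_s)


def behavior_labels(cfg: SimConfig, protocol: StimulusProtocol,
                    n_frames: int, whisk_prob: float = 0.05,
                    motion_prob: float = 0.2,
                    rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Per-frame behavior state labels.

    Frames inside the stimulation window are 'puff' (or 'puff+motion');
    outside it, occasional spontaneous whisking bouts occur; motion is
    superimposed with probability ``motion_prob`` per bout.
    """
    if rng is None:
        rng = cfg.rng(99)
    t = np.arange(n_frames) / cfg.frame_rate_hz
    on, off = protocol.stim_window()
    labels = np.full(n_frames, "rest", dtype=object)
    in_puff = (t >= on) & (t < off)
    labels[in_puff] = "puff+motion" if rng.random() < motion_prob else "puff"
    i = 0
    while i < n_frames:
        if not in_puff[i] and rng.random() < whisk_prob / cfg.frame_rate_hz:
            state = "whisk+motion" if rng.random() < motion_prob else "whisk"
            j = i + int(rng.integers(2, 8))
            sl = slice(i, min(j, n_frames))
            labels[sl] = np.where(in_puff[sl], labels[sl], state)
            i = j
        else:
            i += 1
    return labels.astype(str)


# ---------------------------------------------------------------------------
# Kymographs
# ---------------------------------------------------------------------------

def gen_kymograph(
    cfg: SimConfig,
    speed_mm_s: float,
    flux_rbc_s: float,
    stalls: Sequence[tuple[float, float]] = (),
    n_px: int = 64,
    cell_fwhm_um: float = 6.0,
    cell_contrast: float = 0.6,
) -> tuple[Kymograph, GroundTruth]:
    """Line-scan kymograph with diagonal RBC streaks.

    Cells enter the scanned segment as a Poisson process at
    ``flux_rbc_s`` and advance ``speed * pixel_conversion`` pixels per
    line, rendered as Gaussian-profile dark streaks (~6 um, RBC scale)
    on a bright plasma background.  During ``stalls`` (list of
    (start_s, end_s)) all motion freezes, so streaks run vertical.
    """
    if speed_mm_s < 0 or flux_rbc_s < 0:
        raise ValueError("speed and flux must be non-negative")
    rng = cfg.rng(1)
    n_lines = int(round(cfg.duration_s * cfg.line_rate_hz))
    t_lines = np.arange(n_lines) / cfg.line_rate_hz

    # effective motion time: freezes inside stall intervals
    stalled_before = np.zeros(n_lines)
    for (s0, s1) in sorted(stalls):
        stalled_before += np.clip(t_lines - s0, 0, s1 - s0)
    motion_t = t_lines - stalled_before

    speed_um_s = speed_mm_s * 1000.0
    length_um = n_px * cfg.pixel_size_um
    moving_s = float(motion_t[-1]) if n_lines else 0.0
    min_spacing_um = 1.6 * cell_fwhm_um  # cells exclude each other's volume
    if speed_um_s > 0:
        transit_s = length_um / speed_um_s
        # renewal arrivals on the motion clock (cells neither enter nor
        # move while flow is stalled) with a dead time enforcing the
        # physical minimum headway, at the requested mean rate
        dead_s = min_spacing_um / speed_um_s
        if flux_rbc_s * dead_s >= 1.0:
            raise ValueError("flux too high for non-overlapping cells at "
                             "this speed")
        entries = []
        if flux_rbc_s > 0:
            lam = 1.0 / (1.0 / flux_rbc_s - dead_s)
            t_k = -transit_s + rng.exponential(1.0 / lam)
            while t_k < moving_s:
                entries.append(t_k)
                t_k += dead_s + rng.exponential(1.0 / lam)
        # a stall is a stuck cell: guarantee one is mid-segment when the
        # flow freezes so the stalled streak is visible
        for (s0, s1) in sorted(stalls):
            m0 = s0 - sum(max(min(s0, b) - a, 0.0) for (a, b) in sorted(stalls)
                          if a < s0)
            if not any(m0 - transit_s < e <= m0 for e in entries):
                entries.append(m0 - transit_s / 2.0)
        entry_motion_t = np.sort(np.asarray(entries, dtype=float))
        n_cells = entry_motion_t.size
        entry_x = np.zeros(n_cells)
    else:
        n_cells = rng.poisson(flux_rbc_s * cfg.duration_s)
        entry_motion_t = np.sort(rng.uniform(0, max(moving_s, 1e-12),
                                             size=n_cells))
        entry_x = rng.uniform(0, length_um, size=n_cells)

    img = np.ones((n_lines, n_px))
    sigma_um = cell_fwhm_um / 2.3548
    x_um = (np.arange(n_px) + 0.5) * cfg.pixel_size_um
    for k in range(n_cells):
        xc = entry_x[k] + speed_um_s * (motion_t - entry_motion_t[k])
        visible = (xc > -3 * sigma_um) & (xc < length_um + 3 * sigma_um)
        if not visible.any():
            continue
        rows = np.flatnonzero(visible)
        prof = np.exp(-0.5 * ((x_um[None, :] - xc[rows, None]) / sigma_um) ** 2)
        img[rows] -= cell_contrast * prof
    img = np.clip(img, 0.0, None)
    if cfg.noise.gaussian_sd > 0:
        img = img + rng.normal(0, cfg.noise.gaussian_sd, img.shape)

    kym = Kymograph(image=img, line_rate_hz=cfg.line_rate_hz,
                    pixel_size_um=cfg.pixel_size_um)
    gt: GroundTruth = {
        "speed_mm_s": speed_mm_s,
        "flux_rbc_s": flux_rbc_s,
        "entry_times_s": entry_motion_t,
        "stall_intervals": [tuple(s) for s in stalls],
        "px_per_line": speed_um_s / (cfg.line_rate_hz * cfg.pixel_size_um),
    }
    return kym, gt


# ---------------------------------------------------------------------------
# Vessel movies and segment scenes
# ---------------------------------------------------------------------------

def _band_frame(shape: tuple[int, int], width_um: float, pixel_size_um: float,
                angle_deg: float = 0.0, edge_sigma_px: float = 1.0) -> np.ndarray:
    """Bright band of the given full width, rotated by angle_deg."""
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols].astype(float)
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    th = np.deg2rad(angle_deg)
    # signed distance from the band's center line
    dist_px = -(yy - cy) * np.cos(th) + (xx - cx) * np.sin(th)
    half_px = width_um / pixel_size_um / 2.0
    from scipy.special import erf
    s = edge_sigma_px * np.sqrt(2)
    return 0.5 * (erf((dist_px + half_px) / s) - erf((dist_px - half_px) / s))


def _disk_frame(shape: tuple[int, int], diameter_um: float,
                pixel_size_um: float, edge_sigma_px: float = 1.0) -> np.ndarray:
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols].astype(float)
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    r_px = np.hypot(yy - cy, xx - cx)
    half_px = diameter_um / pixel_size_um / 2.0
    from scipy.special import erf
    s = edge_sigma_px * np.sqrt(2)
    return 0.5 * (1 + erf((half_px - r_px) / s))


def gen_vessel_movie(
    cfg: SimConfig,
    orientation: str,
    diameter_um_fn: Callable[[float], float],
    shape: tuple[int, int] = (64, 64),
    angle_deg: float = 0.0,
) -> tuple[np.ndarray, GroundTruth]:
    """Movie of a vessel with a time-varying diameter.

    ``orientation='parallel'`` renders a bright band whose local full
    width equals diameter(t) (optionally rotated in plane);
    ``'perpendicular'`` renders a filled disk of that diameter.
    Additive Gaussian noise follows ``cfg.noise``.
    """
    if orientation not in ("parallel", "perpendicular"):
        raise ValueError("orientation must be 'parallel' or 'perpendicular'")
    n_frames = int(round(cfg.duration_s * cfg.frame_rate_hz))
    t = np.arange(n_frames) / cfg.frame_rate_hz
    d = np.array([float(diameter_um_fn(tt)) for tt in t])
    if np.any(d <= 0):
        raise ValueError("diameter must be positive at all times")
    frames = np.empty((n_frames,) + shape)
    for i in range(n_frames):
        if orientation == "parallel":
            frames[i] = _band_frame(shape, d[i], cfg.pixel_size_um, angle_deg)
        else:
            frames[i] = _disk_frame(shape, d[i], cfg.pixel_size_um)
    if cfg.noise.gaussian_sd > 0:
        rng = cfg.rng(2)
        frames = frames + rng.normal(0, cfg.noise.gaussian_sd, frames.shape)
    gt: GroundTruth = {"diameter_um": d, "t": t, "angle_deg": angle_deg}
    return frames, gt


#: WT segment response defaults: (baseline diameter um, peak dilation %,
#: latency to half-max s).  Latencies follow the capillary-first temporal
#: sequence of segmental dilation; amplitudes are largest at the sphincter
#: and first-order capillary, smallest in large pial arteries.
WT_SEGMENT_DEFAULTS: dict[str, tuple[float, float, float]] = {
    "cap1": (8.0, 10.0, 0.5),
    "cap2": (7.0, 8.0, 0.7),
    "sphincter": (10.0, 14.0, 0.9),
    "penetrating": (18.0, 9.0, 1.2),
    "pial<25": (20.0, 8.0, 1.5),
    "pial>25": (35.0, 5.0, 1.8),
}


def _dilation_shape(t: np.ndarray, protocol: StimulusProtocol,
                    latency_s: float, decay_s: float = 4.0) -> np.ndarray:
    """Unit response: linear rise reaching 1 at 2*latency (half max at
    latency), plateau during stimulation, exponential return after."""
    on, off = protocol.stim_window()
    r = np.zeros_like(t)
    rise_end = on + 2.0 * latency_s
    rising = (t >= on) & (t < rise_end)
    r[rising] = (t[rising] - on) / (2.0 * latency_s)
    plateau = (t >= rise_end) & (t < off)
    r[plateau] = 1.0
    after = t >= off
    r[after] = np.exp(-(t[after] - off) / decay_s)
    return r


def gen_segment_scene(
    cfg: SimConfig,
    genotype: str = "WT",
    protocol: Optional[StimulusProtocol] = None,
    amplitude_scale_ps19: float = 0.5,
    latency_shift_ps19_s: float = 0.6,
) -> tuple[dict[str, DiameterTrace], GroundTruth]:
    """Diameter traces for the six vascular segment classes.

    WT latencies follow the capillary-first sequence (1st-order
    capillary, then sphincter, penetrating and pial arterioles).  The
    'PS19-like' genotype scales every peak dilation down and delays
    every latency by configured deltas, emulating attenuated and
    delayed segmental responses.
    """
    if genotype not in ("WT", "PS19-like"):
        raise ValueError(f"unknown genotype {genotype!r}")
    if protocol is None:
        protocol = StimulusProtocol(baseline_s=15.0, stim_s=30.0, recovery_s=15.0)
    n_frames = int(round(protocol.total_s * cfg.frame_rate_hz))
    t = np.arange(n_frames) / cfg.frame_rate_hz
    rng = cfg.rng(3)
    traces: dict[str, DiameterTrace] = {}
    truth: dict[str, dict[str, float]] = {}
    for seg, (d0, amp, lat) in WT_SEGMENT_DEFAULTS.items():
        if genotype == "PS19-like":
            amp = amp * amplitude_scale_ps19
            lat = lat + latency_shift_ps19_s
        d = d0 * (1.0 + amp / 100.0 * _dilation_shape(t, protocol, lat))
        if cfg.noise.gaussian_sd > 0:
            d = d + rng.normal(0, cfg.noise.gaussian_sd * d0 / 100.0, d.size)
            d = np.clip(d, 0.1 * d0, None)
        traces[seg] = DiameterTrace(t=t, d_um=d, segment_class=seg,
                                    protocol=protocol)
        truth[seg] = {"baseline_um": d0, "peak_pct": amp, "latency_s": lat}
    gt: GroundTruth = {"genotype": genotype, "segments": truth,
                       "protocol": protocol}
    return traces, gt


# ---------------------------------------------------------------------------
# Calcium populations
# ---------------------------------------------------------------------------

def gen_calcium_population(
    cfg: SimConfig,
    n_cells: int = 30,
    base_rate_hz: float = 0.03,
    loading: float = 0.5,
    puff_gain: float = 4.0,
    latent_rate_hz: float = 0.02,
    kernel_rise_s: float = 0.1,
    kernel_decay_s: float = 0.8,
    amplitude: float = 1.0,
    protocol: Optional[StimulusProtocol] = None,
) -> tuple[CalciumRecording, GroundTruth]:
    """Population ΔF/F with a shared-latent correlation structure.

    Per-cell spikes are independent Poisson trains at ``base_rate_hz``
    plus shared latent events (rate ``latent_rate_hz``, multiplied by
    ``puff_gain`` inside the stimulation window) that each cell joins
    with probability ``loading``.  ΔF/F is the spike train convolved
    with a difference-of-exponentials kernel plus Gaussian noise.
    With loading 0 cells are independent; with loading 1 and no noise
    all cells are identical.
    """
    if n_cells < 2:
        raise ValueError("need at least 2 cells")
    if base_rate_hz < 0 or latent_rate_hz < 0:
        raise ValueError("rates must be non-negative")
    if kernel_decay_s <= 0:
        raise ValueError("kernel decay must be positive")
    rng = cfg.rng(4)
    if protocol is None:
        protocol = StimulusProtocol(baseline_s=15.0, stim_s=5.0,
                                    recovery_s=max(cfg.duration_s - 20.0, 0.0))
    n_frames = int(round(cfg.duration_s * cfg.frame_rate_hz))
    dt = 1.0 / cfg.frame_rate_hz
    t = np.arange(n_frames) * dt
    on, off = protocol.stim_window()

    latent_rate = np.full(n_frames, latent_rate_hz)
    latent_rate[(t >= on) & (t < off)] *= puff_gain
    latent = rng.random(n_frames) < latent_rate * dt
    latent_times = t[latent]

    spikes = np.zeros((n_cells, n_frames), dtype=int)
    spikes += (rng.random((n_cells, n_frames)) < base_rate_hz * dt)
    join = rng.random((n_cells, latent.sum())) < loading
    idx_latent = np.flatnonzero(latent)
    for c in range(n_cells):
        spikes[c, idx_latent[join[c]]] += 1

    # difference-of-exponentials calcium kernel, peak-normalized
    tk = np.arange(0, 6 * kernel_decay_s, dt)
    kern = np.exp(-tk / kernel_decay_s) - np.exp(-tk / max(kernel_rise_s, dt / 4))
    if kern.max() > 0:
        kern = kern / kern.max()
    dff = np.array([np.convolve(s, kern)[:n_frames] for s in spikes]) * amplitude
    if cfg.noise.gaussian_sd > 0:
        dff = dff + rng.normal(0, cfg.noise.gaussian_sd, dff.shape)

    labels = behavior_labels(cfg, protocol, n_frames, rng=cfg.rng(5))
    rec = CalciumRecording(dff=dff, frame_rate_hz=cfg.frame_rate_hz,
                           behavior=labels, protocol=protocol)
    gt: GroundTruth = {
        "spike_times_s": [t[spikes[c] > 0] for c in range(n_cells)],
        "spike_counts": spikes.sum(axis=1),
        "latent_times_s": latent_times,
        "loading": loading,
        "kernel": {"rise_s": kernel_rise_s, "decay_s": kernel_decay_s},
    }
    return rec, gt


# ---------------------------------------------------------------------------
# Phosphorescence decays and tissue maps
# ---------------------------------------------------------------------------

def gen_decays(
    cfg: SimConfig,
    po2_mmhg: Sequence[float],
    calib: Optional[OxyCalibration] = None,
    photons_per_cycle: float = 50.0,
    n_cycles: int = 100,
    bin_width_us: float = 1.0,
    collection_us: float = 290.0,
    background_per_bin: float = 0.0,
    schedule: Optional[AcquisitionSchedule] = None,
) -> tuple[DecaySet, GroundTruth]:
    """Per-ROI photon-count decay histograms with Poisson noise.

    Each ROI's expected histogram over the 290 us collection window is
    proportional to exp(-t/tau(pO2)) with total expected photons
    ``photons_per_cycle * n_cycles``; counts are Poisson.  With
    ``photons_per_cycle=inf`` the noiseless expectation is returned.
    """
    if calib is None:
        calib = OxyCalibration()
    po2 = np.asarray(po2_mmhg, dtype=float)
    if np.any(po2 < 0):
        raise ValueError("pO2 must be non-negative")
    if photons_per_cycle <= 0:
        raise ValueError("photons_per_cycle must be positive")
    rng = cfg.rng(6)
    n_bins = int(round(collection_us / bin_width_us))
    t = (np.arange(n_bins) + 0.5) * bin_width_us
    taus = np.asarray(calib.tau(po2), dtype=float).reshape(-1)
    counts = np.empty((taus.size, n_bins))
    for i, tau in enumerate(taus):
        shape = np.exp(-t / tau)
        if np.isfinite(photons_per_cycle):
            lam = shape / shape.sum() * photons_per_cycle * n_cycles
            counts[i] = rng.poisson(lam + background_per_bin)
        else:
            counts[i] = shape + background_per_bin
    ds = DecaySet(counts=counts, bin_width_us=bin_width_us,
                  n_cycles=n_cycles, schedule=schedule)
    gt: GroundTruth = {"po2_mmhg": po2, "tau_us": taus, "calib": calib}
    return ds, gt


def gen_tissue_map(
    cfg: SimConfig,
    arterioles: Sequence[tuple[int, int]],
    venules: Sequence[tuple[int, int]],
    group_mean_mmhg: float = 29.3,
    group_sd_mmhg: float = 3.0,
    gradient_um_scale: float = 60.0,
    gradient_amp_mmhg: float = 20.0,
    grid: tuple[int, int] = (32, 32),
    pixel_size_um: float = 16.0,
    pixel_noise_sd: float = 0.0,
) -> tuple[TissuePO2Map, GroundTruth]:
    """Gridded tissue pO2 with an arteriole-to-venule gradient.

    The noiseless field decays exponentially with distance from the
    nearest arteriole (scale ``gradient_um_scale``), re-centered so the
    map mean equals a per-animal draw N(group_mean, group_sd).  Values
    at arteriole walls therefore exceed values at venule walls by
    construction, and gradient scale -> infinity flattens the field.
    """
    if len(arterioles) == 0 or len(venules) == 0:
        raise ValueError("need at least one arteriole and one venule")
    from scipy.ndimage import distance_transform_edt
    rng = cfg.rng(7)
    art = np.zeros(grid, dtype=bool)
    ven = np.zeros(grid, dtype=bool)
    for (r, c) in arterioles:
        art[r, c] = True
    for (r, c) in venules:
        ven[r, c] = True
    d_art = distance_transform_edt(~art) * pixel_size_um
    shape = np.exp(-d_art / gradient_um_scale)
    map_mean = rng.normal(group_mean_mmhg, group_sd_mmhg)
    po2 = map_mean + gradient_amp_mmhg * (shape - shape.mean())
    if pixel_noise_sd > 0:
        po2 = po2 + rng.normal(0, pixel_noise_sd, po2.shape)
    po2 = np.clip(po2, 0.0, None)
    tmap = TissuePO2Map(po2=po2, arteriole_mask=art, venule_mask=ven,
                        pixel_size_um=pixel_size_um)
    gt: GroundTruth = {"map_mean_mmhg": map_mean,
                       "group_mean_mmhg": group_mean_mmhg,
                       "gradient_um_scale": gradient_um_scale,
                       "noiseless": pixel_noise_sd == 0}
    return tmap, gt


# ---------------------------------------------------------------------------
# NADH / SR101 trace pairs
# ---------------------------------------------------------------------------

def gen_nadh_traces(
    cfg: SimConfig,
    dip_pct: float = 1.5,
    overshoot_pct: float = 3.0,
    artifact_gain: float = 0.8,
    artifact_amp_pct: float = -2.0,
    frame_rate_hz: float = 1.087,
    protocol: Optional[StimulusProtocol] = None,
) -> tuple[NadhTracePair, GroundTruth]:
    """NADH and SR101 ΔF/F traces sharing a hemodynamic artifact.

    The SR101 trace is artifact only (a smooth blood-volume transient
    during stimulation); the NADH trace is the metabolic component — a
    dip of ``dip_pct`` early in stimulation followed by an overshoot of
    ``overshoot_pct`` — plus ``artifact_gain`` times the artifact.
    """
    if protocol is None:
        protocol = StimulusProtocol(baseline_s=15.0, stim_s=30.0, recovery_s=15.0)
    rng = cfg.rng(8)
    n = int(round(protocol.total_s * frame_rate_hz))
    t = np.arange(n) / frame_rate_hz
    on, off = protocol.stim_window()

    # metabolic component: early dip then sigmoidal overshoot, decaying after
    metabolic = np.zeros(n)
    metabolic -= dip_pct * np.exp(-0.5 * ((t - (on + 2.0)) / 1.2) ** 2)
    ramp = 1.0 / (1.0 + np.exp(-(t - (on + 10.0)) / 3.0))
    envelope = np.where(t < off, 1.0, np.exp(-(t - off) / 8.0))
    metabolic += overshoot_pct * ramp * envelope

    # hemodynamic artifact shared by both channels
    a_ramp = 1.0 / (1.0 + np.exp(-(t - (on + 2.0)) / 1.0))
    artifact = artifact_amp_pct * a_ramp * np.where(
        t < off, 1.0, np.exp(-(t - off) / 5.0))
    # slow vasomotion keeps baseline artifact variance so the channel
    # coupling is identifiable from the pre-stimulus window
    artifact = artifact + 0.5 * np.sin(2 * np.pi * 0.1 * t)

    sd = cfg.noise.gaussian_sd
    sr101 = artifact + (rng.normal(0, sd, n) if sd > 0 else 0.0)
    nadh = metabolic + artifact_gain * artifact + (
        rng.normal(0, sd, n) if sd > 0 else 0.0)
    pair = NadhTracePair(nadh_dff=nadh, sr101_dff=sr101,
                         frame_rate_hz=frame_rate_hz, protocol=protocol)
    gt: GroundTruth = {"metabolic_pct": metabolic, "artifact_pct": artifact,
                       "artifact_gain": artifact_gain,
                       "dip_pct": dip_pct, "overshoot_pct": overshoot_pct}
    return pair, gt


# ---------------------------------------------------------------------------
# Coupled ensemble/dilation scenes
# ---------------------------------------------------------------------------

def gen_coupled_scene(
    cfg: SimConfig,
    n_events: int = 12,
    coupling_gain: float = 0.2,
    pairing_prob: float = 1.0,
    event_pct_range: tuple[float, float] = (20.0, 60.0),
    baseline_um: float = 20.0,
    dilation_lag_s: float = 1.0,
    dilation_width_s: float = 0.5,
    duration_s: Optional[float] = None,
) -> tuple[dict, GroundTruth]:
    """Paired ensemble-event and arteriolar-diameter traces.

    Ensemble events of random magnitude occur at regular intervals;
    with probability ``pairing_prob`` each one is followed by a causal
    gamma-shaped dilation transient peaking ``dilation_lag_s`` after
    the event onset (rise-time spread ``dilation_width_s``) whose
    percent amplitude is ``coupling_gain`` times the ensemble
    magnitude.  The transient is exactly zero before the event onset,
    so pre-event diameter baselines are uncontaminated.

    Returns a dict with keys ``events`` (list of (start_s, end_s,
    peak_pct)), ``t`` and ``d_um``.
    """
    rng = cfg.rng(9)
    dur = duration_s if duration_s is not None else cfg.duration_s
    fr = cfg.frame_rate_hz
    n = int(round(dur * fr))
    t = np.arange(n) / fr
    gap = dur / (n_events + 1)
    starts = gap * (np.arange(n_events) + 1)
    mags = rng.uniform(*event_pct_range, size=n_events)
    paired = rng.random(n_events) < pairing_prob
    d = np.full(n, baseline_um)
    # causal bump: (tau/tp)^a * exp(a*(1 - tau/tp)), peak 1 at tau = tp
    alpha = max(1.0, (dilation_lag_s / dilation_width_s) ** 2)
    for s, m, p in zip(starts, mags, paired):
        if p:
            amp_um = baseline_um * (coupling_gain * m) / 100.0
            tau = np.clip(t - s, 0.0, None) / dilation_lag_s
            d += amp_um * tau ** alpha * np.exp(alpha * (1.0 - tau))
    if cfg.noise.gaussian_sd > 0:
        d = d + rng.normal(0, cfg.noise.gaussian_sd * baseline_um / 100.0, n)
    events = [(float(s), float(s + 1.0), float(m)) for s, m in zip(starts, mags)]
    scene = {"events": events, "t": t, "d_um": np.clip(d, 0.1, None)}
    gt: GroundTruth = {"coupling_gain": coupling_gain, "paired": paired,
                       "event_pct": mags, "event_starts_s": starts}
    return scene, gt
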