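"""Vessel diameter extraction and stimulus-locked response metrics.

Diameters come from three estimators depending on vessel orientation:

* :func:`fwhm_diameter` — full width at half maximum of a transverse
  intensity profile (vessels parallel to the imaging plane).
* :func:`radon_projection_diameter` — per-frame FWHM of the profile
  transverse to the dominant vessel axis, found by maximizing projection
  variance over rotation angle.
* :func:`tirs_diameter` — thresholding in Radon space for vessels
  imaged in cross-section (filled-lumen blobs).

Response metrics are percent changes relative to the mean diameter over
the 5 s immediately preceding stimulation; latency is the time from
stimulus onset to half of the maximum dilation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
from scipy import ndimage, signal
from skimage.measure import label as _cc_label
from skimage.transform import iradon, radon

SEGMENT_CLASSES = ("cap1", "cap2", "sphincter", "penetrating", "pial<25", "pial>25")

#: canonical capillary-first ordering used to break latency ties
_CLASS_RANK = {c: i for i, c in enumerate(SEGMENT_CLASSES)}


class VesselNotFoundError(ValueError):
    """No vessel profile could be extracted (flat/empty input)."""


class AmbiguousVesselError(ValueError):
    """Segmentation produced more than one candidate vessel."""


@dataclass
class DiameterTrace:
    """Vessel diameter time series with its acquisition context.

    Parameters
    ----------
    t : array of float
        Sample times in seconds, strictly increasing and uniform.
    d_um : array of float
        Diameter in micrometers, strictly positive.
    segment_class : str
        One of ``cap1, cap2, sphincter, penetrating, pial<25, pial>25``.
    protocol : object, optional
        Stimulus protocol with ``baseline_s``, ``stim_s``, ``recovery_s``.
    """

    t: np.ndarray
    d_um: np.ndarray
    segment_class: Optional[str] = None
    protocol: Optional[object] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.d_um = np.asarray(self.d_um, dtype=float)
        if self.t.shape != self.d_um.shape:
            raise ValueError("t and d_um must have the same shape")
        if self.t.size >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError("t must be strictly increasing")
        if np.any(self.d_um <= 0):
            raise ValueError("diameters must be positive")
        if self.segment_class is not None and self.segment_class not in SEGMENT_CLASSES:
            raise ValueError(f"unknown segment class {self.segment_class!r}")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


@dataclass
class ResponseMetrics:
    """Stimulus-locked dilation metrics for one vessel segment.

    All percentages are relative to ``baseline_um``, the mean diameter
    over the 5 s immediately preceding stimulus onset.  ``latency_s`` is
    the time from onset to the first crossing of half the maximum
    dilation (``None`` when the trace never dilates).  ``first_peak_pct``
    (max dilation 1-4 s post onset) and ``shallow_peak_pct`` (mean
    dilation 20-30 s into stimulation) are only defined for the 30 s
    protocol and are ``None`` otherwise.
    """

    baseline_um: float
    peak_pct: float
    latency_s: Optional[float]
    first_peak_pct: Optional[float] = None
    shallow_peak_pct: Optional[float] = None


# ---------------------------------------------------------------------------
# FWHM diametry
# ---------------------------------------------------------------------------

def _background_level(profile: np.ndarray) -> float:
    """Mode of the profile's lower quartile (robust to streak shadows)."""
    lo = np.sort(profile)[: max(1, profile.size // 4)]
    if lo.size < 4 or np.ptp(lo) == 0:
        return float(lo[0])
    hist, edges = np.histogram(lo, bins=min(16, lo.size))
    k = int(np.argmax(hist))
    return float(0.5 * (edges[k] + edges[k + 1]))


def fwhm_diameter(profile: Sequence[float], pixel_size_um: float) -> float:
    """Full width at half maximum of a single-lobed intensity profile.

    The background level is the mode of the lower quartile; half max is
    midway between background and the profile peak.  Crossings are
    located with linear sub-pixel interpolation on either side of the
    peak and their separation is scaled by ``pixel_size_um``.

    Raises
    ------
    VesselNotFoundError
        If the profile is flat or no half-max crossing exists.
    """
    p = np.asarray(profile, dtype=float)
    if p.size < 3 or np.ptp(p) == 0:
        raise VesselNotFoundError("flat or empty profile")
    bg = _background_level(p)
    peak_idx = int(np.argmax(p))
    peak = p[peak_idx]
    if peak <= bg:
        raise VesselNotFoundError("no lobe above background")
    half = bg + 0.5 * (peak - bg)

    def _cross(idx_range: range) -> Optional[float]:
        prev = peak_idx
        for i in idx_range:
            if p[i] < half:
                # interpolate between i and the previous (above-half) sample
                frac = (half - p[i]) / (p[prev] - p[i])
                return i + frac * (prev - i)
            prev = i
        return None

    left = _cross(range(peak_idx - 1, -1, -1))
    right = _cross(range(peak_idx + 1, p.size))
    if left is None or right is None:
        raise VesselNotFoundError("half-max crossing not found on both sides")
    return float((right - left) * pixel_size_um)


# ---------------------------------------------------------------------------
# Projection-based diametry for movies (vessel parallel to imaging plane)
# ---------------------------------------------------------------------------

def _profile_sharpness(img: np.ndarray, angle_deg: float) -> float:
    rot = ndimage.rotate(img, angle_deg, reshape=False, order=1, mode="nearest")
    return float(np.var(rot.mean(axis=1)))


def estimate_vessel_angle(image: np.ndarray, coarse_step: float = 5.0,
                          fine_step: float = 0.5) -> float:
    """Angle (degrees) that makes the vessel horizontal after rotation.

    Searches for the rotation maximizing the variance of the
    column-averaged transverse profile — equivalent to the Radon
    projection of maximal variance.  Raises :class:`VesselNotFoundError`
    when the image is isotropic (no dominant axis).
    """
    img = np.asarray(image, dtype=float)
    img = img - img.mean()
    coarse = np.arange(-90.0, 90.0, coarse_step)
    v = np.array([_profile_sharpness(img, a) for a in coarse])
    if not np.isfinite(v).all() or v.max() <= 1.5 * np.median(v):
        raise VesselNotFoundError("no dominant vessel axis")
    a0 = coarse[int(np.argmax(v))]
    fine = np.arange(a0 - coarse_step, a0 + coarse_step + 1e-9, fine_step)
    vf = np.array([_profile_sharpness(img, a) for a in fine])
    return float(fine[int(np.argmax(vf))])


def radon_projection_diameter(
    frames: np.ndarray,
    pixel_size_um: float,
    frame_rate_hz: float,
    segment_class: Optional[str] = None,
    protocol: Optional[object] = None,
) -> DiameterTrace:
    """Per-frame diameter of a roughly linear vessel in a movie.

    The dominant vessel axis is estimated once on the time-averaged
    image; every frame is rotated to make the vessel horizontal and the
    FWHM of the column-averaged transverse profile is reported.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise ValueError("frames must be (time, rows, cols)")
    angle = estimate_vessel_angle(frames.mean(axis=0))
    d = np.empty(frames.shape[0])
    for i, fr in enumerate(frames):
        rot = ndimage.rotate(fr, angle, reshape=False, order=1, mode="nearest")
        d[i] = fwhm_diameter(rot.mean(axis=1), pixel_size_um)
    t = np.arange(frames.shape[0]) / frame_rate_hz
    return DiameterTrace(t=t, d_um=d, segment_class=segment_class, protocol=protocol)


# ---------------------------------------------------------------------------
# TiRS diametry (vessel perpendicular to imaging plane)
# ---------------------------------------------------------------------------

def tirs_diameter(
    frame: np.ndarray,
    pixel_size_um: float,
    radon_threshold: float = 0.5,
    image_threshold: float = 2.0 / 3.0,
) -> float:
    """Equivalent-area diameter of a filled vessel cross-section.

    The frame is Radon-transformed over 0-179 degrees; each angle's
    projection is binarized at ``radon_threshold`` of its own maximum;
    the binary sinogram is back-projected (unfiltered) and thresholded
    at ``image_threshold`` of the reconstruction maximum.  The diameter
    is that of the circle with the segmented area, ``2*sqrt(A/pi)``.

    The default image threshold is exact for an ideal disk: half-max
    binarization keeps the chord ``|s| < (sqrt(3)/2) r``, whose plain
    backprojection at radius ``rho > w`` equals ``(2/pi) asin(w/rho)``
    of the center value, crossing 2/3 precisely at ``rho = r``.

    Raises
    ------
    VesselNotFoundError
        Empty segmentation (no vessel above threshold).
    AmbiguousVesselError
        More than one comparably sized blob in the segmentation.
    """
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2:
        raise ValueError("frame must be 2-D")
    img = img - img.min()
    if np.ptp(img) == 0:
        raise VesselNotFoundError("flat frame")
    theta = np.arange(180.0)
    sino = radon(img, theta=theta, circle=False)
    colmax = sino.max(axis=0)
    if np.any(colmax <= 0):
        raise VesselNotFoundError("empty projection")
    binary = (sino >= radon_threshold * colmax[None, :]).astype(float)
    recon = iradon(binary, theta=theta, filter_name=None, circle=False,
                   output_size=max(img.shape))
    mask = recon >= image_threshold * recon.max()
    if not mask.any():
        raise VesselNotFoundError("empty segmentation")
    lab, n = _cc_label(mask, return_num=True)
    if n > 1:
        sizes = np.sort(np.bincount(lab.ravel())[1:])[::-1]
        if sizes.size > 1 and sizes[1] >= 0.25 * sizes[0]:
            raise AmbiguousVesselError("multiple comparable blobs")
        mask = lab == (1 + int(np.argmax(np.bincount(lab.ravel())[1:])))
    area_px = float(mask.sum())
    return 2.0 * np.sqrt(area_px / np.pi) * pixel_size_um


# ---------------------------------------------------------------------------
# Filtering and response metrics
# ---------------------------------------------------------------------------

def lowpass_zero_phase(trace: Sequence[float], fs_hz: float,
                       cutoff_hz: float = 1.0, order: int = 2) -> np.ndarray:
    """Forward-backward Butterworth low-pass (zero phase, unit DC gain)."""
    x = np.asarray(trace, dtype=float)
    if cutoff_hz >= fs_hz / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    if cutoff_hz <= 0:
        raise ValueError("cutoff must be positive")
    b, a = signal.butter(order, cutoff_hz / (fs_hz / 2))
    # padlen guard for very short traces
    padlen = min(3 * max(len(a), len(b)), x.size - 1)
    return signal.filtfilt(b, a, x, padlen=padlen)


def _window_mask(t: np.ndarray, t0: float, t1: float) -> np.ndarray:
    return (t >= t0) & (t < t1)


def response_metrics(trace: DiameterTrace) -> ResponseMetrics:
    """Stimulus-locked dilation metrics of a diameter trace.

    Baseline is the mean diameter over the 5 s immediately preceding
    stimulus onset.  ``peak_pct`` is the maximum percent dilation within
    the stimulation window.  For 30 s stimulation the first peak (max,
    1-4 s post onset) and shallow peak (mean, 20-30 s post onset) are
    reported as well.  Latency is the interpolated time from onset to
    half the maximum dilation, ``None`` when the vessel never dilates.
    """
    proto = trace.protocol
    if proto is None:
        raise ValueError("trace has no stimulus protocol")
    onset = float(proto.baseline_s)
    stim_end = onset + float(proto.stim_s)
    t, d = trace.t, trace.d_um
    base_mask = _window_mask(t, onset - 5.0, onset)
    if not base_mask.any():
        raise ValueError("baseline window not covered by the recording")
    baseline = float(d[base_mask].mean())
    pct = 100.0 * (d - baseline) / baseline

    stim_mask = _window_mask(t, onset, stim_end)
    if not stim_mask.any():
        raise ValueError("stimulation window not covered by the recording")
    peak_pct = float(pct[stim_mask].max())

    first_peak = shallow = None
    if proto.stim_s >= 30.0:
        m14 = _window_mask(t, onset + 1.0, onset + 4.0)
        m2030 = _window_mask(t, onset + 20.0, onset + 30.0)
        if m14.any():
            first_peak = float(pct[m14].max())
        if m2030.any():
            shallow = float(pct[m2030].mean())

    latency = None
    if peak_pct > 0:
        half = 0.5 * peak_pct
        idx = np.flatnonzero(stim_mask & (pct >= half))
        if idx.size:
            i = idx[0]
            if i > 0 and pct[i - 1] < half and pct[i] > pct[i - 1]:
                frac = (half - pct[i - 1]) / (pct[i] - pct[i - 1])
                t_half = t[i - 1] + frac * (t[i] - t[i - 1])
            else:
                t_half = t[i]
            latency = float(max(t_half - onset, 0.0))
    else:
        peak_pct = 0.0
        first_peak = 0.0 if first_peak is not None else None
        shallow = 0.0 if shallow is not None else None

    return ResponseMetrics(baseline_um=baseline, peak_pct=peak_pct,
                           latency_s=latency, first_peak_pct=first_peak,
                           shallow_peak_pct=shallow)


def segment_onset_order(
    metrics: Mapping[str, ResponseMetrics],
    tie_tol_s: float = 1e-9,
) -> tuple[list[str], bool]:
    """Rank vessel segments by dilation latency (earliest first).

    Segments with undefined latency are excluded.  Exact latency ties
    are broken capillary-first (the canonical segment ordering) and the
    ranking is flagged as tied.

    Returns
    -------
    (order, tied) : list of segment names and a tie flag.
    """
    defined = {k: m.latency_s for k, m in metrics.items() if m.latency_s is not None}
    if len(defined) < 2:
        raise ValueError("need at least two segments with defined latency")
    order = sorted(defined, key=lambda k: (defined[k], _CLASS_RANK.get(k, 99)))
    lats = sorted(defined.values())
    tied = any(b - a <= tie_tol_s for a, b in zip(lats, lats[1:]))
    return order, tied
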