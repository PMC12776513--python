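"""Phosphorescence-lifetime oximetry and oxygen accounting.

Oxygen-sensitive probes phosphoresce with a lifetime shortened by
collisional quenching, following the single-site Stern-Volmer relation
``1/tau = 1/tau0 + kq * pO2``.  Per-ROI photon-count decay histograms
are fit with single exponentials; lifetimes convert to pO2, pO2 to
hemoglobin saturation via the Hill equation (mouse blood: h = 2.59,
P50 = 40.2 mmHg), and arteriolar/venular saturations to the oxygen
extraction fraction OEF = (SO2_A - SO2_V) / SO2_A.  Tissue maps are
classified by distance to the nearest labeled vessel (50 um radius) and
scored against the hypoxic threshold of 18 mmHg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.optimize import curve_fit

HYPOXIC_THRESHOLD_MMHG = 18.0


class DecayFitError(RuntimeError):
    """Decay histogram could not be fit with a single exponential."""


@dataclass
class AcquisitionSchedule:
    """Point-scanning schedule of the lifetime acquisition.

    The intravascular protocol visits ``n_rois`` locations for
    ``cycles_per_roi`` excitation/collection cycles each, repeats the
    sweep ``n_repeats`` times and optionally averages consecutive pairs
    of repeats; the tissue protocol scans a rows x cols ``grid``.
    """

    n_rois: int = 7
    cycles_per_roi: int = 100
    n_repeats: int = 140
    pair_average: bool = True
    excitation_us: float = 10.0
    collection_us: float = 290.0
    move_ms: float = 1.7
    grid: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        for name in ("n_rois", "cycles_per_roi", "n_repeats"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.pair_average and self.n_repeats % 2 != 0:
            raise ValueError("pair averaging requires an even number of repeats")


@dataclass
class DecaySet:
    """Per-ROI phosphorescence decay histograms over the collection window."""

    counts: np.ndarray  # rois x bins
    bin_width_us: float
    n_cycles: int = 1
    schedule: Optional[AcquisitionSchedule] = None

    def __post_init__(self) -> None:
        self.counts = np.atleast_2d(np.asarray(self.counts, dtype=float))
        if np.any(self.counts < 0):
            raise ValueError("photon counts must be non-negative")
        if self.bin_width_us <= 0:
            raise ValueError("bin width must be positive")

    @property
    def n_rois(self) -> int:
        return self.counts.shape[0]

    @property
    def t_us(self) -> np.ndarray:
        """Bin-center times in microseconds."""
        return (np.arange(self.counts.shape[1]) + 0.5) * self.bin_width_us


@dataclass
class OxyCalibration:
    """Single-site Stern-Volmer lifetime/pO2 calibration.

    ``tau0_us`` is the unquenched lifetime (pO2 = 0) and ``kq`` the
    quenching constant in 1/(us * mmHg).  Defaults span lifetimes of
    roughly 12-40 us over 0-160 mmHg, typical of two-photon oxygen
    probes; site-specific constants should be fit with
    :func:`calibrate`.
    """

    tau0_us: float = 40.0
    kq_per_us_mmhg: float = 3.65e-4

    def __post_init__(self) -> None:
        if self.tau0_us <= 0 or self.kq_per_us_mmhg <= 0:
            raise ValueError("calibration constants must be positive")

    def tau(self, po2_mmhg: float | np.ndarray) -> float | np.ndarray:
        """Lifetime (us) at a given pO2 (mmHg); strictly decreasing."""
        po2 = np.asarray(po2_mmhg, dtype=float)
        if np.any(po2 < 0):
            raise ValueError("pO2 must be non-negative")
        out = 1.0 / (1.0 / self.tau0_us + self.kq_per_us_mmhg * po2)
        return float(out) if np.isscalar(po2_mmhg) else out


@dataclass
class HillParams:
    """Hill saturation curve parameters (mouse blood defaults)."""

    h: float = 2.59
    p50_mmhg: float = 40.2

    def __post_init__(self) -> None:
        if self.h <= 0 or self.p50_mmhg <= 0:
            raise ValueError("Hill parameters must be positive")


@dataclass
class TissuePO2Map:
    """Gridded tissue pO2 with vessel masks and derived classifications."""

    po2: np.ndarray
    arteriole_mask: np.ndarray
    venule_mask: np.ndarray
    pixel_size_um: float
    distance_class: Optional[np.ndarray] = None  # 0 near-art, 1 near-ven, 2 between
    tie_flag: Optional[np.ndarray] = None
    hypoxic_threshold_mmhg: float = HYPOXIC_THRESHOLD_MMHG

    @property
    def hypoxic_mask(self) -> np.ndarray:
        return self.po2 < self.hypoxic_threshold_mmhg


@dataclass
class OEFRecord:
    so2_a: float
    so2_v: float

    @property
    def oef(self) -> float:
        return oef(self.so2_a, self.so2_v)


# ---------------------------------------------------------------------------
# Decay fitting and lifetime conversion
# ---------------------------------------------------------------------------

def fit_decay(histogram: Sequence[float], bin_width_us: float
              ) -> dict[str, float]:
    """Nonlinear least-squares single-exponential fit of a photon decay.

    Model: counts(t) = A * exp(-t / tau) + background.  Initial guesses
    come from a log-linear fit of the background-subtracted histogram.

    Returns ``{"tau_us", "amplitude", "background", "fit_residual"}``.
    """
    y = np.asarray(histogram, dtype=float)
    if y.size < 10:
        raise DecayFitError("need at least 10 bins")
    if y.sum() <= 0:
        raise DecayFitError("empty histogram")
    if np.ptp(y) == 0:
        raise DecayFitError("flat histogram has no decay")
    t = (np.arange(y.size) + 0.5) * bin_width_us

    bg0 = max(float(y[-max(3, y.size // 10):].mean()), 0.0)
    amp0 = max(float(y[0] - bg0), 1e-12)
    pos = y - bg0 > amp0 * 0.05
    if pos.sum() >= 2:
        slope = np.polyfit(t[pos], np.log(y[pos] - bg0), 1)[0]
        tau0 = -1.0 / slope if slope < 0 else t[-1] / 2
    else:
        tau0 = t[-1] / 5

    def model(tt, A, tau, b):
        return A * np.exp(-tt / tau) + b

    try:
        popt, _ = curve_fit(model, t, y, p0=[amp0, tau0, bg0],
                            bounds=([0, 1e-6, 0], [np.inf, np.inf, np.inf]),
                            maxfev=10_000)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - rare
        raise DecayFitError(f"decay fit failed: {exc}") from exc
    A, tau, b = popt
    if A <= 0:
        raise DecayFitError("no decaying component found")
    resid = float(np.sqrt(np.mean((model(t, *popt) - y) ** 2)))
    return {"tau_us": float(tau), "amplitude": float(A),
            "background": float(b), "fit_residual": resid}


def lifetime_to_po2(tau_us: float | np.ndarray,
                    calib: OxyCalibration) -> float | np.ndarray:
    """Invert the Stern-Volmer relation: pO2 = (1/tau - 1/tau0) / kq.

    Lifetimes above tau0 (possible under noise) are clipped to pO2 = 0
    with a warning.
    """
    tau = np.asarray(tau_us, dtype=float)
    if np.any(tau <= 0):
        raise ValueError("lifetime must be positive")
    if np.any(tau > calib.tau0_us):
        warnings.warn("lifetime exceeds tau0; clipping pO2 to 0")
    po2 = (1.0 / tau - 1.0 / calib.tau0_us) / calib.kq_per_us_mmhg
    po2 = np.clip(po2, 0.0, None)
    return float(po2) if np.isscalar(tau_us) else po2


def calibrate(tau_us: Sequence[float], po2_mmhg: Sequence[float]
              ) -> OxyCalibration:
    """Fit Stern-Volmer constants from (lifetime, pO2) calibration pairs.

    Linear least squares on 1/tau vs pO2: intercept = 1/tau0, slope = kq.
    """
    tau = np.asarray(tau_us, dtype=float)
    po2 = np.asarray(po2_mmhg, dtype=float)
    if tau.size != po2.size or tau.size < 2:
        raise ValueError("need >= 2 matching calibration pairs")
    slope, intercept = np.polyfit(po2, 1.0 / tau, 1)
    if intercept <= 0 or slope <= 0:
        raise ValueError("calibration pairs are not Stern-Volmer consistent")
    return OxyCalibration(tau0_us=1.0 / intercept, kq_per_us_mmhg=slope)


def fit_decay_set(decays: DecaySet, calib: OxyCalibration) -> np.ndarray:
    """Per-ROI pO2 from a DecaySet (fit each histogram, convert lifetime)."""
    out = np.empty(decays.n_rois)
    for i in range(decays.n_rois):
        tau = fit_decay(decays.counts[i], decays.bin_width_us)["tau_us"]
        out[i] = lifetime_to_po2(tau, calib)
    return out


# ---------------------------------------------------------------------------
# Saturation, extraction, hypoxia
# ---------------------------------------------------------------------------

def hill_so2(po2_mmhg: float | np.ndarray,
             params: HillParams = HillParams()) -> float | np.ndarray:
    """Hemoglobin O2 saturation: SO2 = pO2^h / (pO2^h + P50^h)."""
    po2 = np.asarray(po2_mmhg, dtype=float)
    if np.any(po2 < 0):
        raise ValueError("pO2 must be non-negative")
    ph = po2 ** params.h
    so2 = ph / (ph + params.p50_mmhg ** params.h)
    return float(so2) if np.isscalar(po2_mmhg) else so2


def oef(so2_a: float, so2_v: float) -> float:
    """Oxygen extraction fraction (SO2_A - SO2_V) / SO2_A."""
    if so2_a <= 0:
        raise ValueError("arteriolar SO2 must be positive")
    return (so2_a - so2_v) / so2_a


def oef_trace(po2_a: np.ndarray, po2_v: np.ndarray,
              params: HillParams = HillParams()) -> np.ndarray:
    """Pointwise OEF from paired arteriolar/venular pO2 traces."""
    so2_a = hill_so2(np.asarray(po2_a, float), params)
    so2_v = hill_so2(np.asarray(po2_v, float), params)
    return (so2_a - so2_v) / so2_a


def hypoxic_fraction(po2_values: Sequence[float],
                     threshold_mmhg: float = HYPOXIC_THRESHOLD_MMHG) -> float:
    """Fraction of pO2 values strictly below the hypoxic threshold."""
    x = np.asarray(po2_values, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    return float((x < threshold_mmhg).mean())


# ---------------------------------------------------------------------------
# Distance classes
# ---------------------------------------------------------------------------

NEAR_ARTERIOLE, NEAR_VENULE, IN_BETWEEN = 0, 1, 2
DISTANCE_CLASS_NAMES = {0: "near-arteriole", 1: "near-venule", 2: "in-between"}


def classify_distance(arteriole_mask: np.ndarray, venule_mask: np.ndarray,
                      pixel_size_um: float, radius_um: float = 50.0
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel distance class relative to the nearest labeled vessels.

    Points within ``radius_um`` of an arteriole only are near-arteriole;
    within the radius of a venule only, near-venule; within both, the
    nearer vessel wins (exact ties go to near-arteriole and are
    flagged); farther than the radius from both, in-between.

    Returns ``(classes, tie_flag)`` arrays of the mask shape.
    """
    art = np.asarray(arteriole_mask, dtype=bool)
    ven = np.asarray(venule_mask, dtype=bool)
    if not art.any() or not ven.any():
        raise ValueError("need at least one arteriole and one venule pixel")
    d_art = ndimage.distance_transform_edt(~art) * pixel_size_um
    d_ven = ndimage.distance_transform_edt(~ven) * pixel_size_um
    near_a = d_art < radius_um
    near_v = d_ven < radius_um
    classes = np.full(art.shape, IN_BETWEEN, dtype=np.int8)
    classes[near_a & ~near_v] = NEAR_ARTERIOLE
    classes[near_v & ~near_a] = NEAR_VENULE
    both = near_a & near_v
    classes[both & (d_art <= d_ven)] = NEAR_ARTERIOLE
    classes[both & (d_art > d_ven)] = NEAR_VENULE
    tie = both & (d_art == d_ven)
    return classes, tie


def classify_map(tmap: TissuePO2Map, radius_um: float = 50.0) -> TissuePO2Map:
    """Attach distance classes and tie flags to a tissue pO2 map."""
    classes, tie = classify_distance(tmap.arteriole_mask, tmap.venule_mask,
                                     tmap.pixel_size_um, radius_um)
    tmap.distance_class = classes
    tmap.tie_flag = tie
    return tmap


# ---------------------------------------------------------------------------
# Stimulus-evoked metrics and schedule accounting
# ---------------------------------------------------------------------------

def stimulus_po2_metrics(t: np.ndarray, po2: np.ndarray,
                         protocol: object) -> dict[str, float]:
    """Stimulus-locked tissue pO2 metrics (30 s stimulation protocol).

    All values are deltas from the 5 s pre-stimulus baseline mean:
    initial dip (min, 0-2 s post onset), initial peak (max, 2-4 s),
    shallow peak (mean, 20-30 s); ``net_change`` equals the shallow-peak
    delta, the sustained change over the stimulation period.
    """
    if float(protocol.stim_s) < 30.0:
        raise ValueError("stimulus pO2 metrics require the 30 s protocol")
    t = np.asarray(t, float)
    x = np.asarray(po2, float)
    onset = float(protocol.baseline_s)
    base = (t >= onset - 5.0) & (t < onset)
    m02 = (t >= onset) & (t < onset + 2.0)
    m24 = (t >= onset + 2.0) & (t < onset + 4.0)
    m2030 = (t >= onset + 20.0) & (t < onset + 30.0)
    if not (base.any() and m02.any() and m24.any() and m2030.any()):
        raise ValueError("protocol windows not covered by the trace")
    baseline = float(x[base].mean())
    shallow = float(x[m2030].mean()) - baseline
    return {
        "initial_dip": float(x[m02].min()) - baseline,
        "initial_peak": float(x[m24].max()) - baseline,
        "shallow_peak": shallow,
        "net_change": shallow,
    }


def schedule_accounting(schedule: AcquisitionSchedule) -> dict[str, int]:
    """Time points per ROI and total ROI count implied by a schedule."""
    n_tp = schedule.n_repeats // 2 if schedule.pair_average else schedule.n_repeats
    if schedule.grid is not None:
        rows, cols = schedule.grid
        n_rois = rows * cols
    else:
        n_rois = schedule.n_rois
    return {"n_timepoints_per_roi": int(n_tp), "n_rois_total": int(n_rois)}


# ---------------------------------------------------------------------------
# Respirometry summary ratios
# ---------------------------------------------------------------------------

def respirometry_ratios(state2_rate: float, state3_rate: float,
                        adp_nmol: float, o_consumed_nmol: float
                        ) -> dict[str, float]:
    """Respiratory control ratio (state 3 / state 2) and ADP:O ratio.

    ``o_consumed_nmol`` is in nmol of oxygen atoms (O, not O2).
    """
    if state2_rate <= 0:
        raise ValueError("state-2 rate must be positive")
    if o_consumed_nmol <= 0:
        raise ValueError("oxygen consumed must be positive")
    return {"rcr": state3_rate / state2_rate,
            "adp_o": adp_nmol / o_consumed_nmol}
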