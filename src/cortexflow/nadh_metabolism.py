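"""NADH autofluorescence correction and dip/overshoot quantification.

NADH autofluorescence reports the redox state of the tissue, but in
vivo it is contaminated by hemodynamic optical effects (blood volume
and absorption changes during functional hyperemia).  A co-imaged
non-functional fluorophore (SR101) experiences the same optical
artifact but carries no metabolic signal, so regressing the NADH trace
on the SR101 trace isolates the metabolic component.  Stimulation
evokes an initial NADH dip (increased oxidative metabolism) followed by
an overshoot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np


@dataclass
class NadhTracePair:
    """Aligned NADH and SR101 ΔF/F traces (percent units)."""

    nadh_dff: np.ndarray
    sr101_dff: np.ndarray
    frame_rate_hz: float = 1.087
    protocol: Optional[object] = None

    def __post_init__(self) -> None:
        self.nadh_dff = np.asarray(self.nadh_dff, dtype=float)
        self.sr101_dff = np.asarray(self.sr101_dff, dtype=float)
        if self.nadh_dff.shape != self.sr101_dff.shape:
            raise ValueError("NADH and SR101 traces must be aligned")

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.nadh_dff.size) / self.frame_rate_hz


def correct_nadh(pair: NadhTracePair, method: str = "subtractive"
                 ) -> tuple[np.ndarray, float]:
    """Remove the hemodynamic artifact from the NADH trace.

    The artifact coupling coefficient beta is fit by least squares of
    NADH on SR101 over the pre-stimulus baseline window, where the
    metabolic component is flat and the shared artifact dominates both
    channels.  ``subtractive`` returns ``nadh - beta * sr101``;
    ``ratiometric`` divides the linearized fluorescence ratios,
    ``(1 + nadh) / (1 + beta * sr101) - 1``.  The corrected trace is
    re-referenced so its baseline mean is zero.

    If the SR101 channel carries no variance the NADH trace is passed
    through unchanged with a warning (beta = 0).

    Returns
    -------
    (corrected, beta)
    """
    if method not in ("subtractive", "ratiometric"):
        raise ValueError("method must be 'subtractive' or 'ratiometric'")
    nadh, sr = pair.nadh_dff, pair.sr101_dff
    t = pair.t
    if pair.protocol is not None:
        onset = float(pair.protocol.baseline_s)
        base = t < onset
        if not base.any():
            raise ValueError("baseline window missing")
    else:
        base = np.ones(nadh.size, dtype=bool)

    sr_base = sr[base]
    if sr.var() == 0:
        warnings.warn("SR101 channel has zero variance; passing NADH through")
        beta = 0.0
    elif sr_base.var() > 0:
        beta = float(np.polyfit(sr_base, nadh[base], 1)[0])
    else:
        # artifact silent during baseline: fall back to whole recording
        beta = float(np.polyfit(sr, nadh, 1)[0])

    if method == "subtractive":
        corrected = nadh - beta * sr
    else:
        corrected = 100.0 * ((1 + nadh / 100.0) / (1 + beta * sr / 100.0) - 1)
    corrected = corrected - corrected[base].mean()
    return corrected, beta


def dip_overshoot(corrected: np.ndarray, frame_rate_hz: float,
                  protocol: object,
                  overshoot_window_s: tuple[float, float] = (20.0, 40.0)
                  ) -> dict[str, float]:
    """Stimulus-evoked NADH dip and overshoot, relative to baseline.

    Dip is the minimum in the first 5 s after onset; overshoot is the
    mean over ``overshoot_window_s`` (seconds after onset).  Both are
    deltas from the pre-stimulus baseline mean, so they are invariant
    to any constant offset of the corrected trace.
    """
    x = np.asarray(corrected, dtype=float)
    t = np.arange(x.size) / frame_rate_hz
    onset = float(protocol.baseline_s)
    base = (t >= max(onset - 15.0, 0.0)) & (t < onset)
    dip_m = (t >= onset) & (t < onset + 5.0)
    ov_m = (t >= onset + overshoot_window_s[0]) & (t < onset + overshoot_window_s[1])
    if not (base.any() and dip_m.any() and ov_m.any()):
        raise ValueError("analysis window outside recording")
    baseline = float(x[base].mean())
    return {"dip_pct": float(x[dip_m].min()) - baseline,
            "overshoot_pct": float(x[ov_m].mean()) - baseline}
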