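"""Neurovascular coupling: pairing ensemble events with dilation.

A significant neural ensemble event is "paired" when the arteriolar
diameter exceeds its pre-event baseline by at least a minimum percent
dilation within a short window after event onset.  The neurovascular
coupling (NVC) index of a paired event is the ratio of the dilation
magnitude to the ensemble magnitude.  Group differences in the
dilation-vs-ensemble slope are tested by ordinary least squares with a
genotype interaction term (PctChange ~ Ensemble * Genotype).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)


@dataclass
class PairedEvent:
    """One ensemble event and its (optional) vascular response."""

    onset_s: float
    ensemble_peak_pct: float
    paired: bool
    dilation_pct: Optional[float] = None
    lag_s: Optional[float] = None

    def __post_init__(self) -> None:
        if self.paired and self.dilation_pct is None:
            raise ValueError("paired event requires a dilation magnitude")
        if not self.paired:
            self.dilation_pct = None
            self.lag_s = None


@dataclass
class CouplingResult:
    paired_fraction: float
    nvc_indices: list[float]
    slopes: dict[str, float]
    interaction_coef: Optional[float] = None
    interaction_p: Optional[float] = None


def pair_events(
    ensemble_events: Sequence[tuple[float, float, float]],
    t: np.ndarray,
    d_um: np.ndarray,
    pairing_window_s: float = 4.0,
    min_dilation_pct: float = 2.0,
    baseline_s: float = 5.0,
) -> tuple[list[PairedEvent], float]:
    """Pair significant ensemble events with subsequent vasodilation.

    Parameters
    ----------
    ensemble_events : sequence of (start_s, end_s, peak_pct)
        Significant ensemble events (e.g. from
        :func:`cortexflow.calcium_ensemble.ensemble_analysis`).
    t, d_um : arrays
        Time-aligned arteriolar diameter trace.
    pairing_window_s : float
        Post-onset window in which dilation must occur.
    min_dilation_pct : float
        Minimum percent increase over the pre-event baseline.
    baseline_s : float
        Length of the pre-event window used as the local baseline.

    Events whose pairing window extends past the recording are excluded
    (and logged).  Returns the event list and the paired fraction over
    all retained events.
    """
    t = np.asarray(t, float)
    d = np.asarray(d_um, float)
    out: list[PairedEvent] = []
    for (start, _end, peak) in ensemble_events:
        if start + pairing_window_s > t[-1]:
            logger.info("event at %.2f s excluded: window past recording end", start)
            continue
        base_m = (t >= start - baseline_s) & (t < start)
        win_m = (t >= start) & (t < start + pairing_window_s)
        if not base_m.any() or not win_m.any():
            logger.info("event at %.2f s excluded: empty window", start)
            continue
        baseline = d[base_m].mean()
        pct = 100.0 * (d[win_m] - baseline) / baseline
        peak_dil = float(pct.max())
        if peak_dil >= min_dilation_pct:
            lag = float(t[win_m][int(np.argmax(pct))] - start)
            out.append(PairedEvent(onset_s=float(start), ensemble_peak_pct=peak,
                                   paired=True, dilation_pct=peak_dil, lag_s=lag))
        else:
            out.append(PairedEvent(onset_s=float(start), ensemble_peak_pct=peak,
                                   paired=False))
    if not out:
        return out, float("nan")
    frac = sum(e.paired for e in out) / len(out)
    return out, frac


def nvc_index(event: PairedEvent) -> float:
    """Neurovascular coupling index: dilation % / ensemble activity %."""
    if not event.paired:
        raise ValueError("NVC index is defined for paired events only")
    if event.ensemble_peak_pct <= 0:
        raise ValueError("ensemble magnitude must be positive")
    return event.dilation_pct / event.ensemble_peak_pct


def slope_comparison(ensemble: Sequence[float], dilation: Sequence[float],
                     group: Sequence[str]) -> dict[str, object]:
    """OLS dilation ~ ensemble with a group interaction.

    Fits ``PctChange ~ Ensemble * Group`` and reports the per-group
    slope, the interaction coefficient (slope difference) and its
    two-sided p value.  Requires at least 3 events per group and
    non-degenerate ensemble spread within each group.
    """
    df = pd.DataFrame({"ensemble": np.asarray(ensemble, float),
                       "dilation": np.asarray(dilation, float),
                       "group": list(group)})
    levels = sorted(df["group"].unique())
    if len(levels) != 2:
        raise ValueError("need exactly two groups")
    for g, sub in df.groupby("group"):
        if len(sub) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 events")
        if sub["ensemble"].var() == 0:
            raise ValueError(f"group {g!r} has degenerate ensemble spread")
    model = smf.ols("dilation ~ ensemble * C(group)", data=df).fit()
    ref, other = levels
    inter_name = f"ensemble:C(group)[T.{other}]"
    slope_ref = float(model.params["ensemble"])
    inter = float(model.params[inter_name])
    slopes = {ref: slope_ref, other: slope_ref + inter}
    ci = model.conf_int()
    # CI of the non-reference slope via the linear contrast b_e + b_int
    cov = model.cov_params()
    se_other = float(np.sqrt(cov.loc["ensemble", "ensemble"]
                             + cov.loc[inter_name, inter_name]
                             + 2 * cov.loc["ensemble", inter_name]))
    from scipy import stats as _st
    tcrit = _st.t.ppf(0.975, model.df_resid)
    return {
        "slopes": slopes,
        "interaction_coef": inter,
        "interaction_p": float(model.pvalues[inter_name]),
        "slope_ci": {ref: tuple(ci.loc["ensemble"]),
                     other: (slopes[other] - tcrit * se_other,
                             slopes[other] + tcrit * se_other)},
        "model": model,
    }
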