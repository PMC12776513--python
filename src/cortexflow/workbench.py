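"""Configuration, file I/O conventions and end-to-end orchestration.

A single :class:`RunConfig` (YAML/JSON-serializable) drives a full
synthetic run: one root seed is split into independent per-stage
streams, every generator output is analyzed by the corresponding
pipeline operation, and the results are written as CSV/JSON bundles
with the exact configuration echoed alongside.  Identical
configurations produce byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger("cortexflow")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def setup_logging(level: str = "INFO", logfile: Optional[str] = None) -> None:
    """Log to stderr and optionally to a file."""
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if logfile:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(level=getattr(logging, level.upper()),
                        handlers=handlers, force=True,
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Parameters of an end-to-end synthetic run.

    Serializable to/from YAML or JSON; echoed verbatim into every
    output bundle.
    """

    seed: int = 0
    out_dir: str = "cortexflow_run"
    log_level: str = "INFO"
    # scene scale (kept modest so a full run stays in minutes)
    kymo_duration_s: float = 10.0
    kymo_speed_mm_s: float = 1.0
    kymo_flux_rbc_s: float = 15.0
    n_capillaries: int = 6
    stall_segments: int = 2
    calcium_cells: int = 30
    calcium_duration_s: float = 300.0
    calcium_loading: float = 0.5
    n_shuffles: int = 1000
    coupling_gain_wt: float = 0.2
    coupling_gain_ps19: float = 0.1
    po2_wt_tissue_mmhg: float = 29.3
    po2_ps19_tissue_mmhg: float = 22.1
    po2_arteriole_mmhg: float = 90.0
    po2_venule_mmhg: float = 40.0
    decay_photons_per_cycle: float = 50.0
    decay_cycles: int = 200
    nadh_dip_pct: float = 1.5
    nadh_overshoot_pct: float = 3.0

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text(encoding="utf-8")
        data = yaml.safe_load(text)
        return cls.from_dict(data)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True),
                              encoding="utf-8")


# ---------------------------------------------------------------------------
# I/O conventions
# ---------------------------------------------------------------------------

def write_image_stack(path: str | Path, frames: np.ndarray,
                      metadata: Optional[Mapping[str, Any]] = None) -> None:
    """Write a multi-page TIFF with a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(frames, dtype=np.float32),
                     photometric="minisblack")
    if metadata is not None:
        path.with_suffix(".json").write_text(
            json.dumps(dict(metadata), indent=1, sort_keys=True),
            encoding="utf-8")


def read_image_stack(path: str | Path) -> tuple[np.ndarray, dict[str, Any]]:
    """Read a multi-page TIFF and its JSON metadata sidecar (if present)."""
    path = Path(path)
    try:
        frames = tifffile.imread(path)
    except Exception as exc:
        raise ValueError(f"cannot read TIFF {path}: {exc}") from exc
    if frames is None or np.asarray(frames).size == 0:
        raise ValueError(f"cannot read TIFF {path}: no image pages found")
    meta_path = path.with_suffix(".json")
    meta: dict[str, Any] = {}
    if meta_path.exists():
        meta = json.loads(meta_path.read_text(encoding="utf-8"))
    return np.asarray(frames), meta


def write_table(df: pd.DataFrame, path: str | Path,
                units: Optional[Mapping[str, str]] = None) -> None:
    """Write a CSV with an optional second header row of units."""
    path = Path(path)
    if units:
        unit_row = pd.DataFrame([{c: units.get(c, "") for c in df.columns}])
        out = pd.concat([unit_row, df], ignore_index=True)
    else:
        out = df
    out.to_csv(path, index=False, encoding="utf-8")


def read_table(path: str | Path, units_row: bool = False
               ) -> tuple[pd.DataFrame, dict[str, str]]:
    df = pd.read_csv(path, encoding="utf-8")
    units: dict[str, str] = {}
    if units_row:
        units = {c: ("" if pd.isna(v) else str(v))
                 for c, v in df.iloc[0].items()}
        df = df.iloc[1:].reset_index(drop=True)
        for col in df.columns:
            try:
                df[col] = pd.to_numeric(df[col])
            except (TypeError, ValueError):
                pass
    return df, units


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig, write_outputs: bool = True
                 ) -> dict[str, Any]:
    """Simulate every scene, analyze it, and assemble the report bundle.

    Stages: vessel-segment responses (both genotypes), RBC velocimetry /
    flux / stalling, calcium ensemble statistics, neurovascular
    coupling, intravascular and tissue oximetry, and NADH dynamics.
    Raises :class:`StageError` naming the failing stage.  Returns the
    report dict; with ``write_outputs`` the bundle is also written under
    ``config.out_dir`` (tables as CSV, report and config as JSON).
    """
    from . import (calcium_ensemble, coupling, nadh_metabolism, oximetry,
                   rbc_flow, synthetic_data, vessel_dynamics)

    report: dict[str, Any] = {"config": config.to_dict(), "seed": config.seed}
    root = np.random.SeedSequence(config.seed)
    # one spawned stream per stage keeps stages independent of each other
    stage_seed = {name: int(s.generate_state(1)[0] % (2**31))
                  for name, s in zip(
                      ["vessel", "flow", "calcium", "coupling", "oxy", "nadh"],
                      root.spawn(6))}

    # -- vessel segment scenes ------------------------------------------------
    try:
        seg_tables = {}
        for genotype in ("WT", "PS19-like"):
            cfg = synthetic_data.SimConfig(seed=stage_seed["vessel"],
                                           frame_rate_hz=3.8)
            traces, gt = synthetic_data.gen_segment_scene(cfg, genotype)
            mets = {seg: vessel_dynamics.response_metrics(tr)
                    for seg, tr in traces.items()}
            order, tied = vessel_dynamics.segment_onset_order(mets)
            seg_tables[genotype] = {
                "metrics": {seg: dataclasses.asdict(m) for seg, m in mets.items()},
                "onset_order": order,
                "tied": tied,
            }
        report["vessel_segments"] = seg_tables
    except Exception as exc:
        raise StageError("vessel_segments", exc) from exc

    # -- RBC flow -------------------------------------------------------------
    try:
        cfg = synthetic_data.SimConfig(seed=stage_seed["flow"],
                                       duration_s=config.kymo_duration_s,
                                       line_rate_hz=1000.0, pixel_size_um=1.0)
        kym, gt = synthetic_data.gen_kymograph(
            cfg, config.kymo_speed_mm_s, config.kymo_flux_rbc_s)
        t, v = rbc_flow.radon_velocity(kym, window_s=0.04)
        flux = rbc_flow.count_flux(kym)
        cap_fluxes = []
        for i in range(config.n_capillaries):
            ci = synthetic_data.SimConfig(seed=stage_seed["flow"] + 1 + i,
                                          duration_s=config.kymo_duration_s,
                                          line_rate_hz=1000.0, pixel_size_um=1.0)
            ki, _ = synthetic_data.gen_kymograph(
                ci, config.kymo_speed_mm_s, config.kymo_flux_rbc_s)
            cap_fluxes.append(rbc_flow.count_flux(ki).flux_rbc_s)
        het = rbc_flow.flux_heterogeneity(cap_fluxes)
        stall_traces = {}
        for i in range(config.n_capillaries):
            si = synthetic_data.SimConfig(seed=stage_seed["flow"] + 100 + i,
                                          duration_s=config.kymo_duration_s,
                                          line_rate_hz=1000.0, pixel_size_um=1.0)
            stalls = [(3.0, 5.0)] if i < config.stall_segments else []
            ks, _ = synthetic_data.gen_kymograph(
                si, config.kymo_speed_mm_s, config.kymo_flux_rbc_s, stalls=stalls)
            stall_traces[f"cap{i}"] = rbc_flow.radon_velocity(ks, window_s=0.25)
        stall_table = rbc_flow.detect_stalls(stall_traces)
        report["rbc_flow"] = {
            "median_speed_mm_s": float(np.nanmedian(v)),
            "true_speed_mm_s": config.kymo_speed_mm_s,
            "flux_rbc_s": flux.flux_rbc_s,
            "true_flux_rbc_s": config.kymo_flux_rbc_s,
            "flux_cv": flux.cv,
            "heterogeneity": het,
            "stall_fraction": stall_table.stall_fraction,
        }
    except Exception as exc:
        raise StageError("rbc_flow", exc) from exc

    # -- calcium ensemble -----------------------------------------------------
    try:
        cfg = synthetic_data.SimConfig(
            seed=stage_seed["calcium"], duration_s=config.calcium_duration_s,
            frame_rate_hz=3.8,
            noise=synthetic_data.NoiseModel(gaussian_sd=0.05))
        rec, gt = synthetic_data.gen_calcium_population(
            cfg, n_cells=config.calcium_cells, loading=config.calcium_loading)
        train = calcium_ensemble.detect_events(rec.dff, rec.frame_rate_hz)
        rng = np.random.default_rng(stage_seed["calcium"])
        ens = calcium_ensemble.ensemble_analysis(
            train, n_shuffle=config.n_shuffles, rng=rng)
        _, r_cdf, _ = calcium_ensemble.connectivity_matrix(rec.dff)
        beh = calcium_ensemble.behavior_summary(ens.pct_active, rec.behavior)
        report["calcium"] = {
            "threshold_pct": ens.threshold_pct,
            "n_significant_events": len(ens.significant_events),
            "median_pairwise_r": float(np.median(r_cdf)),
            "behavior": beh,
            "mean_spike_count": float(train.spike_counts.mean()),
        }
    except Exception as exc:
        raise StageError("calcium", exc) from exc

    # -- coupling -------------------------------------------------------------
    try:
        rows = {"ensemble": [], "dilation": [], "group": []}
        coup = {}
        for genotype, gain in (("WT", config.coupling_gain_wt),
                               ("PS19", config.coupling_gain_ps19)):
            cfg = synthetic_data.SimConfig(seed=stage_seed["coupling"],
                                           duration_s=300.0, frame_rate_hz=3.8)
            scene, gt = synthetic_data.gen_coupled_scene(
                cfg, n_events=20, coupling_gain=gain,
                pairing_prob=0.9 if genotype == "WT" else 0.6)
            evs, frac = coupling.pair_events(scene["events"], scene["t"],
                                             scene["d_um"])
            idx = [coupling.nvc_index(e) for e in evs if e.paired]
            coup[genotype] = {"paired_fraction": frac,
                              "median_nvc_index": float(np.median(idx))}
            for e in evs:
                if e.paired:
                    rows["ensemble"].append(e.ensemble_peak_pct)
                    rows["dilation"].append(e.dilation_pct)
                    rows["group"].append(genotype)
        slopes = coupling.slope_comparison(rows["ensemble"], rows["dilation"],
                                           rows["group"])
        coup["slopes"] = slopes["slopes"]
        coup["interaction_p"] = slopes["interaction_p"]
        report["coupling"] = coup
    except Exception as exc:
        raise StageError("coupling", exc) from exc

    # -- oximetry -------------------------------------------------------------
    try:
        calib = oximetry.OxyCalibration()
        oxy = {}
        for genotype, tissue_mean in (("WT", config.po2_wt_tissue_mmhg),
                                      ("PS19", config.po2_ps19_tissue_mmhg)):
            cfg = synthetic_data.SimConfig(seed=stage_seed["oxy"])
            tmap, _ = synthetic_data.gen_tissue_map(
                cfg, arterioles=[(8, 8)], venules=[(24, 24)],
                group_mean_mmhg=tissue_mean, group_sd_mmhg=0.0)
            oximetry.classify_map(tmap)
            away = tmap.distance_class != oximetry.NEAR_ARTERIOLE
            po2_a = config.po2_arteriole_mmhg * (
                1.0 if genotype == "WT" else 1.0 - 0.123)
            po2_v = config.po2_venule_mmhg * (
                1.0 if genotype == "WT" else 1.0 - 0.05)
            ds, gt = synthetic_data.gen_decays(
                cfg, [po2_a, po2_v], calib,
                photons_per_cycle=config.decay_photons_per_cycle,
                n_cycles=config.decay_cycles)
            po2_fit = oximetry.fit_decay_set(ds, calib)
            so2 = oximetry.hill_so2(po2_fit)
            oxy[genotype] = {
                "tissue_mean_mmhg": float(tmap.po2.mean()),
                "hypoxic_fraction_away": oximetry.hypoxic_fraction(
                    tmap.po2[away]),
                "po2_arteriole_mmhg": float(po2_fit[0]),
                "po2_venule_mmhg": float(po2_fit[1]),
                "oef": oximetry.oef(float(so2[0]), float(so2[1])),
            }
        oxy["schedule"] = oximetry.schedule_accounting(
            oximetry.AcquisitionSchedule())
        oxy["pct_reduction_tissue"] = 100.0 * (
            oxy["WT"]["tissue_mean_mmhg"] - oxy["PS19"]["tissue_mean_mmhg"]
        ) / oxy["WT"]["tissue_mean_mmhg"]
        report["oximetry"] = oxy
    except Exception as exc:
        raise StageError("oximetry", exc) from exc

    # -- NADH -----------------------------------------------------------------
    try:
        cfg = synthetic_data.SimConfig(
            seed=stage_seed["nadh"],
            noise=synthetic_data.NoiseModel(gaussian_sd=0.05))
        pair, gt = synthetic_data.gen_nadh_traces(
            cfg, dip_pct=config.nadh_dip_pct,
            overshoot_pct=config.nadh_overshoot_pct)
        corrected, beta = nadh_metabolism.correct_nadh(pair)
        mets = nadh_metabolism.dip_overshoot(corrected, pair.frame_rate_hz,
                                             pair.protocol)
        report["nadh"] = {"beta": beta, **mets}
    except Exception as exc:
        raise StageError("nadh", exc) from exc

    report = _jsonable(report)
    if write_outputs:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(report, indent=1, sort_keys=True), encoding="utf-8")
        config.save(out / "config.yaml")
        rows = []
        for genotype, tab in report["vessel_segments"].items():
            for seg, m in tab["metrics"].items():
                rows.append({"genotype": genotype, "segment": seg, **m})
        write_table(pd.DataFrame(rows), out / "segment_metrics.csv",
                    units={"baseline_um": "um", "peak_pct": "%",
                           "latency_s": "s"})
        logger.info("bundle written to %s", out)
    return report
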