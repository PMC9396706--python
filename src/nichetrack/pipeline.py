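"""Pipeline orchestration: simulate (optional) -> error-filter -> NSD fits ->
timing -> speeds -> climatic-niche overlap, with a JSON manifest.

Everything is driven by :class:`PipelineConfig` and a single seed; with a
fixed seed all numeric outputs are byte-identical between runs (manifest
timings are wall-clock and excluded from that guarantee).
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .crw import CRWFilter
from .io import write_raster, write_report, write_tracking
from .movement import hourly_speeds, summarize_speeds
from .niche import NicheOverlap, extract_climate
from .nsd import (DoubleSigmoidNSD, compute_nsd, day_of_year,
                  derive_migration_metrics, project_to_plane, segment_timing,
                  thin_daily)
from .synthdata import (ARGOS_CLASS_SD_KM, ClimateConfig, SimConfig,
                        corrupt_with_argos_error, simulate_climate_fields,
                        simulate_migratory_path)

log = logging.getLogger("nichetrack")

ALL_STAGES = ("simulate", "filter", "nsd", "timing", "speeds", "niche")


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run."""

    seed: int = 0
    n_animals: int = 4
    sim: SimConfig = field(default_factory=SimConfig)
    climate: ClimateConfig = field(default_factory=ClimateConfig)
    timing_frac: float = 0.025
    speed_window_h: tuple[float, float] = (0.5, 1.0)
    niche_R: int = 100
    niche_correction: bool = True
    #: (winter_start_month, winter_end_month), (summer months) for labelling
    winter_months: tuple[int, ...] = (11, 12, 1, 2)
    summer_months: tuple[int, ...] = (6, 7, 8)
    stages: tuple[str, ...] = ALL_STAGES
    estimate_meas_sd: bool = False

    def __post_init__(self):
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        if not 0.0 < self.timing_frac < 0.5:
            raise ValueError("timing_frac must be in (0, 0.5)")


def _simulate_tracks(cfg: PipelineConfig) -> list[pd.DataFrame]:
    tracks = []
    for i in range(cfg.n_animals):
        sub = np.random.SeedSequence([cfg.seed, i]).generate_state(1)[0] % (2**31)
        sim = replace(cfg.sim, seed=int(sub), animal_id=f"bird{i + 1:02d}")
        truth = simulate_migratory_path(sim)
        tracks.append(corrupt_with_argos_error(truth, sim))
    return tracks


def _season_of(timestamps: pd.Series, cfg: PipelineConfig) -> np.ndarray:
    months = pd.to_datetime(timestamps).dt.month.to_numpy()
    out = np.full(months.shape, "other", dtype=object)
    out[np.isin(months, cfg.winter_months)] = "winter"
    out[np.isin(months, cfg.summer_months)] = "summer"
    return out


def run_pipeline(config: PipelineConfig, outdir,
                 tracks: list[pd.DataFrame] | None = None) -> dict:
    """Run the configured stages, write reports under ``outdir``, and return
    the result bundle (also summarised in ``manifest.json``).

    A stage failure is recorded in the manifest (partial outputs retained)
    and re-raised.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "version": __version__,
                      "numpy": np.__version__, "stages": {}}
    bundle: dict = {}
    try:
        _run_stages(config, outdir, tracks, manifest, bundle)
    finally:
        manifest["complete"] = all(
            v["status"] in ("complete", "skipped")
            for v in manifest["stages"].values()) and len(manifest["stages"]) > 0
        write_report(manifest, outdir / "manifest.json", sig=6)
        bundle["manifest"] = manifest
    return bundle


def _run_stages(config, outdir, tracks, manifest, bundle):
    def stage(name):
        return _StageGuard(name, manifest, config.stages)

    with stage("simulate") as run:
        if run:
            tracks = _simulate_tracks(config)
            write_tracking(tracks, outdir / "tracks.csv")
    if tracks is None:
        raise ValueError("no tracks: enable the simulate stage or pass tracks=")

    smoothed: dict[str, pd.DataFrame] = {}
    with stage("filter") as run:
        if run:
            for traj in tracks:
                aid = str(traj["animal_id"].iloc[0])
                planar = project_to_plane(traj)
                planar["t_h"] = (day_of_year(traj["timestamp"]) - 1.0) * 24.0
                filt = CRWFilter(meas_sd=dict(ARGOS_CLASS_SD_KM),
                                 estimate_meas_sd=config.estimate_meas_sd
                                 ).fit(planar)
                pred = filt.predict()
                sm = traj.copy()
                from .geo import aeqd_inverse
                lon0 = float(traj["lon"].iloc[0])
                lat0 = float(traj["lat"].iloc[0])
                lon, lat = aeqd_inverse(pred["pred_x_km"].to_numpy(),
                                        pred["pred_y_km"].to_numpy(), lon0, lat0)
                sm["lon"], sm["lat"] = lon, lat
                for c in ("pred_x_km", "pred_y_km", "pred_var_km2"):
                    sm[c] = pred[c].to_numpy()
                smoothed[aid] = sm
                log.info("filter: %s beta=%.3g sigma=%.3g ll=%.6g", aid,
                         filt.params_.beta_vel, filt.params_.sigma_vel,
                         filt.log_likelihood_)
            write_tracking(list(smoothed.values()), outdir / "tracks_filtered.csv")
        else:
            smoothed = {str(t["animal_id"].iloc[0]): t for t in tracks}

    fits: dict[str, DoubleSigmoidNSD] = {}
    fit_report: dict = {}
    with stage("nsd") as run:
        if run:
            for aid, traj in smoothed.items():
                series = compute_nsd(traj)
                fit = DoubleSigmoidNSD().score_series(series)
                fits[aid] = fit
                rep = {"converged": fit.converged_, "n": int(fit.n_obs_)}
                if fit.converged_:
                    rep.update(delta=fit.delta_, theta_s=fit.theta_s_,
                               theta_a=fit.theta_a_, phi_s=fit.phi_s_,
                               phi_a=fit.phi_a_, se=fit.se_,
                               resid_sd=fit.resid_sd_,
                               **derive_migration_metrics(fit))
                fit_report[aid] = rep
            write_report({"model": "double_sigmoid", "fits": fit_report},
                         outdir / "nsd_fits.json")
            bundle["fits"] = fit_report

    with stage("timing") as run:
        if run:
            rows = []
            for aid, fit in fits.items():
                if not fit.converged_:
                    continue
                tm = segment_timing(fit, frac=config.timing_frac)
                rows.append({"animal_id": aid,
                             "spring_departure": tm.spring_departure,
                             "spring_arrival": tm.spring_arrival,
                             "autumn_departure": tm.autumn_departure,
                             "autumn_arrival": tm.autumn_arrival,
                             "spring_duration": tm.spring_duration,
                             "autumn_duration": tm.autumn_duration})
            timing_df = pd.DataFrame(rows)
            timing_df.round(4).to_csv(outdir / "timing.csv", index=False)
            bundle["timing"] = timing_df

    with stage("speeds") as run:
        if run:
            samples = []
            for aid, traj in smoothed.items():
                sp = hourly_speeds(traj, interval_window=config.speed_window_h)
                sp["season"] = _season_of(sp["timestamp"], config)
                samples.append(sp[sp["season"].isin(["winter", "summer"])])
            samples = pd.concat(samples, ignore_index=True)
            summary = summarize_speeds(samples)
            summary.round(6).to_csv(outdir / "speeds.csv", index=False)
            bundle["speeds"] = summary

    with stage("niche") as run:
        if run:
            winter_r, summer_r = simulate_climate_fields(config.climate,
                                                         seed=config.seed)
            write_raster(winter_r, outdir / "climate", "winter")
            write_raster(summer_r, outdir / "climate", "summer")
            occ_w, occ_s = [], []
            for i, (aid, traj) in enumerate(sorted(smoothed.items())):
                thin = thin_daily(traj, seed=int(
                    np.random.SeedSequence([config.seed, 7, i])
                    .generate_state(1)[0] % (2**31)))
                season = _season_of(thin["timestamp"], config)
                occ_w.append(thin[season == "winter"])
                occ_s.append(thin[season == "summer"])
            occ_w = pd.concat(occ_w, ignore_index=True)
            occ_s = pd.concat(occ_s, ignore_index=True)
            bg_w = extract_raster_table(winter_r)
            bg_s = extract_raster_table(summer_r)
            env_w = extract_climate(occ_w, winter_r, season="winter")
            env_s = extract_climate(occ_s, summer_r, season="summer")
            overlap = NicheOverlap(R=config.niche_R,
                                   correction=config.niche_correction)
            overlap.fit(env_w, env_s, bg_w, bg_s)
            from .niche import variable_overlap_1d
            wind = variable_overlap_1d(bg_w["wind"], bg_s["wind"])
            rep = overlap.report()
            rep["wind_overlap_1d"] = wind
            rep["n_occurrences"] = {"winter": int(len(occ_w)),
                                    "summer": int(len(occ_s))}
            write_report(rep, outdir / "overlap.json")
            bundle["overlap"] = rep


def extract_raster_table(raster) -> pd.DataFrame:
    """All raster cells as the season's background environment table."""
    return raster.table()


class _StageGuard:
    """Context manager recording stage status and timing in the manifest."""

    def __init__(self, name, manifest, enabled_stages):
        self.name = name
        self.manifest = manifest
        self.enabled = name in enabled_stages

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self.enabled

    def __exit__(self, exc_type, exc, tb):
        status = "complete" if self.enabled else "skipped"
        if exc_type is not None:
            status = "failed"
        self.manifest["stages"][self.name] = {
            "status": status,
            "seconds": round(time.perf_counter() - self.t0, 3),
        }
        if exc_type is not None:
            self.manifest["stages"][self.name]["error"] = str(exc)
            log.error("stage %s failed: %s", self.name, exc)
        else:
            log.info("stage %s: %s", self.name, status)
        return False


def config_from_dict(d: dict) -> PipelineConfig:
    """Build a PipelineConfig from a plain dict (e.g. parsed JSON),
    rejecting unknown keys."""
    d = dict(d)
    kwargs = {}
    if "sim" in d:
        sim = d.pop("sim")
        known = {f.name for f in dataclasses.fields(SimConfig)}
        bad = set(sim) - known
        if bad:
            raise ValueError(f"unknown sim key(s): {sorted(bad)}")
        for k in ("winter_centre", "summer_centre", "spring_window",
                  "autumn_window"):
            if k in sim and sim[k] is not None:
                sim[k] = tuple(sim[k])
        kwargs["sim"] = SimConfig(**sim)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    bad = set(d) - known
    if bad:
        raise ValueError(f"unknown config key(s): {sorted(bad)}")
    for k in ("speed_window_h", "stages", "winter_months", "summer_months"):
        if k in d:
            d[k] = tuple(d[k])
    kwargs.update(d)
    return PipelineConfig(**kwargs)
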