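"""End-to-end orchestration: generate -> design -> adjust -> krige -> assign -> associate.

One YAML config drives a full synthetic study: the district and pollutant
fields are generated, monitoring sites are designed from the residences,
campaign measurements are simulated and temporally adjusted, a variogram is
selected and the annual surface kriged, exposures are assigned and
standardised at the residences, outcomes are simulated from the standardised
exposures, and the association batteries are fitted.  Every stage writes a
plain-text artefact into the run directory and the manifest records config
hash, seed, file digests and wall times, so a rerun with the same config and
seed reproduces identical digests.

The single global seed is expanded into fixed per-stage substreams (keyed by
stage name), so adding a stage does not shift the randomness of the others.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import sensitivity_analyses, association_battery
from .clustering import stratified_site_split
from .exposure import assign_exposure
from .kriging import OrdinaryKriging, select_model
from .synthetic import (
    DistrictSpec,
    OutcomeSpec,
    PollutantFieldSpec,
    generate_cohort,
    generate_pollution_field,
    simulate_campaign_measurements,
    simulate_outcomes,
    write_truth_json,
)
from .temporal import annual_site_means, campaign_corrections

__all__ = ["PipelineConfig", "RunManifest", "load_config", "run_pipeline", "participation_percent"]

# fixed substream keys: inserting a stage must not shift the others
_STAGE_KEYS = {
    "cohort": 0, "sites": 1, "field_formaldehyde": 2, "field_no2": 3,
    "campaigns_formaldehyde": 4, "campaigns_no2": 5, "outcomes": 6,
}


def participation_percent(n_participants: int, n_invited: int) -> int:
    """Participation rate as the rounded whole percentage (e.g. 413 of 656 -> 63)."""
    if n_invited <= 0 or n_participants < 0 or n_participants > n_invited:
        raise ValueError("need 0 <= n_participants <= n_invited with n_invited > 0")
    return round(100.0 * n_participants / n_invited)


@dataclass
class PipelineConfig:
    seed: int
    n_per_stratum: int = 250
    grid_resolution_km: float = 0.5
    n_sites: int = 62
    inner_fraction: float = 0.5
    inner_radius_km: float = 3.0
    missing_rate: float = 0.15
    pollutants: tuple = ("formaldehyde", "no2")
    families: tuple = ("exponential", "gaussian", "spherical")
    angles: tuple = (0.0, 45.0, 90.0, 135.0)
    ratios: tuple = (1.0, 0.7, 0.5)
    district: DistrictSpec = field(default_factory=DistrictSpec)
    outcome_spec: OutcomeSpec = field(default_factory=OutcomeSpec)
    anisotropy_ratio: float = 0.5     # generator truth for both pollutant fields


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    package_version: str
    stages: dict = field(default_factory=dict)   # stage -> {files: {name: sha256}, seconds: float}
    error: dict | None = None

    def to_json(self) -> str:
        return json.dumps(
            {"config_hash": self.config_hash, "seed": self.seed,
             "package_version": self.package_version, "stages": self.stages,
             "error": self.error},
            indent=2, sort_keys=True,
        )


def load_config(path) -> PipelineConfig:
    """Read and validate a YAML pipeline config (seed is mandatory)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    if "seed" not in raw:
        raise ValueError("config validation failed: 'seed' is required")
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"config validation failed: unknown keys {sorted(unknown)}")
    kwargs = dict(raw)
    kwargs["seed"] = int(kwargs["seed"])
    if "district" in kwargs:
        d = kwargs["district"]
        kwargs["district"] = DistrictSpec(**{k: tuple(map(tuple, v)) if k in
                                             ("chipboard_industries", "small_factories")
                                             else (tuple(v) if isinstance(v, list) else v)
                                             for k, v in d.items()})
    if "outcome_spec" in kwargs:
        kwargs["outcome_spec"] = OutcomeSpec(**kwargs["outcome_spec"])
    for key in ("pollutants", "families", "angles", "ratios"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    cfg = PipelineConfig(**kwargs)
    for check, msg in [
        (cfg.n_per_stratum >= 1, "n_per_stratum must be >= 1"),
        (0 <= cfg.missing_rate < 1, "missing_rate must be in [0, 1)"),
        (cfg.n_sites >= 2, "n_sites must be >= 2"),
        (cfg.grid_resolution_km > 0, "grid_resolution_km must be > 0"),
    ]:
        if not check:
            raise ValueError(f"config validation failed: {msg}")
    return cfg


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _rng_for(cfg: PipelineConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, _STAGE_KEYS[stage]]))


def _field_spec(cfg: PipelineConfig, pollutant: str) -> PollutantFieldSpec:
    maker = {"formaldehyde": PollutantFieldSpec.formaldehyde, "no2": PollutantFieldSpec.no2}
    return maker[pollutant](anisotropy_ratio=cfg.anisotropy_ratio)


def run_pipeline(config, outdir, write_report: bool = True) -> RunManifest:
    """Run all stages; returns the manifest (also written to ``manifest.json``)."""
    cfg = config if isinstance(config, PipelineConfig) else load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = hashlib.sha256(repr(cfg).encode()).hexdigest()[:16]
    manifest = RunManifest(config_hash=cfg_hash, seed=cfg.seed, package_version=__version__)

    def record(stage: str, t0: float, files: dict) -> None:
        manifest.stages[stage] = {
            "seconds": round(time.time() - t0, 3),
            "files": {name: _digest(Path(p)) for name, p in files.items()},
        }

    try:
        # -- cohort residences + covariates ---------------------------------
        t0 = time.time()
        cohort = generate_cohort(cfg.district, cfg.n_per_stratum, seed=_rng_for(cfg, "cohort"))
        cohort_path = outdir / "cohort.csv"
        cohort.to_csv(cohort_path, index=False)
        record("cohort", t0, {"cohort.csv": cohort_path})

        # -- monitoring-site design -----------------------------------------
        t0 = time.time()
        plan = stratified_site_split(
            cohort[["x_km", "y_km"]].to_numpy(), cfg.district.chipboard_industries,
            k=cfg.n_sites, inner_fraction=cfg.inner_fraction, radius_km=cfg.inner_radius_km,
        )
        sites = pd.DataFrame({
            "site_id": np.arange(plan.k),
            "x_km": plan.medoids[:, 0], "y_km": plan.medoids[:, 1],
            "cluster_size": plan.cluster_sizes,
        })
        sites_path = outdir / "sites.csv"
        sites.to_csv(sites_path, index=False)
        record("sites", t0, {"sites.csv": sites_path})

        # -- fields, campaigns, adjustment, kriging per pollutant ------------
        exposed = cohort
        model_info = {}
        for pollutant in cfg.pollutants:
            spec = _field_spec(cfg, pollutant)
            t0 = time.time()
            surf = generate_pollution_field(
                spec, cfg.district, cfg.grid_resolution_km,
                seed=_rng_for(cfg, f"field_{pollutant}"),
            )
            truth_path = outdir / f"true_surface_{pollutant}.csv"
            surf.to_dataframe().to_csv(truth_path, index=False)
            record(f"field_{pollutant}", t0, {truth_path.name: truth_path})

            t0 = time.time()
            meas = simulate_campaign_measurements(
                surf, plan.medoids, spec, missing_rate=cfg.missing_rate,
                seed=_rng_for(cfg, f"campaigns_{pollutant}"),
            )
            meas_path = outdir / f"monitoring_{pollutant}.csv"
            meas.to_csv(meas_path, index=False)

            corrections = campaign_corrections(meas)
            adjusted = annual_site_means(meas, corrections)
            annual = adjusted.annual.merge(sites[["site_id", "x_km", "y_km"]], on="site_id")
            annual_path = outdir / f"annual_{pollutant}.csv"
            annual.to_csv(annual_path, index=False)
            record(f"campaigns_{pollutant}", t0,
                   {meas_path.name: meas_path, annual_path.name: annual_path})

            t0 = time.time()
            coords = annual[["x_km", "y_km"]].to_numpy()
            values = annual["annual_ugm3"].to_numpy()
            best, board = select_model(coords, values, families=cfg.families,
                                       angles=cfg.angles, ratios=cfg.ratios)
            board_path = outdir / f"variogram_leaderboard_{pollutant}.csv"
            board.to_csv(board_path, index=False)
            ok = OrdinaryKriging(best).fit(coords, values)
            surf_pred = ok.predict(surf.to_dataframe()[["x_km", "y_km"]].to_numpy(),
                                   return_std=True)
            grid_df = surf.to_dataframe().rename(columns={"value": "true_ugm3"})
            grid_df["pred_ugm3"] = surf_pred[0]
            grid_df["kriging_sd"] = surf_pred[1]
            surface_path = outdir / f"surface_{pollutant}.csv"
            grid_df.to_csv(surface_path, index=False)
            model_info[pollutant] = {
                "model": {"family": best.family, "nugget": best.nugget, "sill": best.sill,
                          "range_km": best.range_, "angle": best.angle, "ratio": best.ratio},
                "loocv_rmse": float(board.loc[0, "loocv_rmse"]),
            }
            record(f"krige_{pollutant}", t0,
                   {board_path.name: board_path, surface_path.name: surface_path})

            exposed, assignment = assign_exposure(ok, exposed, pollutant)
            model_info[pollutant]["exposure_mean"] = assignment.mean
            model_info[pollutant]["exposure_sd"] = assignment.sd

        model_path = outdir / "models.json"
        model_path.write_text(json.dumps(model_info, indent=2, sort_keys=True))

        # -- outcomes ---------------------------------------------------------
        t0 = time.time()
        analysis = simulate_outcomes(exposed, cfg.outcome_spec, seed=_rng_for(cfg, "outcomes"))
        analysis_path = outdir / "analysis_cohort.csv"
        analysis.to_csv(analysis_path, index=False)
        truth_json = outdir / "truth.json"
        write_truth_json(truth_json, cfg.district,
                         [_field_spec(cfg, p) for p in cfg.pollutants],
                         cfg.outcome_spec, seed=cfg.seed)
        record("outcomes", t0, {"analysis_cohort.csv": analysis_path,
                                "truth.json": truth_json, "models.json": model_path})

        # -- associations -----------------------------------------------------
        t0 = time.time()
        battery = association_battery(analysis, pollutants=cfg.pollutants)
        battery_path = outdir / "associations.csv"
        battery.to_csv(battery_path, index=False)
        sens = sensitivity_analyses(analysis, cfg.district)
        files = {"associations.csv": battery_path}
        for name in ("indoor_adjusted", "near_industry"):
            if name in sens:
                p = outdir / f"sensitivity_{name}.csv"
                sens[name].to_csv(p, index=False)
                files[p.name] = p
        record("associate", t0, files)

        if write_report:
            t0 = time.time()
            report_path = outdir / "report.md"
            report_path.write_text(render_report(outdir))
            record("report", t0, {"report.md": report_path})
    except Exception as exc:
        manifest.error = {"stage": _next_stage_name(manifest), "message": str(exc)}
        (outdir / "manifest.json").write_text(manifest.to_json())
        raise
    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest


def _next_stage_name(manifest: RunManifest) -> str:
    done = list(manifest.stages)
    return f"after:{done[-1]}" if done else "cohort"


def _fmt_est(row) -> str:
    return f"{row.estimate:.3f} ({row.ci_low:.3f}, {row.ci_high:.3f}){row.stars}"


def render_report(rundir) -> str:
    """Markdown run report: cohort/outcome summaries, variogram winners, battery."""
    rundir = Path(rundir)
    cohort = pd.read_csv(rundir / "analysis_cohort.csv")
    battery = pd.read_csv(rundir / "associations.csv").fillna({"stars": ""})
    models = json.loads((rundir / "models.json").read_text())

    lines = ["# Synthetic district run report", ""]
    lines += ["## Cohort", "", f"- children: {len(cohort)}",
              f"- strata: {cohort['stratum'].value_counts().to_dict()}", ""]
    lines += ["## Outcome distributions", "", "| outcome | mean | SD |", "|---|---|---|"]
    for col, label in [("ti", "Tail intensity (%)"), ("tl", "Tail length (um)"),
                       ("tm", "Tail moment"), ("bn_pct", "Binucleated cells (%)"),
                       ("mn_pct", "Micronuclei (%)"), ("bud_pct", "Nuclear buds (%)")]:
        lines.append(f"| {label} | {cohort[col].mean():.2f} | {cohort[col].std():.2f} |")
    lines += ["", "## Exposure models", ""]
    for poll, info in models.items():
        m = info["model"]
        lines.append(
            f"- {poll}: {m['family']} (nugget {m['nugget']:.3g}, sill {m['sill']:.3g}, "
            f"range {m['range_km']:.2f} km, angle {m['angle']:.0f}, ratio {m['ratio']:.2f}); "
            f"LOOCV-RMSE {info['loocv_rmse']:.3f}; cohort 1-SD = {info['exposure_sd']:.3g} ug/m3"
        )
    lines += ["", "## Associations per 1-SD exposure", "",
              "| outcome | pollutant | crude | adjusted | n (adj) |", "|---|---|---|---|---|"]
    for (outcome, poll), grp in battery.groupby(["label", "pollutant"], sort=False):
        crude = grp[grp.specification == "crude"].iloc[0]
        adj = grp[grp.specification == "adjusted"].iloc[0]
        lines.append(f"| {outcome} | {poll} | {_fmt_est(crude)} | {_fmt_est(adj)} | {adj.n} |")
    lines.append("")
    return "\n".join(lines)
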