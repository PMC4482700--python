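"""End-to-end orchestration: fixtures -> niche models -> divergence -> dispersal.

The pipeline is driven by a :class:`RunConfig` (loadable from YAML) and
a single global seed; each stage derives its own reproducible seed by
hashing the stage name into the global one, so stages can be rerun
independently with identical results.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enm as enm_mod
from . import gridio, lps, synthdata
from .divergence import niche_divergence
from .enm import ENMConfig
from .lps import LPSConfig

logger = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class DivergenceConfig:
    n_perm: int = 9999
    n_axes: int = 2


@dataclass
class RunConfig:
    output_dir: str = "runs/out"
    seed: int = 0
    occurrences: str | None = None
    predictors: list[str] = field(default_factory=list)
    velocity: str | None = None
    coastline: str | None = None
    stages: list[str] = field(default_factory=lambda: ["enm", "divergence", "lps"])
    enm: ENMConfig = field(default_factory=ENMConfig)
    lps: LPSConfig = field(default_factory=LPSConfig)
    divergence: DivergenceConfig = field(default_factory=DivergenceConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "enm" in kwargs:
            kwargs["enm"] = ENMConfig(**{k: tuple(v) if isinstance(v, list) else v
                                         for k, v in kwargs["enm"].items()})
        if "lps" in kwargs:
            kwargs["lps"] = LPSConfig(**{k: tuple(v) if isinstance(v, list) else v
                                         for k, v in kwargs["lps"].items()})
        if "divergence" in kwargs:
            kwargs["divergence"] = DivergenceConfig(**kwargs["divergence"])
        return cls(**kwargs)

    def validate(self) -> None:
        if "enm" in self.stages or "divergence" in self.stages:
            if not self.occurrences or not self.predictors:
                raise ValueError("enm/divergence stages need occurrence and predictor paths")
            for p in [self.occurrences, *self.predictors]:
                if not Path(p).exists():
                    raise FileNotFoundError(p)
        if "lps" in self.stages:
            if not self.velocity or not self.coastline:
                raise ValueError("lps stage needs velocity and coastline paths")
            for p in (self.velocity, self.coastline):
                if not Path(p).exists():
                    raise FileNotFoundError(p)


# ---------------------------------------------------------------------------
# fixture generation
# ---------------------------------------------------------------------------

#: default synthetic study conditions: a temperate envelope species on a
#: monotone thermal gradient, and a Benguela-like coastal jet domain.
FIXTURE_DEFAULTS = dict(
    # environmental domain for niche modelling (coarser cells, wide lat range)
    env_grid=dict(lon_min=14.0, lat_min=-46.0, cell_size=0.2, n_lon=40, n_lat=120),
    temp_slope=0.667,        # degC per degree latitude (warming equatorward)
    temp_intercept=40.7,     # gives ~10..26 degC over the latitude span
    temp_noise_sd=0.0,       # climatological layer: treated as exactly known
    distractor_noise_sd=1.0,
    t_min=15.0,
    t_max=22.0,
    edge_width=0.1,          # degC; near-hard envelope edges
    n_presence=500,
    n_survey_absence=200,
    invaded_band=(-36.5, -30.5),   # central part of the envelope (~16-20 degC)
    # dispersal domain (fine cells, coast-parallel jet with a front)
    lps_grid=dict(lon_min=10.0, lat_min=-30.0, cell_size=0.08, n_lon=14, n_lat=70),
    n_coastal_cells=60,
    jet_speed=0.15,          # m/s, northward Benguela-like flow
    front_cell=45,           # coastal cell just south of the offshore front
    offshore_deflection=0.15,
    velocity_noise_sd=0.01,
)


def make_fixtures(out_dir, seed: int = 0, years=(2008,), months=(5,),
                  counter_current_speed: float = 0.0, overrides: dict | None = None) -> dict:
    """Materialise the standard synthetic fixture set under ``out_dir``.

    Writes occurrence CSV, predictor NetCDFs, a coastline CSV and a
    velocity NetCDF; returns the path map.  ``years``/``months`` bound
    the velocity series (a buffer of 95 days past the last release day
    is included so particles can complete a 90-day drift).
    """
    p = dict(FIXTURE_DEFAULTS)
    if overrides:
        p.update(overrides)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    env_grid = gridio.GridSpec(**p["env_grid"])
    temp, distractor = synthdata.gen_env_predictors(
        env_grid,
        gradients=[p["temp_slope"], 0.0],
        noise_sd=0.0,
        seed=int(rng.integers(2**31 - 1)),
        intercepts=[p["temp_intercept"], 35.0],
        names=["sst_extreme", "salinity_extreme"],
    )
    noise_rng = np.random.default_rng(int(rng.integers(2**31 - 1)))
    temp.values += noise_rng.normal(0, p["temp_noise_sd"], env_grid.shape)
    distractor.values += noise_rng.normal(0, p["distractor_noise_sd"], env_grid.shape)

    truth = synthdata.NicheTruth(t_min=p["t_min"], t_max=p["t_max"], w=p["edge_width"])
    # the non-native (invaded) region: geographically separate (eastern half)
    # and environmentally nested — a central latitude band of the envelope —
    # so range comparison exhibits niche narrowing, not divergence
    lon_mid = env_grid.lon_min + env_grid.n_lon * env_grid.cell_size / 2
    ranges = {
        "non-native": {"lon": (lon_mid, 1e9), "lat": p["invaded_band"]},
        "native": (-90.0, 90.0),
    }
    occ = synthdata.gen_occurrences(
        truth, temp, n_presence=p["n_presence"], n_survey_absence=p["n_survey_absence"],
        ranges=ranges, seed=int(rng.integers(2**31 - 1)),
    )

    lps_grid = gridio.GridSpec(**p["lps_grid"])
    coastal, land = synthdata.gen_coastline(p["n_coastal_cells"], "meridional", lps_grid)
    front_lat = coastal.centers()[p["front_cell"], 1] + lps_grid.cell_size / 2
    start = pd.Timestamp(f"{min(years)}-01-01")
    last_release = pd.Timestamp(f"{max(years)}-{max(months):02d}-28") + pd.offsets.MonthEnd(0)
    dates = pd.date_range(start, last_release + pd.Timedelta(days=95), freq="D")
    series = synthdata.gen_velocity_jet(
        lps_grid, dates, jet_speed=p["jet_speed"], jet_direction="north",
        front_lat=float(front_lat), offshore_deflection=p["offshore_deflection"],
        counter_current_speed=counter_current_speed,
        noise_sd=p["velocity_noise_sd"], seed=int(rng.integers(2**31 - 1)), land=land,
    )

    paths = {
        "occurrences": str(out / "occurrences.csv"),
        "predictors": [str(out / "sst_extreme.nc"), str(out / "salinity_extreme.nc")],
        "coastline": str(out / "coastline.csv"),
        "velocity": str(out / "velocity.nc"),
        "truth": {"t_min": p["t_min"], "t_max": p["t_max"],
                  "temp_slope": p["temp_slope"], "temp_intercept": p["temp_intercept"],
                  "front_cell": p["front_cell"], "front_lat": float(front_lat)},
    }
    gridio.write_occurrence_csv(occ, paths["occurrences"])
    gridio.write_raster_netcdf(temp, paths["predictors"][0])
    gridio.write_raster_netcdf(distractor, paths["predictors"][1])
    gridio.write_coastal_csv(coastal, paths["coastline"])
    gridio.write_velocity_netcdf(series, paths["velocity"])
    with open(out / "fixtures.json", "w") as fh:
        json.dump(paths, fh, indent=2)
    return paths


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _load_inputs(cfg: RunConfig):
    occ = gridio.read_occurrence_csv(cfg.occurrences)
    predictors = [gridio.read_raster_netcdf(p) for p in cfg.predictors]
    occ = gridio.grid_occurrences(occ, predictors[0].grid)
    return occ, predictors


def run_enm_stage(cfg: RunConfig, out: Path) -> dict:
    occ, predictors = _load_inputs(cfg)
    econf = replace(cfg.enm, seed=stage_seed(cfg.seed, "enm"))
    combos = enm_mod.enumerate_predictor_combos(predictors, econf.spearman_cutoff)
    cv = enm_mod.run_cv_framework(occ, predictors, combos, econf)
    selected = enm_mod.select_transferable(cv, econf.kw_alpha)
    ens = enm_mod.build_ensemble(selected, occ, predictors, econf)
    importance = enm_mod.predictor_importance(cv)
    survey_eval = enm_mod.validate_against_surveys(ens.binary, occ)

    gridio.write_raster_netcdf(ens.median, out / "ensemble_median.nc")
    gridio.write_raster_netcdf(ens.sd, out / "ensemble_sd.nc")
    gridio.write_raster_netcdf(ens.binary, out / "ensemble_binary.nc")
    importance.to_csv(out / "importance.csv")
    pd.DataFrame({" | ".join(c): pd.Series(s) for c, s in cv.scores.items()}
                 ).to_csv(out / "cv_scores.csv", index=False)
    report = {
        "n_records": len(occ),
        "n_combos": len(combos),
        "selected": [list(c) for c in selected],
        "ensemble_threshold": ens.threshold,
        "ensemble_fit_tss": ens.evaluation.tss,
        "survey_sensitivity": survey_eval.sensitivity,
        "survey_specificity": survey_eval.specificity,
        "survey_tss": survey_eval.tss,
        "importance": importance.reset_index().to_dict(orient="records"),
    }
    return report


def run_divergence_stage(cfg: RunConfig, out: Path) -> dict:
    occ, predictors = _load_inputs(cfg)
    res = niche_divergence(occ, predictors, n_perm=cfg.divergence.n_perm,
                           seed=stage_seed(cfg.seed, "divergence"),
                           n_axes=cfg.divergence.n_axes)
    scores = pd.DataFrame(res.pca.scores[:, :cfg.divergence.n_axes],
                          columns=[f"PC{k+1}" for k in range(cfg.divergence.n_axes)])
    scores["range"] = res.groups
    scores.to_csv(out / "pca_scores.csv", index=False)
    return res.to_dict()


def run_lps_stage(cfg: RunConfig, out: Path) -> dict:
    series = gridio.read_velocity_netcdf(cfg.velocity)
    coastal = gridio.read_coastal_csv(cfg.coastline)
    report: dict = {}
    matrices = {}
    for pld in (30, 90):
        lconf = replace(cfg.lps, pld_days=pld, seed=stage_seed(cfg.seed, f"lps{pld}"))
        runs = lps.run_lps(lconf, series, coastal)
        annual = [lps.connectivity_matrix(r, coastal, lconf) for r in runs]
        mean = lps.average_annual(annual)
        matrices[pld] = mean
        gridio.write_connectivity_csv(mean.to_frame(), out / f"connectivity_pld{pld}.csv")
    c30 = matrices[30]
    mantel = lps.compare_pld(matrices[30], matrices[90], n_perm=999,
                             seed=stage_seed(cfg.seed, "mantel"))
    barriers_up = lps.detect_barriers(c30, coastal, cfg.lps.barrier_threshold, "up")
    barriers_down = lps.detect_barriers(c30, coastal, cfg.lps.barrier_threshold, "down")
    report.update({
        "mean_retention": float(np.mean(c30.retention)),
        "mantel_r_pld30_vs_90": mantel.statistic,
        "mantel_p": mantel.p_value,
        "barriers_up": barriers_up,
        "barriers_down": barriers_down,
    })
    return report


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the configured stages; write a JSON report; return it."""
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed, "stages": {}}
    runners = {"enm": run_enm_stage, "divergence": run_divergence_stage, "lps": run_lps_stage}
    failed = False
    for stage in cfg.stages:
        if stage not in runners:
            raise ValueError(f"unknown stage {stage!r}")
        try:
            report["stages"][stage] = runners[stage](cfg, out)
        except Exception as err:
            logger.exception("stage %s failed", stage)
            report["stages"][stage] = {"error": str(err)}
            failed = True
    report["status"] = "failed" if failed else "ok"
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report
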