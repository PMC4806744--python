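"""End-to-end pipeline: simulate/ingest -> impute -> biomass -> availability
-> diet -> hormone models, with a validated config, persisted
intermediates, and a reproducible report."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import availability as avail_mod
from . import diet as diet_mod
from . import escapement as esc_mod
from . import models as models_mod
from . import synthetic as syn_mod

logger = logging.getLogger(__name__)

__all__ = ["ConfigError", "RunConfig", "RunReport", "run_pipeline",
           "write_report", "read_report"]


class ConfigError(ValueError):
    """Invalid run configuration."""


_TOP_KEYS = {"seed", "source", "sim", "species_mass", "home_range_km2",
             "mixing", "thresholds", "buffers"}
_THRESHOLD_KEYS = {"delta_aicc", "outlier_sd", "vif", "grid_n"}
_BUFFER_KEYS = {"spacing_km", "n_buffers"}


def _tuple_key_map(d: Mapping, what: str) -> dict:
    """Convert {"species": {"sex": v}} nests to {(species, sex): v}."""
    out = {}
    for sp, sexes in d.items():
        if not isinstance(sexes, Mapping):
            raise ConfigError(f"{what}.{sp} must be a mapping of sex to value")
        for sex, v in sexes.items():
            out[(sp, sex)] = float(v)
    return out


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    seed: int = 0
    source: str = "synthetic"            # or a directory of input CSVs
    sim: syn_mod.SimConfig = field(default_factory=syn_mod.SimConfig)
    species_mass: dict = field(default_factory=lambda: dict(syn_mod.DEFAULT_SPECIES_MASS))
    home_range_km2: dict | None = None   # default: sim's ranges
    sources: diet_mod.SourceSpec = field(default_factory=diet_mod.SourceSpec.default_synthetic)
    fractionation: diet_mod.Fractionation = field(default_factory=diet_mod.Fractionation.default_synthetic)
    delta_aicc: float = 2.0
    outlier_sd: float = 2.0
    vif_threshold: float = 10.0
    grid_n: int = 1001
    buffer_spacing_km: float | None = None
    n_buffers: int = 40

    def __post_init__(self):
        if self.home_range_km2 is None:
            self.home_range_km2 = dict(self.sim.home_range_km2)
        self.sim = dataclasses.replace(self.sim, seed=int(self.seed))
        if self.source != "synthetic" and not os.path.isdir(self.source):
            raise ConfigError(f"input directory does not exist: {self.source!r}")

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RunConfig":
        unknown = set(raw) - _TOP_KEYS
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        kwargs = {}
        kwargs["seed"] = int(raw.get("seed", 0))
        kwargs["source"] = str(raw.get("source", "synthetic"))
        sim_block = dict(raw.get("sim", {}))
        sim_fields = {f.name for f in dataclasses.fields(syn_mod.SimConfig)}
        unknown = set(sim_block) - sim_fields
        if unknown:
            raise ConfigError(f"unknown sim key(s): {sorted(unknown)}")
        if "n_bears" in sim_block:
            sim_block["n_bears"] = {k: int(v) for k, v in
                                    _tuple_key_map(sim_block["n_bears"], "sim.n_bears").items()}
        if "home_range_km2" in sim_block:
            sim_block["home_range_km2"] = _tuple_key_map(
                sim_block["home_range_km2"], "sim.home_range_km2")
        if "sampling_years" in sim_block:
            sim_block["sampling_years"] = tuple(sim_block["sampling_years"])
        if "region_km" in sim_block:
            sim_block["region_km"] = tuple(sim_block["region_km"])
        try:
            kwargs["sim"] = syn_mod.SimConfig(seed=kwargs["seed"], **sim_block)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid sim block: {exc}") from exc
        if "species_mass" in raw:
            kwargs["species_mass"] = {k: float(v) for k, v in raw["species_mass"].items()}
        if "home_range_km2" in raw:
            kwargs["home_range_km2"] = _tuple_key_map(raw["home_range_km2"],
                                                      "home_range_km2")
        if "mixing" in raw:
            mix = dict(raw["mixing"])
            unknown = set(mix) - {"sources", "fractionation", "residual_sd"}
            if unknown:
                raise ConfigError(f"unknown mixing key(s): {sorted(unknown)}")
            if "sources" in mix:
                mean = {(s, j): mix["sources"][s][j][0]
                        for s in mix["sources"] for j in mix["sources"][s]}
                sd = {(s, j): mix["sources"][s][j][1]
                      for s in mix["sources"] for j in mix["sources"][s]}
                kwargs["sources"] = diet_mod.SourceSpec(mean=mean, sd=sd)
            frac_mean = {(s, j): raw["mixing"]["fractionation"][s][j][0]
                         for s in mix.get("fractionation", {})
                         for j in mix["fractionation"][s]} if "fractionation" in mix else None
            if "fractionation" in mix or "residual_sd" in mix:
                default = diet_mod.Fractionation.default_synthetic()
                frac_sd = {(s, j): mix["fractionation"][s][j][1]
                           for s in mix.get("fractionation", {})
                           for j in mix["fractionation"][s]} if "fractionation" in mix else default.sd
                res = mix.get("residual_sd", default.residual_sd)
                kwargs["fractionation"] = diet_mod.Fractionation(
                    mean=frac_mean or default.mean, sd=frac_sd,
                    residual_sd=dict(res))
        thr = dict(raw.get("thresholds", {}))
        unknown = set(thr) - _THRESHOLD_KEYS
        if unknown:
            raise ConfigError(f"unknown thresholds key(s): {sorted(unknown)}")
        kwargs["delta_aicc"] = float(thr.get("delta_aicc", 2.0))
        kwargs["outlier_sd"] = float(thr.get("outlier_sd", 2.0))
        kwargs["vif_threshold"] = float(thr.get("vif", 10.0))
        kwargs["grid_n"] = int(thr.get("grid_n", 1001))
        buf = dict(raw.get("buffers", {}))
        unknown = set(buf) - _BUFFER_KEYS
        if unknown:
            raise ConfigError(f"unknown buffers key(s): {sorted(unknown)}")
        if "spacing_km" in buf and buf["spacing_km"] is not None:
            kwargs["buffer_spacing_km"] = float(buf["spacing_km"])
        kwargs["n_buffers"] = int(buf.get("n_buffers", 40))
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, Mapping):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(raw)

    def canonical_dict(self) -> dict:
        def conv(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: conv(getattr(obj, f.name))
                        for f in dataclasses.fields(obj)}
            if isinstance(obj, Mapping):
                return {str(k): conv(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
            if isinstance(obj, (list, tuple, np.ndarray)):
                return [conv(v) for v in obj]
            if isinstance(obj, (np.integer, np.floating)):
                return obj.item()
            return obj
        return conv(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.canonical_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class RunReport:
    """Machine-checkable summary of one pipeline run."""

    config_hash: str
    version: str
    stages: dict = field(default_factory=dict)       # stage -> row counts etc.
    tables: dict = field(default_factory=dict)       # name -> DataFrame
    scalars: dict = field(default_factory=dict)
    output_hashes: dict = field(default_factory=dict)


def _df_hash(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()


def _load_inputs(config: RunConfig):
    if config.source == "synthetic":
        study = syn_mod.generate_study(config.sim)
        return (study.streams.table, study.escapement, study.detections,
                study.hair)
    d = config.source
    streams = pd.read_csv(os.path.join(d, "streams.csv"))
    escapement = pd.read_csv(os.path.join(d, "escapement.csv"))
    detections = pd.read_csv(os.path.join(d, "detections.csv"))
    hair = pd.read_csv(os.path.join(d, "hair.csv"))
    return streams, escapement, detections, hair


def run_pipeline(config: RunConfig, out_dir: str | None = None) -> RunReport:
    """Execute all stages; persist intermediates when out_dir is given."""
    report = RunReport(config_hash=config.config_hash(),
                       version=_version())

    streams_table, escapement, detections, hair = _load_inputs(config)
    streams = syn_mod.StreamNetwork(table=streams_table,
                                    log_level=pd.DataFrame(index=streams_table["stream_id"]))
    report.stages["ingest"] = {"streams": len(streams_table),
                               "escapement_rows": int(len(escapement)),
                               "escapement_missing": int(escapement["count"].isna().sum()),
                               "detections": len(detections),
                               "hair_samples": len(hair)}
    logger.info("stage ingest: %s", report.stages["ingest"])

    # impute
    try:
        model = esc_mod.fit_imputation(escapement)
        filled = esc_mod.impute_missing(escapement, model)
        loo = esc_mod.loo_validation(escapement)
    except Exception as exc:
        raise RuntimeError(f"stage impute failed: {exc}") from exc
    report.stages["impute"] = {"imputed_cells": int(filled["imputed"].sum()),
                               "loo_mean_cv_pct": loo.mean_cv,
                               "loo_excluded": loo.n_excluded}
    report.scalars["loo_mean_cv_pct"] = loo.mean_cv
    logger.info("stage impute: %s", report.stages["impute"])

    # biomass
    try:
        biomass = esc_mod.biomass_density(filled, config.species_mass, streams)
    except Exception as exc:
        raise RuntimeError(f"stage biomass failed: {exc}") from exc
    report.stages["biomass"] = {"stream_years": len(biomass)}

    # availability
    try:
        records = avail_mod.availability_table(
            detections, streams, biomass, config.home_range_km2,
            spacing_km=config.buffer_spacing_km, n_buffers=config.n_buffers)
        metrics = avail_mod.pca_metrics(records)
        records = records.join(metrics.scores)
    except Exception as exc:
        raise RuntimeError(f"stage availability failed: {exc}") from exc
    report.stages["availability"] = {
        "bear_years": len(records),
        "pca_explained": [round(float(v), 6) for v in metrics.explained]}
    report.scalars["pca_explained_pc1"] = float(metrics.explained[0])

    # diet
    try:
        diets = diet_mod.estimate_diet(hair, config.sources, config.fractionation,
                                       grid_n=config.grid_n)
    except Exception as exc:
        raise RuntimeError(f"stage diet failed: {exc}") from exc
    report.stages["diet"] = {"bear_years": len(diets)}

    # assemble analysis rows
    obs = (hair.merge(detections[["bear_id", "species", "sex"]].drop_duplicates("bear_id"),
                      on="bear_id", how="left")
           .merge(diets.rename(columns={"p_median": "p_salmon"}), on=["bear_id", "year"])
           .merge(records[["bear_id", "year", "b10", "bt", "bt1",
                           "productivity", "availability"]],
                  on=["bear_id", "year"], how="left"))

    # models
    rankings, group_weights, coefficients = {}, {}, {}
    excluded = {}
    comparisons = _species_sex_comparisons(obs)
    for species in sorted(obs["species"].dropna().unique()):
        for response in ("cortisol", "testosterone"):
            key = f"{species}_{response}"
            try:
                ana = models_mod.analyze_hormones(
                    obs, species, response, delta_threshold=config.delta_aicc,
                    outlier_sd=config.outlier_sd)
            except Exception as exc:
                raise RuntimeError(f"stage models failed for {key}: {exc}") from exc
            rankings[key] = ana.ranked.table
            group_weights[key] = ana.group_weights
            coefficients[key] = ana.coefficients
            excluded[key] = ana.excluded
    report.stages["models"] = {k: int(len(v)) for k, v in rankings.items()}
    report.stages["outliers_excluded"] = {k: len(v) for k, v in excluded.items()}

    report.tables = {
        "escapement_imputed": filled,
        "biomass_density": biomass,
        "availability": records,
        "diet": diets,
        "observations": obs,
        "loo_cells": loo.cells,
        "comparisons": comparisons,
    }
    for key, tab in rankings.items():
        report.tables[f"ranking_{key}"] = tab
    for key, tab in group_weights.items():
        report.tables[f"group_weights_{key}"] = tab
    for key, tab in coefficients.items():
        report.tables[f"coefficients_{key}"] = tab
    report.output_hashes = {name: _df_hash(df) for name, df in report.tables.items()}

    if out_dir is not None:
        write_report(report, out_dir)
    return report


def _species_sex_comparisons(obs: pd.DataFrame) -> pd.DataFrame:
    """Wilcoxon species/sex comparisons with Holm adjustment per variable."""
    rows = []
    for var in ("p_salmon", "cortisol", "testosterone"):
        groups = {}
        for sex in ("male", "female"):
            a = obs.loc[(obs["species"] == "grizzly") & (obs["sex"] == sex), var].dropna()
            b = obs.loc[(obs["species"] == "black") & (obs["sex"] == sex), var].dropna()
            if len(a) and len(b):
                groups[f"grizzly_vs_black_{sex}"] = (a, b)
        for sp in ("grizzly", "black"):
            a = obs.loc[(obs["species"] == sp) & (obs["sex"] == "male"), var].dropna()
            b = obs.loc[(obs["species"] == sp) & (obs["sex"] == "female"), var].dropna()
            if len(a) and len(b):
                groups[f"{sp}_male_vs_female"] = (a, b)
        if not groups:
            continue
        for r in models_mod.wilcoxon_holm(groups):
            rows.append({"variable": var, "comparison": r.name, "W": r.statistic,
                         "p_raw": r.p_raw, "p_adjusted": r.p_adjusted,
                         "family_size": r.family_size, "method": r.method})
    return pd.DataFrame(rows)


def write_report(report: RunReport, out_dir: str) -> None:
    """Persist the report: JSON summary plus one CSV per table."""
    os.makedirs(out_dir, exist_ok=True)
    tdir = os.path.join(out_dir, "tables")
    os.makedirs(tdir, exist_ok=True)
    for name, df in report.tables.items():
        df.to_csv(os.path.join(tdir, f"{name}.csv"), index=False)
    summary = {"config_hash": report.config_hash, "version": report.version,
               "stages": report.stages, "scalars": report.scalars,
               "output_hashes": report.output_hashes,
               "tables": sorted(report.tables)}
    with open(os.path.join(out_dir, "report.json"), "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def read_report(out_dir: str) -> RunReport:
    """Read a persisted report back; tables round-trip bit-exactly."""
    with open(os.path.join(out_dir, "report.json"), "r", encoding="utf-8") as fh:
        summary = json.load(fh)
    tables = {}
    for name in summary["tables"]:
        tables[name] = pd.read_csv(os.path.join(out_dir, "tables", f"{name}.csv"),
                                   float_precision="round_trip")
    return RunReport(config_hash=summary["config_hash"], version=summary["version"],
                     stages=summary["stages"], scalars=summary["scalars"],
                     tables=tables, output_hashes=summary["output_hashes"])


def _version() -> str:
    from . import __version__
    return __version__
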