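"""Synthetic bear-salmon study generator with known ground truth.

Generates a complete study — spawning streams, multi-species escapement
records with realistic missingness, bear detections, and hair samples
carrying isotopes and hormones — from latent "true" ecology, so every
downstream stage (imputation, availability, diet mixing, model selection)
can be verified against a known answer.

The statistical shape of the truth follows the system's biology:

* Escapement counts are log-scale with per-(stream, species) levels and
  regional per-(species, year) anomalies shared across streams, and ~30%
  of cells are missing at random (the rate observed in coastal spawner
  databases).
* Diet: grizzly consumption saturates with availability,
  p(a) = p_max * a / (a + h) with plateau near 0.9 (most grizzly bears
  assimilate >80% of yearly protein from salmon); black-bear consumption
  is hump-shaped (Ricker), p(a) = p_pk * (a/a_pk) * exp(1 - a/a_pk),
  peaking below 0.7.
* Stress: nutritional stress declines exponentially with availability,
  N(a) = n_max * exp(-a/a_n); social stress is unimodal (Ricker),
  S(a) = s_max * (a/a_s) * exp(1 - a/a_s), peaking at intermediate
  availability where competition over salmon is most intense.  Log
  cortisol is a weighted sum of the two stresses; log testosterone
  responds to watershed productivity, availability deviation, bear
  density and cortisol.  Exponentiating the Gaussian linear predictors
  yields the right-skewed positive hormone scales seen in hair.
* Species presets: grizzly bears are nutrition-dominant (w_nut >> w_soc);
  black bears are social-dominant (w_soc >> w_nut).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .diet import Fractionation, SourceSpec, mixture_moments

SALMON_SPECIES = ("pink", "chum", "coho", "sockeye", "chinook")
BEAR_SPECIES = ("grizzly", "black")

# kg/fish, both sexes pooled at a 1:1 ratio (config-level input)
DEFAULT_SPECIES_MASS = {
    "pink": 1.8, "chum": 4.5, "coho": 3.2, "sockeye": 2.7, "chinook": 9.1,
}
# latent mean log-abundance per species (pink runs dominate numerically)
DEFAULT_LOG_ABUNDANCE = {
    "pink": 9.2, "chum": 8.0, "coho": 6.5, "sockeye": 7.2, "chinook": 5.5,
}

__all__ = [
    "SALMON_SPECIES", "BEAR_SPECIES",
    "DEFAULT_SPECIES_MASS", "DEFAULT_LOG_ABUNDANCE",
    "DietParams", "StressParams", "SimConfig",
    "StreamNetwork", "SyntheticStudy",
    "generate_streams", "generate_escapement", "true_diet_fraction",
    "synthesize_isotopes", "synthesize_hormones",
    "generate_bear_observations", "generate_study",
]


@dataclass(frozen=True)
class DietParams:
    """Consumption-availability curve for one bear species.

    curve="saturating": p(a) = p_max * a / (a + h)         (grizzly)
    curve="ricker":     p(a) = p_pk * (a/a_pk) * e^(1-a/a_pk)  (black)

    jitter_sd is the SD of individual deviations added to the curve value
    (clipped back into [0, 1]).
    """

    curve: str
    p_max: float = 0.9
    h: float = 25_000.0          # half-saturation biomass, kg
    p_pk: float = 0.55
    a_pk: float = 200_000.0      # biomass at the consumption peak, kg
    jitter_sd: float = 0.04


@dataclass(frozen=True)
class StressParams:
    """Hormone-response weights and stress-curve scales for one species.

    All weights act on the log-hormone scale; a_n and a_s are the
    availability scales (kg) of the nutritional and social stress curves;
    b10_ref_kg anchors the watershed-productivity deviation.
    """

    c0: float                    # baseline log cortisol (log pg/mg)
    t0: float                    # baseline log testosterone
    w_nut: float
    w_soc: float
    w_prod: float
    w_avail: float
    w_dens: float
    w_cross: float               # testosterone response to realized cortisol
    a_n: float
    a_s: float
    b10_ref_kg: float
    n_max: float = 1.0
    s_max: float = 1.0
    sd_cortisol: float = 0.2     # log-scale noise SDs
    sd_testosterone: float = 0.25


def _default_diet() -> dict:
    return {
        # wide individual jitter: dominance drives large consumption spread
        "grizzly": DietParams(curve="saturating", p_max=0.9, h=25_000.0,
                              jitter_sd=0.12),
        "black": DietParams(curve="ricker", p_pk=0.55, a_pk=200_000.0,
                            jitter_sd=0.06),
    }


def _default_stress() -> dict:
    return {
        # nutrition-dominant
        "grizzly": StressParams(
            c0=float(np.log(2.5)), t0=float(np.log(1.5)),
            w_nut=1.2, w_soc=0.15, w_prod=0.2, w_avail=0.4, w_dens=0.1,
            w_cross=0.4, a_n=100_000.0, a_s=50_000.0, b10_ref_kg=200_000.0),
        # social-dominant
        "black": StressParams(
            c0=float(np.log(1.5)), t0=float(np.log(3.0)),
            w_nut=0.2, w_soc=1.1, w_prod=0.4, w_avail=0.3, w_dens=0.15,
            w_cross=0.35, a_n=60_000.0, a_s=15_000.0, b10_ref_kg=60_000.0),
    }


def _default_bears() -> dict:
    # bear-years by (species, sex), sized like a coastal hair-snag study
    return {("grizzly", "male"): 54, ("grizzly", "female"): 14,
            ("black", "male"): 59, ("black", "female"): 9}


def _default_ranges() -> dict:
    # km^2, largest MCP-style estimates by species and sex (config input)
    return {("grizzly", "male"): 700.0, ("grizzly", "female"): 250.0,
            ("black", "male"): 120.0, ("black", "female"): 60.0}


@dataclass(frozen=True)
class SimConfig:
    """Full configuration of a synthetic study."""

    seed: int = 0
    n_streams: int = 25
    n_years: int = 13
    start_year: int = 1998
    region_km: tuple = (60.0, 60.0)
    missing_rate: float = 0.30
    species_mass: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_SPECIES_MASS))
    species_log_abundance: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_LOG_ABUNDANCE))
    stream_sdlog: float = 0.8        # between-stream spread of log level
    year_anomaly_sd: float = 0.5     # shared regional year effects
    obs_noise_sd: float = 0.3        # cell-level log noise
    stream_trend_sd: float = 0.0     # misspecification toggle: per-stream trends
    length_km_median: float = 1.0    # spawning-reach length, log-normal
    length_sdlog: float = 0.6
    n_bears: Mapping[tuple, int] = field(default_factory=_default_bears)
    home_range_km2: Mapping[tuple, float] = field(default_factory=_default_ranges)
    sampling_years: tuple = (2009, 2010, 2011)
    recapture_fraction: float = 0.05
    multi_detection_fraction: float = 0.15
    diet_params: Mapping[str, DietParams] = field(default_factory=_default_diet)
    stress_params: Mapping[str, StressParams] = field(default_factory=_default_stress)
    sources: SourceSpec = field(default_factory=SourceSpec.default_synthetic)
    fractionation: Fractionation = field(default_factory=Fractionation.default_synthetic)
    # direct bear-level generator: availability distribution per species
    b10_median_kg: Mapping[str, float] = field(
        default_factory=lambda: {"grizzly": 200_000.0, "black": 60_000.0})
    b10_sdlog: float = 0.7
    avail_sdlog: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must lie in [0, 1]")
        if self.n_streams < 1 or self.n_years < 1:
            raise ValueError("n_streams and n_years must be >= 1")
        if self.region_km[0] <= 0 or self.region_km[1] <= 0:
            raise ValueError("region dimensions must be positive")
        if any(m <= 0 for m in self.species_mass.values()):
            raise ValueError("species masses must be positive")
        if any(n < 1 for n in self.n_bears.values()):
            raise ValueError("bear counts must be >= 1")
        for sd in (self.stream_sdlog, self.year_anomaly_sd, self.obs_noise_sd,
                   self.length_sdlog, self.b10_sdlog, self.avail_sdlog):
            if sd < 0:
                raise ValueError("SDs must be >= 0")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.start_year + self.n_years)


@dataclass
class StreamNetwork:
    """Spawning streams: locations, reach lengths, latent abundance levels."""

    table: pd.DataFrame              # stream_id, x_km, y_km, length_km
    log_level: pd.DataFrame          # stream_id x salmon species latent means

    def __len__(self) -> int:
        return len(self.table)


def generate_streams(config: SimConfig, rng: np.random.Generator) -> StreamNetwork:
    """Place streams uniformly in the rectangular study region.

    Reach lengths are log-normal; each stream carries a latent mean
    log-abundance per salmon species around the regional species level.
    """
    w, h = config.region_km
    n = config.n_streams
    ids = [f"S{i:03d}" for i in range(1, n + 1)]
    xy = rng.uniform([0.0, 0.0], [w, h], size=(n, 2))
    lengths = np.exp(rng.normal(np.log(config.length_km_median), config.length_sdlog, n))
    table = pd.DataFrame({"stream_id": ids, "x_km": xy[:, 0], "y_km": xy[:, 1],
                          "length_km": lengths})
    levels = {
        sp: config.species_log_abundance[sp] + rng.normal(0.0, config.stream_sdlog, n)
        for sp in config.species_log_abundance
    }
    log_level = pd.DataFrame(levels, index=pd.Index(ids, name="stream_id"))
    return StreamNetwork(table=table, log_level=log_level)


def generate_escapement(streams: StreamNetwork, config: SimConfig,
                        rng: np.random.Generator,
                        return_complete: bool = False):
    """Stream x species x year spawner counts with missing cells.

    counts = round(exp(stream-species level + shared year anomaly
    [+ optional stream trend] + noise)); cells are masked missing
    independently with probability ``missing_rate`` (empty, never zero).
    Year anomalies are shared across streams within a species, so the
    two-way imputation model class is correctly specified by default.
    """
    if config.n_years < 2:
        raise ValueError("n_years must be >= 2")
    years = config.years
    species = list(config.species_log_abundance)
    sids = list(streams.log_level.index)
    n_s, n_y = len(sids), len(years)

    frames = []
    complete_frames = []
    for sp in species:
        level = streams.log_level[sp].to_numpy()[:, None]
        anom = rng.normal(0.0, config.year_anomaly_sd, n_y)[None, :]
        log_counts = level + anom
        if config.stream_trend_sd > 0:
            slope = rng.normal(0.0, config.stream_trend_sd, n_s)[:, None]
            t = (years - years.mean())[None, :]
            log_counts = log_counts + slope * t
        log_counts = log_counts + rng.normal(0.0, config.obs_noise_sd, (n_s, n_y))
        counts = np.round(np.exp(log_counts))
        missing = rng.uniform(size=(n_s, n_y)) < config.missing_rate
        base = pd.DataFrame({
            "stream_id": np.repeat(sids, n_y),
            "species": sp,
            "year": np.tile(years, n_s),
        })
        complete = base.assign(count=counts.ravel())
        masked = base.assign(count=np.where(missing.ravel(), np.nan, counts.ravel()))
        frames.append(masked)
        complete_frames.append(complete)
    table = pd.concat(frames, ignore_index=True)
    if return_complete:
        return table, pd.concat(complete_frames, ignore_index=True)
    return table


def true_diet_fraction(availability_kg, species: str, params: DietParams):
    """Noiseless salmon diet fraction at a given availability (kg).

    Saturating (grizzly) or Ricker hump (black); clamped to [0, 1].
    """
    a = np.asarray(availability_kg, dtype=float)
    if np.any(a < 0):
        raise ValueError("availability must be >= 0")
    if params.curve == "saturating":
        p = params.p_max * a / (a + params.h)
    elif params.curve == "ricker":
        with np.errstate(over="ignore"):
            p = params.p_pk * (a / params.a_pk) * np.exp(1.0 - a / params.a_pk)
    else:
        raise ValueError(f"unknown diet curve {params.curve!r} for {species}")
    p = np.clip(p, 0.0, 1.0)
    return float(p) if np.isscalar(availability_kg) else p


def synthesize_isotopes(p_true, sources: SourceSpec, frac: Fractionation,
                        rng: np.random.Generator, noise: bool = True):
    """Hair (d13C, d15N) for true diet fraction(s) ``p_true``.

    The mean is the deterministic mixing line; the noise SD per isotope is
    the mixing model's own propagated SD at p_true, so posteriors computed
    with the same spec are calibrated by construction.  ``noise=False``
    returns the exact mixing line.
    """
    p = np.atleast_1d(np.asarray(p_true, dtype=float))
    moments = mixture_moments(p, sources, frac)
    out = {}
    for j, (mean, sd) in moments.items():
        if noise:
            out[j] = mean + rng.normal(0.0, 1.0, p.shape) * sd
        else:
            out[j] = mean.copy()
    if np.isscalar(p_true):
        return float(out["d13C"][0]), float(out["d15N"][0])
    return out["d13C"], out["d15N"]


def nutritional_input(availability_kg, p_true=None, p_baseline=None):
    """Consumption-scaled availability driving nutritional stress.

    A bear that eats proportionally less than the species' consumption
    curve predicts at its availability (a subordinate at a contested
    stream) experiences the nutrition of a correspondingly poorer site:
    x = a * p_true / p_baseline, falling back to x = a where the baseline
    curve is zero or no individual consumption is supplied.
    """
    a = np.asarray(availability_kg, dtype=float)
    if p_true is None or p_baseline is None:
        return a
    p_true = np.asarray(p_true, dtype=float)
    p_baseline = np.asarray(p_baseline, dtype=float)
    ratio = np.divide(p_true, p_baseline, out=np.ones_like(a, dtype=float),
                      where=p_baseline > 0)
    return a * ratio


def nutritional_stress(x, params: StressParams):
    """N(x) = n_max * exp(-x/a_n): high when little salmon is taken in."""
    return params.n_max * np.exp(-np.asarray(x, dtype=float) / params.a_n)


def social_stress(a, params: StressParams):
    """S(a): Ricker hump peaking at a = a_s (intermediate availability)."""
    a = np.asarray(a, dtype=float)
    with np.errstate(over="ignore"):
        return params.s_max * (a / params.a_s) * np.exp(1.0 - a / params.a_s)


def synthesize_hormones(availability_kg, b10_kg, bt_kg, density_high,
                        params: StressParams, rng: np.random.Generator,
                        noise: bool = True, nutritional_kg=None):
    """Cortisol and testosterone (pg/mg) from the conceptual stress model.

    log cortisol = c0 + w_nut*N(x) + w_soc*S(a) + eps_c
    log testosterone = t0 + w_prod*prod_dev - w_avail*avail_dev
                       + w_dens*1[high density] + w_cross*(log C - c0) + eps_t

    where x is the consumption-scaled availability (``nutritional_kg``,
    defaulting to a itself), prod_dev = log1p(B10) - log1p(b10_ref) and
    avail_dev = log1p(Bt) - log1p(B10).  Returns (cortisol, testosterone,
    noiseless log-cortisol mean, noiseless log-testosterone mean).
    """
    a = np.atleast_1d(np.asarray(availability_kg, dtype=float))
    b10 = np.atleast_1d(np.asarray(b10_kg, dtype=float))
    bt = np.atleast_1d(np.asarray(bt_kg, dtype=float))
    dens = np.atleast_1d(np.asarray(density_high, dtype=float))
    x = a if nutritional_kg is None else np.atleast_1d(np.asarray(nutritional_kg, dtype=float))
    N = nutritional_stress(x, params)
    S = social_stress(a, params)
    log_c_mean = params.c0 + params.w_nut * N + params.w_soc * S
    eps_c = rng.normal(0.0, params.sd_cortisol, a.shape) if noise else 0.0
    log_c = log_c_mean + eps_c
    prod_dev = np.log1p(b10) - np.log1p(params.b10_ref_kg)
    avail_dev = np.log1p(bt) - np.log1p(b10)
    log_t_mean = (params.t0 + params.w_prod * prod_dev - params.w_avail * avail_dev
                  + params.w_dens * dens + params.w_cross * (log_c - params.c0))
    eps_t = rng.normal(0.0, params.sd_testosterone, a.shape) if noise else 0.0
    log_t = log_t_mean + eps_t
    return np.exp(log_c), np.exp(log_t), log_c_mean, log_t_mean


def generate_bear_observations(n: int, species: str, config: SimConfig,
                               rng: np.random.Generator,
                               sex: str = "male") -> pd.DataFrame:
    """Analysis-ready bear-year rows generated directly at the bear level.

    Skips the spatial sampling machinery: per bear, a 10-year-mean home
    range biomass B10 is log-normal, the growth-year biomass Bt (and the
    prior year Bt1) deviate log-normally from it, availability a = Bt
    drives diet and stress, and isotopes/hormones follow the full noise
    model.  Used for parameter-recovery experiments where many replicates
    are needed.
    """
    dp = config.diet_params[species]
    sp = config.stress_params[species]
    b10 = np.exp(rng.normal(np.log(config.b10_median_kg[species]), config.b10_sdlog, n))
    bt = b10 * np.exp(rng.normal(0.0, config.avail_sdlog, n))
    bt1 = b10 * np.exp(rng.normal(0.0, config.avail_sdlog, n))
    a = bt
    p_curve = true_diet_fraction(a, species, dp)
    p_true = np.clip(p_curve + rng.normal(0.0, dp.jitter_sd, n), 0.0, 0.995)
    x = nutritional_input(a, p_true, p_curve)
    d13c, d15n = synthesize_isotopes(p_true, config.sources, config.fractionation, rng)
    dens = rng.uniform(size=n) < 0.5
    cort, testo, log_c_mean, log_t_mean = synthesize_hormones(
        a, b10, bt, dens, sp, rng, nutritional_kg=x)
    return pd.DataFrame({
        "bear_id": [f"{species[0].upper()}{i:04d}" for i in range(1, n + 1)],
        "species": species, "sex": sex,
        "year": config.sampling_years[0],
        "b10": b10, "bt": bt, "bt1": bt1,
        "d13C": d13c, "d15N": d15n,
        "cortisol": cort, "testosterone": testo,
        "density_stratum": np.where(dens, "high", "low"),
        "true_availability": a, "p_true": p_true,
        "true_nutritional": nutritional_stress(x, sp),
        "true_social": social_stress(a, sp),
        "log_cortisol_mean": log_c_mean, "log_testosterone_mean": log_t_mean,
    })


@dataclass
class SyntheticStudy:
    """All tables of one synthetic study plus the latent truth."""

    config: SimConfig
    streams: StreamNetwork
    escapement: pd.DataFrame          # masked (analysis input)
    escapement_complete: pd.DataFrame  # unmasked (truth side)
    detections: pd.DataFrame          # bear_id, species, sex, year, x_km, y_km
    hair: pd.DataFrame                # bear_id, year, d13C, d15N, hormones, density
    truth: pd.DataFrame               # per bear-year latent quantities

    def write_csvs(self, out_dir) -> dict:
        """Write the study as the CSV interchange set; returns name->path."""
        import os
        os.makedirs(out_dir, exist_ok=True)
        paths = {}
        tables = {
            "streams.csv": self.streams.table,
            "escapement.csv": self.escapement,
            "escapement_complete.csv": self.escapement_complete,
            "detections.csv": self.detections,
            "hair.csv": self.hair,
            "truth.csv": self.truth,
        }
        for name, df in tables.items():
            path = os.path.join(out_dir, name)
            df.to_csv(path, index=False)
            paths[name] = path
        return paths


def _true_biomass_matrix(streams: StreamNetwork, complete: pd.DataFrame,
                         masses: Mapping[str, float]) -> pd.DataFrame:
    """(stream x year) total true biomass (kg) from the complete counts."""
    df = complete.copy()
    df["biomass"] = df["count"] * df["species"].map(masses)
    return df.pivot_table(index="stream_id", columns="year", values="biomass",
                          aggfunc="sum")


def generate_study(config: SimConfig) -> SyntheticStudy:
    """Generate the full spatial study from a single seed."""
    rng = np.random.default_rng(config.seed)
    streams = generate_streams(config, rng)
    escapement, complete = generate_escapement(streams, config, rng,
                                               return_complete=True)
    biomass = _true_biomass_matrix(streams, complete, config.species_mass)
    xy = streams.table[["x_km", "y_km"]].to_numpy()
    years = config.years

    det_rows, hair_rows, truth_rows = [], [], []
    counter = 0
    for (bsp, sex), n in config.n_bears.items():
        radius = float(np.sqrt(config.home_range_km2[(bsp, sex)] / np.pi))
        dp, sp = config.diet_params[bsp], config.stress_params[bsp]
        for _ in range(n):
            counter += 1
            bear_id = f"{bsp[0].upper()}{counter:04d}"
            n_years_detected = 2 if rng.uniform() < config.recapture_fraction else 1
            bear_years = rng.choice(config.sampling_years, size=n_years_detected,
                                    replace=False)
            centre = rng.uniform([0.0, 0.0], list(config.region_km))
            for year in np.sort(bear_years):
                growth_year = int(year) - 1
                # true availability: biomass within the bear's own range
                dist = np.hypot(xy[:, 0] - centre[0], xy[:, 1] - centre[1])
                inside = dist < radius
                yr_idx = [y - config.start_year
                          for y in range(growth_year - 10, growth_year + 1)
                          if 0 <= y - config.start_year < config.n_years]
                sub = biomass.to_numpy()[inside][:, yr_idx]
                if sub.size and len(yr_idx) >= 2:
                    bt = float(sub[:, -1].sum())
                    b10 = float(sub[:, :-1].sum(axis=0).mean())
                else:
                    bt = b10 = 0.0
                a = bt
                p_curve = true_diet_fraction(a, bsp, dp)
                p_true = float(np.clip(
                    p_curve + rng.normal(0.0, dp.jitter_sd), 0.0, 0.995))
                x = float(nutritional_input(np.array(a), p_true, p_curve))
                d13c, d15n = synthesize_isotopes(p_true, config.sources,
                                                 config.fractionation, rng)
                dens_high = centre[0] < config.region_km[0] / 2.0
                cort, testo, lcm, ltm = synthesize_hormones(
                    a, b10, bt, dens_high, sp, rng, nutritional_kg=x)
                n_det = 2 if rng.uniform() < config.multi_detection_fraction else 1
                for _ in range(n_det):
                    offset = rng.uniform(-0.3 * radius, 0.3 * radius, 2)
                    px = float(np.clip(centre[0] + offset[0], 0.0, config.region_km[0]))
                    py = float(np.clip(centre[1] + offset[1], 0.0, config.region_km[1]))
                    det_rows.append({"bear_id": bear_id, "species": bsp, "sex": sex,
                                     "year": int(year), "x_km": px, "y_km": py})
                hair_rows.append({
                    "bear_id": bear_id, "year": int(year),
                    "d13C": d13c, "d15N": d15n,
                    "cortisol": float(cort[0]), "testosterone": float(testo[0]),
                    "density_stratum": "high" if dens_high else "low",
                })
                truth_rows.append({
                    "bear_id": bear_id, "species": bsp, "sex": sex,
                    "year": int(year), "true_availability": a, "true_b10": b10,
                    "p_true": p_true,
                    "true_nutritional": float(nutritional_stress(x, sp)),
                    "true_social": float(social_stress(a, sp)),
                    "log_cortisol_mean": float(lcm[0]),
                    "log_testosterone_mean": float(ltm[0]),
                })
    detections = pd.DataFrame(det_rows)
    hair = pd.DataFrame(hair_rows)
    truth = pd.DataFrame(truth_rows)
    # referential integrity by construction; assert anyway
    assert set(hair["bear_id"]) <= set(detections["bear_id"])
    return SyntheticStudy(config=config, streams=streams, escapement=escapement,
                          escapement_complete=complete, detections=detections,
                          hair=hair, truth=truth)
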