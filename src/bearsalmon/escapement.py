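"""Escapement imputation, leave-one-out validation, and biomass conversion.

Spawner-count records (stream x species x year) from long-running
escapement databases are typically ~30% missing.  Missing cells are
filled with a two-way additive model on the log(count + 1) scale,

    log(count_ijy + 1) ~ alpha[stream i, species j] + gamma[species j, year y],

fitted by alternating row/column means on the observed cells only (the
least-squares solution for the additive model).  The per-(species, year)
anomalies gamma are shared across streams, so a stream's missing year is
predicted from that stream's own level plus the regional year signal.
Agreement between predictions and held-out observed cells is summarised
by a leave-one-out coefficient of variability on the log scale.

Counts are then converted to biomass by multiplying abundance by average
per-fish mass (kg) and summing across species, and to biomass per
spawning-reach length (kg/km).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .synthetic import StreamNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "UnimputableStratumError",
    "ImputationModel",
    "LooValidation",
    "fit_imputation",
    "impute_missing",
    "loo_validation",
    "biomass_density",
]

_TOL = 1e-8
_MAX_ITER = 2000


class UnimputableStratumError(ValueError):
    """A (stream, species) or (species, year) stratum has no observed cell."""


def _validate_table(table: pd.DataFrame) -> None:
    required = {"stream_id", "species", "year", "count"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"escapement table missing columns: {sorted(missing)}")
    keys = table[["stream_id", "species", "year"]]
    if keys.duplicated().any():
        dup = keys[keys.duplicated()].iloc[0]
        raise ValueError(f"duplicate escapement key: {tuple(dup)}")
    obs = table["count"].dropna()
    if (obs < 0).any():
        raise ValueError("counts must be >= 0")


def _fit_two_way(mat: np.ndarray, tol: float = _TOL):
    """Alternating-means fit of row + column effects on a matrix with NaNs.

    Returns (alpha, gamma) with gamma mean-centred (unweighted over
    columns) and the centre folded into alpha.
    """
    import warnings

    obs = ~np.isnan(mat)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # empty-column slices
        alpha = np.nanmean(mat, axis=1)
        gamma = np.zeros(mat.shape[1])
        for _ in range(_MAX_ITER):
            gamma_new = np.nanmean(mat - alpha[:, None], axis=0)
            alpha_new = np.nanmean(mat - gamma_new[None, :], axis=1)
            delta = np.nanmax(np.abs(np.concatenate(
                [alpha_new - alpha, gamma_new - gamma])))
            alpha, gamma = alpha_new, gamma_new
            if delta < tol:
                break
    observed_cols = obs.any(axis=0)
    centre = gamma[observed_cols].mean()
    gamma = gamma - centre
    gamma[~observed_cols] = 0.0  # unobserved years: mean anomaly
    return alpha + centre, gamma, obs


@dataclass
class ImputationModel:
    """Fitted two-way additive model on log(count + 1).

    alpha is indexed by (stream_id, species); gamma by (species, year)
    and mean-centred within each species.
    """

    alpha: pd.Series
    gamma: pd.Series

    def predict_log(self, stream_id, species, year) -> float:
        try:
            a = self.alpha[(stream_id, species)]
        except KeyError as exc:
            raise KeyError(f"stratum ({stream_id}, {species}) not covered by model") from exc
        try:
            g = self.gamma[(species, year)]
        except KeyError as exc:
            raise KeyError(f"stratum ({species}, {year}) not covered by model") from exc
        return float(a + g)

    def predict_count(self, stream_id, species, year) -> float:
        """Back-transformed imputed count: round(exp(alpha+gamma)-1), >= 0."""
        return max(0.0, float(np.round(np.expm1(self.predict_log(stream_id, species, year)))))


def fit_imputation(table: pd.DataFrame) -> ImputationModel:
    """Fit the additive imputation model from observed cells only."""
    _validate_table(table)
    alpha_parts, gamma_parts = [], []
    for sp, sub in table.groupby("species", sort=True):
        mat_df = sub.pivot(index="stream_id", columns="year", values="count")
        mat = np.log1p(mat_df.to_numpy(dtype=float))
        obs = ~np.isnan(mat)
        empty_rows = np.where(~obs.any(axis=1))[0]
        if empty_rows.size:
            sid = mat_df.index[empty_rows[0]]
            raise UnimputableStratumError(
                f"unimputable stratum: stream {sid!r}, species {sp!r} has no observed year")
        empty_cols = np.where(~obs.any(axis=0))[0]
        if empty_cols.size:
            # a year with no observed stream carries no regional signal;
            # fall back to the mean anomaly (gamma = 0) for that year
            logger.warning("species %r: year(s) %s have no observed stream; "
                           "using the mean anomaly", sp,
                           list(mat_df.columns[empty_cols]))
        alpha, gamma, _ = _fit_two_way(mat)
        alpha_parts.append(pd.Series(
            alpha, index=pd.MultiIndex.from_product([mat_df.index, [sp]],
                                                    names=["stream_id", "species"])))
        gamma_parts.append(pd.Series(
            gamma, index=pd.MultiIndex.from_product([[sp], mat_df.columns],
                                                    names=["species", "year"])))
    return ImputationModel(alpha=pd.concat(alpha_parts), gamma=pd.concat(gamma_parts))


def impute_missing(table: pd.DataFrame, model: ImputationModel) -> pd.DataFrame:
    """Fill missing cells; observed cells are returned unchanged.

    Adds an ``imputed`` provenance column.  Filled value is
    round(exp(alpha + gamma) - 1) clamped at 0.
    """
    _validate_table(table)
    out = table.copy()
    mask = out["count"].isna()
    out["imputed"] = mask
    fills = [
        model.predict_count(r.stream_id, r.species, r.year)
        for r in out.loc[mask].itertuples(index=False)
    ]
    out.loc[mask, "count"] = fills
    return out


@dataclass
class LooValidation:
    """Leave-one-out validation summary of the imputation model."""

    cells: pd.DataFrame   # stream_id, species, year, obs_log, pred_log, cv_pct
    mean_cv: float
    n_excluded: int = 0


def _pair_cv(obs_log: float, pred_log: float) -> float:
    """Two-value coefficient of variability (%) on the log scale."""
    m = 0.5 * (obs_log + pred_log)
    # sample SD of two values = |difference| / sqrt(2)
    s = abs(obs_log - pred_log) / np.sqrt(2.0)
    return 100.0 * s / m


def loo_validation(table: pd.DataFrame) -> LooValidation:
    """Refit without each observed cell in turn and score the prediction.

    For each observed cell, the model is refitted on the remaining cells
    of that species, the cell is predicted on the log(count + 1) scale,
    and CV_i = 100 * sd(obs, pred) / mean(obs, pred) is recorded.  Cells
    whose removal would empty a stratum, or whose obs/pred log mean is 0,
    are excluded with a logged warning.
    """
    _validate_table(table)
    rows = []
    n_excluded = 0
    for sp, sub in table.groupby("species", sort=True):
        mat_df = sub.pivot(index="stream_id", columns="year", values="count")
        mat = np.log1p(mat_df.to_numpy(dtype=float))
        obs = ~np.isnan(mat)
        row_counts = obs.sum(axis=1)
        col_counts = obs.sum(axis=0)
        for i, j in zip(*np.where(obs)):
            if row_counts[i] < 2 or col_counts[j] < 2:
                logger.warning("LOO skipped cell (%s, %s, %s): stratum would be empty",
                               mat_df.index[i], sp, mat_df.columns[j])
                n_excluded += 1
                continue
            held = mat[i, j]
            work = mat.copy()
            work[i, j] = np.nan
            alpha, gamma, _ = _fit_two_way(work)
            pred = alpha[i] + gamma[j]
            if (held + pred) == 0.0:
                logger.warning("LOO excluded cell (%s, %s, %s): zero log mean",
                               mat_df.index[i], sp, mat_df.columns[j])
                n_excluded += 1
                continue
            rows.append({"stream_id": mat_df.index[i], "species": sp,
                         "year": mat_df.columns[j], "obs_log": held,
                         "pred_log": pred, "cv_pct": _pair_cv(held, pred)})
    cells = pd.DataFrame(rows)
    mean_cv = float(cells["cv_pct"].mean()) if len(cells) else float("nan")
    return LooValidation(cells=cells, mean_cv=mean_cv, n_excluded=n_excluded)


def biomass_density(table: pd.DataFrame, masses: Mapping[str, float],
                    streams: StreamNetwork | pd.DataFrame) -> pd.DataFrame:
    """Total salmon biomass and biomass per spawning length per stream-year.

    ``table`` must be complete (post-imputation).  B = sum over species of
    count x mass (kg); density = B / spawning length (kg/km).
    """
    _validate_table(table)
    if table["count"].isna().any():
        raise ValueError("biomass_density requires a complete (imputed) table")
    unknown = sorted(set(table["species"]) - set(masses))
    if unknown:
        raise KeyError(f"no mass for species: {unknown}")
    stream_table = streams.table if isinstance(streams, StreamNetwork) else streams
    if (stream_table["length_km"] <= 0).any():
        raise ValueError("spawning lengths must be > 0")
    df = table.copy()
    df["biomass_kg"] = df["count"] * df["species"].map(masses)
    out = (df.groupby(["stream_id", "year"], as_index=False)["biomass_kg"].sum())
    out = out.merge(stream_table[["stream_id", "length_km"]], on="stream_id",
                    how="left", validate="many_to_one")
    if out["length_km"].isna().any():
        bad = out.loc[out["length_km"].isna(), "stream_id"].unique()
        raise KeyError(f"streams without length: {sorted(bad)}")
    out["density_kg_per_km"] = out["biomass_kg"] / out["length_km"]
    return out[["stream_id", "year", "biomass_kg", "density_kg_per_km"]]
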