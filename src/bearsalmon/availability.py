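"""Per-bear salmon availability from detections and stream biomass.

A bear detected at a hair snag could have been anywhere inside its home
range, so a regular grid of 40 candidate circular buffers — each with the
radius of a species/sex MCP-equivalent home range, each containing the
detection — is scanned, and the buffer with the highest mean salmon
biomass over the 10 years preceding hair growth (B10) is taken as the
bear's home range, on the assumption that bears maximize access to this
fitness-enhancing resource.  Bears detected at several locations in one
year get the best buffer across all their detections.

The selected buffer yields the biomass triplet (B10, growth-year biomass
Bt, prior-year biomass Bt1).  The triplet is strongly collinear, so a
principal components analysis of the correlation matrix of the
log(x + 1)-transformed triplet supplies two interpretable axes:
"watershed productivity" (long-term level, axis 1) and "salmon
availability" (year-specific deviation from that level, axis 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .synthetic import StreamNetwork

__all__ = [
    "CandidateBuffer",
    "AvailabilityRecord",
    "SalmonMetrics",
    "home_range_radius",
    "candidate_buffers",
    "buffer_biomass",
    "select_home_range",
    "availability_table",
    "pca_metrics",
]


def home_range_radius(area_km2: float) -> float:
    """Radius (km) of the circle with the given home-range area."""
    if area_km2 <= 0:
        raise ValueError("home-range area must be > 0")
    return math.sqrt(area_km2 / math.pi)


@dataclass(frozen=True)
class CandidateBuffer:
    """One candidate circular home range for a detection."""

    center_x: float
    center_y: float
    radius_km: float
    offset_km: float          # distance from the detection to the centre

    def contains(self, x: float, y: float) -> bool:
        return math.hypot(x - self.center_x, y - self.center_y) <= self.radius_km


def candidate_buffers(x: float, y: float, radius_km: float,
                      spacing_km: float | None = None,
                      n_buffers: int = 40) -> list[CandidateBuffer]:
    """The ``n_buffers`` nearest lattice-point buffers around a detection.

    Centres are points of a square lattice anchored at the detection
    (default spacing r/4), restricted to distance <= r so every buffer
    contains the detection; the nearest ``n_buffers`` are kept, ties
    broken by x then y offset.  Deterministic.
    """
    if radius_km <= 0:
        raise ValueError("radius must be > 0")
    s = spacing_km if spacing_km is not None else radius_km / 4.0
    if s <= 0:
        raise ValueError("spacing must be > 0")
    kmax = int(math.floor(radius_km / s + 1e-9))
    limit = (radius_km / s) ** 2 + 1e-9
    pts = [(i * i + j * j, i, j)
           for i in range(-kmax, kmax + 1)
           for j in range(-kmax, kmax + 1)
           if i * i + j * j <= limit]
    if len(pts) < n_buffers:
        raise ValueError(
            f"only {len(pts)} lattice points within the home-range radius; "
            f"reduce spacing (got {s:g} km) or n_buffers")
    pts.sort()  # by squared offset, then i (x), then j (y): exact integer keys
    return [CandidateBuffer(center_x=x + i * s, center_y=y + j * s,
                            radius_km=radius_km, offset_km=s * math.sqrt(d2))
            for d2, i, j in pts[:n_buffers]]


def buffer_biomass(buffer: CandidateBuffer, streams: StreamNetwork | pd.DataFrame,
                   biomass: pd.DataFrame, growth_year: int):
    """(B10, Bt, Bt1) biomass sums (kg) for one candidate buffer.

    A stream is inside the buffer iff its point location is within the
    radius of the centre (half-open: distance < r).  Bt is total stream
    biomass in the hair-growth year, Bt1 the year before, and B10 the
    mean over the 10 years preceding the growth year.  ``biomass`` is the
    (stream_id, year, biomass_kg) table; missing years raise an error
    naming the gap.
    """
    st = streams.table if isinstance(streams, StreamNetwork) else streams
    dist = np.hypot(st["x_km"].to_numpy() - buffer.center_x,
                    st["y_km"].to_numpy() - buffer.center_y)
    inside = set(st.loc[dist < buffer.radius_km, "stream_id"])
    if not inside:
        return 0.0, 0.0, 0.0
    need = list(range(growth_year - 10, growth_year + 1))
    sub = biomass[biomass["stream_id"].isin(inside)]
    have = set(sub["year"])
    gaps = [y for y in need if y not in have]
    if gaps:
        raise ValueError(f"biomass table missing years {gaps} needed for "
                         f"growth year {growth_year}")
    totals = sub.groupby("year")["biomass_kg"].sum()
    bt = float(totals.get(growth_year, 0.0))
    bt1 = float(totals.get(growth_year - 1, 0.0))
    b10 = float(np.mean([totals.get(yr, 0.0) for yr in need[:-1]]))
    return b10, bt, bt1


@dataclass
class AvailabilityRecord:
    """Selected home range and biomass triplet for one bear-year."""

    bear_id: str
    year: int                 # sampling year
    growth_year: int
    b10: float
    bt: float
    bt1: float
    center_x: float
    center_y: float
    radius_km: float
    detection_index: int


def select_home_range(detections: Sequence[tuple], candidates: Sequence[Sequence[CandidateBuffer]],
                      streams, biomass: pd.DataFrame, growth_year: int):
    """Argmax-by-B10 buffer across all detections of one bear-year.

    ``detections`` is a sequence of (x, y); ``candidates`` the parallel
    candidate lists.  Ties on B10 go to the candidate nearest its own
    detection, then to the lowest detection index.  Returns
    (best_buffer, detection_index, (b10, bt, bt1)).
    """
    if len(detections) == 0:
        raise ValueError("at least one detection required")
    best = None
    for d_idx, cands in enumerate(candidates):
        for c in cands:
            b10, bt, bt1 = buffer_biomass(c, streams, biomass, growth_year)
            key = (-b10, c.offset_km, d_idx)
            if best is None or key < best[0]:
                best = (key, c, d_idx, (b10, bt, bt1))
    return best[1], best[2], best[3]


def availability_table(detections: pd.DataFrame, streams, biomass: pd.DataFrame,
                       home_range_km2: Mapping[tuple, float],
                       spacing_km: float | None = None, n_buffers: int = 40,
                       lag_years: int = 1) -> pd.DataFrame:
    """AvailabilityRecords for every bear-year in a detection table.

    ``detections`` has columns bear_id, species, sex, year, x_km, y_km;
    ``home_range_km2`` maps (species, sex) to area.  Hair sampled in year
    y reflects the previous growth season, so growth_year = y - lag_years
    (default 1).  Vectorized over the candidate lattice for speed.
    """
    st = streams.table if isinstance(streams, StreamNetwork) else streams
    xy = st[["x_km", "y_km"]].to_numpy()
    piv = biomass.pivot(index="stream_id", columns="year", values="biomass_kg")
    piv = piv.reindex(st["stream_id"]).fillna(0.0)
    years_avail = list(piv.columns)

    rows = []
    for (bear_id, year), grp in detections.groupby(["bear_id", "year"], sort=True):
        growth_year = int(year) - lag_years
        need = list(range(growth_year - 10, growth_year + 1))
        gaps = [yv for yv in need if yv not in years_avail]
        if gaps:
            raise ValueError(f"biomass table missing years {gaps} for bear "
                             f"{bear_id} sampled in {year}")
        mat10 = piv[need[:-1]].to_numpy()        # streams x 10
        col_t = piv[growth_year].to_numpy()
        col_t1 = piv[growth_year - 1].to_numpy()
        sp_sex = (grp.iloc[0]["species"], grp.iloc[0]["sex"])
        radius = home_range_radius(home_range_km2[sp_sex])
        best = None
        for d_idx, det in enumerate(grp.itertuples(index=False)):
            for c in candidate_buffers(det.x_km, det.y_km, radius,
                                       spacing_km=spacing_km, n_buffers=n_buffers):
                dist = np.hypot(xy[:, 0] - c.center_x, xy[:, 1] - c.center_y)
                inside = dist < radius
                b10 = float(mat10[inside].sum(axis=0).mean()) if inside.any() else 0.0
                key = (-b10, c.offset_km, d_idx)
                if best is None or key < best[0]:
                    bt = float(col_t[inside].sum())
                    bt1 = float(col_t1[inside].sum())
                    best = (key, c, d_idx, (b10, bt, bt1))
        _, c, d_idx, (b10, bt, bt1) = best
        rows.append({"bear_id": bear_id, "year": int(year),
                     "growth_year": growth_year, "b10": b10, "bt": bt,
                     "bt1": bt1, "center_x": c.center_x, "center_y": c.center_y,
                     "radius_km": radius, "detection_index": d_idx})
    return pd.DataFrame(rows)


@dataclass
class SalmonMetrics:
    """PCA of the log biomass triplet: loadings, variance shares, scores."""

    loadings: pd.DataFrame        # variables x components
    explained: np.ndarray         # variance fraction per component
    scores: pd.DataFrame          # productivity, availability per record
    means: np.ndarray
    sds: np.ndarray


def pca_metrics(records: pd.DataFrame, cols=("b10", "bt", "bt1")) -> SalmonMetrics:
    """Correlation-matrix PCA of log(x + 1) biomass variables.

    Axis 1 ("productivity") is oriented to correlate positively with
    log(B10 + 1); axis 2 ("availability") with log(Bt + 1) - log(B10 + 1).
    Scores are mean-zero and mutually orthogonal.
    """
    if len(records) < 3:
        raise ValueError("PCA needs >= 3 records")
    X = np.log1p(records[list(cols)].to_numpy(dtype=float))
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    if np.any(sds == 0):
        bad = [c for c, s in zip(cols, sds) if s == 0]
        raise ValueError(f"zero-variance column(s) for PCA: {bad}")
    Z = (X - means) / sds
    corr = (Z.T @ Z) / (len(Z) - 1)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.clip(evals[order], 0.0, None), evecs[:, order]
    scores = Z @ evecs
    # sign conventions
    targets = [X[:, 0], X[:, 1] - X[:, 0], None]
    for k, tgt in enumerate(targets[: scores.shape[1]]):
        if tgt is None:
            continue
        c = np.dot(scores[:, k] - scores[:, k].mean(), tgt - tgt.mean())
        if c < 0:
            evecs[:, k] *= -1.0
            scores[:, k] *= -1.0
    loadings = pd.DataFrame(evecs, index=list(cols),
                            columns=[f"PC{k + 1}" for k in range(evecs.shape[1])])
    score_df = pd.DataFrame({"productivity": scores[:, 0],
                             "availability": scores[:, 1]},
                            index=records.index)
    return SalmonMetrics(loadings=loadings, explained=evals / evals.sum(),
                         scores=score_df, means=means, sds=sds)
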