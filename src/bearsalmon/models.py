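"""Transformations, screening, OLS + AICc multimodel inference, and
non-parametric comparisons for hair cortisol/testosterone analyses.

The workflow mirrors standard ecological multimodel inference: variables
are transformed toward residual normality (arcsine-sqrt for proportions,
natural log or the stronger negative reciprocal for right-skewed
hormones), standardized to mean 0 / SD 1, screened for extreme values
(> 2 SD from the mean on the raw hormone scale) and collinearity
(pairwise correlations and variance inflation factors).  A priori
candidate model sets, grouped into environment / individual / combined
categories, are fitted by ordinary least squares and ranked by AICc

    AICc = -2 logL + 2k + 2k(k+1)/(n-k-1),    k = #coefficients + 1 (sigma^2),

with Akaike weights w_i = exp(-Delta_i/2)/sum exp(-Delta/2), a top set at
Delta AICc <= 2, and group-relative weights comparing the top model of
each category.  Distributional comparisons between species and sexes use
Wilcoxon rank-sum tests (Mann-Whitney form of W) with Holm-Bonferroni
step-down adjustment, plus a two-sided F ratio test for equality of
variances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "TransformSpec", "transform_variables",
    "flag_outliers", "collinearity_screen", "CollinearityReport",
    "ModelFit", "fit_ols", "RankedModels", "aicc_rank",
    "group_relative_weights", "default_model_sets",
    "TestResult", "rank_sum_test", "holm_adjust", "wilcoxon_holm",
    "variance_ratio_test",
]

TRANSFORMS = ("identity", "ln", "negative_reciprocal", "arcsine_sqrt")


@dataclass(frozen=True)
class TransformSpec:
    """Transform + standardization request for one variable."""

    transform: str = "identity"
    standardize: bool = True

    def __post_init__(self):
        if self.transform not in TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")


def _apply_transform(x: np.ndarray, name: str, spec: TransformSpec) -> np.ndarray:
    t = spec.transform
    if t == "identity":
        return x.astype(float)
    if t == "ln":
        if np.any(x <= 0):
            row = int(np.where(x <= 0)[0][0])
            raise ValueError(f"ln transform needs positive values: {name!r} row {row}")
        return np.log(x)
    if t == "negative_reciprocal":
        if np.any(x <= 0):
            row = int(np.where(x <= 0)[0][0])
            raise ValueError(f"negative reciprocal needs positive values: {name!r} row {row}")
        return -1.0 / x
    if t == "arcsine_sqrt":
        if np.any((x < 0) | (x > 1)):
            row = int(np.where((x < 0) | (x > 1))[0][0])
            raise ValueError(f"arcsine-sqrt needs values in [0, 1]: {name!r} row {row}")
        return np.arcsin(np.sqrt(x))
    raise AssertionError(t)


def transform_variables(data: pd.DataFrame, spec: Mapping[str, TransformSpec]):
    """Apply per-variable transforms, then optional standardization.

    Returns (transformed DataFrame, metadata) where metadata records the
    transform and the centring/scaling used, for inverse reporting.
    """
    out = data.copy()
    meta = {}
    for name, ts in spec.items():
        if name not in out.columns:
            raise KeyError(f"variable {name!r} not in data")
        x = _apply_transform(out[name].to_numpy(dtype=float), name, ts)
        mean = sd = None
        if ts.standardize:
            mean, sd = float(np.mean(x)), float(np.std(x, ddof=1))
            if sd == 0:
                raise ValueError(f"zero variance at standardization: {name!r}")
            x = (x - mean) / sd
        out[name] = x
        meta[name] = {"transform": ts.transform, "mean": mean, "sd": sd}
    return out, meta


def flag_outliers(values, threshold_sd: float = 2.0):
    """Partition values into kept/excluded by the |z| > threshold rule.

    The mean and sample SD (ddof=1) are computed once on the full raw
    vector — no iterative re-screening.  With SD = 0 nothing is excluded.
    Returns a boolean keep-mask aligned with ``values``.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("outlier screen needs n >= 3")
    sd = x.std(ddof=1)
    if sd == 0:
        return np.ones(x.shape, dtype=bool)
    z = np.abs(x - x.mean()) / sd
    return z <= threshold_sd


@dataclass
class CollinearityReport:
    correlations: pd.DataFrame
    vif: pd.Series
    flagged_pairs: list
    flagged_vif: list


def collinearity_screen(data: pd.DataFrame, predictors: Sequence[str],
                        r_threshold: float = 0.7,
                        vif_threshold: float = 10.0) -> CollinearityReport:
    """Pairwise Pearson correlations and VIF = 1/(1 - R^2_j).

    Perfect collinearity yields an infinite VIF with a flag, never an
    exception.
    """
    if len(predictors) < 2:
        raise ValueError("need >= 2 predictors")
    X = data[list(predictors)].to_numpy(dtype=float)
    corr = pd.DataFrame(np.corrcoef(X, rowvar=False), index=predictors,
                        columns=predictors)
    vifs = {}
    for j, name in enumerate(predictors):
        others = np.delete(X, j, axis=1)
        design = np.column_stack([np.ones(len(X)), others])
        beta, *_ = np.linalg.lstsq(design, X[:, j], rcond=None)
        resid = X[:, j] - design @ beta
        tss = np.sum((X[:, j] - X[:, j].mean()) ** 2)
        rss = float(np.sum(resid**2))
        if tss == 0 or rss / tss < 1e-12:
            vifs[name] = np.inf
        else:
            vifs[name] = float(1.0 / (rss / tss))
    vif = pd.Series(vifs, name="vif")
    pairs = [(a, b, float(corr.loc[a, b]))
             for i, a in enumerate(predictors) for b in predictors[i + 1:]
             if abs(corr.loc[a, b]) > r_threshold]
    return CollinearityReport(correlations=corr, vif=vif, flagged_pairs=pairs,
                              flagged_vif=[n for n, v in vif.items() if v > vif_threshold])


def _build_design(data: pd.DataFrame, terms: Sequence[str]) -> pd.DataFrame:
    """Design matrix with intercept; 'a:b' denotes a product interaction."""
    cols = {"Intercept": np.ones(len(data))}
    for t in terms:
        if ":" in t:
            a, b = t.split(":", 1)
            cols[t] = data[a].to_numpy(dtype=float) * data[b].to_numpy(dtype=float)
        else:
            cols[t] = data[t].to_numpy(dtype=float)
    return pd.DataFrame(cols, index=data.index)


@dataclass
class ModelFit:
    """One fitted candidate model on the standardized scale."""

    name: str
    terms: tuple
    params: pd.Series
    bse: pd.Series
    n: int
    k: int                      # coefficients + 1 for the residual variance
    llf: float                  # Gaussian log-likelihood at the MLE variance
    adj_r2: float
    category: str | None = None
    degenerate: bool = False    # zero residual SS; log-likelihood unbounded


def fit_ols(terms: Sequence[str], data: pd.DataFrame, response: str,
            name: str | None = None, category: str | None = None) -> ModelFit:
    """Least-squares fit of ``response ~ 1 + terms`` (terms may be empty).

    SEs come from (X'X)^-1 sigma-hat^2; the log-likelihood is evaluated
    at the ML variance estimate; rank deficiency raises an error naming
    the aliased terms.
    """
    X = _build_design(data, terms)
    y = data[response].to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"n = {n} too small for {p} coefficients")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < p:
        # identify aliased columns via pivoted QR of the design
        from scipy.linalg import qr as _qr
        _, _, pivot = _qr(X.to_numpy(), pivoting=True)
        aliased = [X.columns[i] for i in pivot[rank:]]
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")
    res = sm.OLS(y, X).fit()
    ssr = float(np.sum(res.resid**2))
    tss = float(np.sum((y - y.mean()) ** 2))
    degenerate = ssr <= 1e-12 * max(tss, 1.0)
    llf = np.inf if degenerate else float(res.llf)
    adj_r2 = float(res.rsquared_adj) if tss > 0 else np.nan
    return ModelFit(name=name or ("~1" if not terms else "+".join(terms)),
                    terms=tuple(terms), params=res.params, bse=res.bse,
                    n=n, k=p + 1, llf=llf, adj_r2=adj_r2,
                    category=category, degenerate=degenerate)


def aicc_of(fit: ModelFit) -> float:
    n, k = fit.n, fit.k
    if n - k - 1 <= 0:
        return np.nan
    return -2.0 * fit.llf + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass
class RankedModels:
    """A candidate set ranked by AICc."""

    table: pd.DataFrame          # name, category, k, n, aicc, delta, weight, adj_r2
    fits: dict
    delta_threshold: float = 2.0

    @property
    def top_set(self) -> pd.DataFrame:
        return self.table[self.table["delta"] <= self.delta_threshold]

    @property
    def best(self) -> ModelFit:
        return self.fits[self.table.iloc[0]["name"]]


def aicc_rank(fits: Sequence[ModelFit], delta_threshold: float = 2.0) -> RankedModels:
    """Rank fits by AICc; Delta, Akaike weights, top set at Delta <= threshold.

    Models with n - k - 1 <= 0 are dropped with a logged warning.  All
    fits must share the same rows and response.
    """
    kept = []
    for f in fits:
        if f.n - f.k - 1 <= 0:
            logger.warning("model %s dropped: n - k - 1 <= 0 (n=%d, k=%d)",
                           f.name, f.n, f.k)
            continue
        kept.append(f)
    if not kept:
        raise ValueError("no rankable models")
    if len({f.n for f in kept}) != 1:
        raise ValueError("all fits must use identical rows")
    rows = [{"name": f.name, "category": f.category, "k": f.k, "n": f.n,
             "aicc": aicc_of(f), "adj_r2": f.adj_r2} for f in kept]
    tab = pd.DataFrame(rows)
    best = tab["aicc"].min()
    tab["delta"] = tab["aicc"] - best
    with np.errstate(over="ignore"):
        rel = np.exp(-0.5 * tab["delta"].to_numpy())
    rel = np.where(np.isnan(rel), 0.0, rel)
    tab["weight"] = rel / rel.sum()
    tab = tab.sort_values(["aicc", "name"], kind="mergesort").reset_index(drop=True)
    return RankedModels(table=tab, fits={f.name: f for f in kept},
                        delta_threshold=delta_threshold)


def group_relative_weights(rankings: Mapping[str, RankedModels]) -> pd.DataFrame:
    """Relative weight of each category's top model.

    For each category the top model keeps the Akaike weight from its own
    ranking; omega_c = w_c / sum_c' w_c', reported in percent with the
    category's model count.  Empty categories are excluded with a warning.
    """
    rows = []
    for cat, ranked in rankings.items():
        if ranked is None or len(ranked.table) == 0:
            logger.warning("category %s empty; excluded from group weights", cat)
            continue
        top = ranked.table.iloc[0]
        rows.append({"category": cat, "model": top["name"],
                     "weight": float(top["weight"]),
                     "n_models": len(ranked.table),
                     "adj_r2": float(top["adj_r2"])})
    if not rows:
        raise ValueError("no non-empty categories")
    out = pd.DataFrame(rows)
    out["omega_pct"] = 100.0 * out["weight"] / out["weight"].sum()
    return out


def default_model_sets(predictors: Sequence[str]) -> dict:
    """A priori candidate sets built from the available predictors.

    Categories follow the environment / individual / combined scheme.
    ``predictors`` may include: productivity, availability, consumption,
    other_hormone, year dummies (year_*), density.  Only models whose
    terms are all available are emitted; an intercept-only model is
    included in every category.  Interaction models deliberately drop a
    main effect relative to the full additive model, so no candidate is a
    strict superset of another's term set plus interactions.
    """
    avail = set(predictors)
    year_terms = sorted(t for t in avail if t.startswith("year_"))

    def filt(models):
        out = {}
        for name, terms in models:
            if all(all(part in avail for part in t.split(":")) for t in terms):
                out[name] = list(terms)
        return out

    env = [("intercept_only", []),
           ("productivity", ["productivity"]),
           ("availability_", ["availability"]),
           ("prod+avail", ["productivity", "availability"]),
           ("prod*avail", ["productivity", "availability",
                           "productivity:availability"])]
    env2 = [("env2_intercept", [])]
    if year_terms:
        env2.append(("year", list(year_terms)))
    if "density" in avail:
        env2.append(("density_", ["density"]))
    if year_terms and "density" in avail:
        env2.append(("year+density", list(year_terms) + ["density"]))
    ind = [("ind_intercept", []),
           ("consumption", ["consumption"]),
           ("other_hormone", ["other_hormone"]),
           ("consumption+hormone", ["consumption", "other_hormone"])]
    comb = [("comb_intercept", []),
            ("additive_full", ["productivity", "availability", "consumption",
                               "other_hormone"]),
            ("avail*consumption", ["availability", "consumption",
                                   "availability:consumption"]),
            ("avail*hormone", ["availability", "other_hormone",
                               "availability:other_hormone"]),
            ("prod*avail+consumption", ["productivity", "availability",
                                        "productivity:availability", "consumption"])]
    sets = {"environment": filt(env), "individual": filt(ind),
            "combined": filt(comb)}
    env2_f = filt(env2)
    if len(env2_f) > 1:
        sets["environment2"] = env2_f
    return sets


@dataclass
class TestResult:
    """One hypothesis test with multiplicity bookkeeping."""

    name: str                  # comparison label
    statistic_name: str        # "W" or "F"
    statistic: float
    df: tuple | None
    p_raw: float
    p_adjusted: float | None = None
    family_size: int | None = None
    method: str | None = None
    flag: str | None = None


def rank_sum_test(x, y) -> TestResult:
    """Two-sided Wilcoxon rank-sum with the Mann-Whitney W convention.

    W = (midrank sum of sample 1) - n1(n1+1)/2.  Exact p by enumeration
    when n1 + n2 <= 12 and there are no ties, else normal approximation
    with tie and continuity corrections.  All-tied samples give p = 1
    with a flag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    ties = len(np.unique(combined)) < combined.size
    if np.all(combined == combined[0]):
        w = x.size * y.size / 2.0
        return TestResult(name="", statistic_name="W", statistic=w, df=None,
                          p_raw=1.0, method="degenerate", flag="all values tied")
    method = "exact" if (x.size + y.size <= 12 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return TestResult(name="", statistic_name="W", statistic=float(res.statistic),
                      df=None, p_raw=float(res.pvalue), method=method)


def holm_adjust(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """Holm-Bonferroni step-down adjusted p values.

    Sorted ascending, adjusted_(i) = max_{j<=i} (m - j + 1) p_(j), capped
    at 1; ``m`` defaults to the number of p values (pass a larger family
    size to reproduce P_adj(m)-style reporting).
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    m = int(m) if m is not None else p.size
    if m < p.size:
        raise ValueError("family size m cannot be smaller than the number of tests")
    order = np.argsort(p, kind="mergesort")
    adj_sorted = np.maximum.accumulate((m - np.arange(p.size)) * p[order])
    adj = np.empty_like(p)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def wilcoxon_holm(groups: Mapping[str, tuple], m: int | None = None) -> list:
    """Rank-sum tests for a family of comparisons with Holm adjustment.

    ``groups`` maps a comparison label to an (x, y) pair.  The family
    size ``m`` defaults to the number of comparisons and is recorded on
    each result (the P_adj(m) convention).
    """
    labels = list(groups)
    results = []
    for lab in labels:
        x, y = groups[lab]
        r = rank_sum_test(x, y)
        r.name = lab
        results.append(r)
    fam = m if m is not None else len(results)
    adj = holm_adjust([r.p_raw for r in results], m=fam)
    for r, a in zip(results, adj):
        r.p_adjusted = float(a)
        r.family_size = fam
    return results


@dataclass
class HormoneAnalysis:
    """Model-selection results for one species x response."""

    species: str
    response: str
    n: int
    excluded: list
    ranked: RankedModels                  # union of all categories
    per_category: dict                    # category -> RankedModels
    group_weights: pd.DataFrame
    coefficients: pd.DataFrame            # top-set standardized estimates +- SE
    transform_meta: dict = field(default_factory=dict)


def _hormone_transform(species: str) -> str:
    # grizzly hormone distributions are more skewed: stronger transform
    return "negative_reciprocal" if species == "grizzly" else "ln"


def analyze_hormones(obs: pd.DataFrame, species: str, response: str,
                     delta_threshold: float = 2.0, outlier_sd: float = 2.0,
                     model_sets: Mapping[str, Mapping[str, list]] | None = None,
                     males_only: bool = True) -> HormoneAnalysis:
    """Full model-selection stage for one species and hormone response.

    ``obs`` needs columns species, sex, year, cortisol, testosterone,
    p_salmon, productivity, availability and optionally density_stratum.
    Rows extreme in either raw hormone (> outlier_sd SD) are excluded;
    consumption is arcsine-sqrt transformed, hormones ln (black) or
    negative-reciprocal (grizzly); continuous variables are standardized;
    year enters as 0/1 dummies (first year as reference).  Candidate sets
    default to :func:`default_model_sets` over the available predictors.
    """
    other = "testosterone" if response == "cortisol" else "cortisol"
    sub = obs[obs["species"] == species]
    if males_only and "sex" in sub.columns:
        sub = sub[sub["sex"] == "male"]
    sub = sub.reset_index(drop=True)
    keep = flag_outliers(sub["cortisol"], outlier_sd) & \
        flag_outliers(sub["testosterone"], outlier_sd)
    excluded = [(r.bear_id, r.year) for r in sub.loc[~keep].itertuples(index=False)] \
        if "bear_id" in sub.columns else list(np.where(~keep)[0])
    sub = sub.loc[keep].reset_index(drop=True)

    ht = _hormone_transform(species)
    data = pd.DataFrame(index=sub.index)
    data["response"] = sub[response].to_numpy(dtype=float)
    data["other_hormone"] = sub[other].to_numpy(dtype=float)
    data["consumption"] = sub["p_salmon"].to_numpy(dtype=float)
    data["productivity"] = sub["productivity"].to_numpy(dtype=float)
    data["availability"] = sub["availability"].to_numpy(dtype=float)
    spec = {
        "response": TransformSpec(ht, True),
        "other_hormone": TransformSpec(ht, True),
        "consumption": TransformSpec("arcsine_sqrt", True),
        "productivity": TransformSpec("identity", True),
        "availability": TransformSpec("identity", True),
    }
    data, meta = transform_variables(data, spec)
    predictors = ["productivity", "availability", "consumption", "other_hormone"]
    if "density_stratum" in sub.columns:
        dens = (sub["density_stratum"] == "high").astype(float)
        if dens.nunique() > 1:
            data["density"] = dens.to_numpy()
            predictors.append("density")
    if "year" in sub.columns and sub["year"].nunique() > 1:
        for yr in sorted(sub["year"].unique())[1:]:
            col = f"year_{yr}"
            data[col] = (sub["year"] == yr).astype(float).to_numpy()
            predictors.append(col)

    sets = model_sets if model_sets is not None else default_model_sets(predictors)
    all_fits, per_category, seen = [], {}, set()
    for cat, models in sets.items():
        fits = [fit_ols(terms, data, "response", name=name, category=cat)
                for name, terms in models.items()]
        per_category[cat] = aicc_rank(fits, delta_threshold)
        for f in fits:  # the union ranking counts each distinct model once
            sig = tuple(sorted(f.terms))
            if sig not in seen:
                seen.add(sig)
                all_fits.append(f)
    ranked = aicc_rank(all_fits, delta_threshold)
    gw = group_relative_weights(per_category)

    coef_rows = []
    for rank_idx, row in enumerate(ranked.top_set.itertuples(index=False), start=1):
        f = ranked.fits[row.name]
        for term in f.params.index:
            if term == "Intercept":
                continue
            coef_rows.append({"model_rank": rank_idx, "model": f.name,
                              "term": term, "estimate": float(f.params[term]),
                              "se": float(f.bse[term])})
    coefficients = pd.DataFrame(coef_rows)
    return HormoneAnalysis(species=species, response=response, n=len(sub),
                           excluded=excluded, ranked=ranked,
                           per_category=per_category, group_weights=gw,
                           coefficients=coefficients, transform_meta=meta)


def variance_ratio_test(x, y) -> TestResult:
    """Two-sided F test of equal variances, F = s1^2/s2^2, df (n1-1, n2-1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need n >= 2 in both samples")
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    df = (x.size - 1, y.size - 1)
    if v2 == 0:
        return TestResult(name="", statistic_name="F", statistic=np.inf, df=df,
                          p_raw=0.0 if v1 > 0 else 1.0, flag="zero variance in sample 2")
    f = float(v1 / v2)
    cdf = stats.f.cdf(f, *df)
    p = float(min(1.0, 2.0 * min(cdf, 1.0 - cdf)))
    return TestResult(name="", statistic_name="F", statistic=f, df=df, p_raw=p)
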