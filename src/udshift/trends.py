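"""Trend models for overlap indices and individual behavioral metrics.

Overlap indices (PHR, UDOI) are regressed on year and the winter climate
index (NPI) by ordinary least squares, one model per herd x season x
index x target.  Individual-level metrics (daily movement rate, home
range size, mean elevation, habitat-use proportions) are modeled with a
linear mixed model — fixed effects for year, NPI, and the proportion of
the individual home range disturbed, and a random intercept per animal
fitted by REML.

A term is "supported" when its 95% confidence interval excludes zero.
Intervals are the fitting routine's native 95% CI (t-based for OLS,
normal for the mixed model); ``ci="wald"`` switches to beta +/- 1.96 SE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .grids import Raster
from .ud import HomeRange

METRIC_COLUMNS = ["animal_id", "herd", "season", "year", "movement_rate",
                  "home_range_km2", "elevation", "prop_conifer",
                  "prop_nonforest", "prop_disturbed", "npi"]


@dataclass
class TrendResult:
    """Coefficient table of one fitted trend model."""

    model_id: dict
    table: pd.DataFrame          # term, beta, se, ci_low, ci_high, supported
    n: int
    random_effect_var: float | None = None
    flags: dict = field(default_factory=dict)

    def term(self, name: str) -> pd.Series:
        return self.table.set_index("term").loc[name]


def home_range_disturbed_fraction(hr: HomeRange, dist: Raster) -> float:
    """Mean disturbance proportion over the home-range member cells."""
    if dist.representation != "proportion":
        raise ValueError("expected the proportion-disturbed raster, got "
                         f"{dist.representation!r}")
    if hr.grid != dist.grid:
        raise ValueError("home range and disturbance raster are not co-registered")
    if hr.n_cells == 0:
        raise ValueError("empty home range")
    return float(dist.values[hr.mask].mean())


def extract_use_metrics(track: pd.DataFrame, elevation: Raster,
                        landcover: Raster, conifer_class: int = 1,
                        nonforest_class: int = 2,
                        max_off_raster: float = 0.05) -> dict:
    """Habitat-use summaries from fix locations (points as UD surrogate).

    Returns mean elevation over fixes and the proportions of fixes in the
    conifer and nonforest land-cover classes.  Fixes outside the raster
    extent are dropped with a count; more than ``max_off_raster`` of them
    off-raster is an error.
    """
    x = track["x"].to_numpy(dtype=float)
    y = track["y"].to_numpy(dtype=float)
    elev = elevation.sample(x, y)
    lc = landcover.sample(x, y)
    off = np.isnan(elev) | np.isnan(lc)
    if off.mean() > max_off_raster:
        raise ValueError(f"{off.sum()} of {off.size} fixes fall outside the "
                         "raster extent")
    elev, lc = elev[~off], lc[~off]
    return {
        "elevation": float(elev.mean()),
        "prop_conifer": float((lc == conifer_class).mean()),
        "prop_nonforest": float((lc == nonforest_class).mean()),
        "n_off_raster": int(off.sum()),
    }


def remove_hr_outlier(records: pd.DataFrame, col: str = "home_range_km2",
                      ) -> tuple[pd.DataFrame, list]:
    """Drop home-range sizes more than double all other home ranges.

    A record is an outlier when its size exceeds twice the maximum of the
    remaining records; the rule is reapplied until stable.  Returns the
    cleaned frame and the list of removed sizes.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 records for outlier screening")
    out = records.copy()
    removed: list[float] = []
    while len(out) >= 2:
        sizes = out[col].to_numpy(dtype=float)
        top = np.argmax(sizes)
        rest_max = np.max(np.delete(sizes, top))
        if sizes[top] > 2.0 * rest_max:
            removed.append(float(sizes[top]))
            out = out.drop(out.index[top])
        else:
            break
    return out, removed


def vif_screen(design: pd.DataFrame, threshold: float = 3.0) -> pd.DataFrame:
    """Pairwise variance inflation factors, VIF = 1 / (1 - r^2).

    Returns one row per predictor pair with columns ``a, b, r, vif,
    passed``; the screen passes when every pairwise VIF is below the
    threshold (predictors may then enter the same model).
    """
    cols = list(design.columns)
    for c in cols:
        if design[c].nunique() <= 1:
            raise ValueError(f"constant predictor column {c!r}")
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            r = float(np.corrcoef(design[a], design[b])[0, 1])
            vif = 1.0 / (1.0 - r * r) if abs(r) < 1 else np.inf
            rows.append({"a": a, "b": b, "r": r, "vif": vif,
                         "passed": vif < threshold})
    return pd.DataFrame(rows)


def _coef_table(params, bse, conf, ci: str) -> pd.DataFrame:
    if ci == "wald":
        lo, hi = params - 1.96 * bse, params + 1.96 * bse
    else:
        lo, hi = conf[0], conf[1]
    tab = pd.DataFrame({
        "term": params.index, "beta": params.to_numpy(),
        "se": bse.to_numpy(), "ci_low": np.asarray(lo, dtype=float),
        "ci_high": np.asarray(hi, dtype=float),
    })
    tab["supported"] = (tab["ci_low"] > 0) | (tab["ci_high"] < 0)
    return tab


def ols_trend(records: pd.DataFrame, response: str = "value",
              terms: tuple[str, ...] = ("year", "npi"), ci: str = "t",
              model_id: dict | None = None) -> TrendResult:
    """Multiple linear regression of an overlap index on year and climate."""
    n = len(records)
    if n < len(terms) + 2:
        raise ValueError(f"n={n} too small for {len(terms)} terms")
    X = sm.add_constant(records[list(terms)].astype(float), has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(f"rank-deficient design: collinear terms among {terms}")
    fit = sm.OLS(records[response].astype(float), X).fit()
    conf = fit.conf_int(alpha=0.05)
    table = _coef_table(fit.params, fit.bse, (conf[0], conf[1]), ci)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = float(fit.rsquared)
    return TrendResult(model_id or {}, table, n,
                       flags={"r2": r2 if np.isfinite(r2) else None})


def lmm_trend(records: pd.DataFrame, response: str,
              terms: tuple[str, ...] = ("year", "npi", "prop_disturbed"),
              group: str = "animal_id", ci: str = "native",
              model_id: dict | None = None) -> TrendResult:
    """Linear mixed model with a random intercept per individual (REML).

    The random intercept absorbs between-animal differences in behavior
    and local landscape composition.  Singular (boundary) fits are
    reported in ``flags`` rather than silently accepted.
    """
    groups = records[group]
    sizes = groups.value_counts()
    if len(sizes) < 2:
        raise ValueError("mixed model requires >= 2 individuals")
    if (sizes < 2).all():
        raise ValueError("each individual has a single record; "
                         "random intercept is not identifiable")
    X = sm.add_constant(records[list(terms)].astype(float), has_constant="add")
    model = sm.MixedLM(records[response].astype(float), X, groups=groups)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True)
    fe = fit.fe_params
    bse = fit.bse_fe
    conf = fit.conf_int().loc[fe.index]
    table = _coef_table(fe, bse, (conf[0], conf[1]), ci if ci != "native" else "t")
    re_var = float(np.asarray(fit.cov_re)[0, 0])
    flags = {"converged": bool(fit.converged),
             "singular": re_var < 1e-8 * float(fit.scale)}
    return TrendResult(model_id or {}, table, len(records), re_var, flags)


def overlap_trends(overlap: pd.DataFrame, climate: pd.Series,
                   baseline_years: tuple[int, int] = (2006, 2013),
                   ci: str = "t") -> pd.DataFrame:
    """Fit OLS year/NPI trends for every (herd, season, index, target).

    ``climate`` maps year -> NPI.  Returns a tidy coefficient table with
    a ``supported`` flag (95% CI excludes zero).
    """
    rows = []
    df = overlap.copy()
    df["npi"] = df["year"].map(climate)
    for (herd, season, index, target), g in df.groupby(
            ["herd", "season", "index", "target"]):
        if len(g) < 4:
            continue
        res = ols_trend(g, "value", ("year", "npi"), ci=ci)
        for _, row in res.table.iterrows():
            rows.append({"herd": herd, "season": season, "index": index,
                         "target": target, "term": row["term"],
                         "beta": row["beta"], "se": row["se"],
                         "ci_low": row["ci_low"], "ci_high": row["ci_high"],
                         "supported": bool(row["supported"]), "n": res.n})
    return pd.DataFrame(rows)


def metric_trends(metrics: pd.DataFrame,
                  responses: tuple[str, ...] = ("movement_rate",
                                                "home_range_km2", "elevation",
                                                "prop_conifer", "prop_nonforest"),
                  terms: tuple[str, ...] = ("year", "npi", "prop_disturbed"),
                  ci: str = "native") -> pd.DataFrame:
    """Per herd x season x response mixed-model coefficient table."""
    rows = []
    for (herd, season), g in metrics.groupby(["herd", "season"]):
        usable = [t for t in terms if g[t].nunique() > 1]
        for resp in responses:
            if g[resp].nunique() <= 1 or len(g) < len(usable) + 3:
                continue
            try:
                res = lmm_trend(g, resp, tuple(usable), ci=ci)
            except (ValueError, np.linalg.LinAlgError):
                continue
            for _, row in res.table.iterrows():
                rows.append({"herd": herd, "season": season, "response": resp,
                             "term": row["term"], "beta": row["beta"],
                             "se": row["se"], "ci_low": row["ci_low"],
                             "ci_high": row["ci_high"],
                             "supported": bool(row["supported"]),
                             "re_var": res.random_effect_var, "n": res.n})
    return pd.DataFrame(rows)
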