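"""Per-year HFA estimation, trend regression, and the stability trade-off.

Within a single year the yield model loses its year terms and becomes
``yield = genotype + site + HFA · is_home + ε``.  Yearly response
distributions in trial data are often skewed (weather shocks hit sites
asymmetrically), so the per-year fit uses median (LAD) quantile regression,
with standard errors from a case bootstrap.  The resulting HFA-by-year
series is then regressed on calendar year by OLS to test for a secular
change in local adaptation; the same trend machinery serves the yearly
mean-yield series.  The stability regression quantifies the
specialist/generalist trade-off: varieties with a larger home advantage
tend to have more variable relative yields across environments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .home import HomeMap, relative_yields
from .lm import build_design, median_quantile_regression
from .model import HOME_TERM
from .trials import TrialDataset

logger = logging.getLogger(__name__)

YEARLY_TERMS = ["genotype", "site"]


@dataclass
class YearlyHfa:
    """Per-year HFA estimates from median quantile regression.

    ``table`` is indexed by year with columns ``estimate`` (Mg·ha⁻¹), ``se``
    (case-bootstrap SE; NaN when the bootstrap is disabled) and
    ``n_home_records``.  ``skipped`` lists years without an estimable home
    indicator.
    """

    table: pd.DataFrame
    skipped: list[int]

    @property
    def estimates(self) -> pd.Series:
        return self.table["estimate"]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="year")


def _fit_one_year(frame: pd.DataFrame, is_home: np.ndarray) -> float | None:
    dframe = frame.copy()
    dframe["genotype"] = dframe["variety"]
    X, names = build_design(dframe, YEARLY_TERMS, {HOME_TERM: is_home})
    try:
        fit = median_quantile_regression(X, dframe["yield"].to_numpy(), names)
    except ValueError:  # n <= rank: the year is too thin to estimate
        return None
    val = fit.coefficients[HOME_TERM]
    return None if not np.isfinite(val) else float(val)


def yearly_hfa(
    dataset: TrialDataset,
    home: HomeMap,
    n_boot: int = 200,
    seed: int | None = None,
) -> YearlyHfa:
    """Estimate the HFA separately in each year.

    Years where no record sits at its variety's home site (or where the
    indicator is aliased) are skipped and logged.  ``n_boot = 0`` disables
    the bootstrap; SEs are then reported as NaN.
    """
    rng = np.random.default_rng(seed)
    rows = {}
    skipped: list[int] = []
    for year, sub in dataset.frame.groupby("year", sort=True):
        sub = sub.reset_index(drop=True)
        is_home = home.is_home_indicator(sub)
        if not is_home.any():
            logger.info("year %s skipped: no at-home records", year)
            skipped.append(int(year))
            continue
        est = _fit_one_year(sub, is_home)
        if est is None:
            logger.info("year %s skipped: home indicator aliased", year)
            skipped.append(int(year))
            continue
        boots = []
        for _ in range(n_boot):
            idx = rng.integers(0, len(sub), size=len(sub))
            bsub = sub.iloc[idx].reset_index(drop=True)
            bh = home.is_home_indicator(bsub)
            if not bh.any():
                continue
            bval = _fit_one_year(bsub, bh)
            if bval is not None:
                boots.append(bval)
        se = float(np.std(boots, ddof=1)) if len(boots) > 1 else np.nan
        rows[int(year)] = {
            "estimate": est,
            "se": se,
            "n_home_records": int(is_home.sum()),
        }
    table = pd.DataFrame(rows).T
    if len(table):
        table.index.name = "year"
        table["n_home_records"] = table["n_home_records"].astype(int)
    return YearlyHfa(table=table, skipped=skipped)


@dataclass
class TrendFit:
    """OLS of a yearly series on calendar year."""

    slope: float  # response units per year
    intercept: float
    adj_r2: float
    p_slope: float
    n: int


def trend_regression(series: pd.Series) -> TrendFit:
    """Ordinary least squares of ``series`` values on their year index."""
    series = series.dropna()
    if len(series) < 3:
        raise ValueError(f"need at least 3 years, got {len(series)}")
    years = series.index.to_numpy(dtype=float)
    center = years.mean()  # centering keeps calendar years well conditioned
    X = sm.add_constant(years - center)
    res = sm.OLS(series.to_numpy(dtype=float), X).fit()
    return TrendFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0] - res.params[1] * center),
        adj_r2=float(res.rsquared_adj),
        p_slope=float(res.pvalues[1]),
        n=len(series),
    )


@dataclass
class StabilityFit:
    """Home advantage vs cross-environment variability, across varieties."""

    slope: float
    intercept: float
    r2: float
    p_slope: float
    n_varieties: int
    table: pd.DataFrame  # per-variety home_advantage, variability


def stability_regression(dataset: TrialDataset, home: HomeMap) -> StabilityFit:
    """Regress yield variability on home advantage across varieties.

    Per variety: home advantage = mean relative yield at the home site minus
    mean relative yield elsewhere; variability = sample SD of the variety's
    relative yields over all its site-year cells.  Varieties without away
    observations or with fewer than two cells are excluded (logged).
    """
    rel = relative_yields(dataset).frame
    rows = {}
    excluded = 0
    for variety, sub in rel.groupby("variety", sort=True):
        if variety not in home.home.index:
            excluded += 1
            continue
        hsite = home.home[variety]
        at_home = sub.loc[sub["site"] == hsite, "rel_yield"]
        away = sub.loc[sub["site"] != hsite, "rel_yield"]
        if len(away) == 0 or len(sub) < 2:
            excluded += 1
            continue
        rows[variety] = {
            "home_advantage": float(at_home.mean() - away.mean()),
            "variability": float(sub["rel_yield"].std(ddof=1)),
        }
    if excluded:
        logger.info("stability regression excluded %d varieties", excluded)
    table = pd.DataFrame(rows).T
    if len(table) < 3:
        raise ValueError("need at least 3 varieties with home and away records")
    x = table["home_advantage"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("degenerate input: home advantage identical across varieties")
    res = sm.OLS(table["variability"].to_numpy(dtype=float), sm.add_constant(x)).fit()
    return StabilityFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r2=float(res.rsquared),
        p_slope=float(res.pvalues[1]),
        n_varieties=len(table),
        table=table,
    )
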