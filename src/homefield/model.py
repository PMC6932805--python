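"""The home-field-advantage (HFA) model and its fitted results.

The observed yield of variety *i* at site *j* in year *k* is modelled as

    yield_ijk = genotype_i + site_j + year_k + (site:year)_jk
                + HFA · is_home_ij + ε_ijk

where ``is_home`` flags records grown at the variety's home site.  The
coefficient on ``is_home`` is the home-field advantage: the extra yield a
variety realises at its location of best relative performance beyond what
its genetic potential, the site's productivity, the year's weather and the
site-year interaction already explain.  Variety-site, variety-year and
three-way interactions are not estimable in check-variety networks (too few
replicates per variety) and are deliberately absent.

:class:`HomeFieldModel` follows the familiar model/results idiom: construct
it from a :class:`~homefield.trials.TrialDataset` (homes are assigned from
relative yields unless a :class:`~homefield.home.HomeMap` is supplied),
``fit()`` returns a :class:`HomeFieldResults` carrying the HFA estimate,
its uncertainties, information criteria against the no-home control model,
and methods for the variance partition, yearly series, trend and stability
regressions, and the within-cell permutation null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .home import HomeMap, assign_home, relative_yields
from .lm import LinearFit, build_design, fit_least_squares
from .trials import FilterRules, TrialDataset, filter_trials, read_trials

logger = logging.getLogger(__name__)

EQ1_TERMS = ["genotype", "site", "year", ("site", "year")]
HOME_TERM = "is_home"


class DegenerateDesignError(ValueError):
    """Raised when the home indicator carries no information (all zero)."""


def _design_frame(dataset: TrialDataset) -> pd.DataFrame:
    frame = dataset.frame.copy()
    frame["genotype"] = frame["variety"]
    frame["year"] = frame["year"].astype(str)  # factor, not covariate
    return frame


def fit_hfa_full(dataset: TrialDataset, home: HomeMap) -> LinearFit:
    """Fit the full model including the home-site indicator."""
    frame = _design_frame(dataset)
    is_home = home.is_home_indicator(dataset.frame)
    if not is_home.any():
        raise DegenerateDesignError(
            "no record is grown at its variety's home site; the home "
            "indicator is identically zero"
        )
    X, names = build_design(frame, EQ1_TERMS, {HOME_TERM: is_home})
    fit = fit_least_squares(X, frame["yield"].to_numpy(), names)
    if HOME_TERM in fit.aliased:
        raise DegenerateDesignError("home indicator aliased with the design")
    return fit


def fit_hfa_control(dataset: TrialDataset) -> LinearFit:
    """Fit the control model (same terms, no home indicator)."""
    frame = _design_frame(dataset)
    X, names = build_design(frame, EQ1_TERMS)
    return fit_least_squares(X, frame["yield"].to_numpy(), names)


@dataclass
class ModelComparison:
    """AIC/BIC comparison of the full (with-home) vs control model.

    Deltas are control − full, so positive values favour the home term.
    """

    aic_full: float
    aic_control: float
    bic_full: float
    bic_control: float

    @property
    def delta_aic(self) -> float:
        return self.aic_control - self.aic_full

    @property
    def delta_bic(self) -> float:
        return self.bic_control - self.bic_full


def compare_models(full: LinearFit, control: LinearFit) -> ModelComparison:
    if full.n != control.n:
        raise ValueError("models were fit to different numbers of records")
    if full.rank <= control.rank:
        raise DegenerateDesignError(
            "full model adds no estimable parameter over the control"
        )
    return ModelComparison(
        aic_full=full.aic,
        aic_control=control.aic,
        bic_full=full.bic,
        bic_control=control.bic,
    )


@dataclass
class VariancePartition:
    """Type-II sums of squares and normalized variance shares.

    In unbalanced data Type-II sums of squares need not add up to the total
    sum of squares, so ``share`` normalizes each term (and the residual)
    over ΣSS_terms + SS_residual; shares then sum to one by construction.
    Raw sums of squares are kept alongside.
    """

    table: pd.DataFrame  # index: term; columns: sum_sq, df, share, F, p

    @property
    def shares(self) -> pd.Series:
        return self.table["share"]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="term")


def _contains(parent, child) -> bool:
    """Marginality: does term ``parent`` contain factor term ``child``?"""
    if not isinstance(parent, tuple):
        return False
    return child in parent if not isinstance(child, tuple) else False


def variance_partition(
    dataset: TrialDataset, home: HomeMap | None = None, include_home: bool = False
) -> VariancePartition:
    """Type-II ANOVA of the yield model.

    Each term's SS is the residual-SS drop from adding it to the model that
    already holds every other term not containing it (marginality-respecting
    nested comparisons).  The indicator term is included when
    ``include_home`` is true.
    """
    frame = _design_frame(dataset)
    y = frame["yield"].to_numpy()
    terms: list = list(EQ1_TERMS)
    indicators = {}
    if include_home:
        if home is None:
            raise ValueError("include_home=True requires a HomeMap")
        indicators[HOME_TERM] = home.is_home_indicator(dataset.frame)
        terms.append(HOME_TERM)

    def rss_and_rank(term_subset) -> tuple[float, int]:
        sub_terms = [t for t in term_subset if t != HOME_TERM]
        sub_ind = {HOME_TERM: indicators[HOME_TERM]} if HOME_TERM in term_subset else None
        X, names = build_design(frame, sub_terms, sub_ind)
        fit = fit_least_squares(X, y, names)
        return fit.rss, fit.rank

    full_rss, full_rank = rss_and_rank(terms)
    n = len(frame)
    df_resid = n - full_rank
    rows = {}
    for term in terms:
        others = [t for t in terms if t != term and not _contains(t, term)]
        base_rss, base_rank = rss_and_rank(others)
        with_rss, with_rank = rss_and_rank(others + [term])
        ss = base_rss - with_rss
        df = with_rank - base_rank
        label = ":".join(term) if isinstance(term, tuple) else term
        if df == 0:
            logger.warning("term %s not estimable (zero df)", label)
            ss = 0.0
        rows[label] = {"sum_sq": max(ss, 0.0), "df": df}
    rows["residual"] = {"sum_sq": full_rss, "df": df_resid}
    table = pd.DataFrame(rows).T
    total = table["sum_sq"].sum()
    table["share"] = table["sum_sq"] / total
    ms_resid = full_rss / df_resid if df_resid > 0 else np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        table["F"] = (table["sum_sq"] / table["df"]) / ms_resid
    table.loc["residual", "F"] = np.nan
    from scipy import stats

    table["p"] = stats.f.sf(table["F"], table["df"], df_resid)
    table["df"] = table["df"].astype(int)
    return VariancePartition(table=table)


@dataclass
class HomeShare:
    """How much of the control model's residual SS the home term explains."""

    of_residual: float  # (RSS_control − RSS_full) / RSS_control
    of_total: float  # same numerator over the total (centred) SS
    degenerate: bool = False  # control residual SS was zero


def home_share_of_residual(dataset: TrialDataset, home: HomeMap) -> HomeShare:
    full = fit_hfa_full(dataset, home)
    control = fit_hfa_control(dataset)
    return _home_share(full, control, dataset)


def _home_share(full: LinearFit, control: LinearFit, dataset: TrialDataset) -> HomeShare:
    y = dataset.frame["yield"].to_numpy()
    tss = float(((y - y.mean()) ** 2).sum())
    num = control.rss - full.rss
    if control.rss <= 1e-12 * max(tss, 1.0):  # saturated control: nothing left
        logger.warning("control model has zero residual SS; home share set to 0")
        return HomeShare(of_residual=0.0, of_total=0.0, degenerate=True)
    return HomeShare(of_residual=num / control.rss, of_total=num / tss)


class HomeFieldModel:
    """Home-field-advantage model for a multi-environment trial dataset.

    Parameters
    ----------
    dataset
        Validated long-format trial data.
    home
        Optional precomputed home map (e.g. the generative truth in
        simulations).  When omitted, homes are assigned from within-cell
        relative yields (argmax of mean relative yield across years).
    min_cells
        Minimum number of site-year observations a variety needs to be
        assigned a home (only used when ``home`` is None).
    """

    def __init__(
        self,
        dataset: TrialDataset,
        home: HomeMap | None = None,
        min_cells: int = 1,
    ):
        if len(dataset) == 0:
            raise ValueError("empty dataset")
        self.dataset = dataset
        self.rel = relative_yields(dataset)
        self.home = home if home is not None else assign_home(self.rel, min_cells)
        self.min_cells = min_cells

    @classmethod
    def from_csv(
        cls,
        path,
        column_map=None,
        rules: FilterRules | None = None,
        min_cells: int = 1,
    ) -> "HomeFieldModel":
        """Read a trial CSV, optionally filter it, and build the model."""
        dataset = read_trials(path, column_map)
        if rules is not None:
            dataset = filter_trials(dataset, rules)
        return cls(dataset, min_cells=min_cells)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "HomeFieldModel":
        return cls(TrialDataset(frame), **kwargs)

    def fit(self) -> "HomeFieldResults":
        full = fit_hfa_full(self.dataset, self.home)
        control = fit_hfa_control(self.dataset)
        return HomeFieldResults(model=self, full=full, control=control)


@dataclass
class HomeFieldResults:
    """Fitted HFA model: estimates, uncertainties and downstream analyses."""

    model: HomeFieldModel
    full: LinearFit
    control: LinearFit
    _boot: dict = field(default_factory=dict, repr=False)

    # -- headline quantities ------------------------------------------------
    @property
    def hfa(self) -> float:
        """The home-field advantage (Mg·ha⁻¹): the is_home coefficient."""
        return float(self.full.coefficients[HOME_TERM])

    @property
    def hfa_se(self) -> float:
        """Model-based (OLS) standard error of the HFA."""
        return float(self.full.se[HOME_TERM])

    @property
    def params(self) -> pd.Series:
        return self.full.coefficients

    @property
    def bse(self) -> pd.Series:
        return self.full.se

    @property
    def aic(self) -> float:
        return self.full.aic

    @property
    def bic(self) -> float:
        return self.full.bic

    @property
    def comparison(self) -> ModelComparison:
        return compare_models(self.full, self.control)

    @property
    def mean_yield(self) -> float:
        return float(self.model.dataset.frame["yield"].mean())

    @property
    def hfa_relative(self) -> float:
        """HFA as a fraction of the dataset mean yield."""
        return self.hfa / self.mean_yield

    # -- uncertainties ------------------------------------------------------
    def bootstrap_se(self, n_boot: int = 200, seed: int | None = None) -> float:
        """Case-bootstrap SE of the HFA (records resampled within year)."""
        key = (n_boot, seed)
        if key in self._boot:
            return self._boot[key]
        rng = np.random.default_rng(seed)
        frame = self.model.dataset.frame
        groups = [sub.index.to_numpy() for _, sub in frame.groupby("year", sort=True)]
        est = []
        for _ in range(n_boot):
            idx = np.concatenate(
                [rng.choice(g, size=len(g), replace=True) for g in groups]
            )
            boot = frame.loc[idx].reset_index(drop=True)
            dframe = boot.copy()
            dframe["genotype"] = dframe["variety"]
            dframe["year"] = dframe["year"].astype(str)
            is_home = self.model.home.is_home_indicator(boot)
            if not is_home.any():
                continue
            X, names = build_design(dframe, EQ1_TERMS, {HOME_TERM: is_home})
            fit = fit_least_squares(X, dframe["yield"].to_numpy(), names)
            val = fit.coefficients[HOME_TERM]
            if np.isfinite(val):
                est.append(float(val))
        se = float(np.std(est, ddof=1)) if len(est) > 1 else np.nan
        self._boot[key] = se
        return se

    # -- downstream analyses ------------------------------------------------
    def variance_partition(self, include_home: bool = False) -> VariancePartition:
        return variance_partition(
            self.model.dataset, self.model.home, include_home=include_home
        )

    def home_share(self) -> HomeShare:
        return _home_share(self.full, self.control, self.model.dataset)

    def yearly_hfa(self, n_boot: int = 200, seed: int | None = None):
        from .yearly import yearly_hfa

        return yearly_hfa(self.model.dataset, self.model.home, n_boot=n_boot, seed=seed)

    def null_distribution(self, n_perm: int = 999, seed: int | None = None, **kw):
        from .permutation import null_distribution

        return null_distribution(
            self.model.dataset,
            n_perm=n_perm,
            seed=seed,
            min_cells=self.model.min_cells,
            **kw,
        )

    def stability(self):
        from .yearly import stability_regression

        return stability_regression(self.model.dataset, self.model.home)

    def mean_yield_trend(self):
        from .yearly import trend_regression

        frame = self.model.dataset.frame
        series = frame.groupby("year")["yield"].mean()
        return trend_regression(series)

    # -- reporting ----------------------------------------------------------
    def summary(self) -> str:
        cmp_ = self.comparison
        share = self.home_share()
        lines = [
            "Home Field Advantage Model",
            "=" * 60,
            f"records: {self.full.n}    varieties: {len(self.model.dataset.varieties)}"
            f"    sites: {len(self.model.dataset.sites)}"
            f"    years: {len(self.model.dataset.years)}",
            f"site-years: {self.model.dataset.n_cells}"
            f"    model rank: {self.full.rank}",
            "-" * 60,
            f"HFA (is_home coef):    {self.hfa: .4f} Mg/ha"
            f"   (model SE {self.hfa_se:.4f})",
            f"mean yield:            {self.mean_yield: .4f} Mg/ha"
            f"   (HFA = {100 * self.hfa_relative:.1f}% of mean)",
            f"AIC  full / control:   {self.aic:.1f} / {cmp_.aic_control:.1f}"
            f"   (delta {cmp_.delta_aic:.1f})",
            f"BIC  full / control:   {self.bic:.1f} / {cmp_.bic_control:.1f}"
            f"   (delta {cmp_.delta_bic:.1f})",
            f"home share of control residual SS: {100 * share.of_residual:.1f}%",
            f"home share of total SS:            {100 * share.of_total:.1f}%",
            "=" * 60,
        ]
        return "\n".join(lines)

    def plot_yearly(self, yearly=None, null_summary=None, ax=None):
        """Yearly HFA series with optional permutation-null envelopes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if yearly is None:
            yearly = self.yearly_hfa(n_boot=0)
        tbl = yearly.table
        ax.errorbar(
            tbl.index, tbl["estimate"], yerr=tbl["se"], fmt="o-", label="observed HFA"
        )
        if null_summary is not None:
            q = null_summary.quantiles
            for prob in q.columns:
                ax.plot(q.index, q[prob], color="gray", lw=1, alpha=0.6)
        ax.axhline(0.0, color="k", lw=0.5)
        ax.set_xlabel("year")
        ax.set_ylabel("home field advantage (Mg/ha)")
        ax.legend()
        return ax
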