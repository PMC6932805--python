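"""The yield model: HFA estimation, model comparison, variance partition."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
import statsmodels.formula.api as smf

from homefield import (
    DegenerateDesignError,
    HomeFieldModel,
    SynthParams,
    TrialDataset,
    compare_models,
    fit_hfa_control,
    fit_hfa_full,
    generate_trials,
    home_share_of_residual,
    variance_partition,
)

from conftest import make_dataset


def test_noise_free_additive_data_has_zero_hfa():
    """Without GxE there is nothing to unlock: the home coefficient is 0."""
    params = SynthParams(
        delta=0.0, sigma_sy=0.0, sigma_e=0.0, sigma_gs=0.0, trend=0.0,
        n_sites=6, n_years=6, n_regions=2, site_presence=1.0, seed=3,
    )
    ds, truth = generate_trials(params)
    res = HomeFieldModel(ds, home=truth.home_map()).fit()
    assert res.hfa == pytest.approx(0.0, abs=1e-8)
    # estimated homes are all ties here (identical relative yields at every
    # site), so the argmax indicator degenerates into a site contrast and
    # the model refuses it loudly rather than reporting an arbitrary number
    with pytest.raises(DegenerateDesignError):
        HomeFieldModel(ds).fit()


def test_planted_premium_recovered_with_true_homes():
    """Planted delta = 1.5 is recovered when the model is told the truth."""
    params = SynthParams(
        delta=1.5, sigma_e=0.5, site_presence=1.0, trend=0.0,
        n_sites=12, n_years=12, n_regions=3, varieties_per_cell=6,
        years_per_variety=3, seed=11,
    )
    ds, truth = generate_trials(params)
    assert len(ds) > 800
    res = HomeFieldModel(ds, home=truth.home_map()).fit()
    assert res.hfa == pytest.approx(1.5, abs=3 * res.hfa_se)


def test_all_away_home_map_is_degenerate():
    ds = make_dataset([("A", "S1", 2001, 10.0), ("B", "S1", 2001, 12.0)])
    from homefield import HomeMap

    fake = HomeMap(home=pd.Series({"A": "S9", "B": "S9"}))
    with pytest.raises(DegenerateDesignError):
        fit_hfa_full(ds, fake)


def test_compare_models_guards():
    params = SynthParams(n_sites=5, n_years=4, n_regions=1, seed=0,
                         site_presence=1.0)
    ds, truth = generate_trials(params)
    full = fit_hfa_full(ds, truth.home_map())
    control = fit_hfa_control(ds)
    cmp_ = compare_models(full, control)
    assert cmp_.delta_aic == pytest.approx(control.aic - full.aic)
    # identical fits (home term effectively absent) must not pass silently
    with pytest.raises(DegenerateDesignError):
        compare_models(control, control)
    # differing n is an error
    ds2 = TrialDataset(ds.frame.iloc[:-1])
    with pytest.raises(ValueError, match="different"):
        compare_models(full, fit_hfa_control(ds2))


def test_delta_aic_favors_home_term_under_alternative():
    """With a real premium the home model wins on AIC in >= 95% of seeds."""
    wins = 0
    for seed in range(100):
        params = SynthParams(
            delta=2.0, sigma_e=1.0, n_sites=6, n_years=5, n_regions=2,
            site_presence=1.0, trend=0.0, seed=seed,
        )
        ds, truth = generate_trials(params)
        cmp_ = compare_models(fit_hfa_full(ds, truth.home_map()),
                              fit_hfa_control(ds))
        wins += cmp_.delta_aic > 0
    assert wins >= 95


def test_single_factor_noise_free_takes_all_variance():
    rows = []
    for i, site in enumerate(["S1", "S2", "S3"]):
        for v in ["A", "B"]:
            rows.append((v, site, 2001, 10.0 + 2.0 * i))
    vp = variance_partition(make_dataset(rows))
    assert vp.shares["site"] == pytest.approx(1.0)
    assert vp.shares["genotype"] == pytest.approx(0.0, abs=1e-12)
    assert vp.shares.sum() == pytest.approx(1.0, abs=1e-9)


def test_balanced_orthogonal_type2_equals_type1_and_projection_oracle():
    rng = np.random.default_rng(8)
    rows = []
    for v in ["A", "B", "C"]:
        for site in ["S1", "S2"]:
            for year in (2001, 2002):
                rows.append((v, site, year, float(rng.normal(10, 1))))
    ds = make_dataset(rows)
    vp = variance_partition(ds)

    frame = ds.frame.copy()
    frame["genotype"] = frame["variety"]
    frame["yr"] = frame["year"].astype(str)
    ols = smf.ols("Q('yield') ~ C(genotype) + C(site) + C(yr) + C(site):C(yr)",
                  data=frame).fit()
    a1 = sm.stats.anova_lm(ols, typ=1)
    a2 = sm.stats.anova_lm(ols, typ=2)
    for label, key in [("genotype", "C(genotype)"), ("site", "C(site)"),
                       ("year", "C(yr)"), ("site:year", "C(site):C(yr)")]:
        assert vp.table.loc[label, "sum_sq"] == pytest.approx(
            a2.loc[key, "sum_sq"], abs=1e-8)
        assert a1.loc[key, "sum_sq"] == pytest.approx(
            a2.loc[key, "sum_sq"], abs=1e-8)  # orthogonality: I == II
    assert vp.table.loc["residual", "sum_sq"] == pytest.approx(
        a2.loc["Residual", "sum_sq"], abs=1e-8)


def test_variance_shares_sum_to_one_and_order_invariant(small_synth):
    ds, truth = small_synth
    vp = variance_partition(ds, truth.home_map(), include_home=True)
    assert vp.shares.sum() == pytest.approx(1.0, abs=1e-9)
    shuffled = TrialDataset(
        ds.frame.sample(frac=1, random_state=1).reset_index(drop=True)
    )
    vp2 = variance_partition(shuffled, truth.home_map(), include_home=True)
    assert np.allclose(vp.shares.to_numpy(), vp2.shares.to_numpy(), atol=1e-9)


def test_home_share_matches_definition_oracle(small_synth):
    ds, truth = small_synth
    home = truth.home_map()
    share = home_share_of_residual(ds, home)
    full = fit_hfa_full(ds, home)
    control = fit_hfa_control(ds)
    y = ds.frame["yield"].to_numpy()
    tss = ((y - y.mean()) ** 2).sum()
    assert share.of_residual == pytest.approx(
        (control.rss - full.rss) / control.rss, abs=1e-10)
    assert share.of_total == pytest.approx(
        (control.rss - full.rss) / tss, abs=1e-10)
    assert 0 <= share.of_total <= share.of_residual <= 1


def test_home_share_zero_when_control_is_saturated():
    params = SynthParams(delta=0.0, sigma_sy=0.0, sigma_e=0.0, sigma_gs=0.0,
                         trend=0.0, n_sites=4, n_years=4, n_regions=1,
                         site_presence=1.0, seed=2)
    ds, truth = generate_trials(params)
    share = home_share_of_residual(ds, truth.home_map())
    assert share.degenerate
    assert share.of_residual == 0.0


def test_selection_bias_inflates_hfa_at_delta_zero():
    """Estimating homes and the HFA from the same data biases the HFA up
    even when no premium exists (the winner's-curse the null quantifies)."""
    estimates = []
    for seed in range(50):
        params = SynthParams(delta=0.0, n_sites=6, n_years=5, n_regions=2,
                             site_presence=1.0, trend=0.0, seed=seed)
        ds, _ = generate_trials(params)
        estimates.append(HomeFieldModel(ds).fit().hfa)
    assert np.mean(estimates) > 0
    assert np.mean(estimates) > 3 * np.std(estimates) / np.sqrt(len(estimates))


def test_results_summary_mentions_key_quantities(small_synth):
    ds, _ = small_synth
    res = HomeFieldModel(ds).fit()
    text = res.summary()
    assert "HFA" in text and "AIC" in text
    assert f"{res.full.n}" in text
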