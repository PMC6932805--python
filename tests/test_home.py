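"""Within-cell standardization and home-site assignment."""

import math

import numpy as np
import pandas as pd
import pytest

from homefield import (
    HomeFieldModel,
    SynthParams,
    TrialDataset,
    assign_home,
    generate_trials,
    relative_yields,
)

from conftest import make_dataset, random_dataset


def test_z_scores_simple_cell():
    ds = make_dataset([("A", "S", 2001, 10.0), ("B", "S", 2001, 12.0),
                       ("C", "S", 2001, 14.0)])
    rel = relative_yields(ds)
    assert np.allclose(sorted(rel.frame["rel_yield"]), [-1.0, 0.0, 1.0])
    assert rel.degenerate == []


def test_zero_variance_cell_flagged():
    ds = make_dataset([("A", "S", 2001, 9.0), ("B", "S", 2001, 9.0),
                       ("C", "S", 2001, 9.0), ("A", "T", 2001, 5.0)])
    rel = relative_yields(ds)
    sub = rel.frame[rel.frame["site"] == "S"]
    assert (sub["rel_yield"] == 0).all()
    assert ("S", 2001) in rel.degenerate
    assert ("T", 2001) in rel.degenerate  # singleton cell


def test_cell_moments_against_two_pass_oracle():
    rng = np.random.default_rng(11)
    rows = []
    for c in range(200):
        site, year = f"S{c}", 2000
        for v in range(int(rng.integers(2, 7))):
            rows.append((f"V{v}", site, year, float(rng.gamma(30, 0.4))))
    ds = make_dataset(rows)
    rel = relative_yields(ds)
    for (_, _), sub in TrialDataset(rel.frame[ds.frame.columns]).cells():
        z = rel.frame.loc[sub.index, "rel_yield"].tolist()
        # independent two-pass mean/SD on plain floats
        mean = math.fsum(z) / len(z)
        sd = math.sqrt(math.fsum((x - mean) ** 2 for x in z) / (len(z) - 1))
        assert abs(mean) < 1e-9
        assert abs(sd - 1.0) < 1e-9


def test_single_site_variety_gets_that_home():
    ds = make_dataset([("A", "S1", 2001, 10.0), ("B", "S1", 2001, 12.0),
                       ("A", "S1", 2002, 10.0), ("B", "S1", 2002, 12.0)])
    home = assign_home(relative_yields(ds))
    assert home.home["A"] == "S1"
    assert home.home["B"] == "S1"


def test_argmax_of_mean_relative_yield():
    # variety A: z at site1 = {0.5, 0.7} (mean 0.6), z at site2 = {0.9}
    frame = pd.DataFrame(
        {
            "variety": ["A"] * 3 + ["B"] * 3,
            "site": ["S1", "S1", "S2"] * 2,
            "year": [2001, 2002, 2003] * 2,
            "yield": [1.0] * 6,
            "rel_yield": [0.5, 0.7, 0.9, -0.5, -0.7, -0.9],
        }
    )
    from homefield import RelativeYieldTable

    home = assign_home(RelativeYieldTable(frame=frame))
    # brute-force argmax over the mean_rel matrix
    means = frame.groupby(["variety", "site"])["rel_yield"].mean().unstack()
    assert home.home["A"] == means.loc["A"].idxmax() == "S2"
    assert home.home["B"] == "S1"
    assert home.mean_rel.loc["A", "S1"] == pytest.approx(0.6)


def test_tie_breaks_to_lexicographically_smallest_site():
    from homefield import RelativeYieldTable

    frame = pd.DataFrame(
        {
            "variety": ["A", "A"],
            "site": ["S2", "S1"],
            "year": [2001, 2002],
            "yield": [1.0, 1.0],
            "rel_yield": [0.4, 0.4],
        }
    )
    home = assign_home(RelativeYieldTable(frame=frame))
    assert home.home["A"] == "S1"


def test_min_cells_excludes_sparse_varieties():
    ds = make_dataset([("A", "S1", 2001, 10.0), ("B", "S1", 2001, 12.0),
                       ("A", "S1", 2002, 10.0), ("B", "S1", 2002, 12.0),
                       ("C", "S1", 2002, 11.0)])
    home = assign_home(relative_yields(ds), min_cells=2)
    assert "C" not in home.home.index
    assert set(home.home.index) == {"A", "B"}


@pytest.mark.parametrize("seed", range(5))
def test_home_invariant_to_per_cell_affine_transform(seed):
    rng = np.random.default_rng(seed)
    ds = random_dataset(rng, n_sites=5, n_years=4)
    base = assign_home(relative_yields(ds))
    frame = ds.frame.copy()
    for key, idx in frame.groupby(["site", "year"]).indices.items():
        a, b = rng.uniform(0.5, 3.0), rng.uniform(0.0, 5.0)
        frame.loc[frame.index[idx], "yield"] = frame.loc[frame.index[idx], "yield"] * a + b
    scaled = assign_home(relative_yields(TrialDataset(frame)))
    pd.testing.assert_series_equal(base.home, scaled.home)


def test_home_map_invariant_to_record_order():
    rng = np.random.default_rng(3)
    ds = random_dataset(rng, n_sites=5, n_years=4)
    shuffled = TrialDataset(ds.frame.sample(frac=1, random_state=9).reset_index(drop=True))
    a = assign_home(relative_yields(ds))
    b = assign_home(relative_yields(shuffled))
    pd.testing.assert_series_equal(a.home, b.home)


def test_strong_planted_home_is_recovered():
    """With delta >> residual SD and a full design, the argmax rule finds
    the true home for at least 95% of varieties."""
    # panels of 6 over 3-year tenures: small panels cap |z| at (m-1)/sqrt(m)
    # and single-year varieties give the argmax nothing to average over
    params = SynthParams(
        delta=3.0, sigma_e=0.3, sigma_gs=0.0, site_presence=1.0,
        n_sites=8, n_years=9, n_regions=2, varieties_per_cell=6,
        years_per_variety=3, seed=5, trend=0.0,
    )
    ds, truth = generate_trials(params)
    home = assign_home(relative_yields(ds))
    common = truth.home.index
    hit = np.mean([home.home[v] == truth.home[v] for v in common])
    assert hit >= 0.95


def test_home_map_tsv_export(tmp_path):
    rng = np.random.default_rng(1)
    ds = random_dataset(rng)
    home = assign_home(relative_yields(ds))
    path = tmp_path / "home.tsv"
    home.to_tsv(path)
    table = pd.read_csv(path, sep="\t")
    assert list(table.columns) == ["variety", "home_site", "mean_rel_at_home",
                                   "n_obs_at_home"]
    assert len(table) == len(home)
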