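"""Trial-table I/O, validation and inclusion-filter behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from homefield import (
    FilterRules,
    TrialDataError,
    filter_trials,
    read_trials,
    write_trials,
)

from conftest import make_dataset, random_dataset


def test_header_only_csv_gives_empty_dataset(tmp_path):
    path = tmp_path / "empty.csv"
    path.write_text("variety,site,year,yield\n")
    assert len(read_trials(path)) == 0


def test_column_map_roundtrip(tmp_path):
    path = tmp_path / "toy.csv"
    path.write_text(
        "Hybrid,Location,Season,BuAc\nA,Urbana,2001,10.5\nB,Urbana,2001,9.0\nA,Dekalb,2002,11.25\n"
    )
    ds = read_trials(
        path,
        column_map={"variety": "Hybrid", "site": "Location", "year": "Season",
                    "yield": "BuAc"},
    )
    assert len(ds) == 3
    assert ds.varieties == ["A", "B"]
    assert ds.frame.loc[2, "yield"] == 11.25

    out = tmp_path / "out.csv"
    write_trials(ds, out)
    again = read_trials(out)
    assert again == ds  # bit-for-bit roundtrip of all records


def test_duplicate_key_rejected_with_key_named(tmp_path):
    path = tmp_path / "dup.csv"
    path.write_text("variety,site,year,yield\nA,X,2001,10\nA,X,2001,11\n")
    with pytest.raises(TrialDataError, match=r"'A'.*'X'.*2001"):
        read_trials(path)


@pytest.mark.parametrize(
    "body, match",
    [
        ("variety,site,year,yield\nA,X,2001,abc\n", "non-numeric"),
        ("variety,site,year,yield\nA,X,2001,-1\n", "negative"),
        ("variety,site,year,yield\nA,X,2001,\"1,5\"\n", "decimal"),
    ],
)
def test_bad_values_rejected(tmp_path, body, match):
    path = tmp_path / "bad.csv"
    path.write_text(body)
    with pytest.raises(TrialDataError, match=match):
        read_trials(path)


def test_missing_file_and_missing_column(tmp_path):
    with pytest.raises(FileNotFoundError):
        read_trials(tmp_path / "nope.csv")
    path = tmp_path / "cols.csv"
    path.write_text("variety,site,yield\nA,X,10\n")
    with pytest.raises(TrialDataError, match="year"):
        read_trials(path)


def test_all_permissive_rules_are_identity():
    rng = np.random.default_rng(7)
    ds = random_dataset(rng)
    rules = FilterRules(checks_only=False, exclude_years=frozenset(),
                        min_checks_per_cell=0, min_years_per_site=0)
    assert filter_trials(ds, rules) == ds


def test_min_checks_drops_whole_cell_only():
    rows = [
        ("A", "S1", 2001, 10.0), ("B", "S1", 2001, 11.0), ("C", "S1", 2001, 12.0),
        ("A", "S2", 2001, 10.0), ("B", "S2", 2001, 11.0),          # only 2 checks
        ("A", "S1", 2002, 10.0), ("B", "S1", 2002, 11.0), ("C", "S1", 2002, 12.0),
    ]
    ds = make_dataset(rows)
    rules = FilterRules(checks_only=False, exclude_years=frozenset(),
                        min_checks_per_cell=3, min_years_per_site=0)
    out = filter_trials(ds, rules)
    # brute-force recount: every surviving cell keeps >= 3 distinct varieties
    for (site, year), sub in out.cells():
        assert sub["variety"].nunique() >= 3
    assert ("S2", 2001) not in {c for c, _ in out.cells()}
    assert len(out) == 6


def test_checks_only_without_column_is_config_error():
    ds = make_dataset([("A", "S1", 2001, 10.0)])
    with pytest.raises(TrialDataError, match="is_check"):
        filter_trials(ds, FilterRules(checks_only=True))


def test_exclude_years_and_min_years_per_site():
    rows = []
    for year in (2000, 2001, 2002, 2012):
        rows.append(("A", "S1", year, 10.0))
    rows.append(("A", "S2", 2000, 9.0))
    ds = make_dataset(rows)
    rules = FilterRules(checks_only=False, exclude_years=frozenset({2012}),
                        min_checks_per_cell=0, min_years_per_site=3)
    out = filter_trials(ds, rules)
    assert out.sites == ["S1"]
    assert out.years == [2000, 2001, 2002]  # 2012 removed before site-year count


@pytest.mark.parametrize("seed", range(8))
def test_filtering_is_idempotent(seed):
    rng = np.random.default_rng(seed)
    ds = random_dataset(rng, n_sites=5, n_years=4, with_checks=True)
    rules = FilterRules(checks_only=True, exclude_years=frozenset({2001}),
                        min_checks_per_cell=2, min_years_per_site=2)
    once = filter_trials(ds, rules)
    twice = filter_trials(once, rules)
    assert once == twice
    for (_, _), sub in once.cells():
        assert sub["variety"].nunique() >= 2


@st.composite
def trial_frames(draw):
    keys = draw(
        st.sets(
            st.tuples(
                st.sampled_from(["V1", "V2", "V3", "V4"]),
                st.sampled_from(["S1", "S2", "S3"]),
                st.integers(2000, 2003),
            ),
            min_size=1,
            max_size=20,
        )
    )
    yields = draw(
        st.lists(
            st.floats(0, 30, allow_nan=False, width=32),
            min_size=len(keys), max_size=len(keys),
        )
    )
    return make_dataset([(v, s, y, float(w)) for (v, s, y), w in zip(sorted(keys), yields)])


@settings(max_examples=40, deadline=None, derandomize=True)
@given(ds=trial_frames(), k=st.integers(0, 3), my=st.integers(0, 2))
def test_filter_idempotence_property(ds, k, my):
    rules = FilterRules(checks_only=False, exclude_years=frozenset({2001}),
                        min_checks_per_cell=k, min_years_per_site=my)
    once = filter_trials(ds, rules)
    assert filter_trials(once, rules) == once
    for (_, _), sub in once.cells():
        assert sub["variety"].nunique() >= k


def test_filter_can_empty_dataset_without_error():
    ds = make_dataset([("A", "S1", 2001, 10.0)])
    rules = FilterRules(checks_only=False, exclude_years=frozenset(),
                        min_checks_per_cell=5, min_years_per_site=0)
    assert len(filter_trials(ds, rules)) == 0
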