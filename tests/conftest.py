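import numpy as np
import pandas as pd
import pytest

from homefield import SynthParams, TrialDataset, generate_trials


def make_dataset(rows, **extra_cols) -> TrialDataset:
    """Build a TrialDataset from (variety, site, year, yield) tuples."""
    frame = pd.DataFrame(rows, columns=["variety", "site", "year", "yield"])
    for name, values in extra_cols.items():
        frame[name] = values
    return TrialDataset(frame)


def random_dataset(rng: np.random.Generator, n_sites=4, n_years=3, n_varieties=6,
                   with_checks=False) -> TrialDataset:
    """Small random unbalanced dataset for property checks."""
    rows = []
    seen = set()
    for site in [f"S{i}" for i in range(n_sites)]:
        for year in range(2000, 2000 + n_years):
            if rng.random() < 0.2:
                continue  # site absent that year
            k = rng.integers(1, n_varieties + 1)
            for v in rng.choice(n_varieties, size=k, replace=False):
                key = (f"V{v}", site, year)
                if key in seen:
                    continue
                seen.add(key)
                rows.append((*key, float(rng.gamma(20, 0.5))))
    if not rows:
        rows = [("V0", "S0", 2000, 10.0)]
    ds = make_dataset(rows)
    if with_checks:
        frame = ds.frame.copy()
        frame["is_check"] = True
        ds = TrialDataset(frame)
    return ds


@pytest.fixture
def small_synth():
    """A compact synthetic network used across tests (fixed seed)."""
    params = SynthParams(
        n_sites=6, n_years=6, n_regions=2, varieties_per_cell=3,
        years_per_variety=3, site_presence=1.0, trend=0.0, seed=42,
    )
    return generate_trials(params)
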