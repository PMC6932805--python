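"""Within-cell permutation null for the home-field advantage.

The permutation scheme represents a strategy-neutral counterfactual: within
every site-year cell, yields are reassigned uniformly at random among the
varieties present in that cell.  Cell-level structure (site, year and
site-year effects, within-cell spread) is preserved exactly — the yield
multiset of each cell is invariant — while any genotype-specific advantage
is destroyed.  Re-running home assignment and per-year HFA estimation on
each permuted dataset yields the null distribution of the statistic.

Note the null mean is *not* zero: the home site is chosen by the argmax of
mean relative yield and the HFA is then estimated on the same data, so pure
noise already produces a positive apparent advantage (a winner's-curse /
Beavis-type selection bias).  The permutation null quantifies exactly this
bias, which is why the observed HFA is compared against the null envelope
rather than against zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .home import assign_home, relative_yields
from .trials import TrialDataset
from .yearly import yearly_hfa

logger = logging.getLogger(__name__)

DEFAULT_PROBS = (0.05, 0.25, 0.5, 0.75, 0.95)


def permute_within_cells(
    dataset: TrialDataset, rng: np.random.Generator
) -> TrialDataset:
    """Uniformly permute yields among the varieties of each site-year cell.

    All identity fields are untouched; only the ``yield`` column moves, so
    each cell's multiset of yields is conserved by construction.
    """
    frame = dataset.frame.copy()
    y = frame["yield"].to_numpy().copy()
    # sorted group order makes the stream of rng draws deterministic
    indices = frame.groupby(["site", "year"], sort=True).indices
    for key in sorted(indices):
        idx = indices[key]
        if len(idx) > 1:
            y[idx] = y[idx[rng.permutation(len(idx))]]
    frame["yield"] = y
    return TrialDataset(frame)


@dataclass
class NullDistribution:
    """Permutation replicates of the per-year HFA.

    ``draws`` is long-format (replicate, year, estimate); each year appears
    once per replicate unless that permutation-year was skipped (logged in
    ``skipped`` as (replicate, year) pairs, never silently padded).
    """

    draws: pd.DataFrame
    n_perm: int
    seed: int | None
    skipped: list[tuple[int, int]] = field(default_factory=list)

    def per_year(self) -> dict[int, np.ndarray]:
        return {
            int(year): sub["estimate"].to_numpy()
            for year, sub in self.draws.groupby("year", sort=True)
        }

    @property
    def estimates(self) -> np.ndarray:
        return self.draws["estimate"].to_numpy()

    def to_tsv(self, path) -> None:
        self.draws.to_csv(path, sep="\t", index=False)


def null_distribution(
    dataset: TrialDataset,
    n_perm: int = 999,
    n_boot: int = 0,
    seed: int | None = None,
    min_cells: int = 1,
) -> NullDistribution:
    """Build the within-cell permutation null of the yearly HFA.

    Each replicate permutes yields within cells, re-assigns home sites on
    the permuted data (same ``min_cells`` and tie-break as the observed
    analysis), and re-estimates the per-year HFA.  Replicates are driven by
    independent substreams spawned from the master seed, so results do not
    depend on execution order.  Bootstrap SEs inside the null are off by
    default (``n_boot = 0``) and the estimates are unaffected by them.
    """
    if n_perm < 0:
        raise ValueError("n_perm must be >= 0")
    streams = np.random.SeedSequence(seed).spawn(n_perm)
    rows = []
    skipped: list[tuple[int, int]] = []
    for rep, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        permuted = permute_within_cells(dataset, rng)
        home = assign_home(relative_yields(permuted), min_cells=min_cells)
        yh = yearly_hfa(permuted, home, n_boot=n_boot,
                        seed=rng.integers(2**31) if n_boot else None)
        for year, row in yh.table.iterrows():
            rows.append(
                {"replicate": rep, "year": int(year), "estimate": row["estimate"]}
            )
        for year in yh.skipped:
            skipped.append((rep, year))
    if skipped:
        logger.info("null: %d permutation-years skipped", len(skipped))
    draws = pd.DataFrame(rows, columns=["replicate", "year", "estimate"])
    return NullDistribution(draws=draws, n_perm=n_perm, seed=seed, skipped=skipped)


@dataclass
class NullSummary:
    """Per-year quantile envelopes and tail position of the observed HFA."""

    quantiles: pd.DataFrame  # index: year; columns: probabilities
    tail: pd.Series | None  # per-year fraction of null values <= observed

    def to_tsv(self, path) -> None:
        long = self.quantiles.stack().reset_index()
        long.columns = ["year", "prob", "quantile"]
        long.to_csv(path, sep="\t", index=False)


def null_summary(
    nd: NullDistribution,
    probs=DEFAULT_PROBS,
    observed: pd.Series | None = None,
) -> NullSummary:
    """Type-7 (linear-interpolation) quantiles of the null, per year.

    When ``observed`` (year → estimate) is given, also reports the per-year
    empirical tail proportion: the fraction of null values ≤ the observed
    estimate.
    """
    if len(nd.draws) == 0:
        raise ValueError("empty null distribution")
    probs = list(probs)
    per_year = nd.per_year()
    qrows = {
        year: np.quantile(vals, probs)  # numpy default = type 7
        for year, vals in per_year.items()
    }
    quantiles = pd.DataFrame(qrows, index=probs).T.sort_index()
    quantiles.index.name = "year"
    tail = None
    if observed is not None:
        tail = pd.Series(
            {
                year: float(np.mean(per_year[year] <= observed[year]))
                for year in quantiles.index
                if year in observed.index
            },
            dtype=float,
        )
    return NullSummary(quantiles=quantiles, tail=tail)
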