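"""Relative yields and home-site assignment.

Yields are only comparable among varieties grown side by side, so every
comparison starts from *relative yields*: within each site-year cell the
yields are centred and scaled to a z-score (mean 0, sample SD 1).  Site,
year and site-year effects cancel inside a cell, leaving each variety's
standing against its cell mates.  A variety's *home site* is then the site
where its average relative yield across years is highest — the location of
best relative performance, the operational definition of its adaptive home.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trials import TrialDataset

logger = logging.getLogger(__name__)


@dataclass
class RelativeYieldTable:
    """Per-record within-cell z-scores.

    ``frame`` carries the trial columns plus ``rel_yield``; ``degenerate``
    lists the (site, year) cells where the z-score is defined as 0 because
    the cell had a single record or zero yield variance.
    """

    frame: pd.DataFrame
    degenerate: list[tuple[str, int]] = field(default_factory=list)


@dataclass
class HomeMap:
    """Per-variety home sites plus the variety × site mean relative yields.

    ``home`` maps variety → home site; ``mean_rel`` is the variety × site
    matrix of mean relative yield (NaN where unobserved); ``n_obs`` the
    matching observation counts.  ``home[v]`` maximises ``mean_rel.loc[v]``,
    ties broken toward the lexicographically smallest site identifier.
    """

    home: pd.Series
    mean_rel: pd.DataFrame | None = None
    n_obs: pd.DataFrame | None = None
    min_cells: int = 1

    def __len__(self) -> int:
        return len(self.home)

    def is_home_indicator(self, frame: pd.DataFrame) -> np.ndarray:
        """0/1 vector flagging records grown at the variety's home site."""
        homes = frame["variety"].map(self.home)
        return (homes == frame["site"]).to_numpy(dtype=float)

    def to_tsv(self, path) -> None:
        if self.mean_rel is None or self.n_obs is None:
            raise ValueError("this HomeMap carries no relative-yield matrix")
        rows = []
        for v in self.home.index:
            s = self.home[v]
            rows.append(
                {
                    "variety": v,
                    "home_site": s,
                    "mean_rel_at_home": self.mean_rel.loc[v, s],
                    "n_obs_at_home": int(self.n_obs.loc[v, s]),
                }
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def relative_yields(dataset: TrialDataset) -> RelativeYieldTable:
    """Centre and scale yields within each site-year cell.

    z = (yield − cell mean) / cell sample SD (n−1 denominator).  Cells with
    a single record or zero variance get z = 0 and are flagged degenerate.
    """
    if len(dataset) == 0:
        raise ValueError("cannot compute relative yields of an empty dataset")
    frame = dataset.frame.copy()
    grp = frame.groupby(["site", "year"])["yield"]
    mean = grp.transform("mean")
    sd = grp.transform("std")  # ddof=1; NaN for singleton cells
    z = (frame["yield"] - mean) / sd
    bad = ~np.isfinite(z) | (sd == 0)
    frame["rel_yield"] = np.where(bad, 0.0, z)
    degenerate = sorted(
        {(r.site, int(r.year)) for r in frame[bad].itertuples(index=False)}
    )
    if degenerate:
        logger.info("degenerate cells (z set to 0): %s", degenerate)
    return RelativeYieldTable(frame=frame, degenerate=degenerate)


def assign_home(rel: RelativeYieldTable, min_cells: int = 1) -> HomeMap:
    """Assign each variety the site of its maximum mean relative yield.

    Varieties observed in fewer than ``min_cells`` site-year cells are
    excluded (logged, not an error).  Mean relative yield weights each
    site-year equally.  Ties go to the lexicographically smallest site.
    """
    frame = rel.frame
    if len(frame) == 0:
        raise ValueError("empty relative-yield table")
    stats = (
        frame.groupby(["variety", "site"])["rel_yield"]
        .agg(["mean", "count"])
        .reset_index()
    )
    mean_rel = stats.pivot(index="variety", columns="site", values="mean")
    n_obs = (
        stats.pivot(index="variety", columns="site", values="count")
        .fillna(0)
        .astype(int)
    )
    total_cells = frame.groupby("variety")["rel_yield"].size()
    eligible = sorted(total_cells.index[total_cells >= min_cells])
    dropped = sorted(set(total_cells.index) - set(eligible))
    if dropped:
        logger.info(
            "%d varieties below min_cells=%d excluded from home assignment",
            len(dropped), min_cells,
        )
    homes = {}
    for v in eligible:
        row = mean_rel.loc[v].dropna()
        # idxmax on a sorted index already breaks ties lexicographically,
        # but make the rule explicit and float-noise proof
        best = row.max()
        candidates = sorted(row.index[np.isclose(row.values, best, atol=0.0)])
        homes[v] = candidates[0] if candidates else row.idxmax()
    home = pd.Series(homes, dtype=object).sort_index()
    home.index.name = "variety"
    return HomeMap(
        home=home,
        mean_rel=mean_rel.sort_index(),
        n_obs=n_obs.sort_index(),
        min_cells=min_cells,
    )
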