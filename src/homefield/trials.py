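"""Trial-data container, CSV I/O and inclusion filters for variety yield trials.

The canonical representation of a multi-environment trial (MET) is a long
table with one row per variety × site × year holding the mean plot yield in
Mg·ha⁻¹.  Check-variety trial networks are heavily unbalanced: varieties are
entered for a handful of years, sites drop in and out, and only the shared
check varieties anchor comparisons across cells (a *cell* is one site-year).
:class:`TrialDataset` wraps a validated :class:`pandas.DataFrame` in that
canonical schema and provides the cell index the downstream statistics need;
:func:`filter_trials` applies the standard inclusion rules (checks only,
excluded years, minimum checks per cell, minimum years per site).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical column names, in output order.  ``region`` and ``is_check`` are
#: optional on input and preserved when present.
CANONICAL_COLUMNS = ("variety", "site", "year", "yield", "region", "is_check")
REQUIRED_COLUMNS = ("variety", "site", "year", "yield")
KEY = ["variety", "site", "year"]


class TrialDataError(ValueError):
    """Raised when a trial table violates the canonical-schema invariants."""


@dataclass(frozen=True)
class TrialRecord:
    """One variety × site × year observation (mean plot yield, Mg·ha⁻¹)."""

    variety: str
    site: str
    year: int
    yield_mgha: float
    region: str | None = None
    is_check: bool | None = None


@dataclass(frozen=True)
class FilterRules:
    """Inclusion rules applied to a raw trial table, in a fixed order.

    Order of application: ``checks_only`` → ``exclude_years`` →
    ``min_checks_per_cell`` (drops whole site-year cells) →
    ``min_years_per_site`` (drops whole sites).  Applied in this order the
    filter is idempotent.

    Defaults reproduce the standard check-variety analysis: checks only,
    seasons 2012 and 2016 excluded, at least three distinct check varieties
    per cell, and sites represented in more than three years.
    """

    checks_only: bool = True
    exclude_years: frozenset[int] = frozenset({2012, 2016})
    min_checks_per_cell: int = 3
    min_years_per_site: int = 4

    def __post_init__(self) -> None:
        if self.min_checks_per_cell < 0 or self.min_years_per_site < 0:
            raise ValueError("filter thresholds must be non-negative")
        object.__setattr__(self, "exclude_years", frozenset(self.exclude_years))


def _validate_frame(frame: pd.DataFrame) -> pd.DataFrame:
    frame = frame.copy()
    for col in REQUIRED_COLUMNS:
        if col not in frame.columns:
            raise TrialDataError(f"missing required column {col!r}")
    frame["variety"] = frame["variety"].astype(str)
    frame["site"] = frame["site"].astype(str)
    try:
        frame["year"] = frame["year"].astype(int)
    except (TypeError, ValueError) as exc:
        raise TrialDataError(f"non-integer year value: {exc}") from exc
    y = pd.to_numeric(frame["yield"], errors="coerce")
    bad = frame.index[~np.isfinite(y)]
    if len(bad):
        raise TrialDataError(
            f"non-numeric or non-finite yield at row(s) {list(bad[:5])}"
        )
    if (y < 0).any():
        bad = frame.index[(y < 0).to_numpy()]
        raise TrialDataError(f"negative yield at row(s) {list(bad[:5])}")
    frame["yield"] = y.astype(float)
    dup = frame.duplicated(subset=KEY, keep=False)
    if dup.any():
        first = frame.loc[dup, KEY].iloc[0]
        raise TrialDataError(
            "duplicate (variety, site, year) key: "
            f"({first['variety']!r}, {first['site']!r}, {int(first['year'])})"
        )
    if "is_check" in frame.columns:
        frame["is_check"] = frame["is_check"].map(_parse_bool)
    keep = [c for c in CANONICAL_COLUMNS if c in frame.columns]
    return frame[keep].reset_index(drop=True)


def _parse_bool(value) -> bool | None:
    if pd.isna(value):
        return None
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in {"true", "t", "1", "yes", "y"}:
        return True
    if s in {"false", "f", "0", "no", "n"}:
        return False
    raise TrialDataError(f"cannot interpret is_check value {value!r}")


class TrialDataset:
    """A validated long-format MET table with a (site, year) cell index.

    Parameters
    ----------
    frame
        Long table with columns ``variety, site, year, yield`` and optionally
        ``region`` and ``is_check``.  Yields must be finite, non-negative
        decimals; the (variety, site, year) key must be unique.
    """

    def __init__(self, frame: pd.DataFrame):
        self.frame = _validate_frame(frame)

    # -- basic introspection ------------------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        if not isinstance(other, TrialDataset):
            return NotImplemented
        a = self.frame.sort_values(KEY).reset_index(drop=True)
        b = other.frame.sort_values(KEY).reset_index(drop=True)
        return a.equals(b)

    @property
    def varieties(self) -> list[str]:
        return sorted(self.frame["variety"].unique())

    @property
    def sites(self) -> list[str]:
        return sorted(self.frame["site"].unique())

    @property
    def years(self) -> list[int]:
        return sorted(self.frame["year"].unique())

    @property
    def n_cells(self) -> int:
        return len(self.frame.drop_duplicates(["site", "year"]))

    def cells(self) -> Iterable[tuple[tuple[str, int], pd.DataFrame]]:
        """Iterate over (site, year) cells in deterministic sorted order."""
        grouped = self.frame.groupby(["site", "year"], sort=True)
        for (site, year), sub in grouped:
            yield (site, int(year)), sub

    def records(self) -> Iterable[TrialRecord]:
        for row in self.frame.itertuples(index=False):
            yield TrialRecord(
                variety=row.variety,
                site=row.site,
                year=int(row.year),
                yield_mgha=float(getattr(row, "yield")),
                region=getattr(row, "region", None),
                is_check=getattr(row, "is_check", None),
            )

    # -- I/O ----------------------------------------------------------------
    def to_csv(self, path) -> None:
        write_trials(self, path)


def read_trials(path, column_map: Mapping[str, str] | None = None) -> TrialDataset:
    """Read a long-format trial CSV into a :class:`TrialDataset`.

    Parameters
    ----------
    path
        CSV file (RFC-4180, UTF-8, header row required).
    column_map
        Optional mapping from canonical names (``variety``, ``site``,
        ``year``, ``yield``, ``region``, ``is_check``) to the file's column
        names.  Unmapped canonical names are looked up verbatim.
    """
    try:
        raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    except FileNotFoundError:
        raise FileNotFoundError(f"trial file not found: {path}") from None
    column_map = dict(column_map or {})
    rename: dict[str, str] = {}
    for canonical in CANONICAL_COLUMNS:
        source = column_map.get(canonical, canonical)
        if source in raw.columns:
            rename[source] = canonical
        elif canonical in REQUIRED_COLUMNS:
            raise TrialDataError(
                f"column {source!r} (mapped to {canonical!r}) absent from "
                f"{path}; header is {list(raw.columns)}"
            )
    frame = raw.rename(columns=rename)
    # decimal point only; reject locale thousands separators outright
    if frame["yield"].astype(str).str.contains(",").any():
        raise TrialDataError("yield values must use '.' decimal separator only")
    return TrialDataset(frame)


def write_trials(dataset: TrialDataset, path) -> None:
    """Write the canonical CSV (companion of :func:`read_trials`)."""
    out = dataset.frame.copy()
    out.to_csv(path, index=False)


def filter_trials(dataset: TrialDataset, rules: FilterRules) -> TrialDataset:
    """Apply inclusion rules and return the filtered dataset.

    Rules are applied in order checks_only → exclude_years →
    min_checks_per_cell → min_years_per_site; an empty result is permitted
    (and logged), never an error.
    """
    frame = dataset.frame
    n0 = len(frame)
    if rules.checks_only:
        if "is_check" not in frame.columns:
            raise TrialDataError(
                "checks_only=True but the dataset has no is_check column"
            )
        frame = frame[frame["is_check"].fillna(False).astype(bool)]
        logger.info("checks_only: %d -> %d records", n0, len(frame))
    if rules.exclude_years:
        before = len(frame)
        frame = frame[~frame["year"].isin(rules.exclude_years)]
        logger.info("exclude_years %s: %d -> %d records",
                    sorted(rules.exclude_years), before, len(frame))
    if rules.min_checks_per_cell > 0 and len(frame):
        counts = frame.groupby(["site", "year"])["variety"].transform("nunique")
        before = len(frame)
        frame = frame[counts >= rules.min_checks_per_cell]
        logger.info("min_checks_per_cell=%d: %d -> %d records",
                    rules.min_checks_per_cell, before, len(frame))
    if rules.min_years_per_site > 0 and len(frame):
        years_per_site = frame.groupby("site")["year"].transform("nunique")
        before = len(frame)
        frame = frame[years_per_site >= rules.min_years_per_site]
        logger.info("min_years_per_site=%d: %d -> %d records",
                    rules.min_years_per_site, before, len(frame))
    if len(frame) == 0:
        logger.warning("filter_trials produced an empty dataset")
    return TrialDataset(frame.reset_index(drop=True))
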