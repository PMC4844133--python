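"""Time-binned outcome panels for the autoregression analysis.

Two outcome families are supported: the 21-point autocracy-democracy Polity
score, sampled biennially (every other year, 1898-2012 by default, because
regime change is rare), and sovereign-default event counts summed over 5-year
bins starting 1899 (default is rarer still). Each state panel has a companion
*change* panel of first differences across consecutive bins.

Panels are country x bin matrices with missingness; each bin's vector must be
aligned with the weight matrices (dropping countries missing in that bin)
before fitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .weights import InputError, NodeSet, WeightMatrix, subset_weights

logger = logging.getLogger(__name__)

#: Polity special codes for interruption / interregnum / transition — not
#: values on the -10..10 scale, treated as missing.
POLITY_SPECIAL_CODES = (-66, -77, -88)

MIN_NODES_PER_BIN = 3


class InsufficientDataError(ValueError):
    """A bin retains fewer nodes than the model can be estimated on."""


@dataclass(frozen=True)
class CountryYearTable:
    """Long-format (country, year, value) records for one data stream."""

    data: pd.DataFrame  # columns: country, year, value

    def __post_init__(self) -> None:
        df = self.data
        required = {"country", "year", "value"}
        if not required.issubset(df.columns):
            raise InputError(f"table must have columns {sorted(required)}")
        if not np.issubdtype(df["year"].dtype, np.integer):
            years = df["year"].to_numpy()
            if not np.allclose(years, np.round(years)):
                raise InputError("years must be integers")
            df = df.assign(year=df["year"].astype(int))
        if df.duplicated(["country", "year"]).any():
            raise InputError("duplicate (country, year) records")
        object.__setattr__(self, "data", df.reset_index(drop=True))


@dataclass(frozen=True)
class PanelOutcome:
    """Country x time-bin outcome matrix with missingness (NaN)."""

    nodes: NodeSet
    bins: tuple[tuple[int, int], ...]  # (start_year, width) per bin
    values: np.ndarray  # n_nodes x n_bins, NaN = missing
    variable: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.nodes), len(self.bins)):
            raise InputError(
                f"panel shape {v.shape} does not match {len(self.nodes)} nodes x {len(self.bins)} bins"
            )
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "bins", tuple(tuple(b) for b in self.bins))

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def bin_labels(self) -> list[str]:
        return [f"{s}" if w == 1 else f"{s}-{s + w - 1}" for s, w in self.bins]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.nodes.ids), columns=self.bin_labels())

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, float_format="%.12g")


def biennial_polity(table: CountryYearTable, start: int = 1898, end: int = 2012) -> PanelOutcome:
    """Sample the Polity score at every other year from ``start`` to ``end``.

    Special codes (-66 interruption, -77 interregnum, -88 transition) become
    missing; they are not values on the autocracy-democracy scale.
    """
    if start > end:
        raise InputError("start year must not exceed end year")
    years = list(range(start, end + 1, 2))
    df = table.data
    mask = ~df["value"].isin(POLITY_SPECIAL_CODES)
    lookup = df[mask].set_index(["country", "year"])["value"]
    countries = tuple(sorted(df["country"].astype(str).unique()))
    vals = np.full((len(countries), len(years)), np.nan)
    for i, c in enumerate(countries):
        for j, yr in enumerate(years):
            try:
                vals[i, j] = lookup.loc[(c, yr)]
            except KeyError:
                pass
    nodes = NodeSet(ids=countries)
    return PanelOutcome(
        nodes=nodes,
        bins=tuple((yr, 1) for yr in years),
        values=vals,
        variable="polity_state",
    )


def panel_change(p: PanelOutcome) -> PanelOutcome:
    """First differences across consecutive bins (value_t - value_{t-1}).

    Missing whenever either side is missing; the result has one fewer bin.
    """
    if p.n_bins < 2:
        raise InputError("change panel needs at least 2 bins")
    diffs = p.values[:, 1:] - p.values[:, :-1]
    variable = {
        "polity_state": "polity_change",
        "default_count": "default_change",
    }.get(p.variable, p.variable + "_change")
    return PanelOutcome(nodes=p.nodes, bins=p.bins[1:], values=diffs, variable=variable)


def bin_defaults(foreign: CountryYearTable, domestic: CountryYearTable,
                 start: int = 1899, width: int = 5,
                 end: int | None = None) -> PanelOutcome:
    """Sum foreign + domestic default event-years into fixed-width bins.

    Bin b covers years [start + width*b, start + width*b + width - 1]; only
    bins fully contained in the data span (or ``end``, when given) are kept.
    Each yearly event flag contributes 1 per stream.
    """
    if width < 1:
        raise InputError("bin width must be at least 1")
    frames = [foreign.data, domestic.data]
    combined = pd.concat(frames, ignore_index=True)
    if combined.empty:
        raise InputError("no default records supplied")
    if end is not None:
        # only bins fully contained in [start, end]
        n_bins = (int(end) - start + 1) // width
    else:
        # cover every event: include the (possibly partial) last bin
        last_year = int(combined["year"].max())
        n_bins = (last_year - start) // width + 1 if last_year >= start else 0
    if n_bins < 1:
        raise InputError("data span shorter than one bin")
    countries = tuple(sorted(combined["country"].astype(str).unique()))
    cidx = {c: i for i, c in enumerate(countries)}
    vals = np.zeros((len(countries), n_bins))
    for _, row in combined.iterrows():
        yr = int(row["year"])
        b = (yr - start) // width
        if yr < start or b >= n_bins:
            continue
        vals[cidx[str(row["country"])], b] += float(row["value"])
    nodes = NodeSet(ids=countries)
    bins = tuple((start + width * b, width) for b in range(n_bins))
    return PanelOutcome(nodes=nodes, bins=bins, values=vals, variable="default_count")


def align_bin(p: PanelOutcome, bin_index: int,
              weights: Sequence[WeightMatrix]) -> tuple[np.ndarray, list[WeightMatrix], list[str]]:
    """Extract one bin's outcome vector and node-aligned weight matrices.

    Countries missing in the bin (or absent from any weight matrix) are
    dropped; every matrix is restricted with ``subset_weights``. Raises
    :class:`InsufficientDataError` if fewer than 3 countries remain.
    """
    if not (0 <= bin_index < p.n_bins):
        raise InputError(f"bin index {bin_index} out of range")
    col = p.values[:, bin_index]
    common = set(p.nodes.ids)
    for w in weights:
        common &= set(w.nodes.ids)
    retained = [
        nid for nid, v in zip(p.nodes.ids, col)
        if np.isfinite(v) and nid in common
    ]
    if len(retained) < MIN_NODES_PER_BIN:
        raise InsufficientDataError(
            f"bin {p.bins[bin_index]} retains {len(retained)} nodes (< {MIN_NODES_PER_BIN})"
        )
    idx = p.nodes.index_of(retained)
    y = col[idx]
    sub = [subset_weights(w, retained) for w in weights]
    return y, sub, retained


# ---------------------------------------------------------------------------
# Readers for the two CSV dialects

def read_country_year_csv(path: str | Path, country_col: str = "country",
                          year_col: str = "year", value_col: str = "value") -> CountryYearTable:
    """Read a long-format country-year CSV (configurable column names)."""
    df = pd.read_csv(path)
    for col in (country_col, year_col, value_col):
        if col not in df.columns:
            raise InputError(f"missing column {col!r} in {path}")
    out = df[[country_col, year_col, value_col]].rename(
        columns={country_col: "country", year_col: "year", value_col: "value"}
    )
    out["country"] = out["country"].astype(str)
    return CountryYearTable(out)


def read_event_grid_csv(path: str | Path) -> CountryYearTable:
    """Read a countries x years grid of 0/1 event flags (wide dialect).

    The first column holds country names; remaining column headers are years.
    """
    df = pd.read_csv(path, index_col=0)
    try:
        years = [int(c) for c in df.columns]
    except ValueError as exc:
        raise InputError(f"non-year column header in event grid: {exc}") from None
    long = df.stack().reset_index()
    long.columns = ["country", "year", "value"]
    long["country"] = long["country"].astype(str)
    long["year"] = long["year"].astype(int)
    long = long[long["value"] != 0]
    return CountryYearTable(long.reset_index(drop=True))
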