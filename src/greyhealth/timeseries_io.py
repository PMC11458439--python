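"""Data model and CSV ingestion for annual expenditure series and composition tables.

The central containers are :class:`YearSeries` (one positive-valued annual
series, the original sequence a grey model is fitted to) and
:class:`CompositionTable` (per-year amounts and/or percentage shares for the
named components of a total, e.g. the government/social/out-of-pocket split of
China's total health expenditure).

The bundled fixtures ``table1``-``table3`` carry the 2012-2022 Chinese health
expenditure accounts: financing sources plus the THE/GDP ratio, the
institutional distribution (shares only), and the pharmaceutical-expenditure
composition.  Printed share columns are stored verbatim and never recomputed:
the published 2012 out-of-pocket share (31.34) disagrees with the raw division
(9656.32/28119.00 = 34.34), and every downstream variation table is built from
the printed figure.  :func:`compute_shares` exposes the recomputed pathway.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "YearSeries",
    "CompositionTable",
    "TableFormatError",
    "read_composition_csv",
    "compute_shares",
    "load_fixture",
    "write_table_csv",
    "FIXTURE_IDS",
]

#: Minimum series length accepted by the grey model.
MIN_FIT_POINTS = 4

#: Relative tolerance for row-sum == total additivity checks.
ADDITIVITY_RTOL = 1e-6

FIXTURE_IDS = ("table1", "table2", "table3")


class TableFormatError(ValueError):
    """Raised when a CSV does not conform to the composition-table layout."""


@dataclass
class YearSeries:
    """A named annual series of strictly positive currency amounts.

    The internal time index is ``t = 1`` for the first year, so a series
    starting in 2012 has 2012 at t=1 and 2023 at t=12.
    """

    name: str
    years: list[int]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.years = [int(y) for y in self.years]
        self.values = np.asarray(self.values, dtype=float)
        if len(self.years) != len(self.values):
            raise ValueError("years and values must have equal length")
        if len(self.years) == 0:
            raise ValueError(f"series {self.name!r} is empty")
        if any(b <= a for a, b in zip(self.years, self.years[1:])):
            raise ValueError(f"series {self.name!r}: years must be strictly increasing")
        if not np.all(self.values > 0):
            raise ValueError(f"series {self.name!r}: all values must be strictly positive")

    def __len__(self) -> int:
        return len(self.years)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, YearSeries):
            return NotImplemented
        return (
            self.name == other.name
            and self.years == other.years
            and np.array_equal(self.values, other.values)
        )

    def value_at(self, year: int) -> float:
        try:
            return float(self.values[self.years.index(int(year))])
        except ValueError:
            raise KeyError(f"year {year} not in series {self.name!r}") from None


@dataclass
class CompositionTable:
    """Per-year amounts and/or percentage shares of the components of a total.

    ``raw`` and ``shares`` are pandas DataFrames indexed by year with one
    column per component; either may be absent (Table 2 publishes shares
    only).  ``aux`` holds additional published series attached to the table,
    such as the GDP series recovered from the THE/GDP ratio of Table 1.
    ``non_additive_years`` lists years whose raw components do not sum to the
    stated total within a relative tolerance of 1e-6.
    """

    years: list[int]
    components: list[str]
    raw: pd.DataFrame | None = None
    shares: pd.DataFrame | None = None
    total: YearSeries | None = None
    aux: dict[str, YearSeries] = field(default_factory=dict)
    non_additive_years: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.years = [int(y) for y in self.years]
        if any(b <= a for a, b in zip(self.years, self.years[1:])):
            raise ValueError("years must be strictly increasing")
        if self.raw is None and self.shares is None:
            raise ValueError("a composition table needs raw amounts or shares")
        for df in (self.raw, self.shares):
            if df is not None and (list(df.index) != self.years or list(df.columns) != self.components):
                raise ValueError("matrix index/columns must match years/components")
        if self.shares is not None:
            vals = self.shares.to_numpy(float)
            if np.any(vals < 0) or np.any(vals > 100):
                raise ValueError("shares must lie in [0, 100]")
        if self.total is not None and self.total.years != self.years:
            raise ValueError("total must cover the same years")
        self._flag_non_additive()

    def _flag_non_additive(self) -> None:
        if self.raw is None or self.total is None:
            return
        sums = self.raw.sum(axis=1).to_numpy(float)
        tot = self.total.values
        bad = ~np.isclose(sums, tot, rtol=ADDITIVITY_RTOL, atol=0.0)
        self.non_additive_years = [y for y, b in zip(self.years, bad) if b]

    def component_series(self, name: str) -> YearSeries:
        """Raw-amount series of one component."""
        if self.raw is None:
            raise ValueError("table carries no raw amounts")
        if name not in self.components:
            raise KeyError(f"unknown component {name!r}")
        return YearSeries(name, self.years, self.raw[name].to_numpy(float))

    def share_at(self, component: str, year: int) -> float:
        """Share (%) of one component in one year, printed if available."""
        df = self.shares if self.shares is not None else self.effective_shares()
        if component not in df.columns:
            raise KeyError(f"unknown component {component!r}")
        if int(year) not in df.index:
            raise KeyError(f"year {year} not in table")
        return float(df.loc[int(year), component])

    def effective_shares(self) -> pd.DataFrame:
        """Printed shares when the table carries them, else computed shares."""
        if self.shares is not None:
            return self.shares
        total = self.total.values if self.total is not None else self.raw.sum(axis=1).to_numpy(float)
        return compute_shares(self.raw, pd.Series(total, index=self.raw.index))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CompositionTable):
            return NotImplemented

        def df_eq(a: pd.DataFrame | None, b: pd.DataFrame | None) -> bool:
            if (a is None) != (b is None):
                return False
            return a is None or a.equals(b)

        return (
            self.years == other.years
            and self.components == other.components
            and df_eq(self.raw, other.raw)
            and df_eq(self.shares, other.shares)
            and self.total == other.total
        )


def compute_shares(raw: pd.DataFrame, total: pd.Series) -> pd.DataFrame:
    """Percentage shares ``100 * raw / total``, row by row.

    Reveals discrepancies against published share columns (Table 1's 2012
    out-of-pocket row prints 31.34 where the division gives 34.34).
    """
    total = pd.Series(total)
    if not np.all(total.to_numpy(float) > 0):
        raise ValueError("totals must be strictly positive")
    return raw.div(total.to_numpy(float), axis=0) * 100.0


def read_composition_csv(path: str | Path, has_total: bool = False) -> CompositionTable:
    """Read a composition table from CSV.

    Layout: UTF-8, comma separated, header mandatory, first column ``year``
    (integer calendar years), one numeric column per component, and, when
    ``has_total`` is set, a ``total`` column.  Rows are sorted by year; shares
    are computed from the raw amounts.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise TableFormatError(f"{path}: empty file, header row required") from None
    if df.columns.empty or df.columns[0] != "year":
        raise TableFormatError(f"{path}: first column must be named 'year'")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise TableFormatError(f"{path}: non-numeric cell at row {row}, column {col!r}")
        if df[col].isna().any():
            row = int(df[col].isna().idxmax())
            raise TableFormatError(f"{path}: missing cell at row {row}, column {col!r}")
    if df["year"].duplicated().any():
        dup = int(df.loc[df["year"].duplicated(), "year"].iloc[0])
        raise TableFormatError(f"{path}: duplicate year {dup}")
    df = df.sort_values("year").set_index(df.columns[0])
    df.index = df.index.astype(int)

    components = [c for c in df.columns if c != "total"]
    if has_total:
        if "total" not in df.columns:
            raise TableFormatError(f"{path}: has_total set but no 'total' column")
        total = YearSeries("total", list(df.index), df["total"].to_numpy(float))
    else:
        total = None
    if not components:
        raise TableFormatError(f"{path}: no component columns")
    years = list(df.index)
    raw = df[components].astype(float)
    tot_vals = total.values if total is not None else raw.sum(axis=1).to_numpy(float)
    shares = compute_shares(raw, pd.Series(tot_vals, index=raw.index))
    return CompositionTable(
        years=years, components=components, raw=raw, shares=shares, total=total
    )


def write_table_csv(table, path: str | Path) -> Path:
    """Write a CompositionTable (raw + total) or any DataFrame-like table to CSV.

    Round-trips through :func:`read_composition_csv` to within 1e-9 relative.
    """
    path = Path(path)
    if isinstance(table, CompositionTable):
        if table.raw is not None:
            df = table.raw.copy()
        else:
            df = table.shares.copy()
        if table.total is not None:
            df["total"] = table.total.values
        df.index.name = "year"
        df.to_csv(path)
    elif isinstance(table, pd.DataFrame):
        table.to_csv(path)
    else:  # ProjectionTable quacks via .to_frame()
        table.to_frame().to_csv(path)
    return path


def _fixture_path(name: str):
    return resources.files("greyhealth.data").joinpath(name)


def _read_bundled(name: str) -> pd.DataFrame:
    with resources.as_file(_fixture_path(name)) as p:
        df = pd.read_csv(p)
    return df.set_index(df.columns[0])


def load_printed_table(table_id: str) -> pd.DataFrame:
    """Published results tables (``table4`` .. ``table10``) exactly as printed,
    for cell-by-cell comparison against recomputed values."""
    n = table_id.removeprefix("table")
    if n not in {"4", "5", "6", "7", "8", "9", "10"}:
        raise KeyError(f"no printed table {table_id!r}")
    return _read_bundled(f"printed_table{n}.csv")


def load_fixture(fixture_id: str) -> CompositionTable:
    """Bundled source-data tables.

    ``table1``: THE by financing source, raw amounts + printed shares + total,
    with the THE/GDP ratio and the implied GDP series in ``aux``.
    ``table2``: institutional distribution, printed shares only.
    ``table3``: pharmaceutical expenditure composition, raw + printed shares +
    total, with the pharma-share-of-THE column in ``aux``.
    """
    if fixture_id not in FIXTURE_IDS:
        raise KeyError(f"unknown fixture {fixture_id!r}; expected one of {FIXTURE_IDS}")
    df = _read_bundled(f"{fixture_id}.csv")
    df.index = df.index.astype(int)
    years = list(df.index)

    if fixture_id == "table2":
        components = list(df.columns)
        return CompositionTable(years=years, components=components, shares=df.astype(float))

    share_cols = [c for c in df.columns if c.endswith("_share")]
    components = [c.removesuffix("_share") for c in share_cols]
    raw = df[components].astype(float)
    shares = df[share_cols].astype(float)
    shares.columns = components
    total = YearSeries("total", years, df["total"].to_numpy(float))
    aux: dict[str, YearSeries] = {}
    if fixture_id == "table1":
        gdp_share = df["the_share_of_gdp"].to_numpy(float)
        aux["the_share_of_gdp"] = YearSeries("the_share_of_gdp", years, gdp_share)
        # GDP is not published directly; recover it from THE and its GDP ratio.
        aux["gdp"] = YearSeries("gdp", years, total.values / (gdp_share / 100.0))
    if fixture_id == "table3":
        aux["pharma_share_of_the"] = YearSeries(
            "pharma_share_of_the", years, df["pharma_share_of_the"].to_numpy(float)
        )
    return CompositionTable(
        years=years, components=components, raw=raw, shares=shares, total=total, aux=aux
    )
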