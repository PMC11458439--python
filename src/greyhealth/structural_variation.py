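"""Structural-variation statistics for cost-composition tables.

For a component *i* whose share of the total is ``X_i0`` at the start and
``X_i1`` at the end of a period (both in percent):

* VSV (value of structure variation) ``= X_i1 - X_i0`` — signed change in
  percentage points; positive means the component's weight grew.
* DSV (degree of structure variation) ``= sum_i |VSV_i|`` — the overall
  magnitude of compositional change for the period.
* CRSV (contribution rate of structural variation)
  ``= 100 * |VSV_i| / DSV`` — the component's slice of the total change.
* Driving force ``= CRSV * growth rate`` — contribution weighted by the
  component's compound annual growth, on the percent-times-percent scale of
  the published driving-force tables.

All operations consume printed shares when the table carries them, so
published variation tables reproduce exactly even where a printed share
disagrees with raw division.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

from .timeseries_io import CompositionTable

__all__ = [
    "VariationResult",
    "DrivingForceResult",
    "vsv",
    "dsv",
    "crsv",
    "annualized_growth_rate",
    "driving_force",
    "analyze_period",
    "analyze_consecutive",
    "driving_force_table",
]


@dataclass
class VariationResult:
    """Per-component VSV and CRSV plus the overall DSV for one period."""

    period: tuple[int, int]
    components: list[str]
    vsv: dict[str, float]
    crsv: dict[str, float]  # NaN per component when dsv == 0
    dsv: float

    def to_frame(self) -> pd.DataFrame:
        label = f"{self.period[0]}-{self.period[1]}"
        return pd.DataFrame(
            {
                "period": label,
                "component": self.components,
                "vsv": [self.vsv[c] for c in self.components],
                "crsv": [self.crsv[c] for c in self.components],
                "dsv": self.dsv,
            }
        )


@dataclass
class DrivingForceResult:
    component: str
    growth_rate_pct: float
    crsv_pct: float
    driving_force: float


def _check_share(x: float) -> float:
    x = float(x)
    if not 0.0 <= x <= 100.0:
        raise ValueError(f"share {x} outside [0, 100]")
    return x


def vsv(share_begin: float, share_end: float) -> float:
    """Signed share change in percentage points (positive = proportion grew)."""
    return _check_share(share_end) - _check_share(share_begin)


def dsv(vsvs) -> float:
    """Sum of absolute per-component VSVs; the period's overall variation."""
    vsvs = list(vsvs)
    if not vsvs:
        raise ValueError("dsv of an empty component list is undefined")
    return float(sum(abs(float(v)) for v in vsvs))


def crsv(vsv_i: float, dsv_value: float) -> float:
    """Component contribution ``100 * |vsv_i| / dsv`` in percent."""
    if dsv_value <= 0:
        raise ValueError("CRSV is undefined when DSV is zero")
    return 100.0 * abs(float(vsv_i)) / float(dsv_value)


def annualized_growth_rate(value_begin: float, value_end: float, n_years: int) -> float:
    """Compound annual growth rate in % per year over ``n_years`` years."""
    if value_begin <= 0 or value_end <= 0:
        raise ValueError("growth rate requires strictly positive values")
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    return 100.0 * ((value_end / value_begin) ** (1.0 / n_years) - 1.0)


def driving_force(crsv_pct: float, growth_rate_pct: float) -> float:
    """Product of the two percentage figures (CRSV and growth both as
    fractions, times 1e4 — the scale the published tables use)."""
    if crsv_pct < 0:
        raise ValueError("CRSV must be non-negative")
    return float(crsv_pct) * float(growth_rate_pct)


def analyze_period(table: CompositionTable, begin: int, end: int) -> VariationResult:
    """Full variation decomposition of one (begin, end) year pair.

    When DSV is zero (identical share vectors) the CRSVs are reported as NaN
    with a warning: 0/0 has no contribution semantics.
    """
    comps = table.components
    vs = {c: vsv(table.share_at(c, begin), table.share_at(c, end)) for c in comps}
    d = dsv(vs.values())
    if d > 0:
        cr = {c: crsv(vs[c], d) for c in comps}
    else:
        warnings.warn(
            f"DSV is zero for {begin}-{end}: contribution rates undefined",
            stacklevel=2,
        )
        cr = {c: math.nan for c in comps}
    return VariationResult((int(begin), int(end)), list(comps), vs, cr, d)


def analyze_consecutive(table: CompositionTable) -> list[VariationResult]:
    """One VariationResult per adjacent year pair, in chronological order."""
    if len(table.years) < 2:
        raise ValueError("need at least two years for consecutive analysis")
    return [analyze_period(table, a, b) for a, b in zip(table.years, table.years[1:])]


def driving_force_table(
    table: CompositionTable, begin: int, end: int
) -> list[DrivingForceResult]:
    """Growth rate, CRSV and driving force per component over one period.

    Requires raw amounts (growth rates are computed from component levels,
    not shares).
    """
    if table.raw is None:
        raise ValueError("driving forces need raw component amounts")
    res = analyze_period(table, begin, end)
    n_years = int(end) - int(begin)
    out = []
    for c in table.components:
        g = annualized_growth_rate(
            table.raw.loc[int(begin), c], table.raw.loc[int(end), c], n_years
        )
        out.append(DrivingForceResult(c, g, res.crsv[c], driving_force(res.crsv[c], g)))
    return out
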