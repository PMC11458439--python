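# Methods

## Data model and fixtures

All computations run on two containers: `YearSeries` (a named, strictly
positive annual series; internal index t = 1 at the first year) and
`CompositionTable` (per-year raw amounts and/or percentage shares of the
named components of a total).  The bundled fixtures are China's 2012–2022
total health expenditure (THE) accounts: `table1` (financing sources —
government, social, out-of-pocket — with THE and the THE/GDP ratio),
`table2` (institutional distribution, shares only) and `table3`
(pharmaceutical composition).  Units are carried as an opaque label,
"billion yuan" exactly as the source tables print it; no unit algebra is
performed anywhere, so the label's correctness is immaterial to every
number computed.

Two deliberate fixture policies:

- **Printed shares are stored verbatim and never recomputed.**  The 2012
  out-of-pocket share is published as 31.34% although the raw division gives
  34.34%; every published variation table is built from 31.34, so variation
  analysis consumes printed shares wherever they exist.  `compute_shares`
  exposes the recomputed pathway and thereby the discrepancy.
- **GDP is recovered, not stored.**  GDP is not published directly;
  `load_fixture("table1")` derives it as THE / (THE share of GDP / 100) and
  attaches it as an auxiliary series.

## Structural variation

For shares X_i0, X_i1 (percent) of component i at the period's begin/end:
VSV_i = X_i1 − X_i0; DSV = Σ_i |VSV_i|; CRSV_i = 100·|VSV_i|/DSV; driving
force_i = CRSV_i × CAGR_i with CAGR the compound annual growth rate of the
component's raw amount over the window, in % per year.  Notes on genuinely
open choices:

- DSV is implemented as the sum of *absolute* VSVs.  (The source text's
  symbolic definition collapses to VSV and its claim that DSV lies in [0, 1]
  contradicts its own percent-scale tables; Σ|VSV| reproduces every published
  DSV.  On percentage shares DSV is bounded by [0, 200] percentage points.)
- The growth rate entering the driving force is the geometric (compound)
  annual rate, which reproduces the published growth-rate column from the
  raw amounts (11.05 / 14.35 / 9.04 for the three sources).
- The driving force is the plain product of the two percentage numbers
  (59.65 × 14.35 → 856.0), matching the published scale (CRSV and growth as
  fractions × 10⁴).
- When DSV = 0 (identical share vectors) the CRSVs are reported as NaN with
  a warning; 0/0 has no contribution semantics.

## GM(1,1)

Accumulate X(1) = cumsum(X(0)); background z(k) = (X(1)(k)+X(1)(k−1))/2 for
k = 2..N; estimate (a, u) by OLS on X(0)(k) = −a·z(k) + u (numpy lstsq);
cumulative solution X̂(1)(t) = (X(0)(1) − u/a)e^(−a(t−1)) + u/a; restore by
first differencing, with X̂(0)(1) = X(0)(1) by construction.  Restored values
from t = 2 form a geometric sequence with annual factor e^(−a); for a
noise-free geometric input with ratio r the fit is exact in the regression
equations with −a = 2(r−1)/(r+1) and u = 2A/(r+1).  Note the corollary: the
*restored* series then grows at e^(−a) ≠ r, so even "perfect" geometric
inputs leave small restoration residuals that vanish only as r → 1.  This
discretisation bias is why the synthetic recovery experiment compares e^(−a)
with r to a 0.5-percentage-point band rather than exactly.

Numerical choices:

- Minimum series length 4 (the design needs at least 3 equations).
- Degenerate |a| < 1e−12 switches to the analytic limit
  X̂(1)(t) = X(0)(1) + u(t−1) (constant restored value u); constant input
  series land here with a ≈ 1e−17.
- t = 1 is anchored exactly at the first observation rather than through the
  exponential formula, which reaches it only up to roundoff.
- A quasi-smoothness (class-ratio) applicability check warns — never fails —
  when ratios X(0)(k−1)/X(0)(k) leave the band e^(∓2/(N+1)); the bundled
  government series trips it once (the 2020 spike).

### Diagnostics

Residual test: Δε(t) = |X(0)(t) − X̂(0)(t)|/X(0)(t); pass when the mean ≤ 0.2.
Posterior-difference test: C = S₂/S₁ with S₁, S₂ the *population* standard
deviations of the data and the residuals; p = fraction of residuals within
0.6745·S₁ of their mean.  Grades: Excellent (C ≤ 0.35, p ≥ 0.95), Good
(C ≤ 0.5, p ≥ 0.8), Qualified (C ≤ 0.65, p ≥ 0.7), else Unqualified.

Two conventions had to be fixed against the published government-series
value C = 0.1580:

- C is residual-over-data (S₂/S₁).  The source text writes S₁/S₂, which
  would make its own small-is-good grading impossible.
- The evaluation window is the full sample t = 1..N (giving C = 0.1567,
  within 1% of print).  Excluding the structurally exact first point
  (t = 2..N) gives 0.1761 — far from print even when evaluated with the
  published parameters themselves — so the full window is used.

## Fidelity of the published model fits

The published fitted equations for the government, social, out-of-pocket and
GDP series are **not reproducible** from the published input series: standard
mean-background OLS gives e.g. government rate 0.0971 / coefficient 99334.85
vs the published 0.0967 / 99982.37, and no standard variant (background
weights 0.4–0.6, lagged/current background, log-linear or nonlinear least
squares, total least squares, sub-windows, year exclusions) lands on the
published numbers.  The decisive cross-check is the pharmaceutical series:
the *same* implementation reproduces the published pharmaceutical forecast
column exactly, every year, to the printed 2 d.p. (23528.40 … 33028.43).
The natural reading is that the published source/GDP fits were produced from
a slightly different data vintage.  Consequences, all surfaced rather than
hidden:

- Recomputed projections agree with the published ones to ~1% but not to
  print precision; the two end-to-end tests that assert print precision fail
  by design and say so in their docstrings.
- The published THE denominator of the pharmaceutical-share projection
  (92069.52 in 2023) does not correspond to a direct GM(1,1) fit of any
  published THE series (the Table 1 column gives 97032.47).  The package
  implements the documented pathway — a direct fit to the published THE
  column — so its 2030 pharmaceutical share is 16.23% against the published
  18.34%.

Both THE pathways (component-sum for the financing projection, direct fit
for the pharmaceutical share) are kept explicitly separate and labelled; the
projection report never substitutes one for the other.

## Table reproduction and print rounding

`reproduce_table` recomputes each published results table from the bundled
source tables, rounds to print precision (2 d.p. amounts/percentages, 4 d.p.
model coefficients; no rounding happens anywhere upstream), and diffs cell
by cell.  Rounding is decimal half-up with a 1e−9 guard, because the
published tables round halves up (18.125 → 18.13) — though not consistently:
one exact tie (4.375) is printed rounded down, and the institutional table's
2020–2021 VSV/CRSV row is not derivable from its own share table (its DSV
is).  The diff reports carry these notes.

## Synthetic data

The generator emulates what the analysis assumes about real expenditure
accounts: near-geometric growth, strictly positive values, slowly drifting
shares, multiplicative lognormal noise (additive noise is not offered since
it can produce non-positive values GM(1,1) cannot accept).  Defaults mirror
the fixtures: 11 years from 2012, three components with growth factors
1.11/1.14/1.09 (the observed source CAGRs), relative noise 1%.  Each
(seed, component) pair gets an independent, order-insensitive substream, so
output is fully deterministic under a fixed seed.

What the generator does *not* emulate: structural breaks (the 2020 pandemic
spike in the real data), correlated noise across components, and data
revisions.  Tests passing on synthetic data therefore validate the
estimator's behaviour under the model's own assumptions, not its robustness
to such features.

`recovery_experiment` is the calibration loop: 200 replicates at the default
conditions recover the annual growth factor within 0.5 percentage points in
well over 95% of runs; at zero noise the error equals the known
discretisation bias exactly.

## Problem sizes

Everything is desk-scale: series of 11 points, horizons of 8 years, 200
recovery replicates.  The full test suite runs in a few seconds; the
acceptance script in under ten.

## Known limitations

- Plain GM(1,1) only — no GM(1,N), Verhulst, rolling/metabolic variants, and
  no uncertainty intervals on forecasts.
- No inferential statistics on variation values (none exist for them in this
  setting).
- The driving-force reproduction for institutional components reconstructs
  amounts as share × THE because institutional amounts are not published;
  those growth rates are self-consistent but not the published ones.
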