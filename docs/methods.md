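# Methods

This note documents the models, parameter defaults and numerical choices
behind `streampulse`, and what the synthetic-data experiments do and do
not demonstrate.

## Hydrological classification

Rainfall arrives as mm per 10-minute step; water level as cm every
15 minutes.  An **event** is a maximal wet spell: consecutive steps with
rain > 0, never interrupted by ≥ 2 h without rain (`event_gap`, default
2 h).  Events are **large** when the maximum intensity exceeds
`intensity_threshold` = 1 mm/10 min, else **small** — classification uses
rain intensity alone; the observation that only large events push water
levels above ~20 cm is treated as a diagnostic, not a second criterion,
to avoid circular dual definitions.  Each event carries an analysis
window from its start (3 h small / 14 h large); these windows are
attachments for downstream analysis, not part of the event boundaries.
Events touching the record edges cannot have their separating dry spell
verified and are flagged `partial` rather than dropped.

A **dry day** is a calendar day with zero rain and water-level standard
deviation ≤ `dry_level_sd_threshold`.  No published value exists for this
threshold; the default 0.5 cm is our choice (a typical gauge noise floor)
and is a plain config parameter.  Days not fully covered by both records
are never classified dry.

Grid alignment treats rainfall as an accumulation (rebinned by
interpolating the cumulative-mass curve at the target bin edges, so
totals are conserved to < 1e-9 mm for any spacing ratio) and water level
as an instantaneous state (linear interpolation).

## Species screening and the uncertainty model

All screening rules operate on the raw stored values; censored cells keep
their measured value, and substitution is context-specific:

- factorization input: x < LOQ → LOQ/2;
- composite emulation: x < LOQ → LOQ (the monitoring convention).

Per-cell uncertainty: u = √((a·x)² + LOQ²) for x > LOQ, u = ⅚·LOQ for
x ≤ LOQ (boundary in the censored branch).  The per-compound relative
error a is an input (defaults span 1–11 %); no attempt is made to
estimate it from duplicates, which this sampling design does not provide.
Signal-to-noise is the mean of d (0 below LOQ; (x−u)/u above), and the
classes are bad (S/N ≤ 0.2, excluded), weak (≤ 1, uncertainty ×3), good.

One subtlety: S/N is *not* exactly monotone decreasing in LOQ when a > 0.
As the LOQ crosses a sample's value, d jumps from 1/√(1+a²) − 1 (slightly
negative) to 0 — an upward jump of order a²/2 (≤ 0.006 at a = 0.11).  The
property tests assert exact monotonicity at a = 0 and monotonicity within
this analytic slack otherwise.

## Robust weighted factorization

The model is X ≈ G F, G ≥ 0 (n × p contributions), F ≥ 0 (p × m
profiles), minimising Q = Σ ((x − (GF))/u)².  The solver is weighted
**HALS** (hierarchical alternating least squares): each factor's profile
row and contribution column is updated by exact coordinate minimisation
under nonnegativity, so the objective is monotonically non-increasing.
The inner loop is compiled with numba; a fit of the default study shape
(≈ 2800 × 17, p = 6) takes on the order of a second.

- **Initialisation**: entries uniform on (0, 1], profile rows scaled by
  the column means of X; every run's seed is explicit (run r uses
  `random_state + r`).
- **Convergence**: relative Q change < 1e-8 over 10 consecutive sweeps,
  capped at 5000 sweeps.
- **Floor**: entries are projected to a tiny positive floor (1e-12 of the
  data scale); a factor that still collapses to the floor everywhere is
  re-seeded once and reported, never silently accepted.
- **Robust mode**: from the fourth sweep on, any cell with scaled
  residual |e/u| > 4 has its weight capped at (4/|e|)² — equivalently its
  effective uncertainty inflated to |e|/4.  This bounds each cell's
  objective contribution (a redescending M-loss whose reweighted updates
  stay monotone) and, crucially, engages *during* optimisation: applying
  it only after a plain least-squares fit lets a gross outlier be
  absorbed into G first and then protects that solution.  The reported
  Q_robust excludes the flagged cells entirely; Q_true reports the full
  sum.  Runs are compared by the *capped* objective
  (Q_robust + 16·#outliers), which is comparable across runs that
  exclude different numbers of cells.
- **Multi-start**: 20 runs by default; the stability report is the
  relative spread (max − min)/median of per-run Q_robust.
- **Factor number**: the scan fits each p in a range and reports
  Q_robust, Q_exp = n·m_good − p(n + m_good) and their ratio.  Selection
  is the analyst's; `detect_elbow` automates the obvious heuristic
  (maximum second difference of log Q over p) for the recovery
  experiments and the run report.
- **Scale ambiguity** is left in the G·F product (no row normalisation);
  all recovery metrics (cosine similarity of profiles, correlation of
  contributions) are scale-invariant, and factor matching uses the
  Hungarian algorithm on the cosine matrix.
- **Bootstrap**: moving blocks of rows (default 72 samples = one day),
  refit warm-started from the base solution, replicate factors mapped to
  base factors by profile correlation (threshold 0.6); reported are
  per-factor mapping rates, 25–75 % profile envelopes and the fraction of
  unmapped replicate factors.
- Out of scope by design: rotational exploration (FPEAK-style),
  constrained fits, displacement-style error estimation.

## Synthetic catchment

The generator provides study-shaped data with known truth; its defaults
describe the campaign regime the analysis targets and are fixed, not
tuning knobs.

- **Rainfall**: events arrive at ≈ 0.55/day over 41 days, ~35 % large;
  large-event peaks are 1.3 + Exp(2.2) mm/10 min capped at 14.5, with a
  sharp-peaked hyetograph rescaled to a Gamma-distributed event total;
  small events stay below 1 mm/10 min.  Ensemble behaviour: ~90–115 mm
  campaign totals, ~7 large and ~15 small events.
- **Water level**: single linear reservoir (time constant 20 h, 1.2 cm
  per mm), evaluated exactly between inputs, so recession is exponential
  with half-life k·ln 2.
- **Concentrations**: six sources over 17 compounds.  Factor 1 is a
  *legacy* source: contribution = baseline · min(level)/level, so it
  dilutes during events (its dominant compound carries ~99 % of its
  fingerprint, emulating a withdrawn fungicide used as a pre-event-water
  tracer).  The five pulse sources convolve rainfall with shape-2 gamma
  kernels (lags 20–480 min, time constants 0.7–3 h) and are
  event-selectively activated (each source responds to a given storm with
  probability 0.6 and a Gamma-distributed amplitude) — different storms
  mobilise different sources, which is both realistic and what makes the
  six contributions statistically distinguishable.  Pulse gains are large
  relative to the baselines; with near-zero baselines too many species
  fall below LOQ (screening then demotes them and the uncertainty model
  overestimates), while large baselines leave rotational ambiguity in the
  factorization — the defaults sit deliberately between these regimes.
- **Noise**: zero-truncated Gaussian with sd √((a·x)² + κ·LOQ²), κ = 1 by
  default — the same functional form the screening uncertainty assumes,
  so Q_robust/Q_exp ≈ 1 is the *expected* outcome at the true p, and
  deviations of the ratio are interpretable.  Censoring flags values
  below LOQ but keeps the drawn value; ~5 % of rows are blanked in
  contiguous maintenance-style gap blocks.

What passing recovery tests show: the full chain (screening →
factorization → diagnostics) identifies the planted sources under the
stated noise, censoring and gap regime.  What they do not show: behaviour
under misspecified uncertainties, strongly correlated sources sharing
identical event responses, compound-specific error structure beyond the
(a, LOQ) model, or real instrument drift — the generator makes no claim
to physical hydrology (no infiltration or drainage-network simulation).

## Exposure assessment

Composite windows are half-open, aligned to the record start plus a
configurable offset, emulating 3.5-day (in-season) or 14-day composites.
Values below LOQ enter as LOQ by default; windows with more than 10 %
missing samples are flagged invalid but still reported.  The
underestimation factor is max(20-min)/composite within a window; when the
composite itself is censored the factor is reported against the LOQ and
flagged as a lower bound.  Because no clock alignment of the real
sampler is knowable, `start_offset_sweep` recomputes the factors across
offsets and reports the worst case (for a single spike of height h on
baseline b it approaches h·W/(h + (W−1)·b) for a W-sample window, which
the tests check in closed form).

Exceedances are counted three ways, since "an exceedance" is ambiguous:
per sample, per *episode* (maximal run of consecutive exceeding samples),
and per distinct compound; composite-resolution exceedances compare
composite means against the same standards.  Compounds lacking both AQS
and RAC are excluded from tallies and listed.  Chronic assessment is the
same machinery with a 14-day window and a chronic standards table.

## Pipeline and reproducibility

Stage seeds derive from the single global seed as
`(seed · 1000003 + crc32(stage)) mod 2³¹`, so any stage can be deleted
and recomputed in isolation byte-identically (`--resume`).  Every run
directory contains `manifest.json` with the effective config, its hash
and all derived seeds.

## Problem sizes in the test and acceptance runs

The test suite and `scripts/acceptance.py` run everything at the default
study shape (41 days, 17 species, n ≈ 2950).  Sizes chosen for the
routine experiments: the recovery fit uses 8 restarts at p = 6; the
factor-number scan experiment uses 20 replicate campaigns scanning
p = 3–9 with 2 restarts and a 400-sweep cap per fit (the elbow is a
coarse feature of the Q(p) curve and does not require converged optima);
the multi-start-vs-brute-force check compares 20 against 200 restarts on
30 × 5 instances; the rainfall ensemble check uses 50 seeded campaigns.
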