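# Methods

## The growth-law model

The package models steady-state exponential growth as a balance of two
proteome-limited fluxes. Translation flux is κt(φR − φ0): φR is the
proteome fraction of ribosomes plus co-scaling biosynthesis pathways, φ0
the offset fraction extrapolated to zero growth, and κt the translational
capacity (1/h per unit fraction, proportional to ribosome elongation
speed). Nutrient flux is κn·φP: φP is the catabolic P-sector and κn the
nutrient quality of the carbon source. Both relations are taken as
equalities, with any proportionality constants absorbed into κt and κn —
that normalization is what makes the closed form below exact. With the
proteome constraint φR + φP = φR^max, the steady state solves the linear
balance κt(φR − φ0) = κn(φR^max − φR), giving

    φR = (κt φ0 + κn φR^max) / (κn + κt),
    λ  = λmax κn / (κn + κt),     λmax = κt (φR^max − φ0).

λ is strictly increasing and concave in κn, λ(0) = 0, λ → λmax, and
λ = λmax/2 exactly at κn = κt. The growth-rate-invariant fraction
φfixed = 1 − (φR^max − φ0) and λmax are always derived from (κt, φ0,
φR^max), never set independently, so λmax = (1 − φfixed)κt holds by
construction.

**Plasticity extension.** The P-sector is decomposed by the expression
fraction f ∈ (0, 1] of substrate-specific machinery (the C*-sector):
φC* = f·φP, adaptability sector φAD = φP − φC*, and effective nutrient
quality κn = f·κn*. κn* aggregates the kinetic properties (Vmax etc.) of
the dedicated transporters/enzymes; individual enzyme kinetics are not
modelled separately. A promoter-swap intervention is modelled as changing
f alone: λ_new = λ(f_new·κn*).

**Parameter values.** No published numeric values exist for κt, φ0,
φR^max in the setting this package targets; the defaults used in the
examples and tests (κt = 4/h, φ0 = 0.1, φR^max = 0.6, hence λmax = 2/h)
are illustrative, chosen to give E. coli-like rate magnitudes, and are
not fit to data. All fractions are validated strictly (errors, never
clamping), because a silently clamped configuration mistake would
propagate invisibly into every downstream number.

## Titration model

Under external induction of the C/P-sector the induction fraction x is a
free variable rather than the solution of the balance. Two flux
combination rules are implemented:

* `hard_min` (default): λ(x) = min(κn·x, κt(φR^max − x − φ0)). Its
  optimum x* = κt(φR^max − φ0)/(κn + κt) is the balance point, and λ(x*)
  equals the closed-form growth law exactly — the default because it
  keeps the titration picture and the growth law one model.
* `harmonic`: λ(x) = (κn·x · κt·y)/(κn·x + κt·y), y = φR^max − x − φ0; a
  smooth series-bottleneck alternative for fitting smooth measured
  curves. It is bounded above by `hard_min` pointwise and peaks at
  x*/span = √κt/(√κn + √κt) (derived by setting the derivative of
  u(1−u)/(au + b(1−u)) to zero; cross-checked against a dense grid
  search in the tests).

The abscissa is the induction *fraction* itself; no cAMP-concentration
dose–response map is assumed, because none is defined in this setting. A
monotone map, if known, can be composed externally without changing any
result that depends only on ranks or optima.

**Fitting.** `fit_titration` holds (κt, φ0, φR^max) fixed and estimates
only κn by least squares: a coarse log-grid over κn ∈ [1e−3, 1e3] (241
points) brackets the minimum, then Brent refinement in log space
(xatol 1e−12) localizes it. Fitting all four parameters from a single
curve is unidentifiable (κn and κt trade off against the span), which
matches the intended use: the context is shared across substrates, κn is
the substrate-specific unknown. Curves must contain ≥5 points and bracket
their peak; all-zero curves are rejected.

## Proteome-cost integration

Three tables are inner-joined on gene id (dropped genes are counted and
logged, an empty intersection is an error): reference-condition absolute
copy numbers with protein lengths, fold-changes to a slow carbon-limited
reference (λ = 0.45/h — carried as metadata, not used in arithmetic),
and a substrate → transporter/first-enzyme map with wild-type growth
rates. Then copies_slow = copies × fold-change, cost_aa = copies_slow ×
length, and both are rank-correlated with growth rate.

Spearman with average ranks for ties is the primary statistic (the claim
under test is about rank order); Pearson on log cost is a secondary
output. The two-sided p-value is exact by full enumeration of the n!
orderings for n ≤ 8 and uses the t-approximation with n − 2 degrees of
freedom above that. Zero reference abundances are rejected rather than
imputed: a fold change applied to zero carries no information.

## Phenotype estimators

**Growth rate.** Ordinary least squares of ln OD600 on time (the
standard semi-log fit), ≥4 points, with R² reported (R² ≡ 1 for an
exactly constant series, where the fit is exact with slope 0). Doubling
time = ln 2/λ. `auto_window` automates steady-state window selection by
exhaustively scoring every contiguous window of ≥ `min_points` (default
4) with R² ≥ `r2_min` (default 0.99) and returning the one with the
largest fitted rate; rate ties within 1e−9 go to the longer window, then
the earlier start. Background subtraction is the caller's responsibility.

**Diauxic shift.** The instantaneous rate is estimated as centered finite
differences of ln OD (one-sided at the ends), smoothed by a centered
moving average of width `smooth_points` (odd; default 3, edge-normalized).
Shift onset is the first time this rate drops below θ·λ1 (default
θ = 0.5). The lag is the time lost relative to instantaneous resumption:
the post-shift exponential (λ2, fitted) is back-extrapolated to the OD at
shift onset,

    lag = t_ref − t_shift − (ln ÔD(t_ref) − ln OD(t_shift)) / λ2,

using fitted values at t_ref, which makes the result exactly independent
of the reference-point choice. Noise can produce small negative lags;
these are clamped to 0. The end-to-end pipeline (`analyze_diauxie`) fits
λ1 on the leading quarter of the series, detects the shift, detects
regrowth (the smoothed rate sustained above half the terminal rate for
`smooth_points` consecutive samples, with the terminal rate taken as the
median of fully-smoothed interior points near the series end — the
trailing half-window of the smoothed derivative is edge-dominated and
must not be used), fits λ2 from just after regrowth to the end, and
estimates ln OD at the shift from the mean of the observed plateau points
when at least three exist (identical to the single-point read on exact
data, ~√m less noisy on real data).

For noisy plate-reader-like data (≈2% multiplicative OD error at 0.05 h
sampling) the 3-point default smoothing is too narrow for reliable shift
detection — the centered-difference noise is ~0.3/h — so the recovery
studies use `smooth_points = 9`, which brings the rate noise to ~0.04/h
while the centered window keeps detection unbiased. The intrinsic
resolution of the lag estimate is one grid step; for a true lag of 0 h a
relative tolerance is meaningless, so recovery there is judged against
the grid step.

**Survival.** CFU density = colonies × dilution / plated volume (CFU/mL);
replicate densities are averaged at each timepoint before the ratio, and
survival = 100 × final/initial. The statistic is invariant to the
dilution used. Averaging densities before the ratio matches plating each
replicate in triplicate and reporting a mean survival.

**Motility.** Per-colony area fold changes (mean and sample SD, SD = 0
for a single pair) and the fraction of colonies exceeding an area
threshold (or flagged) as swarming.

## Synthetic-data generators

Every generator is a pure function of its arguments including the seed
(NumPy `default_rng`; the proteomics generator derives one sub-stream per
table from a single `SeedSequence`), and each dataset carries its ground
truth, so parameter recovery — not resemblance to any particular
published figure — is the acceptance surface.

* **OD curves:** exact exponentials (or piecewise
  exponential–plateau–exponential for diauxie) times unit-mean lognormal
  noise, the natural error model for a positive density readout;
  `noise_cv = 0` is exactly noise-free. The diauxic generator refuses an
  `od_shift` the first phase cannot reach on the grid; λ2 = 0 is allowed
  as a deliberate negative fixture for the no-regrowth error path.
* **Proteomics tables:** per substrate, growth rate ~ U(0.2, 1.2)/h and
  realized copies_slow = exp(a − b·λ)·ε with a = 11, b = 3 and lognormal
  ε at CV 20% — about 1.5k–35k copies per cell, a plausible range for
  transporters at slow growth. Fold changes ~ U(1.5, 8) and
  copies_per_cell = copies_slow/fold-change, so the pipeline's product
  reconstructs the latent value exactly; lengths ~ U{300, …, 900} aa;
  5 decoy genes appear in exactly one table each to exercise the join.
  The inverse relation is generated phenomenologically (not derived from
  the growth-law model) because the measured anticorrelation is the
  hypothesis under test, and the generator must also produce the b = 0
  null. Defaults are the conditions of the recovery studies: n = 20
  substrates, b = 3, CV 20%.
* **CFU counts:** Poisson with mean density × volume / dilution;
  expectations above 1e6 per plate are refused as physically uncountable.
* **Titration curves:** model curve plus additive Gaussian noise
  truncated at zero.

What the generators deliberately do **not** emulate: plate-reader drift
and background, non-exponential (Monod-depletion) rounding of the first
growth phase, overdispersed colony counts, proteomics batch structure, or
any cAMP dose–response. Passing recovery tests therefore demonstrates the
estimators' correctness and noise robustness under these idealized error
models, not their performance on every artifact of real instruments.

## Problem sizes and numerics

The recovery studies use 200 replicates each: growth-rate fits on 10
points over 3 h at 2% noise; diauxic curves on a 0.05 h grid over 14 h
cycling lags {0, 1, 2, 4} h; titration fits on 41-point curves with noise
at 2% of the peak rate; proteomics datasets of 20 substrates. Model
self-consistency uses 1000 random parameter draws against a bisection
solver (tolerance 1e−14; the closed form makes the solver redundant in
production, so it lives with the tests as an independent oracle). These
sizes keep the whole suite and the acceptance script in the
seconds-to-a-minute range while leaving the binomial pass-rate thresholds
comfortable margins.

Other numeric choices: strict validation everywhere (no clamping);
half-away-from-zero decimal rounding for recipe-table comparison (via
`decimal`, since binary floats make `round()` unreliable for printed
recipes); TSV floats written with 17 significant digits and read with
pandas' round-trip parser so write→read is lossless; window indices are
half-open Python ranges.

## Known limitations

* Steady state only — no dynamic reallocation ODEs; the titration model
  is phenomenological, with no mechanistic cAMP–CRP binding.
* The growth-context defaults are illustrative; quantitative use requires
  user-supplied (κt, φ0, φR^max) from rate–φR calibration data.
* `auto_window` is O(n²) in series length — fine for plate-reader series
  (hundreds of points), not intended for very long high-frequency logs.
* The exact permutation p-value is limited to n ≤ 8 (8! orderings); the
  t-approximation above that is standard but approximate in small n with
  heavy ties.
* Lag estimation assumes a single shift with a clean post-shift
  exponential; multi-phasic curves with slow rate drift need manual
  windows.
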