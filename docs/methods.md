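# Methods

## Scope and model

`prisafe` covers the safety-risk side of low-molecular-weight
process-related impurity (LMW PRI) management for mAb processes:
categorisation, the two-step risk assessment, clearance-fold accounting,
and the diafiltration washout model.  It deliberately excludes assay
chemistry, chromatography operating protocols (kept only as fixture
metadata), biological impurities (host-cell protein, DNA, Protein A
leachate), immunogenicity and protein-stability risk, and any mechanistic
chromatography or membrane-transport modelling.

## Units

Units are fixed per field: PRI concentrations μg/ml, protein mg/ml,
product dose mg, NOEL/LOEL mg/kg/day, LD50 mg/kg, PDE/TTC μg/day, body
weight kg.  Conversion happens at the I/O boundary only; all internal
arithmetic is unit-consistent by construction, which removes the main
source of 1000-fold errors when μg and mg quantities are mixed.

## Parameters and defaults

| Parameter | Default | Why |
| --- | --- | --- |
| body weight | 50 kg | conventional adult figure for health-based exposure limits; configurable and echoed in every report |
| F2 | 10 | fixed convention for inter-individual variability |
| F1, F3, F4, F5 | 1 | must be set deliberately; the tool refuses to invent toxicological judgment, and F5 > 1 is demanded whenever a LOEL is the point of departure |
| TTC | 1.5 μg/day | generic lifelong threshold of toxicological concern |
| ISF threshold | none | has to be determined from the dose–response data for the compound class; a required configuration input, recorded in the report |
| fit acceptance R² | 0.95 | washout fits below this are flagged rejected, not silently used |

Decision conventions, all chosen conservatively:

- Every pass/fail comparison is a strict inequality; ties fail.
- A per-product-dose amount (μg) is compared to a daily limit (μg/day)
  assuming one dose per day.
- Worst case carries the PRI-to-protein mass ratio at the introduction
  point unchanged into drug substance (no dilution or clearance credit).
- LD50 (mg/kg) is converted to a per-patient toxicity dose via body weight
  before the impurity-safety-factor ratio; the ratio is then dimensionless
  on a per-patient basis.
- A medium-risk impurity lacking either an LD50 or a configured ISF
  threshold is escalated to the TTC comparison rather than passed on
  missing data.
- Mixed evidence (e.g. metabolite + medium toxicity) takes the more severe
  branch; genuinely contradictory evidence (known-safe + genotoxic) is a
  validation error, not a silent worst case, since conflicting references
  need human resolution.
- No-data impurities follow the severe-toxicity branch against the TTC.

Test-point placement leverages where clearance is demonstrated: impurities
introduced at or before harvest (or pre-Protein-A downstream) test at the
Protein A pool, pre-CEX downstream at the CEX pool, later introductions at
the viral-filtration pool.  A platform switch places every test at the
viral-filtration pool instead, which matches programmes that keep a single
qualified sample point.

## Clearance semantics

The clearance fold normalises impurity concentrations by protein
concentration on both sides of a step, so volume changes cancel and the
fold measures genuine removal.  Cumulative clearance is the product of
per-step folds (log-additive accumulation — consistent with the
100 × 10 × 5 = 5,000 platform arithmetic).  A non-detect final
concentration is substituted with the assay LOD before the ratio, and the
result carries a lower-bound flag; the flag propagates through any product
containing it.  Bound flags, not interval arithmetic: demonstrated
clearance is reported as "greater than N-fold", and nothing downstream
needs the unbounded upper end.

The packaged Protein A / CEX spiking-study tables ship without eluate
protein concentrations, so regression tests over them use an equal-protein
assumption (load = pool at 5 mg/ml) and are labelled bound-style checks:
the true folds, computed with the higher eluate protein concentration, are
larger than what the tests assert.

## Diafiltration model

`C = C0·exp(−N·S)` for constant-retentate-volume diafiltration.  Fitting
is single-parameter nonlinear least squares on the concentration scale
with C0 fixed at the profile's anchor and the closed-form log-linear slope
(regression of ln C/C0 on N through the origin) as initial guess; the
log-linear estimate is also reported for transparency.  R² is computed on
the concentration scale as 1 − SS_res/SS_tot.  Points at or below the
assay LOD are *excluded* from the fit rather than substituted — LOD
substitution would bias S downward; this intentionally differs from the
clearance-fold LOD rule, which applies to fold ratios only.  Fitted
coefficients slightly above 1 are kept as-is: electrostatic repulsion
between a positively charged solute and a positively charged retained
protein genuinely enhances expulsion, so clipping at 1 would discard
signal.

Reference coefficients carried by the fixture module: copper ion 1.09,
MSX 1.02, EDTA 0.81, caprolactam 0.6, Pluronic F68 0.11, and two readings
for tropolone (0.7 as reported, and ln(100)/8.2 ≈ 0.56 as implied by its
100-fold diavolume requirement) whose source values are mutually
inconsistent; neither is privileged.  EDTA's 0.81 sits inside the reported
0.58–0.83 range and reproduces the ≈5.7-diavolume figure for 100-fold
clearance.

The surfactant guard warns when a spike exceeds the critical micelle
concentration (micelles exceed the membrane cut-off, so the washout model
does not apply) and emits an informational note when a surfactant's CMC is
unknown.

## Synthetic worked example

`generate_example_inventory` emulates the inventory shape of a
representative mAb programme: 96 known-safe impurities (amino acids,
vitamins, salts, buffers, approved excipients, padded with generic media
components), and 9 medium-risk impurities with NOEL-derivable PDEs of
which 6 pass the worst-case assessment and 3 require testing, all three
then clearing at the assay LOD.  Composition counts, dose context
(500 mg dose at 50 mg/ml, 50 kg body weight), the 0.5 μg/ml assay LOD and
the 5 mg/ml test-point protein concentration are data on the
`FixtureSpec`, not constants in the engine.  Pass/fail placements keep at
least 2× separation from the PDE on either side so dispositions are robust
to floating-point noise, with the generator verifying feasibility
(including that the LOD-based dose can actually clear the PDE) and
rejecting impossible specs.  Everything is seed-deterministic.

What the generator does **not** emulate: real toxicity heterogeneity
(every medium-risk impurity uses a NOEL-derived PDE; no B1/ISF or
Category C members by default), assay variability in measurements, or
correlations between usage concentration and toxicity.  Passing the
worked-example tests therefore demonstrates the decision logic and
arithmetic, not calibration against any real programme's inventory.

Diafiltration profiles are simulated at integer diavolumes 0..6 with
optional multiplicative lognormal noise (median 1, shape σ); the N = 0
anchor stays noise-free because it defines C0.  σ = 0.05 reflects a
well-qualified impurity assay's run-to-run variability.

## Numerical choices

- Sieving fits need ≥ 3 usable (non-LOD) points; fewer is a `FitError`.
- The planner `N = ln(fold)/S` is an exact inversion; planner and
  evaluator agree to 1e-10 relative tolerance (property-tested).
- `S = 0` makes any clearance target unreachable and is rejected with an
  explicit signal rather than returning infinity.
- Curve fitting uses scipy's Levenberg–Marquardt with the log-linear
  initial guess; on noiseless data it recovers the generating coefficient
  to better than 1e-6 across S ∈ [0.05, 1.2].
- Workflow reports are sorted by impurity id, making runs byte-identical
  for identical inputs.

## Problem sizes

The test suite and the acceptance script run the 105-impurity worked
example, 7-point washout profiles, and exhaustive enumeration of the
evidence-code × data-availability space (≈ 400 combinations) — sizes at
which every check is exact or deterministic and the whole suite completes
in a few seconds.

## Known limitations

- Single TTC value only; no less-than-lifetime TTC schedules or
  route-to-route extrapolation.
- No toxicity-database lookups or chemical-structure handling; evidence
  codes and reference values are inputs.
- Clearance prediction from physicochemistry is out of scope; charge and
  hydrophobicity classes are metadata for warnings only.
- The report schema is published and validated through the pydantic
  models (`report_json_schema()` / `validate_report_json`).
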