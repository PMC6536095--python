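# Methods

## Model and estimation

The core quantity is the output-oriented, variable-returns-to-scale (VRS)
DEA expansion factor. For target unit *k* with needs `x_k` (inputs) and
services `y_k` (outputs), phase 1 solves

    max φ  s.t.  Σ λ_j x_j ≤ x_k,  Σ λ_j y_j ≥ φ y_k,  Σ λ_j = 1,  λ ≥ 0

in the envelopment (primal) form, with the convexity constraint giving
VRS. Orientation is toward outputs because the policy question is how much
*service* a unit should receive given its needs, not how much need it
could shed. Feasibility is guaranteed (λ = e_k, φ = 1), so φ ≥ 1 always
and the equity index EI = 1/φ lies in (0, 1]. Phase 2 fixes φ at its
optimum and maximises the sum of input and output slacks, making the
projected service vector `φ·y_k + s⁺` unique in practice even when the
peer weights are degenerate; only φ, EI and the projection are treated as
contractual, since alternative optimal λ supports are unavoidable in LP.

Both phases run on `scipy.optimize.linprog` (HiGHS). If phase 2 is
reported infeasible at the phase-1 optimum (a boundary artefact), φ is
relaxed by one part in 10⁹ and the phase is retried. A unit is classified
`on_frontier` when φ ≤ 1 + 1e-6 and every slack is ≤ 1e-6. A target whose
selected services are all zero has no defined radial expansion; it is
flagged degenerate, assigned EI = 0 and excluded from the frontier.

The EI definition as the reciprocal of φ is the natural reading of a
"relative coverage deficit": the unit receives fraction 1/φ of what the
frontier says comparable units can receive. The underlying algebra of the
published index is not printed; 1/φ matches its range, frontier value and
ordering.

## MDEA ensemble

With 27 units and 5+2 variables, plain DEA loses discrimination. The MDEA
ensemble solves the DEA for every non-empty needs-subset × services-subset
pair — (2⁵−1)(2²−1) = 93 submodels per unit, enumerated exhaustively in a
fixed bitmask order, never sampled — and summarises each unit's EI
distribution. Per unit: mean EI; standard error; CI = mean ∓/± 1.96·se.
Two SE conventions are supported because the published tables do not say
which was used: `sd_over_sqrt_n` (default; ensemble SD / √93) and `sd`
(raw ensemble SD). Both satisfy the only relation the published tables let
us verify, CI half-width = 1.96·se. The CI is not truncated at 1 (the
published tables print an upper bound of 1.0038 for one state). Degenerate
submodels contribute EI = 0 and are counted per unit.

Only phase 1 runs inside the ensemble (EI needs no slacks), halving LP
count; the full model is solved in two phases so projections come from the
same fit. The whole 27-DMU × 93-submodel ensemble is ~2,500 small LPs and
runs in seconds on one core. The ensemble is deterministic and
bit-reproducible; dimension monotonicity (enlarging the variable set never
lowers EI) implies mean EI ≤ full-model EI, which the tests assert.

Regional averages are unweighted means of member-state mean EIs.

## Projections, capture and reallocation

Projected ("optimal") values are the full-model peer targets. Capture is
`100·effective/projected` per state and programme (one decimal); the
aggregate required increase is `100·(projected − effective)/projected`
(two decimals) — this form, rather than the increase relative to the
effective total, is what reproduces both published aggregate percentages
(22.71 % BPPP, 46.71 % BCPA) from the published totals.

The budget-constrained schemes redistribute the existing budget in
proportion to projected values. Complementary: within each programme,
`coef_i = proj_i / Σ_j proj_j` and `alloc_i = coef_i · Σ_j eff_j`.
Substitution: coefficients normalise over all state × programme cells and
the pooled effective total is redistributed. The published source states
no formula; this proportional rule was reverse-engineered from its printed
coefficient/allocation pairs (e.g. 0.168 = 397.22/2360.30) and reproduces
them to print rounding. Pooled totals always use exact sums of the state
rows (the printed grand total 2,850.00 disagrees with its own rows' sum
2,850.34 by 0.34; exact sums are required for conservation to 1e-9 and
match the printed substitution allocations slightly better). Reported
tables round half-even: coefficients to 3 decimals, values to 2; full
precision is kept internally.

The coverage-deficit regression (deficit = 1 − mean EI on the
accredited-pharmacy share) is ordinary least squares via statsmodels. The
published covariate is not printed, so this regression is exercised on
synthetic covariates only.

## Bundled reference tables

Four small CSVs carry the published 2013 per-state results: descriptive
statistics, equity indices with SE/CI, effective vs projected values, and
the reallocation coefficients/allocations. Known print defects,
documented in `pharmaequity/fixtures/`: a garbled Minas Gerais
substitution coefficient (reconstructed as 0.070 from its unambiguous
allocation); two complementary allocation cells (Minas Gerais BCPA 80.07,
Rio Grande do Sul BPPP 196.69) that contradict their own printed
coefficients and are treated as transcription errors by the tests; a
hypertension descriptive row whose unit is likely millions though printed
as thousands. All stored verbatim.

## Synthetic data generator

The generator emulates the 27-unit federative layout: five needs drawn
log-normally at the published orders of magnitude (heavy right skew across
units), two services. `n_frontier` units sit exactly on a concave
increasing frontier `y = a·z^0.7` of the aggregate need `z = Σ w_i x_i`
(weights 1/median make variables commensurate; a linear shape is
available). Every other unit copies a frontier unit's needs, jittered
*upward* by at most 1 %, and receives fraction `u ~ U(inefficiency_range)`
of the frontier service level at its own jittered needs. Consequences,
proved by the concavity of the frontier and asserted in tests: planted
frontier units always score EI = 1; a copy's full-model EI equals `u`
within about 0.7 % for 1 % jitter (exactly, for zero jitter); `u = 1`
copies are exactly efficient. Larger jitter is available but voids the
exact-recovery guarantee.

Defaults are the study conditions: 27 units, 5 planted-efficient,
inefficiency range (0.6, 1.0) spanning the published EI range, needs
medians (1200, 340, 240, 980, 0.54) at the published magnitudes. All
draws flow from one `SeedSequence` root with per-purpose spawned
sub-streams, so results are independent of draw order and bit-reproducible
per seed. The pharmacy-ratio covariate is `clip(a + slope·(1−u) + ε, 0, 1)`
with the intercept centring ratios at 0.4.

What the generator does **not** emulate: Brazil's actual inter-state
correlation structure, measurement error in survey prevalence, or any
spatial autocorrelation. Passing tests therefore demonstrate correctness
of the frontier machinery and the identifiability of planted
inefficiency — not that the published indices would be recovered from the
(unavailable) raw needs data.

## Numerical choices and limitations

* LP tolerances are HiGHS defaults; frontier classification at 1e-6;
  convexity checked to 1e-7 in tests.
* The negative-income transform is `(max(inc) − inc)/sd(inc) + 0.01` —
  any strictly positive, income-decreasing transform is acceptable; this
  one is unit-free up to the additive floor that keeps the richest unit's
  input positive.
* Ties/degeneracy: alternative optimal peer supports are allowed;
  deterministic results are guaranteed for φ/EI/projection given the
  dataset, not for λ.
* Test problem sizes (≤ 6 DMUs for oracle grids, 12 DMUs for full MDEA
  ensembles, 20 generator seeds) were chosen to exercise every code path
  with comfortable margins while keeping the default suite fast; the
  oracle grid refines to step ≈ 4e-5 on the weight simplex, well inside
  the 1e-3 comparison tolerance.
* The exhaustive ensemble scales as (2^m−1)(2^s−1) LPs per unit: fine for
  the 5+2 layout, impractical beyond ~15 variables. No bootstrap or
  smoothed-DEA inference is provided; the reported dispersion is the
  subset-ensemble spread only, as in the source analysis.
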