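# Methods

## The two parameterizations

Valuation regressions for the EQ-5D-3L are fit on disutilities
`d = 1 − TTO`, observed only for impaired states: perfect health (`11111`)
anchors the scale at 1 axiomatically and is outside the prediction scope.
The package treats this convention as structural: `predict_value` returns
exactly 1 for `11111` under any tariff, the intercept of a constant-term
tariff is interpreted as a constant over the 242 impaired states, and
prediction SEs for `11111` are 0.

The D1-style specification (`D1O`) regresses disutility on the ten level
dummies, I3, I2², I3² and D1 = max(#impaired − 1, 0), with no intercept.
Its constant-term equivalent (`D1C`) replaces D1 with an intercept. The two
are linked by an exact linear map — constant = −β_D1, each dummy shifted by
β_D1, the I-terms unchanged — because over impaired states the identity

```
Σ (level dummies) − D1 = 1
```

holds exactly: the constant already lies in the D1O column span. The
package verifies the map symbolically (round-trip identity to 1e−12 on
arbitrary coefficients) and by exhaustive enumeration (identical values for
all 243 states). The same identity is why the two designs fit any dataset
identically (same fitted values, residuals, R²) and why D1O is so
collinear. Similarly `I3 = n3 − N3` puts the `D1C_N3` design in the same
column span as `D1C`.

Coefficients are stored on the signed "add to 1" utility scale (dummies
negative, D1 positive), exactly as the published worked examples add them,
and the published US coefficients ship at their printed 3-decimal
precision. Two published numbers are inconsistent with exact 3-decimal
arithmetic and are reported here as computed:

- states `33133`/`33233` sum to **−0.095**, not the −.100 the original
  value table prints (that table was produced from unrounded coefficients,
  which are not public at full precision); the substantive claim — the two
  states tie exactly — holds either way;
- the re-expressed P2 coefficient is −.173 + .140 = **−0.033**, not the
  printed −.032.

## VIFs over the design space

VIF_j = 1/(1 − R²_j), with R²_j from regressing predictor j on the model's
*other* columns, computed over the 242 impaired states with equal weight —
a property of the design space, not of any sample. Two conventions exist
and the choice matters here:

- **Intercept models (D1C, D1C_N3):** auxiliary regression includes the
  intercept; R² is centered. This reproduces the published constant-term
  column (level-2 dummies 1.913, level-3 3.591, I3 21.211, I2² 3.893,
  I3² 7.066; N3 3.01 under the substitution).
- **The intercept-free D1O model:** the centered convention degenerates —
  by the identity above, adding an intercept to the auxiliary regression
  makes every dummy and D1 *exactly* collinear (R² = 1, VIF infinite). The
  published finite values (dummies 5.336/5.038, I3 38.529, I2² 5.384,
  I3² 9.773, D1 113.184) are reproduced exactly by the auxiliary
  regression over the other model columns only, with uncentered
  R² = 1 − SSR/Σy² — the convention standard software applies to
  no-intercept models.

The default (`convention="match_model"`) therefore centers iff the model
has an intercept; both conventions can be forced, in which case only the
R² normalization changes (an intercept model keeps its intercept among the
auxiliary regressors under the uncentered convention). Every VIF is
cross-checked against an independent route — the diagonal of the inverse
(Pearson or cosine) correlation matrix — to 1e−8, and against statsmodels'
`variance_inflation_factor` where that function's implicit-constant
detection does not override the convention. Auxiliary R² above
1 − 1e−12 is reported as an infinite VIF rather than an error.

A consequence worth noting: swapping N3 for I3 in the constant-term design
leaves the level-2 dummies and the quadratic terms untouched but *does*
move the level-3 dummy VIFs (3.591 → 3.245), because I3 = n3 − N3 ties the
swapped column to the level-3 dummies. The claim that all other VIFs are
unchanged under this substitution is true only for the non-level-3 terms.

### SE inflation and √VIF

√VIF measures how much a coefficient's SE exceeds what an orthogonal design
would give. Comparing the *same* dummy across the two designs fitted to
the same data, the SE ratio equals √(VIF_D1O/VIF_D1C) exactly **when both
VIFs use one R² normalization** (uncentered, the normalization the SE
algebra of an intercept-free model is built on): 1.362 for level-2
dummies, 0.966 for level-3. Mixing each design's reporting convention
(√(5.336/1.913) = 1.670) misstates the true ratio by ~18%, because the
centered and uncentered baselines differ by a factor √(1−p̄) for a dummy
with mean p̄. The Monte-Carlo acceptance check uses the consistent
convention.

Per-state prediction SEs are offered in two modes. `full_covariance`
(√(xᵀΣx)) is invariant under re-parameterization: equivalent models give
identical prediction SEs for every state, so neither parameterization
"reduces the uncertainty" of the predictions themselves. `diagonal_only`
ignores coefficient covariances; under that accounting the D1 term's
variance enters a five-impairment state with multiplier 4² while a
constant's enters once, which is the sense in which the D1-style design
inflates apparent uncertainty. Both modes are exposed; the package does not
adjudicate between them beyond this note.

## Calculation-step counting

"Number of calculation steps" is formalized as: one step per invoked
additive term (nonzero predictor; the intercept counts when in scope), plus
one per nontrivial multiplication (predictor value ∉ {0, 1}). Starting
points: `perfect_health` (from the anchor 1) or, for intercept tariffs,
`any_impaired` (the constant folded into the start value, .860 − disutility
for the published tariff). Under this rule, exhaustively over the 242
impaired states: the constant-term form needs exactly one more step for
each of the 10 single-impairment states, the same number for the 40
two-impairment states, and exactly one step fewer for all 192 states with
three or more impairments; with the `any_impaired` start it needs fewer
steps for all 232 states with ≥2 impairments and ties on the rest.

## Tied-state enumeration

Two states are "tied" when their predicted values differ by less than
5e−4 — half the printed coefficient precision, so values equal at 3
printed decimals are tied and distinct ones are not ("−.000" is read as
exactly zero). For usual activities moving 1→2 with no other dimension at
level 2 there are 2⁴ = 16 candidate pairs; the U2 coefficient (−.140) and
the D1 increment (+.140) cancel exactly for the 15 pairs whose start state
is already impaired, while `11111→11211` keeps D1 at 0 and loses the full
.140.

## The synthetic valuation generator

`simulate_tto` draws, for each state s and respondent r,

```
d_obs(s, r) = 1 − u_true(s) + ε,   ε ~ N(0, σ²) iid
```

with u_true from a known tariff (default: the published coefficients).
Defaults: all 242 impaired states, n = 50 respondents per state, σ = 0.2
disutility units — the order of respondent-level TTO scatter, large enough
that SE behaviour is measurable and small enough that recovery is sharp at
these sizes. Optional symmetric clipping is available because real TTO
disutilities are bounded, but is off by default since no canonical bounds
attach to the model. Deliberately *not* emulated: respondent random
effects, population sampling weights, the handful-of-states-per-respondent
subset designs of real valuation studies, and non-Gaussian TTO response
distributions. Passing tests therefore demonstrate properties of the
estimator and of the model algebra under clean conditions — equivalence of
the parameterizations, unbiased coefficient recovery, SE scaling as
σ/√n·√VIF — not robustness to real survey structure.

Seeding: a `SimConfig` seed fixes the dataset byte-for-byte; the
Monte-Carlo driver spawns per-replicate seeds from the master seed via
`numpy.random.SeedSequence`, so experiments are reproducible and replicates
independent.

## Problem sizes and numerics

The design space is tiny (≤ 243 × 15 dense), so all enumerations are
exhaustive and all linear algebra dense (`numpy.linalg.lstsq` for auxiliary
regressions; statsmodels OLS for data fits, reported on the tariff scale by
sign flip). The Monte-Carlo recovery study runs 200 replicates of
242 × 50 observations — enough for Monte-Carlo SEs of ~7% of an empirical
SE — and completes in well under two minutes on one core. Rank deficiency
in a requested fit is detected by matrix rank and reported with the
dependent columns identified via pivoted QR, rather than silently
pseudo-inverted.

## Known limitations

- The published coefficient SEs (and all significance statements about the
  original survey) depend on the original respondent-level data, which were
  never deposited; they are not reproduced, only the design-driven SE
  *ratios* are.
- Only the three named specifications are supported; arbitrary interaction
  structures are out of scope.
- The generator's independence assumptions make its SEs smaller than those
  of a clustered respondent design with the same n; comparisons between
  parameterizations are unaffected (both fit the same data), absolute SE
  magnitudes are not meaningful beyond scaling.
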