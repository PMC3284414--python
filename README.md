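# eqtariff

Tools for analysing the algebraic structure of EQ-5D-3L value sets
("tariffs"), aimed at health economists and valuation-study methodologists.

The EQ-5D-3L describes health along five dimensions — mobility (M),
self-care (S), usual activities (U), pain/discomfort (P),
anxiety/depression (A) — each at three levels, giving 243 states written as
five-digit codes (`11111` = perfect health, `33333` = worst). National
valuation studies assign each state a utility on a scale anchored at 1
(perfect health) and 0 (death) by regressing observed time trade-off (TTO)
disutilities, `1 − TTO`, on state descriptors.

The US valuation model ("D1-style", here `D1O`) has no intercept; in its
place it uses the term D1 = max(#impaired dimensions − 1, 0):

```
u(s) = 1 − [ Σ_d β_d2 X_d2(s) + Σ_d β_d3 X_d3(s)
             + β_I3·I3 + β_I22·I2² + β_I32·I3² + β_D1·D1 ]
```

with level dummies `X_d2, X_d3`, and `I2`/`I3` the counts of level-2 /
level-3 dimensions beyond the first. This package implements that model,
its mathematically equivalent constant-term re-expression (`D1C`:
constant = −β_D1, each dummy shifted by β_D1), and the `D1C_N3` variant in
which the UK-style N3 dummy (any level-3 problem) replaces I3. Around that
core it provides:

- exact scoring of all 243 states and proof-by-enumeration that the two
  parameterizations value every state identically;
- variance inflation factors (VIF = 1/(1 − R²) from auxiliary regressions)
  for every predictor over the 242-state design space, with an independent
  inverse-correlation-matrix oracle;
- calculation-step accounting and enumeration of state pairs with tied
  values;
- a synthetic TTO valuation simulator and a statsmodels-style
  `DisutilityModel` / `DisutilityResults` pair for refitting either
  parameterization, converting fits back to tariffs, and propagating
  coefficient uncertainty into per-state prediction SEs.

## Worked example

```python
import eqtariff as eq

tariff = eq.US_D1O_TARIFF                    # published 3-decimal coefficients
print("value(33133) =", round(eq.predict_value(tariff, "33133"), 3))
d1c = eq.reparameterize(tariff)              # exact constant-term form
print("constant     =", round(d1c.coef("const"), 3))
print("U2 (D1c)     =", round(d1c.coef("U2"), 3))
print("tied pairs   =", len(eq.find_tied_pairs(tariff)))
print("VIF(D1)      =", round(eq.vif_all("D1O").vif("D1"), 3))
print("VIF(I3,D1c)  =", round(eq.vif_all("D1C").vif("I3"), 3))
```

prints

```
value(33133) = -0.095
constant     = -0.14
U2 (D1c)     = 0.0
tied pairs   = 15
VIF(D1)      = 113.184
VIF(I3,D1c)  = 21.211
```

Read: state `33133` scores −0.095 under the published 3-decimal
coefficients (the originally published value table, computed from
unrounded coefficients, prints −.100 for this state; see
`docs/methods.md`). The constant-term form makes visible what the D1-style
coefficients obscure — moving usual activities from level 1 to level 2
costs nothing (U2 coefficient 0.000) once any other dimension is impaired,
which ties 15 pairs of states such as `33133`/`33233`. The D1 term's VIF
of 113.2 versus a maximum of 21.2 in the constant-term design quantifies
the extra collinearity the intercept-free parameterization buys.

Refitting simulated valuation data shows the machinery end to end:

```python
data = eq.simulate_tto(eq.SimConfig(n_respondents=50, noise_sd=0.2, seed=7))
fit = eq.DisutilityModel.from_dataframe(data, "D1C").fit()
print(fit.summary())
```

```
Disutility OLS fit  spec=D1C  nobs=12100  R^2=0.554598  resid SD=0.199658

term          coef        SE         t     P>|t|
const      -0.1363    0.0075    -18.11    0.0000
M2         -0.0017    0.0053     -0.33    0.7447
...
I32         0.0172    0.0021      8.25    0.0000
```

The fitted constant (−0.136) recovers the generating −0.140 within noise,
and the M2 and U2 dummies — significant-looking in the D1-style fit of the
same data — are correctly seen to be indistinguishable from zero.

A CLI mirrors the library: `eqtariff tables`, `values`, `vif`,
`compare-vif`, `ties`, `steps`, `simulate` (see `eqtariff --help`).
Tariffs are exchanged as JSON (`examples/us_d1o_tariff.json`), simulation
configs as YAML (`examples/sim_config.yaml`), tables as CSV.

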