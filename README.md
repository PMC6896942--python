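# reefcal

Method-agreement analysis and calibration between the two standard reef
benthic monitoring protocols: **chain point-intercept (CPI)** transects,
which record the component under regularly spaced marks on a chain
draped along the substrate contour, and **photoquadrats (PQ)**, which
annotate random points on top-down photographs of fixed quadrats.
Because CPI samples the reef's vertical relief while PQ samples a planar
projection, their percent-cover estimates differ systematically — by
component, by abundance, and by reef type. Long-term monitoring
programs switching from chains to photographs need these biases
quantified and corrected before new data can be compared with decades of
chain-based baselines.

`reefcal` is for reef monitoring scientists and biostatisticians doing
that comparison. It implements:

* **Difference-vs-average (Bland–Altman) analysis** — per site and
  component, `d = PQ − CPI` against `a = (PQ + CPI)/2`, with per-reef
  mean differences and site-resampling bootstrap CIs;
* the **heteroscedastic GLS ANCOVA**
  `d = β0_r + β1_r·a + ε, ε ~ N(0, σ²δ²_r)` (REML, reef-specific
  variance multipliers, sequential F-tests, backward reduction), in
  statsmodels style: `DifferenceGLS(...).fit()` returns a results object
  with `summary()`, `anova()` and per-reef coefficients;
* **conversion rules**: inverting the reduced difference model gives
  `CPI = a + b·PQ` with `a = −β0/(1 + β1/2)` and
  `b = (1 − β1/2)/(1 + β1/2)`, classified into bias scenario classes
  (constant offset pooled/per-reef, common slope, reef-specific slope),
  applied, exported as JSON, and validated by round-trip refitting;
* **major-axis (Model II) regression** as the alternative conversion
  estimator, with an estimator-comparison table;
* **synthetic data** at two levels: site-level paired covers generated
  under parameterized bias scenarios, and a mechanistic plot simulator
  (patch mosaic, draped chains with per-component rugosity,
  quadrat sampling with planar inflation) reproducing the contour and
  gorgonian effects;
* a **CLI** (`reefcal simulate | aggregate | compare | convert |
  temporal | report`) orchestrating the whole analysis with seeded,
  bit-reproducible outputs.

## Worked example

Simulate a study-sized survey (3 reef types × 7 sites, six benthic
components) and derive the hard-coral conversion:

```python
import reefcal as rc

covers, truth = rc.simulate.gen_site_level(rc.simulate.study_spec(), seed=1)
pairs = rc.io.pair_methods(covers)
diffs = rc.agreement.difference_and_average(
    pairs[pairs.component == "hard_corals"])

print(rc.fit_gls(diffs).summary())          # full-model F-table
reduced, trace = rc.reduce_model(diffs)     # backward elimination
print(rc.classify_scenario(reduced).value)
for r in rc.build_rules(reduced, "hard_corals"):
    print(f"{r.reef_type:9s} CPI = {r.intercept:.2f} + {r.slope:.2f} x PQ")
```

prints (abridged):

```
Sequential F-tests:
                     term  df_num  df_den         F         p
                Intercept       1      15  690.3093    0.0000
                Reef type       2      15   19.5936    0.0001
            Average cover       1      15    2.8775    0.1105
Reef type x Average cover       2      15    0.4054    0.6738

CONSTANT_BY_REEF
bank      CPI = 3.81 + 1.00 x PQ
fringing  CPI = 4.91 + 1.00 x PQ
patch     CPI = 6.53 + 1.00 x PQ
```

Read: with 21 sites and 6 parameters every F-test carries 15
denominator df. Reef type is significant but neither the abundance
covariate nor the interaction is, so the between-method difference is a
reef-specific *constant*: photographs underestimate coral cover by
3.8–6.5 percentage points depending on reef type (the generator's true
offsets were 3.15, 5.24 and 6.16), and conversion just adds that
constant back. A site-bootstrap CI for the patch-reef mean difference,

```python
rc.agreement.bootstrap_ci(diffs[diffs.reef_type == "patch"]["d"],
                          B=9999, seed=0)
```

gives `estimate −6.53, 95% CI [−7.22, −6.02]` — clearly excluding zero.

The same chain runs from the shell:

```sh
reefcal simulate --kind site --seed 1 --outdir data/
reefcal compare data/covers.csv --outdir results/ --seed 1
reefcal report results/
```

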