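# Methods

`reefcal` quantifies and corrects the systematic differences between two
standard reef benthic survey protocols — the chain point-intercept
transect (CPI), which samples along the substrate's vertical contour,
and the photoquadrat (PQ), which samples a top-down planar projection —
and derives equations for converting PQ percent-cover estimates into
CPI-equivalent ones. This note records the models, the choices behind
them, and what the simulations do and do not establish.

## The difference-vs-average model

For each site and benthic component the two protocols give paired
percent covers (PQ, CPI). Following the Bland–Altman logic of method
comparison, the analysis works in the coordinates

    d = PQ − CPI          (the between-method difference)
    a = (PQ + CPI) / 2    (the average, the best proxy for true cover)

and fits, per component, the ANCOVA

    d_i = β0_r(i) + β1_r(i) · a_i + ε_i,
    ε_i ~ N(0, σ² δ²_r(i)),   δ_reference = 1,

where `r(i)` is the site's reef type (fringing, patch or bank). Each
reef type carries its own residual-variance multiplier δ_r, estimated
jointly with the coefficients by REML: the variance parameters are
profiled (given δ, the coefficient estimate is weighted least squares
and σ² is the whitened residual sum of squares over n − p), and the
restricted likelihood is maximised over log δ with Nelder–Mead
(absolute tolerance 1e-8 on −2·logLik, iteration cap 2000 evaluations,
started from the OLS residual SD ratios). This reproduces the standard
`gls + varIdent` fit of the R package nlme; the test suite checks
coefficients, σ, δ and the F-table against that implementation on the
same data through `Rscript`.

Inference uses sequential (Type I) F-tests in the entry order
intercept → reef type → average cover → interaction, with denominator
degrees of freedom n − p of the fitted model (21 sites and 6 parameters
give 15, matching the design this package targets). ML estimation is
available as an option; REML is the default because it is the reference
implementation's default and less biased for variance parameters at
n = 21.

Degenerate inputs: a perfect fit (zero residual) returns exact
coefficient estimates with σ = 0; F-tests on such a fit raise a
degenerate-variance error rather than emitting spurious statistics.
Reef types with fewer than 3 sites cannot support a free variance
multiplier; the model then pools variances with a warning. A reef type
with a single site makes the interaction design singular, which is a
hard error.

## Model reduction and scenario classes

The most parsimonious model is found by backward elimination at
α = 0.05, respecting marginality: the interaction is tested first (it
is last in the sequential order, so its sequential F is its marginal
test); once removed, each remaining removable term is tested *as if
ordered last* (equivalent to a Type II test given the other retained
terms) and the least significant term with p > α is dropped before
refitting. The intercept is always retained. The retained terms map to
a bias *scenario class*:

| retained terms                  | class                 | conversion shape            |
|---------------------------------|-----------------------|-----------------------------|
| none (intercept n.s.)           | NO_DIFFERENCE         | identity                    |
| intercept only                  | CONSTANT_POOLED       | one constant, all reefs     |
| + reef type                     | CONSTANT_BY_REEF      | constant per reef           |
| + average cover                 | COMMON_SLOPE_POOLED   | one line, all reefs         |
| + both main effects             | COMMON_SLOPE_BY_REEF  | one slope, reef intercepts  |
| + interaction                   | SLOPE_BY_REEF         | line per reef               |

## The conversion equation

If the difference law holds, solving d = β0 + β1·a for CPI gives the
direct conversion

    CPI = a + b · PQ,
    a = −β0 / (1 + β1/2),   b = (1 − β1/2) / (1 + β1/2),

singular at β1 = −2 (a conversion is refused there, and fitted rules
with non-positive slope are flagged and never applied). The map and its
inverse are exact closed forms; the test suite verifies round-trip
identity to 1e-10 over a parameter grid. Converted values outside
[0, 100] are reported raw and flagged, not clamped — clamping would
bias the round-trip validation; an optional clamp exists for display.
When the reduced model retains nothing significant, the identity rule
is emitted rather than a non-significant fitted constant.

Round-trip validation converts the PQ values with the derived rules,
recomputes d against CPI, refits the full ANCOVA and checks that zero
lies inside the 95% intervals of every reef-type mean difference
(t-interval) and fitted slope (Wald). Conversion-parameter uncertainty
is not propagated into converted values; that is future work.

## Major-axis regression

As an alternative estimator, CPI is regressed on PQ by major-axis
(Model II) regression, appropriate because both variables carry
comparable sampling error: the slope is the leading-eigenvector
direction of the 2×2 sample covariance matrix (closed form, sign taken
from the covariance; zero covariance is an error), the line passes
through the centroid, and slope(x→y)·slope(y→x) = 1. MA fits are always
per component × reef type; `compare_estimators` reports converted means
and SDs under both estimators per stratum. No MA confidence intervals
are computed, and no standardized/ranged variants are offered.

## Synthetic data

### Site level

`gen_site_level` draws, per site and component, a true cover
T ~ N(mean, sd) truncated to [0, 100], then applies the generating law

    D = β0_r + β1_r·T + ε,   PQ = T + D/2,   CPI = T − D/2,

so the method average equals T and the fitted model is exactly the
generating model — making parameter recovery well-posed. A filler
`other` category closes every composition to exactly 100, which forces
the per-site differences to sum to zero across components (the
compositional-closure invariant). Values pushed outside [0, 100] are
clamped and counted; a scenario whose clamp rate exceeds 3% of draws is
rejected as unrealizable (threshold set at roughly three times the
expected clamping of the default scenario). Because the six components
are drawn independently, a joint draw can exceed 100 before the filler;
such sites are redrawn (bounded at 100 attempts), i.e. the joint cover
distribution is truncated to the feasible simplex. The difference law
is conditional on T and unaffected by either truncation.

The default `study_spec()` mirrors the targeted monitoring design — 3
reef types × 7 sites, six components — with difference laws taken from
the published per-component conversion lines and residual SD σ = 1.5
(the printed hard-coral reef-type F of 8.36 back-calculates to
σ ≈ 1.4). Cover means and SDs are calibration choices, not published
values: they are set to realistic Caribbean magnitudes with strong,
aligned cross-reef gradients (turf-rich fringing reefs,
macroalgae/CCA-rich bank reefs, hard coral averaging ≈ 20% on patch
reefs) so that the stand-in reproduces the strong between-method
correlations (r ≳ 0.86 per component at n = 21) the study design
exhibits. The fringing-reef gorgonian stratum, with ~3% cover, carries
a proportionally smaller residual SD.

What these data do *not* emulate: count-based sampling noise (covers
are continuous), within-site spatial structure, inter-annual dynamics,
and observer error. Tests passing on them show the estimation chain is
correct under its own assumptions, not that the field data satisfy
those assumptions.

### Plot level

`gen_plot` tessellates a 10 × 20 m plot into seeded random patches
(cells of ~`patch_area`, exact largest-remainder proportions), so
realized planar fractions match targets within one cell. Two bias
mechanisms are modelled:

* **Contour effect** — chains drape the relief: a cell of planar
  length ℓ and rugosity ρ_c consumes ℓ·ρ_c of chain, stretching chains
  beyond their 10 m planar span (ρ = 1.3 gives ~13 m and ~1,300 marks
  per plot at 10 cm spacing) and weighting intercept probability by
  f_c·ρ_c. Rugose components (corals, sponges) are therefore
  *underestimated by PQ relative to CPI*.
* **Gorgonian inflation** — within each photoquadrat, labels are drawn
  with probability ∝ local planar fraction × γ_c (renormalized), the
  simplest mechanism for canopy-like colonies claiming image points
  beyond their holdfast footprint. γ > 1 *overestimates* the component
  in PQ, with a bias that grows with abundance.

The PQ design is fixed at 11 transects × 6 quadrats of 0.90 × 0.60 m
with 25 random points each (1,650 records, 35.64 m² = 17.8% of the
plot); the CPI design at 10 chains, 5 mm wide (~0.65 m², 0.33%, at
13 m chains). Closed-form expectations (e.g. CPI share
f·ρ / Σ f·ρ) are exact in the fine-patch limit; with default patch
size, local-fraction variability shifts quadrat expectations slightly
(Jensen effect), so closed-form checks in the tests use a finer mosaic.
No 3-D meshes, camera optics or image rendering are modelled.

## Operating characteristics and known limitations

`reefcal.validation` measures the chain's behaviour on known truth:

* **Conversion algebra** is exact to numerical precision (~1e-15 over
  the tested grid).
* **Scenario recovery** at the study size (7 sites/reef) is bounded by
  the compounding of the sequential tests' false-positive rates: a
  class with k truly-null terms can be recovered at best near
  (1 − α_actual)^k. At n = 21 the sequential interaction F-test
  rejects a true null at ~0.10 — a property shared exactly with the R
  reference implementation on identical replicates, reflecting the
  small-sample cost of estimating three variance parameters — so
  recovery is ~0.7–0.8 for constant-offset classes and >0.95 for the
  interaction class. At 50 sites/reef the test level is close to
  nominal (~0.05–0.06) and full-model coefficient estimates fall within
  3 SEs of truth in ≥99% of replicates.
* **Bootstrap CIs** resample sites with replacement (percentile
  method, B = 9,999 by default, seeded; BCa optional). The percentile
  method is exactly checkable against exhaustive enumeration at tiny n.
* **Signed-rank test** (temporal change): exact null distribution for
  n ≤ 25 without ties, normal approximation otherwise; zeros dropped by
  default (Pratt optional); both the min(W+, W−) statistic and W+ are
  reported since conventions differ.

The simulation sizes used by the test suite and the acceptance script
(20 stand-in replicates, 500 recovery replicates per class, 2,000
level-check replicates) were chosen to keep Monte-Carlo error well
below the assertion margins while completing in a few minutes on one
CPU.
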