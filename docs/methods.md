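# Methods

## The model chain

`ecoserv` couples three standard components of land-change science.

**Markov composition dynamics.** The landscape composition is a probability
vector **s** over seven classes (cropland, forestland, grassland, wetland,
urban, bare land, water bodies — fixed canonical order everywhere). Two
co-registered epochs are cross-tabulated over their common support into
counts n<sub>ij</sub>; rows are normalised to the transition matrix
*A*<sub>ij</sub> = n<sub>ij</sub>/Σ<sub>j</sub>n<sub>ij</sub>, and
composition advances as **s**(t+1) = **s**(t)*A*. One Markov step is one
inter-epoch interval (a decade in the packaged Central Asia series);
longer horizons are matrix powers. Rows whose source class is absent
become identity rows — an absent class cannot donate cells, and the
convention keeps *A* stochastic without inventing transitions. By default
cells are counted; with per-cell (latitude-corrected) area grids an
area-weighted cross-tabulation is available. The model is first-order and
stationary: it assumes the recent interval's transition rates persist,
which is the standard — and strong — assumption of this family of
projections.

**Cellular-automata allocation.** Markov projection fixes how much area
each class gains or loses; the CA stage decides where. Suitability of cell
*c* for class *k* is the fraction of class-*k* cells among the valid cells
in a square window centered on *c* (default 5×5, the conventional
contiguity filter; edges use the truncated window, so scores always
partition the neighborhood and sum to 1). Allocation is demand-driven
greedy reassignment: target areas are converted to integer cell quotas by
largest-remainder apportionment (conserving the valid-cell count exactly),
classes above quota donate to classes below quota, and donors flip in
order of (suitability of gaining class − suitability of current class),
ties broken by a seeded shuffle then stable cell index — fully
deterministic per seed. Flips i→j with *A*<sub>ij</sub> = 0 are forbidden:
the estimated matrix defines the feasible change set. Up to `max_iter`
sweeps (default 10) are run, recomputing suitability from the evolving map
after the first sweep so growth attaches to existing patches; residual
demand after the last sweep is reported, never silently dropped. No
external driver layers (roads, slope, climate) enter the rule; the
neighborhood term is the only spatial force, which keeps the stage fully
specified by the data it is given.

**Benefit transfer and elasticity.** Class areas (hectares, full precision
internally; tables render 10⁴ ha at 2 decimals) multiply a 7×9
value-coefficient matrix (US$ ha⁻¹ yr⁻¹). The class margin ESV_k, function
margin ESV_f and total ESV are different margins of one matrix product, so
Σ_k ESV_k = Σ_f ESV_f holds to machine precision and is asserted, not
assumed. Change between years is 100·(ESV₂−ESV₁)/ESV₁, with zero baselines
flagged as undefined (NaN + warning) rather than 0 or ∞. The coefficient
of sensitivity perturbs one class's whole row by a signed fraction δ
(default ±0.5) and reports CS = relative change of total / δ. Valuation is
linear, so CS equals the class's value share ESV_k/ESV for any δ — the
tests verify this numerically at δ ∈ {±0.1, ±0.5} instead of assuming it —
and CS for an all-zero row (bare land) is defined as 0, since the formula
degenerates to 0/0.

**Kappa validation.** Simulated and observed maps are compared over their
harmonized mask via the confusion matrix: p₀ is the diagonal fraction, p_c
the chance agreement from the product of marginals, κ = (p₀−p_c)/(1−p_c)
(Cohen's form). When both maps are constant and identical p_c = 1 and κ is
undefined; the result is flagged instead of coerced. The implementation is
cross-checked in the test suite against scikit-learn's
`cohen_kappa_score` as an independent oracle.

## Packaged reference inputs

`ecoserv.data` ships, at the published precision, the Central Asia
per-class area table (1995/2005/2015 observed from a 300 m satellite
land-cover product, 2025/2035 CA-Markov projections; constant total
40,010.48 × 10⁴ ha) and the 7-class × 9-function value-coefficient matrix
(class totals 5,567 / 3,137 / 4,166 / 25,681 / 6,661 / 0 / 12,512 US$
ha⁻¹ yr⁻¹, derived from the de Groot et al. global unit values). The
packaged CCI-LC-style legend is a documented best-effort stand-in: the
exact raw-code mapping behind the reference tables was never published.

### Known inconsistencies in the reference tables

A faithful implementation reproduces ~90% of the published derived cells
to within 0.01–0.07% (the residue of rounding areas to 2 decimals of
10⁴ ha). The remaining cells are internally inconsistent with their own
printed inputs, and the package reproduces the formulas, not those cells:

- **2025 wetland and urban class values** (32.47 and 6.45 billion US$)
  do not follow from the printed 2025 areas (125.25 and 90.82 × 10⁴ ha →
  32.17 and 6.05). The urban value implies an area of ~96.83 × 10⁴ ha,
  consistent with the 89.19 → 116.47 trajectory, suggesting the printed
  2025 area is the typo.
- **Gas-regulation function row**: printed values sit ~1% above
  grassland-area × 9 US$/ha and match a coefficient of 9.1 — but the
  printed grassland total (4,166) is only consistent with 9.
- **Soil-formation function row**: printed values match a wetland
  coefficient of 4,231 rather than the printed 4,320 (a digit
  transposition in one of the two places); the printed wetland total
  (25,681) is only consistent with 4,320.
- **Sensitivity table, wetland 2005/2015** (1.42%/0.03 and 1.79%/0.04):
  inconsistent with the linear model, under which the wetland share — and
  hence the percent change — is ~1.03–1.08% and CS 0.02 in every year
  (the published 2025/2035 wetland cells agree with the model).

The corresponding acceptance tests assert the published values and
therefore fail on exactly these cells; that failure is the documentation.

Comparisons against published 2-decimal values use a 0.1% relative band
floored at 0.005 absolute — never tighter than the precision the values
were printed with (for a value like 1.84, printed precision alone is
±0.27%).

## Synthetic landscapes

The multi-epoch rasters behind the reference tables are not deposited in
any archive, so the spatial stages are exercised on neutral landscapes:
a standard-normal field smoothed with a Gaussian kernel (radius =
`patchiness`, in cells; 0 gives independent noise) is ranked, and ranks
are cut at the cumulative class proportions — realized composition
therefore matches the request to within one cell at any patchiness, and
generation is O(cells) and bitwise deterministic per seed. Defaults mirror
the study conditions: 1995 Central Asia class shares (grassland 51.4%,
bare 23.9%, cropland 19.0%), 9 ha cells (a 300 m grid), patchiness 3.

`evolve` advances a landscape under a known matrix *A*: unclustered mode
samples each cell's next class independently from its row of *A* — the
exact generative inverse of the estimator, enabling recovery tests —
while clustered mode draws per-(source, destination) flip counts from the
same multinomial law but assigns flips to the cells most suitable for the
destination class, producing spatially aggregated change with
multinomially faithful composition. A fixture matrix
(`reference_transition`) encodes the reference drift pattern — strong
diagonal persistence, cropland/urban expanding, water shrinking.

What the synthetic tests do **not** show: real products carry spatially
structured classification error, anisotropic geography (mountain ranges,
the Aral basin) and non-stationary transition rates, none of which the
neutral generator emulates. Passing the recovery and allocation tests
demonstrates correctness of the algorithms, not skill of the projections
on real Central Asian data; the published hindcast kappa of 0.93 for the
2015 map requires the external satellite product and is out of scope here.

## Problem sizes and numerical choices

The test and acceptance workloads are desk-scale by design: transition
recovery uses a 320×320 grid (≈10⁵ cells) with every class holding ≥5% of
cells — with the highly skewed real shares, rare-class rows (urban,
0.07%) would be dominated by binomial noise (σ ≈ 0.04 at 10⁵ cells)
rather than estimator error, so the recovery bound max|Â−A| < 0.02 is
checked where it is statistically meaningful. Allocation is checked on
200×200 grids with the demand from one Markov step; the greedy allocator
reaches zero integer residual there in one or two sweeps. Composition
agreement between `evolve` and `project_state` is asserted within 3σ
binomial error plus one cell of rounding. The whole suite runs in well
under two minutes on one CPU.

Other numerical conventions: state vectors are validated to sum to 1
within 10⁻⁹ and renormalised after projection only against accumulated
round-off; transition rows must sum to 1 within 10⁻⁹; masks are always
harmonized (union of nodata) before any two-map operation; all
randomness flows through `numpy.random.default_rng` seeds exposed in every
generator, the allocator and the CLI.

## Design choices where the design was open

- **Raster formats**: single-band integer TIFF (geo-metadata as JSON in
  the ImageDescription tag) and ESRI ASCII grid for plain-text fixtures.
  Inputs are assumed co-registered; reprojection/resampling is explicitly
  out of scope.
- **Model-object surface**: the estimation half is exposed
  statsmodels-style (`LandChangeModel.fit() → LandChangeResults`,
  `BenefitTransferModel.fit() → ValuationResults` with `summary()` and
  `plot()`), over a functional core (`raster`, `markov`, `ca`,
  `valuation`, `sensitivity`, `synthetic`) that remains the library API.
- **CA parameters**: window 5×5 and 10 sweeps per interval are the
  conventional defaults of this model family; both are explicit
  configuration, since no canonical values exist for the reference study.
- **Cell area**: explicit user-supplied hectares per cell (scalar or
  per-cell grid); the package never guesses how grid cells convert to
  hectares.

## Limitations

Stationary first-order Markov dynamics; a single neighborhood-density CA
driver; benefit-transfer valuation inherits all criticisms of global unit
values (homogeneity within classes, no cost accounting, urban coefficients
of debated meaning); no currency-year adjustment; no uncertainty
propagation beyond the ±50% elasticity screen.
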