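# Methods

This note documents the models implemented by `dentaccess`, the choices
made where the methodology left room, and what the synthetic study regions
do and do not establish about real data.

## Two-step floating catchment area (2SFCA)

Demand points are villages with populations `P_k` at planar centroids;
supply points are dental facilities with dentist counts `S_j`. With a
travel-time threshold `t0` (default 10 minutes at 60 km/h):

1. **Facility ratios.** Each facility's catchment is the set of villages
   within `t0` minutes (closed boundary: a village exactly at `t0` is
   inside). Its supply-to-demand ratio is
   `R_j = S_j / Σ_{k ∈ catchment(j)} P_k`.
2. **Village scores.** Each village's accessibility is the sum of ratios of
   all facilities it can reach within the same threshold:
   `R_i = Σ_{j : t(i,j) ≤ t0} R_j`.

`R_i` is the per-person annual supply of dentist services. The classic
provider-to-population language converts by reciprocal: one dentist per
2,000 persons per year is `R = 0.0005`; the 1:4,000 shortage criterion is
`R = 0.00025`. A township is flagged **dental-resource deficient** when the
population-weighted mean of its villages' scores falls below a threshold.
The weighting is a package choice — the aggregation rule is not canonical —
and is exposed in `classify_deficiency`; quartile groups (plus a separate
zero-access group) use unweighted village-level quantiles with half-open
`(low, cut]` bins, because the conventional five-group presentation uses near-equal
village *counts*, not population shares.

Key invariant: with symmetric travel times and no empty catchments, the
method conserves supply exactly — `Σ_i P_i R_i = Σ_j S_j`. This identity is
enforced in the tests at 1e-9 relative tolerance and achieves ~1e-16 in
practice.

Degenerate conventions: a facility whose catchment is empty (or has zero
population) gets `R_j = 0` with a logged warning; villages reached by no
facility score 0; ties at a quartile cut stay in the lower bin; if all
positive scores are identical the four quartiles are filled by stable rank
order with a warning.

## Spatial weights

Rook contiguity: two polygons are neighbours iff their intersection has
positive length (shared corner points do not count). From an edge list,
adjacency is taken as given after symmetrization. Row standardization
divides each row by its neighbour count; islands (no neighbours) are kept
explicit and excluded from statistics that are undefined for them. On the
synthetic lattice, township polygons are square cells, so rook adjacency is
exactly the 4-neighbourhood — which is what makes the builder testable
against a closed form.

## Local and global Moran's I

With row-standardized weights and deviations `z_i = y_i − ȳ`,
`m2 = Σ z²/n`:

    I_i = (z_i / m2) · Σ_j w_ij z_j,      I = Σ_i I_i / n.

Inference is by conditional permutation: `y_i` stays fixed while the other
`n − 1` values are randomly reassigned to the neighbour slots. The pseudo
p-value is two-sided,

    p_i = (#{ |I_perm − E[I_i]| ≥ |I_obs − E[I_i]| } + 1) / (n_perm + 1),

centred on the **exact** conditional permutation mean
`E[I_i] = (z_i/m2) · mean(z_{−i})` (globally, `E[I] = −1/(n−1)`). Using the
analytic centre rather than the empirical permutation mean matters: with an
estimated centre, statistic values exactly mirror-tied around it are
classified inconsistently between finite sampling and full enumeration, and
the sampled pseudo p fails to converge to the enumerated one. With the
analytic centre, Monte-Carlo p-values converge to the full-enumeration
reference (verified on 5-unit paths where all 4! conditional permutations
can be enumerated).

Units significant at `alpha` (default 0.05, no multiple-testing correction)
are labelled by the quadrant of `(z_i, lag_i)`: HH/LL clusters, HL/LH
outliers; the rest are "not-significant", islands are "island". Two-sided
inference is a deliberate choice consistent with the rest of the package's
testing conventions; note that GeoDa's default LISA p-values are one-sided,
so labels need not match a GeoDa run at the same nominal level. Calibration
is checked empirically: on iid Normal fields (15×15 lattice, 999
permutations) the share of significant labels at alpha = 0.05 sits in
[0.03, 0.08].

## Spatial error model (SEM)

Model: `y = Xβ + u`, `u = λWu + ε`, `ε ~ N(0, σ²I)`, with W
row-standardized from a symmetric adjacency without islands. Estimation
maximizes the log-likelihood concentrated in λ:

    β(λ)  = (X'B'BX)⁻¹ X'B'B y,   B = I − λW
    σ²(λ) = e'e/n,                e = B(y − Xβ(λ))
    L(λ)  = −(n/2)(ln 2π + 1 + ln σ²(λ)) + Σ_i ln(1 − λω_i)

where `ω_i` are the eigenvalues of W, computed densely via the symmetric
similarity transform `D^{−1/2} A D^{−1/2}` (the intended problem sizes are
hundreds of townships/counties, so exactness beats scalability). λ is
maximized by bounded scalar optimization over `(1/ω_min, 1/ω_max)` shrunk
by 1e-5 to keep the log-Jacobian finite; the optimizer agrees with a 1e-4
grid search to within 2e-4. At `λ = 0` the likelihood reduces exactly to
the Gaussian OLS likelihood with MLE variance `e'e/n` (a variance floor of
1e-20 guards exact fits), which makes the likelihood-ratio diagnostic for
spatial dependence — `2(L_SEM − L_OLS)` against chi-square(1) — well
defined and non-negative by construction.

Standard errors come from the numerical Hessian (central differences) of
the full log-likelihood in `(β, λ, σ²)` at the optimum; coefficient
p-values are asymptotic two-sided normal z-tests. If the Hessian is not
finite (e.g. a numerically exact fit), SEs are reported as NaN with a
warning rather than fabricated. The reported fit measure is a pseudo-R²,
`1 − var(y − Xβ̂)/var(y)`; it is *not* claimed to match any particular
software's "R-squared".

Calibration, verified by simulation in the test suite: on a 12×12 lattice
with `λ = 0.6`, `β = (1, −2, 0.5)`, `σ = 1`, 200 replicates give mean λ̂ in
[0.52, 0.68] and mean β̂ within ±0.1 of truth; under `λ = 0` the LR test
rejects at the 5% level in 2–9% of 400 replicates (the size simulation uses
a 10×10 lattice); |bias(λ̂)| shrinks from the 7×7 to the 15×15 lattice.

## Synthetic study regions

The generator produces the data structure the analysis needs, at roughly
the scale of a national dental-care study area, with full seed control
(independent spawned RNG streams for placement, populations, facilities and
noise, so adding a draw to one stream never perturbs another):

- **Geometry.** An 18×20 lattice of 10 km square townships (360 cells,
  counties = lattice rows); villages placed uniformly inside their cell,
  roughly 12–30 per township (~7,500 total). Coordinates are planar metres;
  no geodesy, because the analysis only consumes distances.
- **Population.** Village populations are log-normal (μ = 7.5, σ = 1, mean
  ≈ 3,000) multiplied by a spatially correlated township density field
  (SAR-smoothed Gaussian, ρ = 0.7, SD 0.6 on the log scale). The field
  creates contiguous urban cores and remote peripheries instead of
  salt-and-pepper heterogeneity; urbanization is labelled by density
  septiles, densest block = "highly urban", giving the 7-level ordered
  gradient used for stratified reporting.
- **Supply.** 6,900 facilities with `1 + Poisson(1.2)` dentists each
  (~15,000 dentists, about one per 1,500 persons — the approximate national
  ratio of the study setting), hosted by villages drawn with probability
  `∝ population^1.4`. The super-proportional exponent concentrates supply
  in dense areas, which is what produces a small zero-access group and a
  few percent of townships deficient at the 1:4,000 line, the qualitative
  structure seen in real national data. Facilities sit 50–300 m off the host
  centroid so distinct points never have zero travel time.
- **Travel times.** Euclidean distance at 60 km/h times a road detour
  factor drawn uniformly in [1.0, 1.4] per unordered pair (symmetric by
  construction; zero distance is zero minutes).
- **Quality panel.** Three indexes on a percent scale (fluoride service for
  under-6s, calculus removal for 13+, 2-year filling preservation) are
  generated township-by-year from the same spatial-error process the
  regression assumes: `y = Xβ + (I − λW)⁻¹ε` with X = (intercept,
  township accessibility, county DMFT). Default coefficients are chosen so
  the cross-sections resemble levels typical of national insurance
  quality reporting (medians ≈ 43%, 55%,
  99.9%) with a visible accessibility effect for the first two indexes and
  a negligible one for filling preservation, plus a rising year trend for
  fluoride service only. The DMFT caries-experience covariate is county-
  level Normal(2.5, 0.5). Values are clipped to [0, 100].

**What passing tests show — and don't.** The synthetic regions exercise
every code path with known ground truth: conservation identities,
estimator recovery, permutation-test calibration and determinism. They do
not reproduce real road networks, actual administrative geography, claims-
level behaviour, or real descriptive statistics (which depend on
restricted national data); agreement of pipeline outputs with real-world
tables is structural (same groups, same arithmetic conventions), not
numerical.

## Numerical and reporting conventions

- Quantiles everywhere use linear interpolation between order statistics.
- Percentages print to two decimals, accessibility scores to five;
  internal computation is full precision.
- Pipeline runs are deterministic: fixed config + seed gives byte-identical
  artifact bundles; the manifest records a config hash and all counts.
- The LISA stage and per-index SEM fits degrade gracefully on degenerate
  inputs (zero-variance values, collinear design): the stage is skipped
  with a logged warning and an explicit marker in the manifest rather than
  aborting the run.
- Problem sizes in the validation suite (200 LISA replicates on 15×15, 200
  SEM recoveries on 12×12, 400 LR-size replicates on 10×10, 50 small
  regions for conservation) were chosen to give stable Monte-Carlo bands at
  desk scale.

## Known limitations

- Plain 2SFCA only: no distance-decay (enhanced/Gaussian) variants, no
  isochrone geometry, no multi-modal transport.
- SEM only: no spatial-lag or Durbin models, no GMM, no robust SEs.
- The P/D (population per dentist) column is reported under two
  definitions — stratum totals divided, and the mean of village-level
  ratios over villages hosting dentists — because the canonical definition
  is ambiguous; the columns are labelled accordingly.
- With ~20 spatial units (county-level fits) ML standard errors are
  optimistic; the package's validation is by simulation recovery at larger
  n, not by matching any real county-level fit.
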