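# dentaccess

Spatial accessibility of dental care and its association with care quality.

`dentaccess` is a reusable, tested implementation of the spatial analysis
chain used in health-services geography to ask: *where are dental resources
scarce, and is care quality worse there?* It targets researchers and health
planners working with village-level population data, facility registers and
area-level quality indicators. The package covers:

- **2SFCA accessibility** — the two-step floating catchment area method:
  each facility's supply-to-demand ratio `R_j = S_j / Σ_{k∈catchment(j)} P_k`
  over the population within a 10-minute drive-time catchment, then each
  village's score `R_i = Σ_{j reachable} R_j` (per-person annual supply of
  dentist services).
- **Deficiency classification** — thresholds from provider-to-population
  ratios (1 dentist : 2,000 persons ⇔ R = 0.0005; 1 : 4,000 ⇔ R = 0.00025),
  applied to population-weighted township aggregates, plus quartile
  grouping with a separate zero-access group.
- **LISA cluster detection** — local Moran's I
  `I_i = (z_i/m2)·Σ_j w_ij z_j` with rook-contiguity weights, two-sided
  conditional-permutation pseudo p-values and HH/LL/HL/LH labelling.
- **Spatial error regression** — maximum-likelihood estimation of
  `y = Xβ + u`, `u = λWu + ε` via the concentrated likelihood
  `L(λ) = −(n/2)(ln 2π + 1 + ln σ²(λ)) + Σ ln(1 − λω_i)`, with a 1-df
  likelihood-ratio diagnostic for spatial dependence.
- **Synthetic study regions** — a seeded generator producing lattice
  townships, villages with a spatially correlated density gradient,
  facilities clustered toward dense areas, symmetric noisy travel times and
  quality indexes drawn from a known spatial-error process, so the whole
  chain is testable end to end with ground truth.

See `docs/methods.md` for the full model documentation and design choices.

## Worked example

```python
import dentaccess as da

cfg = da.PipelineConfig(seed=1)          # defaults: 10-min catchment, 60 km/h
manifest = da.run_pipeline(cfg, "out")   # writes the full artifact bundle
```

On the default synthetic region (360 townships, 7,511 villages, 26.2M
persons, ~15k dentists) this prints, via the bundled report tables:

```text
group  n_villages  total_population  pct_population  mean_R    sd_R
 zero           5              2230            0.01 0.00000 0.00000
   Q1        1877           3634819           13.86 0.00027 0.00007
   Q2        1876           5554785           21.18 0.00042 0.00003
   Q3        1876           6898089           26.30 0.00054 0.00004
   Q4        1877          10138643           38.65 0.00076 0.00013
total        7511          26228566          100.00 0.00050 0.00019

 threshold  n_deficient  n_townships  pct_deficient
   0.00050          199          360          55.28
   0.00025           14          360           3.89
```

Reading it: five villages have no facility within a 10-minute drive; the
zero group plus four near-equal quartile groups split the region by
accessibility, and richer quartiles hold disproportionately more people
(supply clusters where people are). At the strict 1:4,000 shortage line,
3.89% of townships are dental-resource deficient; the looser 1:2,000 line
flags far more. Downstream stages report spatial clustering of township
accessibility (global Moran's I = 0.4821, pseudo p = 0.001) and the
spatial-error fits, e.g. for the simulated fluoride-service index
λ̂ = 0.45 with a significant accessibility coefficient (p = 0.019) and
LR spatial-dependence p = 7.5e-11 — recovering the generative process the
panel was drawn from.

The same stages are scriptable from a shell:

```bash
dentaccess run-all --seed 1 --out out/           # everything
dentaccess synth  --seed 1 --out region/         # region + OD matrix only
dentaccess access --region-dir region/ --out acc/
```

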