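# cumimpact

Data-driven cumulative impact assessment for benthic marine habitats.

Maritime spatial planning needs to know how much habitat a management scenario
— more or less nutrient loading, invasive species spread, offshore wind-park
construction — will cost or create, and with what confidence. `cumimpact`
implements the full chain for that question on a 1 km² analysis grid:

1. **Evidence compilation** — a flat table of quantitative impact-site vs
   reference-site comparisons (mean, dispersion, n per arm) for each benthic
   habitat × human pressure, the kind of data extracted from field surveys and
   manipulative experiments.
2. **Meta-analysis** — per-study response ratios RR = x̄ᵢ/x̄ᵣ analysed on the
   log scale with delta-method variance
   `var(ln RR) = sdᵢ²/(nᵢ x̄ᵢ²) + sdᵣ²/(nᵣ x̄ᵣ²)`, pooled per habitat ×
   pressure with DerSimonian–Laird random effects
   (`τ² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw))`) into *sensitivity scores*:
   pooled RR with a 95 % CI. RR < 1 means habitat loss, RR > 1 gain. A one-way
   ANOVA on the ratio-scale effect sizes screens whether pressures differ
   within a habitat.
3. **Scenario prediction** — co-registered habitat-cover and
   pressure-intensity rasters; per cell
   `ln RR_cell = Σₚ intensityₚ · ln RRₚ` (direct jointly-observed scores
   override the product rule), new cover = `clip(cover · RR_cell, 0, 1)`;
   CI bounds propagate into min/mean/max cover maps; impacts are strictly
   local to each cell and regional totals are sums over impacted cells.

A synthetic-data module generates evidence tables and seascapes (cover
fields, coastal nutrient gradients, invader presence, wind-park polygons)
with known ground truth, so the whole chain is testable by parameter
recovery without access to any real habitat maps.

## Worked example

Simulate a demonstration data set (450 evidence records with the published
observation-count structure, plus a 30×30-cell seascape), pool it, and run
three scenarios on the reef habitat:

```sh
cumimpact simulate-data --out sim --seed 1 --rows 30 --cols 30
cumimpact build-matrix --evidence sim/evidence.csv --out matrix
```

```text
ANOVA reef: df=(4,167) SS=(3.047,35.722) MS=(0.762,0.214) F=3.561 p=0.008137 *
ANOVA sandbank: df=(4,242) SS=(106.791,203.670) MS=(26.698,0.842) F=31.722 p=2.999e-21 *
...
sensitivity matrix: 19 keys -> matrix/sensitivity_matrix.csv
```

Each matrix row is one habitat × pressure-set score, e.g.
`fucus,nutrient_load,10,0.463,0.315,0.682,0.372,direct`: 10 studies pool to
RR 0.46 (95 % CI 0.31–0.68, τ² = 0.37) — nutrient load roughly halves
bladder-wrack cover. With a scenario config listing habitat and pressure
rasters:

```sh
cumimpact run-scenario --config scenarios.yaml \
    --matrix matrix/sensitivity_matrix.csv --out runs
```

```text
s1_current_nutrients x reef: pct(min/max/mean)=(-27.7,-5.6,-13.8) cells(habitat/impacted)=(900,900) cover=277.7 km2 change=-40.3 km2 total=-15 %
s3_nonnative_species x reef: pct(min/max/mean)=(-56.5,-27.5,-40.8) cells(habitat/impacted)=(900,791) cover=277.7 km2 change=-111.2 km2 total=-40 %
s2_mai_reduction x reef: pct(min/max/mean)=(-21.6,-4.2,-10.6) cells(habitat/impacted)=(900,900) cover=277.7 km2 change=-31.0 km2 total=-11 %
```

Reading the first line: under the current nutrient load the per-cell reef
cover change ranges from −27.7 % to −5.6 % (mean −13.8 %) over the 900
impacted cells; of 277.7 km² of total reef cover, 40.3 km² is predicted lost,
a −15 % total change. The run directory also holds min/mean/max cover
GeoTIFFs (the propagated 95 % CI envelope), a percent-change GeoTIFF per
habitat, the summary CSV and a checksummed manifest. Comparing the
business-as-usual and 25 %-reduction nutrient runs:

```sh
cumimpact compare --result-a run_s1/scenario_summary.csv \
    --result-b run_s2/scenario_summary.csv --out delta.csv
```

```text
habitat_id           scenario_a       scenario_b  delta_total_pct_change  delta_areal_change_km2
      reef s1_current_nutrients s2_mai_reduction                       4                9.297278
```

— the load reduction saves 9.3 km² of reef (+4 percentage points), and the
same comparison is non-negative for every habitat whose nutrient RR < 1.

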