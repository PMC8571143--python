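# tmediv

Immune-infiltrate **diversity analysis for multiplex-immunofluorescence TMA
cores**, aimed at the follicular-lymphoma tumour microenvironment: from
per-cell marker intensities to Shannon diversity indices, per-core feature
tables, and prognostic survival statistics — plus a synthetic TMA-cohort
generator so every stage is testable against known ground truth.

## The problem

Follicular lymphoma outcomes vary widely, and the non-neoplastic immune
microenvironment (T-helper cells, cytotoxic T cells, macrophages, Tregs,
follicular-helper cells) carries prognostic information that single-marker
counts capture poorly. Multiplex immunofluorescence (here: DAPI, CD4, CD8,
CD68, FOXP3, PD-1, CD21) phenotypes every cell in a 1.2 mm TMA core, and
ecology-style diversity indices summarise the composition of that
infiltrate in a single number per core.

## The indices

Each cell is scored positive per marker by a global intensity threshold on
its designated compartment (nucleus for FOXP3, membrane otherwise) and
labelled with one of the 2⁵ = 32 positivity-combination phenotypes over
CD4/CD8/CD68/FOXP3/PD-1 (cells positive for none are `DAPI_ONLY`, or
`CD21_ONLY` when CD21⁺; both are excluded from composition analysis as
potential tumour B cells). Two Shannon indices (natural log) follow:

* **phenotype entropy**  H = −Σᵢ pᵢ ln pᵢ over the phenotype proportions;
* **interaction entropy**  H = −Σ_{i≤j} p_ij ln p_ij over the proportions
  of phenotype-pair co-occurrences, where a co-occurrence is any unordered
  pair of cells within 30 μm (a 3–4 cell neighbourhood).

Alongside: subset densities (cells/mm² of artefact-free tissue), the
immune-infiltrate ratio (immune cells per DAPI-only cell), and the CD21⁺
follicular-dendritic meshwork area fraction. Per patient (triplicate
cores), the median feature is tested as a continuous covariate in Cox
proportional-hazards models (univariable and FLIPI-adjusted), dichotomised
at a maximally selected log-rank cutpoint with a Contal–O'Quigley adjusted
p-value, and related to POD24 by Mann–Whitney and logistic regression, with
Bonferroni correction over the feature family.

## Worked example

Simulate a small cohort and run the staged pipeline:

```sh
tmediv run-all --seed 7 --n-patients 20 --cell-density 600 --out demo
```

```
wrote synthetic cohort (40921 cells) to demo/data
scored 40921 cells -> demo/scored.csv
profiled 60 cores -> demo/features.csv
wrote survival results to demo/results
```

`demo/features.csv` holds one row per core:

```
   core_id  phenotype_entropy  interaction_entropy  immune_ratio  cd21_area_fraction
P000_core0           2.045188             3.254753      0.621810            0.184385
P000_core1           2.100522             3.240649      0.683117            0.187274
P000_core2           2.007541             3.365927      0.752427            0.176850
```

Phenotype entropy ~2.05 nats means this core's immune infiltrate is about
as diverse as e^2.05 ≈ 7.8 equally abundant phenotypes (max ln 32 ≈ 3.47);
an immune ratio of 0.62 means 0.62 immune cells per tumour-like DAPI-only
cell; 18% of the tissue is CD21⁺ meshwork. `demo/results/` then contains
the Cox tables (HR per unit feature with 95% CI — the generator links
higher entropy to lower hazard, so the entropy HR is far below 1 here),
the cutpoint report (for phenotype entropy: cut 1.968, standardised
supremum q = 1.374, adjusted p = 0.0457), POD24 tests and intra-patient
CoV summaries. Every output starts with `#` metadata lines (version, seed,
config hash), so identical invocations are byte-identical.

The same operations are available as a library:

```python
from tmediv import (SimulationConfig, generate_cohort, score_cells,
                    assign_phenotypes, build_cores, profile_core)

cohort = generate_cohort(SimulationConfig(seed=7, n_patients=20))
panel = cohort.config.panel()
cells = assign_phenotypes(score_cells(cohort.cells, panel), panel)
cores = build_cores(cells, cohort.annotations)
profile = profile_core(cores[0], panel)
print(profile.phenotype_entropy, profile.interaction_entropy)
```

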