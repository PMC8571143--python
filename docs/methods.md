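# Methods

`tmediv` quantifies the diversity of the non-neoplastic immune infiltrate in
follicular-lymphoma tissue microarray (TMA) cores imaged by multiplex
immunofluorescence, and evaluates those diversity indices as prognostic
biomarkers. This note documents the models, conventions, and numerical
choices, and what the synthetic-data tests do and do not demonstrate.

## Cell scoring and phenotyping

Input is a cell table produced by upstream segmentation: one row per cell
with centroid coordinates (μm, image convention — origin top-left, y
increasing downward) and the median intensity of each stain on each
compartment (nucleus, membrane). The panel is DAPI, CD4, CD8, CD68, FOXP3,
PD-1, CD21; FOXP3 is scored on the nucleus, all other stains on the
membrane. A single global threshold per marker converts intensities to
positivity calls; a cell is positive when its designated-compartment
intensity is **greater than or equal to** the threshold (the closed rule is
a convention — the boundary case is measure-zero in real data — chosen so
the call is deterministic and covered by a boundary test). DAPI drives the
segmentation, so every segmented cell is treated as DAPI-positive and no
DAPI threshold is applied.

Phenotypes are the 2⁵ = 32 positivity combinations of the five phenotyping
markers (CD4, CD8, CD68, FOXP3, PD-1), e.g. `CD4+CD8-CD68-FOXP3+PD-1-` for
a regulatory-T-like cell. Cells positive for none of the five are
`DAPI_ONLY` (predominantly tumour B cells) or, when CD21-positive,
`CD21_ONLY` (follicular dendritic cells). CD21 never enters a combination
code: a CD21⁺CD8⁺ cell is labelled by its phenotyping markers only. Each
cell receives exactly one label.

Cells are retained when inside the tissue polygon and outside every
artefact-exclusion polygon; polygon membership is boundary-inclusive
(`covers`), so a cell on an exclusion boundary is excluded.

## Diversity indices

**Phenotype entropy** is Shannon entropy, in nats, of the label proportions
among included cells: H = −Σᵢ pᵢ ln pᵢ, with 0·ln 0 ≡ 0. `DAPI_ONLY` and
`CD21_ONLY` cells are excluded (they may contain tumour B-cell subsets);
the exclusion set is configurable. Upper bound ln 32 ≈ 3.4657. Cores with
0 or 1 included cells return 0 with a logged warning rather than erroring.

**Interaction entropy** applies a co-occurrence (neighbourhood) analysis:
every unordered pair of distinct cells whose centroids lie within 30 μm —
roughly a 3–4 cell neighbourhood — is one interaction, typed by its
unordered phenotype pair {i, j}. The entropy of the interaction-type
proportions is H = −Σ_{i≤j} p_ij ln p_ij. Only `DAPI_ONLY` cells are
ignored here (so CD21-only cells do participate, following the narrower
stated exclusion for this index; both exclusion sets are configurable).
Conventions fixed by this package: closed distance rule (≤ radius),
Euclidean distance on centroids, no edge correction at core boundaries,
each cell pair counted once (ordered counting would double every count and
leave the proportions — hence the entropy — unchanged). The implementation
uses a k-d tree radius query; tests require exact agreement with a naive
all-pairs enumeration, including pairs at exactly the radius.

**Densities and ratios.** Subset densities divide the count of cells
matching a marker-positivity expression (e.g. `CD4+CD68-PD-1+`; unmentioned
markers unconstrained, so `CD68+` counts all CD68⁺ cells regardless of
co-expression) by the artefact-free tissue area in mm². The default
reported subsets are CD4+CD68− (T helper), CD4+FOXP3+ (Treg), CD8+, CD68+,
CD4+CD68−PD-1+ and CD8+PD-1+. The immune-infiltrate ratio divides cells
positive for ≥1 phenotyping marker by `DAPI_ONLY` cells (CD21-only cells in
neither term); it is undefined, and raises, when a core has no DAPI-only
cells. The CD21 meshwork area fraction is the union of the annotated
meshwork polygons, clipped to tissue and minus exclusions, over the
artefact-free tissue area.

## Patient-level statistics

Cores are sampled in triplicate; the per-patient value of each feature is
the **median** over available cores. Intra-patient heterogeneity is the
coefficient of variation, 100·sd/mean (n−1 sd), across a patient's cores;
patients with <2 cores or non-positive mean are skipped with a notice, and
the cohort summary is the **median** CoV across contributing patients
(median chosen over the mean for robustness at small cohort sizes).

Cox proportional-hazards models (lifelines, Efron tie handling — monthly
resolution produces many ties) treat each feature as continuous, one model
per feature, optionally adjusted for the FLIPI ordinal score 0–5 with
listwise deletion of missing FLIPI (reduced n logged). Kaplan–Meier curves
report linear Greenwood 95% bands, S(t) ± 1.96·S(t)·√(Σ d/(n(n−d))),
clipped to [0, 1]. POD24 (progression within 24 months) is compared by
two-sided Mann–Whitney U and by logistic regression (univariable and
FLIPI-adjusted). Bonferroni controls the family of features tested in one
run: with the default 10 features at α = 0.05 the per-test threshold is
0.005, flags use the closed ≤ rule, and raw p-values are always reported
alongside.

### Optimal cutpoint

Continuous features are dichotomised for Kaplan–Meier display at the cut
maximising the two-sample log-rank statistic. Because the maximum is taken
over many candidate cuts, the best cut's raw log-rank p is anti-conservative;
the adjusted p follows the Contal–O'Quigley construction: with D events and
per-subject log-rank scores uᵢ = δᵢ − Λ̂(tᵢ) (pooled Nelson–Aalen), the
numerator at cut k is the score sum over the high group, the supremum of
|S_k| over admissible cuts is standardised by s·√(D−1) with
s² = (D−1)⁻¹ Σ aᵢ², aᵢ = 1 − Σ_{j≤i} 1/(D−j+1), and referred to the tail of
the supremum of a Brownian bridge, 2Σ_{j≥1}(−1)^{j+1}exp(−2j²q²)
(series truncated below 1e−12, clamped to [0, 1]; q = 1 gives 0.2700).
Candidate cuts are the distinct observed values leaving ≥10% of subjects in
each group (configurable); ties at the cut go to the low group; the first
(smallest) maximiser is chosen deterministically. The standardisation is
validated against a permutation null of the supremum statistic — the
authoritative internal oracle — and a 500-cohort null simulation shows
near-nominal type-I error for the adjusted p while the naive minimum-p is
far above nominal (both numbers are recomputed by the acceptance script).

## Synthetic cohorts

The generator emulates the study design: circular cores of diameter 1.2 mm
in triplicate, homogeneous Poisson cell counts at a default 1800 cells/mm²
(~2000 cells per core), phenotype labels drawn from per-patient proportions
that are Dirichlet perturbations (concentration 1/sd², default sd 0.08) of
a follicular-lymphoma-like base mixture (55% DAPI-only tumour cells, 2%
CD21-only, the rest spread over T-helper, cytotoxic, macrophage, Treg and
PD-1⁺ subsets). Follicles are discs (default 3 of radius 150 μm) emitted as
the CD21 meshwork annotations; labels with a follicle multiplier (default:
CD4⁺PD-1⁺ codes, 4×, emulating follicular-helper enrichment) have their
positions re-weighted by rejection sampling, which clusters them spatially
without touching the marginal label proportions.

Intensities are two-component log-normals per marker (log-sd 0.4, log-means
0 and 3.2): the positive and negative components each sit 4 log-sd from the
geometric-midpoint threshold, i.e. positive cells are ~25× brighter —
representative of a well-separated stain. Under these conditions midpoint
thresholds recover >99.9% of generated labels; per-marker misclassification
is Φ(−4) ≈ 3×10⁻⁵. (Were the component *means* only 4 sd apart, the
per-marker error Φ(−2) ≈ 2.3% would compound over five markers to ~89%
per-cell accuracy — a useful reminder that per-cell phenotype accuracy
degrades much faster than per-marker accuracy.)

Survival follows a Weibull proportional-hazards model (shape 1.2, OS scale
240 months) with log-hazard linear in the cohort-standardised true
phenotype entropy (default −1.5 per SD, i.e. higher diversity →
better survival) plus an ordinal FLIPI term (0.25 per point). Censoring is
an independent exponential time whose rate is calibrated (Brent's method on
the realised event times) to the target expected censoring fraction
(default 70% for OS); rate 1 censors everyone (guard case). Times are
rounded to whole months to exercise tie handling. PFS uses a faster
baseline and is emitted for the rituximab-treated subset only; POD24 is
derived from PFS (event ≤24 months; undefined without 24 months of
progression follow-up).

Each patient owns an independent seed sub-stream, so cell tables are
invariant to adding patients; clinical outcomes standardise the feature
across the cohort and therefore are cohort-level by construction.

**What passing these tests shows** — that the pipeline arithmetic, counting,
geometry and statistical calibration are correct under a known generative
model. **What it does not show** — robustness to real-data phenomena the
generator omits: segmentation error, spectral bleed-through, spatially
varying staining intensity, non-disc follicles, informative censoring, or
correlation between FLIPI and the microenvironment.

## Problem sizes and numerics

Simulation studies use sizes chosen to give tight Monte-Carlo error at
interactive run times: cutpoint calibration, 500 null cohorts of n = 100
with ~40% events; Cox recovery, 200 cohorts of n = 500 via the
patient-level feature path (cell-level simulation adds nothing to a
survival-calibration question); spatial-oracle equivalence, 100 random
cores up to 500 cells; the end-to-end pipeline demonstration, 60 patients ×
3 cores at 700 cells/mm². Determinism checks compare output bytes, which is
size-independent. Entropy sums skip zero-probability terms; empty or
single-cell cores yield entropy 0 with a warning; degenerate model fits
(no events, constant feature, separation in logistic models) raise typed
errors or report NaN rather than silently continuing.

## Known limitations

* The spatial-interaction index uses a single radius per run; multi-radius
  curves are out of scope.
* Follicular/interfollicular region inference from CD21 staining is not
  performed; meshwork polygons are inputs.
* FLIPI is consumed as an ordinal score, never computed from raw clinical
  variables.
* The Brownian-bridge adjustment is asymptotic; at very small event counts
  it drifts from the exact permutation tail (the permutation null in
  `tmediv.cutpoint.permutation_sup_null` is available when exactness
  matters).
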