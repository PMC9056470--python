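# pollinet

Trait-based analysis of resource overlap between wild pollinators and the
honeybee (*Apis mellifera*) on bipartite plant–pollinator visitation
networks.

Managed honeybees can compete with wild pollinators for floral resources.
Whether and where that potential competition is strongest depends on
functional traits: a wild bee whose proboscis matches the honeybee's can
drink from the same flowers, a central-place forager cannot simply move
away from a honeybee-rich site, and the structure of the local plant
community determines how much room there is to partition resources.
`pollinet` implements, as a tested and reusable pipeline, the full
analysis a field study of this question runs after the specimens are
identified: per-network niche overlap with a focal species, plant
functional diversity, pollinator trait similarity, and an AICc
multimodel-averaging regression suite — plus seeded synthetic-data
generators with known ground truth, so every stage can be validated end
to end.

It is aimed at community ecologists working with site × species × species
visitation records (one bipartite network per site) and a focal
super-generalist present everywhere.

## What it computes

**Niche overlap** (`pollinet.niche_overlap`). For each wild pollinator
*i* with visit-count vector *x* over the site's plants, and the focal with
vector *y*, Morisita's index

C_λ = 2 Σ xᵢyᵢ / ((λ_x + λ_y) · X · Y),  λ_x = Σ xᵢ(xᵢ−1) / (X(X−1)),

or the Morisita–Horn proportion form C_H = 2 Σ pᵢqᵢ / (Σ pᵢ² + Σ qᵢ²),
which is guaranteed to lie in [0, 1] (the count-corrected original can
slightly exceed 1 on small samples). Site-level responses are
community-weighted means (CWM): per-species values weighted by species
abundance, optionally split by trait category.

**Plant functional diversity** (`pollinet.functional_diversity`). Corolla
length is z-scored, colour and Kugler flower type are dummy-coded; a
Euclidean distance matrix over the pooled species list is ordinated with
PCoA; communities are scored in the shared reduced space by FRic (convex
hull volume, standardised by the global pool's hull, so FRic ∈ (0, 1])
and FDis (abundance-weighted mean distance to the abundance-weighted
centroid).

**Trait similarity** (`pollinet.trait_metrics`). Gower similarity of each
wild species to the focal over four equally weighted traits: proboscis
length, body length (range-normalised over the pooled species list),
foraging-range class and taxonomic family. Also: banding of proboscis
(<4 / 4–7 / ≥7 mm) and body (<8 / 8–15 / ≥15 mm) relative to the focal's
morphology, and pooling of families with fewer than ten collected
individuals into "other".

**Multimodel inference** (`pollinet.multimodel`). Predictors scaled to
mean 0 / sd 1; all marginality-respecting sub-models of a global model
enumerated (an interaction enters only with all its lower-order terms);
OLS or ML random-intercept fits; AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1);
Akaike weights over the full candidate set; full ("zero-substitution")
model averaging with Burnham–Anderson unconditional SEs and 95% CIs;
VIFs; Moran's I on residuals with inverse-distance weights.

**Pipeline** (`pollinet.pipeline`, CLI `pollinet`). Six model sets: ln CWM
overlap regressed on ln focal abundance (*Apis*), temperature, FRic (or
FDis) and trait similarity with their two- and three-way interactions
(Models 1–2, 38 candidates each), and four mixed models on the site ×
trait-category table — proboscis band, body band, foraging range, family —
with a site random intercept (Models 3–6).

## Worked example

```
pollinet all --seed 42 --out run/
```

simulates a 51-site study (trait-matching visitation mechanism, honeybee-
like focal present everywhere), computes all site metrics and runs the six
model sets. From `run/metrics/site_metrics.csv` and
`run/models/model1_averaged.csv` of that run:

```
>>> import pandas as pd
>>> sm = pd.read_csv("run/metrics/site_metrics.csv")
>>> sm[["cwm_overlap", "cwm_similarity", "fric_std", "fdis"]].mean().round(3)
cwm_overlap       0.523
cwm_similarity    0.654
fric_std          0.315
fdis              0.891
>>> pd.read_csv("run/models/model1_averaged.csv", index_col=0).loc["tsim"].round(3)
estimate            0.108
unconditional_se    0.049
ci_low              0.012
ci_high             0.205
importance          0.933
```

Mean resource overlap with the honeybee is ~0.52 and the model-averaged
trait-similarity coefficient is positive with a 95% CI excluding zero:
sites whose wild pollinator communities are functionally closer to the
honeybee show systematically higher resource overlap — the pattern the
trait-matching simulation builds in, recovered by the full inference
chain. `run/models/model1_table.csv` lists the 38 candidate models with
AICc, ΔAICc and weights; `diagnostics.csv` reports Moran's I for each
set (expected value −1/50 ≈ −0.02 at 51 sites).

The same stages run separately on your own CSV files (headers documented
in `pollinet.data_model`):

```
pollinet metrics --interactions interactions.csv --sites sites.csv \
    --plant-traits plant_traits.csv --floral-abundance floral_abundance.csv \
    --pollinator-traits pollinator_traits.csv --focal "Apis mellifera" \
    --variant morisita --out metrics/
pollinet models --metrics metrics/ --models 1,2,3,4,5,6 --out models/
```

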