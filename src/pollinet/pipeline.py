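"""End-to-end orchestration: site metrics -> model suites -> diagnostics.

``compute_site_metrics`` turns validated input tables into one row per site
(CWM resource overlap with the focal pollinator, CWM trait similarity,
standardized functional richness and functional dispersion of the plant
community, focal abundance and temperature) plus an unbalanced site x
trait-category table of CWM overlaps.

``run_model_suite`` reproduces the six-model analysis layout:

* Model 1 — site-level linear models: ln CWM overlap ~ ln focal abundance
  (Apis), temperature, plant FRic and trait similarity (TSim), with the
  Apis:FRic, Apis:TSim, FRic:TSim and Apis:FRic:TSim interactions.
* Model 2 — Model 1 with FRic replaced by FDis.
* Models 3–6 — mixed models on the site x category table, one per
  pollinator trait (proboscis band, body band, foraging range, family),
  each with Apis, temperature, the trait category, the Apis:category
  interaction, and a site random intercept.

For every set: predictors are scaled to mean 0 / sd 1, all
marginality-respecting sub-models are fitted, AICc/delta/Akaike weights are
computed over the full candidate set, coefficients are fully model-averaged
with unconditional SEs and 95% CIs, VIFs are taken on the interaction-free
global design, and Moran's I is run on the best model's residuals
(averaged per site for the mixed sets).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import functional_diversity as fd
from . import multimodel as mm
from . import niche_overlap as no
from . import trait_metrics as tm
from .data_model import (
    FloralAbundanceTable,
    InteractionTable,
    PlantTraitTable,
    PollinatorTraitTable,
    SiteInfo,
    build_site_network,
)
from .errors import ValidationError

logger = logging.getLogger(__name__)

TRAIT_NAMES = ("proboscis", "body", "foraging", "family")
# reference levels for the category models: the bands matching the focal,
# central-place foragers, and the focal's own family
REFERENCE_LEVELS = {"proboscis": "similar", "body": "similar", "foraging": "central",
                    "family": "Apidae"}


@dataclass
class SiteMetricsResult:
    site_metrics: pd.DataFrame
    category_metrics: pd.DataFrame
    overlap_long: pd.DataFrame
    similarity_long: pd.DataFrame
    metadata: dict


def _category_maps(
    poll_traits: PollinatorTraitTable, interactions: InteractionTable
) -> dict[str, dict[str, str]]:
    fam = tm.aggregate_rare_families(poll_traits, interactions)
    maps: dict[str, dict[str, str]] = {t: {} for t in TRAIT_NAMES}
    for _, row in poll_traits.data.iterrows():
        sp = row["species"]
        maps["proboscis"][sp] = tm.categorize_relative_to_focal(row["proboscis_mm"], "proboscis")
        maps["body"][sp] = tm.categorize_relative_to_focal(row["body_mm"], "body")
        maps["foraging"][sp] = row["foraging_range"]
        maps["family"][sp] = fam[sp]
    return maps


def compute_site_metrics(
    interactions: InteractionTable,
    sites: SiteInfo,
    plant_traits: PlantTraitTable,
    floral: FloralAbundanceTable,
    poll_traits: PollinatorTraitTable,
    focal: str,
    variant: str = "morisita",
    m_axes: int = 3,
) -> SiteMetricsResult:
    """Compute all per-site and per-site-per-category responses and predictors.

    The plant community of a site is every species with a floral-abundance
    row there; the global trait space pools those communities over all
    sites, so FRic standardisation shares one hull.
    """
    site_ids = interactions.sites
    pool_species = sorted(floral.data["plant"].unique())
    plant_sub = PlantTraitTable.from_frame(
        plant_traits.data[plant_traits.data["species"].isin(pool_species)]
    )
    encoded = fd.encode_plant_traits(plant_sub)
    dist = fd.trait_distance_matrix(encoded)
    space = fd.pcoa(dist, m=m_axes)

    ranges = tm.TraitRanges.from_table(poll_traits)
    similarity = tm.similarity_vs_focal(poll_traits, focal, ranges)
    cat_maps = _category_maps(poll_traits, interactions)

    site_rows, cat_rows, overlap_rows, sim_rows = [], [], [], []
    info = sites.data.set_index("site")
    for sid in site_ids:
        net = build_site_network(interactions, sid)
        res = no.overlap_vs_focal(net, focal, variant=variant)
        wild = sorted(res.per_species)
        values = [res.per_species[sp] for sp in wild]
        weights = [res.abundances[sp] for sp in wild]
        cwm_overlap = no.cwm(values, weights)
        sims = [float(similarity[sp]) for sp in wild]
        cwm_sim = no.cwm(sims, weights)

        community = floral.data.loc[floral.data["site"] == sid, "plant"].tolist()
        rel = floral.site_abundances(sid).loc[community].to_numpy()
        fric = fd.functional_richness(space, community)
        fdis = fd.functional_dispersion(space, community, rel)

        row = info.loc[sid]
        site_rows.append(
            dict(
                site=sid,
                cwm_overlap=cwm_overlap,
                cwm_similarity=cwm_sim,
                fric_std=fric,
                fdis=fdis,
                focal_abundance=float(row["focal_abundance"]),
                ln_focal_abundance=float(np.log(max(row["focal_abundance"], 1.0))),
                temperature=float(row["temperature_C"]),
                x_km=float(row["x_km"]),
                y_km=float(row["y_km"]),
                n_plants=len(community),
                n_pollinator_species=len(wild) + 1,
                n_wild_individuals=int(sum(weights)),
            )
        )
        for sp, v, wgt, sim in zip(wild, values, weights, sims):
            overlap_rows.append(dict(site=sid, pollinator=sp, abundance=wgt,
                                     overlap=v, variant=variant))
            sim_rows.append(dict(site=sid, pollinator=sp, abundance=wgt, similarity=sim))
        for trait in TRAIT_NAMES:
            by_cat = no.overlap_by_category(net, focal, cat_maps[trait], variant=variant)
            for label, val in by_cat.items():
                ab = sum(res.abundances[sp] for sp in wild if cat_maps[trait][sp] == label)
                cat_rows.append(
                    dict(site=sid, trait=trait, category=label, cwm_overlap=val, abundance=ab)
                )

    meta = dict(focal=focal, variant=variant, m_axes=space.m,
                global_hull_volume=space.global_hull_volume,
                corolla_scaling="z-score (sample sd), dummies unscaled")
    return SiteMetricsResult(
        site_metrics=pd.DataFrame(site_rows),
        category_metrics=pd.DataFrame(cat_rows),
        overlap_long=pd.DataFrame(overlap_rows),
        similarity_long=pd.DataFrame(sim_rows),
        metadata=meta,
    )


@dataclass
class ModelSetResult:
    name: str
    table: mm.ModelTable
    averaged: pd.DataFrame
    vif: dict[str, float]
    moran: mm.MoranResult
    metadata: dict


def _fit_set(
    data: pd.DataFrame,
    global_spec: mm.ModelSpec,
    coords: pd.DataFrame,
    site_index: pd.Series,
    name: str,
    metadata: dict,
    conditional: bool = False,
) -> ModelSetResult:
    candidates = mm.enumerate_candidate_models(global_spec)
    fitted = [mm.fit_model(spec, data) for spec in candidates]
    table = mm.aicc_table(fitted)
    averaged = mm.average_coefficients(fitted, table.weights, conditional=conditional)
    # VIF on the interaction-free global design (dummy columns for categories)
    mains = [t for t in global_spec.terms if ":" not in t]
    design = pd.get_dummies(data[mains], drop_first=True, dtype=float) if any(
        data[t].dtype == object or isinstance(data[t].dtype, pd.CategoricalDtype)
        for t in mains
    ) else data[mains]
    vifs = mm.vif(design, list(design.columns))
    best_id = int(table.frame.iloc[0]["model_id"])
    resid = fitted[best_id].residuals
    per_site = resid.groupby(site_index).mean()
    moran = mm.morans_i(
        per_site.to_numpy(),
        coords.loc[per_site.index, ["x", "y"]].to_numpy(),
        weighting="inverse_distance",
    )
    return ModelSetResult(name=name, table=table, averaged=averaged, vif=vifs,
                          moran=moran, metadata=metadata)


def run_model_suite(
    metrics: SiteMetricsResult,
    which=(1, 2, 3, 4, 5, 6),
    conditional: bool = False,
) -> dict[int, ModelSetResult]:
    """Fit the requested model sets on computed site metrics."""
    sm_df = metrics.site_metrics
    coords = pd.DataFrame(
        {"x": sm_df["x_km"].to_numpy(), "y": sm_df["y_km"].to_numpy()},
        index=sm_df["site"],
    )

    results: dict[int, ModelSetResult] = {}
    for mid in sorted(which):
        if mid in (1, 2):
            fdvar = "fric" if mid == 1 else "fdis"
            data = pd.DataFrame(
                dict(
                    site=sm_df["site"],
                    apis=sm_df["ln_focal_abundance"],
                    temp=sm_df["temperature"],
                    tsim=sm_df["cwm_similarity"],
                )
            )
            data[fdvar] = sm_df["fric_std"] if mid == 1 else sm_df["fdis"]
            y, offset = mm.transform_response(
                sm_df["cwm_overlap"].to_numpy(), transform="ln_offset"
            )
            data["overlap"] = y
            data, scaling = mm.scale_predictors(data, ["apis", "temp", fdvar, "tsim"])
            terms = (
                "apis", "temp", fdvar, "tsim",
                f"apis:{fdvar}", "apis:tsim", f"{fdvar}:tsim", f"apis:{fdvar}:tsim",
            )
            spec = mm.ModelSpec(response="overlap", terms=terms, transform="ln_offset")
            meta = dict(response_offset=offset, scaling=scaling,
                        response="ln(cwm_overlap + offset)", averaging="full")
            results[mid] = _fit_set(
                data, spec, coords, data["site"], f"model{mid}", meta, conditional,
            )
        else:
            trait = TRAIT_NAMES[mid - 3]
            sub = metrics.category_metrics[metrics.category_metrics["trait"] == trait].copy()
            if len(sub) == 0:
                raise ValidationError(f"no category rows for trait {trait!r}")
            ref = REFERENCE_LEVELS[trait]
            levels = sorted(sub["category"].unique())
            if ref in levels:
                levels = [ref] + [l for l in levels if l != ref]
            sub["category"] = pd.Categorical(sub["category"], categories=levels)
            site_cols = sm_df.set_index("site")
            sub["apis"] = site_cols.loc[sub["site"], "ln_focal_abundance"].to_numpy()
            sub["temp"] = site_cols.loc[sub["site"], "temperature"].to_numpy()
            y, offset = mm.transform_response(
                sub["cwm_overlap"].to_numpy(), transform="ln_offset"
            )
            sub["overlap"] = y
            sub, scaling = mm.scale_predictors(sub, ["apis", "temp"])
            sub = sub.reset_index(drop=True)
            spec = mm.ModelSpec(
                response="overlap",
                terms=("apis", "temp", "category", "apis:category"),
                random_intercept="site",
                transform="ln_offset",
            )
            meta = dict(response_offset=offset, scaling=scaling, trait=trait,
                        reference_level=levels[0], averaging="full",
                        response="ln(cwm_overlap + offset)")
            results[mid] = _fit_set(
                sub, spec, coords, sub["site"], f"model{mid}", meta, conditional,
            )
    return results
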