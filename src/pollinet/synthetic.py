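"""Seeded generators of synthetic plant–pollinator study data.

Two independent tiers:

* **Mechanistic tier** (:func:`generate_species_pools` +
  :func:`simulate_visitation`) — a trait-matching visitation simulator.
  Species pools, per-site communities, floral abundances and site metadata
  emulate the structure of a 51-grassland single-visit survey (roughly 20
  flowering plants and 24 pollinator species per site, a super-generalist
  focal pollinator present everywhere with strongly right-skewed abundance,
  temperature independent of focal abundance).  Visits of pollinator *p* to
  plant *q* are Poisson with rate proportional to floral abundance, the
  pollinator's individual count and a Gaussian proboscis–corolla matching
  kernel ``exp(-(proboscis - corolla)^2 / (2 sigma^2))``.  This tier
  exercises the metric pipeline end to end; it makes no distributional
  promise about regression coefficients.

* **Regression tier** (:func:`simulate_site_level`) — draws standardized
  predictors and a Gaussian response directly from a known linear model, so
  inference machinery can be validated against exact ground truth.

Every function takes an explicit seed and returns its realized ground
truth; the same seed always reproduces the same tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import rankdata as scipy_rankdata

from .data_model import (
    FloralAbundanceTable,
    InteractionTable,
    PlantTraitTable,
    PollinatorTraitTable,
    SiteInfo,
)

FOCAL_SPECIES = "Apis_mellifera"

COLOURS = ("yellow", "white", "purple", "pink", "blue")
FLOWER_TYPES = ("disc", "funnel", "bell", "lip", "flag", "tube", "head")
FAMILIES = (
    "Apidae", "Halictidae", "Megachilidae", "Colletidae", "Andrenidae",
    "Syrphidae", "Tachinidae", "Conopidae", "Vespidae", "Crabronidae",
    "Tenthredinidae", "Melittidae", "Scoliidae", "Cimbicidae",
)
FAMILY_WEIGHTS = (
    0.22, 0.14, 0.10, 0.07, 0.08,
    0.16, 0.06, 0.03, 0.04, 0.04,
    0.03, 0.011, 0.009, 0.01,
)
# characteristic body length (mm, median of the family's species) — families
# differ systematically in size, so site-level family composition moves the
# community's morphology
FAMILY_BODY_MM = {
    "Apidae": 13.0, "Halictidae": 7.5, "Megachilidae": 11.0, "Colletidae": 8.0,
    "Andrenidae": 10.0, "Syrphidae": 10.5, "Tachinidae": 9.0, "Conopidae": 11.5,
    "Vespidae": 14.0, "Crabronidae": 7.0, "Tenthredinidae": 9.5,
    "Melittidae": 10.0, "Scoliidae": 16.0, "Cimbicidae": 18.0,
}
# nest-provisioning (central-place) taxa: bees and most wasps; flies and
# sawflies forage freely
CENTRAL_PLACE_FAMILIES = frozenset({
    "Apidae", "Halictidae", "Megachilidae", "Colletidae", "Andrenidae",
    "Melittidae", "Vespidae", "Crabronidae",
})
# flower-type preferences are treated as biological constants of each
# family: long-tongued bees handle zygomorphic and deep flowers, flies and
# wasps concentrate on open disc/head flowers, short-tongued bees sit in
# between
FAMILY_FLOWER_PREFS = {
    "Apidae": ("tube", "bell", "funnel", "lip", "flag"),
    "Megachilidae": ("lip", "flag", "bell", "funnel"),
    "Melittidae": ("bell", "funnel", "tube"),
    "Halictidae": ("disc", "bell", "funnel"),
    "Colletidae": ("disc", "bell", "head"),
    "Andrenidae": ("disc", "bell", "funnel"),
    "Syrphidae": ("disc", "head"),
    "Tachinidae": ("disc", "head"),
    "Conopidae": ("disc", "head", "funnel"),
    "Vespidae": ("disc", "head"),
    "Crabronidae": ("disc", "head"),
    "Tenthredinidae": ("disc", "head"),
    "Scoliidae": ("disc", "head"),
    "Cimbicidae": ("disc", "head"),
}


@dataclass
class SimConfig:
    """Study-design parameters of the mechanistic simulator.

    Defaults mirror the emulated survey: 51 sites, 8–35 plants per site
    (mean ~20), ~24 pollinator species and ~81 wild individuals per site
    (range 16–332), focal abundance log-normal clipped to [2, 768] (mean
    ~132), temperature 18–38 °C drawn independently of focal abundance, and
    trait spans of 0.05–33 mm (corolla), 0.4–16 mm (proboscis) and
    4–22.5 mm (body length).
    """

    n_sites: int = 51
    plant_pool_size: int = 130
    pollinator_pool_size: int = 160
    plants_per_site: tuple[int, int] = (8, 35)
    plants_per_site_mean: float = 20.0
    pollinators_per_site: tuple[int, int] = (9, 49)
    pollinators_per_site_mean: float = 24.0
    wild_individuals: tuple[int, int] = (16, 332)
    wild_individuals_logmean: float = 4.17
    wild_individuals_logsd: float = 0.65
    focal_abundance_range: tuple[int, int] = (2, 768)
    focal_abundance_logmean: float = 4.2
    focal_abundance_logsd: float = 1.2
    temperature_range: tuple[float, float] = (18.0, 38.0)
    elevation_range: tuple[float, float] = (150.0, 2100.0)
    corolla_range: tuple[float, float] = (0.05, 33.0)
    proboscis_range: tuple[float, float] = (0.4, 16.0)
    body_range: tuple[float, float] = (4.0, 22.5)
    extent_km: tuple[float, float] = (50.0, 30.0)
    min_spacing_km: float = 0.53
    sigma_match: float = 2.0  # proboscis-corolla kernel width, mm
    hard_accessibility: bool = False
    access_tolerance_mm: float = 2.0
    visits_per_individual: float = 1.0
    negative_binomial: bool = False
    nb_dispersion: float = 2.0
    plant_archetypes: int | None = None
    # elevational community assembly: species carry an elevation optimum
    # (correlated with morphology) and site membership is weighted by the
    # match between optimum and site elevation; the defaults give strong
    # species turnover over the 150-2100 m gradient (occupied bands of
    # roughly +-2 sd around the optimum)
    elevation_filter_sd_m: float = 250.0
    trait_elevation_corr: float = 0.5
    # per-site family composition (bee- vs fly-dominated assemblages):
    # site family weights are Dirichlet around the pool frequencies; a
    # smaller concentration means stronger compositional turnover
    family_turnover_concentration: float = 4.0
    # trait-linked foraging behaviour: families carry fixed flower-type
    # preferences (non-preferred types are visited at a reduced rate) and
    # central-place foragers respond more steeply to local floral
    # abundance; both make the non-morphological traits matter for
    # resource choice
    nonpreferred_rate: float = 0.05
    central_abundance_exponent: float = 2.2
    focal_proboscis_mm: float = 5.0
    focal_body_mm: float = 12.0

    def validate(self) -> None:
        if self.plant_pool_size < self.plants_per_site[1]:
            raise ValueError("plant pool smaller than maximum per-site richness")
        if self.pollinator_pool_size < self.pollinators_per_site[1]:
            raise ValueError("pollinator pool smaller than maximum per-site richness")
        for name in ("plants_per_site", "pollinators_per_site", "wild_individuals",
                     "corolla_range", "proboscis_range", "body_range",
                     "temperature_range", "focal_abundance_range"):
            lo, hi = getattr(self, name)
            if not (0 <= lo < hi):
                raise ValueError(f"{name} must be an ordered positive range, got ({lo}, {hi})")


@dataclass
class SpeciesPools:
    """Species pools, per-site communities and site metadata."""

    plant_traits: PlantTraitTable
    pollinator_traits: PollinatorTraitTable
    site_info: SiteInfo
    floral: FloralAbundanceTable
    plant_membership: dict[str, list[str]]
    pollinator_individuals: dict[str, dict[str, int]]  # site -> species -> individuals
    family_flower_prefs: dict[str, tuple[str, ...]] | None = None


@dataclass
class GroundTruth:
    """Realized parameters of a mechanistic simulation run."""

    seed: int
    config: SimConfig
    site_rates: dict[str, pd.DataFrame] = field(default_factory=dict)
    site_totals: dict[str, int] = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        return {
            "seed": self.seed,
            "config": asdict(self.config),
            "site_totals": self.site_totals,
        }


def _clipped_lognormal(rng, logmean, logsd, lo, hi, size):
    return np.clip(rng.lognormal(logmean, logsd, size=size), lo, hi)


def _bounded_count(rng, lo, hi, mean, size):
    """Integers in [lo, hi] with the requested mean (shifted binomial)."""
    span = hi - lo
    p = (mean - lo) / span
    return lo + rng.binomial(span, p, size=size)


def _site_coordinates(rng, config: SimConfig) -> np.ndarray:
    w, h = config.extent_km
    pts: list[np.ndarray] = []
    for _ in range(10000):
        cand = rng.uniform((0, 0), (w, h))
        if all(np.hypot(*(cand - p)) >= config.min_spacing_km for p in pts):
            pts.append(cand)
            if len(pts) == config.n_sites:
                return np.array(pts)
    raise ValueError("could not place sites with the requested minimum spacing")


def _plant_pool(rng, config: SimConfig) -> pd.DataFrame:
    n = config.plant_pool_size
    lo, hi = config.corolla_range
    if config.plant_archetypes:
        k = config.plant_archetypes
        arch_corolla = np.exp(rng.uniform(np.log(max(lo, 0.5)), np.log(hi * 0.8), size=k))
        arch_colour = rng.choice(COLOURS, size=k)
        arch_type = rng.choice(FLOWER_TYPES, size=k)
        which = rng.integers(0, k, size=n)
        corolla = np.clip(arch_corolla[which] * rng.lognormal(0, 0.08, size=n), lo, hi)
        colour = arch_colour[which]
        ftype = arch_type[which]
    else:
        corolla = _clipped_lognormal(rng, np.log(4.0), 1.0, lo, hi, n)
        colour = rng.choice(COLOURS, size=n)
        ftype = rng.choice(FLOWER_TYPES, size=n)
    return pd.DataFrame(
        dict(
            species=[f"Plant_{i:03d}" for i in range(n)],
            corolla_mm=np.round(corolla, 3),
            colour=colour,
            flower_type=ftype,
        )
    )


def _pollinator_pool(rng, config: SimConfig) -> pd.DataFrame:
    n = config.pollinator_pool_size
    plo, phi = config.proboscis_range
    blo, bhi = config.body_range
    family = rng.choice(FAMILIES, size=n, p=np.asarray(FAMILY_WEIGHTS) / sum(FAMILY_WEIGHTS))
    fam_body = np.array([FAMILY_BODY_MM[f] for f in family])
    body = np.clip(fam_body * rng.lognormal(0.0, 0.22, size=n), blo, bhi)
    # proboscis-body allometry: tongues scale with body size, with spread
    proboscis = np.clip(
        0.45 * body ** 1.05 * rng.lognormal(0.0, 0.30, size=n), plo, phi
    )
    foraging = np.where(np.isin(family, list(CENTRAL_PLACE_FAMILIES)),
                        "central", "non_central")
    df = pd.DataFrame(
        dict(
            species=[f"Poll_{i:03d}" for i in range(n)],
            proboscis_mm=np.round(proboscis, 3),
            body_mm=np.round(body, 3),
            foraging_range=foraging,
            family=family,
        )
    )
    focal = pd.DataFrame(
        dict(
            species=[FOCAL_SPECIES],
            proboscis_mm=[config.focal_proboscis_mm],
            body_mm=[config.focal_body_mm],
            foraging_range=["central"],
            family=["Apidae"],
        )
    )
    return pd.concat([focal, df], ignore_index=True)


def generate_species_pools(config: SimConfig, seed: int) -> SpeciesPools:
    """Draw species pools, per-site communities and site metadata.

    The focal species belongs to every site.  Floral relative abundances
    are Dirichlet per site; temperature is drawn independently of focal
    abundance (the emulated design enforces that independence); elevation
    and temperature are negatively coupled.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    plant_pool = _plant_pool(rng, config)
    poll_pool = _pollinator_pool(rng, config)
    coords = _site_coordinates(rng, config)
    site_ids = [f"S{i + 1:02d}" for i in range(config.n_sites)]

    elo, ehi = config.elevation_range
    tlo, thi = config.temperature_range
    elevation = rng.uniform(elo, ehi, size=config.n_sites)
    # lapse-rate coupling with noise: keeps temp-elevation correlated while
    # temperature stays independent of focal abundance
    temp = np.clip(
        thi + 1.0 - (elevation - elo) / (ehi - elo) * (thi - tlo - 2.0)
        + rng.normal(0, 2.5, size=config.n_sites),
        tlo, thi,
    )
    flo, fhi = config.focal_abundance_range
    focal_ab = np.round(
        _clipped_lognormal(
            rng, config.focal_abundance_logmean, config.focal_abundance_logsd,
            flo, fhi, config.n_sites,
        )
    ).astype(int)

    n_plants = _bounded_count(
        rng, *config.plants_per_site, config.plants_per_site_mean, config.n_sites
    )
    n_polls = _bounded_count(
        rng, *config.pollinators_per_site, config.pollinators_per_site_mean, config.n_sites
    )
    wild_totals = np.round(
        _clipped_lognormal(
            rng, config.wild_individuals_logmean, config.wild_individuals_logsd,
            *config.wild_individuals, config.n_sites,
        )
    ).astype(int)

    def _optima(values: np.ndarray) -> np.ndarray:
        """Elevation optima correlated with a (log) morphological trait."""
        z = np.log(values)
        z = (z - z.mean()) / z.std()
        corr = config.trait_elevation_corr
        latent = corr * z + np.sqrt(1 - corr ** 2) * rng.standard_normal(len(z))
        ranks = scipy_rankdata(latent)
        return elo + (ehi - elo) * (ranks - 0.5) / len(z)

    plant_opt = _optima(np.maximum(plant_pool["corolla_mm"].to_numpy(), 0.05))
    wild_mask = poll_pool["species"] != FOCAL_SPECIES
    poll_opt = np.full(len(poll_pool), np.nan)
    poll_opt[wild_mask.to_numpy()] = _optima(
        poll_pool.loc[wild_mask, "body_mm"].to_numpy()
    )

    def _weighted_sample(names, optima, site_elev, size):
        w = np.exp(-((site_elev - optima) ** 2) / (2 * config.elevation_filter_sd_m ** 2))
        w = w + 1e-12
        return sorted(rng.choice(names, size=size, replace=False, p=w / w.sum()))

    plant_membership: dict[str, list[str]] = {}
    poll_individuals: dict[str, dict[str, int]] = {}
    floral_rows = []
    wild_names = np.asarray(poll_pool.loc[wild_mask, "species"])
    wild_opt = poll_opt[wild_mask.to_numpy()]
    wild_fam = np.asarray(poll_pool.loc[wild_mask, "family"])
    base_fam_p = {f: w for f, w in zip(FAMILIES, FAMILY_WEIGHTS)}
    for i, sid in enumerate(site_ids):
        plants = _weighted_sample(
            np.asarray(plant_pool["species"]), plant_opt, elevation[i], n_plants[i]
        )
        plant_membership[sid] = plants
        rel = rng.dirichlet(np.full(len(plants), 0.8))
        for p, a in zip(plants, rel):
            floral_rows.append((sid, p, a))
        # site assemblage type: family weights drawn around pool frequencies
        conc = config.family_turnover_concentration
        fam_w_site = rng.dirichlet(
            conc * len(FAMILIES) * np.asarray(FAMILY_WEIGHTS) / sum(FAMILY_WEIGHTS)
        )
        fam_ratio = {
            f: fam_w_site[j] / base_fam_p[f] for j, f in enumerate(FAMILIES)
        }
        k = min(n_polls[i], len(wild_names))
        elev_w = np.exp(-((elevation[i] - wild_opt) ** 2)
                        / (2 * config.elevation_filter_sd_m ** 2))
        comp_w = elev_w * np.array([fam_ratio[f] for f in wild_fam]) + 1e-12
        wild = sorted(rng.choice(wild_names, size=k, replace=False,
                                 p=comp_w / comp_w.sum()))
        # abundance follows habitat suitability: species near their
        # elevational optimum and of locally dominant families dominate,
        # with lognormal demographic noise
        name_to_w = dict(zip(wild_names, comp_w))
        suit = np.array([name_to_w[sp] for sp in wild])
        shares = suit * rng.lognormal(0.0, 1.0, size=k)
        shares = shares / shares.sum()
        counts = np.maximum(1, np.round(shares * (wild_totals[i] - k)).astype(int) + 1)
        indiv = {sp: int(c) for sp, c in zip(wild, counts)}
        indiv[FOCAL_SPECIES] = int(focal_ab[i])
        poll_individuals[sid] = indiv

    site_df = pd.DataFrame(
        dict(
            site=site_ids,
            x_km=np.round(coords[:, 0], 4),
            y_km=np.round(coords[:, 1], 4),
            elevation_m=np.round(elevation, 1),
            temperature_C=np.round(temp, 2),
            focal_abundance=focal_ab,
        )
    )
    floral_df = pd.DataFrame(floral_rows, columns=["site", "plant", "rel_abundance"])
    return SpeciesPools(
        family_flower_prefs=dict(FAMILY_FLOWER_PREFS),
        plant_traits=PlantTraitTable.from_frame(plant_pool),
        pollinator_traits=PollinatorTraitTable.from_frame(poll_pool),
        site_info=SiteInfo.from_frame(site_df),
        floral=FloralAbundanceTable.from_frame(floral_df),
        plant_membership=plant_membership,
        pollinator_individuals=poll_individuals,
    )


def _matching_weights(
    traits: pd.Series,
    plants: pd.DataFrame,
    rel_ab: np.ndarray,
    config: SimConfig,
    prefs: dict[str, tuple[str, ...]] | None,
) -> np.ndarray:
    proboscis = float(traits["proboscis_mm"])
    corolla = plants["corolla_mm"].to_numpy(dtype=float)
    kernel = np.exp(-((proboscis - corolla) ** 2) / (2.0 * config.sigma_match ** 2))
    if config.hard_accessibility:
        kernel = kernel * (corolla <= proboscis + config.access_tolerance_mm)
    if prefs is not None and traits["family"] in prefs:
        preferred = np.isin(plants["flower_type"].to_numpy(), prefs[traits["family"]])
        kernel = kernel * np.where(preferred, 1.0, config.nonpreferred_rate)
    gamma = (config.central_abundance_exponent
             if traits["foraging_range"] == "central" else 1.0)
    return rel_ab ** gamma * kernel


def simulate_visitation(
    pools: SpeciesPools, config: SimConfig, seed: int
) -> tuple[InteractionTable, GroundTruth]:
    """Draw the visitation records for every site.

    Each pollinator's visit counts over the site's plants are Poisson with
    per-plant rates proportional to floral abundance times the
    proboscis–corolla matching kernel, normalised so the expected total
    equals the species' individual count times ``visits_per_individual``.
    A species whose realized total is 0 is redrawn (it was observed at the
    site, so it must appear in the records); an all-zero rate row cannot be
    fixed by redrawing and raises after 100 attempts.
    """
    rng = np.random.default_rng(seed)
    truth = GroundTruth(seed=seed, config=config)
    traits = pools.pollinator_traits.data.set_index("species")
    rows = []
    for sid, plants in pools.plant_membership.items():
        pl = pools.plant_traits.data.set_index("species").loc[plants].reset_index()
        rel = pools.floral.site_abundances(sid).loc[plants].to_numpy()
        rate_rows = {}
        site_total = 0
        for sp, n_indiv in sorted(pools.pollinator_individuals[sid].items()):
            w = _matching_weights(traits.loc[sp], pl, rel, config,
                                  pools.family_flower_prefs)
            if w.sum() == 0:
                raise ValueError(
                    f"all-zero visitation rate for {sp} at {sid}: no accessible plant"
                )
            lam = n_indiv * config.visits_per_individual * w / w.sum()
            for attempt in range(100):
                if config.negative_binomial:
                    r = config.nb_dispersion
                    counts = rng.negative_binomial(r, r / (r + lam))
                else:
                    counts = rng.poisson(lam)
                if counts.sum() >= 1:
                    break
            else:
                raise ValueError(f"could not draw a nonzero visit total for {sp} at {sid}")
            rate_rows[sp] = lam
            site_total += int(counts.sum())
            for p, c in zip(plants, counts):
                if c > 0:
                    rows.append((sid, p, sp, int(c)))
        truth.site_rates[sid] = pd.DataFrame(rate_rows, index=plants)
        truth.site_totals[sid] = site_total
    table = InteractionTable.from_frame(
        pd.DataFrame(rows, columns=["site", "plant", "pollinator", "count"])
    )
    return table, truth


# ---------------------------------------------------------------- regression tier

MODEL1_MAINS = ("apis", "temp", "fric", "tsim")


@dataclass
class RegressionTruth:
    seed: int
    beta: dict[str, float]
    noise_sd: float
    random_intercept_sd: float = 0.0
    category_effects: dict[str, float] | None = None


def _term_column(df: pd.DataFrame, term: str) -> np.ndarray:
    cols = term.split(":")
    out = np.ones(len(df))
    for c in cols:
        out = out * df[c].to_numpy()
    return out


def simulate_site_level(
    beta: dict[str, float],
    noise_sd: float,
    seed: int,
    n_sites: int = 51,
    predictors: tuple[str, ...] = MODEL1_MAINS,
    categories: tuple[str, ...] | None = None,
    category_effects: dict[str, float] | None = None,
    random_intercept_sd: float = 0.0,
) -> tuple[pd.DataFrame, RegressionTruth]:
    """Draw a site-level (or site x category) dataset with known coefficients.

    Predictors are iid standard normal; interaction terms in ``beta`` (e.g.
    ``"apis:fric"``) are products of the named mains.  With ``categories``,
    rows expand to site x category with additive category effects and a
    Gaussian site random intercept of sd ``random_intercept_sd``.
    """
    rng = np.random.default_rng(seed)
    for term in beta:
        if not set(term.split(":")) <= set(predictors):
            raise ValueError(f"beta term {term!r} uses unknown predictors")
    df = pd.DataFrame(
        {p: rng.standard_normal(n_sites) for p in predictors}
    )
    df.insert(0, "site", [f"S{i + 1:02d}" for i in range(n_sites)])
    if categories is None:
        mu = np.zeros(n_sites)
        for term, b in beta.items():
            mu += b * _term_column(df, term)
        df["response"] = mu + rng.normal(0, noise_sd, size=n_sites)
        return df, RegressionTruth(seed=seed, beta=dict(beta), noise_sd=noise_sd)

    effects = category_effects or {c: 0.0 for c in categories}
    b_site = rng.normal(0, random_intercept_sd, size=n_sites)
    long = df.loc[df.index.repeat(len(categories))].reset_index(drop=True)
    long["category"] = list(categories) * n_sites
    mu = np.zeros(len(long))
    for term, b in beta.items():
        mu += b * _term_column(long, term)
    mu += long["category"].map(effects).to_numpy()
    mu += np.repeat(b_site, len(categories))
    long["response"] = mu + rng.normal(0, noise_sd, size=len(long))
    return long, RegressionTruth(
        seed=seed, beta=dict(beta), noise_sd=noise_sd,
        random_intercept_sd=random_intercept_sd, category_effects=dict(effects),
    )
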