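import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from pollinet import data_model as dm
from pollinet import synthetic

settings.register_profile("ci", derandomize=True, max_examples=100, deadline=None)
settings.load_profile("ci")

logging.getLogger("pollinet").setLevel(logging.ERROR)
logging.getLogger("pollinet.niche_overlap").setLevel(logging.ERROR)


@pytest.fixture
def toy_interactions() -> dm.InteractionTable:
    """3 sites, 5 plants, 6 pollinators; focal 'Apis' visits every site."""
    rows = [
        ("s1", "P1", "Apis", 5), ("s1", "P2", "Apis", 3), ("s1", "P1", "B1", 4),
        ("s1", "P2", "B2", 2), ("s1", "P3", "B2", 2),
        ("s2", "P3", "Apis", 6), ("s2", "P4", "B3", 3), ("s2", "P3", "B1", 2),
        ("s3", "P5", "Apis", 2), ("s3", "P5", "B4", 3), ("s3", "P1", "B5", 4),
    ]
    return dm.InteractionTable.from_frame(
        pd.DataFrame(rows, columns=["site", "plant", "pollinator", "count"])
    )


@pytest.fixture
def toy_tables(toy_interactions):
    sites = dm.SiteInfo.from_frame(pd.DataFrame(
        dict(site=["s1", "s2", "s3"], x_km=[0.0, 5.0, 9.0], y_km=[0.0, 2.0, 7.0],
             elevation_m=[300, 900, 1500], temperature_C=[30.0, 25.0, 20.0],
             focal_abundance=[8, 6, 2])
    ))
    plant_traits = dm.PlantTraitTable.from_frame(pd.DataFrame(
        dict(species=["P1", "P2", "P3", "P4", "P5"],
             corolla_mm=[2.0, 8.0, 5.0, 12.0, 1.0],
             colour=["yellow", "white", "purple", "white", "yellow"],
             flower_type=["disc", "funnel", "bell", "lip", "disc"])
    ))
    floral_rows = []
    per_site = {"s1": ["P1", "P2", "P3"], "s2": ["P3", "P4"], "s3": ["P1", "P5"]}
    for s, plants in per_site.items():
        share = 1.0 / len(plants)
        for p in plants:
            floral_rows.append((s, p, share))
    floral = dm.FloralAbundanceTable.from_frame(
        pd.DataFrame(floral_rows, columns=["site", "plant", "rel_abundance"])
    )
    poll_traits = dm.PollinatorTraitTable.from_frame(pd.DataFrame(
        dict(species=["Apis", "B1", "B2", "B3", "B4", "B5"],
             proboscis_mm=[5.0, 2.0, 6.0, 10.0, 3.0, 5.0],
             body_mm=[12.0, 6.0, 13.0, 18.0, 9.0, 12.0],
             foraging_range=["central", "non_central", "central", "central",
                             "non_central", "central"],
             family=["Apidae", "Syrphidae", "Apidae", "Apidae", "Halictidae",
                     "Apidae"])
    ))
    return sites, plant_traits, floral, poll_traits


@pytest.fixture(scope="session")
def small_sim():
    """A reduced mechanistic simulation shared across tests (12 sites)."""
    cfg = synthetic.SimConfig(n_sites=12, plant_pool_size=60, pollinator_pool_size=80)
    pools = synthetic.generate_species_pools(cfg, 11)
    interactions, truth = synthetic.simulate_visitation(pools, cfg, 12)
    return cfg, pools, interactions, truth


@pytest.fixture(scope="session")
def full_sim():
    """A default-condition (51-site) simulation shared across tests."""
    cfg = synthetic.SimConfig()
    pools = synthetic.generate_species_pools(cfg, 7)
    interactions, truth = synthetic.simulate_visitation(pools, cfg, 8)
    return cfg, pools, interactions, truth


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
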