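"""Typed tables, validation and CSV I/O for visitation data.

All inputs are long-format UTF-8 CSV with '.' decimal separator and a header
row.  Species and site names are opaque, case-sensitive identifiers.  The
documented headers are::

    interactions.csv:       site,plant,pollinator,count
    sites.csv:              site,x_km,y_km,elevation_m,temperature_C,focal_abundance
    plant_traits.csv:       species,corolla_mm,colour,flower_type
    floral_abundance.csv:   site,plant,rel_abundance
    pollinator_traits.csv:  species,proboscis_mm,body_mm,foraging_range,family
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import DataFormatError, ValidationError

logger = logging.getLogger(__name__)

INTERACTION_COLUMNS = ["site", "plant", "pollinator", "count"]
SITE_COLUMNS = ["site", "x_km", "y_km", "elevation_m", "temperature_C", "focal_abundance"]
PLANT_TRAIT_COLUMNS = ["species", "corolla_mm", "colour", "flower_type"]
FLORAL_COLUMNS = ["site", "plant", "rel_abundance"]
POLLINATOR_TRAIT_COLUMNS = ["species", "proboscis_mm", "body_mm", "foraging_range", "family"]

FORAGING_CLASSES = ("central", "non_central")


def _require_columns(df: pd.DataFrame, columns: Iterable[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise DataFormatError(f"{what}: missing column(s) {missing}; got {list(df.columns)}")


def _read_csv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise DataFormatError(f"{path}: empty file")
    return df


@dataclass(frozen=True)
class InteractionTable:
    """Aggregated (site, plant, pollinator, count) visit records.

    Counts are positive integers: the field protocol counts individuals, so
    fractional visits are rejected.  Duplicate (site, plant, pollinator)
    rows are summed on construction; zero-count rows are dropped with a
    warning so zero-padded exports re-import cleanly.
    """

    data: pd.DataFrame

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "InteractionTable":
        _require_columns(df, INTERACTION_COLUMNS, "interactions")
        df = df[INTERACTION_COLUMNS].copy()
        if len(df) == 0:
            raise DataFormatError("interactions: no data rows")
        counts = pd.to_numeric(df["count"], errors="coerce")
        bad = counts.isna() | (counts != np.floor(counts)) | (counts < 0)
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise DataFormatError(
                f"interactions: row {i} has non-integer or negative count "
                f"{df['count'].iloc[i]!r} ({df['site'].iloc[i]},{df['plant'].iloc[i]},"
                f"{df['pollinator'].iloc[i]})"
            )
        df["count"] = counts.astype(np.int64)
        n_zero = int((df["count"] == 0).sum())
        if n_zero:
            logger.warning("interactions: dropping %d zero-count row(s)", n_zero)
            df = df[df["count"] > 0]
        if len(df) == 0:
            raise DataFormatError("interactions: all rows have count 0")
        df = (
            df.groupby(["site", "plant", "pollinator"], as_index=False, sort=True)["count"]
            .sum()
        )
        return cls(df.reset_index(drop=True))

    @property
    def sites(self) -> list[str]:
        return sorted(self.data["site"].unique())

    @property
    def plants(self) -> list[str]:
        return sorted(self.data["plant"].unique())

    @property
    def pollinators(self) -> list[str]:
        return sorted(self.data["pollinator"].unique())

    def write_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


@dataclass(frozen=True)
class SiteInfo:
    """One row per site: planar coordinates (km), elevation, temperature,
    and the focal pollinator's abundance."""

    data: pd.DataFrame

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SiteInfo":
        _require_columns(df, SITE_COLUMNS, "sites")
        df = df[SITE_COLUMNS].copy()
        for col in ["x_km", "y_km", "elevation_m", "temperature_C", "focal_abundance"]:
            df[col] = pd.to_numeric(df[col], errors="coerce")
        if df["site"].duplicated().any():
            dup = df.loc[df["site"].duplicated(), "site"].tolist()
            raise ValidationError(f"sites: duplicated site id(s) {dup}")
        for col in ["x_km", "y_km", "temperature_C"]:
            if not np.isfinite(df[col]).all():
                raise ValidationError(f"sites: non-finite values in {col}")
        if (df["focal_abundance"] < 0).any() or df["focal_abundance"].isna().any():
            raise ValidationError("sites: focal_abundance must be >= 0")
        return cls(df.reset_index(drop=True))

    def write_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


@dataclass(frozen=True)
class PlantTraitTable:
    """Species-level plant traits: corolla length (mm), flower colour, and
    Kugler flower type."""

    data: pd.DataFrame

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PlantTraitTable":
        _require_columns(df, PLANT_TRAIT_COLUMNS, "plant_traits")
        df = df[PLANT_TRAIT_COLUMNS].copy()
        df["corolla_mm"] = pd.to_numeric(df["corolla_mm"], errors="coerce")
        if df["species"].duplicated().any():
            dup = df.loc[df["species"].duplicated(), "species"].tolist()
            raise ValidationError(f"plant_traits: duplicated species {dup}")
        if df.isna().any().any():
            bad = df.loc[df.isna().any(axis=1), "species"].tolist()
            raise ValidationError(f"plant_traits: missing values for {bad}")
        if (df["corolla_mm"] < 0).any():
            raise ValidationError("plant_traits: corolla_mm must be >= 0")
        return cls(df.reset_index(drop=True))

    @property
    def species(self) -> list[str]:
        return self.data["species"].tolist()

    def write_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


@dataclass(frozen=True)
class FloralAbundanceTable:
    """Per-site floral relative abundances; within each site they sum to 1."""

    data: pd.DataFrame

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FloralAbundanceTable":
        _require_columns(df, FLORAL_COLUMNS, "floral_abundance")
        df = df[FLORAL_COLUMNS].copy()
        df["rel_abundance"] = pd.to_numeric(df["rel_abundance"], errors="coerce")
        if df["rel_abundance"].isna().any() or (df["rel_abundance"] < 0).any():
            raise ValidationError("floral_abundance: rel_abundance must be in [0,1]")
        sums = df.groupby("site")["rel_abundance"].sum()
        bad = sums[(sums - 1.0).abs() > 1e-6]
        if len(bad):
            raise ValidationError(
                "floral_abundance: per-site sums differ from 1: "
                + ", ".join(f"{s}={v:.6f}" for s, v in bad.items())
            )
        if df.duplicated(["site", "plant"]).any():
            raise ValidationError("floral_abundance: duplicated (site, plant) rows")
        return cls(df.reset_index(drop=True))

    def site_abundances(self, site_id: str) -> pd.Series:
        sub = self.data[self.data["site"] == site_id]
        return pd.Series(sub["rel_abundance"].to_numpy(), index=sub["plant"].to_numpy())

    def write_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


@dataclass(frozen=True)
class PollinatorTraitTable:
    """Species-level pollinator traits: proboscis length (mm), body length
    (mm), foraging-range class (central-place vs not) and taxonomic family."""

    data: pd.DataFrame

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PollinatorTraitTable":
        _require_columns(df, POLLINATOR_TRAIT_COLUMNS, "pollinator_traits")
        df = df[POLLINATOR_TRAIT_COLUMNS].copy()
        for col in ["proboscis_mm", "body_mm"]:
            df[col] = pd.to_numeric(df[col], errors="coerce")
        if df["species"].duplicated().any():
            dup = df.loc[df["species"].duplicated(), "species"].tolist()
            raise ValidationError(f"pollinator_traits: duplicated species {dup}")
        if df.isna().any().any():
            bad = df.loc[df.isna().any(axis=1), "species"].tolist()
            raise ValidationError(f"pollinator_traits: missing values for {bad}")
        if (df["proboscis_mm"] <= 0).any() or (df["body_mm"] <= 0).any():
            raise ValidationError("pollinator_traits: proboscis_mm and body_mm must be > 0")
        unknown = set(df["foraging_range"]) - set(FORAGING_CLASSES)
        if unknown:
            raise ValidationError(
                f"pollinator_traits: foraging_range must be one of {FORAGING_CLASSES}, "
                f"got {sorted(unknown)}"
            )
        return cls(df.reset_index(drop=True))

    @property
    def species(self) -> list[str]:
        return self.data["species"].tolist()

    def row(self, species: str) -> pd.Series:
        sub = self.data[self.data["species"] == species]
        if len(sub) == 0:
            raise ValidationError(f"pollinator_traits: unknown species {species!r}")
        return sub.iloc[0]

    def write_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


@dataclass(frozen=True)
class SiteNetwork:
    """Bipartite plant x pollinator visit-count matrix for one site.

    Species orders are lexicographic and the matrix has no all-zero rows or
    columns (every listed species has at least one recorded visit).
    """

    site_id: str
    plants: tuple[str, ...]
    pollinators: tuple[str, ...]
    counts: np.ndarray  # shape (n_plants, n_pollinators), int64

    def total(self) -> int:
        return int(self.counts.sum())

    def pollinator_vector(self, species: str) -> np.ndarray:
        """Visit counts over plants for one pollinator (a column)."""
        try:
            j = self.pollinators.index(species)
        except ValueError:
            raise KeyError(f"pollinator {species!r} not in network {self.site_id}")
        return self.counts[:, j].copy()

    def pollinator_totals(self) -> pd.Series:
        return pd.Series(self.counts.sum(axis=0), index=list(self.pollinators))


def load_interactions(path) -> InteractionTable:
    """Read and validate an interactions CSV (duplicates summed)."""
    return InteractionTable.from_frame(_read_csv(path))


def load_tables(
    sites_path,
    plant_traits_path,
    floral_abundance_path,
    pollinator_traits_path,
    interactions: InteractionTable | None = None,
) -> tuple[SiteInfo, PlantTraitTable, FloralAbundanceTable, PollinatorTraitTable]:
    """Load the four auxiliary tables and cross-validate against interactions.

    Every species appearing in the interaction records must have a trait row
    and every interaction site must have metadata and floral abundances; all
    orphans are reported at once.
    """
    sites = SiteInfo.from_frame(_read_csv(sites_path))
    plant_traits = PlantTraitTable.from_frame(_read_csv(plant_traits_path))
    floral = FloralAbundanceTable.from_frame(_read_csv(floral_abundance_path))
    poll_traits = PollinatorTraitTable.from_frame(_read_csv(pollinator_traits_path))
    if interactions is not None:
        cross_validate(interactions, sites, plant_traits, floral, poll_traits)
    return sites, plant_traits, floral, poll_traits


def cross_validate(
    interactions: InteractionTable,
    sites: SiteInfo,
    plant_traits: PlantTraitTable,
    floral: FloralAbundanceTable,
    poll_traits: PollinatorTraitTable,
) -> None:
    problems: list[str] = []
    known_sites = set(sites.data["site"])
    orphan_sites = sorted(set(interactions.sites) - known_sites)
    if orphan_sites:
        problems.append(f"sites missing from sites.csv: {orphan_sites}")
    orphan_plants = sorted(set(interactions.plants) - set(plant_traits.species))
    if orphan_plants:
        problems.append(f"plants missing from plant_traits.csv: {orphan_plants}")
    orphan_polls = sorted(set(interactions.pollinators) - set(poll_traits.species))
    if orphan_polls:
        problems.append(f"pollinators missing from pollinator_traits.csv: {orphan_polls}")
    # every interacting plant must have a floral-abundance row at its site
    floral_pairs = set(zip(floral.data["site"], floral.data["plant"]))
    missing_floral = sorted(
        {(s, p) for s, p in zip(interactions.data["site"], interactions.data["plant"])}
        - floral_pairs
    )
    if missing_floral:
        problems.append(f"(site, plant) pairs missing from floral_abundance.csv: {missing_floral}")
    if problems:
        raise ValidationError("; ".join(problems))


def build_site_network(interactions: InteractionTable, site_id: str) -> SiteNetwork:
    """Tabulate one site's records into a plant x pollinator count matrix."""
    sub = interactions.data[interactions.data["site"] == site_id]
    if len(sub) == 0:
        raise KeyError(f"unknown site {site_id!r}")
    mat = (
        sub.pivot_table(index="plant", columns="pollinator", values="count",
                        aggfunc="sum", fill_value=0)
        .sort_index(axis=0)
        .sort_index(axis=1)
    )
    return SiteNetwork(
        site_id=site_id,
        plants=tuple(mat.index),
        pollinators=tuple(mat.columns),
        counts=mat.to_numpy(dtype=np.int64),
    )
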