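"""Gower trait similarity of wild pollinators to the focal species.

Four traits enter the coefficient with equal weight: proboscis length and
body length (continuous, range-normalised over the pooled species list),
foraging-range class (binary: central-place vs not) and taxonomic family
(nominal).  With no ordinal traits, Podani's extension of Gower's
coefficient reduces to the original partial similarities: continuous
``s_k = 1 - |a_k - b_k| / R_k``, categorical ``s_k = 1`` iff equal.

Trait ranges ``R_k`` are computed once over the global species pool so a
given species pair scores identically at every site.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import InteractionTable, PollinatorTraitTable
from .errors import ValidationError

CONTINUOUS_TRAITS = ("proboscis_mm", "body_mm")
CATEGORICAL_TRAITS = ("foraging_range", "family")

# trait bands relative to the focal's morphology (proboscis c. 5 mm,
# body c. 12 mm); half-open to close the printed gaps (e.g. 3.9-4.0 mm)
PROBOSCIS_BANDS = ((4.0, "shorter"), (7.0, "similar"), (np.inf, "longer"))
BODY_BANDS = ((8.0, "smaller"), (15.0, "similar"), (np.inf, "larger"))


@dataclass(frozen=True)
class TraitRanges:
    """(min, max) of each continuous trait over the reference species pool."""

    ranges: dict[str, tuple[float, float]]

    @classmethod
    def from_table(cls, traits: PollinatorTraitTable) -> "TraitRanges":
        out = {}
        for col in CONTINUOUS_TRAITS:
            lo = float(traits.data[col].min())
            hi = float(traits.data[col].max())
            if hi <= lo:
                raise ValidationError(f"trait {col} is constant over the pool (range 0)")
            out[col] = (lo, hi)
        return cls(out)

    def span(self, trait: str) -> float:
        lo, hi = self.ranges[trait]
        return hi - lo


@dataclass
class SimilarityResult:
    site_id: str
    per_species: dict[str, float]
    cwm: float | None = None


def gower_similarity(a: pd.Series, b: pd.Series, ranges: TraitRanges) -> float:
    """Unweighted Gower similarity between two pollinator trait records."""
    parts = []
    for col in CONTINUOUS_TRAITS:
        lo, hi = ranges.ranges[col]
        va, vb = float(a[col]), float(b[col])
        if not (lo <= va <= hi and lo <= vb <= hi):
            raise ValidationError(
                f"{col} value outside pooled range [{lo}, {hi}]: {va}, {vb}"
            )
        parts.append(1.0 - abs(va - vb) / (hi - lo))
    for col in CATEGORICAL_TRAITS:
        parts.append(1.0 if a[col] == b[col] else 0.0)
    return float(np.mean(parts))


def similarity_vs_focal(
    traits: PollinatorTraitTable,
    focal: str,
    ranges: TraitRanges | None = None,
) -> pd.Series:
    """Gower similarity of every non-focal species to the focal.

    Returns a Series indexed by species, length ``len(table) - 1``.
    """
    if focal not in traits.species:
        raise ValidationError(f"focal species {focal!r} absent from trait table")
    if ranges is None:
        ranges = TraitRanges.from_table(traits)
    focal_row = traits.row(focal)
    out = {}
    for _, row in traits.data.iterrows():
        if row["species"] == focal:
            continue
        out[row["species"]] = gower_similarity(row, focal_row, ranges)
    return pd.Series(out)


def categorize_relative_to_focal(value: float, trait: str) -> str:
    """Band a proboscis or body length relative to the focal's morphology.

    Proboscis: shorter < 4 mm, similar 4-7 mm, longer >= 7 mm.
    Body: smaller < 8 mm, similar 8-15 mm, larger >= 15 mm.
    """
    if trait == "proboscis":
        bands = PROBOSCIS_BANDS
    elif trait == "body":
        bands = BODY_BANDS
    else:
        raise ValueError("trait must be 'proboscis' or 'body'")
    if not value > 0:
        raise ValueError(f"{trait} length must be positive, got {value}")
    for upper, label in bands:
        if value < upper:
            return label
    raise AssertionError("unreachable")


def aggregate_rare_families(
    traits: PollinatorTraitTable,
    interactions: InteractionTable,
    min_individuals: int = 10,
) -> dict[str, str]:
    """Map species -> family, relabelling rare families as ``"other"``.

    A family is rare when its total collected individuals, pooled over all
    sites, is strictly below ``min_individuals``.
    """
    fam = dict(zip(traits.data["species"], traits.data["family"]))
    per_species = interactions.data.groupby("pollinator")["count"].sum()
    fam_totals: dict[str, int] = {}
    for sp, n in per_species.items():
        if sp not in fam:
            raise ValidationError(f"species {sp!r} has no family in the trait table")
        fam_totals[fam[sp]] = fam_totals.get(fam[sp], 0) + int(n)
    rare = {f for f, n in fam_totals.items() if n < min_individuals}
    return {sp: ("other" if f in rare else f) for sp, f in fam.items()}
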