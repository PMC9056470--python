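"""Plant functional diversity: trait encoding, PCoA, FRic and FDis.

The workflow mirrors the standard distance-based functional-diversity
recipe: encode mixed traits numerically (continuous traits z-scored,
categorical traits dummy-expanded), build a Euclidean distance matrix over
the pooled species list, ordinate it with principal coordinates analysis
(PCoA), and compute per-community indices in the shared reduced space:

* FRic — the convex-hull volume of the community's species in the first
  ``m`` axes, standardised by the hull volume of the *global* pool so values
  lie in (0, 1] and 1 means the community spans the whole pool's trait
  space.
* FDis — the abundance-weighted mean distance of species to the
  abundance-weighted community centroid; 0 for a single species, unbounded
  above.

A single global PCoA is essential: hull volumes from per-site ordinations
would not be comparable, and dividing by the global hull would be
meaningless.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist, squareform

from .data_model import PlantTraitTable
from .errors import DegenerateHullError, ValidationError

logger = logging.getLogger(__name__)

_EIG_TOL = 1e-8  # relative tolerance for calling an eigenvalue zero/negative


@dataclass(frozen=True)
class TraitSpace:
    """Global PCoA embedding of the plant species pool.

    ``coords`` holds all positive axes (columns ordered by decreasing
    eigenvalue); indices computed from the space use the first ``m``.
    """

    species: tuple[str, ...]
    coords: np.ndarray
    eigenvalues: np.ndarray
    m: int
    global_hull_volume: float

    def community_coords(self, community) -> np.ndarray:
        idx = []
        missing = []
        pos = {sp: i for i, sp in enumerate(self.species)}
        for sp in community:
            if sp in pos:
                idx.append(pos[sp])
            else:
                missing.append(sp)
        if missing:
            raise ValidationError(f"species not in trait space: {missing}")
        return self.coords[idx, : self.m]


@dataclass(frozen=True)
class FDResult:
    site_id: str
    fric_std: float
    fdis: float


def encode_plant_traits(traits: PlantTraitTable) -> pd.DataFrame:
    """Numeric encoding of plant traits over the global pool.

    Corolla length is z-scored (sample sd); colour and flower type become
    one 0/1 indicator column per level.  A categorical trait with a single
    level contributes no distance and is dropped with a warning.
    """
    df = traits.data.set_index("species")
    blocks = []
    corolla = df["corolla_mm"].astype(float)
    sd = corolla.std(ddof=1)
    if sd == 0 or len(df) < 2:
        raise ValidationError("corolla_mm is constant; cannot z-score")
    blocks.append(((corolla - corolla.mean()) / sd).rename("corolla_z").to_frame())
    for col in ("colour", "flower_type"):
        levels = sorted(df[col].unique())
        if len(levels) < 2:
            logger.warning("trait %s has a single level (%s); dropped", col, levels[0])
            continue
        dummies = pd.get_dummies(df[col], prefix=col, dtype=float)
        blocks.append(dummies[[f"{col}_{lv}" for lv in levels]])
    return pd.concat(blocks, axis=1)


def trait_distance_matrix(encoded: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Euclidean distances between encoded species rows."""
    if len(encoded) < 2:
        raise ValidationError("need at least 2 species for a distance matrix")
    d = squareform(pdist(encoded.to_numpy(dtype=float), metric="euclidean"))
    return pd.DataFrame(d, index=encoded.index, columns=encoded.index)


def pcoa(
    dist: pd.DataFrame,
    m: int | str = "auto",
    min_community_size: int | None = None,
) -> TraitSpace:
    """Principal coordinates analysis of a distance matrix.

    The Gower-centred matrix ``-0.5 * J D^2 J`` is eigendecomposed; axes are
    ordered by decreasing eigenvalue and only positive axes are kept.  If
    materially negative eigenvalues appear (impossible for Euclidean input,
    but guarded), distances are square-root transformed once and the
    analysis retried.  ``m="auto"`` retains
    ``min(#positive axes, min_community_size - 1, 3)``.
    """
    D = np.asarray(dist, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    species = tuple(dist.index) if isinstance(dist, pd.DataFrame) else tuple(
        f"sp{i}" for i in range(D.shape[0])
    )

    def _decompose(Dm: np.ndarray):
        n = Dm.shape[0]
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ (Dm ** 2) @ J
        vals, vecs = scipy.linalg.eigh(B)
        order = np.argsort(vals)[::-1]
        return vals[order], vecs[:, order]

    vals, vecs = _decompose(D)
    scale = max(abs(vals[0]), 1.0)
    if vals[-1] < -_EIG_TOL * scale:
        logger.warning("negative PCoA eigenvalues; applying sqrt distance correction")
        vals, vecs = _decompose(np.sqrt(D))
        scale = max(abs(vals[0]), 1.0)
        if vals[-1] < -_EIG_TOL * scale:
            raise ValidationError("distance matrix not embeddable even after sqrt correction")
    pos = vals > _EIG_TOL * scale
    eigenvalues = vals[pos]
    coords = vecs[:, pos] * np.sqrt(eigenvalues)

    n_pos = int(pos.sum())
    if m == "auto":
        m_eff = min(n_pos, 3)
        if min_community_size is not None:
            m_eff = min(m_eff, min_community_size - 1)
    else:
        m_eff = int(m)
        if m_eff > n_pos:
            raise ValueError(f"requested m={m_eff} axes but only {n_pos} positive axes exist")
    if m_eff < 1:
        raise ValidationError("no positive PCoA axis retained")

    global_hull = _hull_volume(coords[:, :m_eff], "global pool")
    return TraitSpace(
        species=species,
        coords=coords,
        eigenvalues=eigenvalues,
        m=m_eff,
        global_hull_volume=global_hull,
    )


def _hull_volume(points: np.ndarray, what: str) -> float:
    m = points.shape[1]
    if m == 1:
        v = float(points.max() - points.min())
        if v <= 0:
            raise DegenerateHullError(f"{what}: 1-D hull has zero extent")
        return v
    if points.shape[0] < m + 1:
        raise DegenerateHullError(
            f"{what}: {points.shape[0]} points cannot span a {m}-D hull"
        )
    try:
        return float(ConvexHull(points).volume)
    except QhullError as e:
        raise DegenerateHullError(f"{what}: degenerate hull ({e})") from e


def functional_richness(space: TraitSpace, community) -> float:
    """Standardised FRic: community hull volume / global hull volume.

    Degenerate communities (too few or affinely dependent points) raise,
    carrying the community identity; the caller may reduce ``m`` for the
    whole run, never per site, because standardisation requires a shared
    dimensionality.
    """
    pts = space.community_coords(community)
    vol = _hull_volume(pts, f"community {list(community)[:3]}...")
    return vol / space.global_hull_volume


def functional_dispersion(space: TraitSpace, community, abundances) -> float:
    """FDis: abundance-weighted mean distance to the weighted centroid."""
    pts = space.community_coords(community)
    a = np.asarray(abundances, dtype=float)
    if a.shape[0] != pts.shape[0]:
        raise ValueError("abundances must align with the community")
    if (a < 0).any() or a.sum() <= 0:
        raise ValueError("abundances must be non-negative with positive sum")
    a = a / a.sum()
    centroid = a @ pts
    return float(a @ np.linalg.norm(pts - centroid, axis=1))
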