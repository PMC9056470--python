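"""Morisita-family niche overlap against a focal pollinator.

Two variants of the index are provided, because the literature's "Morisita's
index" covers both:

* ``morisita`` — the count-corrected original,
  :math:`C_\\lambda = 2\\sum x_i y_i / ((\\lambda_x + \\lambda_y) X Y)` with
  :math:`\\lambda_x = \\sum x_i (x_i - 1) / (X (X - 1))`.  On small samples it
  can slightly exceed 1.
* ``horn`` — the Morisita–Horn proportion form,
  :math:`C_H = 2\\sum p_i q_i / (\\sum p_i^2 + \\sum q_i^2)`, guaranteed in
  [0, 1].

Both are symmetric in their arguments and 0 exactly when the two species use
disjoint plant sets.  Community-weighted means (CWM) aggregate per-species
values weighted by species abundance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data_model import SiteNetwork
from .errors import FocalMissingError, UndefinedOverlapError, ValidationError

logger = logging.getLogger(__name__)

VARIANTS = ("morisita", "horn")


@dataclass
class OverlapResult:
    """Per-species overlap with the focal plus the site-level CWM."""

    site_id: str
    variant: str
    per_species: dict[str, float]
    abundances: dict[str, int]
    cwm: float | None = field(default=None)


def _as_counts(v, name: str) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be a 1-D count vector")
    if (arr < 0).any():
        raise ValueError(f"{name} has negative counts")
    return arr


def morisita_index(x, y, variant: str = "morisita") -> float:
    """Niche overlap between two visit-count vectors over the same plants."""
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    x = _as_counts(x, "x")
    y = _as_counts(y, "y")
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    X, Y = x.sum(), y.sum()
    if X == 0 or Y == 0:
        raise UndefinedOverlapError("overlap undefined for a species with zero total visits")
    if variant == "morisita" and (X < 2 or Y < 2):
        logger.warning(
            "morisita variant requires totals >= 2 (got %g, %g); falling back to horn", X, Y
        )
        variant = "horn"
    cross = float(np.dot(x, y))
    if variant == "horn":
        p, q = x / X, y / Y
        return 2.0 * float(np.dot(p, q)) / (float(np.dot(p, p)) + float(np.dot(q, q)))
    lam_x = float(np.dot(x, x - 1)) / (X * (X - 1))
    lam_y = float(np.dot(y, y - 1)) / (Y * (Y - 1))
    if lam_x + lam_y == 0:
        # both species are maximally even singleton-per-plant samples; the
        # correction degenerates, fall back to the proportion form
        logger.warning("degenerate Morisita correction (lambda_x + lambda_y = 0); using horn")
        return morisita_index(x, y, variant="horn")
    # grouped so the expression is bitwise symmetric in (x, y)
    return 2.0 * cross / ((lam_x + lam_y) * (X * Y))


def overlap_vs_focal(net: SiteNetwork, focal: str, variant: str = "morisita") -> OverlapResult:
    """Overlap of every wild pollinator in the network against the focal.

    The focal must be present with at least one visit; its absence is a data
    problem (the study design has the focal at every site), not a zero.
    """
    if focal not in net.pollinators:
        raise FocalMissingError(f"focal species {focal!r} absent from site {net.site_id}")
    fx = net.pollinator_vector(focal)
    if fx.sum() < 1:
        raise FocalMissingError(f"focal species {focal!r} has zero visits at {net.site_id}")
    per: dict[str, float] = {}
    abund: dict[str, int] = {}
    for sp in net.pollinators:
        if sp == focal:
            continue
        v = net.pollinator_vector(sp)
        per[sp] = morisita_index(v, fx, variant=variant)
        abund[sp] = int(v.sum())
    return OverlapResult(site_id=net.site_id, variant=variant, per_species=per, abundances=abund)


def cwm(values, weights) -> float:
    """Community-weighted mean: sum(w*v)/sum(w), bounded by [min(v), max(v)]."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.shape != w.shape:
        raise ValueError("values and weights must have the same length")
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ValueError("weights sum to zero; CWM undefined")
    return float(np.dot(v, w) / total)


def overlap_by_category(
    net: SiteNetwork,
    focal: str,
    categories: dict[str, str],
    variant: str = "morisita",
) -> dict[str, float]:
    """CWM overlap with the focal, split by a wild-species categorisation.

    Labels with no species at the site are absent from the result, which is
    what makes the site x category table for the trait models unbalanced.
    """
    res = overlap_vs_focal(net, focal, variant=variant)
    unlabeled = sorted(set(res.per_species) - set(categories))
    if unlabeled:
        raise ValidationError(f"species without a category label: {unlabeled}")
    out: dict[str, float] = {}
    for label in sorted({categories[sp] for sp in res.per_species}):
        members = [sp for sp in res.per_species if categories[sp] == label]
        out[label] = cwm(
            [res.per_species[sp] for sp in members],
            [res.abundances[sp] for sp in members],
        )
    return out
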