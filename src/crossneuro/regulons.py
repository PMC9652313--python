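"""Regulon activity scoring, bimodal binarisation and activation grouping.

Regulon gene sets (TF + targets) enter as input; per-cell activity is an
AUCell-style recovery-curve statistic on within-cell expression ranks,
binarised per regulon with a two-component Gaussian mixture, summarised as
the fraction of active cells per subtype, and grouped by k-means into a
fixed number of activation patterns (eight by default).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

from .io_core import CellTable, GeneSet, ValidationError
from .preprocess_integrate import ParameterError

logger = logging.getLogger("crossneuro")


@dataclass
class ActivityMatrix:
    """Cells x regulons activity scores with per-regulon thresholds."""

    scores: pd.DataFrame  # cells x regulons
    thresholds: pd.Series  # per regulon; +inf marks an all-inactive regulon

    @property
    def binarized(self) -> pd.DataFrame:
        return (self.scores >= self.thresholds).astype(int)


@dataclass
class ActivationProfile:
    """Regulons x subtypes activated-cell fractions plus group labels."""

    fractions: pd.DataFrame
    group: pd.Series = field(default_factory=lambda: pd.Series(dtype=int))

    def __post_init__(self) -> None:
        v = self.fractions.to_numpy(float)
        if v.size and (v.min() < 0 or v.max() > 1):
            raise ValidationError("activation fractions outside [0, 1]")


def _top_rank_orders(table: CellTable, top: int) -> np.ndarray:
    """Per cell, the indices of the ``top`` highest-expressed genes in rank
    order (descending expression, ties broken by gene id)."""
    id_rank = np.empty(table.n_genes, dtype=int)
    id_rank[np.argsort(np.array(table.gene_ids))] = np.arange(table.n_genes)
    expr = table.counts.astype(float)
    orders = np.empty((table.n_cells, top), dtype=int)
    for c in range(table.n_cells):
        # lexsort: last key is primary
        full = np.lexsort((id_rank, -expr[c]))
        orders[c] = full[:top]
    return orders


def _recovery_auc(
    orders: np.ndarray, target_mask: np.ndarray, n_targets: int
) -> np.ndarray:
    hits = target_mask[orders]  # cells x top
    top = orders.shape[1]
    best_hits = np.minimum(np.arange(1, top + 1), n_targets)
    max_area = float(best_hits.sum())
    return hits.cumsum(axis=1).sum(axis=1) / max_area


def activity_score(
    table: CellTable,
    regulon: GeneSet,
    top_fraction: float = 0.05,
    _orders: np.ndarray | None = None,
) -> np.ndarray:
    """AUCell-style per-cell activity of a regulon.

    For each cell, genes are ranked by descending raw expression (ties
    broken lexicographically by gene id); the score is the area under the
    target-recovery step curve within the top ``ceil(top_fraction * G)``
    ranks, normalised so that a cell whose targets occupy the very top ranks
    scores exactly 1.
    """
    targets = sorted(regulon.genes & set(table.gene_ids))
    if not targets:
        raise ValidationError(
            f"regulon {regulon.name!r} has no target in the gene universe"
        )
    G = table.n_genes
    top = math.ceil(top_fraction * G)
    if top < 1:
        raise ParameterError("top_fraction selects no gene")
    target_mask = np.zeros(G, dtype=bool)
    target_mask[table.gene_index(targets)] = True
    orders = _orders if _orders is not None else _top_rank_orders(table, top)
    return _recovery_auc(orders, target_mask, len(targets))


def binarize_bimodal(
    scores: np.ndarray, seed: int = 0, min_sep: float = 0.05,
    min_weight: float = 0.01,
) -> float:
    """Threshold separating the two modes of a regulon's score distribution.

    A two-component 1-D Gaussian mixture is fitted (10 seeded restarts); the
    threshold is the point between the component means where the posterior
    responsibility switches.  If the fit degenerates (component means closer
    than ``min_sep`` as a fraction of the score range, or a component weight
    below ``min_weight``) a global-valley histogram threshold is used
    instead.  Constant scores give ``+inf`` (no cell active).
    """
    x = np.asarray(scores, float)
    if len(x) < 20:
        raise ValidationError("need >= 20 cells to fit the bimodal model")
    if np.ptp(x) == 0:
        logger.warning("constant activity scores; regulon marked inactive")
        return float("inf")
    # a point mass at the minimum (cells recovering no target at all) is
    # inactive by definition and would hijack the two-component fit; fit the
    # mixture to the remaining scores
    at_min = x == x.min()
    if 0.05 * len(x) < at_min.sum() and (~at_min).sum() >= 20:
        floor = float(x.min())
        thr = binarize_bimodal(
            x[~at_min], seed=seed, min_sep=min_sep, min_weight=min_weight
        )
        return max(thr, np.nextafter(floor, np.inf))
    gm = GaussianMixture(
        n_components=2, n_init=10, random_state=int(seed) & 0x7FFFFFFF,
        reg_covar=1e-8,
    ).fit(x.reshape(-1, 1))
    means = gm.means_.ravel()
    weights = gm.weights_.ravel()
    lo, hi = float(means.min()), float(means.max())
    degenerate = (hi - lo) < min_sep * np.ptp(x) or weights.min() < min_weight
    if degenerate:
        return _valley_threshold(x)
    grid = np.linspace(lo, hi, 512)
    post = gm.predict_proba(grid.reshape(-1, 1))
    hi_comp = int(np.argmax(means))
    above = post[:, hi_comp] >= 0.5
    if not above.any() or above.all():
        return _valley_threshold(x)
    # unequal variances can give several responsibility crossings; take the
    # one nearest the midpoint of the component means
    crossings = np.flatnonzero(np.diff(above.astype(int)) != 0)
    mid = 0.5 * (lo + hi)
    best = crossings[np.argmin(np.abs(grid[crossings] - mid))]
    return float(grid[best + 1])


def _valley_threshold(x: np.ndarray, bins: int = 50) -> float:
    """Deepest histogram valley between the two outermost peaks."""
    hist, edges = np.histogram(x, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    peak_lo = int(np.argmax(hist[: bins // 2]))
    peak_hi = bins // 2 + int(np.argmax(hist[bins // 2 :]))
    if peak_hi <= peak_lo + 1:
        return float(np.median(x))
    inner = slice(peak_lo + 1, peak_hi)
    valley = peak_lo + 1 + int(np.argmin(hist[inner]))
    return float(centers[valley])


def score_regulons_raw(
    table: CellTable,
    regulons: list[GeneSet],
    top_fraction: float = 0.05,
) -> pd.DataFrame:
    """Activity scores (cells x regulons) without binarisation."""
    top = math.ceil(top_fraction * table.n_genes)
    orders = _top_rank_orders(table, top)
    scores = {
        reg.name: activity_score(
            table, reg, top_fraction=top_fraction, _orders=orders
        )
        for reg in regulons
    }
    return pd.DataFrame(scores, index=table.cell_ids)


def score_regulons(
    table: CellTable,
    regulons: list[GeneSet],
    top_fraction: float = 0.05,
    seed: int = 0,
) -> ActivityMatrix:
    """Score and binarise every regulon on a table."""
    scores = score_regulons_raw(table, regulons, top_fraction=top_fraction)
    thresholds = pd.Series(
        {
            name: binarize_bimodal(scores[name].to_numpy(), seed=seed + i)
            for i, name in enumerate(scores.columns)
        }
    )
    return ActivityMatrix(scores=scores, thresholds=thresholds)


def filter_active(binarized: pd.DataFrame) -> list[str]:
    """Regulons active in at least one cell."""
    return [c for c in binarized.columns if binarized[c].sum() >= 1]


def activation_profile(
    binarized: pd.DataFrame, subtypes
) -> ActivationProfile:
    """Fraction of active cells per (regulon, subtype); exact ratios."""
    subtypes = np.asarray(subtypes)
    if len(subtypes) != len(binarized):
        raise ValidationError("subtype labels do not cover all cells")
    uniq = list(pd.unique(subtypes))
    rows = {}
    for st in uniq:
        sel = binarized.loc[subtypes == st]
        if len(sel) == 0:
            raise ValidationError(f"subtype {st!r} has no cell")
        rows[st] = sel.mean(axis=0)
    frac = pd.DataFrame(rows)  # regulons x subtypes
    return ActivationProfile(fractions=frac)


def group_regulons(
    profile: ActivationProfile, k: int = 8, seed: int = 0,
    n_restarts: int = 50,
) -> pd.Series:
    """K-means grouping of regulon activation patterns into ``k`` groups.

    Groups are relabelled 1..k by descending size (ties by first occurrence)
    so reports are reproducible.
    """
    X = profile.fractions.to_numpy(float)
    if len(X) < k:
        raise ValidationError(f"only {len(X)} regulons for k={k}")
    km = KMeans(
        n_clusters=k, init="k-means++", n_init=n_restarts,
        random_state=int(seed) & 0x7FFFFFFF,
    ).fit(X)
    raw = km.labels_
    sizes = pd.Series(raw).value_counts()
    first_seen = {lab: int(np.argmax(raw == lab)) for lab in sizes.index}
    order = sorted(sizes.index, key=lambda lab: (-sizes[lab], first_seen[lab]))
    remap = {lab: i + 1 for i, lab in enumerate(order)}
    groups = pd.Series(
        [remap[lab] for lab in raw], index=profile.fractions.index, name="group"
    )
    profile.group = groups
    return groups
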