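"""Normalisation, feature selection, PCA, reciprocal-PCA anchor correction
and graph clustering.

The integration step is a transparent re-statement of reciprocal-PCA
anchoring: both datasets are projected into each other's principal-component
bases, anchors are cell pairs that are mutual nearest neighbours in *both*
reciprocal projections, and query cells are shifted by a Gaussian-kernel
weighted average of their anchors' displacement vectors.  It deliberately
omits CCA, anchor scoring and weight trees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse
from scipy.spatial import cKDTree

from .io_core import CellTable, ValidationError

logger = logging.getLogger("crossneuro")


class ParameterError(ValueError):
    pass


@dataclass
class EmbeddedCells:
    """Low-dimensional cell coordinates aligned with a CellTable."""

    coords: np.ndarray  # cells x d
    cell_ids: list[str]
    d: int

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != self.d:
            raise ValidationError("coords shape inconsistent with d")
        if len(self.cell_ids) != self.coords.shape[0]:
            raise ValidationError("cell ids do not match coordinate rows")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("non-finite embedding coordinates")


@dataclass
class Clustering:
    labels: np.ndarray  # per-cell integer cluster id
    k: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.k < 1 or len(np.unique(self.labels)) != self.k:
            raise ValidationError("cluster count inconsistent with labels")


# ---------------------------------------------------------------------------


def normalize_log1p(
    table: CellTable | np.ndarray, scale: float = 10_000.0
) -> np.ndarray:
    """Library-size normalisation: x -> ln(1 + scale * x / cell_total).

    Cells with zero total are returned as all-zero rows with a warning.
    """
    counts = table.counts if isinstance(table, CellTable) else np.asarray(table)
    counts = counts.astype(float)
    totals = counts.sum(axis=1)
    zero = totals == 0
    if zero.any():
        logger.warning("%d cell(s) with zero total counts", int(zero.sum()))
    safe = np.where(zero, 1.0, totals)
    return np.log1p(scale * counts / safe[:, None])


def select_hvg(norm_matrix: np.ndarray, n: int, gene_ids=None,
               n_bins: int = 20) -> list:
    """Top-``n`` highly variable genes by mean-binned standardised dispersion.

    Dispersion = variance/mean is z-scored within equal-frequency mean bins;
    genes are returned in descending rank order, ties broken by gene id.
    """
    if n <= 0:
        raise ParameterError("n must be positive")
    X = np.asarray(norm_matrix, dtype=float)
    G = X.shape[1]
    if n > G:
        raise ParameterError(f"n={n} exceeds gene count {G}")
    if gene_ids is None:
        gene_ids = list(range(G))
    mean = X.mean(axis=0)
    var = X.var(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(G)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    # equal-frequency bins on the mean; keep ~10 genes per bin minimum
    n_bins = max(1, min(n_bins, G // 10))
    order = np.argsort(mean, kind="stable")
    bins = np.empty(G, dtype=int)
    bins[order] = np.minimum(
        (np.arange(G) * n_bins) // max(G, 1), n_bins - 1
    )
    z = np.zeros(G)
    for b in range(n_bins):
        sel = bins == b
        if not sel.any():
            continue
        mu, sd = disp[sel].mean(), disp[sel].std()
        z[sel] = (disp[sel] - mu) / sd if sd > 0 else 0.0
    z[var == 0] = -1e18  # constant genes always rank last
    key = sorted(range(G), key=lambda i: (-z[i], str(gene_ids[i])))
    return [gene_ids[i] for i in key[:n]]


def scale_columns(X: np.ndarray, clip: float = 10.0) -> np.ndarray:
    """Zero-mean, unit-variance columns, clipped at ``clip`` absolute z."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return np.clip((X - mu) / sd, -clip, clip)


def _deterministic_sign(components: np.ndarray) -> np.ndarray:
    """Flip each component so its largest-magnitude loading is positive."""
    flips = np.ones(components.shape[0])
    for i, row in enumerate(components):
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            flips[i] = -1.0
    return flips


def pca_embed(
    scaled_matrix: np.ndarray, d: int, cell_ids=None,
    return_basis: bool = False,
):
    """Scores of the top-``d`` principal components via SVD.

    Sign convention: each component's largest-magnitude loading is positive,
    so the embedding is deterministic.
    """
    X = np.asarray(scaled_matrix, dtype=float)
    n, g = X.shape
    if not (1 <= d <= min(n, g)):
        raise ParameterError(f"d={d} invalid for matrix {X.shape}")
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    flips = _deterministic_sign(Vt[:d])
    scores = (U[:, :d] * S[:d]) * flips
    basis = Vt[:d] * flips[:, None]
    if cell_ids is None:
        cell_ids = [str(i) for i in range(n)]
    emb = EmbeddedCells(coords=scores, cell_ids=list(cell_ids), d=d)
    if return_basis:
        return emb, basis, X.mean(axis=0)
    return emb


def _mnn_pairs(A: np.ndarray, B: np.ndarray, k: int) -> set[tuple[int, int]]:
    """Mutual nearest-neighbour index pairs (i in A, j in B)."""
    k_a = min(k, len(B))
    k_b = min(k, len(A))
    tree_b = cKDTree(B)
    tree_a = cKDTree(A)
    _, nb_of_a = tree_b.query(A, k=k_a)
    _, na_of_b = tree_a.query(B, k=k_b)
    nb_of_a = np.atleast_2d(nb_of_a.reshape(len(A), -1))
    na_of_b = np.atleast_2d(na_of_b.reshape(len(B), -1))
    fwd = {(i, int(j)) for i in range(len(A)) for j in nb_of_a[i]}
    pairs = set()
    for j in range(len(B)):
        for i in na_of_b[j]:
            if (int(i), j) in fwd:
                pairs.add((int(i), j))
    return pairs


def anchor_correct(
    ref_scaled: np.ndarray,
    query_scaled: np.ndarray,
    ref_ids,
    query_ids,
    d: int = 30,
    k_anchor: int = 5,
) -> tuple[EmbeddedCells, list[tuple[int, int]]]:
    """Reciprocal-PCA anchor correction of a query dataset onto a reference.

    Both inputs are column-scaled expression on a shared gene space.  Anchors
    are cell pairs that are mutual nearest neighbours in the reference PCA
    projection *and* in the query PCA projection; each query cell is shifted
    by a Gaussian-kernel weighted average of its anchors' displacements in
    the reference basis.  Returns the combined embedding (reference rows
    first) and the anchor pairs.
    """
    if k_anchor < 1:
        raise ParameterError("k_anchor must be >= 1")
    ref_scaled = np.asarray(ref_scaled, float)
    query_scaled = np.asarray(query_scaled, float)
    if ref_scaled.shape[1] != query_scaled.shape[1]:
        raise ValidationError("reference and query gene spaces differ")
    d_eff = min(d, min(ref_scaled.shape) - 1, min(query_scaled.shape) - 1)

    _, basis_r, mu_r = pca_embed(ref_scaled, d_eff, return_basis=True)
    _, basis_q, mu_q = pca_embed(query_scaled, d_eff, return_basis=True)

    # projection of both datasets into each basis
    r_in_r = (ref_scaled - mu_r) @ basis_r.T
    q_in_r = (query_scaled - mu_r) @ basis_r.T
    r_in_q = (ref_scaled - mu_q) @ basis_q.T
    q_in_q = (query_scaled - mu_q) @ basis_q.T

    pairs_r = _mnn_pairs(r_in_r, q_in_r, k_anchor)
    pairs_q = _mnn_pairs(r_in_q, q_in_q, k_anchor)
    anchors = sorted(pairs_r & pairs_q)
    if not anchors:
        raise ValidationError(
            "no anchors found between datasets; increase k_anchor"
        )
    a_ref = np.array([a for a, _ in anchors])
    a_qry = np.array([b for _, b in anchors])
    displacement = r_in_r[a_ref] - q_in_r[a_qry]  # per anchor, in ref basis

    # smooth displacements over query cells with a Gaussian kernel anchored
    # at pair midpoints, so symmetric anchor pairs cancel exactly when the
    # datasets coincide
    midpoints = 0.5 * (r_in_r[a_ref] + q_in_r[a_qry])
    # anchors sharing a midpoint (e.g. the two orientations of one pair)
    # are aggregated by averaging their displacements
    uniq_mid, inverse = np.unique(midpoints, axis=0, return_inverse=True)
    agg_disp = np.zeros((len(uniq_mid), midpoints.shape[1]))
    counts = np.bincount(inverse, minlength=len(uniq_mid)).astype(float)
    for dim in range(midpoints.shape[1]):
        agg_disp[:, dim] = np.bincount(
            inverse, weights=displacement[:, dim], minlength=len(uniq_mid)
        )
    displacement = agg_disp / counts[:, None]
    tree = cKDTree(uniq_mid)
    k_w = min(max(3 * k_anchor, 10), len(uniq_mid))
    dist, idx = tree.query(q_in_r, k=k_w)
    dist = dist.reshape(len(q_in_r), -1)
    idx = idx.reshape(len(q_in_r), -1)
    sigma = np.median(dist[:, -1]) + 1e-12
    w = np.exp(-0.5 * (dist / sigma) ** 2)
    w /= w.sum(axis=1, keepdims=True)
    shift = np.einsum("ck,ckd->cd", w, displacement[idx])
    q_corrected = q_in_r + shift

    coords = np.vstack([r_in_r, q_corrected])
    emb = EmbeddedCells(
        coords=coords, cell_ids=list(ref_ids) + list(query_ids), d=d_eff
    )
    return emb, anchors


def _snn_graph(coords: np.ndarray, k: int = 15):
    """Shared-nearest-neighbour graph with Jaccard edge weights."""
    import igraph as ig

    n = len(coords)
    k_eff = min(k + 1, n)
    tree = cKDTree(coords)
    _, nbrs = tree.query(coords, k=k_eff)
    nbrs = nbrs.reshape(n, -1)
    neighbor_sets = [set(row.tolist()) for row in nbrs]
    rows, cols, weights = [], [], []
    for i in range(n):
        for j in nbrs[i]:
            j = int(j)
            if j <= i:
                continue
            shared = len(neighbor_sets[i] & neighbor_sets[j])
            union = len(neighbor_sets[i] | neighbor_sets[j])
            w = shared / union
            if w > 0:
                rows.append(i)
                cols.append(j)
                weights.append(w)
    g = ig.Graph(n=n, edges=list(zip(rows, cols)))
    g.es["weight"] = weights
    return g


def cluster_cells(
    emb: EmbeddedCells,
    target_k: int = 31,
    seed: int = 0,
    method: str = "snn",
    k_neighbors: int = 15,
    max_iter: int = 30,
) -> Clustering:
    """Cluster the embedding into at least ``target_k`` communities.

    Default: Leiden modularity communities on a shared-nearest-neighbour
    graph, with the resolution raised by bisection until the community count
    reaches ``target_k``.  ``method="kmeans"`` is a deterministic fallback
    that clusters directly into ``target_k`` groups.
    """
    n = len(emb.cell_ids)
    if target_k > n:
        raise ParameterError(f"target_k={target_k} exceeds {n} cells")
    if method == "kmeans":
        from sklearn.cluster import KMeans

        km = KMeans(
            n_clusters=target_k, n_init=10, random_state=seed & 0x7FFFFFFF
        ).fit(emb.coords)
        labels = km.labels_
        return Clustering(labels=labels, k=len(np.unique(labels)))
    if method != "snn":
        raise ParameterError(f"unknown clustering method {method!r}")

    import leidenalg

    graph = _snn_graph(emb.coords, k=k_neighbors)

    def run(resolution: float) -> np.ndarray:
        part = leidenalg.find_partition(
            graph,
            leidenalg.RBConfigurationVertexPartition,
            weights="weight",
            resolution_parameter=resolution,
            seed=int(seed) & 0x7FFFFFFF,
            n_iterations=2,
        )
        return np.array(part.membership)

    lo, hi = 0.1, 2.0
    labels = run(hi)
    tries = 0
    while len(np.unique(labels)) < target_k and tries < max_iter:
        hi *= 2.0
        labels = run(hi)
        tries += 1
    if len(np.unique(labels)) < target_k:
        raise ValidationError(
            f"could not reach {target_k} communities (got "
            f"{len(np.unique(labels))})"
        )
    best = labels
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        lab = run(mid)
        if len(np.unique(lab)) >= target_k:
            best, hi = lab, mid
        else:
            lo = mid
        if hi - lo < 1e-3:
            break
    labels = best
    # compact label ids
    _, labels = np.unique(labels, return_inverse=True)
    return Clustering(labels=labels, k=len(np.unique(labels)))
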