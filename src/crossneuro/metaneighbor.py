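"""Supervised neighbour-voting AUROC for gene-set evaluation.

Measures how well a gene set lets cells of a labelled class (here,
inhibitory neurons = 1 vs others = 0) find each other across batches: build
a rank-standardised Spearman similarity network on the gene-set submatrix,
hold out one batch at a time, score each held-out cell by the
degree-normalised sum of its network weights to labelled cells in the other
batches, and take the AUROC of those scores against the held-out labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io_core import CellTable, GeneSet, ValidationError
from .preprocess_integrate import normalize_log1p

logger = logging.getLogger("crossneuro")


@dataclass
class VotingNetwork:
    """Rank-standardised cell-cell similarity in (0, 1] with batch labels."""

    weights: np.ndarray  # cells x cells, symmetric
    batches: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, float)
        if w.shape[0] != w.shape[1]:
            raise ValidationError("network must be square")
        if not np.allclose(w, w.T):
            raise ValidationError("network must be symmetric")
        off = w[~np.eye(len(w), dtype=bool)]
        if off.size and (off.min() <= 0 or off.max() > 1):
            raise ValidationError("network values must lie in (0, 1]")


def build_network(
    norm_submatrix: np.ndarray, batches=None
) -> VotingNetwork:
    """Spearman similarity across cells, rank-standardised to (0, 1].

    All pairwise similarities are jointly ranked (average ranks for ties)
    and divided by the maximum rank; the matrix is then symmetrised by
    averaging with its transpose.
    """
    X = np.asarray(norm_submatrix, float)
    n, g = X.shape
    if n < 2 or g < 2:
        raise ValidationError("need at least 2 cells and 2 genes")
    # Spearman: Pearson on within-cell ranks of genes
    ranks = np.apply_along_axis(rankdata, 1, X)
    ranks = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(ranks, axis=1)
    norms = np.where(norms == 0, 1.0, norms)
    sim = (ranks / norms[:, None]) @ (ranks / norms[:, None]).T
    flat = rankdata(sim.ravel())
    net = (flat / flat.max()).reshape(n, n)
    net = 0.5 * (net + net.T)
    if batches is None:
        batches = np.zeros(n, dtype=int)
    return VotingNetwork(weights=net, batches=np.asarray(batches))


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney U statistic scaled to [0, 1] (ties get half credit)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUROC needs both classes")
    r = rankdata(scores)
    u = r[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def neighbor_vote_auroc(
    network: VotingNetwork, labels01, batches=None
) -> dict:
    """Cross-batch neighbour voting; returns per-batch and mean AUROC.

    Batches containing a single class are skipped with a warning.
    """
    labels = np.asarray(labels01).astype(int)
    if set(np.unique(labels)) - {0, 1}:
        raise ValidationError("labels must be binary")
    batches = np.asarray(batches if batches is not None else network.batches)
    uniq = pd.unique(batches)
    if len(uniq) < 2:
        raise ValidationError("need at least 2 batches for cross-validation")
    W = network.weights.copy()
    np.fill_diagonal(W, 0.0)  # a cell never votes for itself
    per_batch: dict = {}
    for b in uniq:
        test = batches == b
        train = ~test
        y_test = labels[test]
        if y_test.min() == y_test.max():
            logger.warning("batch %r has a single class; skipped", b)
            continue
        w_block = W[np.ix_(test, train)]
        votes = w_block @ labels[train]
        degree = w_block.sum(axis=1)
        degree = np.where(degree == 0, 1.0, degree)
        per_batch[b] = auroc(votes / degree, y_test)
    if not per_batch:
        raise ValidationError("no batch with both classes")
    return {
        "per_batch": per_batch,
        "mean": float(np.mean(list(per_batch.values()))),
    }


def run_supervised(
    table: CellTable,
    gene_set: GeneSet,
    n_cells: int = 20,
    n_iter: int = 10,
    seed: int = 0,
    label_column: str = "subtype",
    positive_prefix: str = "Inc",
    cluster_column: str = "subtype",
    scale: float = 10_000.0,
) -> tuple[float, float]:
    """Mean and SD of the neighbour-voting AUROC over random subsamples.

    Each iteration subsamples ``n_cells`` per cluster (all cells if fewer),
    builds the gene-set voting network, and scores
    inhibitory-vs-rest labels (positives = clusters whose label starts with
    ``positive_prefix``) across batches.
    """
    genes = sorted(gene_set.genes & set(table.gene_ids))
    if not genes:
        raise ValidationError(
            f"gene set {gene_set.name!r} shares no gene with the table"
        )
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    clusters = table.annot[cluster_column].to_numpy()
    labels_all = (
        table.annot[label_column].astype(str).str.startswith(positive_prefix)
    ).to_numpy().astype(int)
    batches_all = table.annot["batch"].to_numpy()
    norm_all = normalize_log1p(table, scale=scale)[:, table.gene_index(genes)]

    aurocs = []
    for _ in range(n_iter):
        keep: list[int] = []
        for cl in pd.unique(clusters):
            idx = np.flatnonzero(clusters == cl)
            if len(idx) > n_cells:
                idx = rng.choice(idx, size=n_cells, replace=False)
            keep.extend(idx.tolist())
        keep = sorted(keep)
        net = build_network(norm_all[keep], batches=batches_all[keep])
        res = neighbor_vote_auroc(net, labels_all[keep], batches_all[keep])
        aurocs.append(res["mean"])
    return float(np.mean(aurocs)), float(np.std(aurocs))
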