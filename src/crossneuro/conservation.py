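"""Cross-species cell-type conservation scoring.

The central statistic: after subsampling each annotated subtype, jointly
integrating two species and clustering the union into a fine partition, each
subtype is summarised by its distribution over clusters, and the conservation
of a (query subtype, reference subtype) pair is the sum over clusters of the
minimum of the two proportions.  This equals one minus the total-variation
distance between the two distributions, so identical cluster usage scores 1
and disjoint usage scores 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import CellTable, HomologyMap, ValidationError, map_to_reference
from .preprocess_integrate import (
    Clustering,
    anchor_correct,
    cluster_cells,
    normalize_log1p,
    scale_columns,
    select_hvg,
)

logger = logging.getLogger("crossneuro")


@dataclass
class SubtypeDistribution:
    """A subtype's empirical distribution over joint-cluster ids."""

    subtype: str
    species: str
    p: dict[int, float]

    def __post_init__(self) -> None:
        vals = np.array(list(self.p.values()), dtype=float)
        if (vals < 0).any():
            raise ValidationError("negative cluster proportion")
        if abs(vals.sum() - 1.0) > 1e-12:
            raise ValidationError(
                f"cluster proportions sum to {vals.sum()!r}, not 1"
            )


@dataclass
class OverlapMatrix:
    """Query subtypes (rows) x reference subtypes (cols), values in [0, 1]."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if v.size and (v.min() < -1e-12 or v.max() > 1 + 1e-12):
            raise ValidationError("overlap scores outside [0, 1]")


def subsample_subtypes(
    table: CellTable, n: int = 100, seed: int = 0
) -> CellTable:
    """Sample up to ``n`` cells per subtype without replacement.

    Subtypes with fewer than ``n`` cells are retained in full.
    """
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    subtypes = table.annot["subtype"].to_numpy()
    keep: list[int] = []
    for st in pd.unique(subtypes):
        idx = np.flatnonzero(subtypes == st)
        if len(idx) > n:
            idx = np.sort(rng.choice(idx, size=n, replace=False))
        keep.extend(idx.tolist())
    keep.sort()
    return table.subset_cells(np.array(keep, dtype=int))


def overlap_score(pA: SubtypeDistribution, pB: SubtypeDistribution) -> float:
    """Sum over the cluster union of min(pA_c, pB_c); symmetric, in [0, 1]."""
    clusters = set(pA.p) | set(pB.p)
    return float(sum(min(pA.p.get(c, 0.0), pB.p.get(c, 0.0)) for c in clusters))


def subtype_distributions(
    clustering: Clustering, annot: pd.DataFrame, species: str
) -> dict[str, SubtypeDistribution]:
    """Per-subtype cluster-proportion vectors for one species."""
    mask = (annot["species"] == species).to_numpy()
    labels = clustering.labels[mask]
    subtypes = annot.loc[mask, "subtype"].to_numpy()
    out: dict[str, SubtypeDistribution] = {}
    for st in pd.unique(subtypes):
        labs = labels[subtypes == st]
        vals, counts = np.unique(labs, return_counts=True)
        p = {int(c): float(n) / len(labs) for c, n in zip(vals, counts)}
        out[st] = SubtypeDistribution(subtype=st, species=species, p=p)
    return out


def conservation_matrix(
    clustering: Clustering,
    annot: pd.DataFrame,
    query_species: str,
    reference_species: str,
) -> OverlapMatrix:
    """Overlap score for every (query subtype, reference subtype) pair.

    Row/column order is the first-appearance order of subtypes in the
    annotation.  The score is invariant to cluster relabeling.
    """
    if len(annot) != len(clustering.labels):
        raise ValidationError("annotation and clustering disagree on cells")
    for sp in (query_species, reference_species):
        if not (annot["species"] == sp).any():
            raise ValidationError(f"species {sp!r} absent from annotation")
    q_dist = subtype_distributions(clustering, annot, query_species)
    r_dist = subtype_distributions(clustering, annot, reference_species)
    q_order = [
        st
        for st in pd.unique(
            annot.loc[annot["species"] == query_species, "subtype"].to_numpy()
        )
    ]
    r_order = [
        st
        for st in pd.unique(
            annot.loc[
                annot["species"] == reference_species, "subtype"
            ].to_numpy()
        )
    ]
    mat = pd.DataFrame(
        [
            [overlap_score(q_dist[q], r_dist[r]) for r in r_order]
            for q in q_order
        ],
        index=q_order,
        columns=r_order,
    )
    return OverlapMatrix(values=mat)


def extract_inhibitory(
    table: CellTable,
    markers: tuple[str, ...] = ("GAD1", "GAD2"),
    min_norm_expr: float = 0.0,
    scale: float = 10_000.0,
) -> CellTable:
    """Cells with normalised expression of any inhibitory marker above
    ``min_norm_expr`` (default: any nonzero marker count)."""
    present = [m for m in markers if m in table.gene_ids]
    if not present:
        raise ValidationError(
            f"no inhibitory marker of {markers} in gene universe"
        )
    idx = table.gene_index(present)
    norm = normalize_log1p(table, scale=scale)[:, idx]
    keep = (norm > min_norm_expr).any(axis=1)
    return table.subset_cells(keep)


def subtype_correlation(
    table: CellTable, scale: float = 10_000.0
) -> pd.DataFrame:
    """Pearson correlation of per-subtype mean normalised expression.

    Subtypes with zero-variance mean vectors get NaN correlations (with a
    warning) rather than an error.
    """
    subtypes = pd.unique(table.annot["subtype"].to_numpy())
    if len(subtypes) < 2:
        raise ValidationError("need at least two subtypes")
    norm = normalize_log1p(table, scale=scale)
    means = np.vstack(
        [
            norm[(table.annot["subtype"] == st).to_numpy()].mean(axis=0)
            for st in subtypes
        ]
    )
    sd = means.std(axis=1)
    corr = np.full((len(subtypes), len(subtypes)), np.nan)
    for i in range(len(subtypes)):
        for j in range(len(subtypes)):
            if sd[i] == 0 or sd[j] == 0:
                if i == j:
                    corr[i, j] = 1.0
                continue
            corr[i, j] = np.corrcoef(means[i], means[j])[0, 1]
    if (sd == 0).any():
        bad = [str(subtypes[i]) for i in np.flatnonzero(sd == 0)]
        logger.warning(
            "zero-variance mean profile for subtype(s) %s; correlations "
            "recorded as missing",
            bad,
        )
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=list(subtypes), columns=list(subtypes))


def run_conservation(
    ref_table: CellTable,
    query_table: CellTable,
    hmap: HomologyMap | None,
    n_subsample: int = 100,
    n_hvg: int = 2000,
    d: int = 30,
    k_anchor: int = 5,
    target_k: int = 31,
    markers: tuple[str, ...] = ("GAD1", "GAD2"),
    seed: int = 0,
    scale: float = 10_000.0,
) -> tuple[OverlapMatrix, Clustering, pd.DataFrame]:
    """End-to-end conservation scoring for one species pair.

    Extract inhibitory neurons, subsample each subtype, map the query to the
    reference gene space, integrate via reciprocal-PCA anchors on shared
    variable genes, cluster the union finely, and score every subtype pair.
    """
    if hmap is not None:
        query_table = map_to_reference(query_table, hmap)
    ref = subsample_subtypes(
        extract_inhibitory(ref_table, markers=markers, scale=scale),
        n=n_subsample,
        seed=seed,
    )
    qry = subsample_subtypes(
        extract_inhibitory(query_table, markers=markers, scale=scale),
        n=n_subsample,
        seed=seed + 1,
    )
    shared = [g for g in ref.gene_ids if g in set(qry.gene_ids)]
    if len(shared) < 10:
        raise ValidationError("fewer than 10 shared genes after mapping")
    ref = ref.subset_genes(shared)
    qry = qry.subset_genes(shared)

    ref_norm = normalize_log1p(ref, scale=scale)
    qry_norm = normalize_log1p(qry, scale=scale)
    n_hvg_eff = min(n_hvg, len(shared))
    hvg_r = select_hvg(ref_norm, n_hvg_eff, gene_ids=shared)
    hvg_q = select_hvg(qry_norm, n_hvg_eff, gene_ids=shared)
    hvg = [g for g in shared if g in (set(hvg_r) | set(hvg_q))]
    g_idx = {g: i for i, g in enumerate(shared)}
    cols = [g_idx[g] for g in hvg]

    emb, _ = anchor_correct(
        scale_columns(ref_norm[:, cols]),
        scale_columns(qry_norm[:, cols]),
        ref.cell_ids,
        qry.cell_ids,
        d=d,
        k_anchor=k_anchor,
    )
    clustering = cluster_cells(emb, target_k=target_k, seed=seed)
    annot = pd.concat([ref.annot, qry.annot])
    mat = conservation_matrix(
        clustering, annot, query_species=qry.species,
        reference_species=ref.species,
    )
    return mat, clustering, annot
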