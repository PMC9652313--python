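"""Pseudocell aggregation and weighted co-expression module detection.

The module core follows the classic weighted-network recipe: soft-threshold
adjacency ``a_ij = |cor(i,j)|**power`` (optionally signed), topological
overlap ``w_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)``,
average-linkage hierarchical clustering of ``1 - w`` with a static cut plus
minimum-size filter, and iterative merging of modules whose eigengenes
(first principal component of the module's standardised profiles) correlate
above ``1 - mergeCutHeight``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .io_core import CellTable, ValidationError
from .preprocess_integrate import ParameterError, normalize_log1p, select_hvg

logger = logging.getLogger("crossneuro")

UNASSIGNED = "unassigned"

# R mad() consistency constant for the normal distribution
MAD_CONSTANT = 1.4826


@dataclass
class PseudocellMatrix:
    """Pseudocells x genes mean-expression matrix with stratum annotations."""

    values: np.ndarray
    gene_ids: list[str]
    subtype: list[str]
    condition: list[str]
    size: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        n, g = self.values.shape
        if g != len(self.gene_ids) or n != len(self.subtype) or n != len(
            self.condition
        ):
            raise ValidationError("pseudocell matrix dimensions inconsistent")


@dataclass
class ModuleAssignment:
    """Gene -> module labels plus module eigengene profiles."""

    labels: dict[str, str]
    eigengenes: pd.DataFrame = field(default_factory=pd.DataFrame)

    def module_genes(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for g, m in self.labels.items():
            if m != UNASSIGNED:
                out.setdefault(m, []).append(g)
        return out


def make_pseudocells(
    table: CellTable,
    size: int = 10,
    seed: int = 0,
    scale: float = 10_000.0,
) -> PseudocellMatrix:
    """Average groups of ``size`` cells within subtype x condition x batch
    strata into pseudocells.

    Within each stratum, cells are shuffled (seeded) and split into
    consecutive groups of ``size``; the remainder group of fewer than
    ``size`` cells is dropped, so a stratum with fewer than ``size`` cells
    contributes nothing.
    """
    if size < 1:
        raise ParameterError("pseudocell size must be >= 1")
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    norm = normalize_log1p(table, scale=scale)
    annot = table.annot
    cond = (
        annot["condition"].fillna("control")
        if "condition" in annot.columns
        else pd.Series("control", index=annot.index)
    )
    strata = pd.DataFrame(
        {
            "subtype": annot["subtype"].to_numpy(),
            "condition": cond.to_numpy(),
            "batch": annot["batch"].to_numpy(),
        }
    )
    rows: list[np.ndarray] = []
    subtype_out: list[str] = []
    cond_out: list[str] = []
    for (st, cd, _b), idx in strata.groupby(
        ["subtype", "condition", "batch"], sort=True
    ).groups.items():
        idx = np.asarray(idx)
        if len(idx) < size:
            logger.info(
                "stratum (%s, %s) with %d cells yields no pseudocell",
                st, cd, len(idx),
            )
            continue
        perm = rng.permutation(idx)
        n_full = len(idx) // size
        for g in range(n_full):
            members = perm[g * size : (g + 1) * size]
            rows.append(norm[members].mean(axis=0))
            subtype_out.append(str(st))
            cond_out.append(str(cd))
    values = np.vstack(rows) if rows else np.empty((0, table.n_genes))
    return PseudocellMatrix(
        values=values,
        gene_ids=list(table.gene_ids),
        subtype=subtype_out,
        condition=cond_out,
        size=size,
    )


def mad_filter(
    pmatrix: PseudocellMatrix | np.ndarray,
    threshold: float = 0.1,
    gene_ids=None,
    scaled: bool = True,
) -> list:
    """Genes whose median absolute deviation reaches ``threshold``.

    ``scaled=True`` multiplies by the 1.4826 normal-consistency constant
    (the R ``mad`` default); ``scaled=False`` is the raw MAD.
    """
    if isinstance(pmatrix, PseudocellMatrix):
        X, gene_ids = pmatrix.values, pmatrix.gene_ids
    else:
        X = np.asarray(pmatrix, float)
        if gene_ids is None:
            gene_ids = list(range(X.shape[1]))
    med = np.median(X, axis=0)
    mad = np.median(np.abs(X - med), axis=0)
    if scaled:
        mad = mad * MAD_CONSTANT
    return [g for g, m in zip(gene_ids, mad) if m >= threshold]


def select_wgcna_genes(
    norm_a: np.ndarray,
    norm_b: np.ndarray,
    genes_a: list,
    genes_b: list,
    n: int = 2000,
) -> list:
    """(top-n variable of A  union  top-n variable of B) intersect shared."""
    shared = set(genes_a) & set(genes_b)
    if not shared:
        raise ValidationError("gene universes of the two groups are disjoint")
    hvg_a = set(select_hvg(norm_a, min(n, len(genes_a)), gene_ids=genes_a))
    hvg_b = set(select_hvg(norm_b, min(n, len(genes_b)), gene_ids=genes_b))
    out = [g for g in genes_a if g in (hvg_a | hvg_b) and g in shared]
    if not out:
        raise ValidationError("no variable gene shared between groups")
    return out


def tom_from_adjacency(adj: np.ndarray) -> np.ndarray:
    """Topological overlap of an adjacency matrix (zero diagonal assumed)."""
    A = np.asarray(adj, float).copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    shared = A @ A
    num = shared + A
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - A
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(denom > 0, num / denom, 0.0)
    np.fill_diagonal(tom, 1.0)
    return tom


def _eigengene(X_std: np.ndarray) -> np.ndarray:
    """First principal component of standardised profiles, sign-aligned to
    the mean profile."""
    Xc = X_std - X_std.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc.T, full_matrices=False)  # genes x cells
    eg = Vt[0]
    ref = X_std.mean(axis=1)
    if np.dot(eg, ref - ref.mean()) < 0:
        eg = -eg
    return eg


def tom_modules(
    pmatrix: PseudocellMatrix | np.ndarray,
    power: float = 6.0,
    min_module_size: int = 10,
    merge_cut_height: float = 0.25,
    gene_ids=None,
    signed: bool = False,
    cut_height: float = 0.99,
) -> ModuleAssignment:
    """Detect co-expression modules via topological overlap.

    Static tree cut at ``cut_height`` on the 1 - TOM average-linkage
    dendrogram, followed by a minimum-size filter and eigengene-based
    merging; genes in clusters below ``min_module_size`` are labelled
    ``unassigned``.  Modules are named ``mod1, mod2, ...`` by decreasing
    size.
    """
    if isinstance(pmatrix, PseudocellMatrix):
        X, gene_ids = pmatrix.values, pmatrix.gene_ids
    else:
        X = np.asarray(pmatrix, float)
        if gene_ids is None:
            gene_ids = [str(i) for i in range(X.shape[1])]
    n_samples, n_genes = X.shape
    if n_genes < min_module_size:
        raise ParameterError(
            f"{n_genes} genes is fewer than min_module_size={min_module_size}"
        )
    sd = X.std(axis=0)
    if (sd == 0).all():
        raise ValidationError("all genes constant; correlations undefined")
    variable = sd > 0
    if (~variable).any():
        logger.warning("%d constant gene(s) left unassigned", int((~variable).sum()))
    Xv = X[:, variable]
    ids_v = [g for g, v in zip(gene_ids, variable) if v]

    corr = np.corrcoef(Xv.T)
    corr = np.nan_to_num(corr, nan=0.0)
    if signed:
        adj = ((1.0 + corr) / 2.0) ** power
    else:
        adj = np.abs(corr) ** power
    np.fill_diagonal(adj, 0.0)
    tom = tom_from_adjacency(adj)
    dist = 1.0 - tom
    np.fill_diagonal(dist, 0.0)
    dist = 0.5 * (dist + dist.T)
    link = sch.linkage(squareform(dist, checks=False), method="average")
    raw = sch.fcluster(link, t=cut_height, criterion="distance")

    labels = {g: UNASSIGNED for g in gene_ids}
    clusters: dict[int, list[int]] = {}
    for i, c in enumerate(raw):
        clusters.setdefault(int(c), []).append(i)
    kept = {
        c: idx for c, idx in clusters.items() if len(idx) >= min_module_size
    }
    if not kept:
        return ModuleAssignment(labels=labels)

    # standardise once for eigengene computation
    mu, sdv = Xv.mean(axis=0), Xv.std(axis=0)
    X_std = (Xv - mu) / np.where(sdv == 0, 1.0, sdv)

    groups: list[list[int]] = sorted(
        kept.values(), key=lambda idx: (-len(idx), idx[0])
    )

    def eig(idx: list[int]) -> np.ndarray:
        return _eigengene(X_std[:, idx])

    # iterative merge of the closest eigengene pair above the threshold
    merged = True
    while merged and len(groups) > 1:
        merged = False
        egs = [eig(g) for g in groups]
        best, best_r = None, 1.0 - merge_cut_height
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                r = float(np.corrcoef(egs[i], egs[j])[0, 1])
                if r >= best_r:
                    best, best_r = (i, j), r
        if best is not None:
            i, j = best
            groups[i] = sorted(groups[i] + groups[j])
            del groups[j]
            merged = True

    groups = sorted(groups, key=lambda idx: (-len(idx), idx[0]))
    eigengenes = {}
    for m, idx in enumerate(groups, start=1):
        name = f"mod{m}"
        for i in idx:
            labels[ids_v[i]] = name
        eigengenes[name] = eig(idx)
    eg_df = pd.DataFrame(eigengenes).T
    eg_df.columns = [f"pc{i}" for i in range(eg_df.shape[1])]
    return ModuleAssignment(labels=labels, eigengenes=eg_df)


def module_celltype_profile(
    assignment: ModuleAssignment,
    pmatrix: PseudocellMatrix,
    by_condition: bool = True,
) -> pd.DataFrame:
    """Mean module expression per cell type (x condition), column z-scored.

    Rows are modules (size-descending), columns cell-type strata; each
    column is scaled to zero mean and unit SD, matching a column-scaled
    heatmap of module average expression.
    """
    mods = assignment.module_genes()
    if not mods:
        raise ValidationError("no assigned module")
    for m, genes in mods.items():
        if not genes:
            raise ValidationError(f"module {m} is empty")
    g_idx = {g: i for i, g in enumerate(pmatrix.gene_ids)}
    if by_condition:
        col_keys = [
            f"{s}|{c}" for s, c in zip(pmatrix.subtype, pmatrix.condition)
        ]
    else:
        col_keys = list(pmatrix.subtype)
    key_arr = np.array(col_keys)
    col_order = list(pd.unique(key_arr))
    mod_order = sorted(mods, key=lambda m: (-len(mods[m]), m))
    raw = np.zeros((len(mod_order), len(col_order)))
    for r, m in enumerate(mod_order):
        cols = [g_idx[g] for g in mods[m] if g in g_idx]
        if not cols:
            raise ValidationError(f"module {m} has no gene in the matrix")
        mod_mean = pmatrix.values[:, cols].mean(axis=1)
        for c, key in enumerate(col_order):
            raw[r, c] = mod_mean[key_arr == key].mean()
    mu = raw.mean(axis=0)
    sd = raw.std(axis=0)
    scaled = (raw - mu) / np.where(sd == 0, 1.0, sd)
    return pd.DataFrame(scaled, index=mod_order, columns=col_order)
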