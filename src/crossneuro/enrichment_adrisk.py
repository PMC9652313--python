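"""Risk-gene enrichment, differential expression and cross-species
comparison of risk-gene expression.

Module-level enrichment uses the upper-tail hypergeometric probability
``P(X >= k)`` with a fixed background universe (default 20,000 genes).
Differential expression between two cell groups uses the two-sided Wilcoxon
rank-sum test on normalised expression with Seurat-style detection-fraction
and log-fold-change pre-filters and Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, linregress, mannwhitneyu, pearsonr
from statsmodels.stats.multitest import multipletests

from .io_core import CellTable, ValidationError
from .preprocess_integrate import ParameterError, normalize_log1p

logger = logging.getLogger("crossneuro")


@dataclass
class EnrichmentRecord:
    module: str
    k: int
    n: int
    M: int
    N: int
    p: float
    stars: str

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.n, self.M)):
            raise ValidationError("overlap count outside [0, min(n, M)]")
        if not (0.0 <= self.p <= 1.0):
            raise ValidationError("p outside [0, 1]")


@dataclass
class DegRecord:
    gene: str
    avg_logFC: float
    pct_in: float
    pct_out: float
    p: float
    p_adj: float


def stars_for(p: float) -> str:
    """Significance tier: 0.01-0.05 '*', 0.001-0.01 '**', below 0.001 '***'."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def hypergeom_upper_tail(M: int, n: int, N: int = 20_000) -> np.ndarray:
    """Upper-tail probabilities P(X >= k) for every k in 0..min(M, n).

    X ~ Hypergeometric(N, M, n); entry ``k`` of the returned array equals
    R's ``1 - phyper(k - 1, M, N - M, n)``.  The tail is accumulated in log
    space (suffix logsumexp over the pmf) for numerical stability.
    """
    M, n, N = int(M), int(n), int(N)
    if not (0 <= M <= N and 0 <= n <= N):
        raise ParameterError(f"invalid sizes M={M}, n={n}, N={N}")
    kmax = min(M, n)
    support = np.arange(0, kmax + 1)
    logp = hypergeom.logpmf(support, N, M, n)
    # suffix logsumexp: log P(X >= k)
    tail = np.empty(kmax + 1)
    running = -np.inf
    for k in range(kmax, -1, -1):
        running = np.logaddexp(running, logp[k])
        tail[k] = running
    out = np.minimum(1.0, np.exp(tail))
    out[0] = 1.0
    return out


def hypergeom_upper(k: int, M: int, n: int, N: int = 20_000) -> float:
    """Upper-tail probability P(X >= k), X ~ Hypergeometric(N, M, n).

    Equivalent to R's ``1 - phyper(k - 1, M, N - M, n)``.
    """
    k = int(k)
    if not (0 <= k <= min(int(M), int(n))):
        raise ParameterError(f"k={k} outside [0, min(M, n)={min(M, n)}]")
    return float(hypergeom_upper_tail(M, n, N)[k])


def module_risk_enrichment(
    modules: dict[str, list[str]],
    risk_genes: set[str] | list[str],
    background: int = 20_000,
) -> list[EnrichmentRecord]:
    """Hypergeometric over-representation of risk genes in each module."""
    risk = set(risk_genes)
    if not risk:
        raise ValidationError("empty risk gene set")
    records = []
    for name, genes in modules.items():
        gset = set(genes)
        k = len(gset & risk)
        p = hypergeom_upper(k, M=len(risk), n=len(gset), N=background)
        records.append(
            EnrichmentRecord(
                module=name, k=k, n=len(gset), M=len(risk), N=background,
                p=p, stars=stars_for(p) if k > 0 else "",
            )
        )
    return records


def _avg_logfc(norm_in: np.ndarray, norm_out: np.ndarray) -> np.ndarray:
    """Natural-log fold change of mean de-logged expression, pseudocount 1."""
    mean_in = np.expm1(norm_in).mean(axis=0)
    mean_out = np.expm1(norm_out).mean(axis=0)
    return np.log(mean_in + 1.0) - np.log(mean_out + 1.0)


def deg_wilcoxon(
    table: CellTable,
    group_by: str,
    group_in: str,
    group_out: str | None = None,
    min_pct: float = 0.25,
    logfc_threshold: float = 0.25,
    scale: float = 10_000.0,
    cell_mask: np.ndarray | None = None,
) -> list[DegRecord]:
    """Wilcoxon rank-sum DE of ``group_in`` vs ``group_out`` cells.

    Genes must be detected in at least ``min_pct`` of either group and show
    ``|avg_logFC| >= logfc_threshold`` to be tested; p-values are BH-adjusted
    over the tested genes only.
    """
    annot = table.annot
    labels = annot[group_by].astype(str).to_numpy()
    base = np.ones(table.n_cells, dtype=bool) if cell_mask is None else cell_mask
    in_mask = base & (labels == group_in)
    out_mask = base & (
        (labels != group_in) if group_out is None else (labels == group_out)
    )
    if in_mask.sum() < 3 or out_mask.sum() < 3:
        raise ValidationError(
            f"need >= 3 cells per group; got {int(in_mask.sum())} vs "
            f"{int(out_mask.sum())}"
        )
    norm = normalize_log1p(table, scale=scale)
    x_in, x_out = norm[in_mask], norm[out_mask]
    pct_in = (x_in > 0).mean(axis=0)
    pct_out = (x_out > 0).mean(axis=0)
    lfc = _avg_logfc(x_in, x_out)
    tested = (np.maximum(pct_in, pct_out) >= min_pct) & (
        np.abs(lfc) >= logfc_threshold
    )
    idx = np.flatnonzero(tested)
    if idx.size == 0:
        return []
    pvals = np.empty(idx.size)
    for j, g in enumerate(idx):
        a, b = x_in[:, g], x_out[:, g]
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            pvals[j] = 1.0
            continue
        pvals[j] = mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic"
        ).pvalue
    p_adj = multipletests(pvals, method="fdr_bh")[1]
    records = [
        DegRecord(
            gene=table.gene_ids[g],
            avg_logFC=float(lfc[g]),
            pct_in=float(pct_in[g]),
            pct_out=float(pct_out[g]),
            p=float(pvals[j]),
            p_adj=float(p_adj[j]),
        )
        for j, g in enumerate(idx)
    ]
    records.sort(key=lambda r: (r.p, r.gene))
    return records


def high_confidence_risk_genes(
    degs_per_celltype: dict[str, list[DegRecord]],
    risk_genes: set[str] | list[str],
    module_genes: set[str] | list[str],
) -> dict[str, list[str]]:
    """Per cell type: DEG intersect risk set intersect module genes."""
    risk = set(risk_genes)
    module = set(module_genes)
    out: dict[str, list[str]] = {}
    for ct, degs in degs_per_celltype.items():
        de = {d.gene for d in degs}
        out[ct] = sorted(de & risk & module)
    return out


def crossspecies_gene_correlation(
    ref_table: CellTable,
    other_table: CellTable,
    genes: list[str],
    scale: float = 10_000.0,
) -> pd.DataFrame:
    """Per shared cell type: Pearson r and least-squares line between the two
    species' mean expression of ``genes``.

    Genes absent from either table (not homology-mapped) are excluded.
    """
    shared_genes = [
        g for g in genes
        if g in set(ref_table.gene_ids) and g in set(other_table.gene_ids)
    ]
    if len(shared_genes) < 3:
        raise ValidationError("fewer than 3 shared genes")
    ref_sub = set(ref_table.annot["subtype"])
    oth_sub = set(other_table.annot["subtype"])
    shared_ct = [
        st for st in pd.unique(ref_table.annot["subtype"].to_numpy())
        if st in oth_sub
    ]
    if not shared_ct:
        raise ValidationError("no shared cell type")
    norm_r = normalize_log1p(ref_table, scale=scale)[
        :, ref_table.gene_index(shared_genes)
    ]
    norm_o = normalize_log1p(other_table, scale=scale)[
        :, other_table.gene_index(shared_genes)
    ]
    rows = []
    for st in shared_ct:
        vr = norm_r[(ref_table.annot["subtype"] == st).to_numpy()].mean(axis=0)
        vo = norm_o[(other_table.annot["subtype"] == st).to_numpy()].mean(
            axis=0
        )
        if vr.std() == 0 or vo.std() == 0:
            r, slope, intercept = np.nan, np.nan, np.nan
        else:
            r = pearsonr(vr, vo).statistic
            fit = linregress(vr, vo)
            slope, intercept = fit.slope, fit.intercept
        rows.append(
            {
                "celltype": st,
                "n_genes": len(shared_genes),
                "pearson_r": float(r),
                "slope": float(slope),
                "intercept": float(intercept),
            }
        )
    return pd.DataFrame(rows)


def crossspecies_deg_flags(
    ref_table: CellTable,
    other_table: CellTable,
    genes: list[str],
    min_pct: float = 0.25,
    logfc_threshold: float = 0.25,
    scale: float = 10_000.0,
    p_cut: float = 0.05,
    lfc_cut: float = 1.0,
) -> pd.DataFrame:
    """Per gene x cell type: reference-vs-other Wilcoxon DE with a star when
    adjusted p < ``p_cut`` and |avg_logFC| > ``lfc_cut``."""
    shared_genes = [
        g for g in genes
        if g in set(ref_table.gene_ids) and g in set(other_table.gene_ids)
    ]
    if not shared_genes:
        raise ValidationError("no shared gene")
    shared_ct = [
        st for st in pd.unique(ref_table.annot["subtype"].to_numpy())
        if st in set(other_table.annot["subtype"])
    ]
    norm_r = normalize_log1p(ref_table, scale=scale)[
        :, ref_table.gene_index(shared_genes)
    ]
    norm_o = normalize_log1p(other_table, scale=scale)[
        :, other_table.gene_index(shared_genes)
    ]
    rows = []
    for st in shared_ct:
        a = norm_r[(ref_table.annot["subtype"] == st).to_numpy()]
        b = norm_o[(other_table.annot["subtype"] == st).to_numpy()]
        if len(a) < 3 or len(b) < 3:
            raise ValidationError(f"cell type {st!r} has < 3 cells in a species")
        lfc = _avg_logfc(a, b)
        pct_a = (a > 0).mean(axis=0)
        pct_b = (b > 0).mean(axis=0)
        pvals = np.ones(len(shared_genes))
        tested = np.maximum(pct_a, pct_b) >= min_pct
        tested &= np.abs(lfc) >= logfc_threshold
        for j in np.flatnonzero(tested):
            if np.all(a[:, j] == b[0, j]) and np.all(b[:, j] == b[0, j]):
                continue
            pvals[j] = mannwhitneyu(
                a[:, j], b[:, j], alternative="two-sided", method="asymptotic"
            ).pvalue
        p_adj = np.ones(len(shared_genes))
        if tested.any():
            p_adj[tested] = multipletests(pvals[tested], method="fdr_bh")[1]
        for j, g in enumerate(shared_genes):
            starred = bool(
                tested[j] and p_adj[j] < p_cut and abs(lfc[j]) > lfc_cut
            )
            rows.append(
                {
                    "gene": g,
                    "celltype": st,
                    "avg_logFC": float(lfc[j]),
                    "p": float(pvals[j]) if tested[j] else np.nan,
                    "p_adj": float(p_adj[j]) if tested[j] else np.nan,
                    "star": "*" if starred else "",
                }
            )
    return pd.DataFrame(rows)
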