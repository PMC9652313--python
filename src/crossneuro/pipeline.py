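"""End-to-end orchestration of the synthetic cross-species analysis.

Each stage function reads its inputs from a run directory, writes its
outputs back as TSVs, and is deterministic given the run config and seed.
The stage layout mirrors the CLI subcommands::

    run/
      inputs/<species>/            MTX bundles
      inputs/homology_<sp>.tsv     one-to-one maps
      inputs/regulons.gmt          planted regulons
      inputs/risk.gmt              planted risk genes
      inputs/truth_*               planted ground truth
      integrate/  conserve/  metaneighbor/  modules/  enrich/  regulons/
      report/manifest.json
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import conservation as cons
from . import coexpression as coex
from . import enrichment_adrisk as enrich
from . import metaneighbor as mn
from . import regulons as reg
from . import synthetic_data as synth
from .io_core import (
    CellTable,
    GeneSet,
    RunConfig,
    export_regulon_network,
    map_to_reference,
    read_bundle,
    read_gmt,
    read_homology_tsv,
    write_cell_table,
    write_gmt,
    write_homology_tsv,
)
from .preprocess_integrate import cluster_cells

logger = logging.getLogger("crossneuro")

STAGES = (
    "simulate",
    "integrate",
    "conserve",
    "metaneighbor",
    "modules",
    "enrich",
    "regulons",
    "report",
)


def _float_fmt(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def _species_dirs(run_dir: Path) -> list[Path]:
    return sorted(
        p for p in (run_dir / "inputs").iterdir()
        if p.is_dir() and (p / "matrix.mtx").exists()
    )


def _load_tables(run_dir: Path) -> dict[str, CellTable]:
    tables = {}
    for d in _species_dirs(run_dir):
        t = read_bundle(d)
        tables[t.species] = t
    return tables


def _reference_species(run_dir: Path) -> str:
    return (run_dir / "inputs" / "reference.txt").read_text().strip()


def stage_simulate(
    design: synth.SimDesign, config: RunConfig, run_dir: str | Path
) -> None:
    run_dir = Path(run_dir)
    inputs = run_dir / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)
    tables, hmaps, truth = synth.simulate(design)
    for sp, table in tables.items():
        write_cell_table(table, inputs / sp)
    for sp, hmap in hmaps.items():
        write_homology_tsv(hmap, inputs / f"homology_{sp}.tsv")
    if truth.regulon_targets:
        write_gmt(synth.regulon_gene_sets(truth), inputs / "regulons.gmt")
    if truth.risk_genes:
        write_gmt([synth.risk_gene_set(truth)], inputs / "risk.gmt")
    synth.write_truth(truth, inputs)
    (inputs / "reference.txt").write_text(design.reference + "\n")
    config.to_yaml(run_dir / "config_used.yaml")


def _mapped_query_tables(
    run_dir: Path, tables: dict[str, CellTable], ref_sp: str
) -> dict[str, CellTable]:
    mapped = {}
    for sp, t in tables.items():
        if sp == ref_sp:
            continue
        hmap_path = run_dir / "inputs" / f"homology_{sp}.tsv"
        if hmap_path.exists():
            mapped[sp] = map_to_reference(t, read_homology_tsv(hmap_path, sp))
        else:
            mapped[sp] = t
    return mapped


def stage_integrate_conserve(
    config: RunConfig, run_dir: str | Path
) -> dict[str, pd.DataFrame]:
    """Cross-species integration + clustering + conservation per pair.

    Writes the joint embedding cluster labels and the overlap matrix for
    each (query species, reference) pair, plus the within-reference subtype
    correlation matrix.
    """
    run_dir = Path(run_dir)
    tables = _load_tables(run_dir)
    ref_sp = _reference_species(run_dir)
    ref = tables[ref_sp]
    out_i = run_dir / "integrate"
    out_c = run_dir / "conserve"
    out_i.mkdir(exist_ok=True)
    out_c.mkdir(exist_ok=True)
    overlaps = {}
    for sp in sorted(tables):
        if sp == ref_sp:
            continue
        hmap_path = run_dir / "inputs" / f"homology_{sp}.tsv"
        hmap = read_homology_tsv(hmap_path, sp) if hmap_path.exists() else None
        mat, clustering, annot = cons.run_conservation(
            ref,
            tables[sp],
            hmap,
            n_subsample=config.subsample_per_subtype,
            n_hvg=config.n_hvg_inhibitory,
            d=config.n_pcs_integrated,
            k_anchor=config.k_anchor,
            target_k=config.target_clusters,
            markers=tuple(config.inhibitory_markers),
            seed=config.seed,
            scale=config.scale_factor,
        )
        lab = pd.DataFrame(
            {
                "cell_id": annot.index,
                "species": annot["species"].to_numpy(),
                "subtype": annot["subtype"].to_numpy(),
                "cluster": clustering.labels,
            }
        )
        lab.to_csv(out_i / f"clusters_{sp}.tsv", sep="\t", index=False)
        _float_fmt(mat.values, out_c / f"overlap_{sp}_vs_{ref_sp}.tsv")
        overlaps[sp] = mat.values
    corr = cons.subtype_correlation(ref, scale=config.scale_factor)
    _float_fmt(corr, out_c / f"subtype_correlation_{ref_sp}.tsv")
    return overlaps


def stage_metaneighbor(
    config: RunConfig, run_dir: str | Path, gene_sets: list[GeneSet] | None = None
) -> pd.DataFrame:
    """Neighbour-voting AUROC of each gene set on the reference species.

    By default evaluates the planted subtype marker blocks (pooled into one
    set) and each planted regulon target set, mirroring a gene-family scan.
    """
    run_dir = Path(run_dir)
    tables = _load_tables(run_dir)
    ref_sp = _reference_species(run_dir)
    table = tables[ref_sp]
    if gene_sets is None:
        truth = synth.read_truth(run_dir / "inputs")
        marker_pool = set().union(*truth.marker_genes.values())
        gene_sets = [GeneSet(name="planted_markers", genes=marker_pool)]
        gene_sets += [
            GeneSet(name=name, genes=set(g))
            for name, g in sorted(truth.regulon_targets.items())
        ]
    rows = []
    for i, gs in enumerate(gene_sets):
        mean, sd = mn.run_supervised(
            table,
            gs,
            n_cells=config.mn_cells_per_cluster,
            n_iter=config.mn_iterations,
            seed=config.seed + i,
            scale=config.scale_factor,
        )
        rows.append({"gene_set": gs.name, "mean_auroc": mean, "sd_auroc": sd})
    df = pd.DataFrame(rows)
    out = run_dir / "metaneighbor"
    out.mkdir(exist_ok=True)
    _float_fmt(df, out / "auroc.tsv", index=False)
    return df


def stage_modules(
    config: RunConfig, run_dir: str | Path
) -> tuple[coex.ModuleAssignment, coex.PseudocellMatrix]:
    """Pseudocell aggregation + co-expression modules on the reference
    species (disease vs control design)."""
    run_dir = Path(run_dir)
    tables = _load_tables(run_dir)
    ref_sp = _reference_species(run_dir)
    table = tables[ref_sp]
    pm = coex.make_pseudocells(
        table, size=config.pseudocell_size, seed=config.seed,
        scale=config.scale_factor,
    )
    cond = np.array(pm.condition)
    genes = coex.mad_filter(
        pm, threshold=config.mad_threshold, scaled=config.mad_scaled
    )
    if {"control", "disease"} <= set(cond):
        a = pm.values[cond == "control"]
        b = pm.values[cond == "disease"]
        sel = coex.select_wgcna_genes(
            a, b, pm.gene_ids, pm.gene_ids, n=config.wgcna_n_var
        )
        genes = [g for g in genes if g in set(sel)]
    g_idx = {g: i for i, g in enumerate(pm.gene_ids)}
    sub = pm.values[:, [g_idx[g] for g in genes]]
    assignment = coex.tom_modules(
        sub,
        power=config.tom_power,
        min_module_size=config.min_module_size,
        merge_cut_height=config.merge_cut_height,
        gene_ids=genes,
        signed=config.tom_signed,
    )
    out = run_dir / "modules"
    out.mkdir(exist_ok=True)
    lab_df = pd.DataFrame(
        sorted(assignment.labels.items()), columns=["gene", "module"]
    )
    lab_df.to_csv(out / "gene_modules.tsv", sep="\t", index=False)
    if not assignment.eigengenes.empty:
        _float_fmt(assignment.eigengenes, out / "eigengenes.tsv")
    profile = coex.module_celltype_profile(assignment, pm)
    _float_fmt(profile, out / "module_profile.tsv")
    return assignment, pm


def stage_enrich(
    config: RunConfig, run_dir: str | Path
) -> dict[str, object]:
    """Risk enrichment of modules, disease DEGs per cell type,
    high-confidence risk genes and cross-species correlation."""
    run_dir = Path(run_dir)
    tables = _load_tables(run_dir)
    ref_sp = _reference_species(run_dir)
    table = tables[ref_sp]
    risk = read_gmt(run_dir / "inputs" / "risk.gmt")[0].genes
    mod_df = pd.read_csv(
        run_dir / "modules" / "gene_modules.tsv", sep="\t"
    )
    modules = {
        m: sorted(g["gene"])
        for m, g in mod_df.groupby("module")
        if m != coex.UNASSIGNED
    }
    records = enrich.module_risk_enrichment(
        modules, risk, background=config.background_size
    )
    out = run_dir / "enrich"
    out.mkdir(exist_ok=True)
    enr_df = pd.DataFrame(
        [dataclasses.asdict(r) for r in records]
    ).sort_values("p", kind="stable")
    _float_fmt(enr_df, out / "module_enrichment.tsv", index=False)

    # disease-vs-control DEGs within each subtype
    best_module = enr_df.iloc[0]["module"] if len(enr_df) else None
    degs_per_ct: dict[str, list[enrich.DegRecord]] = {}
    subtypes = pd.unique(table.annot["subtype"].to_numpy())
    cond = table.annot.get("condition")
    if cond is not None and {"control", "disease"} <= set(cond.dropna()):
        for st in subtypes:
            mask = (table.annot["subtype"] == st).to_numpy()
            try:
                degs = enrich.deg_wilcoxon(
                    table,
                    group_by="condition",
                    group_in="disease",
                    group_out="control",
                    min_pct=config.min_pct,
                    logfc_threshold=config.logfc_threshold,
                    scale=config.scale_factor,
                    cell_mask=mask,
                )
            except Exception as exc:  # subtype too small
                logger.warning("DEG for %s skipped: %s", st, exc)
                continue
            degs_per_ct[st] = [d for d in degs if d.p_adj < 0.05]
            pd.DataFrame(
                [dataclasses.asdict(d) for d in degs]
            ).to_csv(out / f"deg_{st}.tsv", sep="\t", index=False)
    hi_conf = {}
    if best_module is not None and degs_per_ct:
        hi_conf = enrich.high_confidence_risk_genes(
            degs_per_ct, risk, modules[best_module]
        )
        rows = [
            {"celltype": ct, "n_genes": len(g), "genes": ",".join(g)}
            for ct, g in hi_conf.items()
        ]
        pd.DataFrame(rows).to_csv(
            out / "high_confidence_risk_genes.tsv", sep="\t", index=False
        )
    # cross-species correlation of risk-module genes
    corr_frames = []
    gene_list = sorted(risk)
    for sp, qt in sorted(_mapped_query_tables(run_dir, tables, ref_sp).items()):
        df = enrich.crossspecies_gene_correlation(
            table, qt, gene_list, scale=config.scale_factor
        )
        df.insert(0, "species", sp)
        corr_frames.append(df)
    if corr_frames:
        _float_fmt(
            pd.concat(corr_frames, ignore_index=True),
            out / "crossspecies_correlation.tsv",
            index=False,
        )
    return {
        "enrichment": records,
        "degs": degs_per_ct,
        "high_confidence": hi_conf,
    }


def stage_regulons(
    config: RunConfig, run_dir: str | Path
) -> tuple[reg.ActivityMatrix, reg.ActivationProfile, pd.Series]:
    """Regulon scoring on the homolog-mapped union of species, activation
    fractions per species-qualified subtype, and k-means grouping."""
    run_dir = Path(run_dir)
    tables = _load_tables(run_dir)
    ref_sp = _reference_species(run_dir)
    regulon_sets = read_gmt(run_dir / "inputs" / "regulons.gmt", regulons=True)
    mapped = _mapped_query_tables(run_dir, tables, ref_sp)
    mapped[ref_sp] = tables[ref_sp]
    # score on the shared homologous gene space so ranks are comparable,
    # then binarise each regulon once over the merged score vector
    shared = set(mapped[ref_sp].gene_ids)
    for t in mapped.values():
        shared &= set(t.gene_ids)
    shared_genes = [g for g in mapped[ref_sp].gene_ids if g in shared]

    out = run_dir / "regulons"
    out.mkdir(exist_ok=True)
    score_frames = []
    subtype_cols = []
    for sp in sorted(mapped):
        t = mapped[sp].subset_genes(shared_genes)
        scores = reg.score_regulons_raw(
            t, regulon_sets, top_fraction=config.auc_top_fraction
        )
        score_frames.append(scores)
        subtype_cols.extend(
            f"{sp}:{st}" for st in t.annot["subtype"].to_numpy()
        )
        _float_fmt(scores, out / f"activity_{sp}.tsv")
    all_scores = pd.concat(score_frames, axis=0)
    thresholds = pd.Series(
        {
            name: reg.binarize_bimodal(
                all_scores[name].to_numpy(), seed=config.seed + i
            )
            for i, name in enumerate(all_scores.columns)
        }
    )
    binarized = (all_scores >= thresholds).astype(int)
    binarized.to_csv(out / "binarized.tsv", sep="\t")
    active = reg.filter_active(binarized)
    binarized = binarized[active]
    profile = reg.activation_profile(binarized, subtype_cols)
    _float_fmt(profile.fractions, out / "activation_profile.tsv")
    k = min(config.n_regulon_groups, len(profile.fractions))
    groups = reg.group_regulons(profile, k=k, seed=config.seed)
    groups.to_frame().to_csv(out / "groups.tsv", sep="\t")
    export_regulon_network(
        [r for r in regulon_sets if r.name in set(active)],
        out / "network_edges.tsv",
        out / "network_nodes.tsv",
    )
    return None, profile, groups


def run_pipeline(
    design: synth.SimDesign, config: RunConfig, run_dir: str | Path
) -> None:
    """Run every stage in order on a fresh run directory."""
    from .report import build_report

    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    stage_simulate(design, config, run_dir)
    stage_integrate_conserve(config, run_dir)
    stage_metaneighbor(config, run_dir)
    stage_modules(config, run_dir)
    stage_enrich(config, run_dir)
    stage_regulons(config, run_dir)
    build_report(run_dir)
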