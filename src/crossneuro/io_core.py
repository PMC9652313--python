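"""Core data containers and on-disk formats.

The pipeline exchanges four kinds of objects: count tables with per-cell
annotations (:class:`CellTable`), one-to-one orthology maps
(:class:`HomologyMap`), named gene sets / regulons (:class:`GeneSet`), and the
run configuration (:class:`RunConfig`).  On disk a count table is a Matrix
Market bundle (``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv`` +
``annotations.tsv``); gene sets travel as GMT and homology maps as two-column
TSV.  All randomness in the pipeline flows from ``RunConfig.seed`` through
:func:`stage_rng`.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

logger = logging.getLogger("crossneuro")

ANNOT_COLUMNS = ("cell_id", "species", "batch", "subtype", "condition")
CONDITIONS = ("control", "disease")


class FormatError(ValueError):
    """Malformed on-disk input (wrong shape, bad line, missing column)."""


class ValidationError(ValueError):
    """In-memory object violates a container invariant."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class CellTable:
    """Cells x genes count matrix with per-cell annotations.

    ``counts`` is a dense non-negative integer array of shape
    ``(n_cells, n_genes)``; ``annot`` is indexed by ``cell_ids`` and carries
    ``species``, ``batch``, ``subtype`` and an optional ``condition`` column
    restricted to {control, disease}.
    """

    counts: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    annot: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.validate()

    def validate(self) -> None:
        n_cells, n_genes = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise FormatError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix columns"
            )
        if len(self.cell_ids) != n_cells:
            raise FormatError(
                f"{len(self.cell_ids)} cell ids for {n_cells} matrix rows"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise ValidationError("duplicate gene ids")
        if len(set(self.cell_ids)) != n_cells:
            raise ValidationError("duplicate cell ids")
        if self.counts.size and self.counts.min() < 0:
            raise ValidationError("negative count entries")
        if list(self.annot.index) != self.cell_ids:
            raise ValidationError("annotation index does not match cell ids")
        for col in ("species", "batch", "subtype"):
            if col not in self.annot.columns:
                raise ValidationError(f"annotation missing column {col!r}")
        if "condition" in self.annot.columns:
            vals = self.annot["condition"].dropna()
            bad = set(vals) - set(CONDITIONS)
            if bad:
                raise ValidationError(f"invalid condition values: {sorted(bad)}")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def species(self) -> str:
        uniq = self.annot["species"].unique()
        if len(uniq) != 1:
            raise ValidationError(f"table spans several species: {sorted(uniq)}")
        return str(uniq[0])

    def gene_index(self, genes: Iterable[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"genes absent from table: {missing[:5]}")
        return np.array([lookup[g] for g in genes], dtype=int)

    def subset_cells(self, mask_or_idx) -> "CellTable":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CellTable(
            counts=self.counts[idx],
            gene_ids=list(self.gene_ids),
            cell_ids=[self.cell_ids[i] for i in idx],
            annot=self.annot.iloc[idx].copy(),
        )

    def subset_genes(self, genes: Sequence[str]) -> "CellTable":
        idx = self.gene_index(genes)
        return CellTable(
            counts=self.counts[:, idx],
            gene_ids=list(genes),
            cell_ids=list(self.cell_ids),
            annot=self.annot.copy(),
        )

    def equals(self, other: "CellTable") -> bool:
        return (
            self.gene_ids == other.gene_ids
            and self.cell_ids == other.cell_ids
            and np.array_equal(self.counts, other.counts)
            and self.annot.reindex(columns=other.annot.columns).fillna("").astype(str).equals(
                other.annot.fillna("").astype(str)
            )
        )


@dataclass
class HomologyMap:
    """Strict one-to-one gene correspondence from one species to a reference.

    Construction from a raw (possibly many-to-many) pair list must go through
    :meth:`from_pairs`, which drops every ambiguous pair on either side rather
    than electing a winner.
    """

    pairs: list[tuple[str, str]]
    source_species: str

    def __post_init__(self) -> None:
        src = [a for a, _ in self.pairs]
        ref = [b for _, b in self.pairs]
        if len(set(src)) != len(src) or len(set(ref)) != len(ref):
            raise ValidationError("homology map is not one-to-one")

    @classmethod
    def from_pairs(
        cls, raw_pairs: Iterable[tuple[str, str]], source_species: str
    ) -> "HomologyMap":
        raw = [(str(a), str(b)) for a, b in raw_pairs]
        src_count: dict[str, int] = {}
        ref_count: dict[str, int] = {}
        seen = set()
        uniq = []
        for p in raw:
            if p in seen:  # exact duplicates collapse
                continue
            seen.add(p)
            uniq.append(p)
            src_count[p[0]] = src_count.get(p[0], 0) + 1
            ref_count[p[1]] = ref_count.get(p[1], 0) + 1
        kept = [
            p for p in uniq if src_count[p[0]] == 1 and ref_count[p[1]] == 1
        ]
        dropped = len(uniq) - len(kept)
        if dropped:
            logger.info(
                "homology map %s: dropped %d ambiguous pair(s)",
                source_species,
                dropped,
            )
        return cls(pairs=kept, source_species=source_species)

    def as_dict(self) -> dict[str, str]:
        return dict(self.pairs)


@dataclass
class GeneSet:
    """Named gene set; when ``tf`` is set the set is a regulon of that TF."""

    name: str
    genes: set[str]
    tf: str | None = None

    def __post_init__(self) -> None:
        self.genes = {str(g) for g in self.genes}
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")


_CONFIG_DEFAULTS = dict(
    seed=0,
    # normalization / integration
    scale_factor=10_000.0,
    n_hvg=3000,
    n_hvg_inhibitory=2000,
    n_pcs=50,
    n_pcs_integrated=30,
    k_anchor=5,
    target_clusters=31,
    # conservation
    subsample_per_subtype=100,
    inhibitory_markers=("GAD1", "GAD2"),
    min_marker_expr=0.0,
    # metaneighbor
    mn_cells_per_cluster=20,
    mn_iterations=10,
    # coexpression
    pseudocell_size=10,
    mad_threshold=0.1,
    mad_scaled=True,
    wgcna_n_var=2000,
    tom_power=6.0,
    min_module_size=10,
    merge_cut_height=0.25,
    tom_signed=False,
    # enrichment
    background_size=20_000,
    min_pct=0.25,
    logfc_threshold=0.25,
    # regulons
    auc_top_fraction=0.05,
    n_regulon_groups=8,
)

_CONFIG_RANGES = {
    "scale_factor": (0.0, np.inf),
    "n_hvg": (1, np.inf),
    "n_hvg_inhibitory": (1, np.inf),
    "n_pcs": (1, np.inf),
    "n_pcs_integrated": (1, np.inf),
    "k_anchor": (1, np.inf),
    "target_clusters": (1, np.inf),
    "subsample_per_subtype": (1, np.inf),
    "mn_cells_per_cluster": (1, np.inf),
    "mn_iterations": (1, np.inf),
    "pseudocell_size": (1, np.inf),
    "mad_threshold": (0.0, np.inf),
    "wgcna_n_var": (1, np.inf),
    "tom_power": (0.0, np.inf),
    "min_module_size": (1, np.inf),
    "merge_cut_height": (0.0, 1.0),
    "background_size": (1, np.inf),
    "min_pct": (0.0, 1.0),
    "logfc_threshold": (0.0, np.inf),
    "auc_top_fraction": (0.0, 1.0),
    "n_regulon_groups": (1, np.inf),
}


@dataclass
class RunConfig:
    """All stage parameters; defaults are the published settings.

    Scale factor 10,000; 3000 variable genes within species and 2000 for the
    inhibitory-neuron integration; 50 within-species and 30 integrated PCs;
    100 cells subsampled per subtype; 20 cells per cluster over 10 iterations
    of neighbor voting; pseudocells of 10 cells; MAD filter at 0.1 (R-style
    scaled MAD); soft-threshold power 6, minimum module size 10, merge cut
    height 0.25; hypergeometric background 20,000; min.pct and log-FC filters
    at 0.25; eight regulon groups.
    """

    seed: int = _CONFIG_DEFAULTS["seed"]
    scale_factor: float = _CONFIG_DEFAULTS["scale_factor"]
    n_hvg: int = _CONFIG_DEFAULTS["n_hvg"]
    n_hvg_inhibitory: int = _CONFIG_DEFAULTS["n_hvg_inhibitory"]
    n_pcs: int = _CONFIG_DEFAULTS["n_pcs"]
    n_pcs_integrated: int = _CONFIG_DEFAULTS["n_pcs_integrated"]
    k_anchor: int = _CONFIG_DEFAULTS["k_anchor"]
    target_clusters: int = _CONFIG_DEFAULTS["target_clusters"]
    subsample_per_subtype: int = _CONFIG_DEFAULTS["subsample_per_subtype"]
    inhibitory_markers: tuple[str, ...] = _CONFIG_DEFAULTS["inhibitory_markers"]
    min_marker_expr: float = _CONFIG_DEFAULTS["min_marker_expr"]
    mn_cells_per_cluster: int = _CONFIG_DEFAULTS["mn_cells_per_cluster"]
    mn_iterations: int = _CONFIG_DEFAULTS["mn_iterations"]
    pseudocell_size: int = _CONFIG_DEFAULTS["pseudocell_size"]
    mad_threshold: float = _CONFIG_DEFAULTS["mad_threshold"]
    mad_scaled: bool = _CONFIG_DEFAULTS["mad_scaled"]
    wgcna_n_var: int = _CONFIG_DEFAULTS["wgcna_n_var"]
    tom_power: float = _CONFIG_DEFAULTS["tom_power"]
    min_module_size: int = _CONFIG_DEFAULTS["min_module_size"]
    merge_cut_height: float = _CONFIG_DEFAULTS["merge_cut_height"]
    tom_signed: bool = _CONFIG_DEFAULTS["tom_signed"]
    background_size: int = _CONFIG_DEFAULTS["background_size"]
    min_pct: float = _CONFIG_DEFAULTS["min_pct"]
    logfc_threshold: float = _CONFIG_DEFAULTS["logfc_threshold"]
    auc_top_fraction: float = _CONFIG_DEFAULTS["auc_top_fraction"]
    n_regulon_groups: int = _CONFIG_DEFAULTS["n_regulon_groups"]

    def __post_init__(self) -> None:
        for name, (lo, hi) in _CONFIG_RANGES.items():
            val = getattr(self, name)
            if not (lo <= float(val) <= hi):
                raise ValidationError(
                    f"config parameter {name}={val} outside [{lo}, {hi}]"
                )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        if "inhibitory_markers" in raw:
            raw["inhibitory_markers"] = tuple(raw["inhibitory_markers"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["inhibitory_markers"] = list(d["inhibitory_markers"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Derive an independent generator for a named pipeline stage.

    Uses a ``SeedSequence`` spawned from the run seed plus a stable hash of
    the stage name, so stages are decorrelated but each is reproducible in
    isolation.  The derived key is logged for provenance.
    """
    key = np.frombuffer(stage.encode("utf8"), dtype=np.uint8)
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *key.tolist()])
    logger.debug("stage %s uses derived entropy %s", stage, ss.entropy)
    return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# MTX bundle I/O
# ---------------------------------------------------------------------------

def read_cell_table(
    matrix_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
    annot_path: str | Path | None = None,
) -> CellTable:
    """Read a Matrix Market bundle into a :class:`CellTable`.

    The on-disk matrix may be genes x cells (10x convention) or
    cells x genes; orientation is resolved against the sidecar lengths.  A
    square matrix is ambiguous and is only accepted when a ``rows=genes`` /
    ``rows=cells`` comment (which our writer emits) states the orientation.
    """
    mat = scipy.io.mmread(str(matrix_path))
    mat = scipy.sparse.coo_matrix(mat)
    genes = _read_id_column(genes_path)
    cells = _read_id_column(cells_path)
    n_r, n_c = mat.shape
    if n_r == n_c == len(genes) == len(cells):
        orient = _mtx_orientation_comment(matrix_path)
        if orient is None:
            raise FormatError(
                "square matrix is ambiguous: add a 'rows=genes' or "
                "'rows=cells' comment or distinct sidecar lengths"
            )
        dense = np.asarray(
            (mat.T if orient == "genes" else mat).todense()
        )
    elif (n_r, n_c) == (len(cells), len(genes)):
        dense = np.asarray(mat.todense())
    elif (n_r, n_c) == (len(genes), len(cells)):
        dense = np.asarray(mat.T.todense())
    else:
        raise FormatError(
            f"matrix shape {mat.shape} matches neither "
            f"(cells={len(cells)}, genes={len(genes)}) orientation"
        )
    if dense.size and dense.min() < 0:
        raise ValidationError("negative count entries in matrix")
    if not np.allclose(dense, np.round(dense)):
        raise ValidationError("non-integer count entries in matrix")
    dense = np.round(dense).astype(np.int64)

    if annot_path is not None:
        annot = pd.read_csv(annot_path, sep="\t", dtype=str)
        missing = set(ANNOT_COLUMNS[:4]) - set(annot.columns)
        if missing:
            raise FormatError(f"annotations missing columns: {sorted(missing)}")
        annot = annot.set_index("cell_id")
        try:
            annot = annot.loc[cells]
        except KeyError as exc:
            raise FormatError(f"annotation rows do not cover all cells: {exc}")
    else:
        annot = pd.DataFrame(
            {"species": "unknown", "batch": "b0", "subtype": "unknown"},
            index=pd.Index(cells, name="cell_id"),
        )
    return CellTable(counts=dense, gene_ids=genes, cell_ids=cells, annot=annot)


def write_cell_table(table: CellTable, out_dir: str | Path) -> dict[str, Path]:
    """Write a table as matrix.mtx + features/barcodes/annotations TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "matrix.mtx",
        "genes": out / "features.tsv",
        "cells": out / "barcodes.tsv",
        "annot": out / "annotations.tsv",
    }
    coo = scipy.sparse.coo_matrix(table.counts.T)  # genes x cells on disk
    scipy.io.mmwrite(
        str(paths["matrix"]), coo, field="integer", comment="rows=genes"
    )
    paths["genes"].write_text("".join(g + "\n" for g in table.gene_ids))
    paths["cells"].write_text("".join(c + "\n" for c in table.cell_ids))
    annot = table.annot.copy()
    annot.insert(0, "cell_id", table.cell_ids)
    annot.to_csv(paths["annot"], sep="\t", index=False)
    return paths


def read_bundle(bundle_dir: str | Path) -> CellTable:
    d = Path(bundle_dir)
    return read_cell_table(
        d / "matrix.mtx", d / "features.tsv", d / "barcodes.tsv",
        d / "annotations.tsv",
    )


def _mtx_orientation_comment(path: str | Path) -> str | None:
    with open(path) as fh:
        for line in fh:
            if not line.startswith("%"):
                break
            if "rows=genes" in line:
                return "genes"
            if "rows=cells" in line:
                return "cells"
    return None


def _read_id_column(path: str | Path) -> list[str]:
    ids = [
        line.split("\t")[0].strip()
        for line in Path(path).read_text().splitlines()
        if line.strip()
    ]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"duplicate identifiers in {path}")
    return ids


# ---------------------------------------------------------------------------
# homology
# ---------------------------------------------------------------------------

def map_to_reference(table: CellTable, hmap: HomologyMap) -> CellTable:
    """Rename genes to reference orthologue ids, dropping unmapped genes.

    Column order follows the order of retained genes in the input table; cell
    rows and retained count values are untouched.
    """
    if table.species != hmap.source_species:
        raise ValidationError(
            f"table species {table.species!r} != map source "
            f"{hmap.source_species!r}"
        )
    mapping = hmap.as_dict()
    keep_idx = [i for i, g in enumerate(table.gene_ids) if g in mapping]
    if not keep_idx:
        raise ValidationError(
            "no overlap between table genes "
            f"(e.g. {table.gene_ids[:3]}) and homology sources "
            f"(e.g. {[p[0] for p in hmap.pairs[:3]]})"
        )
    new_genes = [mapping[table.gene_ids[i]] for i in keep_idx]
    return CellTable(
        counts=table.counts[:, keep_idx],
        gene_ids=new_genes,
        cell_ids=list(table.cell_ids),
        annot=table.annot.copy(),
    )


def read_homology_tsv(path: str | Path, source_species: str) -> HomologyMap:
    pairs = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise FormatError(f"{path}:{i}: expected 2 tab-separated fields")
        pairs.append((parts[0], parts[1]))
    if pairs and pairs[0] == ("source_gene", "reference_gene"):
        pairs = pairs[1:]
    return HomologyMap.from_pairs(pairs, source_species)


def write_homology_tsv(hmap: HomologyMap, path: str | Path) -> None:
    lines = ["source_gene\treference_gene"]
    lines += [f"{a}\t{b}" for a, b in hmap.pairs]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path, regulons: bool = False) -> list[GeneSet]:
    """Read a GMT file; with ``regulons=True`` column 2 is the TF symbol."""
    sets: list[GeneSet] = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(
                f"{path}:{i}: GMT line needs >= 3 fields, got {len(parts)}"
            )
        name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
        sets.append(
            GeneSet(name=name, genes=set(genes), tf=desc if regulons else None)
        )
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    lines = []
    for s in sets:
        desc = s.tf if s.tf is not None else "na"
        lines.append("\t".join([s.name, desc, *sorted(s.genes)]))
    Path(path).write_text("".join(line + "\n" for line in lines))


def export_regulon_network(
    regulons: Sequence[GeneSet],
    edges_path: str | Path,
    nodes_path: str | Path,
) -> None:
    """Write a Cytoscape-style TF->target edge list plus node roles.

    A node that is both a TF of one regulon and a target of another is
    labeled ``TF`` (TF role wins the tie).
    """
    edges: list[tuple[str, str]] = []
    tfs: list[str] = []
    targets: list[str] = []
    for r in regulons:
        if r.tf is None:
            raise ValidationError(f"gene set {r.name!r} has no TF")
        tfs.append(r.tf)
        for g in sorted(r.genes):
            edges.append((r.tf, g))
            targets.append(g)
    tf_set = set(tfs)
    nodes = []
    for n in sorted(set(tfs) | set(targets)):
        nodes.append((n, "TF" if n in tf_set else "target"))
    with open(edges_path, "w") as fh:
        fh.write("tf\ttarget\n")
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")
    with open(nodes_path, "w") as fh:
        fh.write("node\trole\n")
        for n, role in nodes:
            fh.write(f"{n}\t{role}\n")
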