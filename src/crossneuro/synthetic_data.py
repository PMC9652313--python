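"""Synthetic multi-species single-cell count data with planted ground truth.

The generator emulates the statistical structure the pipeline is built to
recover: a small set of GABAergic-like subtypes shared across species (each
with a disjoint marker block), optional species-private subtypes, batch and
species-divergence noise, co-expression modules driven by per-cell latent
factors, regulons whose targets are shifted in "active" cells, and a disease
condition that up-regulates a designated risk module.

Counts follow a gamma-Poisson (negative binomial) model: for cell ``c`` the
per-gene mean is the library size times the softmax-normalised product of

* a lognormal baseline per gene (shared across species),
* ``2**lfc`` on the marker block of the cell's subtype,
* lognormal batch and species-divergence jitter,
* ``2**(lambda * z_c)`` for each planted module (latent factor ``z_c`` per
  cell, shared across the module's genes — the correlation structure
  co-expression analysis assumes),
* ``2**regulon_lfc`` on regulon targets in cells where the regulon is active,
* ``2**disease_lfc`` on risk-module genes in disease cells.

Every planted assignment is recorded in :class:`Truth` so downstream stages
can be scored against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_core import (
    CellTable,
    GeneSet,
    HomologyMap,
    ValidationError,
    stage_rng,
)

INHIBITORY_MARKER_GENES = ("GAD1", "GAD2")


class DesignError(ValueError):
    """Inconsistent simulation design (e.g. marker blocks exceed gene count)."""


@dataclass
class SubtypeSpec:
    """A planted cell subtype: marker block size, marker log2FC, identity."""

    name: str
    n_markers: int = 40
    lfc: float = 3.0
    inhibitory: bool = True


@dataclass
class ModuleSpec:
    """A planted co-expression module: gene count and latent-factor loading."""

    size: int = 50
    loading: float = 1.0


@dataclass
class RegulonSpec:
    """A planted regulon: TF name, target count, per-subtype active fraction.

    ``active_fraction`` maps a (species, subtype) key — or a plain subtype
    name applying to every species — to the Bernoulli probability that a cell
    of that subtype has the regulon switched on.  Active cells get
    ``lfc`` log2 fold-change on all targets.
    """

    tf: str
    n_targets: int = 30
    active_fraction: dict[str, float] = field(default_factory=dict)
    default_fraction: float = 0.05
    lfc: float = 1.0

    def fraction_for(self, species: str, subtype: str) -> float:
        key = f"{species}:{subtype}"
        if key in self.active_fraction:
            return self.active_fraction[key]
        if species in self.active_fraction:
            return self.active_fraction[species]
        if subtype in self.active_fraction:
            return self.active_fraction[subtype]
        return self.default_fraction


def default_subtypes() -> list[SubtypeSpec]:
    return [
        SubtypeSpec("Inc_SST"),
        SubtypeSpec("Inc_PVALB"),
        SubtypeSpec("Inc_LAMP5"),
        SubtypeSpec("Inc_VIP"),
        SubtypeSpec("Exc_L23", inhibitory=False),
    ]


def default_regulons(species: tuple[str, ...]) -> list[RegulonSpec]:
    """Archetypal activation patterns: conserved-in-all, single-species, off.

    Three regulons per archetype; with two species the archetypes are
    all-on, each single species, and all-off plus subtype-restricted ones.
    """
    specs: list[RegulonSpec] = []
    idx = 0
    patterns: list[dict[str, float]] = [{sp: 0.8 for sp in species}, {}]
    for sp in species:
        patterns.append({sp: 0.8})
    patterns.append({"Inc_SST": 0.8})
    patterns.append({"Inc_PVALB": 0.8})
    for pat in patterns:
        for _ in range(3):
            specs.append(
                RegulonSpec(tf=f"TF{idx:02d}", active_fraction=dict(pat))
            )
            idx += 1
    return specs


@dataclass
class SimDesign:
    """Study design for the synthetic generator; defaults are the standard
    two-species benchmark: four conserved subtypes plus one mouse-private
    subtype, 200 cells per subtype, two batches per species, three planted
    50-gene modules (the first is the disease risk module) and archetypal
    regulons."""

    species: tuple[str, ...] = ("human", "mouse")
    reference: str = "human"
    n_genes: int = 1200
    shared_subtypes: list[SubtypeSpec] = field(default_factory=default_subtypes)
    specific_subtypes: dict[str, list[SubtypeSpec]] = field(
        default_factory=lambda: {"mouse": [SubtypeSpec("Inc_Meis2")]}
    )
    cells_per_subtype: int = 200
    n_batches: int = 2
    batch_lognormal_sd: float = 0.15
    divergence_sd: float = 0.10
    library_size_mean: float = 5000.0
    nb_dispersion: float = 10.0
    planted_modules: list[ModuleSpec] = field(
        default_factory=lambda: [ModuleSpec(50, 1.0)] * 3
    )
    planted_regulons: list[RegulonSpec] | None = None
    disease_effect: float = 1.0
    disease_fraction: float = 0.5
    homolog_fraction: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.planted_regulons is None:
            self.planted_regulons = default_regulons(tuple(self.species))
        if self.reference not in self.species:
            raise DesignError(f"reference {self.reference!r} not in species")
        if self.cells_per_subtype <= 0 or self.n_genes <= 0:
            raise DesignError("sizes must be positive")
        if not (0.0 <= self.disease_fraction <= 1.0):
            raise DesignError("disease_fraction outside [0, 1]")
        if not (0.0 <= self.homolog_fraction <= 1.0):
            raise DesignError("homolog_fraction outside [0, 1]")
        for sd in (self.batch_lognormal_sd, self.divergence_sd):
            if sd < 0:
                raise DesignError("lognormal sd must be >= 0")
        for r in self.planted_regulons:
            for f in list(r.active_fraction.values()) + [r.default_fraction]:
                if not (0.0 <= f <= 1.0):
                    raise DesignError("active fractions must lie in [0, 1]")
        n_marker = sum(s.n_markers for s in self.all_subtypes())
        n_module = sum(m.size for m in self.planted_modules)
        n_target = sum(r.n_targets for r in self.planted_regulons)
        reserved = len(INHIBITORY_MARKER_GENES) + n_marker + n_module + n_target
        if reserved > self.n_genes:
            raise DesignError(
                f"planted structure needs {reserved} genes, design has "
                f"{self.n_genes}"
            )

    def all_subtypes(self) -> list[SubtypeSpec]:
        out = list(self.shared_subtypes)
        for lst in self.specific_subtypes.values():
            out.extend(lst)
        return out

    def subtypes_for(self, species: str) -> list[SubtypeSpec]:
        return list(self.shared_subtypes) + list(
            self.specific_subtypes.get(species, [])
        )


@dataclass
class Truth:
    """Planted ground truth for a simulation run."""

    subtype_of_cell: dict[str, dict[str, str]]  # species -> cell -> subtype
    marker_genes: dict[str, list[str]]  # subtype -> reference gene ids
    marker_lfc: dict[str, float]
    module_genes: dict[str, list[str]]  # module name -> reference gene ids
    risk_module: str
    risk_genes: list[str]
    regulon_targets: dict[str, list[str]]  # regulon name -> targets
    regulon_active: dict[str, dict[str, list[str]]]  # species -> regulon -> cells
    de_genes: list[str]  # genes shifted by the disease condition
    shared_subtype_names: list[str]
    specific_subtype_names: dict[str, list[str]]


def _gene_ids(design: SimDesign) -> list[str]:
    width = max(4, len(str(design.n_genes)))
    ids = [f"G{i:0{width}d}" for i in range(design.n_genes)]
    for j, marker in enumerate(INHIBITORY_MARKER_GENES):
        ids[j] = marker
    return ids


def simulate(
    design: SimDesign,
) -> tuple[dict[str, CellTable], dict[str, HomologyMap], Truth]:
    """Draw one synthetic multi-species experiment.

    Returns per-species count tables (each in its own gene-id namespace for
    non-reference species), a one-to-one homology map per non-reference
    species covering ``homolog_fraction`` of genes, and the planted
    :class:`Truth`.
    """
    rng = stage_rng(design.seed, "simulate")
    genes = _gene_ids(design)
    G = design.n_genes

    # --- assign planted gene blocks (disjoint) -----------------------------
    cursor = len(INHIBITORY_MARKER_GENES)
    marker_idx: dict[str, np.ndarray] = {}
    for st in design.all_subtypes():
        marker_idx[st.name] = np.arange(cursor, cursor + st.n_markers)
        cursor += st.n_markers
    module_idx: dict[str, np.ndarray] = {}
    for m_i, mod in enumerate(design.planted_modules):
        module_idx[f"M{m_i + 1}"] = np.arange(cursor, cursor + mod.size)
        cursor += mod.size
    regulon_idx: dict[str, np.ndarray] = {}
    for reg in design.planted_regulons:
        regulon_idx[f"{reg.tf}(+)"] = np.arange(cursor, cursor + reg.n_targets)
        cursor += reg.n_targets

    baseline = np.exp(rng.normal(0.0, 1.0, size=G))
    # module genes and regulon targets sit in the upper half of the baseline
    # distribution: co-expression and rank-based target recovery are only
    # observable on adequately expressed genes
    for block in (module_idx, regulon_idx):
        for idx in block.values():
            baseline[idx] = np.exp(np.abs(rng.normal(0.0, 1.0, size=len(idx))))
    inhib_cols = np.arange(len(INHIBITORY_MARKER_GENES))
    module_names = list(module_idx)
    risk_module = module_names[0] if module_names else ""

    tables: dict[str, CellTable] = {}
    hmaps: dict[str, HomologyMap] = {}
    subtype_of_cell: dict[str, dict[str, str]] = {}
    regulon_active: dict[str, dict[str, list[str]]] = {}

    for species in design.species:
        sub_specs = design.subtypes_for(species)
        n_cells = design.cells_per_subtype * len(sub_specs)
        # species-level divergence jitter on gene means
        divergence = np.exp(rng.normal(0.0, design.divergence_sd, size=G)) \
            if species != design.reference else np.ones(G)
        batch_effects = np.exp(
            rng.normal(0.0, design.batch_lognormal_sd, size=(design.n_batches, G))
        )

        log2_shift = np.zeros((n_cells, G))
        subtype_labels: list[str] = []
        batch_labels: list[str] = []
        condition_labels: list[str | None] = []
        active_mask: dict[str, np.ndarray] = {
            name: np.zeros(n_cells, dtype=bool) for name in regulon_idx
        }

        row = 0
        for st in sub_specs:
            for _ in range(design.cells_per_subtype):
                subtype_labels.append(st.name)
                batch_labels.append(f"batch{row % design.n_batches}")
                row += 1
        batch_of = np.array([int(b[5:]) for b in batch_labels])
        subtype_arr = np.array(subtype_labels)

        for st in sub_specs:
            cells = np.flatnonzero(subtype_arr == st.name)
            log2_shift[np.ix_(cells, marker_idx[st.name])] += st.lfc
            if st.inhibitory:
                log2_shift[np.ix_(cells, inhib_cols)] += 3.0
            else:
                # GAD1/GAD2 are essentially silent outside inhibitory neurons
                log2_shift[np.ix_(cells, inhib_cols)] -= 6.0

        # module latent factors
        z = rng.normal(0.0, 1.0, size=(n_cells, len(design.planted_modules)))
        for m_i, mod in enumerate(design.planted_modules):
            cols = module_idx[module_names[m_i]]
            log2_shift[:, cols] += mod.loading * z[:, [m_i]]

        # regulon activity masks
        for reg, (name, cols) in zip(design.planted_regulons, regulon_idx.items()):
            p = np.array(
                [reg.fraction_for(species, s) for s in subtype_arr]
            )
            on = rng.random(n_cells) < p
            active_mask[name] = on
            log2_shift[np.ix_(on, cols)] += reg.lfc

        # disease condition on the reference species
        if species == design.reference and design.disease_effect != 0 and risk_module:
            disease = rng.random(n_cells) < design.disease_fraction
            condition_labels = [
                "disease" if d else "control" for d in disease
            ]
            risk_cols = module_idx[risk_module]
            log2_shift[np.ix_(disease, risk_cols)] += design.disease_effect
        else:
            condition_labels = ["control"] * n_cells

        mean = baseline[None, :] * divergence[None, :] * np.exp2(log2_shift)
        mean = mean * batch_effects[batch_of]
        props = mean / mean.sum(axis=1, keepdims=True)
        lib = rng.gamma(shape=5.0, scale=design.library_size_mean / 5.0,
                        size=n_cells)
        mu = props * lib[:, None]
        theta = design.nb_dispersion
        lam = rng.gamma(shape=theta, scale=mu / theta)
        counts = rng.poisson(lam).astype(np.int64)

        prefix = "" if species == design.reference else f"{species[:2]}_"
        sp_genes = [prefix + g for g in genes]
        cell_ids = [f"{species}_c{i:05d}" for i in range(n_cells)]
        annot = pd.DataFrame(
            {
                "species": species,
                "batch": batch_labels,
                "subtype": subtype_labels,
                "condition": condition_labels,
            },
            index=pd.Index(cell_ids, name="cell_id"),
        )
        tables[species] = CellTable(
            counts=counts, gene_ids=sp_genes, cell_ids=cell_ids, annot=annot
        )
        subtype_of_cell[species] = dict(zip(cell_ids, subtype_labels))
        regulon_active[species] = {
            name: [cell_ids[i] for i in np.flatnonzero(mask)]
            for name, mask in active_mask.items()
        }

        if species != design.reference:
            n_map = int(round(design.homolog_fraction * G))
            # inhibitory markers are always orthologous so downstream marker
            # gating works in every species
            always = np.arange(len(INHIBITORY_MARKER_GENES))
            pool = np.arange(len(always), G)
            extra = rng.choice(
                pool, size=max(0, n_map - len(always)), replace=False
            )
            mapped = np.concatenate([always, extra])
            mapped.sort()
            pairs = [(sp_genes[i], genes[i]) for i in mapped]
            hmaps[species] = HomologyMap.from_pairs(pairs, species)

    truth = Truth(
        subtype_of_cell=subtype_of_cell,
        marker_genes={
            name: [genes[i] for i in idx] for name, idx in marker_idx.items()
        },
        marker_lfc={st.name: st.lfc for st in design.all_subtypes()},
        module_genes={
            name: [genes[i] for i in idx] for name, idx in module_idx.items()
        },
        risk_module=risk_module,
        risk_genes=[genes[i] for i in module_idx[risk_module]]
        if risk_module else [],
        regulon_targets={
            name: [genes[i] for i in idx] for name, idx in regulon_idx.items()
        },
        regulon_active=regulon_active,
        de_genes=[genes[i] for i in module_idx[risk_module]]
        if (risk_module and design.disease_effect != 0) else [],
        shared_subtype_names=[s.name for s in design.shared_subtypes],
        specific_subtype_names={
            sp: [s.name for s in lst]
            for sp, lst in design.specific_subtypes.items()
        },
    )
    return tables, hmaps, truth


def regulon_gene_sets(truth: Truth) -> list[GeneSet]:
    """Planted regulons as GMT-ready gene sets (reference gene ids)."""
    return [
        GeneSet(name=name, genes=set(targets), tf=name.split("(")[0])
        for name, targets in truth.regulon_targets.items()
    ]


def risk_gene_set(truth: Truth, name: str = "AD_risk") -> GeneSet:
    return GeneSet(name=name, genes=set(truth.risk_genes))


# ---------------------------------------------------------------------------
# truth serialization
# ---------------------------------------------------------------------------

def truth_report(truth: Truth) -> dict[str, pd.DataFrame]:
    """Deterministic tabular summary of the planted structure."""
    mod_rows = [
        {"module": m, "n_genes": len(g), "genes": ",".join(g)}
        for m, g in truth.module_genes.items()
    ]
    marker_rows = [
        {
            "subtype": s,
            "lfc": truth.marker_lfc[s],
            "n_markers": len(g),
            "genes": ",".join(g),
        }
        for s, g in truth.marker_genes.items()
    ]
    reg_rows = [
        {"regulon": r, "n_targets": len(g), "targets": ",".join(g)}
        for r, g in truth.regulon_targets.items()
    ]
    cell_rows = [
        {"species": sp, "cell_id": c, "subtype": st}
        for sp, d in truth.subtype_of_cell.items()
        for c, st in d.items()
    ]
    active_rows = [
        {"species": sp, "regulon": r, "active_cells": ",".join(cells)}
        for sp, d in truth.regulon_active.items()
        for r, cells in d.items()
    ]
    return {
        "modules": pd.DataFrame(
            mod_rows, columns=["module", "n_genes", "genes"]
        ),
        "markers": pd.DataFrame(
            marker_rows, columns=["subtype", "lfc", "n_markers", "genes"]
        ),
        "regulons": pd.DataFrame(
            reg_rows, columns=["regulon", "n_targets", "targets"]
        ),
        "cells": pd.DataFrame(
            cell_rows, columns=["species", "cell_id", "subtype"]
        ),
        "regulon_activity": pd.DataFrame(
            active_rows, columns=["species", "regulon", "active_cells"]
        ),
    }


def write_truth(truth: Truth, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in truth_report(truth).items():
        df.to_csv(out / f"truth_{name}.tsv", sep="\t", index=False)
    meta = {
        "risk_module": truth.risk_module,
        "risk_genes": truth.risk_genes,
        "de_genes": truth.de_genes,
        "shared_subtype_names": truth.shared_subtype_names,
        "specific_subtype_names": truth.specific_subtype_names,
    }
    (out / "truth_meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_truth(out_dir: str | Path) -> Truth:
    out = Path(out_dir)
    meta = json.loads((out / "truth_meta.json").read_text())

    def _split(s) -> list[str]:
        return [] if (pd.isna(s) or s == "") else str(s).split(",")

    mods = pd.read_csv(out / "truth_modules.tsv", sep="\t")
    markers = pd.read_csv(out / "truth_markers.tsv", sep="\t")
    regs = pd.read_csv(out / "truth_regulons.tsv", sep="\t")
    cells = pd.read_csv(out / "truth_cells.tsv", sep="\t")
    activity = pd.read_csv(out / "truth_regulon_activity.tsv", sep="\t")

    subtype_of_cell: dict[str, dict[str, str]] = {}
    for _, row in cells.iterrows():
        subtype_of_cell.setdefault(row["species"], {})[row["cell_id"]] = row[
            "subtype"
        ]
    regulon_active: dict[str, dict[str, list[str]]] = {}
    for _, row in activity.iterrows():
        regulon_active.setdefault(row["species"], {})[row["regulon"]] = _split(
            row["active_cells"]
        )
    return Truth(
        subtype_of_cell=subtype_of_cell,
        marker_genes={
            r["subtype"]: _split(r["genes"]) for _, r in markers.iterrows()
        },
        marker_lfc={
            r["subtype"]: float(r["lfc"]) for _, r in markers.iterrows()
        },
        module_genes={
            r["module"]: _split(r["genes"]) for _, r in mods.iterrows()
        },
        risk_module=meta["risk_module"],
        risk_genes=meta["risk_genes"],
        regulon_targets={
            r["regulon"]: _split(r["targets"]) for _, r in regs.iterrows()
        },
        regulon_active=regulon_active,
        de_genes=meta["de_genes"],
        shared_subtype_names=meta["shared_subtype_names"],
        specific_subtype_names=meta["specific_subtype_names"],
    )
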