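"""Hypergeometric enrichment, Wilcoxon DE and cross-species comparisons."""

import math

import numpy as np
import pandas as pd
import pytest

from crossneuro.enrichment_adrisk import (
    crossspecies_deg_flags,
    crossspecies_gene_correlation,
    deg_wilcoxon,
    high_confidence_risk_genes,
    hypergeom_upper,
    hypergeom_upper_tail,
    module_risk_enrichment,
    stars_for,
    DegRecord,
)
from crossneuro.io_core import ValidationError, stage_rng
from crossneuro.preprocess_integrate import ParameterError

from .test_io_core import make_table


def enumeration_upper(k, M, n, N):
    """Exact tail by integer enumeration of the hypergeometric pmf."""
    den = math.comb(N, n)
    num = sum(
        math.comb(M, j) * math.comb(N - M, n - j)
        for j in range(k, min(M, n) + 1)
        if n - j <= N - M
    )
    return num / den


class TestHypergeomUpper:
    def test_k_zero_is_one(self):
        assert hypergeom_upper(0, 5, 4, 10) == 1.0

    def test_small_worked_example(self):
        # k=3, M=5, n=4, N=10
        expected = (
            math.comb(5, 3) * math.comb(5, 1) + math.comb(5, 4)
        ) / math.comb(10, 4)
        assert hypergeom_upper(3, 5, 4, 10) == pytest.approx(
            expected, abs=1e-12
        )

    def test_maximum_overlap_single_term(self):
        k = min(6, 8)
        expected = (
            math.comb(6, k) * math.comb(14, 8 - k) / math.comb(20, 8)
        )
        assert hypergeom_upper(k, 6, 8, 20) == pytest.approx(
            expected, rel=1e-10
        )

    def test_matches_enumeration_on_grid(self):
        for N in (10, 23, 41):
            for M in range(0, N + 1, 5):
                for n in range(0, N + 1, 7):
                    tail = hypergeom_upper_tail(M, n, N)
                    for k in range(min(M, n) + 1):
                        assert tail[k] == pytest.approx(
                            enumeration_upper(k, M, n, N), abs=1e-10
                        )

    def test_invalid_bounds(self):
        with pytest.raises(ParameterError):
            hypergeom_upper(5, 3, 3, 10)
        with pytest.raises(ParameterError):
            hypergeom_upper_tail(11, 3, 10)


class TestModuleEnrichment:
    def test_embedded_module_tiny_p(self):
        risk = {f"r{i}" for i in range(100)}
        modules = {"m": [f"r{i}" for i in range(10)]}
        rec = module_risk_enrichment(modules, risk, background=20_000)[0]
        assert rec.k == 10
        assert rec.p < 1e-10
        assert rec.stars == "***"

    def test_disjoint_module_p_one_no_stars(self):
        rec = module_risk_enrichment(
            {"m": ["a", "b"]}, {"x", "y"}, background=100
        )[0]
        assert rec.k == 0 and rec.p == 1.0 and rec.stars == ""

    def test_empty_risk_set_rejected(self):
        with pytest.raises(ValidationError):
            module_risk_enrichment({"m": ["a"]}, set())

    def test_invariant_to_order_and_labels(self):
        risk = {f"g{i}" for i in range(0, 50, 2)}
        genes = [f"g{i}" for i in range(30)]
        p1 = module_risk_enrichment({"A": genes}, risk)[0].p
        p2 = module_risk_enrichment({"zz": genes[::-1]}, risk)[0].p
        assert p1 == p2

    def test_star_tiers(self):
        assert stars_for(0.04) == "*"
        assert stars_for(0.005) == "**"
        assert stars_for(0.0005) == "***"
        assert stars_for(0.2) == ""


def de_table(seed=0, n_per=100, n_genes=60, lfc_genes=(), log2fc=1.0):
    rng = stage_rng(seed, "de")
    base = rng.uniform(2, 10, size=n_genes)
    mean = np.tile(base, (2 * n_per, 1))
    for g in lfc_genes:
        mean[:n_per, g] *= 2.0 ** log2fc
    counts = rng.poisson(mean)
    t = make_table(counts)
    t.annot["condition"] = ["disease"] * n_per + ["control"] * n_per
    return t


class TestDegWilcoxon:
    def test_planted_twofold_gene_detected(self):
        hits = 0
        for seed in range(5):
            t = de_table(seed=seed, n_per=200, lfc_genes=(0,), log2fc=1.0)
            degs = deg_wilcoxon(
                t, "condition", "disease", "control"
            )
            sig = {d.gene for d in degs if d.p_adj < 0.05}
            hits += "g0" in sig
        assert hits == 5

    def test_null_calibration(self):
        frac = []
        for seed in range(5):
            t = de_table(seed=100 + seed, n_per=100)
            degs = deg_wilcoxon(
                t, "condition", "disease", "control",
                logfc_threshold=0.0, min_pct=0.0,
            )
            n_sig = sum(d.p_adj < 0.05 for d in degs)
            frac.append(n_sig / max(len(degs), 1))
        assert np.mean(frac) <= 0.07

    def test_low_detection_gene_not_tested(self):
        rng = stage_rng(3, "lowpct")
        counts = np.zeros((40, 2), dtype=int)
        counts[:, 0] = rng.poisson(5, size=40)
        counts[::10, 1] = 50  # detected in 10% of cells
        t = make_table(counts)
        t.annot["condition"] = ["disease"] * 20 + ["control"] * 20
        degs = deg_wilcoxon(t, "condition", "disease", "control", min_pct=0.25)
        assert "g1" not in {d.gene for d in degs}

    def test_bh_monotone(self):
        t = de_table(seed=7, n_per=80, lfc_genes=(0, 1, 2), log2fc=1.5)
        degs = deg_wilcoxon(
            t, "condition", "disease", "control",
            logfc_threshold=0.0, min_pct=0.0,
        )
        by_p = sorted(degs, key=lambda d: d.p)
        adj = [d.p_adj for d in by_p]
        assert all(a <= b + 1e-15 for a, b in zip(adj, adj[1:]))
        assert all(d.p_adj >= d.p for d in degs)

    def test_missing_group_rejected(self):
        t = de_table(seed=1, n_per=20)
        with pytest.raises(ValidationError):
            deg_wilcoxon(t, "condition", "remission", "control")


class TestHighConfidence:
    def test_intersection_semantics(self):
        degs = {
            "ct1": [DegRecord("a", 1, 0.5, 0.1, 1e-4, 1e-3),
                    DegRecord("b", 1, 0.5, 0.1, 1e-4, 1e-3)],
            "ct2": [],
        }
        out = high_confidence_risk_genes(degs, {"a", "z"}, {"a", "b"})
        assert out == {"ct1": ["a"], "ct2": []}

    def test_output_subset_of_inputs(self):
        rng = stage_rng(5, "hc")
        genes = [f"g{i}" for i in range(30)]
        degs = {
            "ct": [
                DegRecord(g, 1, 0.5, 0.1, 1e-3, 1e-2)
                for g in rng.choice(genes, 10, replace=False)
            ]
        }
        risk = set(rng.choice(genes, 15, replace=False))
        module = set(rng.choice(genes, 15, replace=False))
        out = high_confidence_risk_genes(degs, risk, module)["ct"]
        de = {d.gene for d in degs["ct"]}
        assert set(out) <= de and set(out) <= risk and set(out) <= module


class TestCrossSpecies:
    @staticmethod
    def species_pair(seed=0, copy=True):
        rng = stage_rng(seed, "xs")
        base = rng.uniform(1, 20, size=50)
        counts_h = rng.poisson(base, size=(60, 50))
        t_h = make_table(counts_h, subtypes=["A"] * 30 + ["B"] * 30)
        if copy:
            t_m = make_table(
                counts_h.copy(), subtypes=["A"] * 30 + ["B"] * 30
            )
        else:
            counts_m = rng.poisson(
                rng.uniform(1, 20, size=50), size=(60, 50)
            )
            t_m = make_table(counts_m, subtypes=["A"] * 30 + ["B"] * 30)
        return t_h, t_m

    def test_exact_copy_r_one_slope_one(self):
        t_h, t_m = self.species_pair(copy=True)
        df = crossspecies_gene_correlation(t_h, t_m, t_h.gene_ids)
        assert np.allclose(df["pearson_r"], 1.0)
        assert np.allclose(df["slope"], 1.0)
        assert np.allclose(df["intercept"], 0.0, atol=1e-12)

    def test_independent_species_near_zero(self):
        rs = []
        for seed in range(10):
            t_h, t_m = self.species_pair(seed=seed, copy=False)
            df = crossspecies_gene_correlation(t_h, t_m, t_h.gene_ids)
            rs.extend(df["pearson_r"].tolist())
        assert np.mean(np.abs(rs)) <= 0.15

    def test_too_few_shared_genes(self):
        t_h, t_m = self.species_pair()
        with pytest.raises(ValidationError):
            crossspecies_gene_correlation(t_h, t_m, ["g0", "g1"])

    def test_deg_flags_identical_distributions_unstarred(self):
        t_h, t_m = self.species_pair(copy=True)
        df = crossspecies_deg_flags(t_h, t_m, t_h.gene_ids)
        assert (df["star"] == "").all()

    def test_deg_flags_fourfold_shift_starred(self):
        hits = 0
        for seed in range(5):
            rng = stage_rng(seed, "flags")
            base = rng.uniform(5, 20, size=30)
            shifted = base.copy()
            shifted[0] *= 4.0  # single-gene shift survives normalisation
            c_h = rng.poisson(shifted, size=(200, 30))
            c_m = rng.poisson(base, size=(200, 30))
            t_h = make_table(c_h, subtypes=["A"] * 200)
            t_m = make_table(c_m, subtypes=["A"] * 200)
            df = crossspecies_deg_flags(t_h, t_m, ["g0"])
            hits += (df["star"] == "*").all()
        assert hits >= 5 * 0.95 - 1e-9

    def test_conjunction_rule(self):
        # significant p but small fold change: no star
        rng = stage_rng(9, "conj")
        base = np.full(20, 50.0)
        c_h = rng.poisson(base * 1.3, size=(300, 20))
        c_m = rng.poisson(base, size=(300, 20))
        t_h = make_table(c_h, subtypes=["A"] * 300)
        t_m = make_table(c_m, subtypes=["A"] * 300)
        df = crossspecies_deg_flags(t_h, t_m, t_h.gene_ids)
        tested = df.dropna(subset=["p_adj"])
        small = tested[np.abs(tested["avg_logFC"]) <= 1.0]
        assert (small["star"] == "").all()
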