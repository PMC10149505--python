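"""Differential expression, rank correlation and multi-omics integration."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from omicscreen.datatypes import DifferentialResult, SampleAnnotation
from omicscreen.diffexp import (
    assemble_crgs,
    fc_concordance,
    mrna_protein_correlation,
    overlap_sets,
    spearman,
    wilcoxon_de,
)

from conftest import make_matrix


def brute_force_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided rank-sum p by enumerating every group assignment."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    mean_w = n1 * (len(pooled) + 1) / 2.0
    ws = [
        ranks[list(idx)].sum()
        for idx in itertools.combinations(range(len(pooled)), n1)
    ]
    ws = np.array(ws)
    return float(np.mean(np.abs(ws - mean_w) >= abs(w_obs - mean_w) - 1e-12))


class TestSpearman:
    def test_monotone_is_one(self):
        rho, p, reason = spearman(np.arange(10.0), np.arange(10.0) ** 3)
        assert rho == pytest.approx(1.0) and reason is None

    def test_small_sample_example(self):
        rho, p, _ = spearman(np.array([1.0, 2, 3]), np.array([3.0, 1, 2]))
        assert rho == pytest.approx(-0.5)
        # exact permutation: 6 permutations, all with |rho| >= 0.5
        assert p == pytest.approx(1.0)

    def test_constant_input_gives_reason(self):
        rho, p, reason = spearman(np.ones(5), np.arange(5.0))
        assert np.isnan(rho) and reason == "constant input"

    def test_exact_branch_matches_enumeration(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=7)
        y = rng.normal(size=7)
        rho, p, _ = spearman(x, y)
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        null = []
        for perm in itertools.permutations(ry):
            null.append(np.corrcoef(rx, perm)[0, 1])
        p_expect = np.mean(np.abs(null) >= abs(rho) - 1e-12)
        assert p == pytest.approx(p_expect)

    def test_large_n_uses_t_approximation(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=30), rng.normal(size=30)
        rho, p, _ = spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)


class TestWilcoxonDE:
    def _run_one(self, tumor, bph, layer="proteome", **kw):
        values = np.array([list(bph) + list(tumor)])
        samples = [f"b{i}" for i in range(len(bph))] + [f"t{i}" for i in range(len(tumor))]
        ann = [SampleAnnotation(s, "BPH", "B1") for s in samples[: len(bph)]] + [
            SampleAnnotation(s, "tumor", "B1") for s in samples[len(bph):]
        ]
        m = make_matrix(values, samples=samples, layer=layer)
        return wilcoxon_de(m, ann, **kw)[0]

    def test_exact_p_for_disjoint_triples(self):
        res = self._run_one(tumor=[4.0, 5, 6], bph=[1.0, 2, 3])
        assert res.p_value == pytest.approx(0.1)

    def test_direction_from_thresholds(self):
        r = DifferentialResult("f", "proteome", 1.25, 0.0, 0.04, "up")
        # the contract: p < alpha and FC > 1.2 means up — exercised end to end
        res = self._run_one(
            tumor=[1.30, 1.35, 1.40, 1.28, 1.32, 1.31, 1.29, 1.33],
            bph=[1.0, 1.02, 0.98, 1.01, 0.99, 1.0, 1.03, 0.97],
            layer="transcriptome",
        )
        assert res.p_value < 0.05 and res.fold_change > 1.2
        assert res.direction == "up" == r.direction

    def test_identical_groups_are_ns_with_unit_fc(self):
        res = self._run_one(tumor=[1.0, 2, 3], bph=[1.0, 2, 3], layer="transcriptome")
        assert res.fold_change == pytest.approx(1.0)
        assert res.direction == "ns"

    def test_geometric_fc_on_log_layers(self):
        res = self._run_one(tumor=[2.0, 2.0, 2.0], bph=[1.0, 1.0, 1.0], layer="proteome")
        assert res.fold_change == pytest.approx(2.0)  # 2**(2-1)
        res_lin = self._run_one(tumor=[2.0, 2.0, 2.0], bph=[1.0, 1.0, 1.0], layer="transcriptome")
        assert res_lin.fold_change == pytest.approx(2.0)  # ratio of means

    def test_insufficient_samples_reported_na(self):
        res = self._run_one(tumor=[1.0], bph=[1.0, 2.0, 3.0])
        assert np.isnan(res.p_value) and res.reason is not None

    @pytest.mark.parametrize("n1,n2", [(2, 2), (2, 3), (3, 3), (2, 4), (4, 4), (5, 5), (3, 7)])
    def test_exact_branch_matches_enumeration_oracle(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(5):
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            res = self._run_one(tumor=list(x), bph=list(y))
            assert res.p_value == pytest.approx(brute_force_ranksum_p(x, y))


class TestOverlap:
    @staticmethod
    def _results(layer, sig, ns=()):
        out = [DifferentialResult(g, layer, 2.0, 1.0, 0.01, "up") for g in sig]
        out += [DifferentialResult(g, layer, 1.0, 0.0, 0.9, "ns") for g in ns]
        return out

    def test_disjoint_sets_have_empty_intersections(self):
        table, counts = overlap_sets(
            {
                "proteome": self._results("proteome", ["a"]),
                "surfaceome": self._results("surfaceome", ["b"]),
                "transcriptome": self._results("transcriptome", ["c"]),
            }
        )
        for region, count in counts.items():
            if len(region) > 1:
                assert count == 0

    def test_triple_member_counted_once(self):
        table, counts = overlap_sets(
            {
                "proteome": self._results("proteome", ["g"]),
                "surfaceome": self._results("surfaceome", ["g"]),
                "transcriptome": self._results("transcriptome", ["g"]),
            }
        )
        assert counts[frozenset({"proteome", "surfaceome", "transcriptome"})] == 1
        assert sum(counts.values()) == 1

    def test_random_flags_match_set_algebra(self):
        rng = np.random.default_rng(12)
        genes = [f"g{i}" for i in range(10)]
        for _ in range(25):
            sets = {
                layer: {g for g in genes if rng.uniform() < 0.4}
                for layer in ("proteome", "surfaceome", "transcriptome")
            }
            table, counts = overlap_sets(
                {layer: self._results(layer, sig) for layer, sig in sets.items()}
            )
            union = set().union(*sets.values())
            assert sum(counts.values()) == len(union)
            for g in union:
                region = frozenset(l for l, s in sets.items() if g in s)
                # brute force: recount the region directly
                expected = sum(
                    1
                    for h in union
                    if frozenset(l for l, s in sets.items() if h in s) == region
                )
                assert counts[region] == expected


class TestFCConcordance:
    @staticmethod
    def _de(layer, fcs, ps):
        return [
            DifferentialResult(f"g{i}", layer, fc, 0.0, p, "up")
            for i, (fc, p) in enumerate(zip(fcs, ps))
        ]

    def test_identical_fold_changes_give_rho_one(self):
        fcs = [1.5, 2.0, 0.5, 3.0]
        prot = self._de("proteome", fcs, [0.01] * 4)
        surf = self._de("surfaceome", fcs, [0.01] * 4)
        _, rho, p, reason = fc_concordance(prot, surf)
        assert rho == pytest.approx(1.0) and reason is None

    def test_nonsignificant_proteome_features_excluded(self):
        prot = self._de("proteome", [1.5, 2.0, 0.5, 3.0, 1.1], [0.01, 0.2, 0.01, 0.5, 0.01])
        surf = self._de("surfaceome", [1.4, 2.2, 0.6, 2.5, 1.2], [0.01] * 5)
        table, rho, _, _ = fc_concordance(prot, surf)
        assert len(table) == 3

    def test_sign_flip_gives_minus_one(self):
        fcs = np.array([1.5, 2.0, 0.5, 3.0])
        prot = self._de("proteome", fcs, [0.01] * 4)
        surf = self._de("surfaceome", 1.0 / fcs, [0.01] * 4)
        _, rho, _, _ = fc_concordance(prot, surf)
        assert rho == pytest.approx(-1.0)

    def test_too_few_pairs_reported(self):
        prot = self._de("proteome", [1.5, 2.0], [0.01, 0.5])
        surf = self._de("surfaceome", [1.5, 2.0], [0.01, 0.01])
        _, rho, _, reason = fc_concordance(prot, surf)
        assert np.isnan(rho) and "fewer than 3" in reason


class TestCRGs:
    def test_fifteen_plus_four_disjoint_is_nineteen(self):
        overlap = {f"DEG{i}" for i in range(15)}
        mutated = {"TTN", "NBPF14", "AHNAK2", "COL1A1"}
        crgs = assemble_crgs(overlap, mutated)
        assert len(crgs.genes) == 19
        assert sum(v == "top_mutation" for v in crgs.provenance.values()) == 4

    def test_gene_in_both_counted_once_as_overlap(self):
        crgs = assemble_crgs({"AGR2", "S100P"}, {"AGR2", "TTN"})
        assert len(crgs.genes) == 3
        assert crgs.provenance["AGR2"] == "multiomics_overlap"

    def test_empty_mutated_set(self):
        crgs = assemble_crgs({"AGR2"}, set())
        assert crgs.genes == frozenset({"AGR2"})


class TestMrnaProteinCorrelation:
    def test_perfectly_monotone_gene(self):
        rng = np.random.default_rng(13)
        base = rng.normal(size=(20, 10))
        rna = make_matrix(base, layer="transcriptome")
        protein = make_matrix(base * 2 + 1, layer="proteome")
        table, median_rho, reason = mrna_protein_correlation(rna, protein, sd_quantile=1.0)
        assert median_rho == pytest.approx(1.0) and reason is None

    def test_gene_with_missing_value_excluded(self):
        values = np.random.default_rng(14).normal(size=(5, 8))
        protein_vals = values.copy()
        protein_vals[0, 0] = np.nan
        table, _, _ = mrna_protein_correlation(
            make_matrix(values, layer="transcriptome"),
            make_matrix(protein_vals, layer="proteome"),
            sd_quantile=1.0,
        )
        assert "F0" not in table.index

    def test_sd_filter_keeps_top_fraction(self):
        rng = np.random.default_rng(15)
        values = rng.normal(size=(100, 12))
        values[:10] *= 20  # high-SD genes in both layers
        rna = make_matrix(values, layer="transcriptome")
        protein = make_matrix(values + rng.normal(size=values.shape) * 0.01, layer="proteome")
        table, _, _ = mrna_protein_correlation(rna, protein, sd_quantile=0.1)
        assert set(table.index) == {f"F{i}" for i in range(10)}

    def test_recovers_planted_correlation(self):
        # 200 genes, 25 samples, true per-gene latent correlation ~0.3
        rng = np.random.default_rng(16)
        n_genes, n_samples, rho = 200, 25, 0.3
        latent = rng.normal(size=(n_genes, n_samples))
        noise_sd = np.sqrt(1.0 / rho**2 - 1.0)
        protein = latent + rng.normal(size=latent.shape) * 0.0
        rna = latent + rng.normal(size=latent.shape) * noise_sd
        table, median_rho, _ = mrna_protein_correlation(
            make_matrix(rna, layer="transcriptome"),
            make_matrix(protein, layer="proteome"),
            sd_quantile=1.0,
        )
        assert 0.15 <= median_rho <= 0.45
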