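"""Unit tests for phenotype scores, gene statistics, the quasi-gene null,
normalization, hit calling and sublibrary combination."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import sortscreen as ss
from sortscreen.errors import DegenerateStatisticError, ValidationError

from conftest import mwu_enumeration_pvalue, small_sim_params


def phen_table(eps_by_id: dict[str, tuple[str, bool, float]]) -> pd.DataFrame:
    """Build a phenotype table from {sgrna_id: (gene, is_ntc, epsilon)}."""
    rows = [
        (sg, gene, is_ntc, "lib0", eps) for sg, (gene, is_ntc, eps) in eps_by_id.items()
    ]
    return pd.DataFrame(
        rows, columns=["sgrna_id", "target_gene", "is_ntc", "sublibrary", "epsilon"]
    )


class TestComputePhenotypes:
    def counts(self, low, high, library):
        return pd.DataFrame(
            {"sgrna_id": library["sgrna_id"], "count_low": low, "count_high": high}
        )

    def test_equal_frequencies_give_zero_epsilon(self, toy_library):
        c = self.counts([10, 20, 30, 40, 50, 60], [10, 20, 30, 40, 50, 60], toy_library)
        phen = ss.compute_phenotypes(c, toy_library)
        assert np.allclose(phen["epsilon"], 0.0)

    def test_depth_invariance_both_bins(self, toy_library):
        c1 = self.counts([10, 20, 30, 40, 50, 60], [5, 25, 35, 45, 55, 65], toy_library)
        c2 = c1.assign(count_low=c1.count_low * 10, count_high=c1.count_high * 10)
        p1 = ss.compute_phenotypes(c1, toy_library)
        p2 = ss.compute_phenotypes(c2, toy_library)
        assert np.allclose(p1["epsilon"], p2["epsilon"], atol=1e-12)

    def test_hand_arithmetic_oracle_four_sgrnas(self):
        # 4-sgRNA single-gene-free table, pseudocount 1, no centering:
        # f = c/T + 1/4, eps = log2(f_high/f_low), recomputed by hand here.
        lib = pd.DataFrame(
            {
                "sgrna_id": ["a", "b", "c", "d"],
                "protospacer": ["AA", "AC", "AG", "AT"],
                "target_gene": ["G1", "G1", "NTC", "NTC"],
                "is_ntc": [False, False, True, True],
                "sublibrary": ["lib0"] * 4,
            }
        )
        low = np.array([10, 0, 5, 5])
        high = np.array([2, 8, 5, 5])
        c = self.counts(low, high, lib)
        phen = ss.compute_phenotypes(c, lib, pseudocount=1.0, center_on_ntc=False)
        expected = np.log2((high / 20 + 0.25) / (low / 20 + 0.25))
        assert np.allclose(phen["epsilon"], expected, atol=1e-12)

    def test_ntc_centering_sets_ntc_median_to_zero(self, toy_library):
        c = self.counts([10, 20, 30, 40, 50, 60], [60, 50, 40, 30, 20, 10], toy_library)
        phen = ss.compute_phenotypes(c, toy_library, center_on_ntc=True)
        ntc_eps = phen.loc[phen["is_ntc"], "epsilon"]
        assert abs(np.median(ntc_eps)) < 1e-12

    def test_bad_pseudocount_and_missing_ntc_errors(self, toy_library):
        c = self.counts([1] * 6, [1] * 6, toy_library)
        with pytest.raises(ValidationError):
            ss.compute_phenotypes(c, toy_library, pseudocount=0.0)
        no_ntc = toy_library.assign(is_ntc=False)
        with pytest.raises(ValidationError):
            ss.compute_phenotypes(c, no_ntc, center_on_ntc=True)

    def test_min_count_filter_drops_sgrnas(self, toy_library):
        c = self.counts([10, 0, 30, 40, 50, 60], [10, 5, 30, 40, 50, 60], toy_library)
        phen = ss.compute_phenotypes(c, toy_library, min_count=1)
        assert "g1_sg2" not in set(phen["sgrna_id"])
        assert len(phen) == 5


class TestGenePvalue:
    def test_all_tied_returns_one(self):
        assert ss.gene_pvalue([1.0, 1.0], [1.0, 1.0, 1.0]) == 1.0

    def test_complete_separation_matches_counting_argument(self):
        # 5 gene values above 20 NTC values: the two-sided exact p is
        # 2 / C(25,5) = 2/53130, since only the observed assignment and its
        # mirror are as extreme.
        gene = np.arange(21.0, 26.0)
        ntc = np.arange(1.0, 21.0)
        p = ss.gene_pvalue(gene, ntc, mode="exact")
        assert p == pytest.approx(2 / 53130, abs=1e-15)

    @pytest.mark.parametrize("case", range(20))
    def test_exact_matches_enumeration(self, case):
        rng = np.random.default_rng(100 + case)
        n, m = rng.integers(1, 7), rng.integers(2, 13)
        gene = rng.normal(size=n)
        ntc = rng.normal(size=m)
        p = ss.gene_pvalue(gene, ntc, mode="exact")
        assert p == pytest.approx(mwu_enumeration_pvalue(gene, ntc), abs=1e-12)

    def test_auto_mode_falls_back_on_ties(self):
        gene = np.array([1.0, 2.0, 3.0])
        ntc = np.array([1.0, 4.0, 5.0, 6.0])  # tie with gene value
        p = ss.gene_pvalue(gene, ntc, mode="auto")  # must not raise
        assert 0 < p <= 1

    def test_input_contracts(self):
        with pytest.raises(ValidationError):
            ss.gene_pvalue([], [1.0, 2.0])
        with pytest.raises(ValidationError):
            ss.gene_pvalue([1.0], [2.0])


class TestQuasiGenes:
    def test_printed_library_ntc_count_yields_379_groups(self):
        ids = [f"ntc_{i}" for i in range(1895)]
        qs = ss.build_quasi_genes(ids, m=5, seed=0)
        assert len(qs) == 379
        assert qs.leftover == ()

    def test_floor_division_with_leftover(self):
        qs = ss.build_quasi_genes([f"n{i}" for i in range(12)], m=5, seed=1)
        assert len(qs) == 2
        assert len(qs.leftover) == 2

    def test_same_seed_identical_and_disjoint(self):
        ids = [f"n{i}" for i in range(40)]
        a = ss.build_quasi_genes(ids, m=5, seed=7)
        b = ss.build_quasi_genes(ids, m=5, seed=7)
        assert a.groups == b.groups
        flat = [sg for grp in a.groups for sg in grp]
        assert len(flat) == len(set(flat))

    def test_too_few_ntcs_error(self):
        with pytest.raises(ValidationError):
            ss.build_quasi_genes(["a", "b"], m=5, seed=0)


class TestScoreGenes:
    def make_phen(self):
        eps = {}
        rng = np.random.default_rng(5)
        for i, e in enumerate([3.0, -1.0, 0.5, 0.2, 0.1]):
            eps[f"gA_sg{i}"] = ("GA", False, e)
        for i in range(5):
            eps[f"gZ_sg{i}"] = ("GZ", False, 0.0)
        for i in range(20):
            eps[f"ntc_{i}"] = ("NTC", True, float(rng.normal(0, 0.3)))
        return phen_table(eps)

    def quasi_for(self, phen, m=5, seed=3):
        ntc_ids = sorted(phen.loc[phen["is_ntc"], "sgrna_id"])
        return ss.build_quasi_genes(ntc_ids, m=m, seed=seed)

    def test_top3_aggregation_definition(self):
        phen = self.make_phen()
        genes, _ = ss.score_genes(phen, self.quasi_for(phen))
        ga = genes.set_index("gene").loc["GA"]
        assert ga["phenotype"] == pytest.approx(np.mean([3.0, -1.0, 0.5]), abs=1e-12)

    def test_zero_epsilon_gene_has_zero_score(self):
        phen = self.make_phen()
        genes, _ = ss.score_genes(phen, self.quasi_for(phen))
        gz = genes.set_index("gene").loc["GZ"]
        assert gz["phenotype"] == 0.0
        assert gz["score"] == 0.0

    def test_mean_all_aggregation(self):
        phen = self.make_phen()
        genes, _ = ss.score_genes(phen, self.quasi_for(phen), aggregation="mean_all")
        ga = genes.set_index("gene").loc["GA"]
        assert ga["phenotype"] == pytest.approx(np.mean([3.0, -1.0, 0.5, 0.2, 0.1]))

    def test_quasi_scored_identically_to_genes(self):
        # relabeling each quasi group's members as a gene, while keeping the
        # full NTC population, must reproduce the quasi table row for row
        phen = self.make_phen()
        quasi = self.quasi_for(phen)
        _, quasi_df = ss.score_genes(phen, quasi)
        eps_map = dict(zip(phen["sgrna_id"], phen["epsilon"]))
        extra = []
        for i, members in enumerate(quasi.groups):
            for sg in members:
                extra.append((f"dup_{sg}", f"quasi_lib0_{i:04d}", False, "lib0", eps_map[sg]))
        relabeled = pd.concat(
            [phen, pd.DataFrame(extra, columns=phen.columns)], ignore_index=True
        )
        genes2, _ = ss.score_genes(relabeled, quasi)
        asgenes = genes2[genes2["gene"].str.startswith("quasi_")].reset_index(drop=True)
        merged = asgenes.merge(quasi_df, on="gene", suffixes=("_g", "_q"))
        assert len(merged) == len(quasi_df)
        for col in ("phenotype", "p_value", "score"):
            assert np.allclose(merged[f"{col}_g"], merged[f"{col}_q"], atol=1e-12)

    def test_single_sgrna_gene_is_low_confidence_p1(self):
        phen = self.make_phen()
        extra = phen_table({"solo_sg1": ("SOLO", False, 2.0)})
        phen = pd.concat([phen, extra], ignore_index=True)
        genes, _ = ss.score_genes(phen, self.quasi_for(phen))
        solo = genes.set_index("gene").loc["SOLO"]
        assert solo["p_value"] == 1.0
        assert bool(solo["low_confidence"])


class TestNormalizeAndHits:
    def scored(self, gene_scores, quasi_scores):
        def tbl(scores, prefix):
            return pd.DataFrame(
                {
                    "gene": [f"{prefix}{i}" for i in range(len(scores))],
                    "sublibrary": "lib0",
                    "n_sgrnas": 5,
                    "phenotype": np.sign(scores),
                    "p_value": 0.5,
                    "score": scores,
                    "low_confidence": False,
                    "direction": np.where(np.asarray(scores) >= 0, "+", "-"),
                }
            )

        return tbl(np.asarray(gene_scores, float), "g"), tbl(
            np.asarray(quasi_scores, float), "q"
        )

    def test_quasi_norm_sd_is_one(self):
        rng = np.random.default_rng(0)
        g, q = self.scored(rng.normal(size=50), rng.normal(size=30))
        gn, qn, sigmas = ss.normalize_scores(g, q)
        assert qn["norm_score"].std(ddof=1) == pytest.approx(1.0, abs=1e-12)
        assert sigmas["lib0"] == pytest.approx(q["score"].std(ddof=1))

    def test_doubling_scores_leaves_norm_scores_unchanged(self):
        rng = np.random.default_rng(1)
        g, q = self.scored(rng.normal(size=50), rng.normal(size=30))
        gn1, _, _ = ss.normalize_scores(g, q)
        gn2, _, _ = ss.normalize_scores(
            g.assign(score=g["score"] * 2), q.assign(score=q["score"] * 2)
        )
        assert np.allclose(gn1["norm_score"], gn2["norm_score"], atol=1e-12)

    def test_degenerate_null_errors(self):
        g, q = self.scored([1.0, 2.0], [0.5, 0.5, 0.5])
        with pytest.raises(DegenerateStatisticError):
            ss.normalize_scores(g, q)
        g, q = self.scored([1.0], [0.5])
        with pytest.raises(ValidationError):
            ss.normalize_scores(g, q)

    def test_separated_distributions_make_every_gene_a_hit(self):
        g, q = self.scored([10.0, 12.0, -15.0, 11.0], [0.1, -0.2, 0.3, -0.1, 0.2])
        gn, qn, _ = ss.normalize_scores(g, q)
        hits, _, record = ss.call_hits(gn, qn, alpha=0.05)
        assert hits["is_hit"].all()
        sub = record["sublibraries"]["lib0"]
        curve = pd.DataFrame(sub["fdr_curve"])
        assert curve.loc[curve["threshold"] == sub["threshold"], "fdr_hat"].iloc[0] == 0.0

    def test_gene_table_equal_to_quasi_table_yields_no_hits(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=40)
        g, q = self.scored(scores, scores)
        gn, qn, _ = ss.normalize_scores(g, q)
        hits, _, _ = ss.call_hits(gn, qn, alpha=0.05)
        assert int(hits["is_hit"].sum()) == 0

    def test_alpha_zero_only_calls_genes_beyond_quasi_max(self):
        g, q = self.scored([0.5, 3.0, 10.0], [1.0, -2.0, 1.5, 0.3, -0.7])
        gn, qn, _ = ss.normalize_scores(g, q)
        hits, _, _ = ss.call_hits(gn, qn, alpha=0.0)
        quasi_max = qn["norm_score"].abs().max()
        assert (hits.loc[hits["is_hit"], "norm_score"].abs() > quasi_max).all()

    def test_requires_norm_scores(self):
        g, q = self.scored([1.0, 2.0], [0.5, 0.6, 0.7])
        with pytest.raises(ValidationError):
            ss.call_hits(g, q)


class TestSymmetryAndDeterminism:
    def test_negating_epsilons_negates_scores_keeps_pvalues(self):
        rng = np.random.default_rng(9)
        eps = {}
        for g in range(6):
            for j in range(5):
                eps[f"g{g}_sg{j}"] = (f"G{g}", False, float(rng.normal()))
        for i in range(25):
            eps[f"ntc_{i}"] = ("NTC", True, float(rng.normal()))
        phen = phen_table(eps)
        neg = phen.assign(epsilon=-phen["epsilon"])
        quasi = ss.build_quasi_genes(sorted(k for k in eps if k.startswith("ntc")), 5, 4)
        g1, q1 = ss.score_genes(phen, quasi)
        g2, q2 = ss.score_genes(neg, quasi)
        assert np.allclose(g1["phenotype"], -g2["phenotype"], atol=1e-12)
        assert np.allclose(g1["p_value"], g2["p_value"], atol=1e-12)
        gn1, _, _ = ss.normalize_scores(g1, q1)
        gn2, _, _ = ss.normalize_scores(g2, q2)
        assert np.allclose(gn1["norm_score"], -gn2["norm_score"], atol=1e-12)

    def test_score_screen_is_deterministic(self, small_screen):
        library, counts, _, result = small_screen
        again = ss.score_screen(counts, library, seed=small_sim_params().seed)
        pd.testing.assert_frame_equal(result.genes, again.genes)
        pd.testing.assert_frame_equal(result.quasi, again.quasi)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_depth_invariance_property(self, scale_seed):
        # scaling either bin by any positive constant leaves epsilon unchanged
        rng = np.random.default_rng(scale_seed)
        lib = pd.DataFrame(
            {
                "sgrna_id": [f"s{i}" for i in range(8)],
                "protospacer": [f"A{i:02d}".replace("0", "C").replace("1", "G")[:3] for i in range(8)],
                "target_gene": ["G1"] * 4 + ["NTC"] * 4,
                "is_ntc": [False] * 4 + [True] * 4,
                "sublibrary": ["lib0"] * 8,
            }
        )
        low = rng.integers(0, 500, size=8)
        high = rng.integers(0, 500, size=8)
        c1 = pd.DataFrame({"sgrna_id": lib["sgrna_id"], "count_low": low, "count_high": high})
        lam = int(rng.integers(2, 11))
        c2 = c1.assign(count_high=c1.count_high * lam)
        if c1.count_low.sum() == 0 or c1.count_high.sum() == 0:
            return
        p1 = ss.compute_phenotypes(c1, lib)
        p2 = ss.compute_phenotypes(c2, lib)
        assert np.allclose(p1["epsilon"], p2["epsilon"], rtol=1e-9, atol=1e-9)


class TestCombineSublibraries:
    def two_sublib_results(self):
        rng = np.random.default_rng(3)

        def result(sub, genes):
            g = pd.DataFrame(
                {
                    "gene": genes,
                    "sublibrary": sub,
                    "n_sgrnas": 5,
                    "phenotype": rng.normal(size=len(genes)),
                    "p_value": rng.uniform(0.001, 1, size=len(genes)),
                    "score": rng.normal(size=len(genes)),
                    "low_confidence": False,
                    "direction": "+",
                }
            )
            q = g.copy().assign(gene=[f"quasi_{sub}_{i}" for i in range(len(genes))])
            gn, qn, _ = ss.normalize_scores(g, q)
            gn, qn, _ = ss.call_hits(gn, qn, alpha=0.2)
            return ss.ScreenResult(screen_id="s", genes=gn, quasi=qn, params={})

        a = result("libA", [f"A{i}" for i in range(10)])
        b = result("libB", [f"B{i}" for i in range(10)])
        return a, b

    def test_concatenation_and_preserved_norm_sd(self):
        a, b = self.two_sublib_results()
        combined = ss.combine_sublibraries([a, b])
        assert len(combined.genes) == 20
        for sub in ("libA", "libB"):
            q = combined.quasi[combined.quasi["sublibrary"] == sub]
            assert q["norm_score"].std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_overlapping_genes_error(self):
        a, b = self.two_sublib_results()
        b.genes.loc[0, "gene"] = a.genes["gene"].iloc[0]
        with pytest.raises(ValidationError):
            ss.combine_sublibraries([a, b])

    def test_combining_commutes_with_hit_filtering(self):
        a, b = self.two_sublib_results()
        combined = ss.combine_sublibraries([a, b])
        filtered_after = set(combined.genes.loc[combined.genes["is_hit"], "gene"])
        filtered_before = set(a.genes.loc[a.genes["is_hit"], "gene"]) | set(
            b.genes.loc[b.genes["is_hit"], "gene"]
        )
        assert filtered_after == filtered_before
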