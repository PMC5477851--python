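"""GSEA: ranking metric, running-sum enrichment score against a
brute-force oracle, permutation statistics and GMT handling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import centrosurv as cs
from centrosurv.enrichment import GeneSet, signal_to_noise, write_gmt


def brute_force_es(genes, metric, members, weight_p):
    """Position-by-position running sum, written independently."""
    hits = [g in members for g in genes]
    nr = sum(abs(m) ** weight_p for g, m in zip(genes, metric) if g in members)
    n_miss = len(genes) - sum(hits)
    running = []
    s = 0.0
    for g, m in zip(genes, metric):
        if g in members:
            # all-zero hit weights degenerate to unweighted increments
            s += (abs(m) ** weight_p / nr) if nr > 0 else 1.0 / sum(hits)
        else:
            s -= 1.0 / n_miss
        running.append(s)
    best = max(running, key=abs)
    return best


class TestStratify:
    def test_median_split_even(self, small_cohort):
        m = small_cohort.expression.iloc[:, :10]
        labels = cs.stratify_by_gene(m, None, "KIFC1", "median")
        assert (labels == "high").sum() == 5
        assert (labels == "low").sum() == 5

    def test_constant_gene_fails(self):
        m = pd.DataFrame(np.ones((1, 6)), index=["KIFC1"],
                         columns=[f"s{i}" for i in range(6)])
        with pytest.raises(ValueError, match="constant"):
            cs.stratify_by_gene(m, None, "KIFC1", "median")

    def test_survival_optimal_requires_os(self, small_cohort):
        with pytest.raises(ValueError, match="clinical"):
            cs.stratify_by_gene(small_cohort.expression, None, "KIFC1",
                                "survival_optimal")

    def test_survival_optimal_matches_cutpoint(self, small_cohort):
        labels = cs.stratify_by_gene(small_cohort.expression,
                                     small_cohort.clinical, "KIFC1",
                                     "survival_optimal")
        clin = small_cohort.clinical
        cut = cs.optimal_cutpoint(
            small_cohort.expression.loc["KIFC1"].to_numpy(),
            clin["os_months"].to_numpy(), clin["event"].to_numpy())
        expected = np.where(
            small_cohort.expression.loc["KIFC1"] > cut.threshold,
            "high", "low")
        assert (labels.to_numpy() == expected).all()


class TestRanking:
    def test_null_gene_has_zero_metric(self):
        high = np.array([[5.0, 6.0, 7.0]])
        assert signal_to_noise(high, high)[0] == 0.0

    def test_sd_floor_rule(self):
        # high (10,10): sd 0 -> floored to 0.2*10 = 2; low (0,0): sd 0,
        # mean 0 -> absolute floor 0.2; metric = 10 / 2.2
        val = signal_to_noise(np.array([[10.0, 10.0]]),
                              np.array([[0.0, 0.0]]))[0]
        assert val == pytest.approx(10.0 / 2.2)

    def test_label_reversal_negates_and_reverses(self, padded_matrix):
        labels = pd.Series(["high"] * 60 + ["low"] * 60,
                           index=padded_matrix.columns)
        a = cs.rank_genes(padded_matrix, labels)
        b = cs.rank_genes(padded_matrix, labels.map(
            {"high": "low", "low": "high"}))
        merged = a.merge(b, on="gene", suffixes=("_a", "_b"))
        np.testing.assert_allclose(merged["metric_a"], -merged["metric_b"])
        assert list(a["gene"]) == list(b["gene"])[::-1] or \
            set(a["gene"]) == set(b["gene"])

    def test_strict_deterministic_order(self, padded_matrix):
        labels = pd.Series(["high"] * 60 + ["low"] * 60,
                           index=padded_matrix.columns)
        a = cs.rank_genes(padded_matrix, labels)
        b = cs.rank_genes(padded_matrix, labels)
        pd.testing.assert_frame_equal(a, b)

    def test_small_class_fails(self, padded_matrix):
        labels = pd.Series(["high"] + ["low"] * 119,
                           index=padded_matrix.columns)
        with pytest.raises(ValueError, match="at least 2"):
            cs.rank_genes(padded_matrix, labels)


class TestEnrichmentScore:
    def test_single_member_at_top(self):
        genes = [f"g{i}" for i in range(10)]
        es, run = cs.enrichment_score(genes, np.linspace(2, -2, 10),
                                      GeneSet("s", frozenset(["g0"])),
                                      weight_p=0)
        assert es == pytest.approx(1.0)
        assert run[-1] == pytest.approx(0.0, abs=1e-12)

    def test_single_member_at_bottom(self):
        genes = [f"g{i}" for i in range(10)]
        es, _ = cs.enrichment_score(genes, np.linspace(2, -2, 10),
                                    GeneSet("s", frozenset(["g9"])),
                                    weight_p=0)
        assert es == pytest.approx(-1.0)

    def test_three_member_set_against_oracle(self):
        genes = [f"g{i}" for i in range(12)]
        metric = np.array([3.0, 2.5, 2.0, 1.0, 0.5, 0.2, -0.1, -0.5, -1.0,
                           -1.5, -2.0, -3.0])
        members = {"g1", "g2", "g7"}
        es, _ = cs.enrichment_score(genes, metric, members, weight_p=1.0)
        assert es == pytest.approx(
            brute_force_es(genes, metric, members, 1.0))

    @given(
        n=st.integers(5, 20),
        data=st.data(),
        weight_p=st.sampled_from([0.0, 1.0, 2.0]),
    )
    def test_matches_brute_force_everywhere(self, n, data, weight_p):
        genes = [f"g{i}" for i in range(n)]
        metric = np.array(data.draw(st.lists(
            st.floats(-5, 5), min_size=n, max_size=n)))
        k = data.draw(st.integers(1, n - 1))
        members = set(data.draw(st.permutations(genes))[:k])
        es, run = cs.enrichment_score(genes, metric, members, weight_p)
        assert es == pytest.approx(
            brute_force_es(genes, metric, members, weight_p), abs=1e-12)
        assert -1.0 - 1e-9 <= es <= 1.0 + 1e-9
        assert abs(run[-1]) < 1e-9

    def test_full_coverage_set_fails(self):
        genes = ["a", "b"]
        with pytest.raises(ValueError, match="entire"):
            cs.enrichment_score(genes, [1.0, -1.0], {"a", "b"})

    def test_disjoint_set_fails(self):
        with pytest.raises(ValueError, match="no member"):
            cs.enrichment_score(["a", "b"], [1.0, -1.0], {"zzz"})


@pytest.fixture(scope="module")
def gsea_inputs(padded_matrix, small_cohort):
    labels = cs.stratify_by_gene(padded_matrix, small_cohort.clinical,
                                 "KIFC1", "median")
    sets = [
        GeneSet("ca_block", frozenset(
            ["CCNA2", "NEK2", "E2F1", "CDK1", "E2F2", "AURKA"])),
        GeneSet("noise", frozenset([f"RND{i:03d}" for i in range(12)])),
    ]
    return padded_matrix, labels, sets


class TestGSEAPermutation:
    def test_planted_block_enriched(self, gsea_inputs):
        matrix, labels, sets = gsea_inputs
        res = cs.gsea(matrix, labels, sets, n_permutations=200, seed=0)
        row = res.set_index("set_name").loc["ca_block"]
        assert row["es"] > 0
        assert row["p_nominal"] < 0.05
        assert row["fdr_q"] < 0.25
        assert row["significant"]

    def test_deterministic_under_seed(self, gsea_inputs):
        matrix, labels, sets = gsea_inputs
        a = cs.gsea(matrix, labels, sets, n_permutations=120, seed=42)
        b = cs.gsea(matrix, labels, sets, n_permutations=120, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_label_swap_negates_es(self, gsea_inputs):
        matrix, labels, sets = gsea_inputs
        swapped = labels.map({"high": "low", "low": "high"})
        a = cs.gsea(matrix, labels, sets, n_permutations=100, seed=1)
        b = cs.gsea(matrix, swapped, sets, n_permutations=100, seed=1)
        merged = a.merge(b, on="set_name", suffixes=("_a", "_b"))
        np.testing.assert_allclose(merged["es_a"], -merged["es_b"], atol=1e-12)

    def test_small_permutation_count_warns(self, gsea_inputs):
        matrix, labels, sets = gsea_inputs
        with pytest.warns(UserWarning, match="coarse"):
            cs.gsea(matrix, labels, sets[:1], n_permutations=50, seed=0)

    def test_empty_collection_fails(self, gsea_inputs):
        matrix, labels, _ = gsea_inputs
        with pytest.raises(ValueError, match="no gene sets"):
            cs.gsea(matrix, labels, [], n_permutations=100)


class TestGMT:
    def test_round_trip(self, tmp_path):
        sets = [GeneSet("centrosome", frozenset(["PLK4", "CETN2"]), "desc"),
                GeneSet("cycle", frozenset(["CDK1", "CCNA2", "CCNE1"]))]
        path = tmp_path / "sets.gmt"
        write_gmt(path, sets)
        back = cs.read_gmt(path)
        assert {s.name: s.members for s in back} == \
            {s.name: s.members for s in sets}

    def test_short_line_fails(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("only_name\tdesc\n")
        with pytest.raises(ValueError, match="line 1"):
            cs.read_gmt(path)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            GeneSet("empty", frozenset())
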