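"""Enrichment statistics against brute-force oracles, plus their invariants."""

import numpy as np
import pandas as pd
import pytest

from basalshift.enrichment import (
    EnrichmentParams,
    delta_paired_scores,
    gsva_scores,
    kernel_cdf_stat,
    ssgsea_scores,
    stratify_quartiles,
)
from basalshift.io_formats import GeneSet
from conftest import make_matrix
from _oracles import brute_gsva, brute_kernel, brute_ssgsea


def random_set(rng, genes, m):
    return GeneSet.from_iterable("S", sorted(rng.choice(genes, size=m, replace=False)))


class TestKernelCdf:
    def test_constant_gene_is_half(self):
        m = make_matrix([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]])
        z = kernel_cdf_stat(m)
        np.testing.assert_allclose(z.iloc[0], 0.5)

    def test_two_sample_antisymmetry(self):
        m = make_matrix([[1.0, 4.0]])
        z = kernel_cdf_stat(m)
        assert z.iloc[0, 0] < 0.5 < z.iloc[0, 1]
        np.testing.assert_allclose(z.iloc[0, 0] + z.iloc[0, 1], 1.0, atol=1e-12)

    def test_matches_double_loop_oracle(self, rng):
        vals = rng.normal(8, 2, size=(10, 6))
        m = make_matrix(vals)
        np.testing.assert_allclose(
            kernel_cdf_stat(m).to_numpy(), brute_kernel(vals), atol=1e-12
        )

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            kernel_cdf_stat(make_matrix([[1.0]]))


class TestGsvaScores:
    @pytest.mark.parametrize("mode", ["magnitude_difference", "max_deviation"])
    def test_matches_walk_oracle(self, mode, rng):
        for _ in range(10):
            p, n = int(rng.integers(8, 21)), int(rng.integers(2, 6))
            genes = [f"g{i:02d}" for i in range(p)]
            vals = rng.normal(8, 2, size=(p, n))
            m = make_matrix(vals, genes=genes)
            sg = set(rng.choice(genes, size=4, replace=False))
            gs = GeneSet.from_iterable("S", sorted(sg))
            mine = gsva_scores(m, [gs], EnrichmentParams(mode=mode)).scores["S"].to_numpy()
            oracle = brute_gsva(vals, genes, sg, mode=mode)
            np.testing.assert_allclose(mine, oracle, atol=1e-12)

    def test_top_ranked_set_positive_bottom_negative(self):
        # one sample dominated by the first 3 genes, the other by the last 3
        vals = np.array([[10.0, 1.0], [9.0, 2.0], [8.0, 3.0], [3.0, 8.0], [2.0, 9.0], [1.0, 10.0]])
        m = make_matrix(vals)
        gs = GeneSet.from_iterable("top", m.gene_ids[:3])
        scores = gsva_scores(m, [gs]).scores["top"]
        assert scores.iloc[0] > 0 > scores.iloc[1]

    def test_duplicated_sample_columns_identical(self, rng):
        vals = rng.normal(0, 1, size=(12, 3))
        vals = np.hstack([vals, vals[:, [0]]])
        m = make_matrix(vals)
        gs = random_set(rng, m.gene_ids, 4)
        scores = gsva_scores(m, [gs]).scores["S"]
        np.testing.assert_allclose(scores.iloc[0], scores.iloc[3], atol=1e-12)

    def test_gene_row_permutation_invariant(self, rng):
        vals = rng.normal(0, 1, size=(15, 4))
        genes = [f"g{i:02d}" for i in range(15)]
        m1 = make_matrix(vals, genes=genes)
        perm = rng.permutation(15)
        m2 = make_matrix(vals[perm], genes=[genes[i] for i in perm])
        gs = random_set(rng, genes, 5)
        s1 = gsva_scores(m1, [gs]).scores["S"]
        s2 = gsva_scores(m2, [gs]).scores["S"]
        np.testing.assert_allclose(s1.to_numpy(), s2.to_numpy(), atol=1e-12)

    def test_complement_antisymmetry_max_deviation(self, rng):
        # with uniform weights (tau=0) the complement's walk is the exact negation
        params = EnrichmentParams(tau=0.0, mode="max_deviation")
        for _ in range(5):
            vals = rng.normal(0, 1, size=(15, 4))
            genes = [f"g{i:02d}" for i in range(15)]
            m = make_matrix(vals, genes=genes)
            sub = sorted(rng.choice(genes, size=5, replace=False))
            comp = sorted(set(genes) - set(sub))
            a = gsva_scores(m, [GeneSet.from_iterable("A", sub)], params).scores["A"]
            b = gsva_scores(m, [GeneSet.from_iterable("B", comp)], params).scores["B"]
            np.testing.assert_allclose(a.to_numpy(), -b.to_numpy(), atol=1e-12)

    def test_monotone_in_set_expression(self, rng):
        vals = rng.normal(0, 1, size=(20, 5))
        genes = [f"g{i:02d}" for i in range(20)]
        gs = random_set(rng, genes, 5)
        base = gsva_scores(make_matrix(vals, genes=genes), [gs]).scores["S"].iloc[0]
        boosted = vals.copy()
        rows = [genes.index(g) for g in gs.genes]
        boosted[rows, 0] += 50.0
        high = gsva_scores(make_matrix(boosted, genes=genes), [gs]).scores["S"].iloc[0]
        assert high >= base

    def test_scores_bounded(self, rng):
        vals = rng.normal(0, 2, size=(30, 8))
        m = make_matrix(vals)
        gs = random_set(rng, m.gene_ids, 6)
        for mode in ("magnitude_difference", "max_deviation"):
            s = gsva_scores(m, [gs], EnrichmentParams(mode=mode)).scores["S"]
            assert (s.abs() <= 1.0 + 1e-12).all()

    def test_bad_sets_error_entries_but_others_scored(self, rng):
        m = make_matrix(rng.normal(0, 1, size=(10, 3)))
        good = random_set(rng, m.gene_ids, 3)
        absent = GeneSet.from_iterable("absent", ["nope1", "nope2"])
        full = GeneSet.from_iterable("full", m.gene_ids)
        table = gsva_scores(m, [good, absent, full])
        assert set(table.errors) == {"absent", "full"}
        assert table.scores["S"].notna().all()
        assert table.scores["absent"].isna().all()


class TestSsgsea:
    def test_matches_summation_oracle(self, rng):
        vals = rng.normal(8, 2, size=(15, 4))
        genes = [f"g{i:02d}" for i in range(15)]
        m = make_matrix(vals, genes=genes)
        sg = set(rng.choice(genes, size=4, replace=False))
        mine = ssgsea_scores(m, GeneSet.from_iterable("S", sorted(sg))).to_numpy()
        np.testing.assert_allclose(mine, brute_ssgsea(vals, genes, sg), atol=1e-12)

    def test_top_placement_is_maximal(self, rng):
        # the score with the set occupying the top m ranks beats every
        # other placement of an m-gene set in the same sample
        p, m_size = 10, 3
        genes = [f"g{i:02d}" for i in range(p)]
        vals = np.tile(np.arange(p, 0, -1, dtype=float)[:, None], (1, 2))
        vals[:, 1] += 0.01  # second column irrelevant
        mat = make_matrix(vals, genes=genes)
        top = ssgsea_scores(mat, GeneSet.from_iterable("T", genes[:m_size])).iloc[0]
        from itertools import combinations

        for combo in combinations(genes, m_size):
            s = ssgsea_scores(mat, GeneSet.from_iterable("X", combo)).iloc[0]
            assert s <= top + 1e-12

    def test_alpha_zero_uniform_weights(self, rng):
        vals = rng.normal(0, 1, size=(12, 3))
        genes = [f"g{i:02d}" for i in range(12)]
        m = make_matrix(vals, genes=genes)
        sg = sorted(rng.choice(genes, size=4, replace=False))
        got = ssgsea_scores(m, GeneSet.from_iterable("S", sg), alpha=0.0).to_numpy()
        oracle = brute_ssgsea(vals, genes, set(sg), alpha=0.0)
        np.testing.assert_allclose(got, oracle, atol=1e-12)


class TestDeltaScores:
    def ann(self, rows):
        return pd.DataFrame(rows).set_index("sample_id")

    def test_basic_subtraction(self):
        scores = pd.DataFrame({"S": [0.2, 0.6]}, index=["p1_PRI", "p1_MET"])
        ann = self.ann(
            [
                {"sample_id": "p1_PRI", "patient_id": "p1", "lesion": "primary"},
                {"sample_id": "p1_MET", "patient_id": "p1", "lesion": "metastasis"},
            ]
        )
        d = delta_paired_scores(scores, ann)
        np.testing.assert_allclose(d.loc["p1", "S"], 0.4)

    def test_identical_scores_zero(self):
        scores = pd.DataFrame({"S": [0.3, 0.3]}, index=["a", "b"])
        ann = self.ann(
            [
                {"sample_id": "a", "patient_id": "p", "lesion": "primary"},
                {"sample_id": "b", "patient_id": "p", "lesion": "metastasis"},
            ]
        )
        assert delta_paired_scores(scores, ann).loc["p", "S"] == 0.0

    def test_unpaired_patient_excluded_with_warning(self):
        scores = pd.DataFrame({"S": [0.1, 0.2, 0.9]}, index=["a", "b", "c"])
        ann = self.ann(
            [
                {"sample_id": "a", "patient_id": "p1", "lesion": "primary"},
                {"sample_id": "b", "patient_id": "p1", "lesion": "metastasis"},
                {"sample_id": "c", "patient_id": "p2", "lesion": "primary"},
            ]
        )
        with pytest.warns(UserWarning, match="unpaired"):
            d = delta_paired_scores(scores, ann)
        assert list(d.index) == ["p1"]

    def test_duplicate_lesion_is_error(self):
        scores = pd.DataFrame({"S": [0.1, 0.2, 0.3]}, index=["a", "b", "c"])
        ann = self.ann(
            [
                {"sample_id": "a", "patient_id": "p", "lesion": "primary"},
                {"sample_id": "b", "patient_id": "p", "lesion": "primary"},
                {"sample_id": "c", "patient_id": "p", "lesion": "metastasis"},
            ]
        )
        with pytest.raises(ValueError, match="duplicated lesion"):
            delta_paired_scores(scores, ann)


class TestStratifyQuartiles:
    def test_scores_one_to_eight(self):
        s = pd.Series(np.arange(1.0, 9.0), index=[f"s{i}" for i in range(8)])
        res = stratify_quartiles(s)
        assert set(res.low) == {"s0", "s1"}
        assert set(res.high) == {"s6", "s7"}

    def test_degenerate_all_equal(self):
        s = pd.Series([2.0] * 6, index=list("abcdef"))
        with pytest.warns(UserWarning, match="degenerate"):
            res = stratify_quartiles(s)
        assert (res.labels == "mid").all()

    def test_uniform_draw_quartile_sizes(self, rng):
        s = pd.Series(rng.uniform(size=1000), index=[f"s{i}" for i in range(1000)])
        res = stratify_quartiles(s)
        assert abs(len(res.high) - 250) <= 1
        assert abs(len(res.low) - 250) <= 1

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            stratify_quartiles(pd.Series([1.0, 2.0, 3.0]))
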