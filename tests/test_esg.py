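"""ESG derivation, recurrence, cell-type projection, validation statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tmeniche import (
    stratify_spots,
    per_sample_esg,
    recurrent_esgs,
    celltype_niche_expression,
    validation_lfc,
    paired_lfc_test,
    geomx_score,
    overlap_test,
    normalize_st,
)

from conftest import make_st_toy


class TestStratify:
    def test_hundred_spots_give_ten_and_ten(self):
        rng = np.random.default_rng(0)
        high, low = stratify_spots(rng.normal(size=100))
        assert len(high) == 10 and len(low) == 10
        assert np.intersect1d(high, low).size == 0

    def test_monotone_scores_pick_extreme_deciles(self):
        scores = np.arange(50.0)
        high, low = stratify_spots(scores)
        assert set(high) == set(range(45, 50))
        assert set(low) == set(range(5))

    def test_tiny_sample_overlap_rejected(self):
        with pytest.raises(ValueError):
            stratify_spots(np.array([1.0, 2.0, 3.0]), top=0.9, bottom=0.9)

    def test_ties_broken_by_stable_spot_order(self):
        high, low = stratify_spots(np.zeros(20))
        assert set(low) == set(range(2))
        assert set(high) == {18, 19}


class TestPerSampleESG:
    def _sample_with_de_gene(self, n_spots=100, n_genes=30, seed=1):
        rng = np.random.default_rng(seed)
        counts = rng.poisson(5, size=(n_spots, n_genes))
        counts[: n_spots // 2, 0] += 20  # G0 up in the first half
        s = make_st_toy(counts, rows=10, cols=10)
        normalize_st(s)
        return s

    def test_gene_expressed_only_in_high_selected(self):
        s = self._sample_with_de_gene()
        high = np.arange(10)
        low = np.arange(90, 100)
        assert "G0" in per_sample_esg(s, high, low)

    def test_permuted_labels_select_almost_nothing(self):
        rng = np.random.default_rng(2)
        total = 0
        n_genes = 60
        for seed in range(10):
            counts = np.random.default_rng(seed).poisson(5, size=(100, n_genes))
            s = make_st_toy(counts, rows=10, cols=10)
            normalize_st(s)
            idx = rng.permutation(100)
            total += len(per_sample_esg(s, idx[:10], idx[90:]))
        assert total / 10 <= 0.05 * n_genes * 2

    def test_minimum_spot_counts_enforced(self):
        s = self._sample_with_de_gene()
        with pytest.raises(ValueError):
            per_sample_esg(s, np.arange(3), np.arange(90, 100))


class TestRecurrent:
    def test_half_focal_and_lower_other_kept(self):
        per_sample = {f"F{i}": (["g1"] if i < 5 else []) for i in range(10)}
        per_sample |= {f"O{i}": (["g1"] if i < 2 else []) for i in range(10)}
        groups = {s: ("A" if s.startswith("F") else "B") for s in per_sample}
        esg = recurrent_esgs(per_sample, groups, "A")
        assert esg.recurrent == ["g1"]  # 5/10 vs 2/10

    def test_equal_fractions_dropped(self):
        per_sample = {f"F{i}": ["g1"] for i in range(5)} | {
            f"O{i}": ["g1"] for i in range(5)
        }
        groups = {s: ("A" if s.startswith("F") else "B") for s in per_sample}
        assert recurrent_esgs(per_sample, groups, "A").recurrent == []

    def test_matches_enumeration_oracle_on_random_tables(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(15)]
        for _ in range(20):
            per_sample = {
                f"S{i}": [g for g in genes if rng.random() < 0.4] for i in range(12)
            }
            groups = {f"S{i}": ("A" if i < 6 else "B") for i in range(12)}
            esg = recurrent_esgs(per_sample, groups, "A")
            oracle = []
            for g in genes:
                fa = sum(g in per_sample[f"S{i}"] for i in range(6)) / 6
                fb = sum(g in per_sample[f"S{i}"] for i in range(6, 12)) / 6
                if fa >= 0.5 and fa > fb:
                    oracle.append(g)
            assert esg.recurrent == sorted(oracle)

    def test_opposite_focal_groups_are_disjoint(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(10)]
        per_sample = {
            f"S{i}": [g for g in genes if rng.random() < 0.5] for i in range(10)
        }
        groups = {f"S{i}": ("A" if i < 5 else "B") for i in range(10)}
        ra = set(recurrent_esgs(per_sample, groups, "A").recurrent)
        rb = set(recurrent_esgs(per_sample, groups, "B").recurrent)
        assert not (ra & rb)


class TestCellTypeProjection:
    def _toy(self):
        # 4 spots x 3 genes; niche = first 2 spots
        counts = np.array(
            [[8, 2, 4], [6, 2, 4], [2, 2, 4], [0, 2, 4]]
        )
        s = make_st_toy(counts, rows=2, cols=2)
        normalize_st(s, target_sum=None)
        ref = pd.DataFrame(
            {"CT1": [2.0, 1.0, 1.0], "CT2": [0.5, 3.0, 1.0]},
            index=["G0", "G1", "G2"],
        )
        return s, ref

    def test_hand_oracle_on_four_spot_toy(self):
        s, ref = self._toy()
        niche = np.array([0, 1])
        res = celltype_niche_expression(["G0", "G1"], ref, s, niche)
        E = np.asarray(s.adata.layers["lognorm"])
        for gi, g in enumerate(["G0", "G1"]):
            v_hand = E[:2, gi].mean() - E[:, gi].mean()
            assert res.v[g] == pytest.approx(v_hand, abs=1e-12)
            for ct in ("CT1", "CT2"):
                assert res.matrix.loc[g, ct] == pytest.approx(
                    ref.loc[g, ct] * v_hand, abs=1e-12
                )

    def test_niche_equal_to_background_gives_zero(self):
        s, ref = self._toy()
        res = celltype_niche_expression(["G1", "G2"], ref, s, np.arange(4))
        assert np.allclose(res.matrix.to_numpy(), 0.0, atol=1e-12)

    def test_linearity_in_reference(self):
        s, ref = self._toy()
        niche = np.array([0, 1])
        r1 = celltype_niche_expression(["G0"], ref, s, niche)
        r2 = celltype_niche_expression(["G0"], 2.0 * ref, s, niche)
        np.testing.assert_allclose(
            r2.matrix.to_numpy(), 2.0 * r1.matrix.to_numpy(), atol=1e-12
        )

    def test_missing_reference_gene_omitted(self):
        s, ref = self._toy()
        res = celltype_niche_expression(["G0", "NOPE"], ref, s, np.array([0, 1]))
        assert res.omitted == ["NOPE"]
        assert list(res.matrix.index) == ["G0"]


class TestValidationLFC:
    def test_double_mean_gives_unit_lfc(self):
        # high mean 4, low mean 2 on the normalized layer -> log2(2) = 1
        counts = np.zeros((20, 2), int)
        counts[:, 1] = 10  # equal library sizes via the second gene
        counts[:10, 0] = 4
        counts[10:, 0] = 2
        s = make_st_toy(counts, rows=4, cols=5)
        s.adata.layers["lognorm"] = s.adata.X.toarray().astype(float)
        lfc = validation_lfc(s, np.arange(10), np.arange(10, 20), ["G0"])
        assert lfc["G0"] == pytest.approx(1.0, abs=1e-6)

    def test_equal_means_give_zero(self):
        counts = np.full((20, 2), 3)
        s = make_st_toy(counts, rows=4, cols=5)
        s.adata.layers["lognorm"] = s.adata.X.toarray().astype(float)
        lfc = validation_lfc(s, np.arange(10), np.arange(10, 20), ["G0", "G1"])
        assert np.allclose(lfc, 0.0)

    def test_swapping_high_low_negates_lfc(self):
        rng = np.random.default_rng(5)
        s = make_st_toy(rng.poisson(6, size=(20, 4)), rows=4, cols=5)
        normalize_st(s)
        hi, lo = np.arange(10), np.arange(10, 20)
        genes = [f"G{j}" for j in range(4)]
        a = validation_lfc(s, hi, lo, genes)
        b = validation_lfc(s, lo, hi, genes)
        np.testing.assert_allclose(a.to_numpy(), -b.to_numpy(), atol=1e-9)

    def test_paired_test_detects_planted_shift(self):
        rng = np.random.default_rng(6)
        hits = 0
        for _ in range(50):
            genes = [f"g{i}" for i in range(10)]
            lfc = pd.DataFrame(
                {
                    "SA1": rng.normal(0.5, 0.3, 10),
                    "SA2": rng.normal(0.5, 0.3, 10),
                    "SB1": rng.normal(0.0, 0.3, 10),
                    "SB2": rng.normal(0.0, 0.3, 10),
                },
                index=genes,
            )
            groups = {"SA1": "A", "SA2": "A", "SB1": "B", "SB2": "B"}
            _, p = paired_lfc_test(lfc, groups, "A")
            hits += p < 0.05
        assert hits >= 45


class TestGeomx:
    def test_singleton_geneset_returns_that_gene(self):
        expr = pd.DataFrame(
            {"g1": [1.0, 2.0], "g2": [5.0, 7.0]}, index=["roi1", "roi2"]
        )
        scores = geomx_score(expr, ["g2"])
        assert scores.tolist() == [5.0, 7.0]

    def test_all_zero_gene_leaves_scores_unchanged(self):
        expr = pd.DataFrame(
            {"g1": [1.0, 2.0], "gz": [0.0, 0.0]}, index=["roi1", "roi2"]
        )
        np.testing.assert_allclose(
            geomx_score(expr, ["g1", "gz"]), geomx_score(expr, ["g1"])
        )

    def test_empty_overlap_rejected(self):
        expr = pd.DataFrame({"g1": [1.0]}, index=["roi1"])
        with pytest.raises(ValueError):
            geomx_score(expr, ["nope"])


class TestOverlap:
    def test_matches_direct_tail_summation(self):
        k, p = overlap_test([f"a{i}" for i in range(20)] , [], 1000)
        # build sets with overlap exactly 5
        A = [f"x{i}" for i in range(20)]
        B = A[:5] + [f"y{i}" for i in range(25)]
        k, p = overlap_test(A, B, 1000)
        assert k == 5
        hand = sum(
            math.comb(20, j) * math.comb(980, 30 - j) / math.comb(1000, 30)
            for j in range(5, 21)
        )
        assert p == pytest.approx(hand, rel=1e-9)

    def test_disjoint_sets_in_huge_universe_near_one(self):
        _, p = overlap_test(["a"], ["b"], 10000)
        assert p > 0.99

    def test_identical_sets_give_minimal_p(self):
        A = [f"a{i}" for i in range(5)]
        k, p = overlap_test(A, A, 100)
        assert k == 5
        assert p == pytest.approx(stats.hypergeom.pmf(5, 100, 5, 5), rel=1e-9)

    def test_universe_smaller_than_set_rejected(self):
        with pytest.raises(ValueError):
            overlap_test(list("abcdef"), ["a"], 3)
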