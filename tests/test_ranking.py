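"""Co-expression measures and the composite a*b*c candidate score."""

import numpy as np
import pandas as pd
import pytest

from seedcoex import (DatasetSpec, ScoringConfig, bait_hrr, bait_pearson,
                      composite_rank, concordance_a, down_in_sl_flags,
                      expression_c, intensity_b, score_candidates)

from conftest import design, make_matrix


def atlas_matrix(log2_rows, n_genes=None):
    """Matrix from log2 rows with generic atlas-style sample metadata."""
    log2_rows = np.asarray(log2_rows, float)
    metas = design(varieties=(("A", "SD"),), stages=("S1",),
                   replicates=log2_rows.shape[1])
    return make_matrix(np.exp2(log2_rows), metas)


class TestBaitPearson:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        m = atlas_matrix(np.vstack([rng.normal(8, 1, 10)] * 2))
        r = bait_pearson(m, "g0")
        assert r["g1"] == pytest.approx(1.0)
        assert r["g0"] == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        m = atlas_matrix([[1, 2, 3, 4], [4, 3, 2, 1]])
        r = bait_pearson(m, "g0")
        assert r["g1"] == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # bait [1,3,2,4] vs gene [1,2,3,4]: sum of deviation products 4,
        # both sums of squares 5 -> r = 4/5
        m = atlas_matrix([[1, 3, 2, 4], [1, 2, 3, 4]])
        r = bait_pearson(m, "g0")
        assert r["g1"] == pytest.approx(0.8)

    def test_flat_bait_rejected(self):
        m = atlas_matrix([[5, 5, 5, 5], [1, 2, 3, 4]])
        with pytest.raises(ValueError, match="variance"):
            bait_pearson(m, "g0")

    def test_flat_gene_undefined(self):
        m = atlas_matrix([[1, 2, 3, 4], [7, 7, 7, 7]])
        r = bait_pearson(m, "g0")
        assert np.isnan(r["g1"])


def brute_force_hrr(log2, genes, bait):
    """Independent double-ranking oracle over the full correlation table."""
    C = np.corrcoef(log2)
    n = len(genes)
    bi = genes.index(bait)

    def rank_in(i, j):
        """1-based rank of gene j in gene i's descending neighbor list."""
        order = sorted((k for k in range(n) if k != i),
                       key=lambda k: (-C[i, k], genes[k]))
        return order.index(j) + 1

    out = {}
    for gi, g in enumerate(genes):
        if gi == bi:
            continue
        out[g] = max(rank_in(bi, gi), rank_in(gi, bi))
    return out


class TestBaitHRR:
    def test_reciprocal_best_pair(self):
        rng = np.random.default_rng(1)
        bait = rng.normal(8, 1, 12)
        rows = np.vstack([
            bait,
            bait + rng.normal(0, 0.05, 12),   # near-copy: mutual best
            rng.normal(8, 1, 12),
        ])
        hrr = bait_hrr(atlas_matrix(rows), "g0")
        assert hrr["g1"] == 1

    def test_definition_is_max_of_both_ranks(self):
        rng = np.random.default_rng(2)
        rows = rng.normal(8, 1, (20, 15))
        genes = [f"g{i}" for i in range(20)]
        hrr = bait_hrr(atlas_matrix(rows), "g0")
        oracle = brute_force_hrr(rows, genes, "g0")
        for g, expected in oracle.items():
            assert hrr[g] == expected

    def test_random_matrices_match_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            rows = rng.normal(8, 1, (50, 20))
            genes = [f"g{i:02d}" for i in range(50)]
            metas = design(varieties=(("A", "SD"),), stages=("S1",),
                           replicates=20)
            df = pd.DataFrame(np.exp2(rows), index=genes,
                              columns=[m.sample_id for m in metas])
            from seedcoex import ExpressionMatrix
            m = ExpressionMatrix(df, metas)
            hrr = bait_hrr(m, "g00")
            oracle = brute_force_hrr(rows, genes, "g00")
            assert all(hrr[g] == v for g, v in oracle.items())

    def test_symmetry_between_perspectives(self):
        """HRR(bait, g) computed with g as the bait equals HRR(g)."""
        rng = np.random.default_rng(4)
        rows = rng.normal(8, 1, (15, 12))
        m = atlas_matrix(rows)
        h_from_bait = bait_hrr(m, "g0")
        for g in (f"g{i}" for i in range(1, 15)):
            h_from_g = bait_hrr(m, g)
            assert h_from_g["g0"] == h_from_bait[g]


class TestComponents:
    def test_concordance_fraction(self):
        flags = pd.DataFrame(
            {"d1": [True, False, True], "d2": [True, False, False],
             "d3": [True, False, True]},
            index=["all", "none", "some"],
        )
        a = concordance_a(flags)
        assert a["all"] == 1.0
        assert a["none"] == 0.0
        assert a["some"] == pytest.approx(2 / 3)

    def test_concordance_matches_brute_tally(self):
        rng = np.random.default_rng(5)
        flags = pd.DataFrame(rng.random((50, 4)) > 0.5,
                             index=[f"g{i}" for i in range(50)],
                             columns=list("wxyz"))
        a = concordance_a(flags)
        for g in flags.index:
            assert a[g] == sum(flags.loc[g]) / 4

    def test_intensity_product(self):
        sims = pd.DataFrame({"d1": [0.9], "d2": [0.8], "d3": [0.5]},
                            index=["g"])
        assert intensity_b(sims)["g"] == pytest.approx(0.36)

    def test_intensity_zero_annihilates(self):
        sims = pd.DataFrame({"d1": [0.9], "d2": [0.0]}, index=["g"])
        assert intensity_b(sims)["g"] == 0.0

    def test_intensity_skips_absent_datasets(self):
        sims = pd.DataFrame({"d1": [0.5, np.nan], "d2": [np.nan, np.nan]},
                            index=["measured", "nowhere"])
        b = intensity_b(sims)
        assert b["measured"] == 0.5
        assert np.isnan(b["nowhere"])

    def test_expression_rank_fraction(self):
        metas = design(varieties=(("SD1", "SD"),), stages=("S1",),
                       replicates=2)
        m = make_matrix([[10.0, 10], [40, 40], [30, 30], [20, 20]], metas)
        c = expression_c(m)
        assert c["g1"] == 1.0  # highest mean
        assert c["g2"] == 0.75  # third-lowest of four

    def test_expression_scale_free(self):
        rng = np.random.default_rng(6)
        metas = design(replicates=1)
        vals = rng.lognormal(3, 1, (30, 8))
        c1 = expression_c(make_matrix(vals, metas))
        c2 = expression_c(make_matrix(vals * 37.5, metas))
        pd.testing.assert_series_equal(c1, c2)

    def test_down_in_sl_flag_rule(self):
        metas = design(replicates=1)
        # g0: SD > SL at S2,S3,S4; g1: SD > SL at S3 only; g2: never
        sd = np.array([[8, 9, 9, 9], [8, 8, 9, 8], [8, 8, 8, 8.0]])
        sl = np.array([[8, 8, 8, 8], [8, 8, 8, 8], [8, 9, 9, 9.0]])
        m = make_matrix(np.exp2(np.hstack([sd, sl])), metas)
        flags = down_in_sl_flags(m)
        assert bool(flags["g0"]) and not bool(flags["g1"])
        assert not bool(flags["g2"])


class TestCompositeRank:
    @staticmethod
    def components(scores):
        genes = [f"g{i}" for i in range(len(scores))]
        return pd.DataFrame(
            {"a": 1.0, "b": scores, "c": 1.0,
             "down_in_sl": True},
            index=genes,
        )

    def test_sort_contract(self):
        ranking = composite_rank(self.components([0.5, 0.9, 0.1]),
                                 ScoringConfig(top_k=2))
        assert list(ranking.table.index) == ["g1", "g0", "g2"]
        assert list(ranking.table["rank"]) == [1, 2, 3]
        assert ranking.top_k_ids == {"g1", "g0"}

    def test_score_tie_breaks_on_b_then_id(self):
        comp = pd.DataFrame(
            {"a": [0.5, 1.0, 1.0], "b": [1.0, 0.5, 0.5], "c": 1.0,
             "down_in_sl": True},
            index=["zz", "aa", "bb"],
        )
        ranking = composite_rank(comp, ScoringConfig())
        assert list(ranking.table.index) == ["zz", "aa", "bb"]

    def test_down_in_sl_demotion(self):
        comp = self.components([0.9, 0.5])
        comp["down_in_sl"] = [False, True]
        ranking = composite_rank(comp, ScoringConfig(require_down_in_sl=True))
        assert list(ranking.table.index) == ["g1", "g0"]

    def test_monotone_in_each_component(self):
        rng = np.random.default_rng(7)
        comp = pd.DataFrame(
            {"a": rng.choice([1 / 3, 2 / 3, 1.0], 30),
             "b": rng.uniform(0.1, 1, 30), "c": rng.uniform(0.1, 1, 30),
             "down_in_sl": True},
            index=[f"g{i:02d}" for i in range(30)],
        )
        base = composite_rank(comp, ScoringConfig())
        for col in ("a", "b", "c"):
            boosted = comp.copy()
            boosted.loc["g15", col] = min(1.0, boosted.loc["g15", col] * 1.5)
            new = composite_rank(boosted, ScoringConfig())
            assert (new.table.loc["g15", "rank"]
                    <= base.table.loc["g15", "rank"])


class TestScoreCandidates:
    def test_bait_excluded_and_a0_dropped(self, small_experiment):
        primary, aux, _, truth = small_experiment
        from seedcoex.deg import filter_negative_signals, percentile_normalize
        normalized = percentile_normalize(filter_negative_signals(primary))
        config = ScoringConfig(
            bait_id=truth.bait_id,
            datasets=[DatasetSpec("primary", "pearson"),
                      DatasetSpec("aux0", "pearson"),
                      DatasetSpec("aux1", "hrr")],
        )
        ranking = score_candidates(
            normalized, {"primary": normalized, "aux0": aux[0],
                         "aux1": aux[1]}, config,
        )
        assert truth.bait_id not in ranking.table.index
        assert (ranking.table["a"] > 0).all()
        assert (ranking.table["score"]
                == ranking.table["a"] * ranking.table["b"]
                * ranking.table["c"]).all()

    def test_end_to_end_matches_brute_force_recomputation(
            self, small_experiment):
        """Top-K membership equals an independent recomputation of every
        component followed by the same sort."""
        primary, aux, _, truth = small_experiment
        from seedcoex.deg import filter_negative_signals, percentile_normalize
        normalized = percentile_normalize(filter_negative_signals(primary))
        config = ScoringConfig(
            bait_id=truth.bait_id, top_k=30,
            datasets=[DatasetSpec("primary", "pearson"),
                      DatasetSpec("aux0", "pearson"),
                      DatasetSpec("aux1", "hrr")],
        )
        mats = {"primary": normalized, "aux0": aux[0], "aux1": aux[1]}
        ranking = score_candidates(normalized, mats, config)

        # oracle: recompute each piece with plain pandas/numpy calls
        r_prim = bait_pearson(normalized, truth.bait_id)
        r_aux0 = bait_pearson(aux[0], truth.bait_id)
        hrr1 = bait_hrr(aux[1], truth.bait_id)
        rows = {}
        log2p = normalized.values
        means = log2p.mean(axis=1)
        c_ranks = means.rank() / len(means)
        for g in normalized.gene_ids:
            if g == truth.bait_id:
                continue
            flags = [r_prim[g] >= 0.6, r_aux0[g] >= 0.6, hrr1[g] <= 100]
            a = sum(bool(f) for f in flags) / 3
            if a == 0:
                continue
            sims = [abs(r_prim[g]), abs(r_aux0[g]), 1 / hrr1[g]]
            b = np.prod([s for s in sims if not np.isnan(s)])
            rows[g] = (a, b, a * b * c_ranks[g])
        order = sorted(rows, key=lambda g: (-rows[g][2], -rows[g][1], g))
        assert list(ranking.table.index) == order
        assert ranking.top_k_ids == set(order[:30])
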