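import numpy as np
import pandas as pd
import pytest

from lncm6a import (
    call_associations,
    enrichment_score,
    permutation_p,
    rank_by_drug,
)
from lncm6a.core_io import ExpressionMatrix
from lncm6a.gsea import RankedGeneList

from conftest import naive_enrichment_walk


def _list(metrics, genes=None, drug="d"):
    genes = genes or [f"g{i + 1}" for i in range(len(metrics))]
    return RankedGeneList(
        genes=tuple(genes), metric=np.asarray(metrics, float), drug_id=drug
    )


L4 = _list([4.0, 3.0, 2.0, 1.0])


class TestEnrichmentScore:
    @pytest.mark.parametrize(
        "S, expected",
        [({"g1"}, 1.0), ({"g4"}, -1.0), ({"g2"}, 2 / 3)],
    )
    def test_hand_walks(self, S, expected):
        es, _ = enrichment_score(L4, S)
        assert es == pytest.approx(expected, abs=1e-12)

    def test_whole_list_set_rejected(self):
        with pytest.raises(ValueError):
            enrichment_score(L4, {"g1", "g2", "g3", "g4"})

    def test_empty_or_disjoint_set_rejected(self):
        with pytest.raises(ValueError):
            enrichment_score(L4, {"not_there"})

    def test_zero_hit_weight_rejected(self):
        L = _list([1.0, 1.0, 0.0])
        with pytest.raises(ValueError, match="N_R"):
            enrichment_score(L, {"g3"})

    def test_walk_ends_at_zero(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(5, 50))
            L = _list(np.sort(rng.standard_normal(n))[::-1])
            k = int(rng.integers(1, n))
            S = set(rng.choice(L.genes, size=k, replace=False))
            _, walk = enrichment_score(L, S)
            assert abs(walk[-1]) < 1e-12

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(300):
            n = int(rng.integers(5, 50))
            metrics = np.sort(rng.standard_normal(n))[::-1]
            L = _list(metrics)
            k = int(rng.integers(1, n))
            S = set(rng.choice(L.genes, size=k, replace=False))
            hit = [g in S for g in L.genes]
            es, walk = enrichment_score(L, S)
            es_ref, walk_ref = naive_enrichment_walk(metrics, hit)
            assert es == pytest.approx(es_ref, abs=1e-12)
            np.testing.assert_allclose(walk, walk_ref, atol=1e-12)


class TestPermutationP:
    def test_exact_enumeration_single_hit_top(self):
        # only permuted sets equal to {g1} reach |es| = 1 with positive sign
        n = 10
        L = _list(list(range(n, 0, -1)))
        B = 4000
        es, p = permutation_p(L, {"g1"}, B=B, seed=7)
        assert es == 1.0
        # null draws {g1} with prob 1/n; conditioning on positive sign
        # cannot push p beyond ~2/n; check broad binomial bounds
        assert 1 / (B + 1) < p < 4 / n

    def test_same_seed_reproducible(self):
        _, p1 = permutation_p(L4, {"g2"}, B=50, seed=3)
        _, p2 = permutation_p(L4, {"g2"}, B=50, seed=3)
        assert p1 == p2

    def test_b1_attains_two_values(self):
        ps = {permutation_p(L4, {"g1"}, B=1, seed=s)[1] for s in range(30)}
        assert ps <= {1 / 2, 1.0}

    def test_b_zero_rejected(self):
        with pytest.raises(ValueError):
            permutation_p(L4, {"g1"}, B=0)

    def test_lower_bound(self):
        for s in range(5):
            _, p = permutation_p(L4, {"g1"}, B=100, seed=s)
            assert p >= 1 / 101


class TestRankByDrug:
    def _expr(self, rows, samples):
        values = pd.DataFrame(
            rows, index=[f"g{i}" for i in range(len(rows))], columns=samples
        )
        roles = pd.Series({g: "mRNA" for g in values.index})
        return ExpressionMatrix(values, roles, transformed=True)

    def test_perfect_correlates_rank_ends(self):
        samples = [f"s{i}" for i in range(6)]
        ic = pd.Series([1.0, 2, 3, 4, 5, 6], index=samples)
        expr = self._expr(
            [[1, 2, 3, 4, 5, 6], [6, 5, 4, 3, 2, 1], [2, 1, 2, 1, 2, 1]],
            samples,
        )
        L = rank_by_drug(expr, ic)
        assert L.genes[0] == "g0" and L.metric[0] == pytest.approx(1.0)
        assert L.genes[-1] == "g1" and L.metric[-1] == pytest.approx(-1.0)

    def test_deterministic_under_gene_permutation(self):
        samples = [f"s{i}" for i in range(8)]
        rng = np.random.default_rng(5)
        rows = rng.standard_normal((6, 8))
        ic = pd.Series(rng.standard_normal(8), index=samples)
        a = rank_by_drug(self._expr(rows, samples), ic)
        perm = rng.permutation(6)
        expr_b = self._expr(rows, samples)
        expr_b.values = expr_b.values.iloc[perm]
        expr_b.roles = expr_b.roles.iloc[perm]
        b = rank_by_drug(expr_b, ic)
        assert a.genes == b.genes

    def test_missing_ic50_uses_pairwise_complete(self):
        samples = [f"s{i}" for i in range(6)]
        ic = pd.Series([1.0, 2, np.nan, 4, 5, np.nan], index=samples)
        expr = self._expr([[1, 2, 3, 4, 5, 6], [1, 1, 1, 2, 2, 2]], samples)
        L = rank_by_drug(expr, ic)
        assert L.n == 2

    def test_too_few_complete_pairs_rejected(self):
        samples = ["s0", "s1", "s2"]
        ic = pd.Series([1.0, np.nan, 3.0], index=samples)
        expr = self._expr([[1, 2, 3]], samples)
        with pytest.raises(ValueError, match="3 samples"):
            rank_by_drug(expr, ic)


class TestCallAssociations:
    def test_rule_application(self):
        df = pd.DataFrame(
            {
                "lncrna_id": ["L1", "L2", "L3"],
                "drug_id": ["d"] * 3,
                "es": [0.5, -0.5, -0.5],
                "n_hits": [5, 5, 5],
                "p_perm": [0.001, 0.8, 0.002],
            }
        )
        out = call_associations(df, q_max=0.05)
        calls = dict(zip(out["lncrna_id"], out["call"]))
        assert calls == {"L1": "resistant", "L2": "ns", "L3": "sensitive"}

    def test_call_consistent_with_sign_and_q(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {
                "lncrna_id": [f"L{i}" for i in range(50)],
                "drug_id": "d",
                "es": rng.uniform(-1, 1, 50),
                "n_hits": 5,
                "p_perm": rng.uniform(0, 1, 50),
            }
        )
        out = call_associations(df)
        for row in out.itertuples():
            if row.call == "resistant":
                assert row.es > 0 and row.q < 0.05
            elif row.call == "sensitive":
                assert row.es < 0 and row.q < 0.05
            else:
                assert row.q >= 0.05 or row.es == 0
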