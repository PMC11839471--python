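import itertools
import math

import numpy as np
import pandas as pd
import pytest

from oncopath.containers import PathwayDB
from oncopath.enrichment import (
    add_bootstrap,
    bootstrap_p_from_replicates,
    bootstrap_pathway,
    characteristic_pathways,
    combine_scores,
    fisher_enrich,
    fisher_pvalue,
)


def hypergeom_tail_oracle(k, K, n, N):
    """Exhaustive enumeration of P(X >= k) for X ~ Hypergeom(N, K, n)."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(k, min(K, n) + 1)
    ) / total


class TestFisher:
    def test_perfect_overlap(self):
        # all 5 significant genes inside a 5-gene pathway in a 10-gene universe
        assert fisher_pvalue(5, 5, 5, 10) == pytest.approx(1 / math.comb(10, 5))

    def test_zero_overlap_is_one(self):
        assert fisher_pvalue(0, 4, 3, 10) == pytest.approx(1.0)

    def test_matches_enumeration_oracle_small_universes(self):
        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(max(0, n + K - N), min(K, n) + 1):
                        assert fisher_pvalue(k, K, n, N) == pytest.approx(
                            hypergeom_tail_oracle(k, K, n, N), abs=1e-12
                        )

    def test_monotone_in_overlap(self):
        ps = [fisher_pvalue(k, 20, 30, 200) for k in range(0, 21)]
        assert all(a >= b for a, b in itertools.pairwise(ps))

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_pvalue(6, 5, 5, 10)


class TestFisherEnrich:
    def setup_method(self):
        self.db = PathwayDB(
            gene_sets={
                "P1": frozenset("ABCDE"),
                "P2": frozenset("FGHIJ"),
                "P3": frozenset("XYZ"),  # outside the universe
            }
        )
        self.universe = set("ABCDEFGHIJ")

    def test_counts_and_fdr(self):
        records = fisher_enrich(set("ABCDE"), self.universe, self.db)
        assert list(records.index) == ["P1", "P2"]  # P3 has no gene in the universe
        assert records.loc["P1", ["k", "K", "n", "N"]].tolist() == [5, 5, 5, 10]
        assert records.loc["P1", "p_fisher"] == pytest.approx(1 / 252)
        np.testing.assert_allclose(
            records["p_fdr"], np.minimum(1, records["p_fisher"] * 2 / [1, 2])[: len(records)]
        )

    def test_sig_genes_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside the universe"):
            fisher_enrich({"A", "Q"}, self.universe, self.db)

    def test_null_fdr_rate_controlled(self):
        # random significance labels: few pathways should reach FDR < 0.05
        rng = np.random.default_rng(0)
        universe = {f"G{i}" for i in range(400)}
        sets = {
            f"P{j}": frozenset(rng.choice(sorted(universe), size=20, replace=False))
            for j in range(60)
        }
        db = PathwayDB(gene_sets=sets)
        rates = []
        for rep in range(10):
            sig = set(rng.choice(sorted(universe), size=40, replace=False))
            records = fisher_enrich(sig, universe, db)
            rates.append((records["p_fdr"] < 0.05).mean())
        assert np.mean(rates) <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / (60 * 10))


class TestBootstrap:
    def test_counting_estimator(self):
        # five of 1000 replicate p values below the observed one -> 0.005
        replicates = np.concatenate([np.full(5, 1e-6), np.full(995, 0.5)])
        assert bootstrap_p_from_replicates(1e-3, replicates) == 0.005

    def test_extremes(self):
        reps = np.linspace(0.1, 0.9, 100)
        assert bootstrap_p_from_replicates(0.01, reps) == 0.0
        assert bootstrap_p_from_replicates(0.99, reps) == 1.0

    def test_seed_reproducibility(self):
        a = bootstrap_pathway(8, 20, 50, 500, n_reps=1000, rng=42)
        b = bootstrap_pathway(8, 20, 50, 500, n_reps=1000, rng=42)
        assert a == b

    def test_spread_consistent_with_binomial_sampling(self):
        # moderate-enrichment case: across seeds the bootstrap p scatters
        # around the true tail probability with ~binomial(1000) spread
        k, K, n, N = 5, 20, 50, 500
        true_tail = sum(
            hypergeom_tail_oracle(j, K, n, N) - hypergeom_tail_oracle(j + 1, K, n, N)
            for j in range(k, min(K, n) + 1)
            if fisher_pvalue(j, K, n, N) < fisher_pvalue(k, K, n, N)
        )
        values = [bootstrap_pathway(k, K, n, N, n_reps=1000, rng=s) for s in range(40)]
        se = np.sqrt(true_tail * (1 - true_tail) / 1000)
        assert abs(np.mean(values) - true_tail) < 3 * se / np.sqrt(40) + 1e-3
        assert np.std(values) < 3 * se

    def test_invalid_reps_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_pathway(1, 5, 5, 20, n_reps=0)

    def test_add_bootstrap_only_below_alpha(self):
        records = pd.DataFrame(
            {
                "k": [5, 0], "K": [5, 5], "n": [5, 5], "N": [10, 10],
                "p_fisher": [1 / 252, 1.0], "p_fdr": [1 / 126, 1.0],
            },
            index=pd.Index(["P1", "P2"], name="pathway_id"),
        )
        out = add_bootstrap(records, n_reps=200, rng=1)
        assert not np.isnan(out.loc["P1", "p_bootstrap"])
        assert np.isnan(out.loc["P2", "p_bootstrap"])


class TestCombinedScore:
    @pytest.mark.parametrize(
        "pt, pp, expected", [(1e-4, 1e-4, -4.0), (1e-2, 1e-6, -4.0), (1.0, 1.0, 0.0)]
    )
    def test_mean_of_log10(self, pt, pp, expected):
        assert combine_scores(pt, pp) == pytest.approx(expected)

    def test_zero_floored_with_warning(self):
        with pytest.warns(UserWarning, match="floored"):
            score = combine_scores(0.0, 1e-4)
        assert np.isfinite(score)


class TestCharacteristicPathways:
    @staticmethod
    def records(rows):
        return pd.DataFrame(
            rows, columns=["p_fdr", "p_bootstrap"],
            index=pd.Index([f"P{i}" for i in range(len(rows))], name="pathway_id"),
        ).assign(k=1, K=1, n=1, N=10)

    def test_disjoint_layers_empty(self):
        t = self.records([[0.001, 0.0], [0.9, np.nan]])
        p = self.records([[0.9, np.nan], [0.001, 0.0]])
        assert len(characteristic_pathways(t, p)) == 0

    def test_shared_pathway_scored(self):
        t = self.records([[1e-3, 0.0]])
        p = self.records([[1e-5, 0.0]])
        out = characteristic_pathways(t, p)
        assert len(out) == 1
        assert out.loc[0, "score"] == pytest.approx(-4.0)

    def test_bootstrap_gate_enforced(self):
        # FDR-significant on both layers but failing the bootstrap on one
        t = self.records([[1e-3, 0.2]])
        p = self.records([[1e-5, 0.0]])
        assert len(characteristic_pathways(t, p)) == 0

    def test_sorted_by_score_then_name(self):
        t = self.records([[1e-4, 0.0], [1e-4, 0.0], [1e-8, 0.0]])
        p = self.records([[1e-4, 0.0], [1e-4, 0.0], [1e-2, 0.0]])
        out = characteristic_pathways(t, p)
        assert out["pathway_id"].tolist() == ["P2", "P0", "P1"]

    def test_planted_pathways_rank_first(self, bundle, study_result):
        for cls in bundle.truth["classes"]:
            char = study_result.characteristic[cls]
            top3 = set(char["pathway_id"].head(3))
            for pid in bundle.truth["pathways"][cls]:
                assert pid in top3
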