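import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from milispread import (
    GeneMiRSet,
    TargetInteractionTable,
    assign_mirs_to_gene_set,
    build_gene_mir_sets,
    combine_gene_mir_pvalues,
    concordance_summary,
    enrichment_pvalue,
    set_deregulation_test,
)


def hypergeom_tail_oracle(k, K, n, N):
    """Brute-force upper-tail P(X >= k) by exact integer summation."""
    total = math.comb(N, n)
    acc = 0
    for x in range(k, min(n, K) + 1):
        acc += math.comb(K, x) * math.comb(N - K, n - x)
    return acc / total


def _targets(pairs):
    return TargetInteractionTable(
        pd.DataFrame(pairs, columns=["mirna_id", "gene_id"])
    )


def _stats_frame(values, prefix="f"):
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(
        {"statistic": values},
        index=[f"{prefix}{i}" for i in range(len(values))],
    )


class TestAssignment:
    def test_mirna_targeting_whole_universe_not_assigned(self):
        universe = [f"g{i}" for i in range(30)]
        targets = _targets([("mir1", g) for g in universe])
        assigned = assign_mirs_to_gene_set(universe[:5], targets, universe)
        assert assigned == {}
        # its p-value is exactly 1: no enrichment is possible
        assert enrichment_pvalue(5, 30, 5, 30) == pytest.approx(1.0)

    def test_perfectly_enriched_mirna_p_is_one_over_choose(self):
        universe = [f"g{i}" for i in range(100)]
        gene_set = universe[:5]
        targets = _targets([("mir1", g) for g in gene_set])
        assigned = assign_mirs_to_gene_set(gene_set, targets, universe)
        assert assigned["mir1"] == pytest.approx(1.0 / math.comb(100, 5), rel=1e-12)

    def test_partial_overlap_matches_hypergeometric_tail(self):
        # 1000-gene universe, 50 targeted overall, set of 10 with 5 targeted
        p = enrichment_pvalue(5, 50, 10, 1000)
        assert p == pytest.approx(hypergeom_tail_oracle(5, 50, 10, 1000), rel=1e-10)

    def test_matches_bruteforce_oracle_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            N = int(rng.integers(2, 61))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(max(0, n + K - N), min(n, K) + 1))
            assert enrichment_pvalue(k, K, n, N) == pytest.approx(
                hypergeom_tail_oracle(k, K, n, N), abs=1e-10
            )

    def test_empty_gene_set_and_universe_violations_rejected(self):
        targets = _targets([("mir1", "g0")])
        with pytest.raises(ValueError, match="empty gene set"):
            assign_mirs_to_gene_set([], targets, ["g0"])
        with pytest.raises(ValueError, match="universe"):
            assign_mirs_to_gene_set(["gX"], targets, ["g0"])


class TestSetDeregulationTest:
    def test_all_zero_members_in_symmetric_null(self):
        rng = np.random.default_rng(8)
        stats = _stats_frame(np.concatenate([[0.0] * 10, rng.normal(0, 1, 500)]))
        p, direction = set_deregulation_test(stats, [f"f{i}" for i in range(10)],
                                             n_perm=500, seed=1)
        assert p > 0.5
        assert direction == "up"  # tie at exactly zero breaks to "up"

    def test_whole_feature_set_is_null(self):
        rng = np.random.default_rng(9)
        stats = _stats_frame(rng.normal(0, 1, 200))
        p, _ = set_deregulation_test(stats, list(stats.index), n_perm=300, seed=2)
        assert p > 0.9

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_planted_set_detected(self, seed):
        rng = np.random.default_rng(100 + seed)
        stats = _stats_frame(np.concatenate([[3.0] * 20, rng.normal(0, 1, 1000)]))
        p, direction = set_deregulation_test(
            stats, [f"f{i}" for i in range(20)], n_perm=10_000, seed=seed
        )
        assert p < 0.01
        assert direction == "up"

    def test_permutation_p_values_valid_under_null(self):
        # P(p <= alpha) <= alpha + 2/sqrt(n_perm) for random member sets
        rng = np.random.default_rng(10)
        stats = _stats_frame(rng.normal(0, 1, 400))
        n_perm, alpha = 200, 0.05
        hits = 0
        n_sets = 300
        for i in range(n_sets):
            members = list(rng.choice(stats.index, size=15, replace=False))
            p, _ = set_deregulation_test(stats, members, n_perm=n_perm, seed=i)
            hits += p <= alpha
        assert hits / n_sets <= alpha + 2 / np.sqrt(n_perm)

    def test_input_contract(self):
        stats = _stats_frame([1.0, 2.0])
        with pytest.raises(ValueError, match="empty"):
            set_deregulation_test(stats, [], n_perm=200)
        with pytest.raises(ValueError, match="n_perm"):
            set_deregulation_test(stats, ["f0"], n_perm=10)
        with pytest.raises(ValueError, match="absent"):
            set_deregulation_test(stats, ["nope"], n_perm=200)


class TestCombine:
    def test_both_one_gives_one(self):
        assert combine_gene_mir_pvalues(1.0, 1.0) == pytest.approx(1.0)

    def test_frozen_value_at_005_005(self):
        # -2(ln .05 + ln .05) = 11.983, chi2_4 survival = 0.01749
        p = combine_gene_mir_pvalues(0.05, 0.05)
        assert -2 * (np.log(0.05) + np.log(0.05)) == pytest.approx(11.983, abs=1e-3)
        assert p == pytest.approx(0.017486, abs=1e-5)

    def test_symmetry_and_zero_clipping(self):
        assert combine_gene_mir_pvalues(0.01, 0.3) == combine_gene_mir_pvalues(0.3, 0.01)
        with pytest.warns(UserWarning, match="clipped"):
            assert combine_gene_mir_pvalues(0.0, 0.5) < 1e-100


def _make_set(i, dg, dm, q):
    return GeneMiRSet(
        set_id=f"s{i}", genes=["g"], mirs={"m": 0.01},
        p_gene=0.01, p_mir=0.01, dir_gene=dg, dir_mir=dm,
        p_combined=q, q_combined=q,
    )


class TestConcordance:
    def test_all_gene_down_mir_up(self):
        sets = [_make_set(i, "down", "up", 0.001) for i in range(20)]
        curve = concordance_summary(sets, [0.01, 0.05, 0.5])
        assert np.allclose(curve.pct_opposite, 100.0)
        assert np.allclose(curve.pct_gene_down_mir_up, 100.0)
        assert curve.n_significant == 20

    def test_coin_flip_directions_near_fifty_percent(self):
        rng = np.random.default_rng(11)
        sets = [
            _make_set(i, rng.choice(["up", "down"]), rng.choice(["up", "down"]), 0.001)
            for i in range(1000)
        ]
        curve = concordance_summary(sets, [0.05])
        assert abs(curve.pct_opposite[0] - 50.0) < 5.0

    def test_empty_stratum_reported_missing(self):
        sets = [_make_set(0, "down", "up", 0.5)]
        curve = concordance_summary(sets, [0.01])
        assert np.isnan(curve.pct_opposite[0])
        assert np.isnan(curve.pct_gene_down_mir_up[0])

    def test_invariant_to_set_relabeling(self):
        rng = np.random.default_rng(12)
        sets = [
            _make_set(i, rng.choice(["up", "down"]), rng.choice(["up", "down"]),
                      rng.uniform(0, 0.2))
            for i in range(50)
        ]
        curve1 = concordance_summary(sets, [0.05, 0.1])
        rng.shuffle(sets)
        curve2 = concordance_summary(sets, [0.05, 0.1])
        np.testing.assert_array_equal(curve1.pct_opposite, curve2.pct_opposite)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            concordance_summary([], [])


class TestBuildPipeline:
    def test_no_targets_means_no_combined_p(self):
        rng = np.random.default_rng(13)
        genes = [f"g{i}" for i in range(50)]
        stats_genes = pd.DataFrame(
            {"statistic": rng.normal(0, 1, 50)}, index=genes
        )
        stats_mirs = pd.DataFrame({"statistic": []}, dtype=float)
        empty = TargetInteractionTable(
            pd.DataFrame(columns=["mirna_id", "gene_id"])
        )
        sets = build_gene_mir_sets(
            {"a": genes[:10]}, empty, stats_genes, stats_mirs,
            n_perm=200, seed=0, universe=genes,
        )
        assert sets[0].mirs == {}
        assert sets[0].p_combined is None
        assert sets[0].p_gene is not None

    def test_planted_inverse_regulation_recovered(self):
        # one gene set built from the targets of an upregulated miRNA whose
        # targets are suppressed; pipeline should flag it gene-down / miR-up
        rng = np.random.default_rng(14)
        genes = [f"g{i}" for i in range(300)]
        mirs = [f"m{i}" for i in range(20)]
        pairs = [("m0", g) for g in genes[:20]]
        for m in mirs[1:]:
            pairs += [(m, g) for g in rng.choice(genes, 20, replace=False)]
        targets = _targets(pairs)
        tg = np.zeros(300)
        tg[:20] = -6.0  # suppressed targets
        stats_genes = pd.DataFrame({"statistic": tg + rng.normal(0, 1, 300)}, index=genes)
        tm = np.zeros(20)
        tm[0] = 6.0
        stats_mirs = pd.DataFrame({"statistic": tm + rng.normal(0, 1, 20)}, index=mirs)
        gene_sets = {"planted": genes[:20]}
        for i in range(9):
            gene_sets[f"null{i}"] = list(rng.choice(genes, 20, replace=False))
        out = build_gene_mir_sets(gene_sets, targets, stats_genes, stats_mirs,
                                  n_perm=2000, seed=3)
        planted = next(s for s in out if s.set_id == "planted")
        assert "m0" in planted.mirs
        assert planted.dir_gene == "down" and planted.dir_mir == "up"
        assert planted.q_combined < 0.05
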