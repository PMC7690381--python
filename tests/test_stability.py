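import numpy as np
import pytest

from mirnorm import (
    bestkeeper,
    comprehensive_rank,
    delta_ct_method,
    genorm,
    normfinder,
    pair_sd_matrix,
    top_k_overlap,
)
from mirnorm.stability import StabilityError, complete_candidates

import oracles
from conftest import make_ct, make_samples

FIXTURE = np.array(
    [
        [24.1, 24.9, 23.8, 24.5, 25.2, 24.0],
        [27.3, 28.1, 26.9, 27.8, 28.4, 27.1],
        [30.2, 29.5, 31.1, 30.8, 29.9, 30.4],
        [22.7, 23.9, 22.1, 23.3, 24.6, 22.5],
    ]
)


@pytest.fixture
def fixture_ct():
    return make_ct(FIXTURE, assay_ids=["gA", "gB", "gC", "gD"])


class TestPairSDMatrix:
    def test_matches_brute_force(self, fixture_ct):
        got = pair_sd_matrix(fixture_ct)
        want = np.array(oracles.pair_sd_brute(FIXTURE.tolist()))
        np.testing.assert_allclose(got, want, atol=1e-12)
        assert np.array_equal(got, got.T)
        assert np.all(np.diag(got) == 0)

    def test_constant_offset_gene_pair_has_zero_sd(self):
        a = np.array([25.0, 26.0, 24.5, 25.5])
        ct = make_ct(np.vstack([a, a + 3.0, a * 1.1]))
        m = pair_sd_matrix(ct)
        assert m[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert m[0, 2] > 0

    def test_per_sample_constant_cancels(self, fixture_ct, rng):
        shifted = make_ct(FIXTURE + rng.normal(0, 2, size=FIXTURE.shape[1]))
        np.testing.assert_allclose(
            pair_sd_matrix(shifted), pair_sd_matrix(fixture_ct), atol=1e-12
        )

    def test_too_few_samples_rejected(self):
        with pytest.raises(StabilityError, match="3 samples"):
            pair_sd_matrix(make_ct([[25.0, 26.0], [27.0, 28.0]]))

    def test_missing_values_rejected(self):
        vals = FIXTURE.copy()
        vals[0, 0] = np.nan
        with pytest.raises(StabilityError, match="undetected"):
            pair_sd_matrix(make_ct(vals))


class TestDeltaCt:
    def test_matches_mean_of_row_oracle(self, fixture_ct):
        got = delta_ct_method(fixture_ct)
        want = oracles.delta_ct_brute(FIXTURE.tolist())
        np.testing.assert_allclose(got.values, want, atol=1e-12)

    def test_duplicate_up_to_constant_genes_tie_at_minimum(self, rng):
        base = rng.uniform(24, 30, size=(3, 8))
        a = rng.normal(27, 0.5, 8)
        vals = np.vstack([base, a, a + 2.0])
        ct = make_ct(vals)
        res = delta_ct_method(ct)
        assert res.values[3] == pytest.approx(res.values[4], abs=1e-12)
        assert set(np.argsort(res.values)[:2]) == {3, 4}

    def test_shift_invariance(self, fixture_ct, rng):
        shifted = make_ct(FIXTURE + rng.normal(0, 3, FIXTURE.shape[1]))
        np.testing.assert_allclose(
            delta_ct_method(shifted).values,
            delta_ct_method(fixture_ct).values,
            atol=1e-9,
        )


class TestGenorm:
    def test_matches_brute_force_trajectory(self, rng):
        vals = rng.uniform(20, 34, size=(6, 9))
        ids = [f"g{i}" for i in range(6)]
        ct = make_ct(vals, assay_ids=ids)
        res = genorm(ct)
        elim, values, ranks = oracles.genorm_brute(vals.tolist(), ids)
        assert res.extras["elimination_order"] == elim
        for i, g in enumerate(ids):
            assert res.values[i] == pytest.approx(values[g], abs=1e-12)
            assert res.ranks[i] == ranks[g]

    def test_initial_m_equals_delta_ct_for_three_genes(self, rng):
        vals = rng.uniform(20, 34, size=(3, 7))
        ct = make_ct(vals)
        first_m = genorm(ct).extras["m_trajectory"][0]
        dct = delta_ct_method(ct).value_of()
        for g, m in first_m.items():
            assert m == pytest.approx(dct[g], abs=1e-12)

    def test_planted_stable_pair_survives(self, rng):
        """Two near-copies (pair SD ~0.05) among four noisy genes end up
        as the final pair."""
        base = rng.normal(27, 0.02, 10)
        g1 = base + rng.normal(0, 0.035, 10)
        g2 = base + 1.5 + rng.normal(0, 0.035, 10)
        noisy = [rng.normal(25 + i, 0.8, 10) for i in range(4)]
        vals = np.vstack([g1, g2] + noisy)
        ct = make_ct(vals, assay_ids=["G1", "G2", "n1", "n2", "n3", "n4"])
        res = genorm(ct)
        assert res.extras["final_pair"] == ["G1", "G2"]
        assert res.ranks[0] == res.ranks[1] == 1.5

    def test_shift_invariance_of_trajectory(self, rng):
        vals = rng.uniform(20, 34, size=(5, 8))
        ct = make_ct(vals)
        shifted = make_ct(vals + rng.normal(0, 2, 8))
        a, b = genorm(ct), genorm(shifted)
        assert a.extras["elimination_order"] == b.extras["elimination_order"]
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)

    def test_elimination_is_permutation(self, rng):
        for n in (3, 5, 8):
            vals = rng.uniform(20, 34, size=(n, 7))
            res = genorm(make_ct(vals))
            assert sorted(res.ranks) == [1.5, 1.5] + list(range(3, n + 1))

    def test_needs_three_candidates(self):
        with pytest.raises(StabilityError, match=">=3"):
            genorm(make_ct(np.full((2, 5), 25.0)))


class TestBestkeeper:
    def test_constant_gene_ranks_first(self, rng):
        vals = np.vstack([np.full(6, 30.0), rng.normal(25, 1.0, (3, 6))])
        res = bestkeeper(make_ct(vals))
        assert res.values[0] == 0.0
        assert res.extras["cv_pct"][0] == 0.0
        assert res.ranks[0] == 1.0

    def test_known_mad(self):
        res = bestkeeper(make_ct([[28.0, 30.0, 32.0], [25.0, 25.0, 25.0]]))
        assert res.extras["mean_ct"][0] == pytest.approx(30.0)
        assert res.values[0] == pytest.approx(4.0 / 3.0)

    def test_matches_brute_force(self, rng):
        vals = rng.uniform(18, 35, size=(5, 9))
        res = bestkeeper(make_ct(vals))
        means, mads, cvs = oracles.bestkeeper_brute(vals.tolist())
        np.testing.assert_allclose(res.extras["mean_ct"], means, atol=1e-12)
        np.testing.assert_allclose(res.values, mads, atol=1e-12)
        np.testing.assert_allclose(res.extras["cv_pct"], cvs, atol=1e-12)

    def test_not_shift_invariant(self, rng):
        """Shared per-sample variation inflates BestKeeper dispersion (a
        documented property, not a bug)."""
        vals = np.tile(rng.uniform(24, 30, size=(4, 1)), (1, 10))
        flat = bestkeeper(make_ct(vals))
        shifted = bestkeeper(make_ct(vals + rng.normal(0, 2, 10)))
        assert (shifted.values > flat.values + 0.5).all()


class TestNormfinder:
    def _samples(self, n_ctrl, n_bc):
        return make_samples({"control": n_ctrl, "TaG1": n_bc})

    def test_matches_brute_force(self, rng):
        vals = rng.uniform(20, 32, size=(5, 12))
        samples = self._samples(6, 6)
        ct = make_ct(vals, sample_ids=samples.sample_ids)
        res = normfinder(ct, samples)
        want = oracles.normfinder_brute(
            vals.tolist(), ["control"] * 6 + ["BC"] * 6
        )
        np.testing.assert_allclose(res.values, want, atol=1e-12)

    def test_single_group_zero_residual_gene_wins(self, rng):
        n = 10
        s = rng.normal(0, 1, n)
        perfect = 27.0 + s  # exactly the sample effect: zero residual
        others = [25.0 + s + rng.normal(0, 0.5, n) for _ in range(3)]
        samples = make_samples({"control": n})
        ct = make_ct(np.vstack([perfect] + others), sample_ids=samples.sample_ids)
        res = normfinder(ct, samples)
        assert res.extras["grouping"] == "none"
        assert res.ranks[0] == 1.0

    def test_parameter_recovery(self):
        """The zero-bias, low-noise gene wins; genes with 1-Ct group bias
        never do (6 genes x 40 samples x 2 groups, 200 replicates)."""
        wins, bias_wins = 0, 0
        for rep in range(200):
            r = np.random.default_rng(rep)
            n = 20  # per group
            labels = ["control"] * n + ["TaG1"] * n
            bias = np.array([0.0, 1.0, -1.0, 0.0, 0.5, 0.0])
            sigma = np.array([0.05, 0.3, 0.3, 0.6, 0.3, 0.9])
            s = r.normal(0, 1, 2 * n)
            vals = np.empty((6, 2 * n))
            for i in range(6):
                eff = np.array([0.0] * n + [bias[i]] * n)
                vals[i] = 26 + 2 * i + eff + s + r.normal(0, sigma[i], 2 * n)
            samples = make_samples({"control": n, "TaG1": n})
            ct = make_ct(vals, sample_ids=samples.sample_ids)
            best = int(np.argmin(normfinder(ct, samples).values))
            wins += best == 0
            bias_wins += best in (1, 2)
        assert wins >= 190  # >= 95%
        assert bias_wins == 0

    def test_shift_invariance(self, rng):
        vals = rng.uniform(20, 32, size=(4, 10))
        samples = self._samples(5, 5)
        ct = make_ct(vals, sample_ids=samples.sample_ids)
        shifted = make_ct(vals + rng.normal(0, 3, 10), sample_ids=samples.sample_ids)
        np.testing.assert_allclose(
            normfinder(ct, samples).values,
            normfinder(shifted, samples).values,
            atol=1e-9,
        )

    def test_single_group_fallback_logged(self, rng, caplog):
        import logging

        vals = rng.uniform(20, 30, size=(3, 6))
        samples = make_samples({"control": 6})
        ct = make_ct(vals, sample_ids=samples.sample_ids)
        with caplog.at_level(logging.INFO, logger="mirnorm.stability"):
            res = normfinder(ct, samples)
        assert res.extras["grouping"] == "none"
        assert any("ungrouped" in rec.getMessage() for rec in caplog.records)


class TestComprehensiveRank:
    def _result(self, alg, ids, ranks):
        from mirnorm import StabilityResult

        ranks = np.asarray(ranks, dtype=float)
        return StabilityResult(alg, list(ids), ranks.copy(), ranks)

    def test_unanimous_first(self):
        ids = ["a", "b", "c"]
        res = [self._result(alg, ids, [1, 2, 3]) for alg in ("genorm", "bestkeeper", "delta_ct", "normfinder")]
        agg = comprehensive_rank(res)
        assert agg.best() == "a"
        np.testing.assert_allclose(agg.geomean, [1.0, 2.0, 3.0])

    def test_geometric_mean_arithmetic(self):
        ids = ["a", "b"]
        ranks = {"genorm": [2, 1], "bestkeeper": [8, 1], "delta_ct": [1, 2], "normfinder": [1, 2]}
        res = [self._result(alg, ids, r) for alg, r in ranks.items()]
        agg = comprehensive_rank(res)
        i = agg.assay_ids.index("a")
        assert agg.geomean[i] == pytest.approx((2 * 8 * 1 * 1) ** 0.25)

    def test_invariant_to_result_order(self, rng):
        ids = [f"g{i}" for i in range(6)]
        res = []
        for alg in ("genorm", "bestkeeper", "delta_ct", "normfinder"):
            vals = rng.uniform(0.1, 2.0, 6)
            from scipy.stats import rankdata

            res.append(self._result(alg, ids, rankdata(vals)))
        a = comprehensive_rank(res)
        b = comprehensive_rank(res[::-1])
        assert a.ordered() == b.ordered()
        np.testing.assert_allclose(a.geomean, b.geomean)

    def test_mismatched_sets_list_difference(self):
        res = [
            self._result("genorm", ["a", "b", "c"], [1, 2, 3]),
            self._result("bestkeeper", ["a", "b", "d"], [1, 2, 3]),
        ]
        with pytest.raises(StabilityError, match="'c'.*'d'|'d'.*'c'"):
            comprehensive_rank(res)

    def test_final_rank_is_strict_permutation_with_lexicographic_ties(self):
        ids = ["z", "y"]
        res = [self._result(alg, ids, [1.5, 1.5]) for alg in ("genorm", "bestkeeper")]
        agg = comprehensive_rank(res)
        assert agg.rank_of() == {"y": 1, "z": 2}


class TestTopKOverlap:
    def _result(self, alg, ids, order):
        from mirnorm import StabilityResult

        ranks = np.array([order.index(i) + 1 for i in ids], dtype=float)
        return StabilityResult(alg, list(ids), ranks, ranks)

    def test_identical_lists_all_in_full_region(self):
        ids = [f"g{i}" for i in range(12)]
        res = [self._result(a, ids, ids) for a in ("genorm", "bestkeeper", "delta_ct", "normfinder")]
        regions = top_k_overlap(res, 10)
        assert set(regions) == {frozenset(("genorm", "bestkeeper", "delta_ct", "normfinder"))}
        assert sorted(regions[frozenset(("genorm", "bestkeeper", "delta_ct", "normfinder"))]) == sorted(ids[:10])

    def test_disjoint_lists_only_singleton_regions(self):
        ids = [f"g{i}" for i in range(8)]
        orders = {
            "genorm": ids,
            "bestkeeper": ids[2:] + ids[:2],
            "delta_ct": ids[4:] + ids[:4],
            "normfinder": ids[6:] + ids[:6],
        }
        res = [self._result(a, ids, o) for a, o in orders.items()]
        regions = top_k_overlap(res, 2)
        assert all(len(k) == 1 for k in regions)
        assert sum(len(v) for v in regions.values()) == 8

    def test_region_sizes_sum_to_union(self, rng):
        ids = [f"g{i:02d}" for i in range(20)]
        for _ in range(25):
            res = []
            for alg in ("genorm", "bestkeeper", "delta_ct", "normfinder"):
                order = list(rng.permutation(ids))
                res.append(self._result(alg, ids, order))
            k = int(rng.integers(1, 12))
            regions = top_k_overlap(res, k)
            union = set().union(*(set(r.top_k(k)) for r in res))
            assert sum(len(v) for v in regions.values()) == len(union)
            # regions partition the union
            seen = [a for v in regions.values() for a in v]
            assert len(seen) == len(set(seen))


class TestCompleteCandidates:
    def test_drops_incomplete_and_warns(self, caplog):
        import logging

        vals = np.array([[25.0, 26.0, 24.0], [27.0, np.nan, 28.0]])
        ct = make_ct(vals, assay_ids=["keep", "drop"])
        with caplog.at_level(logging.WARNING, logger="mirnorm.stability"):
            kept = complete_candidates(ct, ["keep", "drop"])
        assert kept == ["keep"]
        assert any("drop" in rec.getMessage() for rec in caplog.records)
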