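import numpy as np
import pytest

import pairseek as ps


class TestSyntheticCounts:
    def test_totals_equal_drawn_depths(self):
        table = ps.synthetic_counts(n_samples=50, n_taxa=10, seed=1,
                                    depth_range=(1000, 2000))
        totals = table.counts.sum(axis=1)
        assert totals.min() >= 1000 and totals.max() <= 2000

    def test_zero_inflation_sets_prevalence(self):
        zi = np.full(5, 0.9)
        zi[0] = 0.0
        table = ps.synthetic_counts(n_samples=1000, n_taxa=5, seed=2,
                                    zero_inflation=zi)
        prevalence = (table.counts > 0).mean(axis=0)
        assert abs(prevalence[1:] - 0.1).max() < 0.03

    def test_seed_reproducibility(self):
        a = ps.synthetic_counts(n_samples=30, n_taxa=6, seed=3)
        b = ps.synthetic_counts(n_samples=30, n_taxa=6, seed=3)
        assert a == b

    def test_default_shape_is_sparse_and_skewed(self):
        table = ps.synthetic_counts(seed=4)
        assert table.counts.shape == (363, 61)
        zero_fraction = (table.counts == 0).mean()
        assert 0.2 < zero_fraction < 0.8
        flat = table.counts[table.counts > 0]
        assert np.mean(flat) > 3 * np.median(flat)  # heavy right tail
        # every taxon survives a 10% prevalence filter by construction
        assert ps.prevalence_filter(table, 0.10).n_taxa == 61

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            ps.synthetic_counts(n_taxa=1)
        with pytest.raises(ValueError):
            ps.synthetic_counts(zero_inflation=np.ones(61))


class TestAlternativeOutcome:
    def test_zero_effect_gives_half_prevalence(self):
        table = ps.synthetic_counts(n_samples=2000, n_taxa=4, seed=5)
        spec = ps.ScenarioSpec("alternative", planted_pairs=[(0, 1, 1.0, 0.0)])
        y = ps.generate_alternative(table, spec, seed=6)
        assert abs(y.values.mean() - 0.5) < 0.03

    def test_linear_predictor_centered_exactly(self):
        table = ps.synthetic_counts(n_samples=200, n_taxa=10, seed=7)
        cs = ps.pick_planted_thresholds(table, [(0, 5), (2, 8)])
        spec = ps.ScenarioSpec("alternative", planted_pairs=[
            (0, 5, cs[0], 2.56), (2, 8, cs[1], 2.28)
        ])
        for seed in range(5):
            _, info = ps.generate_alternative(table, spec, seed=seed,
                                              full_output=True)
            assert abs(info["eta"].mean()) < 1e-12

    def test_strong_effect_separates_groups(self):
        table = ps.synthetic_counts(n_samples=5000, n_taxa=4, seed=8)
        c = ps.pick_planted_thresholds(table, [(0, 2)])[0]
        spec = ps.ScenarioSpec("alternative", planted_pairs=[(0, 2, c, 10.0)])
        y, info = ps.generate_alternative(table, spec, seed=9, full_output=True)
        z = (info["eta"] > 0)
        from scipy.special import expit
        # two eta levels 10 apart: group case rates match the closed form
        lo, hi = np.unique(info["eta"])
        assert hi - lo == pytest.approx(10.0)
        assert abs(y.values[z].mean() - expit(hi)) < 0.02
        assert abs(y.values[~z].mean() - expit(lo)) < 0.02

    def test_invalid_pair_reference(self):
        table = ps.synthetic_counts(n_samples=30, n_taxa=4, seed=10)
        spec = ps.ScenarioSpec("alternative", planted_pairs=[(0, 9, 1.0, 1.0)])
        with pytest.raises(ValueError):
            ps.generate_alternative(table, spec)


class TestPlantedThresholds:
    def test_delegates_to_impurity_search_with_reference_outcome(self):
        table = ps.synthetic_counts(n_samples=100, n_taxa=6, seed=11)
        y = ps.generate_null2(100, seed=12)
        c = ps.pick_planted_thresholds(table, [(0, 3)], y_ref=y, seed=13)[0]
        xi, xj = table.counts[:, 0], table.counts[:, 3]
        grid = ps.build_threshold_grid(xi, xj)
        rng = np.random.default_rng(13)
        want, _ = ps.select_threshold(xi, xj, y.values, grid, rng=rng)
        assert c == want

    def test_median_rule_without_reference(self):
        counts = np.column_stack([np.array([1, 2, 3, 4, 5]),
                                  np.ones(5, dtype=int)])
        table = ps.CountTable([f"s{i}" for i in range(5)], ["a", "b"], counts)
        assert ps.pick_planted_thresholds(table, [(0, 1)]) == [3.0]

    def test_median_rule_balances_indicator(self):
        rng = np.random.default_rng(14)
        for seed in range(5):
            table = ps.synthetic_counts(n_samples=500, n_taxa=6, seed=20 + seed,
                                        zero_inflation=np.zeros(6))
            c = ps.pick_planted_thresholds(table, [(1, 4)])[0]
            z = ps.dichotomize(table.counts[:, 1], table.counts[:, 4], c, rng=rng)
            assert abs(z.mean() - 0.5) < 0.05


class TestNullOutcomes:
    def test_null1_centering_and_betas(self):
        table = ps.synthetic_counts(n_samples=300, n_taxa=10, seed=15)
        prevalent = np.where((table.counts > 0).mean(axis=0) >= 0.4)[0][:2]
        spec = ps.ScenarioSpec("null1", planted_main=[
            (int(m), -0.7) for m in prevalent
        ])
        _, info = ps.generate_null1(table, spec, seed=16, full_output=True)
        assert abs(info["eta"].mean()) < 1e-12

    def test_null1_rejects_rare_taxon(self):
        table = ps.synthetic_counts(n_samples=300, n_taxa=10, seed=17)
        rare = int(np.argmin((table.counts > 0).mean(axis=0)))
        spec = ps.ScenarioSpec("null1", planted_main=[(rare, -0.7)])
        with pytest.raises(ValueError, match="prevalence"):
            ps.generate_null1(table, spec, seed=18)

    def test_null1_effect_size_scales_outcome_variance(self):
        table = ps.synthetic_counts(n_samples=500, n_taxa=8, seed=19)
        m = int(np.argmax((table.counts > 0).mean(axis=0)))
        variances = []
        for beta in (0.7, 1.4, 2.8):
            spec = ps.ScenarioSpec("null1", planted_main=[(m, -beta)])
            _, info = ps.generate_null1(table, spec, seed=20, full_output=True)
            variances.append(info["pi"].var())
        assert variances[0] < variances[1] < variances[2]

    def test_null2_rate_and_reproducibility(self):
        y = ps.generate_null2(10_000, seed=21)
        assert abs(y.values.mean() - 0.5) < 0.015
        np.testing.assert_array_equal(
            y.values, ps.generate_null2(10_000, seed=21).values
        )


class TestScoring:
    @pytest.mark.parametrize(
        "selected,truth,expected",
        [
            ([(1, 2), (3, 4)], [(1, 2), (3, 4)], (2, 0)),
            ([], [(1, 2)], (0, 0)),
            ([(1, 2), (1, 3)], [(1, 2)], (1, 1)),
            ([(2, 1)], [(1, 2)], (1, 0)),  # orientation-free comparison
        ],
    )
    def test_tp_fp_counts(self, selected, truth, expected):
        assert ps.score_selection(selected, truth) == expected

    def test_unique_best_scores_rank_one(self):
        pairs = [(0, 1), (0, 2), (1, 2)]
        ranks, med = ps.rank_truth(pairs, np.array([0.9, 0.1, 0.5]), [(0, 1)])
        assert ranks[(0, 1)] == 1 and med == 1.0

    def test_tied_top_scores_share_rank_one(self):
        pairs = [(0, 1), (0, 2), (1, 2)]
        ranks, _ = ps.rank_truth(pairs, np.array([0.9, 0.9, 0.1]),
                                 [(0, 1), (0, 2)])
        assert ranks[(0, 1)] == ranks[(0, 2)] == 1

    def test_random_ordering_median_rank_expectation(self):
        rng = np.random.default_rng(22)
        pairs = ps.enumerate_pairs(61)
        truth = [pairs[i] for i in rng.choice(len(pairs), 6, replace=False)]
        medians = []
        for _ in range(200):
            scores = rng.random(len(pairs))
            _, med = ps.rank_truth(pairs, scores, truth)
            medians.append(med)
        assert abs(np.mean(medians) - len(pairs) / 2) < 80


class TestRunExperiment:
    def test_alternative_smoke_and_monotone_thresholds(self):
        table = ps.synthetic_counts(n_samples=100, n_taxa=8, seed=23)
        cs = ps.pick_planted_thresholds(table, [(0, 4)])
        spec = ps.ScenarioSpec("alternative", planted_pairs=[(0, 4, cs[0], 2.5)])
        summary = ps.run_experiment(spec, table, methods=["pairseek"],
                                    n_reps=3, B=30, seed=24)
        op = summary.operating.set_index("threshold")
        assert op.loc[0.9, "avg_tp"] <= op.loc[0.8, "avg_tp"] <= op.loc[0.7, "avg_tp"]
        assert (summary.operating["avg_tp"] <= 1).all()
        assert len(summary.ranks) == 1

    def test_null2_reports_fp_only(self):
        table = ps.synthetic_counts(n_samples=100, n_taxa=8, seed=25)
        spec = ps.ScenarioSpec("null2")
        summary = ps.run_experiment(spec, table,
                                    methods=["pairseek", "screen_ra"],
                                    n_reps=2, B=20, seed=26)
        assert (summary.operating["avg_tp"] == 0).all()
        assert len(summary.ranks) == 0

    def test_seed_reproducibility(self):
        table = ps.synthetic_counts(n_samples=80, n_taxa=6, seed=27)
        spec = ps.ScenarioSpec("null2")
        a = ps.run_experiment(spec, table, n_reps=2, B=10, seed=28)
        b = ps.run_experiment(spec, table, n_reps=2, B=10, seed=28)
        assert a.operating.equals(b.operating)

    def test_low_correlation_pair_extension(self):
        table = ps.synthetic_counts(n_samples=150, n_taxa=10, seed=29)
        extra = ps.choose_low_correlation_pairs(table, [(0, 1)], 2, seed=30)
        assert len(extra) == 2
        used = {0, 1}
        for i, j in extra:
            assert i < j and not ({i, j} & used)
            used |= {i, j}
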