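"""Water-balance arithmetic, pooled cut-off conventions and classification."""

import warnings

import numpy as np
import pytest

import dtmilk
from dtmilk.rs import (
    RsPosterior,
    WaterBalanceConstants,
    classify_pair,
    pooled_cutoff,
    rs_from_draw,
    rs_posterior,
)


class TestRsFromDraw:
    def test_closed_balance_is_zero(self):
        assert rs_from_draw(0.8, 0.8, 0.0, 0.0) == pytest.approx(0.0)

    def test_atmospheric_correction_arithmetic(self):
        assert rs_from_draw(0.70, 0.80, 0.0, 0.063) == pytest.approx(49.6)

    def test_negative_values_retained(self):
        assert rs_from_draw(0.75, 0.70, 0.0, 0.0) == pytest.approx(-50.0)

    def test_linearity_slopes(self):
        fa = 0.063
        base = rs_from_draw(0.7, 0.8, 0.01, fa)
        assert rs_from_draw(0.7, 0.9, 0.01, fa) - base == pytest.approx((1 - fa) * 0.1 * 1000)
        assert rs_from_draw(0.8, 0.8, 0.01, fa) - base == pytest.approx(-0.1 * 1000)

    def test_invalid_fa_rejected(self):
        with pytest.raises(ValueError):
            rs_from_draw(0.7, 0.8, 0.0, 1.0)


class TestRsPosterior:
    def test_zero_variance_constants_leave_only_kinetic_spread(self, perfect_fit):
        pid = perfect_fit.pair_ids_[0]
        c0 = WaterBalanceConstants(fa_sd=0.0)
        a = rs_posterior(perfect_fit, pid, c0, seed=1)
        b = rs_posterior(perfect_fit, pid, c0, seed=2)
        # no f_a randomness: identical draws regardless of seed
        assert np.array_equal(a.draws, b.draws)

    def test_fa_uncertainty_widens_interquartile_range(self, perfect_fit):
        pid = perfect_fit.pair_ids_[0]
        narrow = rs_posterior(perfect_fit, pid, WaterBalanceConstants(fa_sd=0.0), seed=3)
        wide = rs_posterior(perfect_fit, pid, WaterBalanceConstants(fa_sd=0.017), seed=3)
        iqr = lambda p: np.diff(p.quantile([0.25, 0.75]))[0]
        assert iqr(wide) > iqr(narrow)

    def test_summary_consistent_with_draws(self):
        draws = np.arange(101.0)
        p = RsPosterior("X", draws)
        s = p.summary()
        assert s["mean"] == pytest.approx(draws.mean())
        assert s["q2.5"] == pytest.approx(np.quantile(draws, 0.025))


class TestPooledCutoff:
    def test_equals_brute_force_quantile(self):
        rng = np.random.default_rng(0)
        posts = [RsPosterior(f"P{i}", rng.normal(50, 10, 500)) for i in range(4)]
        result = pooled_cutoff(posts, percentile=0.90)
        pooled = np.sort(np.concatenate([p.draws for p in posts]))
        # inverted-CDF convention: smallest value with CDF >= 0.9
        k = int(np.ceil(0.90 * pooled.size)) - 1
        assert result.cutoff == pooled[k]

    def test_gaussian_closed_form(self):
        rng = np.random.default_rng(1)
        posts = [RsPosterior(f"P{i}", rng.normal(50, 10, 25_000)) for i in range(4)]
        result = pooled_cutoff(posts, percentile=0.90)
        assert result.cutoff == pytest.approx(50 + 1.2816 * 10, abs=0.3)

    def test_degenerate_two_point_mixture(self):
        # 9000 draws at 0 and 1000 at 100: the 90th percentile of the mixture
        # is exactly 0 under the empirical-quantile convention
        result = pooled_cutoff(
            [RsPosterior("A", np.zeros(5000)),
             RsPosterior("B", np.concatenate([np.zeros(4000), np.full(1000, 100.0)]))],
            percentile=0.90,
        )
        assert result.cutoff == 0.0

    def test_percentile_bounds_enforced(self):
        posts = [RsPosterior("A", np.zeros(10))]
        with pytest.raises(ValueError):
            pooled_cutoff(posts, percentile=1.0)
        with pytest.raises(ValueError):
            pooled_cutoff([], percentile=0.9)

    def test_unequal_draw_counts_rejected(self):
        posts = [RsPosterior("A", np.zeros(10)), RsPosterior("B", np.zeros(20))]
        with pytest.raises(ValueError, match="unequal"):
            pooled_cutoff(posts)


class TestClassification:
    def test_all_below_cutoff(self):
        p = RsPosterior("A", np.full(100, 10.0))
        assert classify_pair(p, 50.0)["p_ebf"] == 1.0

    def test_symmetry_gives_half(self):
        p = RsPosterior("A", np.concatenate([np.full(500, 40.0), np.full(500, 60.0)]))
        res = classify_pair(p, 50.0)
        assert res["p_ebf"] == pytest.approx(0.5)

    def test_threshold_consistency(self):
        rng = np.random.default_rng(2)
        p = RsPosterior("A", rng.normal(80, 30, 2000))
        probs = [classify_pair(p, c)["p_ebf"] for c in (40.0, 60.0, 80.0, 120.0)]
        assert probs == sorted(probs)

    def test_positive_cutoff_required(self):
        with pytest.raises(ValueError):
            classify_pair(RsPosterior("A", np.zeros(10)), 0.0)

    def test_discrimination_between_ebf_and_supplemented_groups(self):
        """Pairs generated with Rs = 0 get systematically higher P(EBF) than
        pairs generated with Rs = 200 g/day."""
        truth = dtmilk.SimulationTruth(rs_per_pair=[0.0, 0.0, 0.0, 200.0, 200.0, 200.0])
        cohort = dtmilk.simulate_cohort(truth, dtmilk.CohortDesign(n_pairs=6), seed=21)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = dtmilk.HierarchicalDtmModel(
                n_chains=2, n_draws=400, n_warmup=800, thin=2, random_state=21
            ).fit(cohort.pairs)
        posts = dtmilk.cohort_rs_posteriors(model, seed=21)
        cut = dtmilk.pooled_cutoff(posts)
        p = np.array([cut.p_ebf[pid] for pid in model.pair_ids_])
        assert p[:3].mean() > p[3:].mean()


class TestTheoreticalLowerLimit:
    def test_limit_monotone_in_fa_uncertainty_and_positive(self):
        truth = dtmilk.SimulationTruth(sigma_add=1.0, sigma_prop=0.01)
        design = dtmilk.CohortDesign()
        kw = dict(n_replicates=1, n_pairs=3, seed=17,
                  fit_kwargs=dict(n_chains=2, n_draws=300, n_warmup=700, thin=3))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            no_fa = dtmilk.theoretical_lower_limit(
                truth, design, WaterBalanceConstants(fa_sd=0.0), **kw
            )
            paper_fa = dtmilk.theoretical_lower_limit(
                truth, design, WaterBalanceConstants(fa_sd=0.017), **kw
            )
        assert paper_fa["limit"] > no_fa["limit"]
        assert paper_fa["limit"] > 0
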