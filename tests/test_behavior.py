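"""Model-free behavioral statistics."""

import numpy as np
import pandas as pd
import pytest

import normadapt as na
from normadapt.behavior import (
    bh_correct,
    block_stats,
    offer_size_regression,
    paired_contrast,
    per_offer_contrasts,
    rating_contrast,
    rejection_contrast,
    rejection_rates,
    sliding_rejection,
)


def _log(pid, offers, choices, block="baseline", ratings=None, start_trial=1):
    n = len(offers)
    return pd.DataFrame(
        {
            "participant_id": pid,
            "trial": np.arange(start_trial, start_trial + n),
            "block": block,
            "offer": offers,
            "choice": choices,
            "rating": pd.array(ratings if ratings is not None else [pd.NA] * n,
                               dtype="Int64"),
        }
    )


def _paired_vectors_with_t(t_target: float, n: int = 30):
    """Pre/post vectors whose paired t equals t_target (sign convention:
    negative t for a post decrease)."""
    pattern = np.tile([1.0, -1.0], n // 2)
    sd = pattern.std(ddof=1)
    shift = abs(t_target) * sd / np.sqrt(n)
    pre = shift + pattern
    post = np.zeros(n)
    return pre, post


class TestRejectionRates:
    def test_all_reject_participant(self):
        df = pd.concat(
            [_log("p01", [8] * 5, ["reject"] * 5, block=b)
             for b in ("baseline", "conditioning", "post")],
            ignore_index=True,
        )
        rates = rejection_rates(df, "block")
        assert (rates["rejection_rate"] == 100.0).all()

    def test_three_of_twenty(self):
        df = _log("p01", [8] * 20, ["reject"] * 3 + ["accept"] * 17)
        rates = rejection_rates(df, "block")
        assert rates["rejection_rate"].iloc[0] == pytest.approx(15.0)

    def test_pooled_rate_is_count_weighted_per_size_rate(self, medium_cohort):
        trials, _ = medium_cohort
        by_block = rejection_rates(trials, "block")
        by_size = rejection_rates(trials, "block_offer")
        merged = by_size.assign(
            rejected=lambda d: d["rejection_rate"] * d["n_trials"] / 100.0
        ).groupby(["participant_id", "block"]).agg(
            rejected=("rejected", "sum"), n=("n_trials", "sum"))
        merged["pooled"] = 100.0 * merged["rejected"] / merged["n"]
        joined = by_block.merge(merged.reset_index(), on=["participant_id", "block"])
        np.testing.assert_allclose(joined["rejection_rate"], joined["pooled"])

    def test_empty_group_absent_not_zero(self):
        df = _log("p01", [8] * 5, ["accept"] * 5, block="baseline")
        rates = rejection_rates(df, "block")
        assert set(rates["block"]) == {"baseline"}  # no phantom blocks

    def test_unknown_grouping(self):
        df = _log("p01", [8], ["accept"])
        with pytest.raises(ValueError):
            rejection_rates(df, "by_phase")


class TestSlidingRejection:
    def test_all_accept_curve_is_zero(self):
        df = _log("p01", [8] * 20, ["accept"] * 20)
        assert (sliding_rejection(df, window=5) == 0).all()

    def test_curve_length(self, medium_cohort):
        trials, _ = medium_cohort
        assert len(sliding_rejection(trials, window=5)) == 60 - 5 + 1

    def test_window_one_is_raw_rate(self):
        df = _log("p01", [8] * 4, ["reject", "accept", "reject", "accept"])
        np.testing.assert_allclose(sliding_rejection(df, 1).to_numpy(),
                                   [100, 0, 100, 0])

    def test_window_tiles_constant_block(self):
        df = _log("p01", [8] * 20, (["reject"] * 2 + ["accept"] * 2) * 5)
        curve = sliding_rejection(df, window=4)
        assert np.allclose(curve.to_numpy(), 50.0)
        assert curve.between(0, 100).all()

    def test_window_exceeding_session_raises(self):
        df = _log("p01", [8] * 5, ["accept"] * 5)
        with pytest.raises(ValueError):
            sliding_rejection(df, window=6)


class TestPairedContrast:
    def test_identical_vectors(self):
        res = paired_contrast([10.0] * 5, [10.0] * 5)
        assert res.t == 0 and res.cohens_d == 0 and res.p == 1.0
        assert res.df == 4

    def test_effect_size_from_printed_t_large(self):
        pre, post = _paired_vectors_with_t(-3.89, n=30)
        res = paired_contrast(pre, post)
        assert res.t == pytest.approx(-3.89, abs=1e-9)
        assert res.df == 29
        assert round(res.cohens_d, 2) == 0.71

    def test_effect_size_from_printed_t_small(self):
        pre, post = _paired_vectors_with_t(-2.44, n=30)
        res = paired_contrast(pre, post)
        assert round(res.cohens_d, 2) == 0.45

    def test_d_confidence_interval_matches_reported(self):
        # noncentral-t CI for d at t = 3.89, n = 30
        pre, post = _paired_vectors_with_t(-3.89, n=30)
        ci = paired_contrast(pre, post).ci_d
        assert ci is not None
        assert ci[0] == pytest.approx(0.31, abs=0.02)
        assert ci[1] == pytest.approx(1.12, abs=0.02)

    def test_scale_invariance_of_t_and_d(self, rng):
        pre = rng.normal(50, 10, 30)
        post = pre + rng.normal(-5, 5, 30)
        a = paired_contrast(pre, post)
        b = paired_contrast(pre * 3.7, post * 3.7)
        assert a.t == pytest.approx(b.t)
        assert a.cohens_d == pytest.approx(b.cohens_d)

    def test_constant_nonzero_shift_t_undefined(self):
        with pytest.warns(UserWarning):
            res = paired_contrast([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert np.isnan(res.t)

    def test_bad_input(self):
        with pytest.raises(ValueError):
            paired_contrast([1.0], [2.0])


class TestBenjaminiHochberg:
    def test_printed_worked_example(self):
        res = bh_correct([0.001, 0.001, 0.021, 0.041, 0.062], q=0.05)
        assert res.cutoff_p == pytest.approx(0.021)
        np.testing.assert_array_equal(res.significant,
                                      [True, True, True, False, False])
        np.testing.assert_allclose(res.critical_values,
                                   [0.01, 0.02, 0.03, 0.04, 0.05])

    def test_all_ones_nothing_significant(self):
        res = bh_correct([1.0] * 4)
        assert res.cutoff_p is None and not res.significant.any()

    def test_all_zeros_everything_significant(self):
        res = bh_correct([0.0] * 4)
        assert res.significant.all()

    def test_significance_is_rank_prefix(self, rng):
        for _ in range(20):
            p = rng.random(8)
            res = bh_correct(p, q=0.2)
            sig_sorted = res.significant[np.argsort(p, kind="stable")]
            k = sig_sorted.sum()
            assert sig_sorted[:k].all() and not sig_sorted[k:].any()

    def test_monotone_in_q(self, rng):
        p = rng.random(10)
        small = bh_correct(p, q=0.01).significant
        large = bh_correct(p, q=0.2).significant
        assert (large | ~small).all()  # larger q never removes significances

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bh_correct([])
        with pytest.raises(ValueError):
            bh_correct([0.5], q=1.5)
        with pytest.raises(ValueError):
            bh_correct([1.2])


class TestOfferSizeRegression:
    def test_odds_ratio_is_exp_of_coefficient(self, medium_cohort):
        trials, _ = medium_cohort
        res = offer_size_regression(trials)
        assert res.odds_ratio == pytest.approx(np.exp(res.coefficient))

    def test_sign_consistent_with_offer_monotone_rejection(self, medium_cohort):
        """Rejection decreasing in offer size yields a positive per-token-
        decrease coefficient, hence an odds ratio above 1."""
        trials, _ = medium_cohort
        res = offer_size_regression(trials)
        assert res.coefficient > 0
        assert res.odds_ratio > 1
        assert res.p < 0.05

    def test_single_outcome_raises(self):
        df = pd.concat([_log(f"p{i}", [8] * 10, ["accept"] * 10) for i in range(3)],
                       ignore_index=True)
        with pytest.raises(ValueError, match="separat"):
            offer_size_regression(df)

    def test_single_participant_raises(self):
        df = _log("p01", [8, 2] * 5, ["accept", "reject"] * 5)
        with pytest.raises(ValueError, match="participants"):
            offer_size_regression(df)


class TestRatingContrast:
    @staticmethod
    def _two_block_log(pid, ratings_pre, ratings_post):
        n = len(ratings_pre)
        pre = _log(pid, [8] * n, ["accept"] * n, "baseline", ratings_pre)
        post = _log(pid, [8] * n, ["accept"] * n, "post", ratings_post,
                    start_trial=n + 1)
        return pd.concat([pre, post], ignore_index=True)

    def test_identical_ratings_give_t_zero(self):
        df = pd.concat(
            [self._two_block_log(f"p{i}", [5, 6, 7], [7, 5, 6]) for i in range(4)],
            ignore_index=True)
        res = rating_contrast(df)
        assert res.t == 0 and res.df == 3

    def test_participants_missing_a_block_excluded(self):
        full = [self._two_block_log(f"p{i}", [5, 6], [7, 8]) for i in range(3)]
        missing = _log("p99", [8] * 2, ["accept"] * 2, "baseline", [5, 5])
        df = pd.concat(full + [missing], ignore_index=True)
        res = rating_contrast(df)
        assert res.n == 3  # p99 dropped

    def test_smoke_on_simulated_cohort(self, medium_cohort):
        trials, _ = medium_cohort
        res = rating_contrast(trials)
        assert np.isfinite(res.t) and np.isfinite(res.p)
        assert res.df == res.n - 1

    def test_no_ratings_raises(self):
        df = _log("p01", [8] * 4, ["accept"] * 4)
        with pytest.raises(ValueError):
            rating_contrast(df)


def test_per_offer_contrasts_and_block_stats(medium_cohort):
    trials, _ = medium_cohort
    table, bh = per_offer_contrasts(trials, q=0.05)
    assert (table["offer"].to_numpy() == np.sort(table["offer"])).all()
    assert len(bh.significant) == len(table)
    stats_ = block_stats(trials)
    assert set(stats_.by_block["block"]) == {"baseline", "conditioning", "post"}
    assert stats_.by_block["rejection_rate"].between(0, 100).all()
    assert stats_.rating_means["rating_mean"].between(1, 9).all()


def test_rejection_contrast_direction_on_conditioned_cohort(medium_cohort):
    """Post-conditioning rejection of medium offers drops, so t < 0 and the
    mean post-minus-baseline difference is negative."""
    trials, _ = medium_cohort
    res = rejection_contrast(trials)
    assert res.t < 0
    assert res.mean_diff < 0
    assert res.cohens_d >= 0
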