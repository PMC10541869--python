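import datetime

import numpy as np
import pandas as pd
import pytest

from allocsim.cohort import generate_candidates
from allocsim.errors import ConfigError, ValidationError
from allocsim.waitlist import (
    DynamicsConfig,
    LogisticExitScorer,
    advance_to,
    check_conservation,
    default_exit_scorer,
    initialize_waitlist,
    rank_for_departure,
    step_arrivals,
    step_departures,
)

START = datetime.date(2010, 1, 1)


def make_config(**kwargs):
    kwargs.setdefault("start_date", START)
    return DynamicsConfig(**kwargs)


class TestInitialize:
    def test_initial_list_size(self, candidate_pool):
        state = initialize_waitlist(candidate_pool, make_config(n0=300, seed=1))
        assert len(state.active) == 300
        assert len(state.pool) == len(candidate_pool) - 300
        assert sum(1 for _, _, e in state.event_log if e == "init") == 300

    def test_pool_smaller_than_n0_rejected(self, candidate_pool):
        with pytest.raises(ValidationError, match="n0"):
            initialize_waitlist(candidate_pool.head(100), make_config(n0=300))

    def test_degenerate_target_concentrates_sampling(self, candidate_pool):
        targets = {"blood_group": {"O": 1.0}}
        state = initialize_waitlist(
            candidate_pool, make_config(n0=100, strata_targets=targets, seed=2)
        )
        assert (state.active_frame["blood_group"] == "O").all()

    def test_uniform_blood_group_targets_recovered(self, marginals):
        # Stratified-sampling oracle: with uniform targets the realised
        # blood-group frequencies land within TV 0.1 of uniform.
        pool = generate_candidates(10_000, marginals, seed=11)
        targets = {"blood_group": {bg: 0.25 for bg in ("O", "A", "B", "AB")}}
        state = initialize_waitlist(
            pool, make_config(n0=400, strata_targets=targets, seed=3)
        )
        freq = state.active_frame["blood_group"].value_counts(normalize=True)
        tv = 0.5 * sum(abs(freq.get(bg, 0) - 0.25) for bg in ("O", "A", "B", "AB"))
        assert tv < 0.1

    def test_determinism(self, candidate_pool):
        a = initialize_waitlist(candidate_pool, make_config(seed=4))
        b = initialize_waitlist(candidate_pool, make_config(seed=4))
        assert np.array_equal(a.active, b.active)
        assert a.event_log == b.event_log


class TestArrivalsAndDepartures:
    def test_zero_rate_means_no_arrivals(self, candidate_pool):
        config = make_config(lambda_in=0.0, lambda_out=0.0, seed=5)
        state = initialize_waitlist(candidate_pool, config)
        n_before = len(state.active)
        advance_to(state, START + datetime.timedelta(days=30), config)
        assert len(state.active) == n_before
        assert state.clock == START + datetime.timedelta(days=30)

    def test_departure_removes_highest_scores(self):
        # Sort oracle: distinct scores .9 .7 .5 .3 .1; the two highest leave.
        scores = np.array([0.5, 0.9, 0.1, 0.7, 0.3])
        order = rank_for_departure(
            scores, np.zeros(5, dtype=np.int64), np.array(list("abcde"), dtype=object)
        )
        assert list(order[:2]) == [1, 3]

    def test_departure_ranking_matches_full_sort(self):
        # Brute-force equivalence on lists up to 100 with ties.
        rng = np.random.default_rng(0)
        for n in (1, 5, 50, 100):
            scores = rng.choice([0.1, 0.5, 0.9], size=n)
            listing = rng.integers(0, 3, size=n)
            ids = np.array([f"c{i:03d}" for i in rng.permutation(n)], dtype=object)
            expected = sorted(range(n), key=lambda i: (-scores[i], listing[i], ids[i]))
            assert list(rank_for_departure(scores, listing, ids)) == expected

    def test_ties_broken_by_earlier_listing_then_id(self):
        scores = np.array([0.5, 0.5, 0.5])
        listing = np.array([10, 5, 5], dtype=np.int64)
        ids = np.array(["z", "b", "a"], dtype=object)
        assert list(rank_for_departure(scores, listing, ids)) == [2, 1, 0]

    def test_arrival_sets_listing_date(self, candidate_pool):
        config = make_config(lambda_in=5.0, lambda_out=0.0, seed=6)
        state = initialize_waitlist(candidate_pool, config)
        day = START + datetime.timedelta(days=1)
        step_arrivals(state, day, config)
        arrived = [cid for d, cid, e in state.event_log if e == "arrival"]
        assert arrived
        frame = state.frame.set_index("id")
        assert all(frame.loc[cid, "listing_date"] == day for cid in arrived)

    def test_departures_capped_at_active_size(self, candidate_pool):
        config = make_config(n0=2, lambda_out=50.0, seed=7)
        state = initialize_waitlist(candidate_pool, config)
        with pytest.warns(UserWarning, match="exceed"):
            step_departures(state, START + datetime.timedelta(days=1), config,
                            default_exit_scorer().bind(state.frame))
        assert len(state.active) == 0

    def test_rate_schedule_multiplier(self, marginals):
        # Poisson thinning: k_in doubles 2010 arrivals relative to 2011.
        pool = generate_candidates(4000, marginals, seed=12)
        config = make_config(
            lambda_in=0.7, lambda_out=0.0, k_in={2010: 2.0}, seed=8,
            start_date=datetime.date(2009, 12, 31),
        )
        state = initialize_waitlist(pool, config)
        advance_to(state, datetime.date(2011, 12, 31), config)
        log = state.event_log_frame()
        arrivals = log[log.event == "arrival"]
        per_year = arrivals.groupby([d.year for d in arrivals.date]).size()
        ratio = per_year[2010] / per_year[2011]
        assert 1.5 < ratio < 2.7


class TestAdvance:
    def test_identity_advance(self, candidate_pool):
        config = make_config(seed=9)
        state = initialize_waitlist(candidate_pool, config)
        log_before = list(state.event_log)
        advance_to(state, state.clock, config)
        assert state.event_log == log_before

    def test_target_before_clock_rejected(self, candidate_pool):
        config = make_config(seed=9)
        state = initialize_waitlist(candidate_pool, config)
        with pytest.raises(ValidationError):
            advance_to(state, START - datetime.timedelta(days=1), config)

    def test_split_advance_equals_single_advance(self, candidate_pool):
        # Day-keyed substreams make composition exact, not just in law.
        config = make_config(seed=10)
        one = initialize_waitlist(candidate_pool, config)
        advance_to(one, START + datetime.timedelta(days=40), config)
        two = initialize_waitlist(candidate_pool, config)
        advance_to(two, START + datetime.timedelta(days=13), config)
        advance_to(two, START + datetime.timedelta(days=40), config)
        assert one.event_log == two.event_log
        assert np.array_equal(np.sort(one.active), np.sort(two.active))

    def test_conservation_holds(self, candidate_pool):
        config = make_config(seed=11)
        state = initialize_waitlist(candidate_pool, config)
        advance_to(state, START + datetime.timedelta(days=120), config)
        assert check_conservation(state)


class TestExitScorer:
    def _zero_coefficients(self):
        return {
            "intercept": 0.0, "age": 0.0, "sex_m": 0.0, "lung_disease": 0.0,
            "smoking": 0.0, "diabetes": 0.0, "cardiovascular_disease": 0.0,
            "cancer": 0.0, "pra": 0.0, "years_on_dialysis": 0.0,
            "blood_group": {bg: 0.0 for bg in ("O", "A", "B", "AB")},
            "state": {s: 0.0 for s in ("NSW", "ACT", "VIC", "TAS", "WA", "SA", "NT", "QLD")},
        }

    def test_all_zero_coefficients_score_half(self, candidate_pool):
        scorer = LogisticExitScorer(self._zero_coefficients())
        scores = scorer(candidate_pool.head(10), START)
        assert np.allclose(scores, 0.5)

    def test_missing_coefficient_rejected(self):
        coefficients = self._zero_coefficients()
        del coefficients["diabetes"]
        with pytest.raises(ConfigError, match="diabetes"):
            LogisticExitScorer(coefficients)

    def test_age_weight_monotone_in_rank(self, candidate_pool):
        # Doubling the age coefficient never demotes an older candidate.
        sub = candidate_pool.head(50).reset_index(drop=True)
        base = self._zero_coefficients() | {"age": 0.05}
        heavier = self._zero_coefficients() | {"age": 0.10}
        s1 = LogisticExitScorer(base)(sub, START)
        s2 = LogisticExitScorer(heavier)(sub, START)
        ages = sub["age"].to_numpy()
        for i in range(len(sub)):
            for j in range(len(sub)):
                if ages[i] > ages[j] and s1[i] >= s1[j]:
                    assert s2[i] >= s2[j]

    def test_scores_finite_at_extreme_ages(self):
        frame = pd.DataFrame(
            {
                "age": [0.0, 90.0], "sex": ["F", "M"], "blood_group": ["O", "AB"],
                "state": ["NSW", "NT"], "pra": [0.0, 100.0],
                "lung_disease": [False, True], "smoking": [False, True],
                "diabetes": [False, True], "cardiovascular_disease": [False, True],
                "cancer": [False, True],
                "dialysis_start_date": [None, datetime.date(1990, 1, 1)],
            }
        )
        scores = default_exit_scorer()(frame, START)
        assert np.isfinite(scores).all()
        assert ((scores >= 0) & (scores <= 1)).all()
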