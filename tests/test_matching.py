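"""Candidate pools, exact-key iterations, resampling, aggregation."""

import numpy as np
import pandas as pd
import pytest

from trialmatch.matching import (aggregate_counts,
                                 build_candidate_entries, build_candidate_pool,
                                 match_iteration, pairs_from_table,
                                 participant_keys, prior_visit_count,
                                 run_resampling)
from trialmatch.participant_selection import select_participants

from conftest import make_store, person_row, trial_row


def visits(*dates, person=1):
    frame = pd.DataFrame([(person, d) for d in dates],
                         columns=["person_id", "visit_date"])
    frame["visit_date"] = pd.to_datetime(frame["visit_date"])
    return frame


class TestPriorVisitCount:
    def test_no_visits(self):
        assert prior_visit_count(visits(), "2014-06-01") == 0

    def test_visit_on_index_day_is_excluded(self):
        assert prior_visit_count(visits("2014-06-01"), "2014-06-01") == 0

    def test_closed_lower_endpoint(self):
        vis = visits("2014-05-22", "2014-02-21", "2013-06-01")  # -10, -100, -365
        assert prior_visit_count(vis, "2014-06-01") == 3
        assert prior_visit_count(visits("2013-05-31"), "2014-06-01") == 0


def _pool_store():
    """One participant (person 1) indexed on concept 110 in 2014-05; persons
    2-5 are would-be candidates with different defects."""
    return make_store(
        persons=[person_row(i) for i in (1, 2, 3, 4, 5, 6)],
        conditions=[
            (1, 110, "2014-05-10"), (1, 110, "2013-12-01"),
            # person 2: exact code, right month, reassurance ok -> candidate
            (2, 110, "2014-05-20"), (2, 110, "2014-01-05"),
            # person 3: only a descendant code -> excluded (exact-code rule)
            (3, 111, "2014-05-20"), (3, 111, "2014-01-05"),
            # person 4: exact code but no reassurance event
            (4, 110, "2014-05-20"),
            # person 5: exact code, wrong month
            (5, 110, "2014-04-20"), (5, 110, "2014-01-05"),
            # person 6: enrolled, otherwise perfect
            (6, 110, "2014-05-20"), (6, 110, "2014-01-05"),
        ],
        enrollment=[(1, "TA", "randomized", "2014-06-01"),
                    (6, "TA", "randomized", "2015-06-01")],
        trials=[trial_row("TA", [110])],
    )


class TestCandidatePool:
    def test_pool_membership_rules(self):
        store = _pool_store()
        assignments, _ = select_participants(store)
        assert len(assignments) == 1
        entries = build_candidate_entries(assignments, store)
        assert set(entries["person_id"]) == {2}
        assert entries.iloc[0]["index_date"] == pd.Timestamp("2014-05-20")

    def test_scalar_pool_carries_match_key(self):
        store = _pool_store()
        assignments, _ = select_participants(store)
        pool = build_candidate_pool(assignments.iloc[0], store)
        assert [c.person_id for c in pool] == [2]
        key = pool[0].match_key
        assert key.index_concept_id == 110
        assert key.index_year_month == (2014, 5)
        assert key.prior_visit_count == 0

    def test_candidate_index_date_is_earliest_in_month(self):
        store = _pool_store()
        extra = pd.DataFrame([(2, 110, "2014-05-02")],
                             columns=["person_id", "concept_id", "event_date"])
        extra["event_date"] = pd.to_datetime(extra["event_date"])
        store.conditions = pd.concat([store.conditions, extra], ignore_index=True)
        assignments, _ = select_participants(store)
        entries = build_candidate_entries(assignments, store)
        assert entries.iloc[0]["index_date"] == pd.Timestamp("2014-05-02")

    def test_visit_count_mismatch_blocks_match(self):
        store = _pool_store()
        store.visits = visits("2014-05-01", person=2)  # candidate has 1, participant 0
        assignments, _ = select_participants(store)
        pool = build_candidate_pool(assignments.iloc[0], store)
        assert pool == []


def parts_frame(rows):
    return pd.DataFrame(rows, columns=["person_id", "index_concept_id",
                                       "index_ym", "prior_visit_count"])


def cands_frame(rows):
    frame = pd.DataFrame(rows, columns=["cand_id", "person_id",
                                        "index_concept_id", "index_ym",
                                        "prior_visit_count"])
    frame["index_date"] = pd.Timestamp("2014-05-01")
    return frame


class TestMatchIteration:
    def test_single_compatible_pair_always_matches(self):
        parts = parts_frame([(1, 110, 201405, 0)])
        cands = cands_frame([(0, 10, 110, 201405, 0)])
        for seed in range(5):
            pairs = match_iteration(parts, cands, np.random.default_rng(seed))
            assert pairs.to_dict("records") == [{"person_id": 1, "cand_id": 0}]

    def test_shared_candidate_splits_evenly(self):
        parts = parts_frame([(1, 110, 201405, 0), (2, 110, 201405, 0)])
        cands = cands_frame([(0, 10, 110, 201405, 0)])
        wins = {1: 0, 2: 0}
        for seed in range(400):
            pairs = match_iteration(parts, cands, np.random.default_rng(seed))
            assert len(pairs) == 1
            wins[pairs.iloc[0]["person_id"]] += 1
        assert 140 < wins[1] < 260  # ~Binomial(400, 1/2)

    def test_no_compatible_candidate_leaves_unmatched(self):
        parts = parts_frame([(1, 110, 201405, 0)])
        cands = cands_frame([(0, 10, 110, 201406, 0)])  # wrong month
        pairs = match_iteration(parts, cands, np.random.default_rng(0))
        assert len(pairs) == 0

    def test_same_person_not_used_twice_across_entries(self):
        # person 10 appears as two candidate entries under different keys
        parts = parts_frame([(1, 110, 201405, 0), (2, 120, 201405, 0)])
        cands = cands_frame([(0, 10, 110, 201405, 0), (1, 10, 120, 201405, 0)])
        for seed in range(20):
            pairs = match_iteration(parts, cands, np.random.default_rng(seed))
            assert len(pairs) == 1


class TestRunResampling:
    def test_empty_pools_puts_everyone_in_never_matched(self):
        parts = parts_frame([(1, 110, 201405, 0), (2, 110, 201405, 1)])
        cands = cands_frame([])
        result = run_resampling(parts, cands, n_iterations=10, seed=0)
        assert result.never_matched == {1, 2}
        assert len(result.pairs) == 0

    def test_private_candidates_give_perfect_matching(self):
        parts = parts_frame([(i, 110, 201405, i) for i in range(5)])
        cands = cands_frame([(i, 100 + i, 110, 201405, i) for i in range(5)])
        result = run_resampling(parts, cands, n_iterations=20, seed=3)
        assert result.never_matched == frozenset()
        per_iter = result.pairs.groupby("iteration").size()
        assert (per_iter == 5).all()

    def test_same_seed_reproduces_result(self):
        parts = parts_frame([(i, 110, 201405, 0) for i in range(4)])
        cands = cands_frame([(i, 100 + i, 110, 201405, 0) for i in range(2)])
        r1 = run_resampling(parts, cands, n_iterations=25, seed=9)
        r2 = run_resampling(parts, cands, n_iterations=25, seed=9)
        pd.testing.assert_frame_equal(r1.pairs, r2.pairs)
        assert r1.never_matched == r2.never_matched

    def test_pairs_from_table_round_trip(self):
        parts = parts_frame([(i, 110 + i % 2, 201405, 0) for i in range(4)])
        cands = cands_frame([(i, 100 + i, 110 + i % 2, 201405, 0)
                             for i in range(3)])
        result = run_resampling(parts, cands, n_iterations=7, seed=1)
        person_of = cands.set_index("cand_id")["person_id"]
        table = result.pairs.assign(
            participant_id=result.pairs["person_id"],
            nonparticipant_id=result.pairs["cand_id"].map(person_of))[
            ["iteration", "participant_id", "nonparticipant_id"]]
        assignments = parts.assign(index_date=pd.Timestamp("2014-05-01"))
        rebuilt = pairs_from_table(table, assignments, cands)
        expect = result.pairs.sort_values(["iteration", "person_id"],
                                          ignore_index=True)
        pd.testing.assert_frame_equal(rebuilt, expect)


class TestAggregateCounts:
    def test_constant_covariate_has_prevalence_one(self):
        parts = parts_frame([(1, 110, 201405, 0)])
        cands = cands_frame([(0, 10, 110, 201405, 0), (1, 11, 110, 201405, 0)])
        values = pd.DataFrame({"X": [True, True]}, index=[0, 1])
        result = run_resampling(parts, cands, n_iterations=50, seed=0)
        agg = aggregate_counts(result, values)
        assert agg.iloc[0]["prevalence"] == 1.0

    def test_single_iteration_equals_that_iterations_counts(self):
        parts = parts_frame([(1, 110, 201405, 0), (2, 120, 201406, 1)])
        cands = cands_frame([(0, 10, 110, 201405, 0), (1, 11, 120, 201406, 1)])
        values = pd.DataFrame({"X": [True, False]}, index=[0, 1])
        result = run_resampling(parts, cands, n_iterations=1, seed=0)
        agg = aggregate_counts(result, values).set_index("covariate")
        assert agg.loc["X", "mean_count"] == 1.0
        assert agg.loc["X", "mean_matched"] == 2.0
        assert agg.loc["X", "prevalence"] == 0.5

    def test_two_candidate_lottery_converges_to_expectation(self):
        """One participant, candidates with X=1 and X=0: the mean count over
        many iterations approaches 1/2."""
        parts = parts_frame([(1, 110, 201405, 0)])
        cands = cands_frame([(0, 10, 110, 201405, 0), (1, 11, 110, 201405, 0)])
        values = pd.DataFrame({"X": [True, False]}, index=[0, 1])
        result = run_resampling(parts, cands, n_iterations=1000, seed=4)
        agg = aggregate_counts(result, values)
        assert agg.iloc[0]["mean_count"] == pytest.approx(0.5, abs=0.05)

    def test_strata_split_counts(self):
        parts = parts_frame([(1, 110, 201405, 0), (2, 120, 201406, 0)])
        cands = cands_frame([(0, 10, 110, 201405, 0), (1, 11, 120, 201406, 0)])
        values = pd.DataFrame({"X": [True, False]}, index=[0, 1])
        result = run_resampling(parts, cands, n_iterations=10, seed=0)
        agg = aggregate_counts(result, values,
                               {"left": {1}, "right": {2}}).set_index("stratum")
        assert agg.loc["left", "prevalence"] == 1.0
        assert agg.loc["right", "prevalence"] == 0.0


def test_simulated_cohort_matching_contract(small_sim):
    """On simulated data: keys match bitwise, nonparticipants are unique per
    iteration, and matched sets only contain retained participants."""
    store = small_sim.store
    assignments, _ = select_participants(store)
    parts = participant_keys(assignments, store)
    cands = build_candidate_entries(assignments, store)
    assert set(cands["person_id"]).isdisjoint(store.enrolled_person_ids())
    result = run_resampling(parts, cands, n_iterations=20, seed=5)
    merged = result.pairs.merge(parts, on="person_id").merge(
        cands, on="cand_id", suffixes=("_p", "_c"))
    for col in ("index_concept_id", "index_ym", "prior_visit_count"):
        assert (merged[f"{col}_p"] == merged[f"{col}_c"]).all()
    assert result.never_matched.isdisjoint(set(result.pairs["person_id"]))
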