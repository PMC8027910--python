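"""Index-event selection: earliest trial, closest code, reassurance, audit."""

import numpy as np
import pandas as pd
import pytest

from trialmatch.cdm_store import ConceptAncestry
from trialmatch.errors import ValidationError
from trialmatch.participant_selection import (earliest_enrollment,
                                              find_index_event,
                                              reassurance_check,
                                              select_participants)

from conftest import ANCESTRY_PAIRS, CONCEPTS, make_store, person_row, trial_row

ANCESTRY = ConceptAncestry(ANCESTRY_PAIRS, CONCEPTS["concept_id"])


def enrollments(*rows):
    frame = pd.DataFrame(rows, columns=["person_id", "trial_id", "status",
                                        "status_date"])
    frame["status_date"] = pd.to_datetime(frame["status_date"])
    return frame


def conditions(*rows, person=1):
    frame = pd.DataFrame([(person, c, d) for c, d in rows],
                         columns=["person_id", "concept_id", "event_date"])
    frame["event_date"] = pd.to_datetime(frame["event_date"])
    return frame


TRIAL = pd.Series(trial_row("TA", [110]))


class TestEarliestEnrollment:
    def test_single_record(self):
        enr = enrollments((1, "TA", "randomized", "2014-01-01"))
        assert earliest_enrollment(enr)["trial_id"] == "TA"

    def test_earlier_date_wins(self):
        enr = enrollments((1, "TB", "randomized", "2014-05-01"),
                          (1, "TA", "randomized", "2014-01-01"))
        assert earliest_enrollment(enr)["trial_id"] == "TA"

    def test_date_tie_breaks_by_trial_id(self):
        enr = enrollments((1, "B", "randomized", "2014-01-01"),
                          (1, "A", "randomized", "2014-01-01"))
        assert earliest_enrollment(enr)["trial_id"] == "A"

    def test_empty_raises(self):
        with pytest.raises(ValidationError):
            earliest_enrollment(enrollments())


class TestFindIndexEvent:
    def test_single_qualifying_event(self):
        ev = conditions((110, "2014-05-22"))
        out = find_index_event(ev, TRIAL, "2014-06-01", ANCESTRY)
        assert out.index_date == pd.Timestamp("2014-05-22")
        assert out.days_from_status == 10

    def test_closest_event_wins(self):
        ev = conditions((110, "2013-08-05"), (110, "2014-05-27"))
        out = find_index_event(ev, TRIAL, "2014-06-01", ANCESTRY)
        assert out.days_from_status == 5

    def test_event_366_days_before_is_outside(self):
        # closed interval of length 365: status - 365 qualifies, -366 does not
        ev = conditions((110, "2013-05-31"))
        assert find_index_event(ev, TRIAL, "2014-06-01", ANCESTRY) is None
        ev = conditions((110, "2013-06-01"))
        assert find_index_event(ev, TRIAL, "2014-06-01", ANCESTRY) is not None

    def test_descendant_code_qualifies(self):
        ev = conditions((111, "2014-05-01"))
        out = find_index_event(ev, TRIAL, "2014-06-01", ANCESTRY)
        assert out.index_concept_id == 111

    def test_date_tie_breaks_by_smallest_concept(self):
        ev = conditions((111, "2014-05-01"), (110, "2014-05-01"))
        out = find_index_event(ev, TRIAL, "2014-06-01", ANCESTRY)
        assert out.index_concept_id == 110

    def test_unmappable_trial_raises(self):
        trial = pd.Series(trial_row("TU", [], mappable=False))
        with pytest.raises(ValidationError):
            find_index_event(conditions((110, "2014-05-01")), trial,
                             "2014-06-01", ANCESTRY)


class TestReassurance:
    def test_event_on_day_before_index_passes(self):
        ev = conditions((110, "2014-05-31"), (110, "2014-06-01"))
        assert reassurance_check(ev, 110, "2014-06-01", ANCESTRY)

    def test_event_on_index_day_does_not_count(self):
        ev = conditions((110, "2014-06-01"))
        assert not reassurance_check(ev, 110, "2014-06-01", ANCESTRY)

    def test_descendant_concept_passes(self):
        ev = conditions((111, "2014-02-21"), (110, "2014-06-01"))
        assert reassurance_check(ev, 110, "2014-06-01", ANCESTRY)

    def test_window_lower_edge_is_inclusive(self):
        ev = conditions((110, "2013-06-01"))
        assert reassurance_check(ev, 110, "2014-06-01", ANCESTRY)
        ev = conditions((110, "2013-05-31"))
        assert not reassurance_check(ev, 110, "2014-06-01", ANCESTRY)


def _four_person_store():
    """1 unmappable-trial person, 1 without a code, 1 failing reassurance,
    1 passing everything."""
    return make_store(
        persons=[person_row(i) for i in (1, 2, 3, 4)],
        conditions=[
            (1, 110, "2014-05-01"), (1, 110, "2014-01-01"),  # unmappable trial
            # person 2: no focus code at all
            (2, 300, "2014-05-01"),
            # person 3: index event but nothing in the prior year
            (3, 110, "2014-05-01"),
            # person 4: index event + prior-year descendant reassurance event
            (4, 110, "2014-05-10"), (4, 111, "2013-12-01"),
        ],
        enrollment=[(1, "TU", "randomized", "2014-06-01"),
                    (2, "TA", "randomized", "2014-06-01"),
                    (3, "TA", "randomized", "2014-06-01"),
                    (4, "TA", "randomized", "2014-06-01")],
        trials=[trial_row("TA", [110]), trial_row("TU", [], mappable=False)],
    )


class TestSelectParticipants:
    def test_hand_traced_fixture(self):
        assignments, audit = select_participants(_four_person_store())
        assert audit.as_dict() == {
            "persons_screened": 4, "excluded_unmappable_trial": 1,
            "excluded_no_qualifying_code": 1, "excluded_failed_reassurance": 1,
            "selected": 1}
        assert len(assignments) == 1
        row = assignments.iloc[0]
        assert row["person_id"] == 4 and row["index_concept_id"] == 110
        assert row["index_date"] == pd.Timestamp("2014-05-10")
        assert row["days_from_status"] == 22

    def test_empty_enrollment_gives_empty_output(self):
        store = make_store(persons=[person_row(1)])
        assignments, audit = select_participants(store)
        assert len(assignments) == 0 and audit.persons_screened == 0

    def test_row_order_independence(self):
        store = _four_person_store()
        shuffled = _four_person_store()
        shuffled.conditions = shuffled.conditions.sample(
            frac=1, random_state=5).reset_index(drop=True)
        shuffled.enrollment = shuffled.enrollment.sample(
            frac=1, random_state=6).reset_index(drop=True)
        a1, _ = select_participants(store)
        a2, _ = select_participants(shuffled)
        pd.testing.assert_frame_equal(a1, a2)

    def test_output_satisfies_assignment_invariants(self, small_sim):
        assignments, _ = select_participants(small_sim.store)
        status = pd.to_datetime(assignments["status_date"])
        index = pd.to_datetime(assignments["index_date"])
        assert ((index <= status)
                & (index >= status - np.timedelta64(365, "D"))).all()
        assert (assignments["days_from_status"]
                == (status - index).dt.days).all()

    def test_matches_simulator_bookkeeping(self, small_sim):
        """Selected count equals the generator's enrollable count minus its
        forced (unmappable-trial) exclusions."""
        _, audit = select_participants(small_sim.store)
        gt = small_sim.ground_truth
        assert audit.selected == gt["expected_selected"]
        assert audit.excluded_unmappable_trial == \
            len(gt["forced_excluded_person_ids"])

    def test_vectorized_path_matches_scalar_operations(self, small_sim):
        """The frame-level pipeline agrees with the per-person reference ops."""
        store = small_sim.store
        assignments, _ = select_participants(store)
        by_assign = assignments.set_index("person_id")
        trials = store.trials.set_index("trial_id")
        for pid, grp in store.enrollment.groupby("person_id"):
            chosen = earliest_enrollment(grp)
            trial = trials.loc[chosen["trial_id"]].copy()
            trial["trial_id"] = chosen["trial_id"]
            ev = store.conditions[store.conditions["person_id"] == pid]
            if not trial["mappable"]:
                assert pid not in by_assign.index
                continue
            found = find_index_event(ev, trial, chosen["status_date"],
                                     store.ancestry)
            if found is None or not reassurance_check(
                    ev, found.index_concept_id, found.index_date, store.ancestry):
                assert pid not in by_assign.index
                continue
            row = by_assign.loc[pid]
            assert row["index_concept_id"] == found.index_concept_id
            assert row["index_date"] == found.index_date

    def test_removing_an_event_never_adds_a_participant(self):
        store = _four_person_store()
        baseline, _ = select_participants(store)
        for drop in range(len(store.conditions)):
            pruned = _four_person_store()
            pruned.conditions = pruned.conditions.drop(index=drop)
            got, _ = select_participants(pruned)
            assert set(got["person_id"]) <= set(baseline["person_id"])
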