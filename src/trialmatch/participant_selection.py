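"""Trial-participant selection: earliest trial, index event, reassurance.

Each enrolled person is limited to their earliest trial (earliest status
date, ties broken by smallest trial id).  The index event is the condition
occurrence whose concept is a focus concept of that trial or a descendant,
dated within the 365 days before and including the status date, closest to
the status date (date ties broken by smallest concept id).  A reassurance
requirement then demands the index concept, or one of its descendants, also
recorded in the 365 days before — but not including — the index date.
Persons whose earliest trial has no mappable focus concepts are excluded
with that trial; persons without a qualifying code or failing reassurance
are excluded individually.  Every exclusion is counted, never silently
dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cdm_store import ConceptAncestry, Store, days
from .errors import ValidationError

LOOKBACK_DAYS = 365


@dataclass(frozen=True)
class IndexAssignment:
    person_id: int
    trial_id: str
    status_date: pd.Timestamp
    index_concept_id: int
    index_date: pd.Timestamp
    days_from_status: int


@dataclass
class SelectionAudit:
    persons_screened: int = 0
    excluded_unmappable_trial: int = 0
    excluded_no_qualifying_code: int = 0
    excluded_failed_reassurance: int = 0
    selected: int = 0

    def consistent(self) -> bool:
        return (self.excluded_unmappable_trial + self.excluded_no_qualifying_code
                + self.excluded_failed_reassurance + self.selected
                == self.persons_screened)

    def as_dict(self) -> dict:
        return {
            "persons_screened": self.persons_screened,
            "excluded_unmappable_trial": self.excluded_unmappable_trial,
            "excluded_no_qualifying_code": self.excluded_no_qualifying_code,
            "excluded_failed_reassurance": self.excluded_failed_reassurance,
            "selected": self.selected,
        }


def earliest_enrollment(enrollments: pd.DataFrame) -> pd.Series:
    """The enrollment record with minimal status date for one person.

    Ties on the date are broken by the lexicographically smallest trial id so
    the choice is deterministic.
    """
    if len(enrollments) == 0:
        raise ValidationError("person has no enrollment records")
    ordered = enrollments.sort_values(["status_date", "trial_id"], kind="mergesort")
    return ordered.iloc[0]


def find_index_event(conditions: pd.DataFrame, trial: pd.Series,
                     status_date, ancestry: ConceptAncestry,
                     lookback_days: int = LOOKBACK_DAYS) -> IndexAssignment | None:
    """The qualifying condition event closest to the status date, or None.

    Qualifying: concept in the descendant expansion of the trial's focus
    concepts, dated in the closed interval [status - lookback, status].
    Date ties break by smallest concept id.
    """
    if not trial["mappable"]:
        raise ValidationError(f"trial {trial['trial_id']} is unmappable")
    status = pd.Timestamp(status_date)
    concepts = ancestry.expand(trial["focus_concept_ids"])
    if len(conditions) == 0:
        return None
    dates = pd.to_datetime(conditions["event_date"])
    mask = (conditions["concept_id"].isin(concepts)
            & (dates >= status - days(lookback_days)) & (dates <= status))
    if not mask.any():
        return None
    hits = conditions.loc[mask, ["concept_id"]].assign(event_date=dates[mask])
    hits = hits.sort_values(["event_date", "concept_id"],
                            ascending=[False, True], kind="mergesort")
    best = hits.iloc[0]
    index_date = pd.Timestamp(best["event_date"])
    return IndexAssignment(
        person_id=int(conditions["person_id"].iloc[0]) if "person_id" in conditions else -1,
        trial_id=str(trial["trial_id"]),
        status_date=status,
        index_concept_id=int(best["concept_id"]),
        index_date=index_date,
        days_from_status=int((status - index_date).days),
    )


def reassurance_check(conditions: pd.DataFrame, index_concept: int,
                      index_date, ancestry: ConceptAncestry,
                      lookback_days: int = LOOKBACK_DAYS) -> bool:
    """True iff the index concept (or a descendant) also appears in the 365
    days before, but not including, the index date."""
    if len(conditions) == 0:
        return False
    index_date = pd.Timestamp(index_date)
    concepts = ancestry.descendants_of(index_concept)
    dates = pd.to_datetime(conditions["event_date"])
    mask = (conditions["concept_id"].isin(concepts)
            & (dates >= index_date - days(lookback_days))
            & (dates <= index_date - days(1)))
    return bool(mask.any())


def select_participants(store: Store,
                        lookback_days: int = LOOKBACK_DAYS
                        ) -> tuple[pd.DataFrame, SelectionAudit]:
    """Run the full selection pipeline over every enrolled person.

    Returns the index assignments (one row per selected participant, sorted
    by person id) and the exclusion audit.  Deterministic and independent of
    input row order.  This is a vectorized rendering of
    ``earliest_enrollment`` -> ``find_index_event`` -> ``reassurance_check``;
    the scalar operations are the behavioural reference.
    """
    audit = SelectionAudit()
    columns = ["person_id", "trial_id", "status_date", "index_concept_id",
               "index_date", "days_from_status"]
    enr = store.enrollment
    if len(enr) == 0:
        return pd.DataFrame(columns=columns), audit
    audit.persons_screened = enr["person_id"].nunique()
    earliest = (enr.sort_values(["status_date", "trial_id"], kind="mergesort")
                .groupby("person_id", as_index=False).first())

    mappable = store.trials.set_index("trial_id")["mappable"]
    is_mappable = earliest["trial_id"].map(mappable)
    audit.excluded_unmappable_trial = int((~is_mappable).sum())
    earliest = earliest[is_mappable]

    # trial -> descendant-expanded focus concepts, as a long merge frame
    focus_rows = []
    for trial in store.trials.itertuples(index=False):
        if not trial.mappable:
            continue
        for concept in sorted(store.ancestry.expand(trial.focus_concept_ids)):
            focus_rows.append((trial.trial_id, concept))
    focus = pd.DataFrame(focus_rows, columns=["trial_id", "concept_id"])

    cond = store.conditions[
        store.conditions["person_id"].isin(earliest["person_id"])
        & store.conditions["concept_id"].isin(focus["concept_id"].unique())]
    hits = earliest.merge(cond, on="person_id").merge(
        focus, on=["trial_id", "concept_id"])
    dates = pd.to_datetime(hits["event_date"])
    status = pd.to_datetime(hits["status_date"])
    hits = hits[(dates >= status - days(lookback_days)) & (dates <= status)]
    # the event closest to the status date; ties break by smallest concept id
    hits = hits.sort_values(["person_id", "event_date", "concept_id"],
                            ascending=[True, False, True], kind="mergesort")
    index_rows = hits.groupby("person_id", as_index=False).first()
    audit.excluded_no_qualifying_code = len(earliest) - len(index_rows)

    # reassurance: index concept or descendant in [index-365, index-1]
    if len(index_rows):
        desc_rows = [(c, d)
                     for c in sorted(index_rows["concept_id"].unique())
                     for d in sorted(store.ancestry.descendants_of(c))]
        desc = pd.DataFrame(desc_rows, columns=["concept_id", "match_concept"])
        expanded = index_rows.merge(desc, on="concept_id")
        ev = store.conditions[
            store.conditions["person_id"].isin(index_rows["person_id"])]
        merged = expanded.merge(
            ev.rename(columns={"concept_id": "match_concept",
                               "event_date": "prior_date"}),
            on=["person_id", "match_concept"])
        pdates = pd.to_datetime(merged["prior_date"])
        idates = pd.to_datetime(merged["event_date"])
        ok = merged.loc[(pdates >= idates - days(lookback_days))
                        & (pdates <= idates - days(1)), "person_id"].unique()
        reassured = index_rows[index_rows["person_id"].isin(ok)]
    else:
        reassured = index_rows
    audit.excluded_failed_reassurance = len(index_rows) - len(reassured)
    audit.selected = len(reassured)

    assignments = pd.DataFrame({
        "person_id": reassured["person_id"].astype(int),
        "trial_id": reassured["trial_id"].astype(str),
        "status_date": pd.to_datetime(reassured["status_date"]),
        "index_concept_id": reassured["concept_id"].astype(int),
        "index_date": pd.to_datetime(reassured["event_date"]),
    }) if len(reassured) else pd.DataFrame(columns=columns)
    if len(assignments):
        assignments["days_from_status"] = (
            assignments["status_date"] - assignments["index_date"]).dt.days
        assignments = assignments.sort_values("person_id", ignore_index=True)
    assert audit.consistent(), "selection audit does not add up"
    return assignments[columns], audit
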