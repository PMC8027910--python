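"""Exact 1:1 matching of participants to nonparticipants with resampling.

Each participant is matched to one randomly selected nonparticipant on an
exact key: (1) the index condition — the same condition code, not a
hierarchical relative; (2) the calendar month and year of the index date;
(3) the number of visits to a health care professional in the 365 days
before (not including) the index date.  Candidates must themselves pass the
reassurance requirement at their candidate index date, and a nonparticipant
person can be matched to at most one participant within an iteration.

The procedure is repeated ``n_iterations`` times (1000 by default).  A
participant matched in no iteration at all is excluded from the downstream
cohort; iterations in which a retained participant finds no free candidate
simply contribute no pair.  Iteration ``i`` draws from an independent stream
seeded ``seed + i`` so individual iterations are reproducible.

Downstream descriptive statistics for nonparticipants use the across-
iteration mean of the per-iteration counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

from .cdm_store import Store, days, year_month

KEY_COLUMNS = ("index_concept_id", "index_ym", "prior_visit_count")


class MatchKey(NamedTuple):
    index_concept_id: int
    index_year_month: tuple[int, int]
    prior_visit_count: int


@dataclass(frozen=True)
class CandidateRecord:
    person_id: int
    candidate_index_date: pd.Timestamp
    match_key: MatchKey


@dataclass
class MatchingResult:
    n_iterations: int
    pairs: pd.DataFrame  # columns: iteration, person_id, cand_id
    never_matched: frozenset[int]
    rng_seed: int


def prior_visit_count(visits: pd.DataFrame, index_date) -> int:
    """Visits dated in [index_date - 365, index_date - 1] (index day excluded)."""
    if len(visits) == 0:
        return 0
    index_date = pd.Timestamp(index_date)
    dates = pd.to_datetime(visits["visit_date"])
    mask = (dates >= index_date - days(365)) & (dates <= index_date - days(1))
    return int(mask.sum())


def prior_visit_counts(queries: pd.DataFrame, visits: pd.DataFrame) -> np.ndarray:
    """Vectorized prior_visit_count for (person_id, index_date) query rows."""
    out = np.zeros(len(queries), dtype=np.int64)
    if len(visits) == 0 or len(queries) == 0:
        return out
    vis = visits.sort_values(["person_id", "visit_date"])
    by_person = {pid: grp["visit_date"].values.astype("datetime64[D]").astype(np.int64)
                 for pid, grp in vis.groupby("person_id")}
    qdates = pd.to_datetime(queries["index_date"]).values.astype("datetime64[D]").astype(np.int64)
    qpersons = queries["person_id"].to_numpy()
    for pid in np.unique(qpersons):
        arr = by_person.get(pid)
        if arr is None:
            continue
        sel = qpersons == pid
        d = qdates[sel]
        out[sel] = np.searchsorted(arr, d) - np.searchsorted(arr, d - 365)
    return out


def participant_keys(assignments: pd.DataFrame, store: Store) -> pd.DataFrame:
    """Match keys for each index assignment (computed at the index date)."""
    out = assignments.copy()
    out["index_ym"] = year_month(out["index_date"])
    out["prior_visit_count"] = prior_visit_counts(
        out[["person_id", "index_date"]], store.visits)
    return out


def build_candidate_entries(assignments: pd.DataFrame, store: Store) -> pd.DataFrame:
    """All distinct candidate entries compatible with some participant's
    (index concept, index month) pair.

    A candidate entry is a non-enrolled person with a condition event of the
    exact index concept dated in the index month; the candidate index date is
    the earliest such event in that month, the reassurance requirement must
    hold at that date, and the visit count is taken at the candidate's own
    index date.  Returns a frame with cand_id, person_id, index_concept_id,
    index_date, index_ym, prior_visit_count.
    """
    columns = ["cand_id", "person_id", "index_concept_id", "index_date",
               "index_ym", "prior_visit_count"]
    if len(assignments) == 0:
        return pd.DataFrame(columns=columns)
    enrolled = store.enrolled_person_ids()
    cond = store.conditions[~store.conditions["person_id"].isin(enrolled)].copy()
    needed = assignments.assign(index_ym=year_month(assignments["index_date"]))[
        ["index_concept_id", "index_ym"]].drop_duplicates()
    cond["index_ym"] = year_month(cond["event_date"])
    hits = cond.merge(needed, left_on=["concept_id", "index_ym"],
                      right_on=["index_concept_id", "index_ym"], how="inner")
    if len(hits) == 0:
        return pd.DataFrame(columns=columns)
    cand = (hits.groupby(["person_id", "concept_id", "index_ym"], as_index=False)
            ["event_date"].min()
            .rename(columns={"concept_id": "index_concept_id",
                             "event_date": "index_date"}))
    cand = cand.sort_values(["index_concept_id", "index_ym", "person_id"],
                            ignore_index=True)
    cand["cand_id"] = np.arange(len(cand))

    # reassurance at the candidate index date: index concept or a descendant
    # recorded in [date-365, date-1]
    desc_rows = [(c, d)
                 for c in sorted(cand["index_concept_id"].unique())
                 for d in sorted(store.ancestry.descendants_of(c))]
    desc = pd.DataFrame(desc_rows, columns=["index_concept_id", "match_concept"])
    expanded = cand.merge(desc, on="index_concept_id")
    ev = store.conditions[store.conditions["person_id"].isin(cand["person_id"].unique())]
    merged = expanded.merge(
        ev.rename(columns={"concept_id": "match_concept"}),
        on=["person_id", "match_concept"], how="inner", suffixes=("", "_ev"))
    ev_dates = pd.to_datetime(merged["event_date"])
    idx_dates = pd.to_datetime(merged["index_date"])
    ok = merged.loc[(ev_dates >= idx_dates - days(365))
                    & (ev_dates <= idx_dates - days(1)), "cand_id"].unique()
    cand = cand[cand["cand_id"].isin(ok)].reset_index(drop=True)
    cand["prior_visit_count"] = prior_visit_counts(
        cand[["person_id", "index_date"]], store.visits)
    return cand[columns]


def build_candidate_pool(participant: Mapping, store: Store) -> list[CandidateRecord]:
    """Candidate records compatible with one participant's match key."""
    assignment = pd.DataFrame([{
        "person_id": participant["person_id"],
        "index_concept_id": participant["index_concept_id"],
        "index_date": pd.Timestamp(participant["index_date"]),
    }])
    keys = participant_keys(assignment, store).iloc[0]
    entries = build_candidate_entries(assignment, store)
    pool = entries[(entries["index_concept_id"] == keys["index_concept_id"])
                   & (entries["index_ym"] == keys["index_ym"])
                   & (entries["prior_visit_count"] == keys["prior_visit_count"])]
    records = []
    for row in pool.itertuples(index=False):
        ym = (int(row.index_ym) // 100, int(row.index_ym) % 100)
        records.append(CandidateRecord(
            person_id=int(row.person_id),
            candidate_index_date=pd.Timestamp(row.index_date),
            match_key=MatchKey(int(row.index_concept_id), ym,
                               int(row.prior_visit_count))))
    return records


def _key_codes(participants: pd.DataFrame, candidates: pd.DataFrame):
    both = pd.concat([participants[list(KEY_COLUMNS)],
                      candidates[list(KEY_COLUMNS)]], ignore_index=True)
    codes, _ = pd.factorize(pd.MultiIndex.from_frame(both), sort=True)
    return codes[:len(participants)], codes[len(participants):]


def match_iteration(participants: pd.DataFrame, candidates: pd.DataFrame,
                    rng: np.random.Generator) -> pd.DataFrame:
    """One matching iteration; returns (person_id, cand_id) pair rows.

    Participants are processed in a shuffled order; each draws uniformly at
    random one still-unused compatible candidate (compatible = bitwise-equal
    match key; unused = that nonparticipant person not yet matched this
    iteration).  Candidates are consumed without replacement.
    """
    part_codes, cand_codes = _key_codes(participants, candidates)
    persons, cands = _one_iteration(
        participants["person_id"].to_numpy(), part_codes,
        candidates["person_id"].to_numpy(),
        candidates["cand_id"].to_numpy(), cand_codes, rng)
    return pd.DataFrame({"person_id": persons, "cand_id": cands})


def _one_iteration(part_persons, part_codes, cand_persons, cand_ids,
                   cand_codes, rng) -> pd.DataFrame:
    stacks: dict[int, np.ndarray] = {}
    pointers: dict[int, int] = {}
    order_codes = np.argsort(cand_codes, kind="stable")
    boundaries = np.searchsorted(cand_codes[order_codes],
                                 np.arange(cand_codes.max() + 2 if len(cand_codes) else 0))
    for code in np.unique(cand_codes):
        members = order_codes[boundaries[code]:boundaries[code + 1]]
        stacks[code] = members[rng.permutation(len(members))]
        pointers[code] = 0
    used: set[int] = set()
    pairs_person, pairs_cand = [], []
    for i in rng.permutation(len(part_persons)):
        code = part_codes[i]
        stack = stacks.get(code)
        if stack is None:
            continue
        ptr = pointers[code]
        while ptr < len(stack) and cand_persons[stack[ptr]] in used:
            ptr += 1
        pointers[code] = ptr
        if ptr >= len(stack):
            continue
        j = stack[ptr]
        pointers[code] = ptr + 1
        used.add(cand_persons[j])
        pairs_person.append(part_persons[i])
        pairs_cand.append(cand_ids[j])
    return pairs_person, pairs_cand


def run_resampling(participants: pd.DataFrame, candidates: pd.DataFrame,
                   n_iterations: int = 1000, seed: int = 0) -> MatchingResult:
    """Repeat the matching ``n_iterations`` times from sub-seeded streams.

    ``participants`` needs person_id plus the key columns (see
    ``participant_keys``); ``candidates`` is ``build_candidate_entries``
    output.  Participants matched in no iteration form ``never_matched``.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    part_codes, cand_codes = _key_codes(participants, candidates)
    part_persons = participants["person_id"].to_numpy()
    cand_persons = candidates["person_id"].to_numpy()
    cand_ids = candidates["cand_id"].to_numpy()
    all_iter, all_person, all_cand = [], [], []
    for i in range(n_iterations):
        rng = np.random.default_rng(seed + i)
        persons, cands = _one_iteration(part_persons, part_codes, cand_persons,
                                        cand_ids, cand_codes, rng)
        all_iter.extend([i] * len(persons))
        all_person.extend(persons)
        all_cand.extend(cands)
    pairs = pd.DataFrame({"iteration": np.asarray(all_iter, dtype=np.int64),
                          "person_id": np.asarray(all_person, dtype=np.int64),
                          "cand_id": np.asarray(all_cand, dtype=np.int64)})

    # run-time invariants: per-iteration injectivity and key fidelity
    cand_person_of = dict(zip(cand_ids, cand_persons))
    per_iter_persons = pairs.assign(
        np_person=pairs["cand_id"].map(cand_person_of))
    assert not per_iter_persons.duplicated(["iteration", "np_person"]).any(), \
        "a nonparticipant was matched twice within an iteration"
    code_of_part = dict(zip(part_persons, part_codes))
    code_of_cand = dict(zip(cand_ids, cand_codes))
    assert (pairs["person_id"].map(code_of_part).to_numpy()
            == pairs["cand_id"].map(code_of_cand).to_numpy()).all(), \
        "matched pair with unequal match keys"

    never = frozenset(part_persons) - frozenset(pairs["person_id"].unique())
    return MatchingResult(n_iterations=n_iterations, pairs=pairs,
                          never_matched=never, rng_seed=seed)


def pairs_from_table(matches: pd.DataFrame, assignments: pd.DataFrame,
                     candidates: pd.DataFrame) -> pd.DataFrame:
    """Rebuild (iteration, person_id, cand_id) pairs from a written matches
    table of (iteration, participant_id, nonparticipant_id).

    The matched candidate entry is identified by the nonparticipant person
    together with the participant's index concept and index month, which the
    matching key makes unique.
    """
    part = assignments.assign(index_ym=year_month(assignments["index_date"]))[
        ["person_id", "index_concept_id", "index_ym"]]
    merged = matches.merge(part, left_on="participant_id", right_on="person_id")
    merged = merged.merge(
        candidates[["cand_id", "person_id", "index_concept_id", "index_ym"]],
        left_on=["nonparticipant_id", "index_concept_id", "index_ym"],
        right_on=["person_id", "index_concept_id", "index_ym"],
        suffixes=("", "_cand"))
    out = merged[["iteration", "participant_id", "cand_id"]].rename(
        columns={"participant_id": "person_id"})
    if len(out) != len(matches):
        raise ValueError("matches table references unknown candidate entries")
    return out.sort_values(["iteration", "person_id"], ignore_index=True)


def aggregate_counts(result: MatchingResult, candidate_values: pd.DataFrame,
                     strata: Mapping[str, Iterable[int]] | None = None
                     ) -> pd.DataFrame:
    """Across-iteration mean nonparticipant counts and prevalences.

    ``candidate_values`` is indexed by cand_id with boolean covariate columns.
    For each covariate the mean of the per-iteration matched-set count is
    reported (iterations with no pair contribute zero), and prevalence is
    mean count / mean matched-set size.  ``strata`` maps stratum label ->
    participant person ids; None means a single "all" stratum.
    """
    if strata is None:
        strata = {"all": set(result.pairs["person_id"].unique())
                  | frozenset(result.never_matched)}
    value_cols = [c for c in candidate_values.columns
                  if candidate_values[c].dtype == bool]
    vals = candidate_values.loc[result.pairs["cand_id"], value_cols].to_numpy()
    person = result.pairs["person_id"].to_numpy()
    rows = []
    for stratum in sorted(strata):
        ids = set(strata[stratum])
        mask = np.isin(person, list(ids))
        n_pairs = int(mask.sum())
        mean_matched = n_pairs / result.n_iterations
        sums = vals[mask].sum(axis=0)
        for col, total in zip(value_cols, sums):
            mean_count = total / result.n_iterations
            prevalence = mean_count / mean_matched if mean_matched > 0 else float("nan")
            rows.append({"stratum": stratum, "covariate": col,
                         "mean_count": mean_count,
                         "mean_matched": mean_matched,
                         "prevalence": prevalence})
    return pd.DataFrame(rows)
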