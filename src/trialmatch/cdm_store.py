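"""Minimal OMOP-CDM-style relational store.

Reads, validates and queries the six delimited tables the pipeline consumes:
persons, condition occurrences, drug exposures, visit occurrences, the concept
vocabulary with its transitively closed ancestor relation, plus the trial
enrollment report and the registry-style trial metadata table.

Conventions used throughout the package:

* concept ids and person ids are opaque integers;
* the ancestor relation is stored as an explicit transitive closure with
  self-pairs excluded (``descendants_of`` adds the concept itself);
* every date interval is closed on both ends, and each caller spells out its
  endpoints explicitly (the selection rules mix "before and including" with
  "before, but not including" windows, so no implicit convention is safe).
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .errors import IntegrityError, SchemaError, ValidationError

SEX_CODES = ("male", "female")
RACE_CODES = ("white", "black", "other", "unknown")
ETHNICITY_CODES = ("hispanic", "not_hispanic", "unknown")

#: file name -> required columns
TABLE_SCHEMAS: Mapping[str, tuple[str, ...]] = {
    "person": ("person_id", "birth_date", "sex", "race", "ethnicity"),
    "condition_occurrence": ("person_id", "concept_id", "event_date"),
    "drug_exposure": ("person_id", "concept_id", "event_date"),
    "visit_occurrence": ("person_id", "visit_date"),
    "concept": ("concept_id", "name", "domain"),
    "concept_ancestor": ("ancestor_id", "descendant_id"),
    "enrollment": ("person_id", "trial_id", "status", "status_date"),
    "trials": (
        "trial_id", "focus_concept_ids", "mappable", "phase", "arms",
        "randomized", "blinded", "model", "industry", "dmc", "multisite",
        "overall_enrollment", "site_enrollment", "status",
    ),
}


class ConceptAncestry:
    """Transitive-closure concept hierarchy with set-lookup descendant queries.

    Mirrors the OMOP ``concept_ancestor`` table: an explicit closure, acyclic,
    with self-pairs excluded.  ``descendants_of`` re-adds the concept itself so
    callers can ask "a direct match or a descendant" with one call.
    """

    def __init__(self, pairs: Iterable[tuple[int, int]],
                 known_concepts: Iterable[int] | None = None):
        self._pairs = frozenset((int(a), int(d)) for a, d in pairs)
        self._down: dict[int, frozenset[int]] = {}
        down: dict[int, set[int]] = {}
        for a, d in sorted(self._pairs):
            down.setdefault(a, set()).add(d)
        self._down = {a: frozenset(v) for a, v in down.items()}
        self._known = frozenset(int(c) for c in known_concepts) if known_concepts is not None else None

    @classmethod
    def from_frame(cls, frame: pd.DataFrame,
                   known_concepts: Iterable[int] | None = None) -> "ConceptAncestry":
        return cls(zip(frame["ancestor_id"], frame["descendant_id"]), known_concepts)

    def to_frame(self) -> pd.DataFrame:
        pairs = sorted(self._pairs)
        return pd.DataFrame(pairs, columns=["ancestor_id", "descendant_id"])

    @property
    def pairs(self) -> frozenset[tuple[int, int]]:
        return self._pairs

    def validate(self) -> None:
        """Raise ValidationError on self-pairs, cycles, or a non-closed relation."""
        for a, d in self._pairs:
            if a == d:
                raise ValidationError(f"ancestry contains self-pair ({a},{a})")
        g = nx.DiGraph(self._pairs)
        if not nx.is_directed_acyclic_graph(g):
            cyc = nx.find_cycle(g)
            raise ValidationError(f"ancestry contains a cycle: {cyc}")
        # closure check: (a,b),(b,c) present => (a,c) present
        for a, mids in self._down.items():
            reach = set()
            for b in mids:
                reach |= self._down.get(b, frozenset())
            missing = reach - self._down[a] - {a}
            if missing:
                raise ValidationError(
                    f"ancestry is not transitively closed: {a} -> {sorted(missing)[:5]} missing")
        if self._known is not None:
            ids = {c for pair in self._pairs for c in pair}
            dangling = ids - self._known
            if dangling:
                raise IntegrityError(
                    f"ancestry references unknown concepts: {sorted(dangling)[:5]}")

    def descendants_of(self, concept_id: int) -> frozenset[int]:
        """The concept itself plus every stored descendant."""
        concept_id = int(concept_id)
        if self._known is not None and concept_id not in self._known:
            raise KeyError(f"unknown concept id {concept_id}")
        return self._down.get(concept_id, frozenset()) | {concept_id}

    def expand(self, concept_ids: Iterable[int]) -> frozenset[int]:
        """Union of ``descendants_of`` over a concept set."""
        out: set[int] = set()
        for c in concept_ids:
            out |= self.descendants_of(c)
        return frozenset(out)


@dataclass
class Store:
    """Validated in-memory bundle of the pipeline's input tables."""

    persons: pd.DataFrame
    conditions: pd.DataFrame
    drugs: pd.DataFrame
    visits: pd.DataFrame
    concepts: pd.DataFrame
    ancestry: ConceptAncestry
    enrollment: pd.DataFrame
    trials: pd.DataFrame
    counts: dict = field(default_factory=dict)

    def enrolled_person_ids(self) -> frozenset[int]:
        return frozenset(self.enrollment["person_id"].tolist())


def _require_columns(frame: pd.DataFrame, table: str) -> None:
    missing = [c for c in TABLE_SCHEMAS[table] if c not in frame.columns]
    if missing:
        raise SchemaError(f"table '{table}' is missing columns {missing}")


def _parse_dates(frame: pd.DataFrame, column: str, table: str) -> None:
    try:
        frame[column] = pd.to_datetime(frame[column], format="%Y-%m-%d")
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"table '{table}', column '{column}': {exc}") from exc


def _parse_bool(series: pd.Series, table: str, column: str) -> pd.Series:
    mapping = {"true": True, "false": False, "1": True, "0": False}
    lowered = series.astype(str).str.strip().str.lower()
    bad = ~lowered.isin(mapping)
    if bad.any():
        raise SchemaError(
            f"table '{table}', column '{column}': unparseable boolean "
            f"{series[bad].iloc[0]!r}")
    return lowered.map(mapping)


def _parse_focus(series: pd.Series) -> pd.Series:
    def split(value) -> tuple[int, ...]:
        if pd.isna(value) or str(value).strip() == "":
            return ()
        return tuple(int(tok) for tok in str(value).split(";"))
    return series.map(split)


def validate_store(store: Store) -> None:
    """Check referential integrity and value-level invariants; raise on failure."""
    persons = store.persons
    if persons["person_id"].duplicated().any():
        dup = persons.loc[persons["person_id"].duplicated(), "person_id"].iloc[0]
        raise IntegrityError(f"duplicate person_id {dup}")
    for col, codes in (("sex", SEX_CODES), ("race", RACE_CODES),
                       ("ethnicity", ETHNICITY_CODES)):
        bad = ~persons[col].isin(codes)
        if bad.any():
            raise SchemaError(
                f"person.{col}: unrecognized code {persons.loc[bad, col].iloc[0]!r}")

    person_ids = set(persons["person_id"])
    concept_ids = set(store.concepts["concept_id"])
    for name, frame in (("condition_occurrence", store.conditions),
                        ("drug_exposure", store.drugs),
                        ("visit_occurrence", store.visits),
                        ("enrollment", store.enrollment)):
        dangling = set(frame["person_id"]) - person_ids
        if dangling:
            row = frame.index[frame["person_id"] == next(iter(dangling))][0]
            raise IntegrityError(
                f"{name} row {row}: person_id {next(iter(dangling))} not in person table")
    for name, frame in (("condition_occurrence", store.conditions),
                        ("drug_exposure", store.drugs)):
        dangling = set(frame["concept_id"]) - concept_ids
        if dangling:
            raise IntegrityError(
                f"{name}: concept_id {sorted(dangling)[0]} not in concept table")

    store.ancestry.validate()

    trial_ids = set(store.trials["trial_id"])
    dangling = set(store.enrollment["trial_id"]) - trial_ids
    if dangling:
        raise IntegrityError(f"enrollment: trial_id {sorted(dangling)[0]!r} not in trials table")
    for _, trial in store.trials.iterrows():
        focus = trial["focus_concept_ids"]
        if trial["mappable"] and not focus:
            raise ValidationError(
                f"trial {trial['trial_id']}: mappable but has no focus concepts")
        bad = set(focus) - concept_ids
        if bad:
            raise IntegrityError(
                f"trial {trial['trial_id']}: focus concept {sorted(bad)[0]} unknown")
    dup = store.enrollment.duplicated(["person_id", "trial_id", "status_date"])
    if dup.any():
        raise IntegrityError(
            f"enrollment: duplicate (person_id, trial_id, status_date) at row {dup.idxmax()}")

    # birth_date <= every event date for that person
    births = persons.set_index("person_id")["birth_date"]
    for name, frame, col in (("condition_occurrence", store.conditions, "event_date"),
                             ("drug_exposure", store.drugs, "event_date"),
                             ("visit_occurrence", store.visits, "visit_date"),
                             ("enrollment", store.enrollment, "status_date")):
        if len(frame) == 0:
            continue
        merged = frame[["person_id", col]].merge(
            births, left_on="person_id", right_index=True)
        bad = merged[col] < merged["birth_date"]
        if bad.any():
            pid = merged.loc[bad, "person_id"].iloc[0]
            raise ValidationError(
                f"{name}: person {pid} has an event before their birth date")


def load_store(directory: str | Path) -> Store:
    """Load and validate the eight CSV tables from ``directory``.

    Raises SchemaError for missing columns, IntegrityError for dangling
    foreign keys, ValidationError for value-level invariant failures.
    """
    directory = Path(directory)
    frames: dict[str, pd.DataFrame] = {}
    for table in TABLE_SCHEMAS:
        path = directory / f"{table}.csv"
        if not path.exists():
            raise SchemaError(f"missing input file: {path}")
        frames[table] = pd.read_csv(path)
        _require_columns(frames[table], table)

    persons = frames["person"]
    _parse_dates(persons, "birth_date", "person")
    for table, col in (("condition_occurrence", "event_date"),
                       ("drug_exposure", "event_date"),
                       ("visit_occurrence", "visit_date"),
                       ("enrollment", "status_date")):
        _parse_dates(frames[table], col, table)

    trials = frames["trials"]
    trials["focus_concept_ids"] = _parse_focus(trials["focus_concept_ids"])
    for col in ("mappable", "randomized", "blinded", "industry", "dmc", "multisite"):
        trials[col] = _parse_bool(trials[col], "trials", col)
    trials["trial_id"] = trials["trial_id"].astype(str)
    frames["enrollment"]["trial_id"] = frames["enrollment"]["trial_id"].astype(str)

    ancestry = ConceptAncestry.from_frame(
        frames["concept_ancestor"], known_concepts=frames["concept"]["concept_id"])

    store = Store(
        persons=persons,
        conditions=frames["condition_occurrence"],
        drugs=frames["drug_exposure"],
        visits=frames["visit_occurrence"],
        concepts=frames["concept"],
        ancestry=ancestry,
        enrollment=frames["enrollment"],
        trials=trials,
    )
    validate_store(store)
    store.counts = {
        "persons": len(store.persons),
        "conditions": len(store.conditions),
        "drugs": len(store.drugs),
        "visits": len(store.visits),
        "concepts": len(store.concepts),
        "ancestry_pairs": len(ancestry.pairs),
        "enrollment": len(store.enrollment),
        "trials": len(store.trials),
    }
    return store


def write_store(store: Store, directory: str | Path) -> dict[str, Path]:
    """Write the store back to CSV in the canonical on-disk format."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _dates(frame: pd.DataFrame, cols: Iterable[str]) -> pd.DataFrame:
        frame = frame.copy()
        for col in cols:
            frame[col] = pd.to_datetime(frame[col]).dt.strftime("%Y-%m-%d")
        return frame

    tables = {
        "person": _dates(store.persons, ["birth_date"]).sort_values("person_id"),
        "condition_occurrence": _dates(store.conditions, ["event_date"]).sort_values(
            ["person_id", "event_date", "concept_id"]),
        "drug_exposure": _dates(store.drugs, ["event_date"]).sort_values(
            ["person_id", "event_date", "concept_id"]),
        "visit_occurrence": _dates(store.visits, ["visit_date"]).sort_values(
            ["person_id", "visit_date"]),
        "concept": store.concepts.sort_values("concept_id"),
        "concept_ancestor": store.ancestry.to_frame(),
        "enrollment": _dates(store.enrollment, ["status_date"]).sort_values(
            ["person_id", "trial_id", "status_date"]),
    }
    trials = store.trials.copy()
    trials["focus_concept_ids"] = trials["focus_concept_ids"].map(
        lambda ids: ";".join(str(i) for i in ids))
    for col in ("mappable", "randomized", "blinded", "industry", "dmc", "multisite"):
        trials[col] = trials[col].map({True: "true", False: "false"})
    tables["trials"] = trials.sort_values("trial_id")

    for name, frame in tables.items():
        path = directory / f"{name}.csv"
        frame.to_csv(path, index=False)
        paths[name] = path
    return paths


def has_code_in_window(events: pd.DataFrame, target_concept: int,
                       ancestry: ConceptAncestry,
                       window_start, window_end) -> tuple[bool, list]:
    """True iff some condition event matches ``target_concept`` or a descendant
    with a date in the closed interval [window_start, window_end].

    ``events`` is a frame with ``concept_id`` and ``event_date`` columns
    (a single person's condition events).  Returns the matching dates too.
    """
    window_start = pd.Timestamp(window_start)
    window_end = pd.Timestamp(window_end)
    if window_start > window_end:
        raise ValueError("window start must not be after window end")
    if len(events) == 0:
        return False, []
    concepts = ancestry.descendants_of(target_concept)
    dates = pd.to_datetime(events["event_date"])
    mask = events["concept_id"].isin(concepts) & (dates >= window_start) & (dates <= window_end)
    matches = sorted(dates[mask].tolist())
    return bool(mask.any()), matches


def days(n: int) -> datetime.timedelta:
    """Shorthand for a timedelta of ``n`` calendar days."""
    return datetime.timedelta(days=int(n))


def year_month(dates: pd.Series) -> pd.Series:
    """(year, month) key of each date, encoded as year*100 + month."""
    dates = pd.to_datetime(dates)
    return dates.dt.year * 100 + dates.dt.month
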