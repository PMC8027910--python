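"""Shared fixtures: a hand-built miniature store and a small simulated study."""

import datetime

import pandas as pd
import pytest
from hypothesis import settings

from trialmatch.cdm_store import ConceptAncestry, Store, validate_store
from trialmatch.synthetic_data import SimConfig, generate

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


def D(text: str) -> pd.Timestamp:
    return pd.Timestamp(text)


# hand-built concept world:
#   100 (anchor A) -> 110 -> 111          (three-level chain)
#   200 (anchor B) -> 210                 210 also under 100 via pair (100,210)
#   300 unrelated condition; 500 -> 501, 502 (two children)
#   400 drug class -> 401
ANCESTRY_PAIRS = [
    (100, 110), (100, 111), (110, 111), (100, 210),
    (200, 210),
    (500, 501), (500, 502),
    (400, 401),
]
CONCEPTS = pd.DataFrame({
    "concept_id": [100, 110, 111, 200, 210, 300, 400, 401, 500, 501, 502],
    "name": ["anchor A", "A child", "A grandchild", "anchor B", "shared leaf",
             "unrelated", "drug class", "drug member", "two-kid parent",
             "kid 1", "kid 2"],
    "domain": ["Condition"] * 6 + ["Drug"] * 2 + ["Condition"] * 3,
})


def make_store(persons=None, conditions=None, drugs=None, visits=None,
               enrollment=None, trials=None, validate=True) -> Store:
    """Assemble a store around the fixed miniature vocabulary."""
    def frame(rows, columns):
        return pd.DataFrame(rows or [], columns=columns)

    persons = frame(persons, ["person_id", "birth_date", "sex", "race", "ethnicity"])
    persons["birth_date"] = pd.to_datetime(persons["birth_date"])
    conditions = frame(conditions, ["person_id", "concept_id", "event_date"])
    conditions["event_date"] = pd.to_datetime(conditions["event_date"])
    drugs = frame(drugs, ["person_id", "concept_id", "event_date"])
    drugs["event_date"] = pd.to_datetime(drugs["event_date"])
    visits = frame(visits, ["person_id", "visit_date"])
    visits["visit_date"] = pd.to_datetime(visits["visit_date"])
    enrollment = frame(enrollment, ["person_id", "trial_id", "status", "status_date"])
    enrollment["status_date"] = pd.to_datetime(enrollment["status_date"])
    trials = frame(trials, ["trial_id", "focus_concept_ids", "mappable", "phase",
                            "arms", "randomized", "blinded", "model", "industry",
                            "dmc", "multisite", "overall_enrollment",
                            "site_enrollment", "status"])
    store = Store(
        persons=persons, conditions=conditions, drugs=drugs, visits=visits,
        concepts=CONCEPTS.copy(),
        ancestry=ConceptAncestry(ANCESTRY_PAIRS, CONCEPTS["concept_id"]),
        enrollment=enrollment, trials=trials)
    if validate:
        validate_store(store)
    return store


def trial_row(trial_id, focus, mappable=True, **overrides):
    row = {"trial_id": trial_id, "focus_concept_ids": tuple(focus),
           "mappable": mappable, "phase": "phase 2", "arms": 2,
           "randomized": True, "blinded": False, "model": "parallel",
           "industry": True, "dmc": True, "multisite": True,
           "overall_enrollment": 100, "site_enrollment": 10,
           "status": "Completed"}
    row.update(overrides)
    return row


def person_row(person_id, birth="1970-06-15", sex="male", race="white",
               ethnicity="not_hispanic"):
    return {"person_id": person_id, "birth_date": birth, "sex": sex,
            "race": race, "ethnicity": ethnicity}


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(seed=42, n_patients=2500, n_enrolled=180, n_trials=18,
                     study_start=datetime.date(2012, 1, 1),
                     study_end=datetime.date(2015, 12, 31))


@pytest.fixture(scope="session")
def small_sim(small_config):
    return generate(small_config)
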