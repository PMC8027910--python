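"""Covariate extraction and standardized-difference balance screening.

A person qualifies for a clinical covariate if at least one event whose
concept falls in the covariate's hierarchy-expanded concept set is recorded
in the 365 days before and including that person's index date (both endpoints
inclusive).  Demographic covariates (age group, sex, race, ethnicity) are
evaluated at the index date.

Imbalance between participants and the iteration-averaged nonparticipant set
is screened with the standardized difference for binary proportions,

    d = (p1 - p2) / sqrt((p1 (1 - p1) + p2 (1 - p2)) / 2),

flagging |d| >= 0.1.  The difference is computed on the participant
proportion versus the across-iteration mean nonparticipant proportion, which
reproduces published balance-table values from their printed percentages.
"""

from __future__ import annotations

import decimal
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .cdm_store import Store, days
from .errors import ValidationError

FLAG_THRESHOLD = 0.1
AGE_GROUPS = ("<18", "18-64", ">=65")

#: demographic indicator columns in report order
DEMOGRAPHIC_COLUMNS = (
    "Age <18", "Age 18-64", "Age >=65",
    "Sex: male", "Sex: female",
    "Ethnicity: Hispanic or Latino", "Ethnicity: not Hispanic or Latino",
    "Ethnicity: Unknown",
    "Race: White", "Race: Black or African American", "Race: Other",
    "Race: Unknown",
)

RACE_LABELS = {"white": "White", "black": "Black or African American",
               "other": "Other", "unknown": "Unknown"}
ETHNICITY_LABELS = {"hispanic": "Hispanic or Latino",
                    "not_hispanic": "not Hispanic or Latino",
                    "unknown": "Unknown"}


@dataclass(frozen=True)
class CovariateDefinition:
    """A named covariate backed by a concept set, expanded through descendants."""

    name: str
    kind: str  # "condition", "drug_class" or "demographic"
    concept_set: frozenset[int] = frozenset()

    def __post_init__(self):
        if self.kind not in ("condition", "drug_class", "demographic"):
            raise ValidationError(f"unknown covariate kind {self.kind!r}")
        if self.kind in ("condition", "drug_class") and not self.concept_set:
            raise ValidationError(f"covariate {self.name!r} has an empty concept set")


def read_covariate_definitions(path) -> list[CovariateDefinition]:
    frame = pd.read_csv(path)
    out = []
    for _, row in frame.iterrows():
        concepts = frozenset(int(tok) for tok in str(row["concept_ids"]).split(";"))
        out.append(CovariateDefinition(row["name"], row["kind"], concepts))
    return out


def floor_age_years(birth_date, at_date) -> int:
    """Completed whole years of age at ``at_date``."""
    birth, at = pd.Timestamp(birth_date), pd.Timestamp(at_date)
    if birth > at:
        raise ValidationError("birth date after index date")
    age = at.year - birth.year - ((at.month, at.day) < (birth.month, birth.day))
    return int(age)


def age_group(age_years: int) -> str:
    if age_years < 18:
        return AGE_GROUPS[0]
    if age_years < 65:
        return AGE_GROUPS[1]
    return AGE_GROUPS[2]


def demographic_covariates(person: Mapping, index_date) -> dict[str, bool]:
    """One-hot demographic indicators for a single person at an index date."""
    grp = age_group(floor_age_years(person["birth_date"], index_date))
    race = RACE_LABELS[person["race"]]
    eth = ETHNICITY_LABELS[person["ethnicity"]]
    out = {name: False for name in DEMOGRAPHIC_COLUMNS}
    out[f"Age {grp}"] = True
    out[f"Sex: {person['sex']}"] = True
    out[f"Ethnicity: {eth}"] = True
    out[f"Race: {race}"] = True
    return out


def demographic_frame(queries: pd.DataFrame, persons: pd.DataFrame) -> pd.DataFrame:
    """Vectorized demographics for a frame of (person_id, index_date) queries.

    Returns a frame indexed like ``queries`` with the one-hot indicator
    columns plus categorical ``age_group``, ``sex``, ``race``, ``ethnicity``.
    """
    merged = queries.merge(persons, on="person_id", how="left", validate="m:1")
    birth = pd.to_datetime(merged["birth_date"])
    at = pd.to_datetime(merged["index_date"])
    if (birth > at).any():
        raise ValidationError("birth date after index date")
    age = at.dt.year - birth.dt.year - (
        (at.dt.month * 100 + at.dt.day) < (birth.dt.month * 100 + birth.dt.day)
    ).astype(int)
    grp = pd.cut(age, bins=[-1, 17, 64, 200], labels=AGE_GROUPS).astype(str)
    out = pd.DataFrame(index=queries.index)
    out["age_group"] = grp.values
    out["sex"] = merged["sex"].values
    out["race"] = merged["race"].map(RACE_LABELS).values
    out["ethnicity"] = merged["ethnicity"].map(ETHNICITY_LABELS).values
    for g in AGE_GROUPS:
        out[f"Age {g}"] = out["age_group"] == g
    out["Sex: male"] = out["sex"] == "male"
    out["Sex: female"] = out["sex"] == "female"
    for code, label in ETHNICITY_LABELS.items():
        out[f"Ethnicity: {label}"] = out["ethnicity"] == label
    for code, label in RACE_LABELS.items():
        out[f"Race: {label}"] = out["race"] == label
    return out


def extract_covariates(queries: pd.DataFrame,
                       definitions: Iterable[CovariateDefinition],
                       store: Store,
                       lookback_days: int = 365) -> pd.DataFrame:
    """Binary covariate matrix for (person_id, index_date) query rows.

    A cell is True iff the person has >=1 event of the covariate's kind whose
    concept lies in the descendant-expanded concept set, dated within
    [index_date - lookback_days, index_date].
    """
    queries = queries.reset_index(drop=True)
    queries = queries.assign(_qid=np.arange(len(queries)))
    out = pd.DataFrame(False, index=queries["_qid"],
                       columns=[d.name for d in definitions if d.kind != "demographic"])
    lo = pd.to_datetime(queries["index_date"]) - days(lookback_days)
    hi = pd.to_datetime(queries["index_date"])
    q = queries[["_qid", "person_id"]].assign(_lo=lo.values, _hi=hi.values)
    for defn in definitions:
        if defn.kind == "demographic":
            continue
        events = store.conditions if defn.kind == "condition" else store.drugs
        concepts = store.ancestry.expand(defn.concept_set)
        ev = events[events["concept_id"].isin(concepts)]
        if len(ev) == 0:
            continue
        merged = ev.merge(q, on="person_id", how="inner")
        dates = pd.to_datetime(merged["event_date"])
        hit = merged.loc[(dates >= merged["_lo"]) & (dates <= merged["_hi"]), "_qid"]
        out.loc[out.index.isin(hit.unique()), defn.name] = True
    out.index = pd.Index(queries["person_id"].values, name="person_id") \
        if queries["person_id"].is_unique else out.index
    return out


def covariate_matrix(queries: pd.DataFrame,
                     definitions: Iterable[CovariateDefinition],
                     store: Store,
                     lookback_days: int = 365,
                     include_demographics: bool = True) -> pd.DataFrame:
    """Clinical indicator matrix plus (optionally) demographic indicators.

    Row order follows ``queries``; the index is positional, with person_id and
    index_date carried as columns ``_person_id`` / ``_index_date``.
    """
    queries = queries.reset_index(drop=True)
    clin = extract_covariates(queries, definitions, store, lookback_days)
    clin = clin.reset_index(drop=True)
    parts = [clin]
    if include_demographics:
        demo = demographic_frame(queries, store.persons).reset_index(drop=True)
        parts.append(demo)
    out = pd.concat(parts, axis=1)
    out.insert(0, "_person_id", queries["person_id"].values)
    out.insert(1, "_index_date", pd.to_datetime(queries["index_date"]).values)
    return out


def std_diff_binary(p1: float, p2: float) -> float:
    """Standardized difference of two proportions.

    Antisymmetric; zero when the proportions agree.  The degenerate case
    p1 == p2 in {0, 1} has a zero denominator and is defined as 0 with a
    warning.
    """
    if not (0.0 <= p1 <= 1.0 and 0.0 <= p2 <= 1.0):
        raise ValueError("proportions must lie in [0, 1]")
    if p1 == p2:
        if p1 in (0.0, 1.0):
            warnings.warn("standardized difference undefined for identical "
                          "degenerate proportions; returning 0", RuntimeWarning,
                          stacklevel=2)
        return 0.0
    denom = np.sqrt((p1 * (1.0 - p1) + p2 * (1.0 - p2)) / 2.0)
    if denom == 0.0:  # p1, p2 are opposite extremes: the formula diverges
        return float(np.inf) if p1 > p2 else float(-np.inf)
    return float((p1 - p2) / denom)


def std_diff_continuous(m1: float, s1: float, m2: float, s2: float) -> float:
    """Standardized difference of two means with pooled spread."""
    if s1 < 0 or s2 < 0:
        raise ValueError("standard deviations must be nonnegative")
    denom = np.sqrt((s1 ** 2 + s2 ** 2) / 2.0)
    if denom == 0.0:
        if m1 == m2:
            return 0.0
        raise ValueError("zero pooled spread with unequal means")
    return float((m1 - m2) / denom)


def round_half_away(value: float, ndigits: int = 3) -> float:
    """Round half away from zero at ``ndigits`` decimals (display convention)."""
    if not np.isfinite(value):
        return float(value)
    quant = decimal.Decimal(1).scaleb(-ndigits)
    return float(decimal.Decimal(repr(float(value))).quantize(
        quant, rounding=decimal.ROUND_HALF_UP))


def compare_cohorts(participant_matrix: pd.DataFrame,
                    strata: Mapping[str, Iterable[int]],
                    nonparticipant_agg: pd.DataFrame,
                    flag_threshold: float = FLAG_THRESHOLD) -> pd.DataFrame:
    """Balance table: one row per (stratum, covariate).

    ``participant_matrix`` is a covariate_matrix frame for participants;
    ``strata`` maps stratum label -> participant person ids;
    ``nonparticipant_agg`` is the aggregate_counts output with columns
    (stratum, covariate, mean_count, mean_matched, prevalence).

    The standardized difference is computed on the participant proportion
    versus the across-iteration mean nonparticipant proportion, and rows with
    |d| >= flag_threshold are flagged.
    """
    value_cols = [c for c in participant_matrix.columns
                  if participant_matrix[c].dtype == bool]
    agg = nonparticipant_agg.set_index(["stratum", "covariate"])
    rows = []
    for stratum in sorted(strata):
        ids = set(strata[stratum])
        sub = participant_matrix[participant_matrix["_person_id"].isin(ids)]
        n1 = len(sub)
        for cov in value_cols:
            key = (stratum, cov)
            if key not in agg.index or n1 == 0:
                continue
            arow = agg.loc[key]
            p1 = float(sub[cov].mean())
            p2 = float(arow["prevalence"])
            if np.isnan(p2):
                continue
            d = std_diff_binary(p1, p2)
            rows.append({
                "domain": stratum, "covariate": cov,
                "n_participants": n1,
                "count_participants": int(sub[cov].sum()),
                "p_participant": p1,
                "mean_n_nonparticipants": float(arow["mean_matched"]),
                "mean_count_nonparticipants": float(arow["mean_count"]),
                "p_nonparticipant": p2,
                "std_diff": d,
                "std_diff_display": round_half_away(d, 3),
                "flagged": bool(abs(d) >= flag_threshold),
            })
    out = pd.DataFrame(rows, columns=[
        "domain", "covariate", "n_participants", "count_participants",
        "p_participant", "mean_n_nonparticipants", "mean_count_nonparticipants",
        "p_nonparticipant", "std_diff", "std_diff_display", "flagged"])
    if len(out):
        out = out.sort_values(["domain", "covariate"], ignore_index=True)
    return out
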