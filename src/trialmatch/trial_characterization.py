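"""Disease-domain derivation and trial-metadata recoding.

Disease domains are derived from ancestor concepts of each trial's
condition(s) of focus: a trial carries domain *d* when some focus concept is
*d*'s anchor concept or one of its descendants, so domains are not mutually
exclusive.  Registry metadata are collapsed into the analysis categories:
combination phases count as their latest phase (phase 1/phase 2 is phase 2),
arms are grouped 1 / 2 / >=3, overall enrollment is binned <50 / 50-499 /
>=500 and site enrollment <5 / 5-19 / >=20 (anticipated enrollment stands in
when the actual figure is absent), and free-text status strings are
normalized to five rows.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .cdm_store import ConceptAncestry
from .errors import ValidationError

CHARACTERISTIC_COLUMNS = (
    "phase_group", "arms_group", "randomized", "blinded", "intervention_model",
    "industry_sponsor", "dmc", "multisite", "overall_enrollment_bin",
    "site_enrollment_bin",
)

STATUS_ROWS = ("completed", "recruiting", "active_not_recruiting",
               "terminated_suspended_withdrawn", "unknown_status")


@dataclass(frozen=True)
class DomainAssignment:
    trial_id: str
    domains: frozenset[str]


def assign_domains(trial: Mapping, ancestry: ConceptAncestry,
                   domain_concepts: Mapping[str, int]) -> DomainAssignment:
    """Domains whose anchor concept covers some focus concept of the trial."""
    if not trial["mappable"]:
        raise ValidationError(
            f"trial {trial['trial_id']} is unmappable and must be excluded upstream")
    focus = set(trial["focus_concept_ids"])
    domains = {label for label, anchor in domain_concepts.items()
               if focus & set(ancestry.descendants_of(anchor))}
    return DomainAssignment(str(trial["trial_id"]), frozenset(domains))


def domain_table(trials: pd.DataFrame, ancestry: ConceptAncestry,
                 domain_concepts: Mapping[str, int]) -> pd.DataFrame:
    """Long (trial_id, domain) table over the mappable trials."""
    rows = []
    for _, trial in trials.iterrows():
        if not trial["mappable"]:
            continue
        for domain in sorted(assign_domains(trial, ancestry, domain_concepts).domains):
            rows.append({"trial_id": trial["trial_id"], "domain": domain})
    return pd.DataFrame(rows, columns=["trial_id", "domain"])


def top_k_domains(domains: pd.DataFrame, k: int = 4) -> list[str]:
    """The k domain labels with the most trials (ties broken alphabetically)."""
    counts = domains.groupby("domain").size().sort_values(ascending=False)
    ordered = sorted(counts.index, key=lambda d: (-counts[d], d))
    return ordered[:k]


def collapse_phase(phase_label) -> int:
    """Latest phase of a possibly-combined label ("phase 1/phase 2" -> 2)."""
    text = str(phase_label).strip().lower()
    found = re.findall(r"[1-4]", text)
    if not found or not re.fullmatch(r"(early\s+)?phase[\s1-4/phase]*|[1-4/ ]+", text):
        raise ValidationError(f"unrecognized phase label {phase_label!r}")
    return max(int(tok) for tok in found)


def normalize_status(status_label) -> str:
    text = str(status_label).strip().lower()
    if "complet" in text:
        return "completed"
    if "active" in text:
        return "active_not_recruiting"
    if "recruit" in text:
        return "recruiting"
    if any(tok in text for tok in ("terminat", "suspend", "withdraw")):
        return "terminated_suspended_withdrawn"
    return "unknown_status"


def bin_enrollment(value: int, edges: tuple[int, int], labels: tuple[str, str, str]) -> str:
    if value < 0:
        raise ValidationError("enrollment cannot be negative")
    if value < edges[0]:
        return labels[0]
    if value < edges[1]:
        return labels[1]
    return labels[2]


def bin_trial(trial: Mapping) -> dict:
    """Analysis categories for one trial record.

    ``overall_enrollment`` / ``site_enrollment`` may be missing when an
    ``anticipated_enrollment`` / ``anticipated_site_enrollment`` figure is
    present; the anticipated value is then used.
    """
    def effective(actual_key: str, anticipated_key: str) -> int:
        actual = trial.get(actual_key)
        if actual is None or (isinstance(actual, float) and pd.isna(actual)):
            actual = trial.get(anticipated_key)
        if actual is None or (isinstance(actual, float) and pd.isna(actual)):
            raise ValidationError(f"trial {trial['trial_id']}: no {actual_key}")
        return int(actual)

    arms = int(trial["arms"])
    if arms < 1:
        raise ValidationError("a trial needs at least one arm")
    return {
        "trial_id": str(trial["trial_id"]),
        "phase_group": collapse_phase(trial["phase"]),
        "arms_group": {1: "1", 2: "2"}.get(arms, "3plus"),
        "randomized": bool(trial["randomized"]),
        "blinded": bool(trial["blinded"]),
        "intervention_model": str(trial["model"]),
        "industry_sponsor": bool(trial["industry"]),
        "dmc": bool(trial["dmc"]),
        "multisite": bool(trial["multisite"]),
        "overall_enrollment_bin": bin_enrollment(
            effective("overall_enrollment", "anticipated_enrollment"),
            (50, 500), ("lt50", "50to499", "ge500")),
        "site_enrollment_bin": bin_enrollment(
            effective("site_enrollment", "anticipated_site_enrollment"),
            (5, 20), ("lt5", "5to19", "ge20")),
        "status_group": normalize_status(trial["status"]),
    }


def categorical_table(trials: pd.DataFrame) -> pd.DataFrame:
    """One recoded row per mappable trial."""
    rows = [bin_trial(trial) for _, trial in trials.iterrows() if trial["mappable"]]
    return pd.DataFrame(rows)
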