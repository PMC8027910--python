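"""Synthetic EHR + enrollment-report + trial-metadata generator.

Emulates the three linked sources the pipeline consumes — an OMOP-style EHR
extract, an internal trial-enrollment report, and a registry-style trial
metadata table — with known ground truth, so every downstream stage can be
exercised without any external data.

Generating mechanism, in brief:

* A small concept vocabulary is built per run: one "focus" condition tree per
  disease domain (root -> branching children -> grandchildren, transitively
  closed), plus one private concept block (a parent and three children) per
  clinical covariate.
* Each person carries an independent Bernoulli indicator per covariate at its
  configured baseline prevalence.  A covariate-positive person receives one
  event per 180-day block across the generation span; consecutive events are
  therefore under 360 days apart, so any 365-day lookback window inside the
  span sees at least one event and windowed prevalence equals the latent
  indicator.
* Enrollment is logistic selection on the covariate indicators: exactly
  ``n_enrolled`` persons are sampled without replacement with weights
  ``exp(sum_c bias_c * x_c)``.  Zero bias gives a uniform draw, so enrolled
  and non-enrolled prevalences differ only by sampling noise.
* Every enrolled person is forced to satisfy the downstream selection rules:
  a focus-condition event within 60 days before the status date (the index
  event) and a same-concept event 1-365 days before that (the reassurance
  event).  Enrollees of an unmappable trial are excluded later by the trial
  rule, which the generator records as forced exclusions.
* Non-enrolled "carrier" persons receive recurring events of one focus
  concept so the matching stage has candidate pools with realistic contention.
* Visit counts are Poisson with the configured rate and uniform dates, giving
  integer prior-visit counts with realistic ties for exact matching.

Fixing the seed makes the output byte-identical.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .cdm_store import ConceptAncestry, Store, days, validate_store, write_store
from .covariate_comparison import CovariateDefinition
from .errors import ConfigError

DOMAIN_LABELS = ("neoplastic", "digestive", "inflammatory", "cardiovascular")
#: trial counts per domain in the emulated registry lean toward neoplastic
#: disease, mirroring the mix at a large academic center (86/31/28/27).
DOMAIN_WEIGHTS = (0.50, 0.18, 0.163, 0.157)

#: registry-style categorical distributions (marginals of the emulated trial
#: population; raw phase strings include combination labels on purpose).
DEFAULT_TRIAL_PARAMS: Mapping[str, tuple[tuple, tuple]] = {
    "phase": (("phase 1", "phase 1/phase 2", "phase 2", "phase 2/phase 3",
               "phase 3", "phase 4"),
              (0.10, 0.08, 0.33, 0.08, 0.32, 0.09)),
    "arms": ((1, 2, 3, 4), (0.28, 0.44, 0.20, 0.08)),
    "randomized": ((True, False), (0.579, 0.421)),
    "blinded": ((True, False), (0.401, 0.599)),
    "model": (("single_group", "parallel", "other"), (0.332, 0.619, 0.049)),
    "industry": ((True, False), (0.901, 0.099)),
    "dmc": ((True, False), (0.693, 0.307)),
    "multisite": ((True, False), (0.837, 0.163)),
    "overall_enrollment_bin": (("lt50", "50to499", "ge500"), (0.243, 0.50, 0.257)),
    "site_enrollment_bin": (("lt5", "5to19", "ge20"), (0.238, 0.55, 0.212)),
    "status": (("Completed", "Recruiting", "Active, not recruiting",
                "Terminated", "Unknown status"),
               (0.545, 0.099, 0.198, 0.124, 0.034)),
}

#: 31 condition covariates and 17 medication-class covariates with baseline
#: prevalences typical of a comorbid hospital population.
CONDITION_COVARIATES: Mapping[str, float] = {
    "Acute respiratory disease": 0.097,
    "Chronic liver disease": 0.056,
    "Chronic obstructive lung disease": 0.079,
    "Depressive disorder": 0.113,
    "Diabetes": 0.179,
    "Gastroesophageal reflux disease": 0.144,
    "Hyperlipidemia": 0.255,
    "Hypertensive disorder": 0.427,
    "Lesion of liver": 0.110,
    "Obesity": 0.059,
    "Osteoarthritis": 0.176,
    "Pneumonia": 0.122,
    "Renal impairment": 0.173,
    "Urinary tract infectious diseases": 0.126,
    "Viral hepatitis C infection": 0.026,
    "Visual system disorder": 0.141,
    "Atrial fibrillation": 0.086,
    "Cerebrovascular disease": 0.060,
    "Coronary arteriosclerosis": 0.124,
    "Heart disease": 0.369,
    "Heart failure": 0.087,
    "Ischemic heart disease": 0.055,
    "Peripheral vascular disease": 0.022,
    "Venous thrombosis": 0.081,
    "Hematologic neoplasm": 0.428,
    "Malignant lymphoma": 0.236,
    "Malignant neoplastic disease": 0.500,
    "Malignant tumor of breast": 0.164,
    "Malignant tumor of lung": 0.094,
    "Malignant tumor of urinary bladder": 0.089,
    "Primary malignant neoplasm of prostate": 0.088,
}
DRUG_COVARIATES: Mapping[str, float] = {
    "Agents acting on the renin-angiotensin system": 0.273,
    "Antibacterial medications for systemic use": 0.625,
    "Antidepressant medications": 0.207,
    "Antiepileptic medications": 0.233,
    "Anti-inflammatory and antirheumatic products": 0.297,
    "Antineoplastic agents": 0.463,
    "Antithrombotic agents": 0.539,
    "Beta blocking agents": 0.279,
    "Calcium channel blockers": 0.228,
    "Diuretic medications": 0.297,
    "Drugs for acid-related disorders": 0.586,
    "Drugs for obstructive airway diseases": 0.237,
    "Drugs used in diabetes": 0.214,
    "Immunosuppressant medications": 0.129,
    "Lipid-modifying agents": 0.310,
    "Opioids": 0.555,
    "Psycholeptic medications": 0.490,
}

#: +/-0.5 log-odds enrollment shifts on mid-prevalence covariates, used by the
#: effect-recovery preset.
EFFECT_RECOVERY_BIAS: Mapping[str, float] = {
    "Heart disease": 0.5,
    "Diuretic medications": 0.5,
    "Hyperlipidemia": -0.5,
    "Beta blocking agents": -0.5,
}


@dataclass
class CovariateSpec:
    name: str
    kind: str  # "condition" or "drug_class"
    prevalence: float


@dataclass
class SimConfig:
    """Full description of one synthetic study; fixing it fixes the output."""

    seed: int = 0
    n_patients: int = 4000
    n_enrolled: int = 200
    n_trials: int = 20
    study_start: datetime.date = datetime.date(2012, 1, 1)
    study_end: datetime.date = datetime.date(2015, 12, 31)
    hierarchy_roots: int = 4
    hierarchy_branching: int = 4
    hierarchy_depth: int = 2
    covariates: Sequence[CovariateSpec] = field(default_factory=lambda: [
        CovariateSpec("Hypertensive disorder", "condition", 0.427),
        CovariateSpec("Diabetes", "condition", 0.179),
        CovariateSpec("Heart disease", "condition", 0.369),
        CovariateSpec("Depressive disorder", "condition", 0.113),
        CovariateSpec("Antithrombotic agents", "drug_class", 0.539),
        CovariateSpec("Opioids", "drug_class", 0.555),
        CovariateSpec("Beta blocking agents", "drug_class", 0.279),
        CovariateSpec("Lipid-modifying agents", "drug_class", 0.310),
    ])
    enrollment_bias: Mapping[str, float] = field(default_factory=dict)
    visit_rate: float = 2.0  # mean visits per person-year
    background_focus_rate: float = 0.6
    event_interval_days: int = 180
    n_unmappable_trials: int = 1
    second_enrollment_rate: float = 0.05
    trial_param_distributions: Mapping[str, tuple[tuple, tuple]] = field(
        default_factory=lambda: dict(DEFAULT_TRIAL_PARAMS))
    domain_labels: Sequence[str] = DOMAIN_LABELS
    domain_weights: Sequence[float] = DOMAIN_WEIGHTS

    def validate(self) -> None:
        if self.n_patients <= 0 or self.n_enrolled < 0:
            raise ConfigError("n_patients must be positive, n_enrolled nonnegative")
        if self.n_enrolled > self.n_patients:
            raise ConfigError("n_enrolled cannot exceed n_patients")
        if self.study_start >= self.study_end:
            raise ConfigError("study_start must precede study_end")
        if (self.study_end - self.study_start).days < 800:
            raise ConfigError("study window must span at least 800 days so "
                              "index and reassurance windows fit inside it")
        if self.n_trials > 0 and (self.hierarchy_roots < 1
                                  or self.hierarchy_branching < 1
                                  or self.hierarchy_depth < 1):
            raise ConfigError("trials require a nonempty concept hierarchy")
        if len(self.domain_labels) != self.hierarchy_roots:
            raise ConfigError("one domain label per hierarchy root is required")
        names = [c.name for c in self.covariates]
        if len(set(names)) != len(names):
            raise ConfigError("covariate names must be unique")
        for cov in self.covariates:
            if not 0.0 <= cov.prevalence <= 1.0:
                raise ConfigError(f"prevalence of {cov.name!r} outside [0,1]")
            if cov.kind not in ("condition", "drug_class"):
                raise ConfigError(f"unknown covariate kind {cov.kind!r}")
        unknown = set(self.enrollment_bias) - set(names)
        if unknown:
            raise ConfigError(f"enrollment_bias names unknown covariates: {sorted(unknown)}")
        if self.n_unmappable_trials >= max(self.n_trials, 1):
            raise ConfigError("at least one trial must remain mappable")
        if self.visit_rate <= 0:
            raise ConfigError("visit_rate must be positive")


@dataclass
class SimBundle:
    """In-memory result of one simulation."""

    store: Store
    ground_truth: dict
    covariate_definitions: list[CovariateDefinition]
    domain_concepts: dict[str, int]
    config: SimConfig


def _build_vocabulary(config: SimConfig):
    """Focus trees (one per domain) + per-covariate concept blocks."""
    concepts: list[tuple[int, str, str]] = []
    pairs: list[tuple[int, int]] = []
    next_id = 1000
    roots: list[int] = []
    focus_children: dict[int, list[int]] = {}
    for label in config.domain_labels:
        root = next_id
        next_id += 1
        roots.append(root)
        concepts.append((root, f"{label} disorder (domain anchor)", "Condition"))
        level = [root]
        for depth in range(config.hierarchy_depth):
            nxt = []
            for parent in level:
                kids = list(range(next_id, next_id + config.hierarchy_branching))
                next_id += config.hierarchy_branching
                focus_children[parent] = kids
                for kid in kids:
                    concepts.append((kid, f"{label} condition {kid}", "Condition"))
                    pairs.append((parent, kid))
                nxt.extend(kids)
            level = nxt
    # transitive closure within each tree
    closure: list[tuple[int, int]] = []
    children = dict(focus_children)

    def reach(node: int) -> list[int]:
        out = []
        stack = list(children.get(node, []))
        while stack:
            k = stack.pop()
            out.append(k)
            stack.extend(children.get(k, []))
        return out

    for root in roots:
        for node in [root] + reach(root):
            for desc in reach(node):
                closure.append((node, desc))

    cov_concepts: dict[str, list[int]] = {}
    for i, cov in enumerate(config.covariates):
        parent = 50_000 + 100 * i
        kids = [parent + 1, parent + 2, parent + 3]
        domain = "Condition" if cov.kind == "condition" else "Drug"
        concepts.append((parent, cov.name, domain))
        for kid in kids:
            concepts.append((kid, f"{cov.name} (subtype {kid - parent})", domain))
            closure.append((parent, kid))
        cov_concepts[cov.name] = [parent] + kids

    concept_df = pd.DataFrame(concepts, columns=["concept_id", "name", "domain"])
    return concept_df, sorted(set(closure)), roots, focus_children, cov_concepts


def _draw_index_concept(rng: np.random.Generator, focus: int,
                        focus_children: dict[int, list[int]]) -> int:
    """The focus concept itself half the time, else one of its children."""
    kids = focus_children.get(focus, [])
    if not kids or rng.random() < 0.5:
        return focus
    return int(kids[rng.integers(len(kids))])


def _block_event_dates(rng: np.random.Generator, n_rows: int,
                       span_days: int, interval: int) -> np.ndarray:
    """(n_rows, n_blocks) day offsets, one uniform draw per interval block."""
    n_blocks = max(span_days // interval, 1)
    base = np.arange(n_blocks) * interval
    jitter = rng.integers(0, interval, size=(n_rows, n_blocks))
    return base[None, :] + jitter


def generate(config: SimConfig) -> SimBundle:
    """Run the generator and return the in-memory bundle (validated store)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    start = pd.Timestamp(config.study_start)
    end = pd.Timestamp(config.study_end)
    history_start = start - days(400)
    span_days = (end - history_start).days
    interval = config.event_interval_days

    concept_df, closure, roots, focus_children, cov_concepts = _build_vocabulary(config)
    ancestry = ConceptAncestry(closure, known_concepts=concept_df["concept_id"])

    # ------------------------------------------------------------------ trials
    mappable = np.ones(config.n_trials, dtype=bool)
    if config.n_unmappable_trials:
        mappable[-config.n_unmappable_trials:] = False
    trial_rows = []
    params = config.trial_param_distributions
    enroll_ranges = {"lt50": (10, 50), "50to499": (50, 500), "ge500": (500, 2000)}
    site_ranges = {"lt5": (1, 5), "5to19": (5, 20), "ge20": (20, 60)}
    for t in range(config.n_trials):
        domain_idx = int(rng.choice(len(roots), p=np.asarray(config.domain_weights)
                                    / np.sum(config.domain_weights)))
        focus = int(rng.choice(focus_children[roots[domain_idx]]))
        focus_set = [focus]
        if rng.random() < 0.15 and len(roots) > 1:
            other = int(rng.choice([i for i in range(len(roots)) if i != domain_idx]))
            focus_set.append(int(rng.choice(focus_children[roots[other]])))
        draw = {key: vals[int(rng.choice(len(vals), p=np.asarray(probs) / np.sum(probs)))]
                for key, (vals, probs) in params.items()}
        overall = int(rng.integers(*enroll_ranges[draw["overall_enrollment_bin"]]))
        site = int(rng.integers(*site_ranges[draw["site_enrollment_bin"]]))
        trial_rows.append({
            "trial_id": f"NCT{1000000 + t:07d}",
            "focus_concept_ids": tuple(focus_set) if mappable[t] else (),
            "mappable": bool(mappable[t]),
            "phase": draw["phase"],
            "arms": int(draw["arms"]),
            "randomized": bool(draw["randomized"]),
            "blinded": bool(draw["blinded"]),
            "model": draw["model"],
            "industry": bool(draw["industry"]),
            "dmc": bool(draw["dmc"]),
            "multisite": bool(draw["multisite"]),
            "overall_enrollment": overall,
            "site_enrollment": site,
            "status": draw["status"],
        })
    trials = pd.DataFrame(trial_rows)

    # ----------------------------------------------------------------- persons
    n = config.n_patients
    person_ids = np.arange(1, n + 1)
    ages = rng.integers(2, 86, size=n)
    birth_offsets = ages * 365 + rng.integers(0, 365, size=n)
    birth_dates = start - pd.to_timedelta(birth_offsets, unit="D")
    persons = pd.DataFrame({
        "person_id": person_ids,
        "birth_date": birth_dates,
        "sex": rng.choice(["male", "female"], size=n),
        "race": rng.choice(["white", "black", "other", "unknown"], size=n,
                           p=[0.45, 0.09, 0.04, 0.42]),
        "ethnicity": rng.choice(["hispanic", "not_hispanic", "unknown"], size=n,
                                p=[0.14, 0.47, 0.39]),
    })

    # --------------------------------------------------- covariate indicators
    cov_names = [c.name for c in config.covariates]
    prevalences = np.array([c.prevalence for c in config.covariates])
    X = rng.random((n, len(cov_names))) < prevalences[None, :]

    # ---------------------------------------------------- enrollment selection
    beta = np.array([config.enrollment_bias.get(name, 0.0) for name in cov_names])
    weights = np.exp(X @ beta)
    probs = weights / weights.sum()
    enrolled_pos = np.sort(rng.choice(n, size=config.n_enrolled, replace=False, p=probs))
    enrolled_ids = person_ids[enrolled_pos]
    enrolled_mask = np.zeros(n, dtype=bool)
    enrolled_mask[enrolled_pos] = True

    status_labels = ["randomized", "completed", "enrolled"]
    enrollment_rows = []
    forced_condition_rows: list[tuple[int, int, pd.Timestamp]] = []
    forced_excluded: list[int] = []
    status_span = (end - (start + days(730))).days
    trial_focus_first = {row["trial_id"]: (row["focus_concept_ids"][0]
                                           if row["focus_concept_ids"] else None)
                         for row in trial_rows}
    trial_ids_all = trials["trial_id"].tolist()
    all_focus_nodes = [kid for root in roots for kid in focus_children[root]]
    for pid in enrolled_ids:
        trial_id = trial_ids_all[int(rng.integers(len(trial_ids_all)))]
        status_date = start + days(730) + days(int(rng.integers(0, status_span + 1)))
        enrollment_rows.append({
            "person_id": int(pid), "trial_id": trial_id,
            "status": status_labels[int(rng.integers(3))],
            "status_date": status_date,
        })
        focus = trial_focus_first[trial_id]
        if focus is None:  # unmappable trial: person will be excluded upstream
            forced_excluded.append(int(pid))
            focus = int(rng.choice(all_focus_nodes))
        concept = _draw_index_concept(rng, focus, focus_children)
        index_date = status_date - days(int(rng.integers(0, 61)))
        reassure_date = index_date - days(int(rng.integers(1, 366)))
        forced_condition_rows.append((int(pid), concept, index_date))
        forced_condition_rows.append((int(pid), concept, reassure_date))
        if rng.random() < config.second_enrollment_rate:
            other_trial = trial_ids_all[int(rng.integers(len(trial_ids_all)))]
            enrollment_rows.append({
                "person_id": int(pid), "trial_id": other_trial,
                "status": status_labels[int(rng.integers(3))],
                "status_date": status_date + days(int(rng.integers(10, 200))),
            })
    enrollment = pd.DataFrame(enrollment_rows).drop_duplicates(
        ["person_id", "trial_id", "status_date"])

    # ------------------------------------------------- background focus events
    mappable_trials = [row for row in trial_rows if row["mappable"]]
    background_pos = np.flatnonzero(~enrolled_mask)
    carrier_mask = rng.random(len(background_pos)) < config.background_focus_rate
    carriers = person_ids[background_pos[carrier_mask]]
    carrier_concepts = np.empty(len(carriers), dtype=np.int64)
    for i in range(len(carriers)):
        trial = mappable_trials[int(rng.integers(len(mappable_trials)))]
        carrier_concepts[i] = _draw_index_concept(rng, trial["focus_concept_ids"][0],
                                                  focus_children)
    focus_offsets = _block_event_dates(rng, len(carriers), span_days, interval)
    n_blocks = focus_offsets.shape[1]
    focus_events = pd.DataFrame({
        "person_id": np.repeat(carriers, n_blocks),
        "concept_id": np.repeat(carrier_concepts, n_blocks),
        "event_date": history_start + pd.to_timedelta(focus_offsets.ravel(), unit="D"),
    })
    focus_events = focus_events[focus_events["event_date"] <= end]

    # ------------------------------------------------------- covariate events
    cond_frames = [focus_events, pd.DataFrame(
        forced_condition_rows, columns=["person_id", "concept_id", "event_date"])]
    drug_frames = []
    for k, cov in enumerate(config.covariates):
        positives = person_ids[X[:, k]]
        if len(positives) == 0:
            continue
        offsets = _block_event_dates(rng, len(positives), span_days, interval)
        blocks = offsets.shape[1]
        pool = np.array(cov_concepts[cov.name])
        concepts = pool[rng.integers(0, len(pool), size=len(positives) * blocks)]
        frame = pd.DataFrame({
            "person_id": np.repeat(positives, blocks),
            "concept_id": concepts,
            "event_date": history_start + pd.to_timedelta(offsets.ravel(), unit="D"),
        })
        frame = frame[frame["event_date"] <= end]
        (cond_frames if cov.kind == "condition" else drug_frames).append(frame)

    conditions = pd.concat(cond_frames, ignore_index=True).sort_values(
        ["person_id", "event_date", "concept_id"], ignore_index=True)
    if drug_frames:
        drugs = pd.concat(drug_frames, ignore_index=True).sort_values(
            ["person_id", "event_date", "concept_id"], ignore_index=True)
    else:
        drugs = pd.DataFrame(columns=["person_id", "concept_id", "event_date"])

    # ------------------------------------------------------------------ visits
    span_years = span_days / 365.0
    visit_counts = rng.poisson(config.visit_rate * span_years, size=n)
    visit_persons = np.repeat(person_ids, visit_counts)
    visit_offsets = rng.integers(0, span_days + 1, size=visit_counts.sum())
    visits = pd.DataFrame({
        "person_id": visit_persons,
        "visit_date": history_start + pd.to_timedelta(visit_offsets, unit="D"),
    }).sort_values(["person_id", "visit_date"], ignore_index=True)

    store = Store(
        persons=persons, conditions=conditions, drugs=drugs, visits=visits,
        concepts=concept_df, ancestry=ancestry, enrollment=enrollment,
        trials=trials,
    )
    validate_store(store)

    prev_enrolled = {name: float(X[enrolled_mask, k].mean()) if enrolled_mask.any() else float("nan")
                     for k, name in enumerate(cov_names)}
    prev_background = {name: float(X[~enrolled_mask, k].mean())
                       for k, name in enumerate(cov_names)}
    ground_truth = {
        "n_patients": int(n),
        "n_enrolled": int(config.n_enrolled),
        "enrolled_person_ids": [int(p) for p in enrolled_ids],
        "forced_excluded_person_ids": sorted(forced_excluded),
        "expected_selected": int(config.n_enrolled - len(forced_excluded)),
        "prevalence_enrolled": prev_enrolled,
        "prevalence_background": prev_background,
        "trial_focus": {row["trial_id"]: list(row["focus_concept_ids"])
                        for row in trial_rows},
        "covariate_concepts": {name: list(ids) for name, ids in cov_concepts.items()},
        "domain_concepts": {label: int(root)
                            for label, root in zip(config.domain_labels, roots)},
    }
    definitions = [
        CovariateDefinition(cov.name, cov.kind, frozenset([cov_concepts[cov.name][0]]))
        for cov in config.covariates
    ]
    domain_concepts = {label: int(root)
                       for label, root in zip(config.domain_labels, roots)}
    return SimBundle(store=store, ground_truth=ground_truth,
                     covariate_definitions=definitions,
                     domain_concepts=domain_concepts, config=config)


def _config_echo(config: SimConfig) -> dict:
    raw = dataclasses.asdict(config)
    raw["study_start"] = config.study_start.isoformat()
    raw["study_end"] = config.study_end.isoformat()
    raw["enrollment_bias"] = dict(config.enrollment_bias)
    raw["trial_param_distributions"] = {
        key: [list(vals), list(probs)]
        for key, (vals, probs) in config.trial_param_distributions.items()}
    raw["domain_labels"] = list(config.domain_labels)
    raw["domain_weights"] = list(config.domain_weights)
    return raw


def simulate_study(config: SimConfig, out_dir: str | Path) -> SimBundle:
    """Generate and write the full file bundle; returns the in-memory bundle.

    Writes the eight store tables, ``covariate_definitions.csv``,
    ``domain_concepts.csv``, ``ground_truth.json`` and ``config_used.yaml``.
    """
    bundle = generate(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_store(bundle.store, out_dir)
    defs = pd.DataFrame({
        "name": [d.name for d in bundle.covariate_definitions],
        "kind": [d.kind for d in bundle.covariate_definitions],
        "concept_ids": [";".join(str(c) for c in sorted(d.concept_set))
                        for d in bundle.covariate_definitions],
    })
    defs.to_csv(out_dir / "covariate_definitions.csv", index=False)
    pd.DataFrame(sorted(bundle.domain_concepts.items()),
                 columns=["domain", "concept_id"]).to_csv(
        out_dir / "domain_concepts.csv", index=False)
    with open(out_dir / "ground_truth.json", "w") as fh:
        json.dump(bundle.ground_truth, fh, indent=1, sort_keys=True)
    with open(out_dir / "config_used.yaml", "w") as fh:
        yaml.safe_dump(_config_echo(config), fh, sort_keys=True)
    return bundle


def _paper_like_covariates() -> list[CovariateSpec]:
    out = [CovariateSpec(name, "condition", prev)
           for name, prev in CONDITION_COVARIATES.items()]
    out += [CovariateSpec(name, "drug_class", prev)
            for name, prev in DRUG_COVARIATES.items()]
    return out


def make_paper_like_preset(seed: int = 0) -> SimConfig:
    """Conditions at the scale of the study this package emulates.

    ~200 registered medication trials, ~1600 enrollable persons, a background
    population twenty times larger, 31 condition covariates and 17
    medication-class covariates, over a 1996-2019 accrual window.
    """
    return SimConfig(
        seed=seed,
        n_patients=1645 * 21,
        n_enrolled=1645,
        n_trials=202,
        study_start=datetime.date(1996, 9, 1),
        study_end=datetime.date(2019, 1, 31),
        covariates=_paper_like_covariates(),
    )


def make_calibration_preset(seed: int = 0,
                            enrollment_bias: Mapping[str, float] | None = None
                            ) -> SimConfig:
    """Paper-sized cohorts on a single-workstation footprint.

    Keeps the 1645 enrolled persons, 202 trials and the full 48-covariate
    panel, with a seven-fold background population and a four-year accrual
    window so that repeated seeded runs complete quickly.
    """
    return SimConfig(
        seed=seed,
        n_patients=1645 * 7,
        n_enrolled=1645,
        n_trials=202,
        study_start=datetime.date(2012, 1, 1),
        study_end=datetime.date(2015, 12, 31),
        covariates=_paper_like_covariates(),
        enrollment_bias=dict(enrollment_bias or {}),
    )
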