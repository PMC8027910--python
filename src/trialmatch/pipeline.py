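"""End-to-end orchestration: simulate -> select -> match -> compare -> scan.

``run_all`` drives every stage from one RunConfig, writes each stage's
artifact under the output directory and finishes with a manifest (config
echo, seeds, library versions, row counts and sha256 checksums) so a rerun
with the same configuration can be verified byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
import pandas as pd

from . import __version__
from .association_scan import manhattan_output, scan
from .cdm_store import load_store
from .covariate_comparison import (compare_cohorts, covariate_matrix,
                                   read_covariate_definitions)
from .errors import ConfigError
from .matching import (aggregate_counts, build_candidate_entries,
                       participant_keys, run_resampling)
from .participant_selection import select_participants
from .synthetic_data import SimConfig, simulate_study
from .trial_characterization import categorical_table, domain_table, top_k_domains

log = logging.getLogger("trialmatch")


@dataclass
class RunConfig:
    """Everything one pipeline run depends on.

    Exactly one of ``sim`` (generate the inputs) or ``data_dir`` (load
    existing tables) must be set.  Defaults reproduce the reference analysis
    parameters: 1000 matching iterations, a 365-day lookback, a 0.1
    standardized-difference flag and a 0.01 within-domain alpha.
    """

    out_dir: str
    sim: SimConfig | None = None
    data_dir: str | None = None
    seed: int = 0
    n_iterations: int = 1000
    alpha: float = 0.01
    flag_threshold: float = 0.1
    lookback_days: int = 365
    domain_top_k: int = 4
    covariate_file: str | None = None
    domain_file: str | None = None
    figure_format: str = "svg"

    def validate(self) -> None:
        if (self.sim is None) == (self.data_dir is None):
            raise ConfigError("set exactly one of sim / data_dir")
        if self.n_iterations < 1:
            raise ConfigError("n_iterations must be >= 1")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.sim is not None:
            self.sim.validate()
        else:
            data_dir = Path(self.data_dir)
            cov = Path(self.covariate_file) if self.covariate_file \
                else data_dir / "covariate_definitions.csv"
            if not cov.exists():
                raise ConfigError(f"covariate definition file not found: {cov}")
            dom = Path(self.domain_file) if self.domain_file \
                else data_dir / "domain_concepts.csv"
            if not dom.exists():
                raise ConfigError(f"domain concept file not found: {dom}")


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _echo(config: RunConfig) -> dict:
    raw = dataclasses.asdict(config)
    if config.sim is not None:
        raw["sim"]["study_start"] = config.sim.study_start.isoformat()
        raw["sim"]["study_end"] = config.sim.study_end.isoformat()
        raw["sim"]["enrollment_bias"] = dict(config.sim.enrollment_bias)
        raw["sim"]["trial_param_distributions"] = {
            k: [list(v), list(p)]
            for k, (v, p) in config.sim.trial_param_distributions.items()}
    return raw


def load_domain_concepts(path) -> dict[str, int]:
    frame = pd.read_csv(path)
    return dict(zip(frame["domain"].astype(str), frame["concept_id"].astype(int)))


def run_all(config: RunConfig) -> dict:
    """Execute every stage; returns the manifest (also written to disk)."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    counts: dict[str, int] = {}

    # stage 1: inputs ------------------------------------------------------
    if config.sim is not None:
        data_dir = out_dir / "data"
        bundle = simulate_study(config.sim, data_dir)
        store = bundle.store
        definitions = bundle.covariate_definitions
        domain_concepts = bundle.domain_concepts
        log.info("simulate: %d persons, %d trials, %d condition rows",
                 len(store.persons), len(store.trials), len(store.conditions))
    else:
        data_dir = Path(config.data_dir)
        store = load_store(data_dir)
        definitions = read_covariate_definitions(
            config.covariate_file or data_dir / "covariate_definitions.csv")
        domain_concepts = load_domain_concepts(
            config.domain_file or data_dir / "domain_concepts.csv")
        log.info("load: %s", store.counts)
    counts.update({f"input_{k}": v for k, v in store.counts.items()})

    # stage 2: participant selection --------------------------------------
    assignments, audit = select_participants(store, config.lookback_days)
    log.info("select: %s", audit.as_dict())
    counts["participants_selected"] = audit.selected
    part_path = out_dir / "participants.csv"
    out = assignments.copy()
    for col in ("status_date", "index_date"):
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
    out.to_csv(part_path, index=False)
    artifacts["participants"] = part_path
    audit_path = out_dir / "selection_audit.json"
    audit_path.write_text(json.dumps(audit.as_dict(), indent=1, sort_keys=True))
    artifacts["selection_audit"] = audit_path

    # stage 3: trial characterization --------------------------------------
    domains = domain_table(store.trials, store.ancestry, domain_concepts)
    keep = top_k_domains(domains, config.domain_top_k)
    domains = domains[domains["domain"].isin(keep)]
    cats = categorical_table(store.trials)
    domains.to_csv(out_dir / "domains.csv", index=False)
    cats.to_csv(out_dir / "trial_categorical.csv", index=False)
    artifacts["domains"] = out_dir / "domains.csv"
    artifacts["trial_categorical"] = out_dir / "trial_categorical.csv"
    log.info("characterize: %d domain rows over %d domains", len(domains), len(keep))

    # stage 4: matching -----------------------------------------------------
    participants = participant_keys(assignments, store)
    candidates = build_candidate_entries(assignments, store)
    result = run_resampling(participants, candidates,
                            n_iterations=config.n_iterations, seed=config.seed)
    counts["candidate_entries"] = len(candidates)
    counts["never_matched"] = len(result.never_matched)
    log.info("match: %d candidate entries, %d/%d participants never matched",
             len(candidates), len(result.never_matched), len(participants))
    matches_path = out_dir / "matches.csv"
    cand_person = candidates.set_index("cand_id")["person_id"]
    pairs_out = result.pairs.assign(
        nonparticipant_id=result.pairs["cand_id"].map(cand_person))
    pairs_out[["iteration", "person_id", "nonparticipant_id"]].rename(
        columns={"person_id": "participant_id"}).to_csv(matches_path, index=False)
    artifacts["matches"] = matches_path
    nm_path = out_dir / "never_matched.csv"
    pd.DataFrame({"person_id": sorted(result.never_matched)}).to_csv(nm_path, index=False)
    artifacts["never_matched"] = nm_path

    retained = assignments[~assignments["person_id"].isin(result.never_matched)]
    counts["participants_retained"] = len(retained)

    # stage 5: covariates ---------------------------------------------------
    part_queries = retained[["person_id", "index_date"]]
    part_matrix = covariate_matrix(part_queries, definitions, store,
                                   config.lookback_days)
    cand_queries = candidates[["person_id", "index_date"]]
    cand_matrix = covariate_matrix(cand_queries, definitions, store,
                                   config.lookback_days)
    cand_matrix.index = pd.Index(candidates["cand_id"].values, name="cand_id")

    trial_domains = domains.groupby("domain")["trial_id"].agg(set)
    strata = {domain: set(retained.loc[retained["trial_id"].isin(trials_),
                                       "person_id"])
              for domain, trials_ in trial_domains.items()}
    strata["all"] = set(retained["person_id"])

    agg = aggregate_counts(result, cand_matrix, strata)
    agg_path = out_dir / "aggregate_counts.csv"
    agg.to_csv(agg_path, index=False)
    artifacts["aggregate_counts"] = agg_path

    # stage 6: comparison ---------------------------------------------------
    comparison = compare_cohorts(part_matrix, strata, agg, config.flag_threshold)
    for domain in sorted(strata):
        sub = comparison[comparison["domain"] == domain]
        path = out_dir / f"comparison_{domain}.csv"
        sub.to_csv(path, index=False)
        artifacts[f"comparison_{domain}"] = path
    counts["comparison_rows"] = len(comparison)
    counts["comparison_flagged"] = int(comparison["flagged"].sum()) if len(comparison) else 0
    log.info("compare: %d rows, %d flagged", counts["comparison_rows"],
             counts["comparison_flagged"])

    # stage 7: association scan --------------------------------------------
    trial_of = retained.set_index("person_id")["trial_id"]
    domain_members = {d: ids for d, ids in strata.items() if d != "all"}
    cells = scan(part_matrix, trial_of, cats, domain_members,
                 alpha=config.alpha, seed=config.seed)
    for domain in sorted(domain_members):
        sub = cells[cells["domain"] == domain]
        path = out_dir / f"associations_{domain}.csv"
        sub.to_csv(path, index=False)
        artifacts[f"associations_{domain}"] = path
    counts["association_cells"] = int(cells["p_value"].notna().sum()) if len(cells) else 0
    counts["association_significant"] = int(cells["significant"].sum()) if len(cells) else 0
    log.info("associate: %d cells tested, %d significant",
             counts["association_cells"], counts["association_significant"])
    figures = manhattan_output(cells, out_dir, config.figure_format)
    artifacts.update(figures)

    # manifest --------------------------------------------------------------
    manifest = {
        "package_version": __version__,
        "versions": {m.__name__: m.__version__ for m in _libs()},
        "config": _echo(config),
        "seed": config.seed,
        "counts": counts,
        "checksums": {name: _sha256(path) for name, path in sorted(artifacts.items())},
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _libs():
    import matplotlib
    import numpy
    import scipy
    return (numpy, pd, scipy, matplotlib)
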