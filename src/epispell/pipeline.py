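"""End-to-end orchestration: simulate -> process x models -> metrics.

All artifacts are delimited text; a run manifest records the config
hash, seed, package version, per-stage row counts and output-file
digests so that identical config + seed reruns are byte-reproducible
and auditable (exclusion accounting is part of the manifest).
"""
from __future__ import annotations

import datetime
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from ._types import EpisodeSet, RegisterEntry
from .config import RunConfig
from .diagnoses import (
    CategoryConfig,
    MappingTable,
    records_from_entry,
    resolve_episode_set,
)
from .episodes import MODELS, identify_episodes
from .io import (
    EraRules,
    entries_from_frame,
    entries_to_frame,
    prepare_entries,
    read_entries,
)
from .metrics import (
    annual_median_los,
    count_annual_episodes,
    count_annual_outpatient_events,
    count_treated_individuals,
    los_histogram,
)
from .synthetic import generate_cohort

logger = logging.getLogger("epispell")


def raw_diagnosis_frame(entries: list[RegisterEntry], mapping: MappingTable) -> pd.DataFrame:
    """All registered diagnoses of validated entries (the non-processed variant)."""
    rows = []
    for e in entries:
        for r in records_from_entry(e, mapping):
            rows.append(
                {
                    "person_id": r.person_id,
                    "category": r.icd10_category,
                    "code": r.code,
                    "record_date": r.record_date,
                }
            )
    return pd.DataFrame(rows, columns=["person_id", "category", "code", "record_date"])


def processed_diagnosis_frame(
    episode_set: EpisodeSet,
    resolved: dict,
    entries: list[RegisterEntry],
    mapping: MappingTable,
) -> pd.DataFrame:
    """Final discharge diagnoses plus independent-event diagnoses."""
    entries_by_id = {e.entry_id: e for e in entries}
    rows = []
    for ds in resolved.values():
        for r in ds.final:
            rows.append(
                {
                    "person_id": r.person_id,
                    "category": r.icd10_category,
                    "code": r.code,
                    "record_date": r.record_date,
                }
            )
    for ev in episode_set.events:
        if not ev.independent:
            continue
        for eid in ev.source_entry_ids:
            src = entries_by_id.get(eid)
            if src is None:
                continue
            for r in records_from_entry(src, mapping, record_date=ev.event_start):
                rows.append(
                    {
                        "person_id": r.person_id,
                        "category": r.icd10_category,
                        "code": r.code,
                        "record_date": r.record_date,
                    }
                )
    return pd.DataFrame(rows, columns=["person_id", "category", "code", "record_date"])


def episodes_to_frame(episode_set: EpisodeSet) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "episode_id": ep.episode_id,
                "person_id": ep.person_id,
                "admission_date": ep.admission_date.isoformat(),
                "discharge_date": ep.discharge_date.isoformat(),
                "has_psychiatry": ep.has_psychiatry,
                "psy_start": ep.psy_start.isoformat() if ep.psy_start else "",
                "psy_end": ep.psy_end.isoformat() if ep.psy_end else "",
                "model_id": ep.model_id,
                "n_member_entries": len(ep.member_entry_ids),
            }
            for ep in episode_set.episodes
        ]
    )


def events_to_frame(episode_set: EpisodeSet) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "event_id": ev.event_id,
                "person_id": ev.person_id,
                "event_start": ev.event_start.isoformat(),
                "event_end": ev.event_end.isoformat(),
                "source": ev.source.value,
                "independent": ev.independent,
                "parent_episode_id": ev.parent_episode_id or "",
                "is_psychiatric": ev.is_psychiatric,
            }
            for ev in episode_set.events
        ]
    )


def crosswalk_frame(episode_set: EpisodeSet) -> pd.DataFrame:
    rows = []
    for ep in episode_set.episodes:
        for eid in ep.member_entry_ids:
            rows.append({"entry_id": eid, "target_id": ep.episode_id, "target": "episode"})
    for ev in episode_set.events:
        for eid in ev.source_entry_ids:
            rows.append({"entry_id": eid, "target_id": ev.event_id, "target": "event"})
    return pd.DataFrame(rows, columns=["entry_id", "target_id", "target"])


def diagnoses_to_frame(resolved: dict) -> pd.DataFrame:
    rows = []
    for episode_id in sorted(resolved):
        ds = resolved[episode_id]
        for status, records in (("final", ds.final), ("preliminary", ds.preliminary)):
            for r in records:
                rows.append(
                    {
                        "episode_id": episode_id,
                        "person_id": r.person_id,
                        "code": r.code,
                        "system": r.system.value,
                        "category": r.icd10_category,
                        "record_date": r.record_date.isoformat(),
                        "status": status,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "episode_id",
            "person_id",
            "code",
            "system",
            "category",
            "record_date",
            "status",
        ],
    )


def _load_components(config: RunConfig):
    era_rules = (
        EraRules.from_yaml(config.era_rules_path)
        if config.era_rules_path
        else EraRules.default()
    )
    mapping = (
        MappingTable.from_csv(config.mapping_path)
        if config.mapping_path
        else MappingTable.default()
    )
    categories = (
        CategoryConfig.from_yaml(config.categories_path)
        if config.categories_path
        else CategoryConfig.default()
    )
    return era_rules, mapping, categories


def _birth_dates(persons: pd.DataFrame) -> dict[str, datetime.date]:
    return {
        str(r.person_id): datetime.date.fromisoformat(str(r.birth_date))
        for r in persons.itertuples(index=False)
    }


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> Path:
    """Execute simulate (if needed) -> normalize/filter -> episodes per
    model -> diagnoses -> metrics, writing all artifacts to ``out_dir``."""
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    era_rules, mapping, categories = _load_components(config)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "stages": {},
    }

    # --- stage: input ---
    if config.entries_path:
        raw_entries = read_entries(config.entries_path, config.schema_map)
        persons = (
            pd.read_csv(config.persons_path, dtype=str)
            if config.persons_path
            else pd.DataFrame(columns=["person_id", "birth_date"])
        )
    else:
        cohort = generate_cohort(config.generator_params())
        cohort.entries.to_csv(out / "entries.csv", index=False)
        cohort.persons.to_csv(out / "persons.csv", index=False)
        cohort.truth.episodes_frame().to_csv(out / "truth_episodes.csv", index=False)
        cohort.truth.crosswalk_frame().to_csv(out / "truth_crosswalk.csv", index=False)
        raw_entries = entries_from_frame(cohort.entries)
        persons = cohort.persons
    manifest["stages"]["input"] = {"rows": len(raw_entries)}
    birth_dates = _birth_dates(persons)

    # --- stage: normalization + quality filters ---
    time_range = (config.time_range.start, config.time_range.end)
    entries, report = prepare_entries(raw_entries, era_rules, time_range)
    entries_to_frame(entries).to_csv(out / "validated_entries.csv", index=False)
    report.to_frame().to_csv(out / "exclusions.csv", index=False)
    manifest["stages"]["quality_filters"] = {
        "rows_in": report.n_input,
        "rows_retained": report.n_retained,
        "excluded": {r.value: report.counts[r] for r in report.counts},
    }

    # --- stage: episodes + diagnoses per model ---
    episode_sets: dict[int, EpisodeSet] = {}
    diag_frames: dict[object, pd.DataFrame] = {
        "raw": raw_diagnosis_frame(entries, mapping)
    }
    for m in config.models:
        es = identify_episodes(entries, MODELS[m])
        episode_sets[m] = es
        resolved = resolve_episode_set(es, entries, mapping)
        episodes_to_frame(es).to_csv(out / f"episodes_m{m}.csv", index=False)
        events_to_frame(es).to_csv(out / f"events_m{m}.csv", index=False)
        crosswalk_frame(es).to_csv(out / f"crosswalk_m{m}.csv", index=False)
        diagnoses_to_frame(resolved).to_csv(out / f"diagnoses_m{m}.csv", index=False)
        frame = processed_diagnosis_frame(es, resolved, entries, mapping)
        frame.assign(record_date=frame["record_date"].map(lambda d: d.isoformat())).to_csv(
            out / f"diag_persons_m{m}.csv", index=False
        )
        diag_frames[m] = frame
        manifest["stages"][f"model_{m}"] = {
            "episodes": len(es.episodes),
            "events": len(es.events),
            "final_diagnoses": int(sum(len(d.final) for d in resolved.values())),
        }

    # --- stage: metrics ---
    years = list(range(config.time_range.start.year, config.time_range.end.year + 1))
    count_annual_episodes(episode_sets, entries, years, config.year_assignment).to_csv(
        out / "annual_inpatient.csv", index=False
    )
    count_annual_outpatient_events(episode_sets, entries, years).to_csv(
        out / "annual_outpatient_events.csv", index=False
    )
    annual_median_los(
        episode_sets, entries, years, config.los_convention, config.year_assignment
    ).to_csv(out / "annual_median_los.csv", index=False)
    los_histogram(
        episode_sets, entries, config.los_convention, tuple(config.los_bins)
    ).to_csv(out / "los_histogram.csv", index=False)
    count_treated_individuals(
        diag_frames, birth_dates, categories, grouping="lifetime"
    ).to_csv(out / "treated_individuals_lifetime.csv", index=False)
    last_year = config.time_range.end.year
    count_treated_individuals(
        diag_frames, birth_dates, categories, grouping="annual", year=last_year
    ).to_csv(out / f"treated_individuals_{last_year}.csv", index=False)

    # --- manifest ---
    digests = {}
    for f in sorted(out.glob("*.csv")):
        digests[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    manifest["outputs"] = digests
    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()
    ).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline complete: %s", out)
    return out
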