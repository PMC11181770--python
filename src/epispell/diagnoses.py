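"""Resolution of discharge diagnoses per inpatient episode.

Discharge diagnoses are collected on the last day of the psychiatric
sub-episode; if the overall episode continues on other wards, diagnoses
on the final overall discharge day and psychiatric ambulatory diagnoses
recorded between psychiatric and overall discharge are also included.
Diagnoses established earlier in the episode are preliminary and are not
discharge diagnoses.  Mental-disorder diagnoses issued by specialties
other than psychiatry are excluded throughout.  The number of discharge
diagnoses per episode is not limited.

Codes from older or foreign classifications (ICD-8, ICD-9, ICPC-2) are
harmonized to ICD-10 sub-chapter categories through a user-suppliable
prefix mapping table; concepts without an ICD-10 counterpart remain
unmapped and are grouped separately.
"""
from __future__ import annotations

import datetime
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from ._types import (
    CodeSystem,
    ConfigurationError,
    ContractViolation,
    DiagnosisRecord,
    DischargeDiagnosisSet,
    EpisodeSet,
    InpatientEpisode,
    OutpatientEvent,
    RegisterEntry,
    UNMAPPED,
)

MENTAL_PREFIX = "F"


class MappingTable:
    """Prefix mapping from source classification codes to ICD-10 categories.

    Rows are ``(system, code_prefix, icd10_category)``; the longest
    matching prefix wins.  ICD-10 inputs map through their own category
    prefixes the same way.
    """

    def __init__(self, rows: list[tuple[str, str, str]]):
        self._by_system: dict[CodeSystem, list[tuple[str, str]]] = {}
        for i, row in enumerate(rows):
            try:
                system, prefix, category = row
                system = CodeSystem(str(system).strip())
                prefix = str(prefix).strip().upper()
                category = str(category).strip()
                if not prefix or not category:
                    raise ValueError("empty prefix or category")
            except (ValueError, TypeError) as exc:
                raise ConfigurationError(f"malformed mapping row {i}: {row!r}") from exc
            self._by_system.setdefault(system, []).append((prefix, category))
        for rows_ in self._by_system.values():
            rows_.sort(key=lambda pc: -len(pc[0]))

    @classmethod
    def from_csv(cls, path: str | Path) -> "MappingTable":
        df = pd.read_csv(path, dtype=str)
        expected = ["system", "code_prefix", "icd10_category"]
        if list(df.columns) != expected:
            raise ConfigurationError(
                f"mapping table must have columns {expected}, got {list(df.columns)}"
            )
        return cls([tuple(r) for r in df.itertuples(index=False)])

    @classmethod
    def default(cls) -> "MappingTable":
        with resources.as_file(
            resources.files("epispell.data").joinpath("demo_mapping.csv")
        ) as p:
            return cls.from_csv(p)

    def convert(self, code: str, system: CodeSystem) -> str:
        code = str(code).strip().upper()
        for prefix, category in self._by_system.get(system, []):
            if code.startswith(prefix):
                return category
        return UNMAPPED


def convert_diagnosis(code: str, system: CodeSystem, mapping_table: MappingTable) -> str:
    """Map one diagnosis code to its ICD-10 category (or ``UNMAPPED``)."""
    return mapping_table.convert(code, system)


class CategoryConfig:
    """Reporting categories with per-category earliest plausible onset age."""

    def __init__(self, raw: dict):
        try:
            self.default_age_floor = int(raw.get("default_age_floor", 5))
            self.any_label = str(raw.get("any_label", "Any mental disorder"))
            self.groups: list[tuple[str, tuple[str, ...], int]] = []
            for g in raw["groups"]:
                floors = int(g.get("age_floor", self.default_age_floor))
                prefixes = tuple(str(p).upper() for p in g["prefixes"])
                if not prefixes:
                    raise ValueError(f"group {g['name']} has no prefixes")
                self.groups.append((str(g["name"]), prefixes, floors))
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigurationError(f"malformed category configuration: {exc}") from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CategoryConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "CategoryConfig":
        text = resources.files("epispell.data").joinpath("categories.yaml").read_text()
        return cls(yaml.safe_load(text))

    def age_floor_for(self, category: str) -> int | None:
        """Floor of the most specific (longest-prefix) matching group.

        ``None`` for non-mental categories, which carry no floor.
        """
        if category == UNMAPPED or not category.startswith(MENTAL_PREFIX):
            return None
        best_len, best_floor = -1, self.default_age_floor
        for _, prefixes, floor in self.groups:
            for p in prefixes:
                if category.startswith(p) and len(p) > best_len:
                    best_len, best_floor = len(p), floor
        return best_floor

    def group_names_for(self, category: str) -> list[str]:
        return [
            name
            for name, prefixes, _ in self.groups
            if any(category.startswith(p) for p in prefixes)
        ]


def _is_mental(record: DiagnosisRecord) -> bool:
    if record.icd10_category != UNMAPPED:
        return record.icd10_category.startswith(MENTAL_PREFIX)
    return record.system == CodeSystem.ICD10 and record.code.upper().startswith(
        MENTAL_PREFIX
    )


def _record_key(r: DiagnosisRecord):
    return (r.record_date, r.code, r.icd10_category, r.source_entry_id, r.role.value)


def records_from_entry(
    entry: RegisterEntry,
    mapping: MappingTable,
    record_date: datetime.date | None = None,
    psychiatric: bool | None = None,
) -> list[DiagnosisRecord]:
    """Expand one entry's diagnosis list into dated records.

    Register entries carry their diagnoses at the discharge date (the
    register documents the state at the end of the contact), so that is
    the default record date.
    """
    date = record_date or entry.discharge_date
    psy = entry.is_psychiatric if psychiatric is None else psychiatric
    return [
        DiagnosisRecord(
            person_id=entry.person_id,
            source_entry_id=entry.entry_id,
            record_date=date,
            code=d.code,
            system=d.system,
            role=d.role,
            issuing_specialty_psychiatric=psy,
            icd10_category=mapping.convert(d.code, d.system),
        )
        for d in entry.diagnoses
    ]


def collect_discharge_diagnoses(
    episode: InpatientEpisode,
    member_entries: list[RegisterEntry],
    attached_events: list[OutpatientEvent],
    entries_by_id: dict[str, RegisterEntry],
    mapping: MappingTable,
    end_date: datetime.date | None = None,
) -> DischargeDiagnosisSet:
    """Resolve final vs. preliminary diagnoses for one psychiatric episode.

    Final diagnoses are (a) diagnoses of psychiatric member entries dated
    at the psychiatric discharge, (b) if other wards continued the stay,
    diagnoses of member entries dated at the overall discharge, and (c)
    psychiatric ambulatory diagnoses dated between psychiatric and
    overall discharge.  In-scope diagnoses dated before the psychiatric
    discharge are preliminary.  Mental-disorder diagnoses from
    non-psychiatric specialties are excluded from both groups (but kept
    in ``all_during_episode``).  Duplicate (code, category) pairs keep
    their final status.

    For non-psychiatric episodes pass ``end_date=episode.discharge_date``
    to run the same machinery against the overall discharge.
    """
    if end_date is None:
        if not episode.has_psychiatry:
            raise ContractViolation(
                f"episode {episode.episode_id} has no psychiatric sub-episode"
            )
        end_date = episode.psy_end

    member_records: list[DiagnosisRecord] = []
    for e in member_entries:
        member_records.extend(records_from_entry(e, mapping))
    event_records: list[DiagnosisRecord] = []
    for ev in attached_events:
        for eid in ev.source_entry_ids:
            src = entries_by_id.get(eid)
            if src is None:
                continue
            event_records.extend(
                records_from_entry(
                    src, mapping, record_date=ev.event_start, psychiatric=src.is_psychiatric
                )
            )

    all_records = sorted(member_records + event_records, key=_record_key)
    in_scope = [
        r
        for r in all_records
        if not (_is_mental(r) and not r.issuing_specialty_psychiatric)
    ]

    final: list[DiagnosisRecord] = []
    for r in in_scope:
        if r in member_records:
            if (
                r.issuing_specialty_psychiatric or not episode.has_psychiatry
            ) and r.record_date == end_date:
                final.append(r)
            elif (
                end_date < episode.discharge_date
                and r.record_date == episode.discharge_date
            ):
                final.append(r)
        else:  # attached ambulatory record
            if (
                r.issuing_specialty_psychiatric
                and end_date <= r.record_date <= episode.discharge_date
            ):
                final.append(r)

    final_keys = {(r.code, r.icd10_category) for r in final}
    preliminary = [
        r
        for r in in_scope
        if r.record_date < end_date and (r.code, r.icd10_category) not in final_keys
    ]

    def dedupe(records: list[DiagnosisRecord]) -> list[DiagnosisRecord]:
        seen: set[tuple[str, str]] = set()
        out = []
        for r in records:
            key = (r.code, r.icd10_category)
            if key not in seen:
                seen.add(key)
                out.append(r)
        return out

    return DischargeDiagnosisSet(
        episode_id=episode.episode_id,
        final=dedupe(final),
        preliminary=dedupe(preliminary),
        all_during_episode=all_records,
    )


def resolve_episode_set(
    episode_set: EpisodeSet,
    entries: list[RegisterEntry],
    mapping: MappingTable,
    include_non_psychiatric: bool = False,
) -> dict[str, DischargeDiagnosisSet]:
    """Resolve discharge diagnoses for every (psychiatric) episode in a set."""
    entries_by_id = {e.entry_id: e for e in entries}
    events_by_episode: dict[str, list[OutpatientEvent]] = {}
    for ev in episode_set.events:
        if ev.parent_episode_id is not None:
            events_by_episode.setdefault(ev.parent_episode_id, []).append(ev)
    out: dict[str, DischargeDiagnosisSet] = {}
    for ep in episode_set.episodes:
        if not ep.has_psychiatry and not include_non_psychiatric:
            continue
        members = [entries_by_id[i] for i in ep.member_entry_ids]
        out[ep.episode_id] = collect_discharge_diagnoses(
            ep,
            members,
            events_by_episode.get(ep.episode_id, []),
            entries_by_id,
            mapping,
            end_date=None if ep.has_psychiatry else ep.discharge_date,
        )
    return out


def completed_years(birth_date: datetime.date, at: datetime.date) -> int:
    return at.year - birth_date.year - (
        (at.month, at.day) < (birth_date.month, birth_date.day)
    )


def apply_age_floor(
    records: list[DiagnosisRecord],
    birth_date: datetime.date,
    categories: CategoryConfig,
) -> list[DiagnosisRecord]:
    """Drop records recorded before the earliest plausible onset age.

    The boundary is inclusive: a record exactly at the floor age is kept.
    Records without a mental-disorder category carry no floor.
    """
    out = []
    for r in records:
        floor = categories.age_floor_for(r.icd10_category)
        if floor is None or completed_years(birth_date, r.record_date) >= floor:
            out.append(r)
    return out
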