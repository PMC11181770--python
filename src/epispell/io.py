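"""Reading, validation and normalization of raw register entries.

The functions here implement the initial quality controls a register
extract needs before episode construction: exclusion of rows without a
person identifier or with defective dates, reconciliation of year-end
census records (patients reported as still in care on Dec 31), and the
era-dependent derivation of service type and psychiatric-care status.

All era/code lists live in a configuration file (see
``data/era_rules.yaml`` for the synthetic-register dialect shipped as
default), never in code.
"""
from __future__ import annotations

import datetime
import logging
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from ._types import (
    CodeSystem,
    ConfigurationError,
    Diagnosis,
    DiagnosisRole,
    ExclusionReason,
    ExclusionReport,
    RegisterEntry,
    ServiceType,
)

logger = logging.getLogger("epispell")

#: Logical column names understood by :func:`read_entries`; a schema_map
#: maps each of these to the actual column name in the input file.
DEFAULT_SCHEMA_MAP = {
    "entry_id": "entry_id",
    "person_id": "person_id",
    "admission_date": "admission_date",
    "discharge_date": "discharge_date",
    "service_code": "service_code",
    "service_code_new": "service_code_new",
    "specialty": "specialty",
    "provider_id": "provider_id",
    "provider_class": "provider_class",
    "main_dg": "main_dg",
    "additional_dgs": "additional_dgs",
    "dg_system": "dg_system",
    "era": "era",
}

_REQUIRED_COLUMNS = (
    "entry_id",
    "person_id",
    "admission_date",
    "discharge_date",
    "service_code",
    "specialty",
)

_OPTIONAL_COLUMNS = tuple(k for k in DEFAULT_SCHEMA_MAP if k not in _REQUIRED_COLUMNS)


class EraRules:
    """Era-dependent service-type and psychiatric-care code maps."""

    def __init__(self, raw: dict):
        try:
            st = raw["service_types"]
            self.inpatient_all_before = int(st["inpatient_all_before"])
            self._service_eras = []
            for block in st["eras"]:
                codes = {
                    str(k): ServiceType(v) for k, v in (block.get("codes") or {}).items()
                }
                codes_new = {
                    str(k): ServiceType(v)
                    for k, v in (block.get("codes_new") or {}).items()
                }
                self._service_eras.append(
                    (int(block["from"]), int(block["to"]), codes, codes_new)
                )
            psy = raw["psychiatric"]
            self.uniform_coding_from = int(psy["uniform_coding_from"])
            self.mental_hospital_classes = set(
                psy.get("mental_hospital_provider_classes", [])
            )
            self._psy_eras = [
                (int(b["from"]), int(b["to"]), set(map(str, b["specialties"])))
                for b in psy["eras"]
            ]
            self.census_reported_from = int(
                (raw.get("census") or {}).get("reported_from", 1996)
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigurationError(f"malformed era-rules configuration: {exc}") from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EraRules":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "EraRules":
        text = resources.files("epispell.data").joinpath("era_rules.yaml").read_text()
        return cls(yaml.safe_load(text))

    def service_era_block(self, era: int):
        for lo, hi, codes, codes_new in self._service_eras:
            if lo <= era <= hi:
                return codes, codes_new
        return None

    def psychiatric_specialties(self, era: int) -> set[str]:
        for lo, hi, specs in self._psy_eras:
            if lo <= era <= hi:
                return specs
        return set()


def _parse_date(value) -> datetime.date | None:
    if value is None:
        return None
    value = str(value).strip()
    if not value:
        return None
    try:
        return datetime.date.fromisoformat(value)
    except ValueError:
        return None


def _parse_diagnoses(main_dg, additional_dgs, dg_system) -> tuple[Diagnosis, ...]:
    try:
        system = CodeSystem(str(dg_system).strip()) if dg_system else CodeSystem.ICD10
    except ValueError:
        system = CodeSystem.ICD10
    out: list[Diagnosis] = []
    if main_dg and str(main_dg).strip():
        out.append(Diagnosis(str(main_dg).strip(), system, DiagnosisRole.MAIN))
    if additional_dgs and str(additional_dgs).strip():
        for code in str(additional_dgs).split(";"):
            code = code.strip()
            if code:
                out.append(Diagnosis(code, system, DiagnosisRole.ADDITIONAL))
    return tuple(out)


def entries_from_frame(df: pd.DataFrame, schema_map: dict | None = None) -> list[RegisterEntry]:
    """Build :class:`RegisterEntry` objects from a raw table, row order preserved."""
    schema = dict(DEFAULT_SCHEMA_MAP)
    if schema_map:
        schema.update(schema_map)
    for logical in _REQUIRED_COLUMNS:
        if schema[logical] not in df.columns:
            raise ConfigurationError(
                f"required column '{schema[logical]}' (for field '{logical}') "
                "is missing from the input"
            )

    def col(row, logical):
        name = schema.get(logical)
        if name is None or name not in df.columns:
            return None
        value = row[name]
        if value is None or (isinstance(value, float) and pd.isna(value)):
            return None
        value = str(value).strip()
        return value or None

    entries: list[RegisterEntry] = []
    for _, row in df.iterrows():
        admission = _parse_date(col(row, "admission_date"))
        discharge = _parse_date(col(row, "discharge_date"))
        era_raw = col(row, "era")
        if era_raw is not None:
            era = int(era_raw)
        elif admission is not None:
            era = admission.year
        elif discharge is not None:
            era = discharge.year
        else:
            era = 0
        entries.append(
            RegisterEntry(
                entry_id=col(row, "entry_id") or "",
                person_id=col(row, "person_id"),
                admission_date=admission,
                discharge_date=discharge,
                register_era=era,
                raw_service_code=col(row, "service_code"),
                raw_service_code_new=col(row, "service_code_new"),
                specialty=col(row, "specialty"),
                provider_id=col(row, "provider_id"),
                provider_class=col(row, "provider_class"),
                diagnoses=_parse_diagnoses(
                    col(row, "main_dg"), col(row, "additional_dgs"), col(row, "dg_system")
                ),
            )
        )
    return entries


def read_entries(path: str | Path, schema_map: dict | None = None) -> list[RegisterEntry]:
    """Read raw register entries from a delimited text file.

    The delimiter is auto-detected from the extension (``.tsv``/``.tab``
    for tab, comma otherwise); a header row is required and dates must be
    ISO-8601.  Unparseable dates become absent values, caught later by
    :func:`apply_quality_filters`.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        logger.warning("input file %s is empty; returning no entries", path)
        return []
    if df.empty:
        logger.warning("input file %s has a header but no rows", path)
    return entries_from_frame(df, schema_map)


def entries_to_frame(entries: list[RegisterEntry]) -> pd.DataFrame:
    """Serialize entries back to the canonical delimited-table layout."""
    rows = []
    for e in entries:
        main = next((d for d in e.diagnoses if d.role == DiagnosisRole.MAIN), None)
        additional = [d for d in e.diagnoses if d.role == DiagnosisRole.ADDITIONAL]
        rows.append(
            {
                "entry_id": e.entry_id,
                "person_id": e.person_id or "",
                "admission_date": e.admission_date.isoformat() if e.admission_date else "",
                "discharge_date": e.discharge_date.isoformat() if e.discharge_date else "",
                "service_code": e.raw_service_code or "",
                "service_code_new": e.raw_service_code_new or "",
                "service_type": e.service_type.value if e.service_type else "",
                "specialty": e.specialty or "",
                "provider_id": e.provider_id or "",
                "provider_class": e.provider_class or "",
                "is_psychiatric": str(e.is_psychiatric),
                "main_dg": main.code if main else "",
                "additional_dgs": ";".join(d.code for d in additional),
                "dg_system": (e.diagnoses[0].system.value if e.diagnoses else ""),
                "era": e.register_era,
                "closed_at_year_end": str(e.closed_at_year_end),
            }
        )
    return pd.DataFrame(rows)


def normalize_service_type(entry: RegisterEntry, era_rules: EraRules) -> RegisterEntry:
    """Derive the service-type enum from era-dependent raw codes.

    Entries before the inpatient-only cutoff are forced to inpatient; day
    hospital care counts as outpatient; and any non-inpatient entry
    spanning more than two calendar days is reclassified to inpatient
    (an outpatient or emergency contact may legitimately end the day
    after it started, around midnight, but not later).
    """
    era = entry.register_era
    if era < era_rules.inpatient_all_before:
        return entry.replace(service_type=ServiceType.INPATIENT)
    block = era_rules.service_era_block(era)
    if block is None:
        raise ConfigurationError(f"no service-type era rules cover era {era}")
    codes, codes_new = block
    st = None
    # 2019 reform: entries may carry the old dialect, the new one, or a
    # mixture of both, so each column is tried against each map.
    for code, table in (
        (entry.raw_service_code, codes),
        (entry.raw_service_code_new, codes_new),
        (entry.raw_service_code, codes_new),
        (entry.raw_service_code_new, codes),
    ):
        if code is not None and code in table:
            st = table[code]
            break
    if st is None:
        raise ConfigurationError(
            f"unmapped service-type code pair (era={era}, "
            f"code={entry.raw_service_code!r}, code_new={entry.raw_service_code_new!r})"
        )
    if st == ServiceType.DAY_HOSPITAL:
        st = ServiceType.OUTPATIENT
    if (
        st != ServiceType.INPATIENT
        and entry.admission_date is not None
        and entry.discharge_date is not None
        and (entry.discharge_date - entry.admission_date).days >= 2
    ):
        # Touches more than two distinct calendar days: inpatient care.
        st = ServiceType.INPATIENT
    return entry.replace(service_type=st)


def classify_psychiatric(entry: RegisterEntry, era_rules: EraRules) -> RegisterEntry:
    """Flag psychiatric care under era-dependent specialty/provider rules."""
    era = entry.register_era
    specs = era_rules.psychiatric_specialties(era)
    psy = False
    if entry.specialty is not None:
        if entry.specialty in specs:
            psy = True
        elif not specs:
            logger.debug("no psychiatric specialty list for era %s", era)
    if (
        not psy
        and era < era_rules.uniform_coding_from
        and entry.provider_class in era_rules.mental_hospital_classes
    ):
        psy = True
    return entry.replace(is_psychiatric=psy)


def resolve_year_end_open_entries(
    entries: list[RegisterEntry], census_policy: dict | None = None
) -> list[RegisterEntry]:
    """Reconcile year-end census records (open inpatient rows).

    From 1996 on, patients still in inpatient care on Dec 31 generate a
    register row whose discharge day should be blank (though this was not
    consistently recorded).  Reconciliation order: a census record wholly
    contained in another inpatient entry of the same person is dropped; an
    open record continued by an admission on/before Jan 1 of the next year
    is closed at that admission (chained); any remaining open record is
    closed at Dec 31 of its year and flagged ``closed_at_year_end``.
    """
    policy = census_policy or {}
    reported_from = int(policy.get("reported_from", 1996))

    closed_by_person: dict[str, list[RegisterEntry]] = {}
    for e in entries:
        if (
            e.person_id is not None
            and e.service_type == ServiceType.INPATIENT
            and e.admission_date is not None
            and e.discharge_date is not None
        ):
            closed_by_person.setdefault(e.person_id, []).append(e)

    out: list[RegisterEntry] = []
    for e in entries:
        is_census_candidate = (
            e.service_type == ServiceType.INPATIENT
            and e.person_id is not None
            and e.admission_date is not None
            and e.discharge_date is None
            and e.admission_date.year >= reported_from
        )
        if not is_census_candidate:
            out.append(e)
            continue
        a = e.admission_date
        year_end = datetime.date(a.year, 12, 31)
        siblings = [s for s in closed_by_person.get(e.person_id, []) if s.entry_id != e.entry_id]
        if any(s.admission_date <= a and s.discharge_date >= year_end for s in siblings):
            continue  # duplicate of a fully recorded stay
        continuations = sorted(
            s.admission_date
            for s in siblings
            if a < s.admission_date <= datetime.date(a.year + 1, 1, 1)
        )
        if continuations:
            out.append(e.replace(discharge_date=continuations[0]))
        else:
            out.append(e.replace(discharge_date=year_end, closed_at_year_end=True))
    return out


def apply_quality_filters(
    entries: list[RegisterEntry],
    time_range: tuple[datetime.date, datetime.date],
) -> tuple[list[RegisterEntry], ExclusionReport]:
    """Exclude defective entries, partitioning exclusions by first matching reason."""
    start, end = time_range
    if start > end:
        raise ValueError("time_range is empty")
    counts = {r: 0 for r in ExclusionReason}
    excluded: dict[ExclusionReason, list[str]] = {r: [] for r in ExclusionReason}
    retained: list[RegisterEntry] = []
    for e in entries:
        reason = None
        if not e.person_id:
            reason = ExclusionReason.MISSING_PERSON_ID
        elif e.admission_date is None:
            reason = ExclusionReason.MISSING_ADMISSION
        elif e.discharge_date is None:
            reason = ExclusionReason.MISSING_DISCHARGE
        elif e.discharge_date < e.admission_date:
            reason = ExclusionReason.DISCHARGE_BEFORE_ADMISSION
        elif not (
            start <= e.admission_date <= end and start <= e.discharge_date <= end
        ):
            reason = ExclusionReason.OUT_OF_TIME_RANGE
        if reason is None:
            retained.append(e)
        else:
            counts[reason] += 1
            excluded[reason].append(e.entry_id)
    report = ExclusionReport(
        counts=counts,
        excluded_ids=excluded,
        n_input=len(entries),
        n_retained=len(retained),
    )
    return retained, report


def prepare_entries(
    entries: list[RegisterEntry],
    era_rules: EraRules,
    time_range: tuple[datetime.date, datetime.date],
    census_policy: dict | None = None,
) -> tuple[list[RegisterEntry], ExclusionReport]:
    """Full normalization pipeline: service type, psychiatric flag, census
    reconciliation, then quality filters (in that contractual order)."""
    normalized = [
        classify_psychiatric(normalize_service_type(e, era_rules), era_rules)
        for e in entries
    ]
    policy = census_policy or {"reported_from": era_rules.census_reported_from}
    resolved = resolve_year_end_open_entries(normalized, policy)
    retained, report = apply_quality_filters(resolved, time_range)
    logger.info(
        "prepared entries: %d in, %d retained, %d excluded",
        report.n_input,
        report.n_retained,
        report.n_excluded,
    )
    return retained, report
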