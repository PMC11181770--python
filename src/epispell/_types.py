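"""Core domain types shared across the package.

The central objects mirror how Nordic discharge registers are organised:
one :class:`RegisterEntry` per administrative record (a ward-stay segment,
an outpatient or emergency visit, a primary-care contact, or a year-end
census row), which the episode builder merges into
:class:`InpatientEpisode` / :class:`OutpatientEvent` objects.
"""
from __future__ import annotations

import dataclasses
import datetime
import enum
from dataclasses import dataclass, field


class ConfigurationError(Exception):
    """A configuration file or mapping is missing or malformed."""


class ContractViolation(ValueError):
    """An operation was called with inputs that violate its preconditions."""


class ServiceType(str, enum.Enum):
    INPATIENT = "inpatient"
    OUTPATIENT = "outpatient"
    EMERGENCY = "emergency"
    DAY_HOSPITAL = "day_hospital"
    PRIMARY_CARE = "primary_care"
    OTHER_CONTACT = "other_contact"


#: Service types that count as ambulatory (non-inpatient) after normalization.
AMBULATORY_TYPES = frozenset(
    {
        ServiceType.OUTPATIENT,
        ServiceType.EMERGENCY,
        ServiceType.PRIMARY_CARE,
        ServiceType.OTHER_CONTACT,
    }
)


class CodeSystem(str, enum.Enum):
    ICD8 = "ICD8"
    ICD9 = "ICD9"
    ICD10 = "ICD10"
    ICPC2 = "ICPC2"


class DiagnosisRole(str, enum.Enum):
    MAIN = "main"
    ADDITIONAL = "additional"


class ExclusionReason(str, enum.Enum):
    """Quality-filter exclusion reasons, in precedence order.

    An entry failing several checks is counted once, under the first
    matching reason in this order, so report sums equal exclusion totals.
    """

    MISSING_PERSON_ID = "missing_person_id"
    MISSING_ADMISSION = "missing_admission"
    MISSING_DISCHARGE = "missing_discharge"
    DISCHARGE_BEFORE_ADMISSION = "discharge_before_admission"
    OUT_OF_TIME_RANGE = "out_of_time_range"


class EventSource(str, enum.Enum):
    SECONDARY_OUTPATIENT = "secondary_outpatient"
    EMERGENCY = "emergency"
    PRIMARY_CARE = "primary_care"
    RECLASSIFIED_SAME_DAY_STAY = "reclassified_same_day_stay"


@dataclass(frozen=True)
class Diagnosis:
    """One diagnosis code carried by a register entry."""

    code: str
    system: CodeSystem
    role: DiagnosisRole


@dataclass
class RegisterEntry:
    """One raw register row.

    ``raw_service_code`` / ``raw_service_code_new`` hold the original
    service-type codes (two columns because the 2019 coding reform left
    entries carrying the old dialect, the new one, or a mixture);
    ``service_type`` and ``is_psychiatric`` are derived during
    normalization.  Dates are inclusive at both ends: a stay Jan 1 - Jan 1
    occupies exactly one calendar day.
    """

    entry_id: str
    person_id: str | None
    admission_date: datetime.date | None
    discharge_date: datetime.date | None
    register_era: int
    raw_service_code: str | None = None
    raw_service_code_new: str | None = None
    service_type: ServiceType | None = None
    specialty: str | None = None
    provider_id: str | None = None
    provider_class: str | None = None
    is_psychiatric: bool = False
    diagnoses: tuple[Diagnosis, ...] = ()
    closed_at_year_end: bool = False

    def replace(self, **changes) -> "RegisterEntry":
        return dataclasses.replace(self, **changes)


@dataclass
class ExclusionReport:
    """Partition of excluded entries by reason.

    Invariant: ``sum(counts.values()) + n_retained == n_input``.
    """

    counts: dict[ExclusionReason, int]
    excluded_ids: dict[ExclusionReason, list[str]]
    n_input: int
    n_retained: int

    @property
    def n_excluded(self) -> int:
        return sum(self.counts.values())

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "reason": [r.value for r in ExclusionReason],
                "count": [self.counts.get(r, 0) for r in ExclusionReason],
            }
        )


@dataclass(frozen=True)
class ModelSpec:
    """One of the four episode-identification models.

    ``merge_gap_days`` is the largest admission-minus-discharge gap (in
    days) still treated as a transfer: 0 merges only same-day re-admissions
    (models 1-2), 1 also merges next-day admissions, i.e. a new episode
    requires a full calendar day outside hospital (models 3-4).
    ``require_overnight`` reclassifies same-day episodes as outpatient
    events (models 2 and 4).
    """

    model_id: int
    merge_gap_days: int
    require_overnight: bool


MODELS: dict[int, ModelSpec] = {
    1: ModelSpec(1, 0, False),
    2: ModelSpec(2, 0, True),
    3: ModelSpec(3, 1, False),
    4: ModelSpec(4, 1, True),
}


@dataclass
class InpatientEpisode:
    """A merged hospital stay with its psychiatric sub-interval."""

    episode_id: str
    person_id: str
    admission_date: datetime.date
    discharge_date: datetime.date
    model_id: int
    member_entry_ids: tuple[str, ...]
    has_psychiatry: bool = False
    psy_start: datetime.date | None = None
    psy_end: datetime.date | None = None
    attached_event_ids: list[str] = field(default_factory=list)

    def los(self, convention: str = "nights") -> int:
        """Overall length of stay (``nights`` or calendar ``days``)."""
        n = (self.discharge_date - self.admission_date).days
        return n + 1 if convention == "days" else n

    def psy_los(self, convention: str = "nights") -> int | None:
        if not self.has_psychiatry:
            return None
        n = (self.psy_end - self.psy_start).days
        return n + 1 if convention == "days" else n


@dataclass
class OutpatientEvent:
    """An ambulatory contact; independent unless it falls inside an episode."""

    event_id: str
    person_id: str
    event_start: datetime.date
    event_end: datetime.date
    source: EventSource
    independent: bool = True
    parent_episode_id: str | None = None
    source_entry_ids: tuple[str, ...] = ()
    is_psychiatric: bool = False


@dataclass
class EpisodeSet:
    """All episodes and ambulatory events for a cohort under one model."""

    model_id: int
    episodes: list[InpatientEpisode]
    events: list[OutpatientEvent]


UNMAPPED = "UNMAPPED"


@dataclass(frozen=True)
class DiagnosisRecord:
    """One dated diagnosis in the scope of an episode."""

    person_id: str
    source_entry_id: str
    record_date: datetime.date
    code: str
    system: CodeSystem
    role: DiagnosisRole
    issuing_specialty_psychiatric: bool
    icd10_category: str = UNMAPPED


@dataclass
class DischargeDiagnosisSet:
    """Final vs. preliminary diagnoses resolved for one episode."""

    episode_id: str
    final: list[DiagnosisRecord]
    preliminary: list[DiagnosisRecord]
    all_during_episode: list[DiagnosisRecord]
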