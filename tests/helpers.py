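"""Shared test utilities: an entry factory and an independent merge oracle."""
from __future__ import annotations

import datetime

from epispell import (
    CodeSystem,
    Diagnosis,
    DiagnosisRole,
    RegisterEntry,
    ServiceType,
)

D = datetime.date


def as_date(v) -> datetime.date | None:
    if v is None or isinstance(v, datetime.date):
        return v
    return datetime.date.fromisoformat(v)


def make_entry(
    entry_id: str,
    person: str | None = "P1",
    adm=None,
    dis=None,
    service: ServiceType | None = ServiceType.INPATIENT,
    psych: bool = True,
    specialty: str = "70",
    dgs: tuple = (),
    era: int | None = None,
    raw_code: str = "1",
    **kw,
) -> RegisterEntry:
    """Build a normalized RegisterEntry for tests; ``dgs`` is a tuple of
    (code,) / (code, role) / (code, role, system) shorthands."""
    adm, dis = as_date(adm), as_date(dis)
    diagnoses = []
    for dg in dgs:
        code = dg[0] if isinstance(dg, tuple) else dg
        role = DiagnosisRole(dg[1]) if isinstance(dg, tuple) and len(dg) > 1 else DiagnosisRole.MAIN
        system = CodeSystem(dg[2]) if isinstance(dg, tuple) and len(dg) > 2 else CodeSystem.ICD10
        diagnoses.append(Diagnosis(code, system, role))
    return RegisterEntry(
        entry_id=entry_id,
        person_id=person,
        admission_date=adm,
        discharge_date=dis,
        register_era=era if era is not None else (adm.year if adm else 2015),
        raw_service_code=raw_code,
        service_type=service,
        specialty=specialty,
        is_psychiatric=psych,
        diagnoses=tuple(diagnoses),
        **kw,
    )


def oracle_merge(
    intervals: list[tuple[datetime.date, datetime.date]], gap_days: int
) -> list[tuple[datetime.date, datetime.date, int]]:
    """Brute-force day-occupancy merge, independent of the implementation.

    Each interval claims its calendar days plus ``gap_days`` dilation past
    its end; intervals sharing any claimed day belong to the same episode
    (transitively, via union-find).  Returns sorted (start, end, size)
    tuples with the undilated bounds of each component.
    """
    parent = list(range(len(intervals)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj

    day_claims: dict[int, int] = {}
    for i, (a, d) in enumerate(intervals):
        for o in range(a.toordinal(), d.toordinal() + gap_days + 1):
            if o in day_claims:
                union(i, day_claims[o])
            else:
                day_claims[o] = i
    components: dict[int, list[tuple[datetime.date, datetime.date]]] = {}
    for i, iv in enumerate(intervals):
        components.setdefault(find(i), []).append(iv)
    out = [
        (min(a for a, _ in ivs), max(d for _, d in ivs), len(ivs))
        for ivs in components.values()
    ]
    return sorted(out)
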