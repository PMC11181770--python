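"""Synthetic register generator with planted ground truth.

Real psychiatric register data are restricted, so every stage of the
pipeline is exercised against generated entry tables that emulate the
structures episode construction must disentangle: hospital stays
fragmented into several entries by transfers (same-day or overlapping
boundaries), emergency-department and outpatient contacts at the outset
of or during stays, preliminary diagnoses earlier in a stay drifting
toward the eventual discharge diagnosis (acute/unspecified psychosis
F23/F29 resolving to schizophrenia F20), same-day stays, year-end open
census rows, the 2019 service-coding mixture, and injected quality
defects.

The planted truth is emitted as sidecar structures (never as columns of
the entry table), and helper functions compute the per-model episode
counts and discharge-diagnosis sets the pipeline is expected to
recover.
"""
from __future__ import annotations

import dataclasses
import datetime
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._types import ModelSpec

_DAY = datetime.timedelta(days=1)

#: Drift sources for preliminary psychosis diagnoses.
_PSYCHOSIS_FINALS = {"F20", "F25", "F31"}
_PSYCHOSIS_PRELIMS = ("F23", "F29")
_SOMATIC_CODE = "I109"

_ICPC2_BY_CATEGORY = {
    "F10": "P15",
    "F20": "P72",
    "F31": "P73",
    "F41": "P74",
    "F32": "P76",
    "F43": "P79",
    "F70": "P85",
}


@dataclass
class GeneratorParams:
    """Parameters of the synthetic register ("finland-like" defaults).

    Probabilities are per true episode unless stated otherwise; rates are
    annual per person.  Defect rates are fractions of clean entries that
    spawn additional defective rows (disjoint by construction, so the
    quality filter's exclusion counts equal the planted defect counts).
    A fixed seed yields byte-identical output.
    """

    n_persons: int = 1000
    date_range: tuple[datetime.date, datetime.date] = (
        datetime.date(2011, 1, 1),
        datetime.date(2020, 12, 31),
    )
    annual_admission_rate: float = 0.35
    annual_outpatient_rate: float = 2.0
    # stays shorter than min_fragment_los nights are never fragmented
    fragment_count_probs: dict[int, float] = field(
        default_factory=lambda: {1: 0.92, 2: 0.06, 3: 0.02}
    )
    min_fragment_los: int = 4
    boundary_style_probs: dict[str, float] = field(
        default_factory=lambda: {"same_day": 0.65, "overlap": 0.35, "next_day": 0.0}
    )
    p_same_day_stay: float = 0.02
    p_ed_prefix: float = 0.10
    p_outpatient_during_stay: float = 0.10
    p_outpatient_on_discharge_day: float = 0.06
    p_preliminary_diagnosis: float = 0.40
    p_additional_final: float = 0.15
    p_psychiatric_episode: float = 0.90
    # readmission gaps in days; "long" draws 3 + Exponential(long_gap_mean)
    readmission_gap_probs: dict[object, float] = field(
        default_factory=lambda: {0: 0.01, 1: 0.02, 2: 0.03, "long": 0.94}
    )
    long_gap_mean_days: float = 150.0
    los_log_mean: float = math.log(9.0)
    los_log_sd: float = 0.9
    max_los_days: int = 365
    p_year_end_open_entry: float = 0.6
    p_census_discharge_filled: float = 0.3
    p_split_at_year_end: float = 0.2
    rate_missing_person_id: float = 0.001
    rate_missing_admission: float = 0.001
    rate_inverted_dates: float = 0.001
    rate_out_of_range: float = 0.001
    p_icpc2_in_primary_care: float = 0.3
    category_mix: dict[str, float] = field(
        default_factory=lambda: {
            "F20": 0.10,
            "F23": 0.05,
            "F29": 0.05,
            "F31": 0.07,
            "F32": 0.22,
            "F33": 0.08,
            "F10": 0.15,
            "F40": 0.07,
            "F41": 0.07,
            "F43": 0.04,
            "F60": 0.05,
            "F00": 0.02,
            "F03": 0.01,
            "F90": 0.02,
        }
    )
    seed: int = 0

    def validate(self) -> None:
        probs = [
            self.p_same_day_stay,
            self.p_ed_prefix,
            self.p_outpatient_during_stay,
            self.p_outpatient_on_discharge_day,
            self.p_preliminary_diagnosis,
            self.p_additional_final,
            self.p_psychiatric_episode,
            self.p_year_end_open_entry,
            self.p_census_discharge_filled,
            self.p_split_at_year_end,
            self.p_icpc2_in_primary_care,
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        rates = [
            self.annual_admission_rate,
            self.annual_outpatient_rate,
            self.rate_missing_person_id,
            self.rate_missing_admission,
            self.rate_inverted_dates,
            self.rate_out_of_range,
        ]
        if any(r < 0 for r in rates):
            raise ValueError("rates must be non-negative")
        for name, dist in (
            ("fragment_count_probs", self.fragment_count_probs),
            ("boundary_style_probs", self.boundary_style_probs),
            ("readmission_gap_probs", self.readmission_gap_probs),
        ):
            total = sum(dist.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9) or any(
                v < 0 for v in dist.values()
            ):
                raise ValueError(f"{name} must be a probability distribution, sums to {total}")
        start, end = self.date_range
        if (end - start).days <= self.max_los_days:
            raise ValueError(
                "date_range must be longer than the maximum planted stay "
                f"({self.max_los_days} days)"
            )
        if self.n_persons < 1:
            raise ValueError("n_persons must be positive")


@dataclass
class TrueEpisode:
    """One planted hospital stay with its diagnosis truth."""

    person_id: str
    index: int
    start: datetime.date
    end: datetime.date
    psychiatric: bool
    final_codes: tuple[str, ...]
    preliminary_codes: tuple[str, ...]
    fragments: tuple[tuple[str, datetime.date, datetime.date], ...]
    gap_after: int | None  # days to the next planted episode of this person

    @property
    def fragment_entry_ids(self) -> tuple[str, ...]:
        return tuple(f[0] for f in self.fragments)


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted alongside the entry table."""

    episodes: list[TrueEpisode]
    crosswalk: dict[str, tuple[str, int, str]]  # entry_id -> (person, episode idx, kind)
    defects: dict[str, list[str]]  # exclusion reason value -> entry ids

    def episodes_by_person(self) -> dict[str, list[TrueEpisode]]:
        out: dict[str, list[TrueEpisode]] = {}
        for ep in self.episodes:
            out.setdefault(ep.person_id, []).append(ep)
        for eps in out.values():
            eps.sort(key=lambda e: e.start)
        return out

    def episodes_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "person_id": e.person_id,
                    "episode_index": e.index,
                    "start": e.start.isoformat(),
                    "end": e.end.isoformat(),
                    "psychiatric": e.psychiatric,
                    "final_codes": ";".join(e.final_codes),
                    "preliminary_codes": ";".join(e.preliminary_codes),
                    "gap_after": "" if e.gap_after is None else e.gap_after,
                }
                for e in self.episodes
            ]
        )

    def crosswalk_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"entry_id": k, "person_id": v[0], "episode_index": v[1], "kind": v[2]}
                for k, v in sorted(self.crosswalk.items())
            ]
        )


@dataclass
class SyntheticCohort:
    entries: pd.DataFrame
    persons: pd.DataFrame
    truth: SyntheticTruth


class _Emitter:
    """Accumulates entry rows with sequential ids."""

    def __init__(self):
        self.rows: list[dict] = []
        self._n = 0

    def emit(
        self,
        person_id,
        admission,
        discharge,
        service_old,
        service_new,
        specialty,
        main_dg="",
        additional_dgs="",
        dg_system="ICD10",
        provider_id="H1",
        provider_class="general_hospital",
    ) -> str:
        self._n += 1
        eid = f"E{self._n:07d}"
        self.rows.append(
            {
                "entry_id": eid,
                "person_id": person_id,
                "admission_date": admission.isoformat() if admission else "",
                "discharge_date": discharge.isoformat() if discharge else "",
                "service_code": service_old,
                "service_code_new": service_new,
                "specialty": specialty,
                "provider_id": provider_id,
                "provider_class": provider_class,
                "main_dg": main_dg,
                "additional_dgs": additional_dgs,
                "dg_system": dg_system,
            }
        )
        return eid


def _service_codes(rng: np.random.Generator, year: int, kind: str) -> tuple[str, str]:
    """Old/new service-code columns, with the 2019+ coding mixture."""
    old = {"inpatient": "1", "outpatient": "83", "emergency": "91", "primary_care": "92"}[kind]
    new = {"inpatient": "R10", "outpatient": "R20", "emergency": "R30", "primary_care": "R40"}[kind]
    if year < 2019:
        return old, ""
    u = rng.random()
    if u < 0.4:
        return old, ""  # old dialect persists
    if u < 0.8:
        return "", new
    return old, new  # mixture of both


def _draw_category(rng: np.random.Generator, mix: dict[str, float]) -> str:
    cats = sorted(mix)
    probs = np.array([mix[c] for c in cats])
    return cats[rng.choice(len(cats), p=probs / probs.sum())]


def _draw_from(rng: np.random.Generator, dist: dict) -> object:
    keys = sorted(dist, key=str)
    probs = np.array([dist[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


def generate_cohort(params: GeneratorParams) -> SyntheticCohort:
    """Generate an entry table, a persons table, and the planted truth."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    start, end = params.date_range
    span_days = (end - start).days + 1
    span_years = span_days / 365.25

    emitter = _Emitter()
    episodes: list[TrueEpisode] = []
    crosswalk: dict[str, tuple[str, int, str]] = {}
    persons_rows = []

    for p in range(params.n_persons):
        person_id = f"P{p + 1:06d}"
        birth = start - datetime.timedelta(
            days=int(rng.integers(9 * 365, 61 * 365))  # ages ~9-61 at range start
        )
        persons_rows.append({"person_id": person_id, "birth_date": birth.isoformat()})
        _generate_person(params, rng, emitter, episodes, crosswalk, person_id, birth)

    n_clean = len(emitter.rows)
    defects = _plant_defects(params, rng, emitter, crosswalk, n_clean, start)

    entries = pd.DataFrame(
        emitter.rows,
        columns=[
            "entry_id",
            "person_id",
            "admission_date",
            "discharge_date",
            "service_code",
            "service_code_new",
            "specialty",
            "provider_id",
            "provider_class",
            "main_dg",
            "additional_dgs",
            "dg_system",
        ],
    )
    persons = pd.DataFrame(persons_rows, columns=["person_id", "birth_date"])
    return SyntheticCohort(
        entries=entries,
        persons=persons,
        truth=SyntheticTruth(episodes=episodes, crosswalk=crosswalk, defects=defects),
    )


def _generate_person(params, rng, emitter, episodes, crosswalk, person_id, birth):
    start, end = params.date_range
    span_days = (end - start).days + 1
    span_years = span_days / 365.25
    n_eps = int(rng.poisson(params.annual_admission_rate * span_years))

    # Draw the stay structure first (lengths and gap kinds), then spread
    # the remaining slack uniformly over the long gaps so admissions cover
    # the whole study window instead of piling up at its start.
    los_list: list[int] = []
    for _ in range(n_eps):
        if rng.random() < params.p_same_day_stay:
            los_list.append(0)
        else:
            los = int(round(rng.lognormal(params.los_log_mean, params.los_log_sd)))
            los_list.append(min(max(los, 1), params.max_los_days))
    gap_kinds: list[object] = []
    for i in range(max(n_eps - 1, 0)):
        kind = _draw_from(rng, params.readmission_gap_probs)
        # same-day stays must stay clear of their neighbours
        if los_list[i] == 0 or los_list[i + 1] == 0:
            kind = "long"
        gap_kinds.append(kind)

    while los_list:
        fixed = sum(los_list) + sum(int(k) for k in gap_kinds if k != "long")
        n_long = sum(1 for k in gap_kinds if k == "long") + 1  # + lead-in offset
        if span_days - 1 - fixed >= 3 * n_long:
            break
        los_list.pop()
        if gap_kinds:
            gap_kinds.pop()
    if not los_list:
        return
    slack = span_days - 1 - sum(los_list) - sum(int(k) for k in gap_kinds if k != "long")
    n_long = sum(1 for k in gap_kinds if k == "long") + 1
    weights = rng.dirichlet(np.ones(n_long))
    long_values = 3 + np.floor(weights * (slack - 3 * n_long)).astype(int)
    long_values[0] -= 3  # the lead-in offset may be zero
    long_iter = iter(long_values)

    planted: list[dict] = []
    cursor = start + datetime.timedelta(days=int(next(long_iter)))
    for i, los in enumerate(los_list):
        ep_start = cursor
        ep_end = ep_start + datetime.timedelta(days=los)
        planted.append({"start": ep_start, "end": ep_end, "los": los, "gap": None})
        if i < len(gap_kinds):
            kind = gap_kinds[i]
            gap = int(next(long_iter)) if kind == "long" else int(kind)
            planted[-1]["gap"] = gap
            cursor = ep_end + datetime.timedelta(days=gap)

    episode_intervals = [(ep["start"], ep["end"]) for ep in planted]

    for j, ep in enumerate(planted):
        _emit_episode(
            params, rng, emitter, episodes, crosswalk, person_id, birth, j, ep
        )

    _emit_independent_contacts(
        params, rng, emitter, crosswalk, person_id, birth, episode_intervals
    )


def _age_at(birth: datetime.date, at: datetime.date) -> int:
    return at.year - birth.year - ((at.month, at.day) < (birth.month, birth.day))


def _pick_final_category(params, rng, birth, at) -> str:
    cat = _draw_category(rng, params.category_mix)
    # respect onset-age plausibility so planted truth survives age floors
    age = _age_at(birth, at)
    floor = 35 if cat in {"F00", "F03"} else (1 if cat[1] in "789" else 5)
    if age < floor:
        cat = "F32" if age >= 5 else "F90"
    return cat


def _pick_preliminary_category(params, rng, final_cat: str) -> str:
    if final_cat in _PSYCHOSIS_FINALS:
        return _PSYCHOSIS_PRELIMS[int(rng.integers(0, len(_PSYCHOSIS_PRELIMS)))]
    for _ in range(10):
        cat = _draw_category(rng, params.category_mix)
        if cat != final_cat:
            return cat
    return "F43"


def _emit_episode(params, rng, emitter, episodes, crosswalk, person_id, birth, j, ep):
    ep_start, ep_end, los = ep["start"], ep["end"], ep["los"]
    psychiatric = rng.random() < params.p_psychiatric_episode
    specialty = "70" if psychiatric else "10"

    if psychiatric:
        final_cat = _pick_final_category(params, rng, birth, ep_end)
        final_code = final_cat + "0"
        final_codes = [final_code]
        additional = ""
        if rng.random() < params.p_additional_final:
            extra = "F100" if final_cat != "F10" else "F410"
            final_codes.append(extra)
            additional = extra
        prelim_cat = _pick_preliminary_category(params, rng, final_cat)
        prelim_code = prelim_cat + "0"
    else:
        final_code, additional, prelim_code = _SOMATIC_CODE, "", _SOMATIC_CODE
        final_codes = []

    preliminary_codes: list[str] = []

    # --- fragmentation into register entries (transfers) ---
    if los >= params.min_fragment_los:
        n_frag = int(_draw_from(rng, params.fragment_count_probs))
    else:
        n_frag = 1
    interior = np.arange(1, los)  # candidate cut offsets
    if n_frag > 1 and len(interior) >= n_frag - 1:
        cuts = sorted(rng.choice(interior, size=n_frag - 1, replace=False))
    else:
        cuts = []
    bounds = [0, *cuts, los]
    fragments: list[tuple[datetime.date, datetime.date]] = []
    for k in range(len(bounds) - 1):
        f_start = ep_start + datetime.timedelta(days=int(bounds[k]))
        f_end = ep_start + datetime.timedelta(days=int(bounds[k + 1]))
        if k < len(bounds) - 2:
            style = _draw_from(rng, params.boundary_style_probs)
            if style == "overlap" and bounds[k + 1] + 1 <= los:
                f_end = f_end + _DAY
            elif style == "next_day":
                f_end = f_end - _DAY
        fragments.append((f_start, f_end))

    frag_records: list[tuple[str, datetime.date, datetime.date]] = []
    for k, (f_start, f_end) in enumerate(fragments):
        last = k == len(fragments) - 1
        main, extra = "", ""
        if last:
            main, extra = final_code, additional
        elif f_end < ep_end and rng.random() < params.p_preliminary_diagnosis:
            main = prelim_code
            if psychiatric:
                preliminary_codes.append(prelim_code)
        old, new = _service_codes(rng, f_start.year, "inpatient")
        eid = emitter.emit(
            person_id, f_start, f_end, old, new, specialty, main_dg=main,
            additional_dgs=extra,
        )
        crosswalk[eid] = (person_id, j, "fragment")
        frag_records.append((eid, f_start, f_end))

    # --- year-end reporting: split stays and census rows ---
    frag_records = _apply_year_end(
        params, rng, emitter, crosswalk, person_id, j, frag_records,
        prelim_code, psychiatric, preliminary_codes,
    )

    # --- ambulatory contacts tied to the stay ---
    if los >= 1 and rng.random() < params.p_ed_prefix:
        ed_end = ep_start + (_DAY if rng.random() < 0.3 else datetime.timedelta(0))
        main = ""
        if rng.random() < 0.5:
            main = prelim_code
            if psychiatric:
                preliminary_codes.append(prelim_code)
        old, new = _service_codes(rng, ep_start.year, "emergency")
        eid = emitter.emit(person_id, ep_start, ed_end, old, new, specialty, main_dg=main)
        crosswalk[eid] = (person_id, j, "ed_prefix")
    if los >= 2 and rng.random() < params.p_outpatient_during_stay:
        day = ep_start + datetime.timedelta(days=int(rng.integers(1, los)))
        main = ""
        if rng.random() < 0.7:
            main = prelim_code
            if psychiatric:
                preliminary_codes.append(prelim_code)
        old, new = _service_codes(rng, day.year, "outpatient")
        eid = emitter.emit(person_id, day, day, old, new, specialty, main_dg=main)
        crosswalk[eid] = (person_id, j, "outpatient_during_stay")
    if psychiatric and rng.random() < params.p_outpatient_on_discharge_day:
        old, new = _service_codes(rng, ep_end.year, "outpatient")
        eid = emitter.emit(person_id, ep_end, ep_end, old, new, "70", main_dg=final_code)
        crosswalk[eid] = (person_id, j, "outpatient_on_discharge_day")

    episodes.append(
        TrueEpisode(
            person_id=person_id,
            index=j,
            start=ep_start,
            end=ep_end,
            psychiatric=psychiatric,
            final_codes=tuple(final_codes),
            preliminary_codes=tuple(sorted(set(preliminary_codes))),
            fragments=tuple(frag_records),
            gap_after=ep["gap"],
        )
    )


def _apply_year_end(
    params, rng, emitter, crosswalk, person_id, j, frag_records,
    prelim_code, psychiatric, preliminary_codes,
):
    """Split a year-spanning fragment into an open row plus continuation,
    or emit a duplicate census row, mimicking Dec-31 reporting."""
    spanning = [
        (i, rec)
        for i, rec in enumerate(frag_records)
        if rec[1].year < rec[2].year
    ]
    if not spanning:
        return frag_records
    i, (eid, f_start, f_end) = spanning[0]
    year_end = datetime.date(f_start.year, 12, 31)
    jan1 = year_end + _DAY
    u = rng.random()
    # A split needs the open row to start clearly before Dec 31; otherwise
    # another entry (a gap-0 readmission or an overlapping transfer) can
    # cover its census interval and the resolver would rightly drop it as
    # a contained duplicate.
    splittable = f_end > jan1 and f_start <= year_end - 2 * _DAY
    if u < params.p_split_at_year_end and splittable:
        # replace the emitted row: open part + continuation
        row = next(r for r in emitter.rows if r["entry_id"] == eid)
        row["discharge_date"] = ""  # blank, to be chained at Jan 1
        old, new = _service_codes(rng, jan1.year, "inpatient")
        specialty = row["specialty"]
        # the continuation inherits the fragment's diagnoses
        cont_id = emitter.emit(
            person_id, jan1, f_end, old, new, specialty,
            main_dg=row["main_dg"], additional_dgs=row["additional_dgs"],
        )
        row["main_dg"], row["additional_dgs"] = "", ""
        crosswalk[cont_id] = (person_id, j, "fragment")
        new_records = list(frag_records)
        new_records[i] = (eid, f_start, jan1)
        new_records.insert(i + 1, (cont_id, jan1, f_end))
        return new_records
    if u < params.p_split_at_year_end + params.p_year_end_open_entry:
        filled = rng.random() < params.p_census_discharge_filled
        main = ""
        if filled and rng.random() < 0.5:
            main = prelim_code
            if psychiatric and f_end > year_end:
                preliminary_codes.append(prelim_code)
        row = next(r for r in emitter.rows if r["entry_id"] == eid)
        old, new = _service_codes(rng, f_start.year, "inpatient")
        census_id = emitter.emit(
            person_id, f_start, year_end if filled else None, old, new,
            row["specialty"], main_dg=main,
        )
        crosswalk[census_id] = (person_id, j, "census")
    return frag_records


def _emit_independent_contacts(
    params, rng, emitter, crosswalk, person_id, birth, episode_intervals
):
    start, end = params.date_range
    span_days = (end - start).days + 1
    n = int(rng.poisson(params.annual_outpatient_rate * span_days / 365.25))
    for _ in range(n):
        day = None
        for _attempt in range(20):
            cand = start + datetime.timedelta(days=int(rng.integers(0, span_days)))
            if not any(a <= cand <= d for a, d in episode_intervals):
                day = cand
                break
        if day is None:
            continue
        kind = _draw_from(
            rng, {"outpatient": 0.6, "primary_care": 0.3, "emergency": 0.1}
        )
        specialty = "70" if rng.random() < 0.6 else "10"
        main, system = "", "ICD10"
        if rng.random() < 0.8:
            cat = _pick_final_category(params, rng, birth, day)
            main = cat + "0"
            if specialty != "70":
                # mental diagnoses in our somatic outpatient rows would be
                # excluded downstream anyway; keep them psychiatric-issued
                specialty = "70"
            if kind == "primary_care" and rng.random() < params.p_icpc2_in_primary_care:
                system = "ICPC2"
                main = _ICPC2_BY_CATEGORY.get(cat, "A04")
        old, new = _service_codes(rng, day.year, kind)
        eid = emitter.emit(
            person_id, day, day, old, new, specialty, main_dg=main, dg_system=system
        )
        crosswalk[eid] = (person_id, -1, "independent_contact")


def _plant_defects(params, rng, emitter, crosswalk, n_clean, range_start):
    defects: dict[str, list[str]] = {
        "missing_person_id": [],
        "missing_admission": [],
        "discharge_before_admission": [],
        "out_of_time_range": [],
    }

    def n_for(rate: float) -> int:
        return int(rng.binomial(n_clean, rate)) if rate > 0 else 0

    def random_day(lo_offset=0, hi_offset=3000) -> datetime.date:
        return range_start + datetime.timedelta(days=int(rng.integers(lo_offset, hi_offset)))

    for _ in range(n_for(params.rate_missing_person_id)):
        d = random_day()
        eid = emitter.emit("", d, d + 5 * _DAY, "1", "", "70", main_dg="F200")
        crosswalk[eid] = ("", -1, "defect")
        defects["missing_person_id"].append(eid)
    for _ in range(n_for(params.rate_missing_admission)):
        d = random_day()
        eid = emitter.emit(
            f"P{int(rng.integers(1, params.n_persons + 1)):06d}", None, d, "83", "", "70"
        )
        crosswalk[eid] = ("", -1, "defect")
        defects["missing_admission"].append(eid)
    for _ in range(n_for(params.rate_inverted_dates)):
        d = random_day()
        eid = emitter.emit(
            f"P{int(rng.integers(1, params.n_persons + 1)):06d}",
            d + datetime.timedelta(days=int(rng.integers(1, 10))),
            d,
            "1",
            "",
            "70",
        )
        crosswalk[eid] = ("", -1, "defect")
        defects["discharge_before_admission"].append(eid)
    for _ in range(n_for(params.rate_out_of_range)):
        d = range_start - datetime.timedelta(days=int(rng.integers(30, 400)))
        eid = emitter.emit(
            f"P{int(rng.integers(1, params.n_persons + 1)):06d}", d, d + 2 * _DAY,
            "1", "", "70", main_dg="F320",
        )
        crosswalk[eid] = ("", -1, "defect")
        defects["out_of_time_range"].append(eid)
    return defects


# ---------------------------------------------------------------------------
# Recovery targets (truth-side oracles)
# ---------------------------------------------------------------------------


def _occupancy_runs(
    intervals: list[tuple[datetime.date, datetime.date]], gap_days: int
) -> list[tuple[datetime.date, datetime.date]]:
    """Day-occupancy merge: mark covered days (each interval dilated by the
    gap at its end), find connected runs, return per-run true bounds.

    Occupancy is marked on a half-day grid (each day -> two units) so
    that intervals merely touching on consecutive days stay separate;
    only intervals sharing a day (after dilation) connect.
    """
    lo = 2 * min(a for a, _ in intervals).toordinal()
    hi = 2 * (max(d for _, d in intervals).toordinal() + gap_days)
    occ = np.zeros(hi - lo + 1, dtype=bool)
    for a, d in intervals:
        occ[2 * a.toordinal() - lo : 2 * (d.toordinal() + gap_days) - lo + 1] = True
    marked = np.flatnonzero(occ)
    splits = np.flatnonzero(np.diff(marked) > 1)
    runs = np.split(marked, splits + 1)
    out = []
    for run in runs:
        run_lo, run_hi = run[0] + lo, run[-1] + lo
        members = [
            (a, d) for a, d in intervals if run_lo <= 2 * a.toordinal() <= run_hi
        ]
        out.append((min(a for a, _ in members), max(d for _, d in members)))
    return out


def expected_model_counts(truth: SyntheticTruth, model: ModelSpec) -> dict[str, int]:
    """Per-person inpatient-episode counts the pipeline should recover.

    Computed from the planted fragment intervals by an independent
    day-occupancy merge (not the pipeline's sorted sweep), with same-day
    runs dropped when the model requires an overnight stay.
    """
    counts: dict[str, int] = {}
    for person_id, eps in truth.episodes_by_person().items():
        intervals = [(a, d) for ep in eps for _, a, d in ep.fragments]
        if not intervals:
            counts[person_id] = 0
            continue
        runs = _occupancy_runs(intervals, model.merge_gap_days)
        if model.require_overnight:
            runs = [r for r in runs if r[0] != r[1]]
        counts[person_id] = len(runs)
    return counts


@dataclass(frozen=True)
class ExpectedPsychiatricEpisode:
    person_id: str
    start: datetime.date
    end: datetime.date
    final_codes: frozenset
    preliminary_codes: frozenset


def expected_psychiatric_episodes(
    truth: SyntheticTruth, model: ModelSpec
) -> list[ExpectedPsychiatricEpisode]:
    """Expected psychiatric episodes with their final/preliminary codes.

    True episodes chain when the planted gap is within the model's merge
    gap; the chained episode's final codes are those of its last
    psychiatric member, while earlier members' finals (and all planted
    preliminaries) become preliminary.
    """
    out: list[ExpectedPsychiatricEpisode] = []
    for person_id, eps in truth.episodes_by_person().items():
        chain: list[TrueEpisode] = []

        def flush():
            if not chain:
                return
            c_start, c_end = chain[0].start, max(e.end for e in chain)
            psych = [e for e in chain if e.psychiatric]
            if model.require_overnight and c_start == c_end:
                return
            if not psych:
                return
            last = psych[-1]
            prelims: set[str] = set()
            for e in chain:
                prelims.update(e.preliminary_codes)
            for e in psych[:-1]:
                prelims.update(e.final_codes)
            out.append(
                ExpectedPsychiatricEpisode(
                    person_id=person_id,
                    start=c_start,
                    end=c_end,
                    final_codes=frozenset(last.final_codes),
                    preliminary_codes=frozenset(prelims),
                )
            )

        for ep in eps:
            if not chain:
                chain = [ep]
            else:
                gap = (ep.start - max(e.end for e in chain)).days
                if gap <= model.merge_gap_days:
                    chain.append(ep)
                else:
                    flush()
                    chain = [ep]
        flush()
    return out
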