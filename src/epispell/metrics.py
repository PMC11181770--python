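"""Comparison statistics between raw register entries and processed episodes.

Three families of metrics quantify what episode construction does to the
data: annual psychiatric inpatient-episode and outpatient-event counts
with reduction percentages against the non-processed entries, annual
median length of stay (LOS) of psychiatric episodes, and the number of
distinct treated individuals per ICD-10 diagnostic category (annual or
lifetime), with per-category earliest-onset age floors applied.

Conventions (configurable): an episode is assigned to the calendar year
of its (psychiatric) discharge; LOS is counted in nights, i.e.
``discharge - admission``; the median of an even-sized sample is the
mean of the two central order statistics, reported unrounded.
"""
from __future__ import annotations

import datetime

import numpy as np
import pandas as pd

from ._types import EpisodeSet, RegisterEntry, ServiceType, UNMAPPED
from .diagnoses import MENTAL_PREFIX, CategoryConfig, completed_years

DEFAULT_LOS_BINS = (1, 4, 8, 15, 31, 91, 366)


def _raw_psych_inpatient(entries: list[RegisterEntry]) -> list[RegisterEntry]:
    return [
        e
        for e in entries
        if e.service_type == ServiceType.INPATIENT and e.is_psychiatric
    ]


def _entry_year(e: RegisterEntry, year_by: str) -> int:
    d = e.discharge_date if year_by == "discharge" else e.admission_date
    return d.year


def _episode_year(ep, year_by: str) -> int:
    if ep.has_psychiatry:
        d = ep.psy_end if year_by == "discharge" else ep.psy_start
    else:
        d = ep.discharge_date if year_by == "discharge" else ep.admission_date
    return d.year


def count_annual_episodes(
    episodes_by_model: dict[int, EpisodeSet],
    raw_entries: list[RegisterEntry],
    years: list[int],
    year_by: str = "discharge",
) -> pd.DataFrame:
    """Annual psychiatric inpatient counts: raw entries vs. per-model episodes.

    ``reduction_pct_m<k> = 100 * (raw - processed) / raw``; merging never
    creates inpatient episodes, so these are non-negative.
    """
    raw_by_year = pd.Series(
        [_entry_year(e, year_by) for e in _raw_psych_inpatient(raw_entries)]
    ).value_counts()
    out = {"year": years, "raw_n": [int(raw_by_year.get(y, 0)) for y in years]}
    for m, es in sorted(episodes_by_model.items()):
        proc_by_year = pd.Series(
            [_episode_year(ep, year_by) for ep in es.episodes if ep.has_psychiatry]
        ).value_counts()
        ns = [int(proc_by_year.get(y, 0)) for y in years]
        out[f"n_m{m}"] = ns
        out[f"reduction_pct_m{m}"] = [
            100.0 * (raw - n) / raw if raw else np.nan
            for raw, n in zip(out["raw_n"], ns)
        ]
    return pd.DataFrame(out)


def count_annual_outpatient_events(
    episodes_by_model: dict[int, EpisodeSet],
    raw_entries: list[RegisterEntry],
    years: list[int],
) -> pd.DataFrame:
    """Annual psychiatric outpatient-event counts, raw vs. independent events.

    Attached events are part of an inpatient episode and therefore not
    counted; reclassified same-day stays add to the processed counts.
    """
    raw_by_year = pd.Series(
        [
            e.admission_date.year
            for e in raw_entries
            if e.service_type != ServiceType.INPATIENT and e.is_psychiatric
        ]
    ).value_counts()
    out = {"year": years, "raw_n": [int(raw_by_year.get(y, 0)) for y in years]}
    for m, es in sorted(episodes_by_model.items()):
        proc_by_year = pd.Series(
            [ev.event_start.year for ev in es.events if ev.independent and ev.is_psychiatric]
        ).value_counts()
        ns = [int(proc_by_year.get(y, 0)) for y in years]
        out[f"n_m{m}"] = ns
        out[f"reduction_pct_m{m}"] = [
            100.0 * (raw - n) / raw if raw else np.nan
            for raw, n in zip(out["raw_n"], ns)
        ]
    return pd.DataFrame(out)


def annual_median_los(
    episodes_by_model: dict[int, EpisodeSet],
    raw_entries: list[RegisterEntry],
    years: list[int],
    convention: str = "nights",
    year_by: str = "discharge",
) -> pd.DataFrame:
    """Annual median LOS of psychiatric stays, raw entries vs. episodes.

    Episode LOS uses the psychiatric sub-interval.  ``convention`` is
    ``nights`` (discharge - admission) or ``days`` (one more).
    """
    plus = 1 if convention == "days" else 0
    if convention not in {"nights", "days"}:
        raise ValueError(f"unknown LOS convention {convention!r}")
    raw_los: dict[int, list[int]] = {y: [] for y in years}
    for e in _raw_psych_inpatient(raw_entries):
        y = _entry_year(e, year_by)
        if y in raw_los:
            raw_los[y].append((e.discharge_date - e.admission_date).days + plus)
    out = {
        "year": years,
        "raw_median": [float(np.median(raw_los[y])) if raw_los[y] else np.nan for y in years],
    }
    for m, es in sorted(episodes_by_model.items()):
        los: dict[int, list[int]] = {y: [] for y in years}
        for ep in es.episodes:
            if not ep.has_psychiatry:
                continue
            y = _episode_year(ep, year_by)
            if y in los:
                los[y].append(ep.psy_los(convention))
        out[f"median_m{m}"] = [
            float(np.median(los[y])) if los[y] else np.nan for y in years
        ]
    return pd.DataFrame(out)


def los_histogram(
    episodes_by_model: dict[int, EpisodeSet],
    raw_entries: list[RegisterEntry],
    convention: str = "nights",
    bin_edges: tuple[int, ...] = DEFAULT_LOS_BINS,
) -> pd.DataFrame:
    """LOS distribution of psychiatric stays in configurable duration bins."""
    plus = 1 if convention == "days" else 0
    edges = [-np.inf, *bin_edges, np.inf]
    labels = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        lo_lab = "0" if np.isinf(lo) else str(int(lo))
        labels.append(f"{lo_lab}+" if np.isinf(hi) else f"{lo_lab}-{int(hi) - 1}")
    variants = {
        "raw": [
            (e.discharge_date - e.admission_date).days + plus
            for e in _raw_psych_inpatient(raw_entries)
        ]
    }
    for m, es in sorted(episodes_by_model.items()):
        variants[f"m{m}"] = [
            ep.psy_los(convention) for ep in es.episodes if ep.has_psychiatry
        ]
    out = {"los_bin": labels}
    for name, values in variants.items():
        counts, _ = np.histogram(values, bins=edges)
        out[name] = counts.astype(int)
    return pd.DataFrame(out)


def count_treated_individuals(
    diagnosis_frames: dict[object, pd.DataFrame],
    birth_dates: dict[str, datetime.date],
    categories: CategoryConfig,
    grouping: str = "lifetime",
    year: int | None = None,
) -> pd.DataFrame:
    """Distinct treated individuals per diagnostic category, raw vs. models.

    ``diagnosis_frames`` maps variant keys (``"raw"`` plus model ids) to
    tidy frames with columns person_id, category, record_date.  Only
    mental-disorder categories are counted; the any-mental row counts
    persons with at least one category.  Age floors are applied at the
    record level using the floor of the most specific matching category.
    ``change_pct`` is signed: negative means fewer individuals than in
    the raw data, positive more (post-discharge outpatient diagnoses can
    push processed counts above raw ones).
    """
    if grouping == "annual" and year is None:
        raise ValueError("annual grouping requires a year")
    if grouping not in {"annual", "lifetime"}:
        raise ValueError(f"unknown grouping {grouping!r}")

    def prepare(df: pd.DataFrame) -> pd.DataFrame:
        if df.empty:
            return pd.DataFrame(columns=["person_id", "category", "record_date"])
        df = df[(df["category"] != UNMAPPED) & df["category"].str.startswith(MENTAL_PREFIX)]
        if grouping == "annual":
            df = df[df["record_date"].map(lambda d: d.year) == year]
        keep = []
        for row in df.itertuples(index=False):
            floor = categories.age_floor_for(row.category)
            birth = birth_dates.get(row.person_id)
            if floor is None or birth is None:
                keep.append(True)
            else:
                keep.append(completed_years(birth, row.record_date) >= floor)
        return df[np.array(keep, dtype=bool)] if keep else df

    prepared = {k: prepare(df) for k, df in diagnosis_frames.items()}
    raw = prepared["raw"]
    model_keys = [k for k in prepared if k != "raw"]

    rows = []
    group_defs = [(categories.any_label, None, None)] + [
        (name, prefixes, floor) for name, prefixes, floor in categories.groups
    ]
    for name, prefixes, floor in group_defs:
        def n_persons(df: pd.DataFrame) -> int:
            if df.empty:
                return 0
            if prefixes is None:
                sel = df
            else:
                sel = df[df["category"].str.startswith(tuple(prefixes))]
            return int(sel["person_id"].nunique())

        raw_n = n_persons(raw)
        row = {"category": name, "age_floor": floor, "raw_n": raw_n}
        for m in sorted(model_keys, key=str):
            n = n_persons(prepared[m])
            row[f"n_m{m}"] = n
            row[f"change_pct_m{m}"] = (
                100.0 * (n - raw_n) / raw_n if raw_n else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)
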