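"""Merging register entries into inpatient episodes.

Four models are supported, crossing two choices: the merge gap (0 days:
only a discharge and re-admission on the same calendar day count as a
transfer; 1 day: a new episode additionally requires a full calendar day
spent outside the hospital) and the overnight requirement (same-day
episodes reclassified as outpatient events).  Model 1 is gap 0 without
the overnight rule (most liberal), model 4 is gap 1 with it (most
conservative).

The overall episode spans the total time in hospital; the psychiatric
sub-episode runs from the first psychiatric admission to the last
psychiatric discharge among the member entries.  Ambulatory contacts
whose start date falls inside an episode are attached to it rather than
counted as independent treatment events.
"""
from __future__ import annotations

from collections import defaultdict

from ._types import (
    ContractViolation,
    EpisodeSet,
    EventSource,
    InpatientEpisode,
    ModelSpec,
    OutpatientEvent,
    RegisterEntry,
    ServiceType,
    MODELS,
)

__all__ = [
    "MODELS",
    "ModelSpec",
    "merge_inpatient_entries",
    "apply_overnight_rule",
    "derive_psychiatric_subepisode",
    "attach_ambulatory_events",
    "identify_episodes",
]

_SOURCE_BY_SERVICE = {
    ServiceType.OUTPATIENT: EventSource.SECONDARY_OUTPATIENT,
    ServiceType.EMERGENCY: EventSource.EMERGENCY,
    ServiceType.PRIMARY_CARE: EventSource.PRIMARY_CARE,
    # Other real-time contacts are reported with secondary outpatient care.
    ServiceType.OTHER_CONTACT: EventSource.SECONDARY_OUTPATIENT,
}


def merge_inpatient_entries(
    entries: list[RegisterEntry], gap_days: int, model_id: int = 0
) -> list[InpatientEpisode]:
    """Merge one person's inpatient entries into episodes.

    Entries are sorted by (admission, discharge, entry_id); two
    consecutive intervals belong to the same episode iff the next
    admission starts at most ``gap_days`` after the running discharge,
    with transitive closure so that chained transfers collapse into one
    episode.  Episode bounds are the min admission / max discharge over
    members.
    """
    if not entries:
        return []
    persons = {e.person_id for e in entries}
    if len(persons) != 1:
        raise ContractViolation(
            f"merge_inpatient_entries expects entries for one person, got {sorted(persons)}"
        )
    person_id = entries[0].person_id
    ordered = sorted(
        entries, key=lambda e: (e.admission_date, e.discharge_date, e.entry_id)
    )
    episodes: list[InpatientEpisode] = []
    cur_start = ordered[0].admission_date
    cur_end = ordered[0].discharge_date
    cur_members = [ordered[0]]

    def flush():
        eid = f"{person_id}:M{model_id}:E{len(episodes)}"
        episodes.append(
            InpatientEpisode(
                episode_id=eid,
                person_id=person_id,
                admission_date=cur_start,
                discharge_date=cur_end,
                model_id=model_id,
                member_entry_ids=tuple(m.entry_id for m in cur_members),
            )
        )

    for e in ordered[1:]:
        if (e.admission_date - cur_end).days <= gap_days:
            cur_end = max(cur_end, e.discharge_date)
            cur_members.append(e)
        else:
            flush()
            cur_start, cur_end, cur_members = e.admission_date, e.discharge_date, [e]
    flush()
    return episodes


def apply_overnight_rule(
    episodes: list[InpatientEpisode], require_overnight: bool
) -> tuple[list[InpatientEpisode], list[OutpatientEvent]]:
    """Reclassify same-day episodes as outpatient events when required."""
    if not require_overnight:
        return episodes, []
    kept: list[InpatientEpisode] = []
    events: list[OutpatientEvent] = []
    for ep in episodes:
        if ep.admission_date == ep.discharge_date:
            events.append(
                OutpatientEvent(
                    event_id=f"{ep.episode_id}:SDS",
                    person_id=ep.person_id,
                    event_start=ep.admission_date,
                    event_end=ep.discharge_date,
                    source=EventSource.RECLASSIFIED_SAME_DAY_STAY,
                    source_entry_ids=ep.member_entry_ids,
                )
            )
        else:
            kept.append(ep)
    return kept, events


def derive_psychiatric_subepisode(
    episode: InpatientEpisode, member_entries: list[RegisterEntry]
) -> InpatientEpisode:
    """Fill the psychiatric sub-interval from the psychiatric members.

    The sub-episode starts at the initial psychiatric admission and ends
    at the last psychiatric discharge; it is absent when no member entry
    is psychiatric.
    """
    psych = [e for e in member_entries if e.is_psychiatric]
    if psych:
        episode.has_psychiatry = True
        episode.psy_start = min(e.admission_date for e in psych)
        episode.psy_end = max(e.discharge_date for e in psych)
    else:
        episode.has_psychiatry = False
        episode.psy_start = episode.psy_end = None
    return episode


def attach_ambulatory_events(
    episodes: list[InpatientEpisode],
    ambulatory: list[RegisterEntry],
    reclassified: list[OutpatientEvent] | None = None,
) -> tuple[list[InpatientEpisode], list[OutpatientEvent]]:
    """Attach ambulatory contacts occurring during episodes.

    An ambulatory entry (or reclassified same-day stay) whose *start*
    date lies within an episode's inclusive date interval becomes an
    attached, non-independent event of that episode; all others are
    independent.  Attachment keys on the start date only, so a contact
    legitimately ending the day after discharge stays attached.
    """
    ordered_eps = sorted(episodes, key=lambda ep: ep.admission_date)
    events: list[OutpatientEvent] = []

    def place(event: OutpatientEvent) -> OutpatientEvent:
        hits = [
            ep
            for ep in ordered_eps
            if ep.admission_date <= event.event_start <= ep.discharge_date
        ]
        # Episodes of one person are separated by construction, so an
        # ambulatory start date can fall inside at most one of them.
        assert len(hits) <= 1, "ambulatory start date inside two episodes"
        if hits:
            event.independent = False
            event.parent_episode_id = hits[0].episode_id
            hits[0].attached_event_ids.append(event.event_id)
        else:
            event.independent = True
            event.parent_episode_id = None
        return event

    for entry in sorted(
        ambulatory, key=lambda e: (e.admission_date, e.discharge_date, e.entry_id)
    ):
        events.append(
            place(
                OutpatientEvent(
                    event_id=f"EV:{entry.entry_id}",
                    person_id=entry.person_id,
                    event_start=entry.admission_date,
                    event_end=entry.discharge_date,
                    source=_SOURCE_BY_SERVICE.get(
                        entry.service_type, EventSource.SECONDARY_OUTPATIENT
                    ),
                    source_entry_ids=(entry.entry_id,),
                    is_psychiatric=entry.is_psychiatric,
                )
            )
        )
    for ev in reclassified or []:
        events.append(place(ev))
    return episodes, events


def identify_episodes(entries: list[RegisterEntry], model: ModelSpec) -> EpisodeSet:
    """Run the full per-person episode pipeline for a whole cohort.

    Per person: merge inpatient entries under the model's gap, apply the
    overnight rule, derive the psychiatric sub-episode, then attach
    ambulatory events -- with reclassified same-day stays joining the
    ambulatory pool before attachment, so a same-day stay inside another
    episode attaches to it instead of counting as an independent contact.
    """
    by_person: dict[str, dict[str, list[RegisterEntry]]] = defaultdict(
        lambda: {"inpatient": [], "ambulatory": []}
    )
    for e in entries:
        bucket = "inpatient" if e.service_type == ServiceType.INPATIENT else "ambulatory"
        by_person[e.person_id][bucket].append(e)

    all_episodes: list[InpatientEpisode] = []
    all_events: list[OutpatientEvent] = []
    for person_id in sorted(by_person):
        groups = by_person[person_id]
        entries_by_id = {e.entry_id: e for e in groups["inpatient"]}
        episodes = merge_inpatient_entries(
            groups["inpatient"], model.merge_gap_days, model.model_id
        )
        episodes, reclassified = apply_overnight_rule(episodes, model.require_overnight)
        for ep in episodes:
            derive_psychiatric_subepisode(
                ep, [entries_by_id[i] for i in ep.member_entry_ids]
            )
        for ev in reclassified:
            ev.is_psychiatric = any(
                entries_by_id[i].is_psychiatric for i in ev.source_entry_ids
            )
        episodes, events = attach_ambulatory_events(
            episodes, groups["ambulatory"], reclassified
        )
        all_episodes.extend(episodes)
        all_events.extend(events)
    return EpisodeSet(model_id=model.model_id, episodes=all_episodes, events=all_events)
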