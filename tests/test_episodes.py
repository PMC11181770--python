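"""Episode merging, overnight rule, sub-episodes, event attachment."""
import datetime
from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epispell import (
    MODELS,
    ContractViolation,
    EventSource,
    ServiceType,
    apply_overnight_rule,
    attach_ambulatory_events,
    derive_psychiatric_subepisode,
    identify_episodes,
    merge_inpatient_entries,
)
from helpers import D, make_entry, oracle_merge


def entries_from_spans(spans, person="P1", psych=True):
    return [
        make_entry(f"E{i}", person=person, adm=a, dis=d, psych=psych)
        for i, (a, d) in enumerate(spans)
    ]


class TestMerge:
    @pytest.mark.parametrize(
        "spans,gap,expected",
        [
            # same-day transfer merges at gap 0
            ([("2015-01-01", "2015-01-05"), ("2015-01-05", "2015-01-10")], 0,
             [("2015-01-01", "2015-01-10")]),
            # next-day admission splits at gap 0 ...
            ([("2015-01-01", "2015-01-05"), ("2015-01-06", "2015-01-10")], 0,
             [("2015-01-01", "2015-01-05"), ("2015-01-06", "2015-01-10")]),
            # ... but merges at gap 1 (a new episode needs a full day outside)
            ([("2015-01-01", "2015-01-05"), ("2015-01-06", "2015-01-10")], 1,
             [("2015-01-01", "2015-01-10")]),
            # a full day outside splits even at gap 1
            ([("2015-01-01", "2015-01-05"), ("2015-01-07", "2015-01-10")], 1,
             [("2015-01-01", "2015-01-05"), ("2015-01-07", "2015-01-10")]),
            # single entry is its own episode
            ([("2015-01-03", "2015-01-08")], 0, [("2015-01-03", "2015-01-08")]),
            # contained transfer collapses into the covering stay
            ([("2015-01-01", "2015-01-20"), ("2015-01-03", "2015-01-05")], 0,
             [("2015-01-01", "2015-01-20")]),
            # chained transfers collapse transitively
            ([("2015-01-01", "2015-01-04"), ("2015-01-04", "2015-01-07"),
              ("2015-01-07", "2015-01-09")], 0, [("2015-01-01", "2015-01-09")]),
        ],
    )
    def test_merge_examples(self, spans, gap, expected):
        episodes = merge_inpatient_entries(entries_from_spans(spans), gap)
        got = [(ep.admission_date.isoformat(), ep.discharge_date.isoformat())
               for ep in episodes]
        assert got == expected

    def test_every_entry_in_exactly_one_episode(self):
        spans = [("2015-01-01", "2015-01-05"), ("2015-01-05", "2015-01-08"),
                 ("2015-02-01", "2015-02-01"), ("2015-03-01", "2015-03-10")]
        entries = entries_from_spans(spans)
        episodes = merge_inpatient_entries(entries, 0)
        member_ids = [i for ep in episodes for i in ep.member_entry_ids]
        assert sorted(member_ids) == sorted(e.entry_id for e in entries)

    def test_multi_person_input_rejected(self):
        entries = [
            make_entry("a", person="P1", adm="2015-01-01", dis="2015-01-02"),
            make_entry("b", person="P2", adm="2015-01-01", dis="2015-01-02"),
        ]
        with pytest.raises(ContractViolation):
            merge_inpatient_entries(entries, 0)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        steps=st.lists(
            st.tuples(st.integers(-5, 5), st.integers(0, 10)), min_size=1, max_size=40
        ),
        gap=st.integers(0, 2),
    )
    def test_merge_matches_day_occupancy_oracle(self, steps, gap):
        """Property: sorted-sweep merging equals the brute-force oracle that
        marks covered days (dilated by the gap) and joins intervals sharing
        a day."""
        base = D(2015, 1, 1)
        spans, cursor = [], base
        for rel_gap, los in steps:
            start = cursor + datetime.timedelta(days=rel_gap)
            if start < base:
                start = base
            end = start + datetime.timedelta(days=los)
            spans.append((start, end))
            cursor = end
        entries = [
            make_entry(f"E{i}", adm=a, dis=d) for i, (a, d) in enumerate(spans)
        ]
        episodes = merge_inpatient_entries(entries, gap)
        got = sorted(
            (ep.admission_date, ep.discharge_date, len(ep.member_entry_ids))
            for ep in episodes
        )
        assert got == oracle_merge(spans, gap)

    def test_gap_monotonicity_and_idempotence(self):
        spans = [("2015-01-01", "2015-01-03"), ("2015-01-05", "2015-01-06"),
                 ("2015-01-06", "2015-01-07"), ("2015-02-01", "2015-02-02")]
        entries = entries_from_spans(spans)
        counts = [len(merge_inpatient_entries(entries, g)) for g in (0, 1, 2, 3)]
        assert counts == sorted(counts, reverse=True)
        # re-merging episodes re-expressed as single entries changes nothing
        for g in (0, 1):
            episodes = merge_inpatient_entries(entries, g)
            re_entries = [
                make_entry(ep.episode_id, adm=ep.admission_date, dis=ep.discharge_date)
                for ep in episodes
            ]
            again = merge_inpatient_entries(re_entries, g)
            assert [(e.admission_date, e.discharge_date) for e in again] == [
                (ep.admission_date, ep.discharge_date) for ep in episodes
            ]

    def test_los_dominance(self):
        spans = [("2015-01-01", "2015-01-05"), ("2015-01-05", "2015-01-10")]
        entries = entries_from_spans(spans)
        (ep,) = merge_inpatient_entries(entries, 0)
        assert ep.los() >= max((e.discharge_date - e.admission_date).days for e in entries)


class TestOvernightRule:
    def test_same_day_episode_reclassified(self):
        (ep,) = merge_inpatient_entries(
            entries_from_spans([("2015-01-03", "2015-01-03")]), 0
        )
        kept, events = apply_overnight_rule([ep], require_overnight=True)
        assert kept == []
        assert len(events) == 1
        assert events[0].source == EventSource.RECLASSIFIED_SAME_DAY_STAY

    def test_rule_disabled_keeps_everything(self):
        (ep,) = merge_inpatient_entries(
            entries_from_spans([("2015-01-03", "2015-01-03")]), 0
        )
        kept, events = apply_overnight_rule([ep], require_overnight=False)
        assert kept == [ep] and events == []

    def test_overnight_episode_kept(self):
        (ep,) = merge_inpatient_entries(
            entries_from_spans([("2015-01-03", "2015-01-04")]), 0
        )
        kept, events = apply_overnight_rule([ep], require_overnight=True)
        assert kept == [ep] and events == []


class TestPsychiatricSubepisode:
    def test_psychiatric_span_inside_mixed_stay(self):
        members = [
            make_entry("s1", adm="2015-01-01", dis="2015-01-03", psych=False),
            make_entry("p1", adm="2015-01-03", dis="2015-01-10", psych=True),
            make_entry("s2", adm="2015-01-10", dis="2015-01-12", psych=False),
        ]
        (ep,) = merge_inpatient_entries(members, 0)
        derive_psychiatric_subepisode(ep, members)
        assert (ep.admission_date, ep.discharge_date) == (D(2015, 1, 1), D(2015, 1, 12))
        assert ep.has_psychiatry
        assert (ep.psy_start, ep.psy_end) == (D(2015, 1, 3), D(2015, 1, 10))

    def test_all_psychiatric_members(self):
        members = entries_from_spans(
            [("2015-01-01", "2015-01-05"), ("2015-01-05", "2015-01-09")]
        )
        (ep,) = merge_inpatient_entries(members, 0)
        derive_psychiatric_subepisode(ep, members)
        assert (ep.psy_start, ep.psy_end) == (ep.admission_date, ep.discharge_date)

    def test_no_psychiatric_member(self):
        members = entries_from_spans([("2015-01-01", "2015-01-05")], psych=False)
        (ep,) = merge_inpatient_entries(members, 0)
        derive_psychiatric_subepisode(ep, members)
        assert not ep.has_psychiatry
        assert ep.psy_start is None and ep.psy_end is None


class TestAttachment:
    def _episode(self):
        members = entries_from_spans([("2015-01-01", "2015-01-10")])
        (ep,) = merge_inpatient_entries(members, 0)
        return ep

    @pytest.mark.parametrize(
        "start,end,attached",
        [
            ("2015-01-02", "2015-01-02", True),   # during the stay
            ("2015-01-10", "2015-01-10", True),   # on the discharge date itself
            ("2015-01-10", "2015-01-11", True),   # ends after discharge, starts inside
            ("2015-02-09", "2015-02-09", False),  # 30 days after discharge
            ("2014-12-31", "2014-12-31", False),  # before admission
        ],
    )
    def test_start_date_keys_attachment(self, start, end, attached):
        ep = self._episode()
        amb = make_entry("ev", adm=start, dis=end, service=ServiceType.EMERGENCY)
        _, events = attach_ambulatory_events([ep], [amb])
        (event,) = events
        assert event.independent is (not attached)
        assert (event.parent_episode_id == ep.episode_id) is attached
        assert (event.event_id in ep.attached_event_ids) is attached


class TestIdentifyEpisodes:
    def test_empty_input(self):
        es = identify_episodes([], MODELS[1])
        assert es.episodes == [] and es.events == []

    def test_transfer_chain_with_ed_prefix(self):
        entries = [
            make_entry("ed", adm="2015-01-01", dis="2015-01-01",
                       service=ServiceType.EMERGENCY),
            make_entry("w1", adm="2015-01-01", dis="2015-01-05"),
            make_entry("w2", adm="2015-01-05", dis="2015-01-12"),
        ]
        es = identify_episodes(entries, MODELS[1])
        assert len(es.episodes) == 1
        (ep,) = es.episodes
        assert (ep.admission_date, ep.discharge_date) == (D(2015, 1, 1), D(2015, 1, 12))
        (event,) = es.events
        assert not event.independent and event.parent_episode_id == ep.episode_id

    def test_reclassified_same_day_stay_joins_event_pool(self):
        entries = [
            make_entry("long", adm="2015-01-01", dis="2015-01-10"),
            make_entry("short", adm="2015-01-13", dis="2015-01-13"),
        ]
        es = identify_episodes(entries, MODELS[2])
        assert len(es.episodes) == 1
        (event,) = es.events
        assert event.source == EventSource.RECLASSIFIED_SAME_DAY_STAY
        assert event.independent  # outside the episode: independent contact

    def test_partition_of_entries(self, small_clean_cohort):
        validated = small_clean_cohort["validated"]
        inpatient_ids = {
            e.entry_id for e in validated if e.service_type == ServiceType.INPATIENT
        }
        ambulatory_ids = {e.entry_id for e in validated} - inpatient_ids
        for m, es in small_clean_cohort["episode_sets"].items():
            member_counts = Counter(
                i for ep in es.episodes for i in ep.member_entry_ids
            )
            reclassified = Counter(
                i
                for ev in es.events
                if ev.source == EventSource.RECLASSIFIED_SAME_DAY_STAY
                for i in ev.source_entry_ids
            )
            covered = member_counts + reclassified
            assert set(covered) == inpatient_ids
            assert all(v == 1 for v in covered.values())
            amb_events = [
                ev
                for ev in es.events
                if ev.source != EventSource.RECLASSIFIED_SAME_DAY_STAY
            ]
            assert sorted(i for ev in amb_events for i in ev.source_entry_ids) == sorted(
                ambulatory_ids
            )

    def test_model_monotonicity(self, small_clean_cohort):
        sets = small_clean_cohort["episode_sets"]
        n = {m: len(es.episodes) for m, es in sets.items()}
        assert n[1] >= n[2] >= n[4]
        assert n[1] >= n[3] >= n[4]
        for m in (1, 3):
            assert not any(
                ev.source == EventSource.RECLASSIFIED_SAME_DAY_STAY
                for ev in sets[m].events
            )

    def test_episode_separation_invariant(self, small_clean_cohort):
        for m, es in small_clean_cohort["episode_sets"].items():
            gap = MODELS[m].merge_gap_days
            by_person = {}
            for ep in es.episodes:
                by_person.setdefault(ep.person_id, []).append(ep)
            for eps in by_person.values():
                eps.sort(key=lambda e: e.admission_date)
                for a, b in zip(eps, eps[1:]):
                    assert (b.admission_date - a.discharge_date).days > gap
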