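"""Generator contracts: determinism, planted structure, recovery targets."""
from collections import Counter

import pytest

from epispell import MODELS, ExclusionReason
from epispell.diagnoses import MENTAL_PREFIX, resolve_episode_set
from epispell.io import entries_from_frame, prepare_entries
from epispell.synthetic import (
    GeneratorParams,
    SyntheticTruth,
    TrueEpisode,
    expected_model_counts,
    expected_psychiatric_episodes,
    generate_cohort,
)
from epispell._types import UNMAPPED
from helpers import D, oracle_merge


def clean_params(**kw):
    defaults = dict(
        n_persons=60,
        seed=5,
        rate_missing_person_id=0.0,
        rate_missing_admission=0.0,
        rate_inverted_dates=0.0,
        rate_out_of_range=0.0,
    )
    defaults.update(kw)
    return GeneratorParams(**defaults)


def degenerate_params(**kw):
    """Every optional phenomenon switched off: one clean entry per stay."""
    defaults = dict(
        fragment_count_probs={1: 1.0},
        boundary_style_probs={"same_day": 1.0, "overlap": 0.0, "next_day": 0.0},
        p_same_day_stay=0.0,
        p_ed_prefix=0.0,
        p_outpatient_during_stay=0.0,
        p_outpatient_on_discharge_day=0.0,
        p_preliminary_diagnosis=0.0,
        p_additional_final=0.0,
        p_year_end_open_entry=0.0,
        p_census_discharge_filled=0.0,
        p_split_at_year_end=0.0,
        annual_outpatient_rate=0.0,
    )
    defaults.update(kw)
    return clean_params(**defaults)


class TestGeneratorContracts:
    def test_degenerate_generator_truth_equals_entries(self):
        cohort = generate_cohort(degenerate_params())
        assert len(cohort.entries) == len(cohort.truth.episodes)
        kinds = {v[2] for v in cohort.truth.crosswalk.values()}
        assert kinds <= {"fragment"}
        for ep in cohort.truth.episodes:
            assert len(ep.fragments) == 1
            (_, a, d) = ep.fragments[0]
            assert (a, d) == (ep.start, ep.end)

    def test_fixed_seed_is_byte_identical(self, tmp_path):
        a = generate_cohort(GeneratorParams(n_persons=40, seed=9))
        b = generate_cohort(GeneratorParams(n_persons=40, seed=9))
        fa, fb = tmp_path / "a.csv", tmp_path / "b.csv"
        a.entries.to_csv(fa, index=False)
        b.entries.to_csv(fb, index=False)
        assert fa.read_bytes() == fb.read_bytes()
        assert a.persons.equals(b.persons)
        assert a.truth.episodes == b.truth.episodes

    def test_different_seed_differs(self):
        a = generate_cohort(GeneratorParams(n_persons=40, seed=9))
        b = generate_cohort(GeneratorParams(n_persons=40, seed=10))
        assert not a.entries.equals(b.entries)

    def test_forced_three_way_fragmentation(self):
        params = degenerate_params(
            fragment_count_probs={3: 1.0},
            los_log_mean=2.6,  # stays ~13 nights, always fragmentable
            los_log_sd=0.1,
        )
        cohort = generate_cohort(params)
        frag_counts = Counter(
            v[:2] for v in cohort.truth.crosswalk.values() if v[2] == "fragment"
        )
        assert set(frag_counts.values()) == {3}
        assert len(cohort.entries) == 3 * len(cohort.truth.episodes)

    def test_no_leakage_columns(self):
        cohort = generate_cohort(clean_params())
        leaky = {c for c in cohort.entries.columns if "episode" in c or "truth" in c}
        assert not leaky

    def test_infeasible_params_rejected(self):
        with pytest.raises(ValueError):
            GeneratorParams(
                date_range=(D(2020, 1, 1), D(2020, 6, 30))  # shorter than max LOS
            ).validate()
        with pytest.raises(ValueError):
            GeneratorParams(p_ed_prefix=1.5).validate()
        with pytest.raises(ValueError):
            GeneratorParams(fragment_count_probs={1: 0.5, 2: 0.2}).validate()


class TestExpectedModelCounts:
    def _truth(self, spans_and_gaps):
        episodes = []
        for i, (start, end, gap) in enumerate(spans_and_gaps):
            start, end = D.fromisoformat(start), D.fromisoformat(end)
            episodes.append(
                TrueEpisode(
                    person_id="P1",
                    index=i,
                    start=start,
                    end=end,
                    psychiatric=True,
                    final_codes=("F200",),
                    preliminary_codes=(),
                    fragments=((f"E{i}", start, end),),
                    gap_after=gap,
                )
            )
        return SyntheticTruth(episodes=episodes, crosswalk={}, defects={})

    def test_wide_gaps_recover_planted_count(self):
        truth = self._truth(
            [("2015-01-01", "2015-01-05", 10), ("2015-01-15", "2015-01-20", None)]
        )
        for m in (1, 2, 3, 4):
            assert expected_model_counts(truth, MODELS[m]) == {"P1": 2}

    def test_one_day_gap_splits_models(self):
        truth = self._truth(
            [("2015-01-01", "2015-01-05", 1), ("2015-01-06", "2015-01-10", None)]
        )
        assert expected_model_counts(truth, MODELS[1]) == {"P1": 2}
        assert expected_model_counts(truth, MODELS[3]) == {"P1": 1}

    def test_same_day_stay_dropped_when_overnight_required(self):
        truth = self._truth([("2015-01-01", "2015-01-01", None)])
        assert expected_model_counts(truth, MODELS[1]) == {"P1": 1}
        assert expected_model_counts(truth, MODELS[2]) == {"P1": 0}

    def test_matches_independent_oracle_on_random_cohort(self):
        cohort = generate_cohort(clean_params(seed=13))
        truth = cohort.truth
        for m in (1, 3):
            expected = expected_model_counts(truth, MODELS[m])
            for person, eps in truth.episodes_by_person().items():
                intervals = [(a, d) for ep in eps for _, a, d in ep.fragments]
                assert expected[person] == len(
                    oracle_merge(intervals, MODELS[m].merge_gap_days)
                )


class TestPipelineRecovery:
    def test_episode_counts_recovered_exactly(self, small_clean_cohort):
        truth = small_clean_cohort["cohort"].truth
        for m, es in small_clean_cohort["episode_sets"].items():
            expected = expected_model_counts(truth, MODELS[m])
            got = Counter(ep.person_id for ep in es.episodes)
            for person, n in expected.items():
                assert got.get(person, 0) == n, (m, person)
            assert sum(got.values()) == sum(expected.values())

    def test_final_diagnoses_recovered_exactly(self, small_clean_cohort, mapping):
        validated = small_clean_cohort["validated"]
        truth = small_clean_cohort["cohort"].truth
        for m, es in small_clean_cohort["episode_sets"].items():
            resolved = resolve_episode_set(es, validated, mapping)
            by_key = {
                (ep.person_id, ep.admission_date, ep.discharge_date): ep
                for ep in es.episodes
            }
            for exp in expected_psychiatric_episodes(truth, MODELS[m]):
                ep = by_key[(exp.person_id, exp.start, exp.end)]
                assert ep.has_psychiatry
                ds = resolved[ep.episode_id]
                finals = {
                    r.code
                    for r in ds.final
                    if r.icd10_category != UNMAPPED
                    and r.icd10_category.startswith(MENTAL_PREFIX)
                }
                assert finals == set(exp.final_codes)
                assert not (set(exp.preliminary_codes) - set(exp.final_codes)) & finals


class TestDefectAccounting:
    def test_planted_defects_equal_exclusions(self, era_rules):
        params = GeneratorParams(
            n_persons=150,
            seed=77,
            rate_missing_person_id=0.01,
            rate_missing_admission=0.01,
            rate_inverted_dates=0.01,
            rate_out_of_range=0.01,
        )
        cohort = generate_cohort(params)
        entries = entries_from_frame(cohort.entries)
        _, report = prepare_entries(entries, era_rules, params.date_range)
        planted = cohort.truth.defects
        assert sum(len(v) for v in planted.values()) > 0
        for reason_name, ids in planted.items():
            reason = ExclusionReason(reason_name)
            assert sorted(report.excluded_ids[reason]) == sorted(ids)
        assert report.n_excluded == sum(len(v) for v in planted.values())
        assert report.n_retained + report.n_excluded == report.n_input
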