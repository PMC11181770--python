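import pytest

from epispell.diagnoses import CategoryConfig, MappingTable
from epispell.episodes import MODELS, identify_episodes
from epispell.io import EraRules, entries_from_frame, prepare_entries
from epispell.synthetic import GeneratorParams, generate_cohort


@pytest.fixture(scope="session")
def era_rules():
    return EraRules.default()


@pytest.fixture(scope="session")
def mapping():
    return MappingTable.default()


@pytest.fixture(scope="session")
def categories():
    return CategoryConfig.default()


def _prepared(params, era):
    cohort = generate_cohort(params)
    entries = entries_from_frame(cohort.entries)
    validated, report = prepare_entries(entries, era, params.date_range)
    episode_sets = {m: identify_episodes(validated, MODELS[m]) for m in (1, 2, 3, 4)}
    return {
        "params": params,
        "cohort": cohort,
        "validated": validated,
        "report": report,
        "episode_sets": episode_sets,
    }


@pytest.fixture(scope="session")
def preset_cohort(era_rules):
    """A cohort under the default ("finland-like") preset, fixed seed."""
    return _prepared(GeneratorParams(n_persons=2000, seed=20240601), era_rules)


@pytest.fixture(scope="session")
def clean_cohort(era_rules):
    """A defect-free cohort for exact parameter-recovery checks."""
    params = GeneratorParams(
        n_persons=2000,
        seed=915,
        rate_missing_person_id=0.0,
        rate_missing_admission=0.0,
        rate_inverted_dates=0.0,
        rate_out_of_range=0.0,
    )
    return _prepared(params, era_rules)


@pytest.fixture(scope="module")
def small_clean_cohort(era_rules):
    params = GeneratorParams(
        n_persons=150,
        seed=42,
        rate_missing_person_id=0.0,
        rate_missing_admission=0.0,
        rate_inverted_dates=0.0,
        rate_out_of_range=0.0,
    )
    return _prepared(params, era_rules)
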