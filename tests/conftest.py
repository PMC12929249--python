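from datetime import date

import pytest

from ehrpheno import notes, synth


@pytest.fixture(scope="session")
def lexicon():
    return notes.default_lexicon()


@pytest.fixture(scope="session")
def small_cohort():
    """Shared 80-patient synthetic cohort (3 true classes, seed 42)."""
    config = synth.default_generator_config(n_patients=80, seed=42)
    return synth.generate_cohort(config)


@pytest.fixture(scope="session")
def small_flags(small_cohort, lexicon):
    return notes.annotate_corpus(small_cohort.notes, lexicon)


@pytest.fixture(scope="session")
def big_cohort():
    """Larger cohort for rate-convergence checks (500 patients)."""
    config = synth.default_generator_config(n_patients=500, seed=7)
    return synth.generate_cohort(config)


@pytest.fixture
def study_window():
    return date(2017, 1, 1), date(2020, 12, 31)
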