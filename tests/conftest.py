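import numpy as np
import pytest

from agosort import (
    ConfidenceSet,
    SortedMiRNA,
    table1_signal_spec,
    generate_sequences,
)


def make_confidence_set(seqs, labels):
    entries = [
        SortedMiRNA(
            id=f"mir-{i + 1}",
            full_seq=s,
            ago_label=lab,
            preference_fraction=0.9,
            rpm_total=100.0,
        )
        for i, (s, lab) in enumerate(zip(seqs, labels))
    ]
    return ConfidenceSet(entries)


@pytest.fixture(scope="session")
def three_class_cohort():
    """A 117-member cohort with the canonical 5'-base sorting signal."""
    spec = table1_signal_spec(three_class=True)
    seqs, labels = generate_sequences(spec, seed=20)
    return seqs, labels


@pytest.fixture(scope="session")
def three_class_cset(three_class_cohort):
    seqs, labels = three_class_cohort
    return make_confidence_set(seqs, labels)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
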