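from pathlib import Path

import pytest

from lapchole import reference as ref

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def reference_scores_labels():
    """Per-patient (score, label) expansion of the published stratum counts."""
    return ref.expand_scores_labels()


@pytest.fixture(scope="session")
def fixture_csv():
    """Shipped synthetic 334-record cohort CSV reproducing the selection
    flowchart."""
    return DATA_DIR / "synthetic_reference_cohort_334.csv"
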