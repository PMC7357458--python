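import sys
from pathlib import Path

import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # for wfdb_fixtures

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

from qrstress import SyntheticEcgSpec, generate_ecg  # noqa: E402


@pytest.fixture(scope="session")
def clean_ecg():
    """60 s of 72 bpm synthetic ECG with mild RR jitter, plus ground truth."""
    return generate_ecg(
        SyntheticEcgSpec(heart_rate=72.0, duration=60.0, rr_jitter_fraction=0.05, seed=7)
    )
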