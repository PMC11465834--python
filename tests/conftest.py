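import numpy as np
import pandas as pd
import pytest

import dkdrisk as dk


@pytest.fixture(scope="session")
def baseline_small():
    """A small eligible synthetic baseline table shared across tests."""
    return dk.generate_baseline(dk.default_profile(n_patients=400, seed=11))


@pytest.fixture(scope="session")
def baseline_large():
    """A study-sized baseline table for marginal-fidelity checks."""
    return dk.generate_baseline(dk.default_profile(n_patients=4000, seed=17))


def make_records(occurred, followup, ids=None):
    """Event-record frame from parallel arrays (one outcome)."""
    occurred = np.asarray(occurred, dtype=bool)
    followup = np.asarray(followup, dtype=float)
    return pd.DataFrame({
        "patient_id": ids if ids is not None else np.arange(1, len(occurred) + 1),
        "outcome": "microalbuminuria",
        "occurred": occurred,
        "followup_years": followup,
    })
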