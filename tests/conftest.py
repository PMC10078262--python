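import numpy as np
import pytest

from idatheta.design import DesignConfig, MovementSequence
from idatheta.simulate import GroundTruth, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Six-subject cohort with EEG epochs (shared; treat as read-only)."""
    truth = GroundTruth(n_subjects=6, seed=11)
    return simulate_cohort(truth, make_epochs=True, seed=11)


@pytest.fixture()
def default_config():
    return DesignConfig(seed=42)


@pytest.fixture()
def mixed_sequences():
    """Hand-built condition streams with a known looked-away pattern."""
    looked = np.ones(20, dtype=bool)
    looked[[3, 10]] = False
    return {
        "normal": MovementSequence("normal", ["normal"] * 20),
        "high": MovementSequence("high", ["high"] * 20),
        "variable": MovementSequence(
            "variable",
            ["normal", "high", "normal", "high", "high"] * 4,
            looked=looked),
    }
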