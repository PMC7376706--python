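import numpy as np
import pytest

from cytoroc import generate_cohort


@pytest.fixture(scope="session")
def study_cohort():
    """Default synthetic cohort (56 suboptimal / 53 optimal), fixed seed."""
    return generate_cohort(seed=42)


def make_labeled(pos_values, neg_values):
    """Pooled (values, labels) arrays with suboptimal as the positive class."""
    values = np.concatenate([np.asarray(pos_values, float),
                             np.asarray(neg_values, float)])
    labels = np.array(["suboptimal"] * len(pos_values)
                      + ["optimal"] * len(neg_values))
    return values, labels
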