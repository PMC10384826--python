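import warnings

import pytest

from gelkill import FilterSpec, apply_filter, generate_study_replica


@pytest.fixture(scope="session")
def study_replica():
    """Synthetic replica of the five gel datasets (451 rows, 13 zero gels)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_study_replica(seed=1)


@pytest.fixture(scope="session")
def filtered_replica(study_replica):
    """Datasets 1-4, CTL <= 1e7 cell/mL, zero-count gels excluded (431 rows)."""
    spec = FilterSpec(max_ctl_conc=1e7, allowed_dataset_ids=frozenset([1, 2, 3, 4]))
    filtered, _ = apply_filter(study_replica, spec)
    return filtered
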