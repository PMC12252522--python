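import numpy as np
import pytest

from gaitphys import GroupParams, SyntheticConfig, generate_cohort

SMALL_SERIES = ("hip_sagittal", "ankle_sagittal", "grf_sagittal")


def null_config(seed=0, n_subjects=4, series=SMALL_SERIES, cycles=(2, 5), **kw):
    """Two groups with identical generator parameters."""
    return SyntheticConfig(
        groups=(GroupParams(name="control"), GroupParams(name="itw")),
        n_subjects_per_group=n_subjects,
        cycles_per_side=cycles,
        series_names=series,
        seed=seed,
        **kw,
    )


@pytest.fixture(scope="session")
def small_null_cohort():
    return generate_cohort(null_config())


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250925)
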