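import numpy as np
import pandas as pd
import pytest

from cpmkit import synth


@pytest.fixture(scope="session")
def small_cohort():
    spec = synth.CohortSpec(n_subjects=40, n_families=18, n_parcels=30,
                            seed=1)
    cohort, truth = synth.generate_cohort(spec)
    return spec, cohort, truth


@pytest.fixture(scope="session")
def edge_sessions():
    """Two-session edge matrices with a planted Openness signal."""
    tm = synth.LatentTraitModel(signal_effect={"O": 0.4}, n_signal_edges=60)
    spec = synth.CohortSpec(n_subjects=80, n_families=40, n_parcels=30,
                            seed=3, trait_model=tm)
    cohort, truth, em = synth.simulate_edges(spec, n_timepoints=300,
                                             sessions=(1, 2))
    return cohort, truth, em


@pytest.fixture
def items_all(request):
    """60-item response table with every cell set to one value."""
    def make(value, n=3):
        d = {"subject_id": [f"S{i}" for i in range(n)]}
        for i in range(1, 61):
            d[f"item_{i}"] = [value] * n
        return pd.DataFrame(d)
    return make


@pytest.fixture(scope="session")
def demo_run(small_cohort):
    spec, cohort, truth = small_cohort
    return synth.generate_run_timeseries(cohort, truth, "REST1_LR",
                                         n_timepoints=300,
                                         subjects=cohort.subject_ids[:1])[0]


@pytest.fixture(scope="session")
def clean_run(small_cohort):
    spec, cohort, truth = small_cohort
    return synth.generate_run_timeseries(cohort, truth, "REST1_LR",
                                         n_timepoints=300, fix_like=True,
                                         subjects=cohort.subject_ids[:1])[0]
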