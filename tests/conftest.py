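import numpy as np
import pytest

from ectobeat.synthetic import SyntheticConfig, generate_cohort, generate_record


@pytest.fixture(scope="session")
def default_cohort():
    """The standard 10-subject evaluation cohort (seed 7)."""
    return list(generate_cohort(10, seed=7))


@pytest.fixture(scope="session")
def cohort_datasets(default_cohort):
    """Per-subject (features, labels) extracted once for the whole session."""
    from ectobeat.pipeline import subject_dataset

    data = {}
    for sid, rec, ann, _ in default_cohort:
        X, y, _, _ = subject_dataset(rec, ann)
        data[sid] = (X, y)
    return data


@pytest.fixture(scope="session")
def short_record():
    """A 60 s record with ectopics, plus annotations and ground truth."""
    cfg = SyntheticConfig(duration_s=60.0)
    return generate_record(cfg, seed=3)


@pytest.fixture(scope="session")
def clean_record():
    """A noise-free sinus record for exact fiducial checks."""
    cfg = SyntheticConfig(
        duration_s=60.0, p_veb=0.0, p_sveb=0.0, snr_db=np.inf,
        wander_amp_ecg=0.0, wander_amp_ppg=0.0, pep_jitter_s=0.0,
    )
    return generate_record(cfg, seed=5)
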