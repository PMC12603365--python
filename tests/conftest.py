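import numpy as np
import pytest

import strokemap as sm


@pytest.fixture(scope="session")
def cohort600():
    """One 600-subject cohort at the study's default conditions."""
    return sm.simulate_cohort(sm.SimulationConfig(n_subjects=600, seed=42))


@pytest.fixture(scope="session")
def frame600(cohort600):
    df, sidecar = sm.analysis_frame(cohort600)
    return df, sidecar


@pytest.fixture(scope="session")
def lesion_setup():
    """Smaller cohort with simulated lesion masks and the toy atlas set."""
    cfg = sm.SimulationConfig(n_subjects=300, seed=7)
    cohort = sm.simulate_cohort(cfg)
    masks, atlas_set = sm.simulate_lesions(cohort, cfg)
    df, _ = sm.analysis_frame(cohort)
    return cohort, df, masks, atlas_set


def random_exam_series(rng, n_exams=None, window=21.0):
    """Random itemized NIHSS trajectory for oracle comparisons."""
    from strokemap.cohort import NIHSS_ITEMS, NIHSSExam

    n = int(rng.integers(1, 6)) if n_exams is None else n_exams
    ts = np.sort(rng.uniform(0, 30, size=n))
    ts[0] = 0.0
    exams = []
    for t in ts:
        items = {k: int(rng.integers(0, m + 1)) for k, m in NIHSS_ITEMS.items()}
        exams.append(NIHSSExam(t_days=float(t), items=items))
    return exams
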