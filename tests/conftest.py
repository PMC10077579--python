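import numpy as np
import pytest

import domdiv as dd
from domdiv.simulate import SurveyConfig, generate_survey


@pytest.fixture(scope="session")
def survey():
    """Default 40-lake synthetic survey (fixed seed) shared across tests."""
    return generate_survey(SurveyConfig(seed=1))


def samples_from_truth(sv):
    """AssignedSample objects built from the generator's emitted ground truth."""
    out = []
    for p in sv.peaklists:
        recs = [
            (mz, it, dd.MolecularFormula.parse(f), 0.0)
            for mz, it, f in zip(p.mz, p.intensity, sv.included[p.sample_id])
        ]
        out.append(dd.AssignedSample.from_records(p.sample_id, recs))
    return out


@pytest.fixture(scope="session")
def truth_samples(survey):
    return samples_from_truth(survey)


@pytest.fixture(scope="session")
def assigned_samples(survey):
    """Full mass-assignment path for every lake (slow; session-cached)."""
    return [dd.assign_sample(p) for p in survey.peaklists]


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
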