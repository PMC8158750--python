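import numpy as np
import pytest

from bcgvf import features, preprocess, synth


@pytest.fixture(scope="session")
def profile():
    return synth.SubjectProfile(
        subject_id="S1",
        beat_amplitude_scale=120.0,
        beat_morphology_seed=7,
        baseline_heart_rate=75.0,
        noise_sd=8.0,
    )


def _first_segment(rec):
    filtered = preprocess.preprocess_recording(rec, use_lms=False)
    return preprocess.segment(filtered)[0]


@pytest.fixture(scope="session")
def sr_segment(profile):
    return _first_segment(synth.generate_sr(7, profile, seed=11))


@pytest.fixture(scope="session")
def vf_segment(profile):
    return _first_segment(synth.generate_vf(7, profile, seed=12))


@pytest.fixture(scope="session")
def ma_segment(profile):
    return _first_segment(synth.generate_ma(7, profile, seed=13))


@pytest.fixture(scope="session")
def mini_cohort_features():
    """Feature matrix of a small preprocessed cohort (shared; ~30 s)."""
    recs = synth.generate_cohort(4, synth.CohortSpec(), seed=99)
    segs = []
    for rec in recs:
        segs.extend(preprocess.segment(preprocess.preprocess_recording(rec)))
    X = np.array([features.extract_features(s).values for s in segs])
    y = np.array([s.label for s in segs])
    sid = np.array([s.subject_id for s in segs])
    return X, y, sid
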