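"""Shared fixtures.

The default 20-subject cohort is expensive (each subject is a ~13-minute
126-channel record at 512 Hz), so it is simulated once per session and
shared by the classifier, contrast-battery and acceptance tests.
"""

import numpy as np
import pytest

from erpmark.features import extract_feature_table, marker_registry
from erpmark.montage import build_default_montage
from erpmark.pipeline import PipelineConfig, process_subject
from erpmark.simulate import noiseless_evokeds


@pytest.fixture(scope="session")
def montage():
    return build_default_montage()


@pytest.fixture(scope="session")
def registry():
    return marker_registry()


@pytest.fixture(scope="session")
def noiseless():
    """Deterministic per-category ground-truth evoked responses."""
    return noiseless_evokeds()


@pytest.fixture(scope="session")
def default_cohort():
    """Full default 20-subject cohort run through the complete pipeline.

    Returns the long-format feature table plus per-subject rejection
    statistics.
    """
    config = PipelineConfig(seed=0)
    montage = build_default_montage()
    evokeds, rejection = {}, []
    for subject in range(config.simulation.n_subjects):
        ev, stats, _ = process_subject(config, subject, montage)
        evokeds[subject] = ev
        rejection.append(stats)
    table = extract_feature_table(evokeds, marker_registry())
    return {"table": table, "rejection": rejection, "config": config}


def make_recording(data, montage, fs=512.0, subject=None):
    """Wrap a (channels x samples) array as a ContinuousRecording."""
    from erpmark.preprocess import ContinuousRecording

    return ContinuousRecording(
        data=np.asarray(data, dtype=np.float64), fs=fs, montage=montage,
        subject=subject,
    )
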