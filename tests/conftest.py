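import numpy as np
import pytest

from seatbcg.extraction import extract
from seatbcg.features import FEATURE_NAMES, extract_feature_vector
from seatbcg.selection import correlation_map
from seatbcg.synthetic import (
    SimulationConfig,
    generate_posture_dataset,
    generate_recording,
    posture_template,
)


@pytest.fixture(scope="session")
def default_dataset():
    """The default 10 x 20 x 6 labelled posture-frame dataset."""
    return generate_posture_dataset(seed=12345)


@pytest.fixture(scope="session")
def default_features(default_dataset):
    """19-feature matrix for the default dataset (computed once per session)."""
    frames, labels = default_dataset
    X = np.array([extract_feature_vector(f) for f in frames])
    assert X.shape == (len(labels), len(FEATURE_NAMES))
    return X, labels


@pytest.fixture(scope="session")
def posture1_pipeline():
    """Default posture-1 simulation run through extraction and correlation."""
    cfg = SimulationConfig(posture_id=1, seed=7)
    recording, truth = generate_recording(cfg)
    result = extract(recording)
    cmap = correlation_map(result, truth.ecg_reference)
    template = posture_template(1)
    return {
        "config": cfg,
        "recording": recording,
        "truth": truth,
        "extraction": result,
        "correlation": cmap,
        "template": template,
    }
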