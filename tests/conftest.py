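import numpy as np
import pytest

from epicyto import AnalysisConfig, generate_section, preset_params, run_pipeline


@pytest.fixture(scope="session")
def default_section():
    """A small homeostatic section with ground truth (fixed seed)."""
    params = preset_params("homeostatic", seed=7)
    return generate_section(params)


@pytest.fixture(scope="session")
def default_result(default_section):
    """Full pipeline run on the default section."""
    image, _ = default_section
    return run_pipeline(image)


@pytest.fixture()
def config():
    return AnalysisConfig(pixel_size_um=1.0)


def match_to_truth(pred_rc: np.ndarray, true_rc: np.ndarray, radius: float = 3.0):
    """Nearest-centroid matching; returns (matched mask, truth indices)."""
    from scipy.spatial import cKDTree

    d, idx = cKDTree(true_rc).query(pred_rc)
    return d <= radius, idx
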