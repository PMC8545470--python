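import numpy as np
import pytest

from nacreorder import detect, synthgen


@pytest.fixture(scope="session")
def mature_sample():
    """Rendered mature-stage scene shared across detection tests."""
    return synthgen.sample_preset("mature", n_layers=400, seed=11, image_width=65)


@pytest.fixture(scope="session")
def mature_detection(mature_sample):
    """(sample, detected InterfaceSet, measured profile) at the center column."""
    s = mature_sample
    col = s.reference_column
    tr = detect.Transect(
        np.arange(s.image.shape[0]) * s.pixel_size, s.image[:, col].astype(float)
    )
    det = detect.detect_sheaths(tr)
    profile = detect.thickness_from_interfaces(det)
    return s, det, profile
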