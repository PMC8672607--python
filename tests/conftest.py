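import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from pdcr.preprocess import FeatureTable, encode_labels


@pytest.fixture
def toy_table():
    """4 samples x 3 features, raw intensities with one zero."""
    return FeatureTable(
        sample_ids=["s1", "s2", "s3", "s4"],
        feature_ids=["f1", "f2", "f3"],
        values=np.array(
            [
                [99.0, 9.0, 0.0],
                [9.0, 99.0, 10.0],
                [999.0, 0.0, 20.0],
                [99.0, 9.0, 30.0],
            ]
        ),
    )


@pytest.fixture
def toy_labels():
    return encode_labels(["a", "b", "a", "b"])
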