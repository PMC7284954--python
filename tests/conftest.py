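from pathlib import Path

import numpy as np
import pytest

from phytoassay.assay_scoring import ClassificationThresholds

DATA_DIR = Path(__file__).resolve().parent.parent / "data"


@pytest.fixture
def thresholds():
    return ClassificationThresholds()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def confirmed_pathogens_path():
    return DATA_DIR / "confirmed_pathogens.tsv"
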