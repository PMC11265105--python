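import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/oracles.py

from spatialcoloc import synthgen


@pytest.fixture
def grid_3x3():
    return synthgen.gen_spot_lattice(3, 3)


@pytest.fixture
def grid_20x20():
    return synthgen.gen_spot_lattice(20, 20)


@pytest.fixture
def shared_blob_params():
    """Blob parameters used by the aggregated-pair fixtures and the demo."""
    return {
        "centers": [(5.0, 5.0), (14.0, 14.0)],
        "sigma": 2.5,
        "binarize_quantile": 0.75,
    }
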