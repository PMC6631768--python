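import numpy as np
import pytest

from samfc.experiment import DifferenceVector, PairedExperiment


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_experiment():
    """3 genes x 6 samples (n = 3 pairs), default first-half/second-half pairing."""
    values = np.array(
        [
            [3.0, 3.0, 3.0, 3.0, 3.0, 3.0],
            [5.0, 6.0, 4.0, 3.0, 2.0, 4.5],
            [1.0, 2.0, 3.0, 0.5, 0.5, 0.5],
        ]
    )
    return PairedExperiment(("gA", "gB", "gC"), values)


def make_dv(values, gene_id="g"):
    return DifferenceVector(gene_id, np.asarray(values, dtype=float))


@pytest.fixture
def make_diff():
    return make_dv
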