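import numpy as np
import pytest

from ecogseg import phonology
from ecogseg.preprocess import Recording


@pytest.fixture(scope="session")
def feature_table():
    return phonology.build_feature_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_recording(data, fs=1200.0, n_grids=1):
    """Wrap an array as a Recording with a contiguous grid split."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n_ch = data.shape[0]
    grid_of = np.minimum(np.arange(n_ch) * n_grids // n_ch, n_grids - 1)
    return Recording(data=data, fs=fs, grid_of=grid_of)


@pytest.fixture(scope="session")
def alignment_frame():
    """A tiny valid alignment table spanning two words."""
    import pandas as pd

    return pd.DataFrame(
        {
            "phoneme": ["AH", "B", "AA", "L", "IH", "SH", "AO", "L"],
            "onset": [1.00, 1.10, 1.20, 1.32, 1.40, 1.50, 2.10, 2.22],
            "offset": [1.10, 1.20, 1.32, 1.40, 1.50, 1.62, 2.22, 2.30],
            "word_index": [0, 0, 0, 0, 0, 0, 1, 1],
        }
    )
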