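import numpy as np
import pytest

from pcgfusion.studies import canonical_feature_table, informative_above_noise

FS = 2205

# re-exported for the test modules
make_canonical_table = canonical_feature_table
informative_above_noise = informative_above_noise


@pytest.fixture(scope="session")
def two_tone():
    """sin(2π·300t) + sin(2π·30t) at 2205 Hz, 1 s, with the clean parts."""
    t = np.arange(FS) / FS
    hi = np.sin(2 * np.pi * 300 * t)
    lo = np.sin(2 * np.pi * 30 * t)
    return hi + lo, hi, lo


@pytest.fixture(scope="session")
def canonical_table():
    return canonical_feature_table()
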