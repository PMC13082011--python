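import numpy as np
import pytest

from mimiscan.catalog import ChainAnnotation, ChainName


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def vp1_annotation():
    """One polyprotein: VP2, VP1 (with CE1 window 860-900), non-structural."""
    return [
        ChainAnnotation("ACC1", ChainName.VP2, 1, 300),
        ChainAnnotation("ACC1", ChainName.VP3, 301, 799),
        ChainAnnotation("ACC1", ChainName.VP1, 800, 1090,
                        ce1_start=860, ce1_end=900),
        ChainAnnotation("ACC1", ChainName.NONSTRUCTURAL, 1091, 2200),
    ]
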