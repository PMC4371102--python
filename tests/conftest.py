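import numpy as np
import pytest

#: classic 6-subject x 4-judge interrater dataset used across the
#: psychometrics literature; published single-measure ICCs are 0.29
#: (two-way, absolute agreement) and 0.71 (two-way, consistency).
SHROUT_FLEISS = np.array(
    [
        [9.0, 2.0, 5.0, 8.0],
        [6.0, 1.0, 3.0, 2.0],
        [8.0, 4.0, 6.0, 8.0],
        [7.0, 1.0, 2.0, 6.0],
        [10.0, 5.0, 6.0, 9.0],
        [6.0, 2.0, 4.0, 7.0],
    ]
)


@pytest.fixture
def shrout_fleiss() -> np.ndarray:
    return SHROUT_FLEISS.copy()
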