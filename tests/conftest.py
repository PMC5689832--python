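import numpy as np
import pytest

from cooc import CountTable, PresenceAbsenceMatrix


@pytest.fixture
def toy_counts() -> CountTable:
    return CountTable(
        taxon_ids=["taxA", "taxB"],
        sample_ids=["s1", "s2", "s3"],
        counts=np.array([[150, 0, 99], [101, 101, 0]]),
    )


@pytest.fixture
def small_pa() -> PresenceAbsenceMatrix:
    """4 taxa x 6 sites with a mix of common and rare rows."""
    occ = np.array(
        [
            [1, 1, 1, 1, 0, 0],
            [1, 1, 0, 0, 0, 0],
            [0, 1, 1, 0, 1, 0],
            [1, 0, 0, 0, 0, 0],
        ]
    )
    return PresenceAbsenceMatrix(
        taxon_ids=[f"t{i}" for i in range(4)],
        sample_ids=[f"s{j}" for j in range(6)],
        occupancy=occ,
    )
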