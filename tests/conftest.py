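import numpy as np
import pytest

import olfstoch as o
from olfstoch.analysis import SignificanceMask


@pytest.fixture(scope="session")
def fly_tensor():
    """A seeded fly-preset tensor shared by read-only tests."""
    return o.generate_responses(o.fly_config(), seed=11)


@pytest.fixture(scope="session")
def fly_mask_table(fly_tensor):
    mask = o.detect_significant(fly_tensor)
    table = o.classify_cells(mask)
    return mask, table


def make_mask(responded, sizes=None, threshold_sd=2.33):
    """Wrap a boolean (cell, odor, trial) array as a significance mask."""
    responded = np.asarray(responded, dtype=bool)
    if sizes is None:
        sizes = responded.astype(float)
    return SignificanceMask(
        responded=responded,
        response_size=np.asarray(sizes, dtype=float),
        threshold_sd=threshold_sd,
        baseline_mean=np.zeros(responded.shape),
        baseline_sd=np.ones(responded.shape),
    )


@pytest.fixture
def toy_schematic_mask():
    """Five cells x one odor x four trials, built to match the schematic
    population: two reliable cells responding in most trials, three
    unreliable cells with exactly one of them responding in each trial."""
    responded = np.zeros((5, 1, 4), dtype=bool)
    responded[0, 0, :3] = True        # reliable, 3/4
    responded[1, 0, :3] = True        # reliable, 3/4
    responded[2, 0, [0, 3]] = True    # unreliable, 2/4 (exactly half)
    responded[3, 0, 1] = True         # unreliable, 1/4
    responded[4, 0, 2] = True         # unreliable, 1/4
    return make_mask(responded)
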