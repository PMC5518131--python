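import numpy as np
import pytest

from tandemscope import ArraySpec, make_genome_with_arrays


@pytest.fixture
def two_copy_truth():
    """A genome with one exact 2-copy array: units of 3000 bp separated by
    a 1000 bp spacer, starting 2000 bp in."""
    return make_genome_with_arrays(
        20_000, [ArraySpec(3000, 2, 1000, 0.0, 2000)], seed=11
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)
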