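import numpy as np
import pytest
from hypothesis import settings

import oriselect as o

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def scenario():
    """Default desk-scale selection scenario (2,000 variants, depth 1e5)."""
    return o.SelectionScenario()


@pytest.fixture(scope="session")
def desk_table(scenario):
    """One simulated MPOS experiment, windowed to the 50-bp motif frame."""
    return o.simulate_mpos(scenario, seed=1).window(1, 50)


@pytest.fixture(scope="session")
def truth_norm(scenario):
    return scenario.truth_motif.normalize()


@pytest.fixture()
def tiny_table():
    """Ten length-4 variants with hand-assigned counts."""
    seqs = ["ACGT", "AAGT", "ACGA", "TCGT", "ACCT", "GCGT", "ACTT", "TAGT",
            "CCGT", "ACGG"]
    lib = dict(zip(seqs, [5, 3, 2, 4, 1, 2, 3, 1, 2, 2]))
    sel = dict(zip(seqs, [9, 1, 4, 2, 1, 1, 2, 1, 3, 6]))
    return o.VariantCountTable.from_samples(lib, sel, wt="ACGT")
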