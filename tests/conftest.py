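import numpy as np
import pytest

import methylguide as mg


@pytest.fixture(scope="session")
def default_model():
    return mg.HelicalModel()


@pytest.fixture(scope="session")
def default_prof():
    return mg.default_profile()


@pytest.fixture(scope="session")
def small_pipeline():
    """A modest simulate->align->call run shared across quantification tests.

    60 background CpGs, one target at gap 12 (cis 10%, trans 34.4%),
    500 molecules, ~300x depth, error-free reads.
    """
    bundle = mg.build_reference(60, [12], "circular", seed=101)
    molecules = mg.sample_molecules(bundle.spec, 500, seed=102)
    reads = mg.sample_reads(molecules, bundle.spec, read_length=75, depth=300, error_rate=0.0, seed=103)
    result = mg.align_bisulfite(reads, bundle.record, max_mismatches=2)
    table = mg.call_methylation(result.placements, bundle.record, bundle.spec.target_labels)
    return bundle, molecules, reads, result, table


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(4, size=n))
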