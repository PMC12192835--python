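import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes oracles importable

from plastobarcode import synthetic_data as sd


@pytest.fixture(scope="session")
def small_spec():
    return sd.SyntheticSpec(seed=0, genome_length=24_000, ir_length=3_000,
                            n_genes=22, accessions_per_group=2)


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    records, truth = sd.generate_dataset(small_spec)
    return records, truth


@pytest.fixture(scope="session")
def default_reference():
    spec = sd.SyntheticSpec(seed=7)
    return sd.generate_reference(spec)
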