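import warnings

import numpy as np
import pytest

from wes.model import LigandLibrary, WesClassifier
from wes.synth import GeneratorConfig, generate


@pytest.fixture(scope="session")
def small_bench():
    """Compact planted-signal benchmark shared across model-level tests."""
    cfg = GeneratorConfig(n_proteins=8, ligands_per_protein=10,
                          n_background=120, n_bits=256, n_desc=48,
                          n_signature_bits=20, n_signature_desc=6,
                          rng_seed=11)
    return generate(cfg)


@pytest.fixture(scope="session")
def small_fit(small_bench):
    """A hybrid classifier fitted once on the small benchmark."""
    lib = LigandLibrary.from_benchmark(small_bench)
    clf = WesClassifier(library=lib, channel="hybrid", random_state=11)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(small_bench.pairs[["protein_id", "ligand_id"]],
                small_bench.pairs["label"])
    return clf


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
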