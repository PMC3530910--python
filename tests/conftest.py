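"""Shared fixtures: a small trained polynomial model family.

The family is fitted once per session from ten synthetic annotated
genomes spanning GC 30-75%, which keeps every test self-contained (no
downloads) while exercising the full training path.
"""

import numpy as np
import pytest

import fsfinder as ff

FAMILY_THETAS = list(range(30, 76, 5))  # 30, 35, ..., 75


@pytest.fixture(scope="session")
def training_genomes():
    return [
        ff.make_fixture_genome(th, n_genes=300, seed=100 + i)
        for i, th in enumerate(FAMILY_THETAS)
    ]


@pytest.fixture(scope="session")
def family(training_genomes):
    return ff.fit_family(ff.count_hexamers(training_genomes), degree=5)


@pytest.fixture(scope="session")
def model50(family):
    return ff.model_for_gc(family, 50.0)
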