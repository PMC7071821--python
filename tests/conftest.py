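import warnings

import numpy as np
import pandas as pd
import pytest

from floranet import netbuild as nb
from floranet import preprocess as pp
from floranet import synthetic_data as sd

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def tree12():
    return sd.simulate_phylogeny(12, seed=1)


@pytest.fixture(scope="session")
def traits12(tree12):
    return sd.simulate_traits(tree12, seed=1)


@pytest.fixture(scope="session")
def two_module_bundle(tree12, traits12):
    """Two planted 30-gene modules (cor 0.8) plus 180 background genes,
    both stages, 12 species x 3 replicates."""
    plan = sd.ModulePlan(
        modules=[sd.ModuleSpec(30, 0.8), sd.ModuleSpec(30, 0.8)], n_background=180
    )
    counts, meta, truth = sd.simulate_expression(
        tree12, traits12, plan, n_replicates=3, stages=("Bud", "D"), seed=1
    )
    return counts, meta, truth


@pytest.fixture(scope="session")
def preprocessed_bud(two_module_bundle):
    counts, meta, _ = two_module_bundle
    bud = counts[meta.index[meta.stage == "Bud"]]
    return pp.quantile_normalize(pp.vst_transform(bud))


@pytest.fixture(scope="session")
def bud_network(preprocessed_bud):
    return nb.build_network(preprocessed_bud)
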