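import numpy as np
import pandas as pd
import pytest

from ionnet.encoding import AnnotatedVariantTable
from ionnet.networks import PathwayMap


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_table():
    """Sample s1 carries 2 nonsynonymous + 1 intronic on gene g1."""
    records = pd.DataFrame(
        {
            "sample": ["s1", "s1", "s1"],
            "gene": ["g1", "g1", "g1"],
            "variant_type": ["nonsynonymous", "nonsynonymous", "intronic"],
        }
    )
    return AnnotatedVariantTable(
        records, sample_ids=("s1", "s2"), gene_ids=("g1", "g2", "g3")
    )


@pytest.fixture
def toy_pathway_map():
    return PathwayMap(
        assignments={"g1": ("p1",), "g2": ("p1", "p2")},
        pathways=("p1", "p2"),
    )


def finite_difference_grads(f, params, eps=1e-6):
    """Central finite differences of scalar f() w.r.t. Parameter list."""
    grads = []
    for p in params:
        g = np.zeros_like(p.value)
        flat = p.value.reshape(-1)
        gflat = g.reshape(-1)
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            hi = f()
            flat[i] = orig - eps
            lo = f()
            flat[i] = orig
            gflat[i] = (hi - lo) / (2 * eps)
        grads.append(g)
    return grads
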