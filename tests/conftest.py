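import dendropy
import numpy as np
import pytest

from ploidpop import TreeSet, rf_distance
from ploidpop.simdata import random_topology


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_base_pair(labels, rng, min_rf=None):
    """Two well-separated base topologies on a shared taxon namespace."""
    if min_rf is None:
        min_rf = 2 * (len(labels) - 3) - 2
    tns = dendropy.TaxonNamespace(labels)
    bases = dendropy.TreeList(taxon_namespace=tns)
    while len(bases) < 2:
        t = random_topology(labels, rng)
        t = dendropy.Tree.get(
            data=t.as_string(schema="newick"), schema="newick",
            taxon_namespace=tns,
        )
        if not bases or rf_distance(bases[0], t) >= min_rf:
            bases.append(t)
    return TreeSet(trees=bases)


@pytest.fixture
def eight_leaf_bases(rng):
    return make_base_pair([f"s{i}" for i in range(8)], rng)
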