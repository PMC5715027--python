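import dendropy
import numpy as np
import pytest

import forceallometry as fa


@pytest.fixture(scope="session")
def among_dataset():
    """Among-species study conditions: 25 species x 10 individuals."""
    ds = fa.simulate_records(fa.make_preset("among", seed=1))
    derived = fa.derive_table(ds.records)
    return ds, derived


@pytest.fixture(scope="session")
def within_dataset():
    """Within-species conditions with a declining load factor."""
    ds = fa.simulate_records(fa.make_preset("within", seed=1))
    derived = fa.derive_table(ds.records)
    return ds, derived


@pytest.fixture
def fast_config():
    """Short chains for structural tests (not for parameter recovery)."""
    return fa.AllometryConfig(n_chains=2, n_iter=2000, burn_in=1000, seed=5)


@pytest.fixture
def five_tip_tree():
    return dendropy.Tree.get(
        data="((A:1,B:1):1,(C:1.5,D:1.5):0.5,E:2);",
        schema="newick", rooting="default-rooted")


@pytest.fixture
def three_tip_pair():
    tns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data="((A:1,B:1):1,C:2);", schema="newick",
                           taxon_namespace=tns, rooting="default-rooted")
    t2 = dendropy.Tree.get(data="((A:1,C:1):1,B:2);", schema="newick",
                           taxon_namespace=tns, rooting="default-rooted")
    return t1, t2
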