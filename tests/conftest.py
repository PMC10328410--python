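import numpy as np
import pytest

from chronodtl import (
    CostScheme,
    DTLReconciliation,
    SimulationConfig,
    parse_chronogram,
    simulate_gene_family,
    simulate_species_chronogram,
    time_slice,
)
from chronodtl.reconcile import PositionGraph


@pytest.fixture(scope="session")
def three_leaf_tree():
    """Caterpillar ((A,B),C) with divergences at 1 and 2 Ga."""
    return parse_chronogram("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def study_batch():
    """200 simulated gene families on a 20-species chronogram at default
    rates, each reconciled under the default cost scheme.

    Shared by the recovery, bound, consistency and containment checks so the
    simulation only runs once per session.
    """
    conf = SimulationConfig(seed=11)
    tree = simulate_species_chronogram(conf)
    graph = PositionGraph(time_slice(tree), CostScheme())
    rng = np.random.default_rng(12)
    batch = []
    while len(batch) < 200:
        fam = simulate_gene_family(tree, conf, rng=rng)
        if fam.newick is None:
            continue
        res = DTLReconciliation(fam.newick, tree, position_graph=graph).fit()
        batch.append((fam, res))
    return tree, graph, batch
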