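import networkx as nx
import numpy as np
import pytest
from hypothesis import settings

from maturewalk import (Connectome, Edge, GeneratorConfig, Parcellation,
                        RegionRecord, generate_study)

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_parcellation(groups, seeds=(), hemispheres=None):
    """Build a parcellation from a list of group labels."""
    regions = []
    for i, g in enumerate(groups):
        regions.append(RegionRecord(
            region_id=i, label=f"r{i}",
            hemisphere=(hemispheres[i] if hemispheres else "L"),
            group=g, is_seed=(i in seeds),
            exclude_from_model_correlation=(g == "SUB")))
    return Parcellation(regions)


def make_connectome(groups, edges, seeds=()):
    """Connectome from group labels and (i, j, weight[, length]) tuples."""
    parc = make_parcellation(groups, seeds=seeds)
    es = []
    for e in edges:
        i, j, w = e[0], e[1], e[2]
        length = e[3] if len(e) > 3 else 1.0
        es.append(Edge(i=min(i, j), j=max(i, j), weight=float(w),
                       length_mm=float(length), presence_count=1))
    return Connectome(parcellation=parc, edges=es)


def random_connectome(n, mean_degree, rng, weight_high=10.0):
    """Random connected weighted graph for oracle/fuzz tests."""
    p = min(1.0, mean_degree / (n - 1))
    while True:
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if g.number_of_edges() >= 2 and nx.is_connected(g):
            break
    edges = [(i, j, float(rng.uniform(1.0, weight_high))) for i, j in g.edges()]
    return make_connectome(["TER"] * n, edges)


@pytest.fixture(scope="session")
def bundle():
    """One default synthetic study, shared across tests."""
    return generate_study(GeneratorConfig(rng_seed=1))
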