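import numpy as np
import pytest

from netweave.data_io import WeeklyNetwork
from netweave.motif_roles import census_roles, enumerate_motifs


@pytest.fixture(scope="session")
def catalog():
    return enumerate_motifs(3, 5)


@pytest.fixture(scope="session")
def catalog33():
    return enumerate_motifs(3, 3)


@pytest.fixture()
def star_net():
    """One plant visited by two pollinators, weights 2 and 4."""
    return WeeklyNetwork(season="s", week=1, edges={("P1", "A1"): 2, ("P1", "A2"): 4})


def random_bipartite(rng, n_plants, n_pols, p_edge=0.4, weighted=True, season="r", week=1):
    """Random connected-enough bipartite weekly network (every node gets at
    least one edge)."""
    edges = {}
    for i in range(n_plants):
        for j in range(n_pols):
            if rng.random() < p_edge:
                w = int(rng.integers(1, 8)) if weighted else 1
                edges[(f"P{i}", f"A{j}")] = w
    for i in range(n_plants):
        if not any(p == f"P{i}" for p, _ in edges):
            j = int(rng.integers(n_pols))
            edges[(f"P{i}", f"A{j}")] = int(rng.integers(1, 8)) if weighted else 1
    for j in range(n_pols):
        if not any(a == f"A{j}" for _, a in edges):
            i = int(rng.integers(n_plants))
            edges[(f"P{i}", f"A{j}")] = int(rng.integers(1, 8)) if weighted else 1
    return WeeklyNetwork(season=season, week=week, edges=edges)


@pytest.fixture()
def roles_of():
    def _roles(net, catalog, **kw):
        return census_roles(net, catalog, **kw)

    return _roles
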