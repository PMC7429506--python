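"""Independent oracles used by the test suite.

These deliberately avoid the package's own algorithms: motif enumeration
and the subgraph census go through networkx isomorphism testing on
explicitly enumerated graphs, and optimal alignment costs come from
exhaustive enumeration or the Hungarian algorithm on an independently
built cost matrix.
"""

from itertools import combinations, permutations, product

import networkx as nx
import numpy as np
from scipy.optimize import linear_sum_assignment

GUILD_MATCH = nx.algorithms.isomorphism.categorical_node_match("guild", None)


def nx_graph(n_plants, n_pols, edges):
    g = nx.Graph()
    for i in range(n_plants):
        g.add_node(("p", i), guild="plant")
    for j in range(n_pols):
        g.add_node(("a", j), guild="pollinator")
    for i, j in edges:
        g.add_edge(("p", i), ("a", j))
    return g


def enumerate_motifs_nx(min_size, max_size):
    """All connected guild-labeled bipartite graphs, dedup by
    guild-preserving isomorphism; returns list of (graph, orbit count)."""
    found = []
    for n in range(min_size, max_size + 1):
        for p in range(1, n):
            a = n - p
            all_edges = [(i, j) for i in range(p) for j in range(a)]
            for mask in range(1 << len(all_edges)):
                edges = [e for k, e in enumerate(all_edges) if mask >> k & 1]
                g = nx_graph(p, a, edges)
                if g.number_of_edges() == 0 or not nx.is_connected(g):
                    continue
                if any(d == 0 for _, d in g.degree()):
                    continue
                if any(nx.is_isomorphic(g, h, node_match=GUILD_MATCH) for h, _ in found
                       if h.number_of_nodes() == n and h.number_of_edges() == g.number_of_edges()):
                    continue
                found.append((g, _orbit_count(g)))
    return found


def _orbit_count(g):
    gm = nx.algorithms.isomorphism.GraphMatcher(g, g, node_match=GUILD_MATCH)
    parent = {v: v for v in g.nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for mapping in gm.isomorphisms_iter():
        for u, v in mapping.items():
            ru, rv = find(u), find(v)
            if ru != rv:
                parent[ru] = rv
    return len({find(v) for v in g.nodes})


def weekly_to_nx(net):
    g = nx.Graph()
    for p in net.plants:
        g.add_node(p, guild="plant")
    for a in net.pollinators:
        g.add_node(a, guild="pollinator")
    for (p, a), w in net.edges.items():
        g.add_edge(p, a, weight=w)
    return g


def census_nx(net, catalog):
    """Brute-force binary census: test every connected induced subgraph of
    catalog sizes against every catalog motif with VF2."""
    motif_graphs = []
    for m in catalog.motifs:
        motif_graphs.append((m, nx_graph(m.n_plants, m.n_pollinators, m.edges)))
    g = weekly_to_nx(net)
    roles = {sp: np.zeros(catalog.n_positions) for sp in g.nodes}
    nodes = sorted(g.nodes)
    for k in range(catalog.min_size, catalog.max_size + 1):
        for combo in combinations(nodes, k):
            sub = g.subgraph(combo)
            if not nx.is_connected(sub):
                continue
            n_p = sum(1 for v in combo if sub.nodes[v]["guild"] == "plant")
            hit = False
            for m, mg in motif_graphs:
                if m.size != k or m.n_plants != n_p:
                    continue
                if mg.number_of_edges() != sub.number_of_edges():
                    continue
                gm = nx.algorithms.isomorphism.GraphMatcher(sub, mg, node_match=GUILD_MATCH)
                if gm.is_isomorphic():
                    for v, mv in gm.mapping.items():
                        side, idx = mv
                        node_i = idx if side == "p" else m.n_plants + idx
                        pos = m.position_offset + m.orbit_of_node[node_i]
                        roles[v][pos] += 1
                    hit = True
                    break
            assert hit, f"subgraph {combo} matched no catalog motif"
    return roles


def _corr(u, v):
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.std(u) == 0 or np.std(v) == 0:
        return 0.0
    return float(np.corrcoef(u, v)[0, 1])


def _guild_cost(la, lb, roles_a, roles_b, penalty):
    na, nb = len(la), len(lb)
    n = max(na, nb)
    D = np.full((n, n), penalty, dtype=float)
    for i, sa in enumerate(la):
        for j, sb in enumerate(lb):
            D[i, j] = 1.0 - _corr(roles_a[sa], roles_b[sb])
    return D


def lap_best_cost(A, B, roles_a, roles_b, penalty=1.0, fixed=None):
    """Exact optimal alignment cost via the Hungarian algorithm (the cost
    is a sum over pairs, so the per-guild optimum is an assignment
    problem).  ``fixed`` maps species of A to species of B."""
    fixed = dict(fixed or {})
    total = 0.0
    for ga, gb in ((A.plants, B.plants), (A.pollinators, B.pollinators)):
        fixed_here = {i: j for i, j in fixed.items() if i in ga}
        for i, j in fixed_here.items():
            total += 1.0 - _corr(roles_a[i], roles_b[j])
        la = [s for s in ga if s not in fixed_here]
        lb = [s for s in gb if s not in set(fixed_here.values())]
        if not la and not lb:
            continue
        D = _guild_cost(la, lb, roles_a, roles_b, penalty)
        r, c = linear_sum_assignment(D)
        total += float(D[r, c].sum())
    return total


def brute_best_cost(A, B, roles_a, roles_b, penalty=1.0):
    """Optimal cost by exhaustive enumeration of guild pairings (tiny
    networks only)."""
    total = 0.0
    for ga, gb in ((A.plants, B.plants), (A.pollinators, B.pollinators)):
        la, lb = list(ga), list(gb)
        if len(la) > len(lb):
            la, lb = lb, la
            ra, rb = roles_b, roles_a
        else:
            ra, rb = roles_a, roles_b
        best = np.inf
        for target in permutations(lb, len(la)):
            cost = sum(1.0 - _corr(ra[i], rb[j]) for i, j in zip(la, target))
            cost += penalty * (len(lb) - len(la))
            best = min(best, cost)
        total += 0.0 if np.isinf(best) else best
    return total
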