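"""Bipartite motif catalog and species role vectors.

A motif is a connected guild-labeled bipartite graph on 3-5 species; plants
and pollinators are never interchangeable, so a plant star and a pollinator
star are distinct motifs.  Within a motif, the *positions* are the node
orbits under guild-preserving automorphisms.  A species' structural role is
the vector counting how many times it occupies each position over all
connected induced subgraphs of the network (binary mode), or crediting each
occurrence with a summary of that occurrence's edge weights (weighted mode).

Internally a motif with p plants and a pollinators is encoded as a tuple of
p bitmasks over the a pollinators; the canonical form is the
lexicographically minimal encoding over guild-preserving relabelings, which
makes catalog order and position indices stable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations, product
from typing import Iterator, Mapping

import numpy as np

from .data_io import PLANT, POLLINATOR, WeeklyNetwork

Rows = tuple[int, ...]


def _permute_bits(mask: int, tau: tuple[int, ...]) -> int:
    """Reorder the bits of ``mask`` so that new bit j is old bit tau[j]."""
    out = 0
    for j, old in enumerate(tau):
        out |= ((mask >> old) & 1) << j
    return out


def _transform(rows: Rows, sigma: tuple[int, ...], tau: tuple[int, ...]) -> Rows:
    """Relabel: new plant i is old plant sigma[i], new pollinator j is old tau[j]."""
    return tuple(_permute_bits(rows[old], tau) for old in sigma)


def _canonical(rows: Rows, p: int, a: int) -> tuple[Rows, tuple[int, ...], tuple[int, ...]]:
    """Canonical encoding plus one (sigma, tau) achieving it."""
    best = None
    best_perms = None
    for sigma in permutations(range(p)):
        for tau in permutations(range(a)):
            cand = _transform(rows, sigma, tau)
            if best is None or cand < best:
                best, best_perms = cand, (sigma, tau)
    return best, best_perms[0], best_perms[1]


def _connected(rows: Rows, p: int, a: int) -> bool:
    # BFS over the bipartite adjacency; nodes 0..p-1 plants, p..p+a-1 pollinators
    adj: list[set[int]] = [set() for _ in range(p + a)]
    for i in range(p):
        for j in range(a):
            if (rows[i] >> j) & 1:
                adj[i].add(p + j)
                adj[p + j].add(i)
    seen = {0}
    stack = [0]
    while stack:
        v = stack.pop()
        for u in adj[v]:
            if u not in seen:
                seen.add(u)
                stack.append(u)
    return len(seen) == p + a


def _orbits(rows: Rows, p: int, a: int) -> list[int]:
    """Node orbits of the canonical representative under guild-preserving
    automorphisms; returns per-node local orbit ids numbered by first member
    (plants 0..p-1 then pollinators p..p+a-1)."""
    parent = list(range(p + a))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    for sigma in permutations(range(p)):
        for tau in permutations(range(a)):
            if _transform(rows, sigma, tau) == rows:
                # new plant i is old plant sigma[i] => old sigma[i] ~ i
                for i in range(p):
                    union(i, sigma[i])
                for j in range(a):
                    union(p + j, p + tau[j])
    roots = []
    ids = []
    for v in range(p + a):
        r = find(v)
        if r not in roots:
            roots.append(r)
        ids.append(roots.index(r))
    return ids


@dataclass(frozen=True)
class Motif:
    """One guild-labeled bipartite motif in canonical encoding."""

    n_plants: int
    n_pollinators: int
    rows: Rows                      # canonical adjacency bitmasks
    orbit_of_node: tuple[int, ...]  # local orbit id per canonical node
    position_offset: int            # global index of this motif's orbit 0

    @property
    def size(self) -> int:
        return self.n_plants + self.n_pollinators

    @property
    def n_positions(self) -> int:
        return max(self.orbit_of_node) + 1

    @property
    def edges(self) -> tuple[tuple[int, int], ...]:
        """Edges as (plant index, pollinator index within guild)."""
        return tuple(
            (i, j)
            for i in range(self.n_plants)
            for j in range(self.n_pollinators)
            if (self.rows[i] >> j) & 1
        )


@dataclass(frozen=True)
class MotifCatalog:
    """All motifs in a size range with stable global position indices."""

    min_size: int
    max_size: int
    motifs: tuple[Motif, ...]
    # (p, a, labeled rows) -> (motif index, global position per labeled node)
    lookup: Mapping[tuple[int, int, Rows], tuple[int, tuple[int, ...]]]

    @property
    def n_positions(self) -> int:
        last = self.motifs[-1]
        return last.position_offset + last.n_positions

    def position_labels(self) -> list[str]:
        labels = []
        for mi, m in enumerate(self.motifs):
            for o in range(m.n_positions):
                side = PLANT if m.orbit_of_node.index(o) < m.n_plants else POLLINATOR
                labels.append(f"motif{mi:02d}_orbit{o}_{side}")
        return labels

    def to_text(self) -> str:
        """Catalog export: one block per motif with guild-labeled edges and
        orbit assignments."""
        out = []
        for mi, m in enumerate(self.motifs):
            out.append(f"motif {mi}: {m.n_plants} plants x {m.n_pollinators} pollinators")
            out.append("  edges: " + " ".join(f"P{i}-A{j}" for i, j in m.edges))
            orbs = [
                f"{'P' if v < m.n_plants else 'A'}{v if v < m.n_plants else v - m.n_plants}"
                f"->pos{m.position_offset + m.orbit_of_node[v]}"
                for v in range(m.size)
            ]
            out.append("  orbits: " + " ".join(orbs))
        return "\n".join(out) + "\n"


def enumerate_motifs(min_size: int = 3, max_size: int = 5) -> MotifCatalog:
    """Enumerate every connected guild-labeled bipartite graph with
    ``min_size``-``max_size`` species, deduplicated by guild-preserving
    isomorphism, with node orbits from the automorphism group."""
    if not (2 <= min_size <= max_size <= 6):
        raise ValueError(f"supported size range is 2..6, got {min_size}..{max_size}")
    canon_info: dict[tuple[int, int, Rows], list[int]] = {}
    labeled: list[tuple[int, int, Rows, Rows, tuple[int, ...], tuple[int, ...]]] = []
    for n in range(min_size, max_size + 1):
        for p in range(1, n):
            a = n - p
            full = (1 << a) - 1
            for rows in product(range(1, full + 1), repeat=p):
                acc = 0
                for r in rows:
                    acc |= r
                if acc != full:  # isolated pollinator
                    continue
                if not _connected(rows, p, a):
                    continue
                canon, sigma, tau = _canonical(rows, p, a)
                key = (p, a, canon)
                if key not in canon_info:
                    canon_info[key] = _orbits(canon, p, a)
                labeled.append((p, a, rows, canon, sigma, tau))
    order = sorted(canon_info, key=lambda k: (k[0] + k[1], k[0], k[2]))
    motifs: list[Motif] = []
    offset = 0
    index_of: dict[tuple[int, int, Rows], int] = {}
    for key in order:
        p, a, canon = key
        orb = canon_info[key]
        index_of[key] = len(motifs)
        motifs.append(
            Motif(n_plants=p, n_pollinators=a, rows=canon,
                  orbit_of_node=tuple(orb), position_offset=offset)
        )
        offset += max(orb) + 1
    lookup: dict[tuple[int, int, Rows], tuple[int, tuple[int, ...]]] = {}
    for p, a, rows, canon, sigma, tau in labeled:
        mi = index_of[(p, a, canon)]
        m = motifs[mi]
        inv_sigma = {old: new for new, old in enumerate(sigma)}
        inv_tau = {old: new for new, old in enumerate(tau)}
        positions = []
        for i in range(p):  # labeled plant i maps to canonical plant inv_sigma[i]
            positions.append(m.position_offset + m.orbit_of_node[inv_sigma[i]])
        for j in range(a):
            positions.append(m.position_offset + m.orbit_of_node[p + inv_tau[j]])
        lookup[(p, a, rows)] = (mi, tuple(positions))
    return MotifCatalog(min_size=min_size, max_size=max_size,
                        motifs=tuple(motifs), lookup=lookup)


def connected_induced_subgraphs(
    nbrs: list[set[int]], kmin: int, kmax: int
) -> Iterator[tuple[int, ...]]:
    """Enumerate every connected induced subgraph with kmin..kmax nodes
    exactly once (ESU-style extension with exclusive neighborhoods)."""
    n = len(nbrs)

    def extend(sub: list[int], ext: set[int], closed: set[int], v: int):
        if len(sub) >= kmin:
            yield tuple(sub)
        if len(sub) == kmax:
            return
        ext = set(ext)
        while ext:
            w = ext.pop()
            excl = {u for u in nbrs[w] if u > v and u not in closed}
            sub.append(w)
            yield from extend(sub, ext | excl, closed | excl | {w}, v)
            sub.pop()

    for v in range(n):
        start = {u for u in nbrs[v] if u > v}
        yield from extend([v], start, start | {v}, v)


def census_roles(
    net: WeeklyNetwork,
    catalog: MotifCatalog,
    mode: str = "binary",
    weight_combine: str = "mean",
) -> dict[str, np.ndarray]:
    """Count each species' appearances in every motif position.

    Binary mode: each occurrence (connected induced subgraph isomorphic to a
    catalog motif) adds 1 to the occupied position of each of its nodes.
    Weighted mode: each occurrence instead adds a summary of its own edge
    weights (arithmetic mean by default; ``sum`` and ``geometric_mean`` are
    the alternatives).
    """
    if mode not in {"binary", "weighted"}:
        raise ValueError(f"unknown census mode {mode!r}")
    plants = net.plants
    pols = net.pollinators
    species = list(plants) + list(pols)
    idx = {sp: i for i, sp in enumerate(species)}
    np_plants = len(plants)
    guild_is_plant = [i < np_plants for i in range(len(species))]
    nbrs: list[set[int]] = [set() for _ in species]
    wt: dict[tuple[int, int], float] = {}
    for (p, a), w in net.edges.items():
        pi, ai = idx[p], idx[a]
        nbrs[pi].add(ai)
        nbrs[ai].add(pi)
        wt[(pi, ai)] = float(w)
    roles = {sp: np.zeros(catalog.n_positions) for sp in species}
    lookup = catalog.lookup
    for sub in connected_induced_subgraphs(nbrs, catalog.min_size, catalog.max_size):
        sub_plants = [v for v in sub if guild_is_plant[v]]
        sub_pols = [v for v in sub if not guild_is_plant[v]]
        p, a = len(sub_plants), len(sub_pols)
        rows = tuple(
            sum(1 << j for j, av in enumerate(sub_pols) if av in nbrs[pv])
            for pv in sub_plants
        )
        _, positions = lookup[(p, a, rows)]
        if mode == "binary":
            contrib = 1.0
        else:
            ws = [wt[(pv, av)] for pv in sub_plants for av in sub_pols
                  if av in nbrs[pv]]
            if weight_combine == "mean":
                contrib = float(np.mean(ws))
            elif weight_combine == "sum":
                contrib = float(np.sum(ws))
            elif weight_combine == "geometric_mean":
                contrib = float(np.exp(np.mean(np.log(ws))))
            else:
                raise ValueError(f"unknown weight_combine {weight_combine!r}")
        for node_i, v in enumerate(sub_plants):
            roles[species[v]][positions[node_i]] += contrib
        for node_j, v in enumerate(sub_pols):
            roles[species[v]][positions[p + node_j]] += contrib
    return roles


def normalize_roles(
    roles: Mapping[str, np.ndarray], mode: str = "unit_sum"
) -> dict[str, np.ndarray]:
    """Rescale role vectors: ``unit_sum`` (zero vectors unchanged),
    ``zscore`` per position across species, or ``none``."""
    if mode == "none":
        return {sp: v.copy() for sp, v in roles.items()}
    if mode == "unit_sum":
        out = {}
        for sp, v in roles.items():
            s = v.sum()
            out[sp] = v / s if s > 0 else v.copy()
        return out
    if mode == "zscore":
        mat = np.array([roles[sp] for sp in roles])
        mu = mat.mean(axis=0)
        sd = mat.std(axis=0)
        sd[sd == 0] = 1.0
        return {sp: (v - mu) / sd for sp, v in roles.items()}
    raise ValueError(f"unknown normalization mode {mode!r}")


def roles_to_frame(roles: Mapping[str, np.ndarray], catalog: MotifCatalog):
    """Role matrix as a DataFrame (rows species, columns position labels)."""
    import pandas as pd

    return pd.DataFrame(
        np.array([roles[sp] for sp in sorted(roles)]),
        index=sorted(roles),
        columns=catalog.position_labels(),
    )
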