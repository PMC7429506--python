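"""Alignment matrix, position groups, and group characterization.

All alignment ensembles are compiled into one occurrence-by-occurrence
matrix M, where an occurrence is a (weekly network, species) pair.  The
entry between occurrences (A, i) and (B, j) is the frequency with which i
and j were paired over the ensemble of alignments between A and B, scaled
by the mean positive role correlation of those pairings (a bounded
frequency-times-quality score in [0, 1]).  Plants and pollinators never
pair, so M is exactly block-diagonal by guild.

Groups of similar positions are the modules of M, found per guild with the
walktrap ("short random walks") community-detection algorithm; partitions
from different algorithms are compared by normalized mutual information.
Groups are then characterized by relative-degree statistics computed in
each occurrence's own weekly network.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import igraph as ig
import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import normalized_mutual_info_score

from .alignment import AlignmentEnsemble
from .data_io import PLANT, POLLINATOR, WeeklyNetwork

Occurrence = tuple[tuple[str, int], str]  # ((season, week), species)


@dataclass(frozen=True)
class AlignmentMatrix:
    occurrences: tuple[Occurrence, ...]
    guilds: tuple[str, ...]
    values: np.ndarray  # symmetric, in [0, 1], zero across guilds

    def index_of(self, occ: Occurrence) -> int:
        return self.occurrences.index(occ)

    def guild_block(self, guild: str) -> tuple[list[int], np.ndarray]:
        idx = [k for k, g in enumerate(self.guilds) if g == guild]
        return idx, self.values[np.ix_(idx, idx)]

    def to_triplets(self) -> pd.DataFrame:
        """Sparse triplet export (upper triangle, nonzero entries)."""
        rows = []
        n = len(self.occurrences)
        for i in range(n):
            for j in range(i, n):
                v = self.values[i, j]
                if v > 0:
                    rows.append({"occurrence_i": i, "occurrence_j": j, "value": v})
        return pd.DataFrame(rows)

    def occurrence_index(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"index": k, "season": occ[0][0], "week": occ[0][1],
              "species": occ[1], "guild": g}
             for k, (occ, g) in enumerate(zip(self.occurrences, self.guilds))]
        )


@dataclass(frozen=True)
class PositionGrouping:
    """Per-guild partition of occurrences; labels 0..k-1 ordered by a
    stated convention (descending size by default, or by group properties
    via :func:`order_groups_by_properties`)."""

    membership: Mapping[Occurrence, int]
    guild_of: Mapping[Occurrence, str]

    def groups(self, guild: str | None = None) -> dict[int, list[Occurrence]]:
        out: dict[int, list[Occurrence]] = {}
        for occ, lab in self.membership.items():
            if guild is None or self.guild_of[occ] == guild:
                out.setdefault(lab, []).append(occ)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"season": occ[0][0], "week": occ[0][1], "guild": self.guild_of[occ],
              "species": occ[1], "group": lab}
             for occ, lab in sorted(self.membership.items())]
        )


def build_alignment_matrix(
    ensembles: Iterable[AlignmentEnsemble],
    networks: Mapping[tuple[str, int], WeeklyNetwork],
    quality_weighting: str = "frequency_x_correlation",
) -> AlignmentMatrix:
    """Compile ensembles into M.

    Requires one ensemble per unordered pair of the given networks,
    including self-pairs.  Entry = pairing frequency x mean positive
    correlation when paired (or frequency alone with
    ``quality_weighting="frequency"``).  Self-pair blocks are symmetrized
    by averaging the two pairing directions.
    """
    if quality_weighting not in {"frequency_x_correlation", "frequency"}:
        raise ValueError(f"unknown quality_weighting {quality_weighting!r}")
    net_ids = sorted(networks)
    occurrences: list[Occurrence] = []
    guilds: list[str] = []
    for nid in net_ids:
        net = networks[nid]
        for sp in net.species:
            occurrences.append((nid, sp))
            guilds.append(net.guild_of(sp))
    occ_idx = {occ: k for k, occ in enumerate(occurrences)}
    ens_by_pair: dict[frozenset, AlignmentEnsemble] = {}
    for ens in ensembles:
        ens_by_pair[frozenset((ens.network_a, ens.network_b))] = ens
    missing = []
    for ia, nid_a in enumerate(net_ids):
        for nid_b in net_ids[ia:]:
            if frozenset((nid_a, nid_b)) not in ens_by_pair:
                missing.append((nid_a, nid_b))
    if missing:
        raise ValueError(f"missing alignment ensembles for pairs: {missing}")
    n = len(occurrences)
    M = np.zeros((n, n))
    for key, ens in ens_by_pair.items():
        nid_a, nid_b = ens.network_a, ens.network_b
        score: dict[tuple[int, int], list[float]] = {}
        for al in ens.runs:
            for i, j in al.pairs.items():
                ki = occ_idx[(nid_a, i)]
                kj = occ_idx[(nid_b, j)]
                c = al.correlations[(i, j)]
                w = max(c, 0.0) if quality_weighting == "frequency_x_correlation" else 1.0
                score.setdefault((ki, kj), []).append(w)
        N = ens.n_runs
        if nid_a == nid_b:
            # directed pairings i->j; average the two directions
            acc = np.zeros((n, n))
            for (ki, kj), ws in score.items():
                acc[ki, kj] = sum(ws) / N
            sym = (acc + acc.T) / 2.0
            mask = sym > 0
            M[mask] = sym[mask]
        else:
            for (ki, kj), ws in score.items():
                v = sum(ws) / N
                M[ki, kj] = v
                M[kj, ki] = v
    return AlignmentMatrix(occurrences=tuple(occurrences), guilds=tuple(guilds), values=M)


def detect_groups(
    M: AlignmentMatrix, method: str = "short_random_walks", steps: int = 4
) -> PositionGrouping:
    """Partition each guild's block of M with walktrap community detection
    (modularity-optimal cut of the merge tree); labels ordered by
    descending group size within guild, offset so guilds never share
    labels is NOT applied — plants and pollinators are partitioned
    independently and labels restart at 0 per guild."""
    if method != "short_random_walks":
        raise ValueError(f"unsupported method {method!r}")
    if steps < 1:
        raise ValueError("steps must be >= 1")
    membership: dict[Occurrence, int] = {}
    guild_of: dict[Occurrence, str] = {}
    for guild in (PLANT, POLLINATOR):
        idx, block = M.guild_block(guild)
        if not idx:
            raise ValueError(f"empty guild block for {guild!r}")
        nb = len(idx)
        edges = []
        weights = []
        for i in range(nb):
            for j in range(i + 1, nb):
                if block[i, j] > 0:
                    edges.append((i, j))
                    weights.append(float(block[i, j]))
        g = ig.Graph(n=nb, edges=edges)
        if edges:
            clustering = g.community_walktrap(weights=weights, steps=steps).as_clustering()
            labels = clustering.membership
        else:
            labels = list(range(nb))
        # relabel by descending size (ties by first appearance)
        sizes: dict[int, int] = {}
        for lab in labels:
            sizes[lab] = sizes.get(lab, 0) + 1
        order = sorted(sizes, key=lambda l: (-sizes[l], l))
        remap = {old: new for new, old in enumerate(order)}
        for local, k in enumerate(idx):
            occ = M.occurrences[k]
            membership[occ] = remap[labels[local]]
            guild_of[occ] = guild
    return PositionGrouping(membership=membership, guild_of=guild_of)


def compare_partitions(p1: PositionGrouping, p2: PositionGrouping) -> float:
    """Normalized mutual information between two partitions of the same
    occurrence set (arithmetic-mean entropy normalization)."""
    occs = sorted(p1.membership)
    if occs != sorted(p2.membership):
        raise ValueError("partitions cover different occurrence sets")
    a = [p1.membership[o] for o in occs]
    b = [p2.membership[o] for o in occs]
    return float(normalized_mutual_info_score(a, b, average_method="arithmetic"))


def relative_degree(net: WeeklyNetwork) -> dict[str, float]:
    """k_i = l_i / l_max with l_i the number of distinct partners of i and
    l_max the maximum over all species of the network.  Weight-free by
    definition."""
    if not net.edges:
        raise ValueError("empty network")
    deg: dict[str, int] = {}
    for (p, a) in net.edges:
        deg[p] = deg.get(p, 0) + 1
        deg[a] = deg.get(a, 0) + 1
    l_max = max(deg.values())
    return {sp: d / l_max for sp, d in deg.items()}


def group_properties(
    grouping: PositionGrouping,
    networks: Mapping[tuple[str, int], WeeklyNetwork],
) -> pd.DataFrame:
    """Per occurrence: k_i, the relative degree of its most connected
    partner (max k^i), and the mean partner relative degree (<k^i>), all in
    the occurrence's own weekly network; with season/week/guild/group."""
    kcache = {nid: relative_degree(net) for nid, net in networks.items()}
    rows = []
    for occ, lab in sorted(grouping.membership.items()):
        nid, sp = occ
        net = networks[nid]
        if sp not in set(net.species):
            raise ValueError(f"occurrence {occ} refers to species absent from its network")
        k = kcache[nid]
        partners = net.neighbors(sp)
        pk = [k[q] for q in partners]
        rows.append({
            "season": nid[0], "week": nid[1], "guild": grouping.guild_of[occ],
            "species": sp, "group": lab, "k": k[sp],
            "max_partner_k": max(pk), "mean_partner_k": float(np.mean(pk)),
        })
    return pd.DataFrame(rows)


def order_groups_by_properties(
    grouping: PositionGrouping,
    networks: Mapping[tuple[str, int], WeeklyNetwork],
) -> PositionGrouping:
    """Relabel groups within each guild by descending group mean of
    max k^i, ties broken by descending mean k — a stable, documented
    ordering under which the highest-degree-partner groups come first."""
    props = group_properties(grouping, networks)
    membership = dict(grouping.membership)
    for guild, sub in props.groupby("guild"):
        means = sub.groupby("group")[["max_partner_k", "k"]].mean()
        order = means.sort_values(["max_partner_k", "k"], ascending=False).index
        remap = {old: new for new, old in enumerate(order)}
        for occ, lab in grouping.membership.items():
            if grouping.guild_of[occ] == guild:
                membership[occ] = remap[lab]
    return PositionGrouping(membership=membership, guild_of=dict(grouping.guild_of))


def degree_sensitivity(
    net: WeeklyNetwork,
    removal_fractions: Sequence[float],
    reps: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Robustness of relative degree to sampling effort.

    Individual interaction events (edge multiplicity = integer weight) are
    removed uniformly at random; for each removal fraction the mean
    absolute change in k over surviving species and the mean fraction of
    distinct links lost are reported over ``reps`` replicates.
    """
    for f in removal_fractions:
        if not 0 <= f <= 1:
            raise ValueError(f"removal fraction {f} outside [0, 1]")
    rng = np.random.default_rng(seed)
    edges = sorted(net.edges.items())
    events = []
    for e_idx, (_, w) in enumerate(edges):
        events.extend([e_idx] * int(round(w)))
    events = np.array(events)
    k0 = relative_degree(net)
    n_links = len(edges)
    rows = []
    for f in removal_fractions:
        n_remove = int(round(f * len(events)))
        dks, losses = [], []
        for _ in range(reps):
            keep = rng.permutation(len(events))[n_remove:]
            surv_counts = np.bincount(events[keep], minlength=n_links)
            surv_edges = {edges[i][0]: int(c) for i, c in enumerate(surv_counts) if c > 0}
            losses.append(1.0 - len(surv_edges) / n_links)
            if not surv_edges:
                dks.append(np.nan)
                continue
            sub = WeeklyNetwork(season=net.season, week=net.week, edges=surv_edges)
            k1 = relative_degree(sub)
            dks.append(float(np.mean([abs(k1[sp] - k0[sp]) for sp in k1])))
        finite = [d for d in dks if not np.isnan(d)]
        rows.append({"fraction": f,
                     "mean_abs_dk": float(np.mean(finite)) if finite else float("nan"),
                     "mean_link_loss": float(np.mean(losses))})
    return pd.DataFrame(rows)


def abundance_regression(
    k_values: Sequence[float], abundance_values: Sequence[float]
) -> tuple[float, float, float]:
    """OLS of relative degree on abundance; returns (slope, intercept,
    unexplained variance share = 1 - R^2)."""
    k_values = np.asarray(k_values, dtype=float)
    abundance_values = np.asarray(abundance_values, dtype=float)
    if len(k_values) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.var(abundance_values) == 0:
        raise ValueError("zero variance in abundance")
    res = sps.linregress(abundance_values, k_values)
    return float(res.slope), float(res.intercept), float(1.0 - res.rvalue**2)
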