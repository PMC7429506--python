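"""Guild-respecting network alignment by role similarity.

Aligning two weekly networks means finding a one-to-one pairing between
their plants and between their pollinators that minimizes a cost

    C = sum over pairs (1 - c_ij)  +  penalty * (number of unpaired species)

where c_ij is the Pearson correlation between the two species' motif-role
vectors.  The pairing is maximal within each guild (the smaller side is
fully paired), so unpaired species arise only from unequal guild sizes.
Optimization is simulated annealing over pairings with partner-swap moves
and a greedy-descent finish; because optima are frequently degenerate
(structurally symmetric species can be exchanged), the alignment of a pair
of networks is always an *ensemble* of independent restarts, and downstream
statistics are computed over that ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .data_io import WeeklyNetwork

Roles = Mapping[str, np.ndarray]


@dataclass(frozen=True)
class AnnealSchedule:
    """Geometric-cooling schedule; ``sweeps`` sweeps of n proposals each."""

    t0: float = 1.0
    cooling: float = 0.995
    sweeps: int = 500


@dataclass(frozen=True)
class Alignment:
    """A guild-respecting partial one-to-one pairing between two networks."""

    network_a: tuple[str, int]
    network_b: tuple[str, int]
    pairs: Mapping[str, str]            # species of A -> species of B
    unpaired_a: tuple[str, ...]
    unpaired_b: tuple[str, ...]
    cost: float
    correlations: Mapping[tuple[str, str], float]
    seed: int | None = None

    def partner_of(self, sp: str) -> str | None:
        return self.pairs.get(sp)


@dataclass(frozen=True)
class AlignmentEnsemble:
    """Independent best-of-run alignments of one network pair."""

    network_a: tuple[str, int]
    network_b: tuple[str, int]
    runs: tuple[Alignment, ...]

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def best(self) -> Alignment:
        return min(self.runs, key=lambda al: al.cost)


def role_correlation(r_i: np.ndarray, r_j: np.ndarray) -> float:
    """Pearson correlation between two role vectors over the same catalog;
    0 by convention when either vector has no variance."""
    if r_i.shape != r_j.shape:
        raise ValueError(f"catalog mismatch: {r_i.shape} vs {r_j.shape}")
    xi = r_i - r_i.mean()
    xj = r_j - r_j.mean()
    denom = np.sqrt((xi @ xi) * (xj @ xj))
    if denom == 0:
        return 0.0
    return float(np.clip((xi @ xj) / denom, -1.0, 1.0))


def correlation_matrix(vecs_a: Sequence[np.ndarray], vecs_b: Sequence[np.ndarray]) -> np.ndarray:
    """Pairwise role correlations, zero-variance fallback 0."""
    A = np.asarray(vecs_a, dtype=float)
    B = np.asarray(vecs_b, dtype=float)
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    na = np.linalg.norm(A, axis=1)
    nb = np.linalg.norm(B, axis=1)
    C = A @ B.T
    denom = np.outer(na, nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.where(denom > 0, C / np.where(denom == 0, 1.0, denom), 0.0)
    return np.clip(C, -1.0, 1.0)


def alignment_cost(
    pairing: Mapping[str, str],
    roles_a: Roles,
    roles_b: Roles,
    unpaired_penalty: float = 1.0,
) -> float:
    """Evaluate C for an explicit pairing.  Every species of either network
    left out of the pairing counts one penalty term."""
    cost = 0.0
    for i, j in pairing.items():
        cost += 1.0 - role_correlation(np.asarray(roles_a[i]), np.asarray(roles_b[j]))
    n_unpaired = (len(roles_a) - len(pairing)) + (len(roles_b) - len(set(pairing.values())))
    return cost + unpaired_penalty * n_unpaired


def _anneal(
    D: np.ndarray,
    rng: np.random.Generator,
    schedule: AnnealSchedule,
) -> tuple[np.ndarray, float]:
    """Minimize sum_i D[i, perm[i]] over permutations by simulated annealing
    with pair-swap moves, then greedy 2-swap descent from the best state."""
    n = D.shape[0]
    if n <= 1:
        return np.arange(n), float(D.trace()) if n else 0.0
    perm = rng.permutation(n)
    cost = float(D[np.arange(n), perm].sum())
    best_perm = perm.copy()
    best_cost = cost
    iters = schedule.sweeps * n
    ii = rng.integers(0, n, size=iters)
    jj = rng.integers(0, n, size=iters)
    log_u = np.log(rng.random(iters))
    temps = schedule.t0 * schedule.cooling ** (np.arange(iters) // n)
    for k in range(iters):
        i, j = ii[k], jj[k]
        if i == j:
            continue
        pi, pj = perm[i], perm[j]
        delta = D[i, pj] + D[j, pi] - D[i, pi] - D[j, pj]
        if delta < 0 or log_u[k] < -delta / temps[k]:
            perm[i], perm[j] = pj, pi
            cost += delta
            if cost < best_cost - 1e-12:
                best_cost = cost
                best_perm = perm.copy()
    # greedy descent from the best state visited
    perm = best_perm
    improved = True
    while improved:
        improved = False
        for i in range(n - 1):
            pi = perm[i]
            row_i = D[i]
            for j in range(i + 1, n):
                pj = perm[j]
                delta = row_i[pj] + D[j, pi] - row_i[pi] - D[j, pj]
                if delta < -1e-12:
                    perm[i], perm[j] = pj, pi
                    best_cost += delta
                    pi = perm[i]
                    improved = True
    return perm, float(best_cost)


def _guild_cost_matrix(
    la: list[str], lb: list[str], roles_a: Roles, roles_b: Roles, penalty: float
) -> tuple[np.ndarray, np.ndarray]:
    """Square cost matrix for one guild, smaller side padded with dummy
    slots (cost = penalty against any real species).  Returns (D, C) with C
    the unpadded correlation matrix."""
    na, nb = len(la), len(lb)
    n = max(na, nb)
    C = correlation_matrix([np.asarray(roles_a[s]) for s in la],
                           [np.asarray(roles_b[s]) for s in lb]) if na and nb else np.zeros((na, nb))
    D = np.full((n, n), penalty, dtype=float)
    if na and nb:
        D[:na, :nb] = 1.0 - C
    return D, C


def align(
    A: WeeklyNetwork,
    B: WeeklyNetwork,
    roles_a: Roles,
    roles_b: Roles,
    seed: int = 0,
    fixed_pairs: Mapping[str, str] | None = None,
    schedule: AnnealSchedule = AnnealSchedule(),
    unpaired_penalty: float = 1.0,
) -> Alignment:
    """One stochastic alignment run; returns the best pairing encountered.

    ``fixed_pairs`` maps species of A to species of B that must be paired;
    they are removed from the search and re-inserted in the result.
    """
    fixed_pairs = dict(fixed_pairs or {})
    set_a, set_b = set(A.species), set(B.species)
    for i, j in fixed_pairs.items():
        if i not in set_a or j not in set_b:
            raise ValueError(f"fixed pair ({i}, {j}) references absent species")
        ga, gb = A.guild_of(i), B.guild_of(j)
        if ga != gb:
            raise ValueError(f"fixed pair ({i}, {j}) crosses guilds")
    if len(set(fixed_pairs.values())) != len(fixed_pairs):
        raise ValueError("infeasible fixed_pairs: duplicate endpoint")
    rng = np.random.default_rng(seed)
    pairs: dict[str, str] = {}
    correlations: dict[tuple[str, str], float] = {}
    unpaired_a: list[str] = []
    unpaired_b: list[str] = []
    total_cost = 0.0
    for guild_a, guild_b in ((A.plants, B.plants), (A.pollinators, B.pollinators)):
        fixed_here = {i: j for i, j in fixed_pairs.items() if i in guild_a}
        la = [s for s in guild_a if s not in fixed_here]
        lb = [s for s in guild_b if s not in set(fixed_here.values())]
        for i, j in fixed_here.items():
            c = role_correlation(np.asarray(roles_a[i]), np.asarray(roles_b[j]))
            pairs[i] = j
            correlations[(i, j)] = c
            total_cost += 1.0 - c
        na, nb = len(la), len(lb)
        if na == 0 and nb == 0:
            continue
        D, C = _guild_cost_matrix(la, lb, roles_a, roles_b, unpaired_penalty)
        perm, cost = _anneal(D, rng, schedule)
        total_cost += cost
        for i_idx in range(len(perm)):
            j_idx = perm[i_idx]
            real_i = i_idx < na
            real_j = j_idx < nb
            if real_i and real_j:
                i, j = la[i_idx], lb[j_idx]
                pairs[i] = j
                correlations[(i, j)] = float(C[i_idx, j_idx])
            elif real_i:
                unpaired_a.append(la[i_idx])
            elif real_j:
                unpaired_b.append(lb[j_idx])
    total_cost = max(total_cost, 0.0)  # guard float dust on perfect alignments
    return Alignment(
        network_a=A.id, network_b=B.id,
        pairs=pairs,
        unpaired_a=tuple(sorted(unpaired_a)),
        unpaired_b=tuple(sorted(unpaired_b)),
        cost=float(total_cost),
        correlations=correlations,
        seed=seed,
    )


def repeat_align(
    A: WeeklyNetwork,
    B: WeeklyNetwork,
    roles_a: Roles,
    roles_b: Roles,
    n_runs: int = 100,
    base_seed: int = 0,
    fixed_pairs: Mapping[str, str] | None = None,
    schedule: AnnealSchedule = AnnealSchedule(),
    unpaired_penalty: float = 1.0,
) -> AlignmentEnsemble:
    """``n_runs`` independent alignment runs with seeds base_seed..base_seed+n-1."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    runs = tuple(
        align(A, B, roles_a, roles_b, seed=base_seed + k, fixed_pairs=fixed_pairs,
              schedule=schedule, unpaired_penalty=unpaired_penalty)
        for k in range(n_runs)
    )
    return AlignmentEnsemble(network_a=A.id, network_b=B.id, runs=runs)


def ensemble_to_frame(ens: AlignmentEnsemble):
    """Alignment export: one row per (run, species of A), unpaired species
    with an empty partner."""
    import pandas as pd

    rows = []
    for run_idx, al in enumerate(ens.runs):
        for i, j in sorted(al.pairs.items()):
            rows.append({"network_a": str(al.network_a), "network_b": str(al.network_b),
                         "run": run_idx, "species_a": i, "species_b": j,
                         "c_ij": al.correlations[(i, j)], "cost": al.cost})
        for i in al.unpaired_a:
            rows.append({"network_a": str(al.network_a), "network_b": str(al.network_b),
                         "run": run_idx, "species_a": i, "species_b": "",
                         "c_ij": float("nan"), "cost": al.cost})
    return pd.DataFrame(rows)
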