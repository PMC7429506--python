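"""Position uniqueness, variability, and fixed-pair quality loss.

Uniqueness of a species' position within a network: the proportion of
repeated self-alignments of that network in which the species is paired to
itself.  Values near 1 mean the position is structurally unique; values
near 1/k flag an automorphism-like symmetry shared by k species.

Variability of a species' position across a season: over all alignments
between pairs of weekly networks that both contain the species, the
fraction in which it is *not* paired to itself (paired to another species,
or left unpaired).  High values mean the species' way of being embedded in
the network changes from week to week.

Fixed-pair loss: the increase in the best alignment cost when a species is
forced to pair with itself across two networks — a per-species measure of
how much its position changed between those weeks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .alignment import Alignment, AlignmentEnsemble, AnnealSchedule, Roles, repeat_align
from .data_io import WeeklyNetwork


@dataclass(frozen=True)
class UniquenessScore:
    network: tuple[str, int]
    species: str
    guild: str
    value: float
    n_runs: int


@dataclass(frozen=True)
class VariabilityScore:
    season: str
    species: str
    guild: str
    value: float
    n_observations: int


@dataclass(frozen=True)
class FixedPairLoss:
    network_a: tuple[str, int]
    network_b: tuple[str, int]
    species: str
    guild: str
    delta: float


def uniqueness(
    net: WeeklyNetwork,
    roles: Roles,
    n_runs: int = 100,
    seed: int = 0,
    schedule: AnnealSchedule = AnnealSchedule(),
    unpaired_penalty: float = 1.0,
) -> dict[str, UniquenessScore]:
    """Align ``net`` to itself ``n_runs`` times; per-species proportion of
    self-pairings over the best-of-run alignments."""
    ens = repeat_align(net, net, roles, roles, n_runs=n_runs, base_seed=seed,
                       schedule=schedule, unpaired_penalty=unpaired_penalty)
    return uniqueness_from_ensemble(net, ens)


def uniqueness_from_ensemble(
    net: WeeklyNetwork, ens: AlignmentEnsemble
) -> dict[str, UniquenessScore]:
    counts = {sp: 0 for sp in net.species}
    for al in ens.runs:
        for i, j in al.pairs.items():
            if i == j:
                counts[i] += 1
    return {
        sp: UniquenessScore(network=net.id, species=sp, guild=net.guild_of(sp),
                            value=counts[sp] / ens.n_runs, n_runs=ens.n_runs)
        for sp in net.species
    }


def variability(
    season: str,
    ensembles: Iterable[AlignmentEnsemble],
    networks: Mapping[tuple[str, int], WeeklyNetwork],
) -> dict[str, VariabilityScore]:
    """Pool all cross-week alignment ensembles of one season.

    For every species present in at least two weekly networks, the score is
    the fraction of (network pair, run) alignments — over pairs where both
    networks contain the species — in which it is not paired to itself.
    Each (pair, run) observation carries equal weight.
    """
    non_self: dict[str, int] = {}
    total: dict[str, int] = {}
    weeks_present: dict[str, set[int]] = {}
    for net in networks.values():
        for sp in net.species:
            weeks_present.setdefault(sp, set()).add(net.week)
    for ens in ensembles:
        net_a = networks[ens.network_a]
        net_b = networks[ens.network_b]
        if ens.network_a == ens.network_b:
            continue
        common = set(net_a.species) & set(net_b.species)
        for al in ens.runs:
            for sp in common:
                total[sp] = total.get(sp, 0) + 1
                if al.pairs.get(sp) != sp:
                    non_self[sp] = non_self.get(sp, 0) + 1
    guild_of = {}
    for net in networks.values():
        for sp in net.species:
            guild_of[sp] = net.guild_of(sp)
    return {
        sp: VariabilityScore(season=season, species=sp, guild=guild_of[sp],
                             value=non_self.get(sp, 0) / total[sp],
                             n_observations=total[sp])
        for sp in total
        if len(weeks_present[sp]) >= 2
    }


def fixed_pair_loss(
    A: WeeklyNetwork,
    B: WeeklyNetwork,
    roles_a: Roles,
    roles_b: Roles,
    species: Sequence[str] | None = None,
    n_runs: int = 100,
    seed: int = 0,
    schedule: AnnealSchedule = AnnealSchedule(),
    unpaired_penalty: float = 1.0,
) -> list[FixedPairLoss]:
    """Per common species i: best cost with the i-i pairing fixed minus the
    unconstrained best cost, both over ``n_runs`` restarts."""
    common = sorted(set(A.species) & set(B.species)) if species is None else list(species)
    for sp in common:
        if sp not in set(A.species) or sp not in set(B.species):
            raise ValueError(f"species {sp!r} absent from one of the networks")
    free = repeat_align(A, B, roles_a, roles_b, n_runs=n_runs, base_seed=seed,
                        schedule=schedule, unpaired_penalty=unpaired_penalty)
    base = free.best.cost
    out = []
    for k, sp in enumerate(common):
        cons = repeat_align(A, B, roles_a, roles_b, n_runs=n_runs,
                            base_seed=seed + (k + 1) * n_runs,
                            fixed_pairs={sp: sp}, schedule=schedule,
                            unpaired_penalty=unpaired_penalty)
        out.append(FixedPairLoss(network_a=A.id, network_b=B.id, species=sp,
                                 guild=A.guild_of(sp), delta=cons.best.cost - base))
    return out


def threshold_fraction(
    scores: Iterable[UniquenessScore] | Iterable[VariabilityScore],
    threshold: float = 0.9,
) -> dict[str, float]:
    """Per guild, the fraction of species-network occurrences whose score
    exceeds ``threshold`` (the headline-style summary)."""
    counts: dict[str, list[int]] = {}
    for s in scores:
        hit, tot = counts.setdefault(s.guild, [0, 0])
        counts[s.guild][1] = tot + 1
        if s.value > threshold:
            counts[s.guild][0] = hit + 1
    return {g: h / t for g, (h, t) in counts.items() if t}


def uniqueness_to_frame(scores: Iterable[UniquenessScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"season": s.network[0], "week": s.network[1], "guild": s.guild,
          "species": s.species, "value": s.value} for s in scores]
    )


def variability_to_frame(scores: Iterable[VariabilityScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"season": s.season, "guild": s.guild, "species": s.species,
          "value": s.value, "n_observations": s.n_observations} for s in scores]
    )


def fixed_pair_loss_to_frame(losses: Iterable[FixedPairLoss]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"season": l.network_a[0], "week_a": l.network_a[1], "week_b": l.network_b[1],
          "guild": l.guild, "species": l.species, "delta": l.delta} for l in losses]
    )
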