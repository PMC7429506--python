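"""Synthetic seasonal plant-pollinator networks with known ground truth.

The generator emulates the statistical shape of a subalpine weekly
interaction dataset: a few seasons of 12-16 weekly weighted bipartite
networks, species with phenology windows, latent position-group
memberships, and group-to-group transition dynamics with optional linear
time dependence.

Latent dynamics come first: every species runs the configured multinomial
transition law as a Markov chain from the ``pre`` state (so entry and exit
weeks — the phenology — emerge from the law, and the no-re-entry rule
holds by construction).  Observed edges are then realized from the latent
groups: each present pollinator draws a group-dependent number of plant
partners with a group-dependent bias toward attractive (generalist-like)
plants, weights are drawn from a geometric count distribution, and an
optional detection-dropout probability hides a species' observations in a
week strictly inside its activity period, producing the
presence-absence-presence patterns the pipeline's gap rule must drop.
Abundance is a lognormal per-species mark coupled to degree with
configurable strength, so degree is abundance-correlated but never
abundance-determined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .data_io import PLANT, POLLINATOR, NetworkSeries, WeeklyNetwork
from .transitions import StateSpace, TransitionParams


def default_transition_params(n_groups: int = 3) -> TransitionParams:
    """A constant transition law with the qualitative dynamic typical of
    seasonal plant-pollinator communities: species mostly enter as
    specialists attached to generalists (group 0), generalists (group 1)
    persist, and specialists attached to specialists (group 2) move to
    group 0 or exit."""
    if n_groups == 1:
        return TransitionParams.from_probabilities(
            group_rows=np.array([[0.8, 0.2]]), pre_row=np.array([0.15, 0.85])
        )
    if n_groups == 2:
        group_rows = np.array([[0.55, 0.20, 0.25],
                               [0.25, 0.65, 0.10]])
        pre_row = np.array([0.10, 0.04, 0.86])
    elif n_groups == 3:
        group_rows = np.array([[0.50, 0.15, 0.05, 0.30],
                               [0.20, 0.70, 0.03, 0.07],
                               [0.25, 0.05, 0.40, 0.30]])
        pre_row = np.array([0.08, 0.02, 0.04, 0.86])
    else:
        raise ValueError("default law defined for 1-3 groups; pass params explicitly")
    return TransitionParams.from_probabilities(group_rows, pre_row)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the generator.

    Defaults mirror the empirical scale: three seasons of 12/15/16 sampled
    weeks with 46 plants and 93 pollinators, three latent position groups,
    and a constant transition law with the canonical enter-as-specialist /
    persist-as-generalist structure.
    """

    weeks: tuple[int, ...] = (12, 15, 16)
    n_plants: int = 46
    n_pollinators: int = 93
    n_groups: int = 3
    params: TransitionParams | None = None  # None -> default law
    pollinator_degree_mean: tuple[float, ...] = (1.6, 5.0, 1.6)
    pollinator_partner_bias: tuple[float, ...] = (1.5, 1.5, -1.5)
    plant_attractiveness: tuple[float, ...] = (4.0, 1.5, 0.4)
    weight_mean: float = 3.0
    abundance_sigma: float = 0.8
    abundance_coupling: float = 0.5
    dropout: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.weeks) < 1 or self.n_plants < 1 or self.n_pollinators < 1:
            raise ValueError("all counts must be positive")
        for prof in (self.pollinator_degree_mean, self.pollinator_partner_bias,
                     self.plant_attractiveness):
            if len(prof) != self.n_groups:
                raise ValueError("group profiles must have one entry per group")

    @property
    def transition_params(self) -> TransitionParams:
        return self.params if self.params is not None else default_transition_params(self.n_groups)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth behind a generated study."""

    states: pd.DataFrame          # season, species, guild, week_pos, state
    params: TransitionParams
    abundance: Mapping[str, float]
    config: SyntheticConfig

    def latent_state(self, season: str, species: str, week_pos: int) -> int:
        sub = self.states
        row = sub[(sub.season == season) & (sub.species == species)
                  & (sub.week_pos == week_pos)]
        return int(row.state.iloc[0])


def _simulate_trajectory(
    params: TransitionParams, W: int, rng: np.random.Generator
) -> list[int]:
    """Latent states at week positions 1..W, Markov chain from ``pre``."""
    space = params.space
    state = space.pre
    out = []
    for pos in range(1, W + 1):
        if state != space.post:
            p = params.probabilities(state, pos / W)
            state = int(rng.choice(space.n_states, p=p))
        out.append(state)
    return out


def _draw_weight(mean: float, rng: np.random.Generator) -> int:
    return int(rng.geometric(1.0 / max(mean, 1.0)))


def generate_series(
    config: SyntheticConfig = SyntheticConfig(),
) -> tuple[dict[str, NetworkSeries], SyntheticTruth]:
    """Generate a full synthetic study; same config (incl. seed) gives an
    identical result."""
    rng = np.random.default_rng(config.seed)
    space = StateSpace(config.n_groups)
    params = config.transition_params
    plants = [f"P{i:03d}" for i in range(config.n_plants)]
    pols = [f"A{i:03d}" for i in range(config.n_pollinators)]
    log_ab = rng.normal(0.0, config.abundance_sigma, size=len(plants) + len(pols))
    abundance = {sp: float(np.exp(v)) for sp, v in zip(plants + pols, log_ab)}
    med = float(np.median(list(abundance.values())))
    series_by_season: dict[str, NetworkSeries] = {}
    truth_rows = []
    for s_idx, W in enumerate(config.weeks):
        season = f"S{s_idx + 1}"
        latent: dict[str, list[int]] = {}
        for sp in plants + pols:
            latent[sp] = _simulate_trajectory(params, W, rng)
            guild = PLANT if sp.startswith("P") else POLLINATOR
            for pos, st in enumerate(latent[sp], start=1):
                truth_rows.append({"season": season, "species": sp, "guild": guild,
                                   "week_pos": pos, "state": st})
        # detection dropout: hide a week strictly inside the activity period
        hidden: set[tuple[str, int]] = set()
        if config.dropout > 0:
            for sp in plants + pols:
                st = latent[sp]
                for pos in range(2, W):
                    here = st[pos - 1] < config.n_groups
                    before = st[pos - 2] < config.n_groups
                    after = st[pos] < config.n_groups
                    if here and before and after and rng.random() < config.dropout:
                        hidden.add((sp, pos))
        networks = []
        for pos in range(1, W + 1):
            pres_plants = [p for p in plants
                           if latent[p][pos - 1] < config.n_groups and (p, pos) not in hidden]
            pres_pols = [a for a in pols
                         if latent[a][pos - 1] < config.n_groups and (a, pos) not in hidden]
            if not pres_plants or not pres_pols:
                continue
            attract = np.array([
                config.plant_attractiveness[latent[p][pos - 1]]
                * (abundance[p] / med) ** config.abundance_coupling
                for p in pres_plants
            ])
            edges: dict[tuple[str, str], int] = {}
            for a in pres_pols:
                g = latent[a][pos - 1]
                mult = (abundance[a] / med) ** config.abundance_coupling
                target = max(1, int(round(config.pollinator_degree_mean[g] * mult)))
                target = min(target, len(pres_plants))
                bias = config.pollinator_partner_bias[g]
                w = attract**bias
                w = w / w.sum()
                chosen = rng.choice(len(pres_plants), size=target, replace=False, p=w)
                for ci in chosen:
                    edges[(pres_plants[ci], a)] = _draw_weight(config.weight_mean, rng)
            # every available plant must appear: attach orphans preferentially
            pol_deg = {a: 0 for a in pres_pols}
            covered = set()
            for (p, a) in edges:
                covered.add(p)
                pol_deg[a] += 1
            for p in pres_plants:
                if p not in covered:
                    w = np.array([pol_deg[a] + 1.0 for a in pres_pols])
                    a = pres_pols[int(rng.choice(len(pres_pols), p=w / w.sum()))]
                    edges[(p, a)] = _draw_weight(config.weight_mean, rng)
            networks.append(WeeklyNetwork(season=season, week=pos, edges=edges))
        series_by_season[season] = NetworkSeries(season=season, networks=tuple(networks))
    truth = SyntheticTruth(states=pd.DataFrame(truth_rows), params=params,
                           abundance=abundance, config=config)
    return series_by_season, truth


def simulate_trajectories(
    params: TransitionParams,
    n_species: int,
    W: int,
    seed: int = 0,
    season: str = "S1",
) -> list:
    """Bare latent trajectories (no networks) from a transition law — the
    direct input for transition-model recovery studies."""
    from .transitions import StateTrajectory, Step

    rng = np.random.default_rng(seed)
    space = params.space
    out = []
    for i in range(n_species):
        states = _simulate_trajectory(params, W, rng)
        steps = []
        for pos in range(2, W + 1):
            origin, dest = states[pos - 2], states[pos - 1]
            if origin == space.post:
                continue
            steps.append(Step(origin=origin, dest=dest, t=pos / W, dropped=False))
        out.append(StateTrajectory(season=season, species=f"X{i:04d}", guild=POLLINATOR,
                                   weeks=tuple(range(1, W + 1)), states=tuple(states),
                                   steps=tuple(steps)))
    return out


def truth_states_to_csv(truth: SyntheticTruth, path) -> None:
    truth.states.to_csv(path, index=False)


def make_alignment_fixture(
    base_size: int = 5,
    permute: bool = True,
    symmetric_pair: bool = False,
    seed: int = 0,
) -> tuple[WeeklyNetwork, WeeklyNetwork, dict[str, str]]:
    """A small network and a relabeled copy with the ground-truth
    correspondence, for exercising the alignment optimizer.

    ``symmetric_pair`` adds one pair of pollinators with identical
    neighborhoods and weights — a genuine automorphic orbit of size 2 that
    makes their positions non-unique.  Distinct weights elsewhere break
    accidental symmetries.
    """
    if base_size > 8:
        raise ValueError("fixture capped at 8 species per guild")
    rng = np.random.default_rng(seed)
    plants = [f"P{i}" for i in range(base_size)]
    pols = [f"A{i}" for i in range(base_size)]
    edges: dict[tuple[str, str], int] = {}
    w = 2
    for j, a in enumerate(pols):
        # pollinator j attaches to plant j (connectivity) plus 0-2 others
        partners = {j}
        for extra in rng.choice(base_size, size=int(rng.integers(0, 3)), replace=False):
            partners.add(int(extra))
        for pi in sorted(partners):
            edges[(plants[pi], a)] = w
            w = w % 9 + 1  # cycle distinct-ish weights
    # connect any separated components: species in a 2-node component have
    # zero role vectors (no 3-species subgraph), which defeats the fixture
    def components(es):
        adj: dict[str, set[str]] = {}
        for (p, a) in es:
            adj.setdefault(p, set()).add(a)
            adj.setdefault(a, set()).add(p)
        seen: set[str] = set()
        comps = []
        for start in sorted(adj):
            if start in seen:
                continue
            comp, stack = {start}, [start]
            while stack:
                v = stack.pop()
                for u in adj[v]:
                    if u not in comp:
                        comp.add(u)
                        stack.append(u)
            seen |= comp
            comps.append(sorted(comp))
        return comps

    comps = components(edges)
    while len(comps) > 1:
        a_node = next(s for s in comps[1] if s.startswith("A"))
        p_node = next(s for s in comps[0] if s.startswith("P"))
        edges[(p_node, a_node)] = w
        w = w % 9 + 1
        comps = components(edges)
    if symmetric_pair:
        twin_a, twin_b = pols[0], pols[1]
        shared = {p for (p, a) in edges if a == twin_a}
        edges = {(p, a): wt for (p, a), wt in edges.items() if a not in (twin_a, twin_b)}
        for p in sorted(shared):
            edges[(p, twin_a)] = 5
            edges[(p, twin_b)] = 5
    net_a = WeeklyNetwork(season="F", week=1, edges=edges)
    mapping = {sp: sp for sp in net_a.species}
    if permute:
        perm_p = rng.permutation(base_size)
        perm_a = rng.permutation(base_size)
        mapping = {plants[i]: f"Q{perm_p[i]}" for i in range(base_size)}
        mapping.update({pols[i]: f"B{perm_a[i]}" for i in range(base_size)})
        mapping = {sp: mapping[sp] for sp in net_a.species}
    edges_b = {(mapping[p], mapping[a]): wt for (p, a), wt in edges.items()}
    net_b = WeeklyNetwork(season="F", week=2, edges=edges_b)
    return net_a, net_b, mapping
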