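"""End-to-end orchestration of the seasonal network-position analysis.

Stages: weekly networks -> motif role vectors -> alignment ensembles
(self, within-season pairs, and cross-season pairs) -> uniqueness /
variability -> alignment matrix -> position groups -> state trajectories
-> transition-model fit.  Each stage is importable on its own; this module
wires them together for the CLI and for reproduction scripts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd

from . import alignment as al
from . import grouping as gr
from . import motif_roles as mr
from . import position_stats as ps
from . import transitions as tr
from .data_io import PLANT, POLLINATOR, NetworkSeries, PipelineConfig, WeeklyNetwork, to_binary


@dataclass
class StudyResult:
    """Everything the pipeline computes, stage by stage.

    Transition modeling is per guild (group labels are not comparable
    across guilds): ``trajectories``, ``spaces``, ``fits`` and ``waic``
    are keyed by guild, and fits/waic additionally by model form.
    """

    networks: dict[tuple[str, int], WeeklyNetwork]
    roles: dict[tuple[str, int], dict[str, np.ndarray]]
    ensembles: dict[frozenset, al.AlignmentEnsemble]
    uniqueness: list[ps.UniquenessScore]
    variability: list[ps.VariabilityScore]
    matrix: gr.AlignmentMatrix
    grouping: gr.PositionGrouping
    group_props: pd.DataFrame
    trajectories: dict[str, list[tr.StateTrajectory]]
    spaces: dict[str, tr.StateSpace]
    fits: dict[str, dict[str, tr.TransitionModelFit]] = field(default_factory=dict)
    waic: dict[str, dict[str, float]] = field(default_factory=dict)


def compute_roles(
    networks: Mapping[tuple[str, int], WeeklyNetwork], config: PipelineConfig
) -> dict[tuple[str, int], dict[str, np.ndarray]]:
    catalog = mr.enumerate_motifs(config.motif_min_size, config.motif_max_size)
    mode = "binary" if config.binary else "weighted"
    out = {}
    for nid, net in networks.items():
        roles = mr.census_roles(net, catalog, mode=mode,
                                weight_combine=config.weight_combine)
        out[nid] = mr.normalize_roles(roles, config.role_normalization)
    return out


def align_study(
    networks: Mapping[tuple[str, int], WeeklyNetwork],
    roles: Mapping[tuple[str, int], dict[str, np.ndarray]],
    config: PipelineConfig,
    cross_season: bool = True,
) -> dict[frozenset, al.AlignmentEnsemble]:
    """Alignment ensembles for all self pairs and all distinct pairs
    (within seasons always; across seasons unless disabled)."""
    schedule = al.AnnealSchedule(config.anneal_t0, config.anneal_cooling,
                                 config.anneal_sweeps)
    net_ids = sorted(networks)
    pairs = [(nid, nid) for nid in net_ids]
    for a_id, b_id in combinations(net_ids, 2):
        if cross_season or a_id[0] == b_id[0]:
            pairs.append((a_id, b_id))
    ensembles: dict[frozenset, al.AlignmentEnsemble] = {}
    rng = np.random.default_rng(config.seed)
    for a_id, b_id in pairs:
        base_seed = int(rng.integers(0, 2**31 - config.n_alignments))
        ens = al.repeat_align(networks[a_id], networks[b_id],
                              roles[a_id], roles[b_id],
                              n_runs=config.n_alignments, base_seed=base_seed,
                              schedule=schedule,
                              unpaired_penalty=config.unpaired_penalty)
        ensembles[frozenset((a_id, b_id))] = ens
    return ensembles


def run_study(
    series_by_season: Mapping[str, NetworkSeries],
    config: PipelineConfig = PipelineConfig(),
    fit_forms: tuple[str, ...] = ("time_dependent", "constant"),
    fit_guilds: tuple[str, ...] = (POLLINATOR, PLANT),
    sampler_kwargs: dict | None = None,
    cross_season: bool = True,
) -> StudyResult:
    """Run the full analysis on a set of seasonal network series."""
    networks: dict[tuple[str, int], WeeklyNetwork] = {}
    for series in series_by_season.values():
        for net in series:
            networks[net.id] = to_binary(net) if config.binary else net
    roles = compute_roles(networks, config)
    ensembles = align_study(networks, roles, config, cross_season=cross_season)

    uniq: list[ps.UniquenessScore] = []
    for nid, net in sorted(networks.items()):
        ens = ensembles[frozenset((nid,))]
        uniq.extend(ps.uniqueness_from_ensemble(net, ens).values())
    vari: list[ps.VariabilityScore] = []
    for season in sorted(series_by_season):
        season_ens = [e for key, e in ensembles.items()
                      if all(nid[0] == season for nid in key)]
        season_nets = {nid: n for nid, n in networks.items() if nid[0] == season}
        vari.extend(ps.variability(season, season_ens, season_nets).values())

    matrix = gr.build_alignment_matrix(ensembles.values(), networks,
                                       quality_weighting=config.quality_weighting)
    raw_grouping = gr.detect_groups(matrix, steps=config.walktrap_steps)
    grouping = gr.order_groups_by_properties(raw_grouping, networks)
    props = gr.group_properties(grouping, networks)

    trajectories: dict[str, list[tr.StateTrajectory]] = {}
    spaces: dict[str, tr.StateSpace] = {}
    for guild in (PLANT, POLLINATOR):
        trajectories[guild] = tr.build_state_sequences(
            grouping, series_by_season, guild=guild
        )
        n_groups = max(grouping.membership[occ] for occ in grouping.membership
                       if grouping.guild_of[occ] == guild) + 1
        spaces[guild] = tr.StateSpace(n_groups)
    result = StudyResult(networks=networks, roles=roles, ensembles=ensembles,
                         uniqueness=uniq, variability=vari, matrix=matrix,
                         grouping=grouping, group_props=props,
                         trajectories=trajectories, spaces=spaces)
    kw = dict(sampler_kwargs or {})
    for gi, guild in enumerate(fit_guilds):
        data = tr.TransitionData.from_trajectories(trajectories[guild], spaces[guild])
        result.fits[guild] = {}
        result.waic[guild] = {}
        for k, form in enumerate(fit_forms):
            fit = tr.fit_transition_model(
                data, form=form, seed=config.seed + 17 * (k + 1) + 1000 * gi, **kw
            )
            result.fits[guild][form] = fit
            result.waic[guild][form] = tr.waic(fit, data)
    return result
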