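import numpy as np
import pytest

from netweave.alignment import Alignment, AlignmentEnsemble
from netweave.data_io import WeeklyNetwork
from netweave.grouping import (
    AlignmentMatrix,
    PositionGrouping,
    abundance_regression,
    build_alignment_matrix,
    compare_partitions,
    degree_sensitivity,
    detect_groups,
    group_properties,
    relative_degree,
)


def _net(week, edges):
    return WeeklyNetwork(season="s", week=week, edges=edges)


def _self_ensemble(net, c=1.0):
    al = Alignment(network_a=net.id, network_b=net.id,
                   pairs={sp: sp for sp in net.species},
                   unpaired_a=(), unpaired_b=(), cost=0.0,
                   correlations={(sp, sp): c for sp in net.species})
    return AlignmentEnsemble(network_a=net.id, network_b=net.id, runs=(al,))


class TestBuildAlignmentMatrix:
    def setup_method(self):
        self.A = _net(1, {("P1", "A1"): 1, ("P1", "A2"): 2})
        self.B = _net(2, {("P1", "A1"): 1, ("P1", "A2"): 2})

    def _cross(self, runs):
        return AlignmentEnsemble(network_a=self.A.id, network_b=self.B.id, runs=tuple(runs))

    def _alignment(self, pairs, corrs):
        return Alignment(network_a=self.A.id, network_b=self.B.id, pairs=pairs,
                         unpaired_a=(), unpaired_b=(), cost=0.0, correlations=corrs)

    def test_frequency_times_positive_correlation(self):
        base = {"P1": "P1"}
        runs = [
            self._alignment({**base, "A1": "A1", "A2": "A2"},
                            {("P1", "P1"): 1.0, ("A1", "A1"): 0.8, ("A2", "A2"): 0.8}),
            self._alignment({**base, "A1": "A2", "A2": "A1"},
                            {("P1", "P1"): 1.0, ("A1", "A2"): 0.8, ("A2", "A1"): 0.8}),
        ]
        M = build_alignment_matrix(
            [self._cross(runs), _self_ensemble(self.A), _self_ensemble(self.B)],
            {self.A.id: self.A, self.B.id: self.B},
        )
        i = M.index_of((self.A.id, "A1"))
        j = M.index_of((self.B.id, "A1"))
        # paired in 1 of 2 runs with c = 0.8 -> 0.5 * 0.8 = 0.4
        assert M.values[i, j] == pytest.approx(0.4)
        assert M.values[j, i] == pytest.approx(0.4)

    def test_negative_correlations_do_not_credit_quality(self):
        runs = [self._alignment({"P1": "P1", "A1": "A1", "A2": "A2"},
                                {("P1", "P1"): 1.0, ("A1", "A1"): -0.5, ("A2", "A2"): 1.0})]
        M = build_alignment_matrix(
            [self._cross(runs), _self_ensemble(self.A), _self_ensemble(self.B)],
            {self.A.id: self.A, self.B.id: self.B},
        )
        i = M.index_of((self.A.id, "A1"))
        j = M.index_of((self.B.id, "A1"))
        assert M.values[i, j] == 0.0

    def test_matrix_invariants(self):
        runs = [self._alignment({"P1": "P1", "A1": "A1", "A2": "A2"},
                                {("P1", "P1"): 1.0, ("A1", "A1"): 0.6, ("A2", "A2"): 0.9})]
        M = build_alignment_matrix(
            [self._cross(runs), _self_ensemble(self.A), _self_ensemble(self.B)],
            {self.A.id: self.A, self.B.id: self.B},
        )
        assert np.allclose(M.values, M.values.T)
        assert M.values.min() >= 0 and M.values.max() <= 1
        for i, gi in enumerate(M.guilds):
            for j, gj in enumerate(M.guilds):
                if gi != gj:
                    assert M.values[i, j] == 0.0

    def test_missing_ensemble_reported(self):
        with pytest.raises(ValueError, match="missing alignment ensembles"):
            build_alignment_matrix([_self_ensemble(self.A), _self_ensemble(self.B)],
                                   {self.A.id: self.A, self.B.id: self.B})


def _planted_matrix(rng, n_per_block=20, n_blocks=3, within=0.9, between=0.05):
    occs, guilds, labels = [], [], []
    for guild, prefix in (("plant", "P"), ("pollinator", "A")):
        for b in range(n_blocks):
            for k in range(n_per_block):
                occs.append((("s", 1), f"{prefix}{b}_{k}"))
                guilds.append(guild)
                labels.append(b)
    n = len(occs)
    V = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if guilds[i] != guilds[j]:
                continue
            mu = within if labels[i] == labels[j] else between
            v = float(np.clip(mu + rng.normal(0, 0.02), 0.0, 1.0))
            V[i, j] = V[j, i] = v
    M = AlignmentMatrix(occurrences=tuple(occs), guilds=tuple(guilds), values=V)
    truth = PositionGrouping(membership=dict(zip(occs, labels)),
                             guild_of=dict(zip(occs, guilds)))
    return M, truth


class TestDetectGroups:
    def test_recovers_planted_blocks(self):
        rng = np.random.default_rng(0)
        M, truth = _planted_matrix(rng)
        got = detect_groups(M, steps=4)
        assert compare_partitions(got, truth) == pytest.approx(1.0)

    def test_uniform_matrix_single_group(self):
        occs = [(("s", 1), f"P{k}") for k in range(6)] + [(("s", 1), f"A{k}") for k in range(6)]
        guilds = tuple(["plant"] * 6 + ["pollinator"] * 6)
        V = np.full((12, 12), 0.5)
        np.fill_diagonal(V, 0.0)
        for i in range(12):
            for j in range(12):
                if guilds[i] != guilds[j]:
                    V[i, j] = 0.0
        M = AlignmentMatrix(occurrences=tuple(occs), guilds=guilds, values=V)
        got = detect_groups(M)
        for guild in ("plant", "pollinator"):
            assert len(got.groups(guild)) == 1


class TestComparePartitions:
    def _partition(self, labels):
        occs = [(("s", 1), f"x{i}") for i in range(len(labels))]
        return PositionGrouping(membership=dict(zip(occs, labels)),
                                guild_of={o: "plant" for o in occs})

    def test_identical_partitions(self):
        p = self._partition([0, 0, 1, 1])
        assert compare_partitions(p, p) == pytest.approx(1.0)

    def test_trivial_partition_zero(self):
        p1 = self._partition([0, 0, 0, 0])
        p2 = self._partition([0, 0, 1, 1])
        assert compare_partitions(p1, p2) == pytest.approx(0.0)

    def test_hand_contingency(self):
        # labels AABB vs AABA: contingency [[2,0],[1,1]] on n=4
        p1 = self._partition([0, 0, 1, 1])
        p2 = self._partition([0, 0, 1, 0])
        n = 4.0
        px = np.array([2, 2]) / n
        py = np.array([3, 1]) / n
        joint = np.array([[2, 0], [1, 1]]) / n
        mi = sum(
            joint[i, j] * np.log(joint[i, j] / (px[i] * py[j]))
            for i in range(2) for j in range(2) if joint[i, j] > 0
        )
        hx = -(px * np.log(px)).sum()
        hy = -(py * np.log(py)).sum()
        expected = mi / ((hx + hy) / 2)
        assert compare_partitions(p1, p2) == pytest.approx(expected)

    def test_mismatched_sets_rejected(self):
        p1 = self._partition([0, 1])
        p2 = self._partition([0, 1, 1])
        with pytest.raises(ValueError):
            compare_partitions(p1, p2)


class TestRelativeDegree:
    def test_star(self):
        net = _net(1, {("P1", f"A{k}"): 1 for k in range(4)})
        k = relative_degree(net)
        assert k["P1"] == 1.0
        assert all(k[f"A{i}"] == 0.25 for i in range(4))

    def test_regular_network_all_one(self):
        net = _net(1, {("P1", "A1"): 1, ("P1", "A2"): 3, ("P2", "A1"): 2, ("P2", "A2"): 1})
        assert set(relative_degree(net).values()) == {1.0}

    def test_weight_invariance(self):
        e1 = {("P1", "A1"): 1, ("P1", "A2"): 9, ("P2", "A1"): 4}
        e2 = {k: 1 for k in e1}
        assert relative_degree(_net(1, e1)) == relative_degree(_net(1, e2))


class TestGroupProperties:
    def test_single_edge_degenerate(self):
        net = _net(1, {("P1", "A1"): 2})
        g = PositionGrouping(
            membership={(net.id, "P1"): 0, (net.id, "A1"): 0},
            guild_of={(net.id, "P1"): "plant", (net.id, "A1"): "pollinator"},
        )
        props = group_properties(g, {net.id: net})
        assert (props[["k", "max_partner_k", "mean_partner_k"]] == 1.0).all().all()

    def test_leaf_attached_to_hub(self):
        net = _net(1, {("P1", f"A{k}"): 1 for k in range(4)})
        occs = {(net.id, sp) for sp in net.species}
        g = PositionGrouping(membership={o: 0 for o in occs},
                             guild_of={o: net.guild_of(o[1]) for o in occs})
        props = group_properties(g, {net.id: net}).set_index("species")
        assert props.loc["A0", "k"] == 0.25
        assert props.loc["A0", "max_partner_k"] == 1.0
        assert props.loc["P1", "mean_partner_k"] == 0.25


class TestDegreeSensitivity:
    def test_zero_fraction_no_change(self):
        net = _net(1, {("P1", "A1"): 3, ("P2", "A1"): 2, ("P1", "A2"): 4})
        tab = degree_sensitivity(net, [0.0], reps=3, seed=0)
        assert tab.mean_abs_dk.iloc[0] == 0.0
        assert tab.mean_link_loss.iloc[0] == 0.0

    def test_full_removal_loses_all_links(self):
        net = _net(1, {("P1", "A1"): 3, ("P2", "A1"): 2})
        tab = degree_sensitivity(net, [1.0], reps=2, seed=0)
        assert tab.mean_link_loss.iloc[0] == 1.0

    def test_weight_concentration_protects_links(self):
        # heavy-tailed weights: removing half the events loses far fewer
        # than half the distinct links
        rng = np.random.default_rng(1)
        edges = {(f"P{i}", f"A{j}"): int(w)
                 for i in range(5) for j, w in enumerate(rng.pareto(1.0, 5) * 5 + 1)}
        net = _net(1, edges)
        tab = degree_sensitivity(net, [0.5], reps=10, seed=2)
        assert tab.mean_link_loss.iloc[0] < 0.5

    def test_invalid_fraction(self):
        net = _net(1, {("P1", "A1"): 1})
        with pytest.raises(ValueError):
            degree_sensitivity(net, [1.5])


class TestAbundanceRegression:
    def test_perfect_line(self):
        slope, intercept, unexplained = abundance_regression([0, 1, 2], [0, 1, 2])
        assert slope == pytest.approx(1.0)
        assert unexplained == pytest.approx(0.0, abs=1e-12)

    def test_uncorrelated_mostly_unexplained(self):
        rng = np.random.default_rng(0)
        k = rng.random(500)
        ab = rng.random(500)
        _, _, unexplained = abundance_regression(k, ab)
        assert unexplained > 0.9

    def test_zero_variance_abundance_rejected(self):
        with pytest.raises(ValueError):
            abundance_regression([0, 1, 2], [1, 1, 1])
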