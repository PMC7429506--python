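import numpy as np
import pytest

from netweave.data_io import NetworkSeries, WeeklyNetwork
from netweave.grouping import PositionGrouping
from netweave.transitions import (
    StateSpace,
    StateTrajectory,
    Step,
    TransitionData,
    TransitionModelFit,
    TransitionParams,
    build_state_sequences,
    pointwise_log_likelihood,
    predict_curves,
    score_linear,
    transition_probability,
    waic,
)


def _series_with_presence(presence, W, groups):
    """One season where pollinator X is present in the given weeks with the
    given group labels; an anchor plant/pollinator pair is always present."""
    nets = []
    membership = {}
    guild_of = {}
    for w in range(1, W + 1):
        edges = {("P0", "Abg"): 1}
        if w in presence:
            edges[("P0", "X")] = 2
        net = WeeklyNetwork(season="s", week=w, edges=edges)
        nets.append(net)
        for sp in net.species:
            occ = (net.id, sp)
            guild_of[occ] = net.guild_of(sp)
            membership[occ] = groups[w] if sp == "X" else 0
    series = {"s": NetworkSeries(season="s", networks=tuple(nets))}
    grouping = PositionGrouping(membership=membership, guild_of=guild_of)
    return series, grouping


class TestBuildStateSequences:
    def test_entry_moves_and_exit(self):
        series, grouping = _series_with_presence(
            presence={2, 3, 4}, W=5, groups={2: 0, 3: 0, 4: 1}
        )
        space = StateSpace(2)
        trajs = build_state_sequences(grouping, series, space)
        x = next(t for t in trajs if t.species == "X")
        assert x.states == (space.pre, 0, 0, 1, space.post)
        got = [(s.origin, s.dest, s.t, s.dropped) for s in x.steps]
        assert got == [
            (space.pre, 0, 2 / 5, False),
            (0, 0, 3 / 5, False),
            (0, 1, 4 / 5, False),
            (1, space.post, 5 / 5, False),
        ]

    def test_gap_steps_dropped(self):
        series, grouping = _series_with_presence(
            presence={1, 3}, W=3, groups={1: 0, 3: 1}
        )
        space = StateSpace(2)
        trajs = build_state_sequences(grouping, series, space)
        x = next(t for t in trajs if t.species == "X")
        assert all(s.dropped for s in x.steps)
        assert x.usable_steps() == ()

    def test_final_week_presence_right_censored(self):
        series, grouping = _series_with_presence(
            presence={4, 5}, W=5, groups={4: 0, 5: 0}
        )
        space = StateSpace(1)
        trajs = build_state_sequences(grouping, series, space)
        x = next(t for t in trajs if t.species == "X")
        # last recorded step arrives at the final week; nothing leaves it
        assert max(s.t for s in x.steps) == 1.0
        assert x.steps[-1].dest == 0
        assert len(x.steps) == 4

    def test_no_steps_out_of_post(self):
        series, grouping = _series_with_presence(presence={2}, W=5, groups={2: 0})
        space = StateSpace(1)
        trajs = build_state_sequences(grouping, series, space)
        x = next(t for t in trajs if t.species == "X")
        assert all(s.origin != space.post for s in x.steps)
        # present week 2 of five: pre->G0 then G0->post; the post->post
        # tail is never recorded
        assert [(s.origin, s.dest) for s in x.steps] == [
            (space.pre, 0), (0, space.post)
        ]


class TestSoftmax:
    def test_uniform_over_five_states(self):
        p = transition_probability(np.zeros(5))
        assert np.allclose(p, 0.2)

    def test_two_state_closed_form(self):
        p = transition_probability(np.array([0.0, np.log(2.0)]))
        assert np.allclose(p, [1 / 3, 2 / 3])

    def test_shift_invariance_and_overflow_safety(self):
        s = np.array([1.0, -2.0, 0.5])
        assert np.allclose(transition_probability(s), transition_probability(s + 1000.0))


class TestScoreLinear:
    def test_zero_params_zero_scores(self):
        params = TransitionParams(2, np.zeros((3, 2)), np.zeros((3, 2)))
        s = score_linear(params, origin=0, t=0.7)
        assert s[0] == 0.0 and s[1] == 0.0
        assert s[params.space.post] == 0.0          # reference destination
        assert np.isneginf(s[params.space.pre])     # no return to pre

    def test_t_zero_reduces_to_intercepts(self):
        alpha = np.array([[0.3, -0.2], [0.1, 0.4], [0.0, 1.0]])
        beta = np.full((3, 2), 5.0)
        params = TransitionParams(2, alpha, beta)
        s = score_linear(params, origin=1, t=0.0)
        assert np.allclose(s[:2], alpha[1])

    def test_hand_evaluation_with_origin_offset(self):
        alpha = np.array([[0.3, -0.2], [0.1, 0.4], [-0.5, 1.0]])
        beta = np.array([[1.0, 0.0], [-2.0, 0.5], [0.3, 0.3]])
        params = TransitionParams(2, alpha, beta)
        space = params.space
        t = 0.5
        s = score_linear(params, origin=space.pre, t=t)
        assert np.allclose(s[:2], alpha[2] + beta[2] * t)
        assert s[space.pre] == 0.0                  # pre row's reference cell
        assert np.isneginf(s[space.post])           # pre cannot jump to post

    def test_probabilities_row_stochastic(self):
        rng = np.random.default_rng(0)
        params = TransitionParams(3, rng.normal(size=(4, 3)), rng.normal(size=(4, 3)))
        for origin in range(5):  # groups, pre, post
            p = params.probabilities(origin, 0.3)
            assert p.sum() == pytest.approx(1.0)
            assert (p >= 0).all()

    def test_from_probabilities_round_trip(self):
        group_rows = np.array([[0.5, 0.2, 0.3], [0.1, 0.8, 0.1]])
        pre_row = np.array([0.15, 0.05, 0.8])
        params = TransitionParams.from_probabilities(group_rows, pre_row)
        space = params.space
        for g in range(2):
            p = params.probabilities(g, 0.5)
            assert np.allclose([p[0], p[1], p[space.post]], group_rows[g])
            assert p[space.pre] == 0.0
        p = params.probabilities(space.pre, 0.0)
        assert np.allclose([p[0], p[1], p[space.pre]], pre_row)
        assert p[space.post] == 0.0


class TestTransitionData:
    def test_dropped_and_post_steps_excluded(self):
        space = StateSpace(1)
        tr = StateTrajectory(
            season="s", species="X", guild="pollinator",
            weeks=(1, 2, 3, 4), states=(0, space.pre, 0, space.post),
            steps=(
                Step(0, space.pre, 0.5, dropped=True),
                Step(space.pre, 0, 0.75, dropped=True),
                Step(0, space.post, 1.0, dropped=False),
            ),
        )
        data = TransitionData.from_trajectories([tr], space)
        assert data.n_obs == 1
        assert data.cell[0] == space.n_groups  # exit is the reference cell

    def test_impossible_step_rejected(self):
        space = StateSpace(1)
        tr = StateTrajectory(
            season="s", species="X", guild="pollinator", weeks=(1, 2),
            states=(0, space.pre),
            steps=(Step(0, space.pre, 1.0, dropped=False),),
        )
        with pytest.raises(ValueError, match="impossible"):
            TransitionData.from_trajectories([tr], space)

    def test_empty_data_rejected(self):
        space = StateSpace(1)
        tr = StateTrajectory(season="s", species="X", guild="pollinator",
                             weeks=(1,), states=(0,), steps=())
        with pytest.raises(ValueError, match="no usable transitions"):
            TransitionData.from_trajectories([tr], space)


def _hand_fit_and_data():
    """1-group model, hand-set posterior 'draws', two observations."""
    space = StateSpace(1)
    # columns: alpha[G0->G0], alpha[pre->G0]; only row G0 has observations
    draws = np.array([[0.0, 0.3], [1.0, -0.2], [-1.0, 0.1]])
    fit = TransitionModelFit(form="constant", space=space, draws=draws, prior_sigma=10.0)
    data = TransitionData(space=space,
                          origin=np.array([0, 0]),
                          cell=np.array([0, 1]),   # one stay, one exit
                          t=np.array([0.5, 1.0]))
    return fit, data


class TestWaic:
    def test_hand_computed_value(self):
        fit, data = _hand_fit_and_data()
        # independent computation with plain python
        import math

        lls = []
        for a in (0.0, 1.0, -1.0):
            z = math.exp(a) + 1.0
            lls.append([a - math.log(z), -math.log(z)])
        lls = np.array(lls)
        lppd = sum(math.log(np.mean(np.exp(lls[:, i]))) for i in range(2))
        p = sum(np.var(lls[:, i], ddof=1) for i in range(2))
        expected = -2 * (lppd - p)
        assert waic(fit, data) == pytest.approx(expected)

    def test_identical_fits_equal_waic(self):
        fit, data = _hand_fit_and_data()
        assert waic(fit, data) == waic(fit, data)

    def test_pointwise_matrix_shape(self):
        fit, data = _hand_fit_and_data()
        L = pointwise_log_likelihood(fit, data)
        assert L.shape == (3, 2)
        assert np.all(L < 0)


class TestPredictCurves:
    def test_constant_fit_flat_curves(self):
        fit, _ = _hand_fit_and_data()
        curves = predict_curves(fit, t_grid=[0.0, 0.5, 1.0])
        for (_, _), sub in curves.groupby(["origin", "destination"]):
            assert sub["mean"].nunique() == 1

    def test_rows_sum_to_one(self):
        fit, _ = _hand_fit_and_data()
        curves = predict_curves(fit, t_grid=[0.25, 0.75])
        sums = curves.groupby(["origin", "t"])["mean"].sum()
        assert np.allclose(sums, 1.0)

    def test_hand_set_parameters_match_direct_evaluation(self):
        space = StateSpace(2)
        alpha = np.array([[0.4, -0.1], [0.2, 0.2], [-0.3, 0.6]])
        beta = np.array([[1.0, -1.0], [0.0, 0.5], [0.2, -0.2]])
        theta = np.concatenate([alpha.ravel(), beta.ravel()])
        fit = TransitionModelFit(form="time_dependent", space=space,
                                 draws=theta[None, :], prior_sigma=10.0)
        curves = predict_curves(fit, t_grid=[0.5]).set_index(["origin", "destination"])
        params = TransitionParams(2, alpha, beta)
        p = params.probabilities(0, 0.5)
        assert curves.loc[("G0", "G1"), "mean"] == pytest.approx(p[1])
        assert curves.loc[("G0", "post"), "mean"] == pytest.approx(p[space.post])
        p_pre = params.probabilities(space.pre, 0.5)
        assert curves.loc[("pre", "G0"), "mean"] == pytest.approx(p_pre[0])
        assert curves.loc[("pre", "pre"), "mean"] == pytest.approx(p_pre[space.pre])
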