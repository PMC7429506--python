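"""Species movement among position groups: a Bayesian multinomial model.

Each species' season is a weekly state sequence over n position groups plus
two boundary states: ``pre`` (not yet entered) and ``post`` (already
exited, absorbing).  Transitions between consecutive sampled weeks are
modeled with a multinomial logistic regression: the probability of moving
from origin state y_i to destination y_j at relative time t is a softmax
over per-destination "scores" that are linear in t, with one score per
origin row fixed to zero as the reference.  Structural zeros are enforced
as restricted choice sets rather than penalized scores: from a group a
species can move to any group or exit (never back to ``pre``); from
``pre`` it can stay or enter any group (never jump to ``post``); ``post``
has no outgoing transitions.

The free parameters are one intercept (and, in the time-dependent form,
one slope) per free (origin, destination) cell, with independent
N(0, sigma=10) priors; this is a one-to-one reparameterization of the
intercept-plus-origin-offset form of the score functions.  Posterior
sampling uses the affine-invariant ensemble sampler (emcee); model forms
are compared with WAIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .data_io import NetworkSeries
from .grouping import PositionGrouping

PRE = "pre"
POST = "post"


@dataclass(frozen=True)
class StateSpace:
    """n group states plus ``pre`` and ``post``.  State indices: groups
    0..n-1, pre = n, post = n+1."""

    n_groups: int

    @property
    def n_states(self) -> int:
        return self.n_groups + 2

    @property
    def pre(self) -> int:
        return self.n_groups

    @property
    def post(self) -> int:
        return self.n_groups + 1

    def label(self, s: int) -> str:
        if s == self.pre:
            return PRE
        if s == self.post:
            return POST
        return f"G{s}"

    def destinations(self, origin: int) -> list[int]:
        """Allowed destination states from ``origin`` (choice set)."""
        if origin == self.post:
            return [self.post]
        if origin == self.pre:
            return list(range(self.n_groups)) + [self.pre]
        return list(range(self.n_groups)) + [self.post]

    def reference_destination(self, origin: int) -> int:
        """The destination whose score is fixed to 0 for this origin row
        (post where reachable; the pre row uses its stay cell)."""
        return self.pre if origin == self.pre else self.post


@dataclass(frozen=True)
class Step:
    origin: int
    dest: int
    t: float
    dropped: bool


@dataclass(frozen=True)
class StateTrajectory:
    """One species' weekly states in one season, with usable steps."""

    season: str
    species: str
    guild: str
    weeks: tuple[int, ...]        # sampled week labels, in order
    states: tuple[int, ...]       # state per sampled week
    steps: tuple[Step, ...]       # transitions between consecutive weeks

    def usable_steps(self) -> tuple[Step, ...]:
        return tuple(s for s in self.steps if not s.dropped)


def build_state_sequences(
    grouping: PositionGrouping,
    series_by_season: Mapping[str, NetworkSeries],
    space: StateSpace | None = None,
    guild: str | None = None,
) -> list[StateTrajectory]:
    """Turn per-week group memberships into state trajectories.

    A species is ``pre`` before its first presence and ``post`` after its
    last; relative time of a step is the 1-based position of its
    destination week among sampled weeks divided by W.  Steps that touch a
    within-activity absence (presence -> absence -> presence) are flagged
    dropped: the exit into the gap, every step inside it, and the
    re-entry.  Steps out of ``post`` are not recorded.  Group labels are
    per guild, so pass ``guild`` to build one guild's trajectories (the
    two guilds are modeled separately); with ``guild=None`` labels are
    assumed comparable across guilds.
    """
    if space is None:
        labels = [lab for occ, lab in grouping.membership.items()
                  if guild is None or grouping.guild_of[occ] == guild]
        space = StateSpace(n_groups=max(labels) + 1)
    trajectories: list[StateTrajectory] = []
    for season, series in sorted(series_by_season.items()):
        W = series.W
        present_in: dict[str, dict[int, int]] = {}  # species -> week pos -> group
        guild_of: dict[str, str] = {}
        for pos, net in enumerate(series, start=1):
            for sp in net.species:
                if guild is not None and net.guild_of(sp) != guild:
                    continue
                occ = (net.id, sp)
                if occ not in grouping.membership:
                    raise KeyError(f"no group membership for occurrence {occ}")
                present_in.setdefault(sp, {})[pos] = grouping.membership[occ]
                guild_of[sp] = net.guild_of(sp)
        for sp in sorted(present_in):
            occ_weeks = present_in[sp]
            first, last = min(occ_weeks), max(occ_weeks)
            states: list[int] = []
            gap = [False] * (W + 1)
            for pos in range(1, W + 1):
                if pos in occ_weeks:
                    states.append(occ_weeks[pos])
                elif pos < first:
                    states.append(space.pre)
                elif pos > last:
                    states.append(space.post)
                else:
                    states.append(space.pre)  # in-activity absence
                    gap[pos] = True
            steps: list[Step] = []
            for pos in range(2, W + 1):
                origin, dest = states[pos - 2], states[pos - 1]
                if origin == space.post:
                    continue
                dropped = gap[pos - 1] or gap[pos]
                steps.append(Step(origin=origin, dest=dest, t=pos / W, dropped=dropped))
            assert all(
                s.origin != space.post for s in steps
            ), "transition out of the absorbing exit state"
            trajectories.append(
                StateTrajectory(season=season, species=sp, guild=guild_of[sp],
                                weeks=series.weeks, states=tuple(states),
                                steps=tuple(steps))
            )
    return trajectories


def trajectories_to_frame(trajectories: Iterable[StateTrajectory], space: StateSpace) -> pd.DataFrame:
    rows = []
    for tr in trajectories:
        W = len(tr.weeks)
        dropped_at = {round(s.t * W): s.dropped for s in tr.steps}
        for pos, (week, st) in enumerate(zip(tr.weeks, tr.states), start=1):
            rows.append({"season": tr.season, "species": tr.species, "guild": tr.guild,
                         "week": week, "t": pos / W, "state": space.label(st),
                         "dropped_step": dropped_at.get(pos, False)})
    return pd.DataFrame(rows)


def transition_probability(scores: np.ndarray) -> np.ndarray:
    """Softmax of a score vector, overflow-safe; -inf marks impossible
    destinations."""
    scores = np.asarray(scores, dtype=float)
    m = np.max(scores)
    e = np.exp(scores - m)
    return e / e.sum()


@dataclass(frozen=True)
class TransitionParams:
    """Free score parameters: one (intercept, slope) per free cell.

    Row r of ``alpha``/``beta`` is origin state r (groups 0..n-1, then
    pre); column d is destination group d.  The reference destination of
    each row (post for group rows, pre-stay for the pre row) has score 0.
    """

    n_groups: int
    alpha: np.ndarray  # (n_groups + 1, n_groups)
    beta: np.ndarray   # (n_groups + 1, n_groups)

    @property
    def space(self) -> StateSpace:
        return StateSpace(self.n_groups)

    def score_vector(self, origin: int, t: float) -> np.ndarray:
        """Scores over all n+2 destination states ordered (groups, pre,
        post); structurally impossible destinations get -inf."""
        sp = self.space
        n = self.n_groups
        s = np.full(sp.n_states, -np.inf)
        if origin == sp.post:
            s[sp.post] = 0.0
            return s
        row = n if origin == sp.pre else origin
        s[:n] = self.alpha[row] + self.beta[row] * t
        s[sp.reference_destination(origin)] = 0.0
        return s

    def probabilities(self, origin: int, t: float) -> np.ndarray:
        return transition_probability(self.score_vector(origin, t))

    @classmethod
    def from_probabilities(
        cls, group_rows: np.ndarray, pre_row: np.ndarray
    ) -> "TransitionParams":
        """Constant-in-time parameters from explicit probabilities.

        ``group_rows``: (n, n+1), row g over destinations (groups..., post);
        ``pre_row``: (n+1,) over (groups..., stay-pre).  Rows must be
        strictly positive and sum to 1.
        """
        group_rows = np.asarray(group_rows, dtype=float)
        pre_row = np.asarray(pre_row, dtype=float)
        n = group_rows.shape[0]
        if group_rows.shape != (n, n + 1) or pre_row.shape != (n + 1,):
            raise ValueError("wrong shapes for transition probabilities")
        if not (np.allclose(group_rows.sum(axis=1), 1.0) and np.isclose(pre_row.sum(), 1.0)):
            raise ValueError("transition rows must sum to 1")
        alpha = np.zeros((n + 1, n))
        alpha[:n] = np.log(group_rows[:, :n]) - np.log(group_rows[:, n:])
        alpha[n] = np.log(pre_row[:n]) - np.log(pre_row[n])
        return cls(n_groups=n, alpha=alpha, beta=np.zeros((n + 1, n)))


def score_linear(params: TransitionParams, origin: int, t: float) -> np.ndarray:
    """Score vector over the n+2 destination states for one origin and
    time (the linear score functions of the model)."""
    return params.score_vector(origin, t)


@dataclass(frozen=True)
class TransitionData:
    """Flattened usable transitions: per-row observation arrays."""

    space: StateSpace
    origin: np.ndarray  # row index 0..n (groups, then pre)
    cell: np.ndarray    # destination cell 0..n (group d, or n = reference)
    t: np.ndarray

    @property
    def n_obs(self) -> int:
        return len(self.origin)

    @classmethod
    def from_trajectories(
        cls, trajectories: Sequence[StateTrajectory], space: StateSpace
    ) -> "TransitionData":
        origins, cells, ts = [], [], []
        for tr in trajectories:
            for s in tr.usable_steps():
                if s.origin == space.post:
                    continue
                row = space.n_groups if s.origin == space.pre else s.origin
                if s.dest == space.reference_destination(s.origin):
                    cell = space.n_groups
                elif s.dest < space.n_groups:
                    cell = s.dest
                else:
                    raise ValueError(
                        f"structurally impossible step {space.label(s.origin)}"
                        f"->{space.label(s.dest)} in usable data"
                    )
                origins.append(row)
                cells.append(cell)
                ts.append(s.t)
        if not origins:
            raise ValueError("no usable transitions")
        return cls(space=space, origin=np.array(origins), cell=np.array(cells),
                   t=np.array(ts, dtype=float))


@dataclass
class TransitionModelFit:
    """Posterior draws of the transition model."""

    form: str                    # "time_dependent" | "constant"
    space: StateSpace
    draws: np.ndarray            # (n_draws, ndim)
    prior_sigma: float
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    def params(self, draw: int) -> TransitionParams:
        n = self.space.n_groups
        a = self.draws[draw, : (n + 1) * n].reshape(n + 1, n)
        if self.form == "time_dependent":
            b = self.draws[draw, (n + 1) * n:].reshape(n + 1, n)
        else:
            b = np.zeros((n + 1, n))
        return TransitionParams(n_groups=n, alpha=a, beta=b)

    def posterior_mean_params(self) -> TransitionParams:
        n = self.space.n_groups
        mean = self.draws.mean(axis=0)
        a = mean[: (n + 1) * n].reshape(n + 1, n)
        b = (mean[(n + 1) * n:].reshape(n + 1, n)
             if self.form == "time_dependent" else np.zeros((n + 1, n)))
        return TransitionParams(n_groups=n, alpha=a, beta=b)


def _unpack(theta: np.ndarray, n: int, time_dependent: bool):
    """theta (nw, ndim) -> alpha (nw, n+1, n), beta (nw, n+1, n)."""
    nw = theta.shape[0]
    a = theta[:, : (n + 1) * n].reshape(nw, n + 1, n)
    if time_dependent:
        b = theta[:, (n + 1) * n:].reshape(nw, n + 1, n)
    else:
        b = np.zeros_like(a)
    return a, b


def _log_likelihood(theta: np.ndarray, data: TransitionData, time_dependent: bool) -> np.ndarray:
    """Vectorized log-likelihood for a batch of parameter vectors."""
    n = data.space.n_groups
    a, b = _unpack(np.atleast_2d(theta), n, time_dependent)
    nw = a.shape[0]
    ll = np.zeros(nw)
    for row in range(n + 1):
        mask = data.origin == row
        if not mask.any():
            continue
        t = data.t[mask]
        c = data.cell[mask]
        scores = a[:, row, None, :] + b[:, row, None, :] * t[None, :, None]
        full = np.concatenate([scores, np.zeros((nw, len(t), 1))], axis=2)
        lse = logsumexp(full, axis=2)
        picked = full[:, np.arange(len(t)), c]
        ll += (picked - lse).sum(axis=1)
    return ll


def pointwise_log_likelihood(fit: TransitionModelFit, data: TransitionData) -> np.ndarray:
    """(n_draws, n_obs) log-likelihood matrix for WAIC."""
    n = fit.space.n_groups
    time_dep = fit.form == "time_dependent"
    a, b = _unpack(fit.draws, n, time_dep)
    nd = a.shape[0]
    out = np.empty((nd, data.n_obs))
    for row in range(n + 1):
        mask = data.origin == row
        if not mask.any():
            continue
        t = data.t[mask]
        c = data.cell[mask]
        scores = a[:, row, None, :] + b[:, row, None, :] * t[None, :, None]
        full = np.concatenate([scores, np.zeros((nd, len(t), 1))], axis=2)
        lse = logsumexp(full, axis=2)
        out[:, mask] = full[:, np.arange(len(t)), c] - lse
    return out


def fit_transition_model(
    trajectories: Sequence[StateTrajectory] | TransitionData,
    space: StateSpace | None = None,
    form: str = "time_dependent",
    prior_sigma: float = 10.0,
    n_walkers: int | None = None,
    n_steps: int = 2000,
    burn: int | None = None,
    thin: int = 4,
    max_draws: int = 4000,
    seed: int = 0,
    rhat_warn: float = 1.1,
) -> TransitionModelFit:
    """Sample the posterior of the multinomial transition model.

    ``form`` is ``time_dependent`` (intercept and slope per free cell) or
    ``constant`` (slopes fixed to 0).  Independent N(0, prior_sigma)
    priors on every free parameter.  Convergence is checked with split
    R-hat over walker groups; non-convergence triggers a warning, never a
    silent pass.
    """
    import emcee

    if form not in {"time_dependent", "constant"}:
        raise ValueError(f"unknown model form {form!r}")
    if isinstance(trajectories, TransitionData):
        data = trajectories
        space = data.space
    else:
        if space is None:
            raise ValueError("space is required when passing trajectories")
        data = TransitionData.from_trajectories(trajectories, space)
    n = space.n_groups
    time_dep = form == "time_dependent"
    ndim = (n + 1) * n * (2 if time_dep else 1)
    if n_walkers is None:
        n_walkers = max(2 * ndim + 2, 32)
    # bound the stored chain (walkers x steps x ndim float64) to ~1 GiB;
    # large state spaces otherwise exhaust memory before convergence matters
    cap = int(2**30 / (n_walkers * ndim * 8))
    if n_steps > max(cap, 200):
        warnings.warn(
            f"reducing sampler steps {n_steps} -> {max(cap, 200)} to bound "
            f"chain memory at ndim={ndim}, walkers={n_walkers}",
            RuntimeWarning,
        )
        n_steps = max(cap, 200)
    if burn is None:
        burn = n_steps // 2

    def log_prob(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        lp = -0.5 * (theta**2).sum(axis=1) / prior_sigma**2
        return lp + _log_likelihood(theta, data, time_dep)

    rng = np.random.default_rng(seed)
    p0 = rng.normal(scale=0.5, size=(n_walkers, ndim))
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(n_walkers, ndim, log_prob, vectorize=True,
                                    moves=moves)
    state = emcee.State(p0, random_state=np.random.RandomState(seed).get_state())
    sampler.run_mcmc(state, n_steps, progress=False)
    chain = sampler.get_chain(discard=burn, thin=thin)  # (steps, walkers, ndim)
    draws = chain.reshape(-1, ndim)
    if len(draws) > max_draws:  # bound downstream pointwise-likelihood memory
        keep = np.linspace(0, len(draws) - 1, max_draws).astype(int)
        draws = draws[keep]
    max_rhat = _split_rhat(chain)
    diagnostics = {
        "mean_acceptance_fraction": float(np.mean(sampler.acceptance_fraction)),
        "max_rhat": max_rhat,
        "n_steps": n_steps,
        "n_walkers": n_walkers,
        "n_obs": data.n_obs,
    }
    if max_rhat > rhat_warn:
        warnings.warn(
            f"transition-model sampler may not have converged: "
            f"max split R-hat = {max_rhat:.3f} "
            f"(acceptance {diagnostics['mean_acceptance_fraction']:.2f}); "
            f"consider more steps",
            RuntimeWarning,
        )
    assert np.all(np.isfinite(draws)), "non-finite posterior draws"
    return TransitionModelFit(form=form, space=space, draws=draws,
                              prior_sigma=prior_sigma, diagnostics=diagnostics)


def _split_rhat(chain: np.ndarray) -> float:
    """Max split R-hat over parameters, treating walker halves as chains."""
    steps, walkers, ndim = chain.shape
    if steps < 4:
        return float("nan")
    half = steps // 2
    segs = np.concatenate([chain[:half], chain[half: 2 * half]], axis=1)  # (half, 2w, ndim)
    m = segs.shape[1]
    means = segs.mean(axis=0)                    # (2w, ndim)
    variances = segs.var(axis=0, ddof=1)         # (2w, ndim)
    W = variances.mean(axis=0)
    B = half * means.var(axis=0, ddof=1)
    var_hat = (half - 1) / half * W + B / half
    with np.errstate(invalid="ignore", divide="ignore"):
        rhat = np.sqrt(var_hat / W)
    return float(np.nanmax(rhat))


def waic(fit: TransitionModelFit, data: TransitionData) -> float:
    """WAIC = -2 (lppd - p_waic), with p_waic the summed posterior
    variance of pointwise log-likelihoods."""
    L = pointwise_log_likelihood(fit, data)
    nd = L.shape[0]
    lppd = float((logsumexp(L, axis=0) - np.log(nd)).sum())
    p_waic = float(L.var(axis=0, ddof=1).sum())
    return -2.0 * (lppd - p_waic)


def fit_season_replicates(
    trajectories: Sequence[StateTrajectory],
    space: StateSpace,
    form: str = "time_dependent",
    seed: int = 0,
    **fit_kwargs,
) -> tuple[dict[str, TransitionModelFit], float]:
    """Treat seasons as independent temporal replicates: fit every season's
    trajectories separately (all parameters season-specific) and return the
    per-season fits plus the summed WAIC, comparable with a pooled fit's
    WAIC over the same transitions."""
    seasons = sorted({tr.season for tr in trajectories})
    fits: dict[str, TransitionModelFit] = {}
    total = 0.0
    for k, season in enumerate(seasons):
        subset = [tr for tr in trajectories if tr.season == season]
        data = TransitionData.from_trajectories(subset, space)
        fit = fit_transition_model(data, form=form, seed=seed + 101 * k, **fit_kwargs)
        fits[season] = fit
        total += waic(fit, data)
    return fits, total


def predict_curves(
    fit: TransitionModelFit, t_grid: Sequence[float] | None = None
) -> pd.DataFrame:
    """Posterior transition-probability curves.

    For every origin row (each group, plus the entry row conditioned on
    ``pre``) and every reachable destination: posterior mean and first and
    third quartiles of the transition probability on the time grid.
    """
    if t_grid is None:
        t_grid = np.linspace(0.0, 1.0, 21)
    t_grid = np.asarray(t_grid, dtype=float)
    space = fit.space
    n = space.n_groups
    time_dep = fit.form == "time_dependent"
    a, b = _unpack(fit.draws, n, time_dep)
    nd = a.shape[0]
    rows = []
    origins = list(range(n)) + [space.pre]
    for origin in origins:
        row = n if origin == space.pre else origin
        dests = space.destinations(origin)
        scores = a[:, row, None, :] + b[:, row, None, :] * t_grid[None, :, None]
        full = np.concatenate([scores, np.zeros((nd, len(t_grid), 1))], axis=2)
        probs = np.exp(full - logsumexp(full, axis=2, keepdims=True))
        assert np.allclose(probs.sum(axis=2), 1.0), "rows must be stochastic per draw"
        for c, dest in enumerate(dests):
            p = probs[:, :, c]
            for ti, t in enumerate(t_grid):
                rows.append({
                    "origin": space.label(origin), "destination": space.label(dest),
                    "t": float(t), "mean": float(p[:, ti].mean()),
                    "q1": float(np.quantile(p[:, ti], 0.25)),
                    "q3": float(np.quantile(p[:, ti], 0.75)),
                })
    return pd.DataFrame(rows)


def posterior_summary(fit: TransitionModelFit) -> pd.DataFrame:
    """Per-parameter posterior mean, sd, and central 95% interval."""
    n = fit.space.n_groups
    names = []
    for kind in (["alpha", "beta"] if fit.form == "time_dependent" else ["alpha"]):
        for row in range(n + 1):
            origin = fit.space.label(row if row < n else fit.space.pre)
            for d in range(n):
                names.append(f"{kind}[{origin}->G{d}]")
    q = np.quantile(fit.draws, [0.025, 0.975], axis=0)
    return pd.DataFrame({
        "parameter": names,
        "mean": fit.draws.mean(axis=0),
        "sd": fit.draws.std(axis=0, ddof=1),
        "q2.5": q[0],
        "q97.5": q[1],
    })
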