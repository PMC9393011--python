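"""Mk models for discrete regimes: likelihood, fitting, parsimony, mapping.

The Mk model is a continuous-time Markov chain on a small set of states
with instantaneous rate matrix Q (rows sum to zero).  Three structures are
supported for binary or multi-state characters:

* ``ER`` — equal rates: one rate for every transition (1 free parameter);
* ``ARD`` — all rates different: one rate per ordered state pair
  (s(s-1) free parameters);
* ``directional`` — a single permitted transition direction (1 free
  parameter); the reverse rate is structurally zero and the root is fixed
  in the source state.

Likelihoods use Felsenstein pruning with matrix exponentials per branch.
Stochastic character mapping samples complete character histories in
proportion to their probability: node states are drawn from their
conditional distributions (root first, then preorder), and each branch's
transition path is sampled conditional on its endpoint states by rejection
sampling, falling back to uniformization on branches where rejection is
inefficient.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize
from scipy.linalg import expm

from .trees import Node, PaintedTree, Phylo

__all__ = [
    "MkModel",
    "mk_loglik",
    "fit_mk",
    "fitch_parsimony",
    "stochastic_map",
]


@dataclass(frozen=True)
class MkModel:
    """A continuous-time Markov model of discrete character evolution."""

    states: tuple[str, ...]
    Q: np.ndarray
    root_prior: np.ndarray

    def __post_init__(self):
        s = len(self.states)
        Q = np.asarray(self.Q, dtype=float)
        if Q.shape != (s, s):
            raise ValueError("Q must be square over the state set")
        if np.abs(Q.sum(axis=1)).max() > 1e-12:
            raise ValueError("rows of Q must sum to zero")
        off = Q[~np.eye(s, dtype=bool)]
        if (off < 0).any():
            raise ValueError("off-diagonal rates must be >= 0")
        prior = np.asarray(self.root_prior, dtype=float)
        if prior.shape != (s,) or abs(prior.sum() - 1.0) > 1e-9 or (prior < 0).any():
            raise ValueError("root prior must be a probability vector over states")
        object.__setattr__(self, "Q", Q)
        object.__setattr__(self, "root_prior", prior)

    def index(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise KeyError(f"state {state!r} not in model states {self.states}")

    @classmethod
    def er(cls, states: Sequence[str], rate: float,
           root_prior: np.ndarray | None = None) -> "MkModel":
        """Equal-rates model; ``rate`` is each pairwise transition rate."""
        s = len(states)
        Q = np.full((s, s), rate, dtype=float)
        np.fill_diagonal(Q, -(s - 1) * rate)
        prior = np.full(s, 1.0 / s) if root_prior is None else root_prior
        return cls(tuple(states), Q, prior)


def _tip_indicator(model: MkModel, state: str) -> np.ndarray:
    v = np.zeros(len(model.states))
    v[model.index(state)] = 1.0
    return v


def _edge_transition_probs(model: MkModel, tree: Phylo) -> dict[Node, np.ndarray]:
    cache: dict[float, np.ndarray] = {}
    out: dict[Node, np.ndarray] = {}
    for node in tree.edges():
        t = node.length
        if t not in cache:
            cache[t] = expm(model.Q * t)
        out[node] = cache[t]
    return out


def _partials(
    tree: Phylo, tips: Mapping[str, str], model: MkModel,
    P: dict[Node, np.ndarray],
) -> tuple[dict[Node, np.ndarray], float]:
    """Pruning partials (conditional likelihoods) with log scaling.

    ``partials[v][s]`` is proportional to the probability of the tip data
    below v given state s at v; the returned scalar is the accumulated
    log of the scaling factors.
    """
    missing = [lb for lb in tree.tip_labels if lb not in tips]
    if missing:
        raise KeyError(f"no state observed for tips: {missing}")
    partials: dict[Node, np.ndarray] = {}
    logscale = 0.0
    for node in tree.postorder():
        if node.is_tip:
            partials[node] = _tip_indicator(model, tips[node.label])
            continue
        L = np.ones(len(model.states))
        for child in node.children:
            L = L * (P[child] @ partials[child])
        m = L.max()
        if m > 0:
            L = L / m
            logscale += math.log(m)
        partials[node] = L
    return partials, logscale


def mk_loglik(tree: Phylo, tips: Mapping[str, str], model: MkModel) -> float:
    """Log-likelihood of tip states via Felsenstein pruning.

    Impossible data (e.g. discordant tips under a zero rate) return
    ``-inf`` rather than raising.
    """
    P = _edge_transition_probs(model, tree)
    partials, logscale = _partials(tree, tips, model, P)
    lik = float(model.root_prior @ partials[tree.root])
    if lik <= 0:
        return -math.inf
    return math.log(lik) + logscale


# ---------------------------------------------------------------------------
# ML fitting
# ---------------------------------------------------------------------------


def _structure_Q(structure: str, states: tuple[str, ...], rates: np.ndarray,
                 direction: tuple[str, str] | None) -> np.ndarray:
    s = len(states)
    Q = np.zeros((s, s))
    if structure == "ER":
        Q[:] = rates[0]
    elif structure == "ARD":
        k = 0
        for i in range(s):
            for j in range(s):
                if i != j:
                    Q[i, j] = rates[k]
                    k += 1
    elif structure == "directional":
        i = states.index(direction[0])
        j = states.index(direction[1])
        Q[i, j] = rates[0]
    else:
        raise ValueError("structure must be 'ER', 'ARD' or 'directional'")
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _n_rates(structure: str, s: int) -> int:
    return {"ER": 1, "ARD": s * (s - 1), "directional": 1}[structure]


def fit_mk(
    tree: Phylo,
    tips: Mapping[str, str],
    structure: str = "ER",
    root_prior: str | Sequence[float] = "flat",
    direction: tuple[str, str] | None = None,
    states: Sequence[str] | None = None,
) -> tuple[MkModel, float, int, float]:
    """Fit an Mk model by maximum likelihood.

    Returns ``(model, loglik, df, aic)`` with ``df`` the number of free
    rates and ``aic = 2 df - 2 logL``.

    ``root_prior`` may be ``"flat"`` (default for ER/ARD), ``"fixed:<state>"``
    to condition the root on a state, or an explicit probability vector.
    The directional structure requires ``direction=(source, target)`` and
    defaults its root prior to fixed at the source state (the ancestral
    condition it hypothesizes).
    """
    if states is None:
        states = sorted(set(tips.values()))
    states = tuple(states)
    s = len(states)
    if s < 2:
        warnings.warn("single observed state: the ML transition rate is 0")
    if structure == "directional":
        if direction is None:
            if s != 2:
                raise ValueError(
                    "directional structure needs direction=(source, target)"
                )
            direction = (states[0], states[1])
        if root_prior == "flat":
            root_prior = f"fixed:{direction[0]}"

    if isinstance(root_prior, str):
        if root_prior == "flat":
            prior = np.full(s, 1.0 / s)
        elif root_prior.startswith("fixed:"):
            prior = np.zeros(s)
            prior[states.index(root_prior.split(":", 1)[1])] = 1.0
        else:
            raise ValueError(f"unknown root prior policy {root_prior!r}")
    else:
        prior = np.asarray(root_prior, dtype=float)

    df = _n_rates(structure, s)
    # initial rate: parsimony changes per unit tree length
    _, changes, _ = fitch_parsimony(tree, tips)
    total = tree.total_length
    init = max(changes, 0.5) / total

    def build(theta: np.ndarray) -> MkModel:
        return MkModel(states, _structure_Q(structure, states, np.exp(theta),
                                            direction), prior)

    def nll(theta: np.ndarray) -> float:
        ll = mk_loglik(tree, tips, build(theta))
        return -ll if np.isfinite(ll) else 1e10

    theta0 = np.full(df, math.log(init))
    res = optimize.minimize(nll, theta0, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10,
                                     "maxfev": 2000 * df})
    if df == 1:
        # 1-D polish on the single log rate; skipped if the surface is too
        # flat to bracket (e.g. degenerate single-state data)
        grid = res.x[0] + np.linspace(-0.5, 0.5, 11)
        vals = [nll(np.array([g])) for g in grid]
        g0 = grid[int(np.argmin(vals))]
        try:
            r2 = optimize.minimize_scalar(
                lambda g: nll(np.array([g])), bracket=(g0 - 0.25, g0, g0 + 0.25)
            )
            if r2.fun < res.fun:
                res.x, res.fun = np.array([r2.x]), r2.fun
        except ValueError:
            pass
    model = build(res.x)
    ll = -res.fun
    return model, ll, df, 2.0 * df - 2.0 * ll


# ---------------------------------------------------------------------------
# Parsimony
# ---------------------------------------------------------------------------


def fitch_parsimony(
    tree: Phylo, tips: Mapping[str, str]
) -> tuple[dict[Node, str], int, list[Node]]:
    """One most-parsimonious ancestral reconstruction (unit change cost).

    Uses the unit-cost dynamic program (valid for polytomies as well as
    binary trees).  Ambiguities resolve toward the parent's state — the
    delayed-transformation flavor — then by sorted state order at the
    root.  Returns ``(assignment, change_count, changed_edges)`` where
    ``changed_edges`` lists the child nodes of branches on which the state
    changes.
    """
    states = sorted(set(tips.values()))
    sidx = {st: i for i, st in enumerate(states)}
    INF = float("inf")
    cost: dict[Node, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_tip:
            v = np.full(len(states), INF)
            v[sidx[tips[node.label]]] = 0.0
            cost[node] = v
        else:
            v = np.zeros(len(states))
            for child in node.children:
                c = cost[child]
                best = c.min()
                v += np.minimum(c, best + 1.0)
            cost[node] = v

    assignment: dict[Node, str] = {}
    for node in tree.preorder():
        c = cost[node]
        if node.is_root:
            choice = int(np.argmin(c))  # argmin takes the first == sorted order
        else:
            p = sidx[assignment[node.parent]]
            local = c + 1.0
            local[p] = c[p]  # staying with the parent state costs nothing extra
            best = local.min()
            if local[p] == best:
                choice = p
            else:
                choice = int(np.argmin(local))
        assignment[node] = states[choice]

    changed = [n for n in tree.edges() if assignment[n] != assignment[n.parent]]
    return assignment, int(cost[tree.root].min()), changed


# ---------------------------------------------------------------------------
# Stochastic character mapping
# ---------------------------------------------------------------------------


def _sample_path_rejection(
    rng: np.random.Generator, Q: np.ndarray, a: int, b: int, t: float,
    max_tries: int,
) -> list[tuple[int, float]] | None:
    """Forward-simulate from state a for time t; accept when it ends in b.

    Returns the path as (state, duration) pairs, or None if no acceptance
    within ``max_tries``.
    """
    s = Q.shape[0]
    exit_rates = -np.diag(Q)
    for _ in range(max_tries):
        path: list[tuple[int, float]] = []
        state, remaining = a, t
        while True:
            lam = exit_rates[state]
            wait = rng.exponential(1.0 / lam) if lam > 0 else math.inf
            if wait >= remaining:
                path.append((state, remaining))
                break
            path.append((state, wait))
            remaining -= wait
            probs = Q[state].copy()
            probs[state] = 0.0
            probs = probs / probs.sum()
            state = int(rng.choice(s, p=probs))
        if state == b:
            return path
    return None


def _sample_path_uniformization(
    rng: np.random.Generator, Q: np.ndarray, P_t: np.ndarray,
    a: int, b: int, t: float, max_jumps: int = 10_000,
) -> list[tuple[int, float]]:
    """Endpoint-conditioned path by uniformization.

    The chain is embedded in a Poisson process of rate mu = max_i(-Q_ii)
    with jump matrix R = I + Q/mu; the number of (possibly virtual) jumps
    is drawn from its conditional distribution given the endpoints, the
    jump states by a backward pass over powers of R, the jump times as
    uniform order statistics; virtual self-jumps are then discarded.
    """
    s = Q.shape[0]
    mu = float(max(-np.diag(Q)))
    if mu == 0.0:
        if a != b:
            raise RuntimeError("impossible endpoints under a zero rate matrix")
        return [(a, t)]
    R = np.eye(s) + Q / mu
    p_ab = P_t[a, b]
    if p_ab <= 0:
        raise RuntimeError("endpoint pair has zero probability")
    # conditional number of jumps
    Rpow = [np.eye(s)]
    weights = []
    logpois = -mu * t
    total = 0.0
    n = 0
    u = rng.uniform() * p_ab
    while True:
        w = math.exp(logpois) * Rpow[n][a, b]
        total += w
        if total >= u or n >= max_jumps:
            break
        n += 1
        logpois += math.log(mu * t) - math.log(n)
        Rpow.append(Rpow[-1] @ R)
    # jump states by backward sampling
    seq = [a]
    for k in range(1, n + 1):
        state = seq[-1]
        probs = R[state] * Rpow[n - k][:, b]
        ssum = probs.sum()
        if ssum <= 0:
            raise RuntimeError("numerical failure in uniformization sampling")
        seq.append(int(rng.choice(s, p=probs / ssum)))
    times = np.sort(rng.uniform(0.0, t, size=n))
    # assemble durations, dropping virtual jumps
    path: list[tuple[int, float]] = []
    prev_time = 0.0
    for state, jump_time in zip(seq[:-1], times):
        dur = float(jump_time - prev_time)
        if path and path[-1][0] == state:
            path[-1] = (state, path[-1][1] + dur)
        elif dur >= 0:
            path.append((state, dur))
        prev_time = float(jump_time)
    last = seq[-1] if n > 0 else a
    dur = t - prev_time
    if path and path[-1][0] == last:
        path[-1] = (last, path[-1][1] + dur)
    else:
        path.append((last, dur))
    return [(st, d) for st, d in path if d > 0] or [(b, t)]


def stochastic_map(
    tree: Phylo,
    tips: Mapping[str, str],
    model: MkModel,
    n_maps: int = 100,
    seed=None,
    rejection_tries: int = 200,
) -> list[PaintedTree]:
    """Sample complete character histories in proportion to probability.

    Each map is a painted tree whose tipmost segment states equal the
    observed tip states.  Deterministic given ``seed``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    P = _edge_transition_probs(model, tree)
    partials, _ = _partials(tree, tips, model, P)
    root_weights = model.root_prior * partials[tree.root]
    if root_weights.sum() <= 0:
        raise ValueError("data have zero likelihood under the model")
    root_probs = root_weights / root_weights.sum()
    s = len(model.states)

    maps: list[PaintedTree] = []
    for _ in range(n_maps):
        out = tree.copy()
        node_state: dict[Node, int] = {}
        pairing = dict(zip(out.preorder(), tree.preorder()))
        for node in out.preorder():
            orig = pairing[node]
            if node.is_root:
                node_state[node] = int(rng.choice(s, p=root_probs))
                continue
            pstate = node_state[node.parent]
            w = P[orig][pstate] * partials[orig]
            node_state[node] = int(rng.choice(s, p=w / w.sum()))
            a, b = pstate, node_state[node]
            t = node.length
            if t == 0:
                node.segments = [(model.states[b], 0.0)]
                continue
            path = _sample_path_rejection(rng, model.Q, a, b, t, rejection_tries)
            if path is None:
                path = _sample_path_uniformization(rng, model.Q, P[orig], a, b, t)
            node.segments = [(model.states[st], d) for st, d in path]
        maps.append(PaintedTree(out.root))
    return maps
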