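"""Simulators: pure-birth trees, Mk regime histories, and bivariate BM data.

These generate the inputs of the simulation experiments: Yule (pure-birth)
trees; three-state regime histories evolved under an equal-rates Mk
process and accepted only when every state reaches a minimum number of
tips; generating parameters with log rates drawn from a standard normal
and correlations from Uniform(-1, 1); and bivariate Brownian tip data
simulated segment by segment down the painted tree.

All simulators are deterministic given their seed (an integer or a
``numpy.random.Generator``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .models import ModelSpec, RateMatrix
from .trees import Node, PaintedTree, Phylo

__all__ = [
    "SimulationDesign",
    "RegimeHistoryError",
    "sim_pure_birth",
    "sim_regime_history",
    "draw_generating_params",
    "sim_mvbm",
]


class RegimeHistoryError(RuntimeError):
    """Raised when no acceptable regime history is found within the cap."""


@dataclass(frozen=True)
class SimulationDesign:
    """Conditions for one simulation experiment.

    Defaults follow the simulation study: 100-taxon pure-birth trees,
    three regimes each observed in at least 20 tips, log rates from
    N(0, 1), correlations from Uniform(-1, 1).
    """

    n_taxa: int = 100
    n_regimes: int = 3
    min_tips: int = 20
    birth_rate: float = 1.0
    #: expected regime transitions per unit tree height (the Mk departure
    #: rate is this divided by the realized tree height)
    transitions_per_height: float = 2.0
    max_rejects: int = 10_000

    def __post_init__(self):
        if self.n_taxa < self.n_regimes * self.min_tips:
            raise ValueError(
                "infeasible design: n_taxa < n_regimes * min_tips"
            )


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def sim_pure_birth(n_taxa: int, birth_rate: float = 1.0, seed=None) -> Phylo:
    """Simulate a Yule (pure-birth) tree with ``n_taxa`` tips.

    Waiting times between speciation events are exponential with rate
    ``birth_rate * (current number of lineages)``; the lineage that splits
    is chosen uniformly.  After the last split, tips are extended by one
    further exponential waiting time, so the tree is ultrametric.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be > 0")
    rng = _rng(seed)

    root = Node()
    # birth time (depth) of each open lineage's parent node
    active: list[tuple[Node, float]] = []
    for _ in range(2):
        child = Node()
        root.add_child(child)
        active.append((child, 0.0))
    t = 0.0
    counter = 0
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        i = rng.integers(len(active))
        node, born = active.pop(i)
        node.length = t - born
        for _ in range(2):
            child = Node()
            node.add_child(child)
            active.append((child, t))
    t += rng.exponential(1.0 / (birth_rate * len(active)))
    for node, born in active:
        node.length = t - born
        counter += 1
        node.label = f"t{counter}"
    return Phylo(root)


def sim_regime_history(
    tree: Phylo,
    n_states: int = 3,
    rate: float | None = None,
    min_tips: int = 20,
    max_rejects: int = 10_000,
    seed=None,
    state_labels: Sequence[str] | None = None,
) -> PaintedTree:
    """Evolve an equal-rates Mk regime history; reject until all states
    are observed in at least ``min_tips`` tips.

    ``rate`` is the total departure rate per unit branch length (so the
    expected number of transitions on the tree is ``rate * total length``);
    when ``None`` it defaults to two expected transitions per unit of tree
    height.  The root state is drawn uniformly.  Raises
    :class:`RegimeHistoryError` after ``max_rejects`` rejected histories.
    """
    rng = _rng(seed)
    if state_labels is None:
        state_labels = [str(i + 1) for i in range(n_states)]
    if len(state_labels) != n_states:
        raise ValueError("state_labels length must equal n_states")
    if tree.n_tips < n_states * min_tips:
        raise ValueError("infeasible: fewer tips than n_states * min_tips")
    if rate is None:
        rate = 2.0 / tree.height
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if n_states == 1:
        rate = 0.0  # nowhere to jump

    edges = tree.edges()
    for attempt in range(max_rejects):
        painted = tree.copy()
        states: dict[Node, int] = {painted.root: int(rng.integers(n_states))}
        counts = np.zeros(n_states, dtype=int)
        for node in painted.preorder():
            if node.is_root:
                continue
            state = states[node.parent]
            segments: list[tuple[str, float]] = []
            remaining = node.length
            pos = 0.0
            while True:
                wait = rng.exponential(1.0 / rate) if rate > 0 else math.inf
                if wait >= remaining:
                    segments.append((state_labels[state], remaining))
                    break
                segments.append((state_labels[state], wait))
                remaining -= wait
                # equal-rates: jump to one of the other states uniformly
                jump = int(rng.integers(n_states - 1))
                state = jump if jump < state else jump + 1
            if node.length == 0:
                segments = [(state_labels[state], 0.0)]
            node.segments = [(s, d) for s, d in segments if d > 0] or segments[-1:]
            states[node] = state
            if node.is_tip:
                counts[state] += 1
        if (counts >= min_tips).all():
            return PaintedTree(painted.root)
    raise RegimeHistoryError(
        f"no history with >= {min_tips} tips per state in {max_rejects} "
        "attempts; consider a different transition rate"
    )


def draw_generating_params(
    spec: ModelSpec, seed=None
) -> dict[str, RateMatrix]:
    """Draw generating parameters for one simulated dataset.

    Each free rate slot gets ``sigma^2 = exp(z)`` with ``z ~ N(0, 1)``;
    each free correlation slot gets ``r ~ Uniform(-1, 1)``.  Slots shared
    across regimes are drawn once and replicated.
    """
    rng = _rng(seed)
    K = spec.K

    def draws(varies: bool, sample) -> np.ndarray:
        if varies:
            return np.asarray([sample() for _ in range(K)])
        return np.repeat(sample(), K)

    s1 = np.exp(draws(spec.rate1_varies, lambda: rng.normal()))
    s2 = np.exp(draws(spec.rate2_varies, lambda: rng.normal()))
    r = draws(spec.corr_varies, lambda: rng.uniform(-1.0, 1.0))
    return {
        g: RateMatrix(s1[i], s2[i], float(np.clip(r[i], -1 + 1e-12, 1 - 1e-12)))
        for i, g in enumerate(spec.regimes)
    }


def sim_mvbm(
    tree: PaintedTree,
    Rs: Mapping[str, RateMatrix],
    roots: tuple[float, float] = (0.0, 0.0),
    seed=None,
) -> pd.DataFrame:
    """Simulate bivariate Brownian tip data on a painted tree.

    Each branch segment of duration t in regime k contributes a bivariate
    normal increment with covariance ``t * R_k``; a tip's value is the sum
    of increments along its root-to-tip path plus the root states.
    Returns a trait table indexed by taxon (columns ``x1``, ``x2``).
    """
    rng = _rng(seed)
    missing = [g for g in tree.regimes if g not in Rs]
    if missing:
        raise KeyError(f"no rate matrix for regimes: {missing}")
    chol = {g: np.linalg.cholesky(Rs[g].matrix) for g in tree.regimes}

    values: dict[Node, np.ndarray] = {tree.root: np.asarray(roots, dtype=float)}
    rows: dict[str, np.ndarray] = {}
    for node in tree.preorder():
        if node.is_root:
            continue
        val = values[node.parent].copy()
        for state, dur in node.segments:
            if dur > 0:
                val = val + math.sqrt(dur) * (chol[state] @ rng.normal(size=2))
        values[node] = val
        if node.is_tip:
            rows[node.label] = val
    return pd.DataFrame.from_dict(rows, orient="index", columns=["x1", "x2"]).loc[
        tree.tip_labels
    ]
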