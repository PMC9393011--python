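"""Seeded simulation studies and the stochastic-map averaging workflow.

Two simulation experiments characterize the method:

* **Model selection** — for each of the eight generating models, simulate
  datasets on pure-birth trees carrying three-state regime histories
  (every state observed in a minimum number of tips), fit all eight
  models, rank them by AIC, and tabulate how often the generating model
  ranks best / second / third / lower, together with the mean Akaike
  weight each fitted model receives under each generating model.

* **Parameter recovery** — simulate under one model, fit that same model,
  and report per-slot correlations between generating and estimated
  values (rates compared on the log scale) and mean differences (bias).

The stochastic-map workflow handles an uncertain regime history: fit
ER/ARD/directional Mk models to the discrete character, sample stochastic
maps under the AIC-best one, fit all eight trait models to every map,
tabulate rank frequencies and mean weights across maps, order models by a
rank-choice vote, and report per-model parameter estimates averaged across
maps with weights proportional to each map's maximized trait likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fitting import MODEL_ORDER, ComparisonTable, FitResult, fit_hierarchy, fit_model
from .likelihood import SingularCovarianceError
from .mk import MkModel, fit_mk, stochastic_map
from .models import ModelSpec, RateMatrix
from .simulate import (
    RegimeHistoryError,
    SimulationDesign,
    draw_generating_params,
    sim_mvbm,
    sim_pure_birth,
    sim_regime_history,
)
from .trees import PaintedTree, Phylo, shared_time_matrices

__all__ = [
    "ModelRecoveryTable",
    "RecoveryStats",
    "SimmapAverageResult",
    "model_selection_study",
    "parameter_recovery_study",
    "simmap_average_workflow",
]

RANK_BINS = ("best", "2nd", "3rd", ">=4th")


@dataclass
class ModelRecoveryTable:
    """Rank fractions of the generating model and mean-weight matrix."""

    rank_fractions: pd.DataFrame  # rows: generating model, cols: RANK_BINS
    mean_weights: pd.DataFrame  # rows: generating model, cols: fitted model
    n_replicates: int
    n_failures: int
    seed: int | None

    @property
    def best_or_second(self) -> float:
        """Overall fraction of replicates with the generating model in the
        top two by AIC."""
        return float(
            self.rank_fractions[["best", "2nd"]].to_numpy().sum(axis=1).mean()
        )


@dataclass
class RecoveryStats:
    """Per-slot precision (correlation) and bias (mean difference)."""

    correlations: dict[str, float]
    mean_differences: dict[str, float]
    generating: pd.DataFrame  # one row per replicate, one column per slot
    estimated: pd.DataFrame
    n_replicates: int
    seed: int | None


def _simulate_dataset(code: str, design: SimulationDesign, rng: np.random.Generator):
    """One tree + regime history + generating parameters + tip data."""
    tree = sim_pure_birth(design.n_taxa, design.birth_rate, rng)
    painted = sim_regime_history(
        tree,
        design.n_regimes,
        rate=design.transitions_per_height / tree.height,
        min_tips=design.min_tips,
        max_rejects=design.max_rejects,
        seed=rng,
    )
    spec = ModelSpec(code, tuple(painted.regimes))
    Rs = draw_generating_params(spec, rng)
    traits = sim_mvbm(painted, Rs, seed=rng)
    return painted, spec, Rs, traits


def model_selection_study(
    design: SimulationDesign = SimulationDesign(),
    n_trees: int = 40,
    seed: int | None = None,
    n_starts: int = 2,
    models: Sequence[str] = MODEL_ORDER,
) -> ModelRecoveryTable:
    """Simulate under every model and score AIC model selection.

    For each of ``n_trees`` replicates and each generating model, a fresh
    tree and regime history are simulated, data are generated, all eight
    models are fitted and ranked by AIC.  Individual fit failures are
    counted and skipped.
    """
    rng = np.random.default_rng(seed)
    ranks = {code: np.zeros(4) for code in models}
    weights = {code: np.zeros(len(models)) for code in models}
    counts = {code: 0 for code in models}
    failures = 0
    for _ in range(n_trees):
        # one tree and one accepted regime history serve all generating models
        tree = sim_pure_birth(design.n_taxa, design.birth_rate, rng)
        painted = sim_regime_history(
            tree,
            design.n_regimes,
            rate=design.transitions_per_height / tree.height,
            min_tips=design.min_tips,
            max_rejects=design.max_rejects,
            seed=rng,
        )
        for code in models:
            spec = ModelSpec(code, tuple(painted.regimes))
            Rs = draw_generating_params(spec, rng)
            traits = sim_mvbm(painted, Rs, seed=rng)
            try:
                table = fit_hierarchy(
                    painted, traits, models=list(models), n_starts=n_starts,
                    seed=int(rng.integers(2**31)),
                )
                rank = table.rank_of(code)
            except (SingularCovarianceError, ValueError, RegimeHistoryError) as exc:
                warnings.warn(f"replicate failed for generating model {code}: {exc}")
                failures += 1
                continue
            ranks[code][min(rank, 4) - 1] += 1
            weights[code] += np.array([table.weight_of(c) for c in models])
            counts[code] += 1
    rank_fractions = pd.DataFrame(
        {code: ranks[code] / max(counts[code], 1) for code in models},
        index=RANK_BINS,
    ).T
    mean_weights = pd.DataFrame(
        {code: weights[code] / max(counts[code], 1) for code in models},
        index=list(models),
    ).T
    return ModelRecoveryTable(rank_fractions, mean_weights, n_trees, failures, seed)


def parameter_recovery_study(
    code: str,
    design: SimulationDesign = SimulationDesign(),
    n_trees: int = 40,
    seed: int | None = None,
    n_starts: int = 2,
) -> RecoveryStats:
    """Simulate and re-fit the same model; measure precision and bias.

    Rates are compared on the log scale (so mean differences read as
    proportional errors); correlations are compared directly.  Slots are
    keyed ``sigma2_1[k]``/``sigma2_2[k]``/``r[k]`` by regime index (1-based
    in order of appearance), collapsing to a single shared slot when the
    model holds them common.
    """
    rng = np.random.default_rng(seed)
    gen_rows, est_rows = [], []
    while len(gen_rows) < n_trees:
        painted, spec, Rs, traits = _simulate_dataset(code, design, rng)
        try:
            fit = fit_model(painted, traits, spec, n_starts=n_starts,
                            seed=int(rng.integers(2**31)))
        except (SingularCovarianceError, ValueError) as exc:
            warnings.warn(f"replicate failed: {exc}")
            continue

        def row(rates: Mapping[str, RateMatrix]) -> dict[str, float]:
            out: dict[str, float] = {}
            for trait_i, varies in ((1, spec.rate1_varies), (2, spec.rate2_varies)):
                slots = spec.regimes if varies else spec.regimes[:1]
                for k, g in enumerate(slots, start=1):
                    val = getattr(rates[g], f"sigma2_{trait_i}")
                    key = f"log_sigma2_{trait_i}[{k}]" if varies else f"log_sigma2_{trait_i}"
                    out[key] = float(np.log(val))
            slots = spec.regimes if spec.corr_varies else spec.regimes[:1]
            for k, g in enumerate(slots, start=1):
                key = f"r[{k}]" if spec.corr_varies else "r"
                out[key] = rates[g].r
            return out

        gen_rows.append(row(Rs))
        est_rows.append(row(fit.rates))
    gen = pd.DataFrame(gen_rows)
    est = pd.DataFrame(est_rows)
    corr = {c: float(np.corrcoef(gen[c], est[c])[0, 1]) for c in gen.columns}
    bias = {c: float((est[c] - gen[c]).mean()) for c in gen.columns}
    return RecoveryStats(corr, bias, gen, est, n_trees, seed)


# ---------------------------------------------------------------------------
# Stochastic-map averaging
# ---------------------------------------------------------------------------


@dataclass
class SimmapAverageResult:
    """Output of the stochastic-map averaging workflow."""

    mk_table: pd.DataFrame  # structure, logL, df, AIC per Mk model
    best_mk: str
    rank_frequencies: pd.DataFrame  # rows: rank 1..m, cols: model code
    mean_weights: pd.Series  # mean Akaike weight per model across maps
    vote_order: list[str]  # models ordered by the rank-choice vote
    averaged: pd.DataFrame  # likelihood-weighted parameter means per model
    averaged_variance: pd.DataFrame  # likelihood-weighted parameter variances
    n_maps: int
    n_failed_fits: int
    seed: int | None


def _model_average(
    fits: list[FitResult], flat_weights: bool
) -> tuple[pd.Series, pd.Series, float]:
    """Average one model's estimates across maps.

    Weights are proportional to each map's maximized trait likelihood for
    this model (normalized within the model), which up-weights regime
    histories that make the continuous data more probable; ``flat_weights``
    reproduces a plain mean.
    """
    lls = np.array([f.loglik for f in fits])
    if flat_weights:
        w = np.full(len(fits), 1.0 / len(fits))
    else:
        w = np.exp(lls - lls.max())
        w = w / w.sum()
    rows = []
    for f in fits:
        row: dict[str, float] = {}
        for g in f.spec.regimes:
            R = f.rates[g]
            row[f"sigma2_1[{g}]"] = R.sigma2_1
            row[f"sigma2_2[{g}]"] = R.sigma2_2
            row[f"r[{g}]"] = R.r
        row["a1"], row["a2"] = f.roots
        rows.append(row)
    df = pd.DataFrame(rows)
    mean = df.mul(w, axis=0).sum()
    var = (df - mean).pow(2).mul(w, axis=0).sum()
    return mean, var, float(w.sum())


def simmap_average_workflow(
    tree: Phylo,
    tips: Mapping[str, str],
    traits: pd.DataFrame,
    n_maps: int = 100,
    seed: int | None = None,
    n_starts: int = 2,
    mk_structures: Sequence[str] = ("ER", "ARD", "directional"),
    direction: tuple[str, str] | None = None,
    flat_weights: bool = False,
) -> SimmapAverageResult:
    """Average the eight-model comparison over stochastic character maps.

    Steps: (i) fit the candidate Mk models and pick the AIC-best; (ii)
    draw ``n_maps`` stochastic maps under it; (iii) fit all eight trait
    models to every map; (iv) tabulate per-model rank frequencies and
    mean Akaike weights across maps; (v) order models by rank-choice vote
    (most first-place finishes, ties broken by second-place, and so on);
    (vi) average each model's parameters across maps with weights
    proportional to the map's maximized trait likelihood.
    """
    rng = np.random.default_rng(seed)
    states = sorted(set(tips.values()))
    rows = []
    fits_mk = {}
    for structure in mk_structures:
        if structure == "directional" and direction is None and len(states) != 2:
            continue
        model, ll, df, aic_val = fit_mk(tree, tips, structure, direction=direction)
        fits_mk[structure] = model
        rows.append({"structure": structure, "logL": ll, "df": df, "AIC": aic_val})
    mk_table = pd.DataFrame(rows).set_index("structure")
    best_mk = mk_table["AIC"].idxmin()

    maps = stochastic_map(tree, tips, fits_mk[best_mk], n_maps=n_maps, seed=rng)

    per_model_fits: dict[str, list[FitResult]] = {c: [] for c in MODEL_ORDER}
    rank_counts = pd.DataFrame(
        0.0, index=range(1, len(MODEL_ORDER) + 1), columns=list(MODEL_ORDER)
    )
    weight_sums = pd.Series(0.0, index=list(MODEL_ORDER))
    n_tables = 0
    n_failed = 0
    for painted in maps:
        try:
            table = fit_hierarchy(painted, traits, n_starts=n_starts,
                                  seed=int(rng.integers(2**31)))
        except (SingularCovarianceError, ValueError) as exc:
            warnings.warn(f"map skipped: {exc}")
            n_failed += 1
            continue
        n_tables += 1
        for rank, f in enumerate(table.ranked(), start=1):
            rank_counts.loc[rank, f.spec.code] += 1
        for code in MODEL_ORDER:
            weight_sums[code] += table.weight_of(code)
            per_model_fits[code].append(
                next(f for f in table.fits if f.spec.code == code)
            )
        n_failed += len(table.failed)
    if n_tables == 0:
        raise RuntimeError("every stochastic map failed to fit")
    rank_freq = rank_counts / n_tables
    mean_w = weight_sums / n_tables

    vote_order = sorted(
        MODEL_ORDER,
        key=lambda c: tuple(-rank_freq.loc[k, c] for k in rank_freq.index),
    )

    means, variances = {}, {}
    for code in MODEL_ORDER:
        if per_model_fits[code]:
            m, v, _ = _model_average(per_model_fits[code], flat_weights)
            means[code], variances[code] = m, v
    averaged = pd.DataFrame(means).T.loc[vote_order]
    averaged_var = pd.DataFrame(variances).T.loc[vote_order]
    return SimmapAverageResult(
        mk_table, best_mk, rank_freq, mean_w, vote_order, averaged,
        averaged_var, n_maps, n_failed, seed,
    )
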