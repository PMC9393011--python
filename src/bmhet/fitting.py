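"""Maximum-likelihood fitting and information-theoretic model comparison.

Each of the eight models is fitted by numerical optimization in the
unconstrained parameterization (log rates, atanh correlations), with the
two root states profiled out analytically.  Fits are compared with
AIC = 2k - 2 logL and Akaike weights w_i = exp(-dAIC_i/2) / sum_j
exp(-dAIC_j/2), and nested pairs can be tested with a likelihood-ratio
chi-square test.

Optimization strategy: the first start is the analytic single-regime fit
(the pooled GLS estimate of one rate matrix) replicated across regimes;
further starts jitter it.  Each start runs a quasi-Newton (L-BFGS-B)
search, falling back to a derivative-free simplex polish if it reports
failure.  ``fit_hierarchy`` additionally warm-starts every model from the
best fit of each model nested directly below it, which both speeds
convergence and keeps the maximized log-likelihoods monotone along the
hierarchy.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .likelihood import SingularCovarianceError, _loglik_from_V, assemble_covariance, trait_matrix
from .models import MODEL_CODES, ModelSpec, RateMatrix, all_specs
from .trees import PaintedTree, SharedTimeMatrices, shared_time_matrices

__all__ = [
    "FitResult",
    "ComparisonTable",
    "aic",
    "akaike_weights",
    "fit_model",
    "fit_hierarchy",
    "likelihood_ratio_test",
]

#: order in which models are reported and used for tie-breaking
MODEL_ORDER = tuple(MODEL_CODES)


def aic(loglik: float, k: int) -> float:
    """Akaike information criterion, 2k - 2 logL."""
    return 2.0 * k - 2.0 * loglik


def akaike_weights(aics: Sequence[float]) -> np.ndarray:
    """Akaike weights from a set of AIC scores (non-finite entries get 0)."""
    a = np.asarray(aics, dtype=float)
    finite = np.isfinite(a)
    if not finite.any():
        raise ValueError("no finite AIC values")
    rel = np.where(finite, a - a[finite].min(), np.inf)
    w = np.where(finite, np.exp(-rel / 2.0), 0.0)
    return w / w.sum()


@dataclass(frozen=True)
class FitResult:
    """One fitted model: estimates, log-likelihood and AIC."""

    spec: ModelSpec
    rates: dict[str, RateMatrix]
    roots: tuple[float, float]
    loglik: float
    converged: bool = True
    n_starts: int = 1
    seed: int | None = None

    @property
    def k(self) -> int:
        return self.spec.count_params

    @property
    def aic(self) -> float:
        return aic(self.loglik, self.k)

    def to_dict(self) -> dict:
        return {
            "model": self.spec.code,
            "regimes": list(self.spec.regimes),
            "rates": {
                g: {"sigma2_1": R.sigma2_1, "sigma2_2": R.sigma2_2, "r": R.r}
                for g, R in self.rates.items()
            },
            "roots": list(self.roots),
            "loglik": self.loglik,
            "k": self.k,
            "aic": self.aic,
            "converged": self.converged,
            "n_starts": self.n_starts,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        spec = ModelSpec(d["model"], tuple(d["regimes"]))
        rates = {
            g: RateMatrix(v["sigma2_1"], v["sigma2_2"], v["r"])
            for g, v in d["rates"].items()
        }
        return cls(
            spec,
            rates,
            tuple(d["roots"]),
            d["loglik"],
            d.get("converged", True),
            d.get("n_starts", 1),
            d.get("seed"),
        )


# ---------------------------------------------------------------------------
# Single-model fitting
# ---------------------------------------------------------------------------


def _pooled_start(Cks: SharedTimeMatrices, x: np.ndarray) -> RateMatrix:
    """Analytic single-regime ML fit used as the universal starting point.

    Under one regime the ML rate matrix is the GLS cross-product of the
    root-centered data, R = (x - 1 a')' C^-1 (x - 1 a') / n.
    """
    C = Cks.total
    n = C.shape[0]
    # guard duplicated root-to-tip paths with a tiny ridge: this is only a
    # starting value, not a reported estimate
    try:
        Ci = np.linalg.inv(C)
    except np.linalg.LinAlgError:
        Ci = np.linalg.inv(C + 1e-10 * np.eye(n) * np.trace(C) / n)
    one = np.ones(n)
    denom = one @ Ci @ one
    a = (one @ Ci @ x) / denom
    xc = x - a
    R = xc.T @ Ci @ xc / n
    s1 = max(R[0, 0], 1e-12)
    s2 = max(R[1, 1], 1e-12)
    r = R[0, 1] / math.sqrt(s1 * s2)
    r = min(max(r, -0.999), 0.999)
    return RateMatrix(s1, s2, r)


def _objective(theta: np.ndarray, spec: ModelSpec, Cks: SharedTimeMatrices,
               x: np.ndarray) -> float:
    try:
        Rs = spec.expand(theta)
        V = assemble_covariance(Cks, Rs)
        ll, _ = _loglik_from_V(V, x)
    except (SingularCovarianceError, ValueError, FloatingPointError, OverflowError):
        return 1e10
    if not np.isfinite(ll):
        return 1e10
    return -ll


def _optimize_from(theta0: np.ndarray, spec: ModelSpec, Cks: SharedTimeMatrices,
                   x: np.ndarray) -> tuple[np.ndarray, float, bool]:
    """Quasi-Newton search with a derivative-free simplex fallback.

    The profiled likelihood surface is smooth in the unconstrained
    coordinates, so L-BFGS-B from a good start converges in a few dozen
    iterations; the simplex pass only runs when it reports failure (e.g.
    on a locally flat surface).
    """
    dim = theta0.size
    res = optimize.minimize(
        _objective, theta0, args=(spec, Cks, x), method="L-BFGS-B",
        options={"maxiter": 300},
    )
    best_x, best_f, ok = res.x, res.fun, bool(res.success)
    if not ok:
        polish = optimize.minimize(
            _objective, best_x, args=(spec, Cks, x), method="Nelder-Mead",
            options={"maxfev": 150 * dim, "xatol": 1e-6, "fatol": 1e-8,
                     "adaptive": dim > 4},
        )
        if polish.fun <= best_f:
            best_x, best_f, ok = polish.x, polish.fun, bool(polish.success)
    return best_x, best_f, ok


def fit_model(
    tree: PaintedTree | SharedTimeMatrices,
    traits: pd.DataFrame,
    spec: ModelSpec | str,
    n_starts: int = 4,
    seed: int | None = None,
    extra_starts: Sequence[np.ndarray] = (),
) -> FitResult:
    """Fit one model of the hierarchy by maximum likelihood.

    ``n_starts`` optimizations are run: the first from the pooled
    single-regime analytic fit, the rest from jittered versions of it
    (log-rates perturbed by N(0,1), atanh correlations by N(0,0.5)).
    ``extra_starts`` adds caller-supplied warm starts (used by
    :func:`fit_hierarchy`).  Deterministic given ``seed``.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    Cks = tree if isinstance(tree, SharedTimeMatrices) else shared_time_matrices(tree)
    if isinstance(spec, str):
        spec = ModelSpec(spec, Cks.regimes)
    if tuple(spec.regimes) != tuple(Cks.regimes):
        raise ValueError(
            f"model regimes {spec.regimes} do not match painting {Cks.regimes}"
        )
    traits = trait_matrix(traits, list(Cks.taxa))
    x = traits.to_numpy()
    if not np.isfinite(x).all():
        raise ValueError("non-finite trait values")

    pooled = _pooled_start(Cks, x)
    base = spec.pack({g: pooled for g in spec.regimes})
    rng = np.random.default_rng(seed)
    starts = [base]
    for _ in range(n_starts - 1):
        jitter = np.empty_like(base)
        i = 0
        for varies, scale in zip(spec.flags, (1.0, 1.0, 0.5)):
            width = spec.K if varies else 1
            jitter[i : i + width] = rng.normal(0.0, scale, width)
            i += width
        starts.append(base + jitter)
    starts.extend(np.asarray(s, dtype=float) for s in extra_starts)

    best: tuple[np.ndarray, float, bool] | None = None
    failures = 0
    for theta0 in starts:
        if _objective(theta0, spec, Cks, x) >= 1e10:
            failures += 1
            continue
        cand = _optimize_from(theta0, spec, Cks, x)
        if best is None or cand[1] < best[1]:
            best = cand
    if best is None:
        raise SingularCovarianceError(
            "covariance singular at every starting point"
        )
    theta, nll, ok = best
    Rs = spec.expand(theta)
    V = assemble_covariance(Cks, Rs)
    ll, roots = _loglik_from_V(V, x)
    return FitResult(spec, Rs, roots, ll, converged=ok,
                     n_starts=len(starts), seed=seed)


# ---------------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------------


#: direct-parent edges of the nesting partial order
_NESTING_PARENTS: dict[str, tuple[str, ...]] = {
    "1": (),
    "2b": ("1",),
    "2c": ("1",),
    "3": ("1",),
    "2": ("2b", "2c"),
    "3b": ("2b", "3"),
    "3c": ("2c", "3"),
    "4": ("2", "3b", "3c"),
}


@dataclass
class ComparisonTable:
    """Ranked model fits with delta-AIC and Akaike weights."""

    fits: list[FitResult]
    failed: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.fits:
            raise ValueError("no successful fits to compare")

    @property
    def weights(self) -> np.ndarray:
        return akaike_weights([f.aic for f in self.fits])

    def ranked(self) -> list[FitResult]:
        # ties: smaller AIC, then smaller k, then canonical code order
        return sorted(
            self.fits,
            key=lambda f: (round(f.aic, 12), f.k, MODEL_ORDER.index(f.spec.code)),
        )

    def best(self) -> FitResult:
        return self.ranked()[0]

    def rank_of(self, code: str) -> int:
        """1-based AIC rank of a model code."""
        for i, f in enumerate(self.ranked(), start=1):
            if f.spec.code == code:
                return i
        raise KeyError(f"model {code!r} not in table")

    def weight_of(self, code: str) -> float:
        w = self.weights
        for f, wi in zip(self.fits, w):
            if f.spec.code == code:
                return float(wi)
        raise KeyError(f"model {code!r} not in table")

    def to_frame(self) -> pd.DataFrame:
        """A table shaped like the standard model-comparison report."""
        w = dict(zip((f.spec.code for f in self.fits), self.weights))
        rows = []
        best_aic = min(f.aic for f in self.fits)
        for rank, f in enumerate(self.ranked(), start=1):
            row: dict[str, object] = {"rank": rank, "model": f.spec.code}
            for i, g in enumerate(f.spec.regimes, start=1):
                R = f.rates[g]
                row[f"sigma2_1[{g}]"] = R.sigma2_1
                row[f"sigma2_2[{g}]"] = R.sigma2_2
                row[f"r[{g}]"] = R.r
            row.update(
                logL=f.loglik, k=f.k, AIC=f.aic, dAIC=f.aic - best_aic,
                w=w[f.spec.code],
            )
            rows.append(row)
        return pd.DataFrame(rows).set_index("rank")


def fit_hierarchy(
    tree: PaintedTree | SharedTimeMatrices,
    traits: pd.DataFrame,
    models: Sequence[str] | None = None,
    n_starts: int = 4,
    seed: int | None = None,
) -> ComparisonTable:
    """Fit a set of models (default: all eight) and build the comparison.

    Models are fitted simplest-first; each model receives warm starts built
    by replicating the estimates of its directly nested sub-models, so the
    maximized log-likelihoods respect the nesting partial order up to
    optimizer slack.  A model whose fit fails is excluded from the weights
    with a warning rather than aborting the run.
    """
    Cks = tree if isinstance(tree, SharedTimeMatrices) else shared_time_matrices(tree)
    codes = list(MODEL_ORDER) if models is None or models == "all" else list(models)
    unknown = [c for c in codes if c not in MODEL_CODES]
    if unknown:
        raise ValueError(f"unknown model codes: {unknown}")
    # fit in nesting order (parents of the partial order first)
    order = [c for c in ("1", "2b", "2c", "3", "2", "3b", "3c", "4") if c in codes]
    ss = np.random.SeedSequence(seed) if seed is not None else np.random.SeedSequence()
    child_seeds = {c: int(s.generate_state(1)[0] % (2**31)) for c, s in
                   zip(order, ss.spawn(len(order)))}

    done: dict[str, FitResult] = {}
    failed: dict[str, str] = {}
    for code in order:
        spec = ModelSpec(code, Cks.regimes)
        warm = []
        for parent in _NESTING_PARENTS[code]:
            if parent in done:
                warm.append(spec.pack(done[parent].rates))
        try:
            done[code] = fit_model(
                Cks, traits, spec, n_starts=n_starts,
                seed=child_seeds[code], extra_starts=warm,
            )
        except (SingularCovarianceError, ValueError) as exc:
            warnings.warn(f"model {code} failed to fit: {exc}")
            failed[code] = str(exc)
    fits = [done[c] for c in codes if c in done]
    return ComparisonTable(fits, failed)


def likelihood_ratio_test(
    simple: FitResult, complex: FitResult
) -> tuple[float, int, float]:
    """Chi-square likelihood-ratio test of two nested fitted models.

    Returns ``(statistic, df, p)`` with statistic ``2 (logL_c - logL_s)``
    and ``df`` the difference in parameter counts.
    """
    if not simple.spec.nests_in(complex.spec):
        raise ValueError(
            f"model {simple.spec.code} is not nested in {complex.spec.code}"
        )
    if complex.loglik < simple.loglik - 1e-6:
        raise ValueError(
            "complex model has lower log-likelihood than its special case; "
            "refit with more starts"
        )
    statistic = max(2.0 * (complex.loglik - simple.loglik), 0.0)
    df = complex.k - simple.k
    if df == 0:
        return statistic, 0, 1.0
    p = float(stats.chi2.sf(statistic, df))
    return statistic, df, p
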