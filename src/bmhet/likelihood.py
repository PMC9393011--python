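"""Exact likelihood of bivariate traits under multi-regime Brownian motion.

Stacking the two trait columns trait-major (all of trait 1, then all of
trait 2), the tip data are multivariate normal with mean ``D a`` — where
``a = (a1, a2)`` are the root states and ``D`` maps each observation to its
trait's root state — and covariance

    V = sum_k  R_k (x) C_k

built blockwise: block (p, q) of V is ``sum_k R_k[p, q] * C_k`` with
``C_k`` the shared-ancestry matrix of regime k.  For a single regime this
reduces to the Kronecker product ``R (x) C``.

The root states enter the likelihood linearly, so for any fixed variance
parameters their maximum-likelihood values are the generalized least
squares estimate; they are profiled out analytically rather than optimized
numerically.  The covariance is factored by Cholesky; a factorization
failure is reported as an error (it indicates a degenerate tree or
painting), never silently regularized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .models import RateMatrix
from .trees import PaintedTree, SharedTimeMatrices, shared_time_matrices

__all__ = [
    "SingularCovarianceError",
    "LikelihoodResult",
    "trait_matrix",
    "assemble_covariance",
    "profile_roots",
    "loglik",
]

LOG_2PI = math.log(2.0 * math.pi)


class SingularCovarianceError(np.linalg.LinAlgError):
    """The trait covariance is not positive definite.

    Typically caused by two tips with identical root-to-tip paths
    (zero-length cherries) or a painting that assigns no time to a regime
    referenced by the model.
    """


@dataclass(frozen=True)
class LikelihoodResult:
    loglik: float
    roots: tuple[float, float]
    covariance: np.ndarray | None = None


def trait_matrix(traits: pd.DataFrame, taxa: list[str] | None = None) -> pd.DataFrame:
    """Validate and order a two-column trait table indexed by taxon."""
    if traits.shape[1] != 2:
        raise ValueError(f"expected exactly 2 trait columns, got {traits.shape[1]}")
    if traits.isna().any().any():
        bad = traits.index[traits.isna().any(axis=1)].tolist()
        raise ValueError(f"missing trait values for taxa: {bad}")
    if traits.index.duplicated().any():
        raise ValueError("duplicate taxa in trait table")
    if taxa is not None:
        missing = set(taxa) - set(traits.index)
        extra = set(traits.index) - set(taxa)
        if missing or extra:
            raise ValueError(
                f"trait table does not match tree tips (missing: {sorted(missing)}, "
                f"extra: {sorted(extra)})"
            )
        traits = traits.loc[list(taxa)]
    return traits.astype(float)


def assemble_covariance(
    Cks: SharedTimeMatrices, Rs: Mapping[str, RateMatrix]
) -> np.ndarray:
    """Assemble the 2n x 2n trait covariance from C_k and per-regime R_k."""
    n = len(Cks.taxa)
    missing = [g for g in Rs if g not in Cks.regimes]
    if missing:
        raise KeyError(f"regimes not present in the painting: {missing}")
    missing = [g for g in Cks.regimes if g not in Rs]
    if missing:
        raise KeyError(f"no rate matrix supplied for regimes: {missing}")

    coef = np.array([Rs[g].matrix for g in Cks.regimes])  # (K, 2, 2)
    V = np.empty((2 * n, 2 * n))
    b11 = np.tensordot(coef[:, 0, 0], Cks.stack, axes=1)
    b22 = np.tensordot(coef[:, 1, 1], Cks.stack, axes=1)
    b12 = np.tensordot(coef[:, 0, 1], Cks.stack, axes=1)
    V[:n, :n] = b11
    V[n:, n:] = b22
    V[:n, n:] = b12
    V[n:, :n] = b12
    return V


def profile_roots(V: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """GLS estimate of the two root states given the covariance.

    ``x`` is the n x 2 trait matrix; the estimate is
    ``(D' V^-1 D)^-1 D' V^-1 vec(x)`` with trait-major stacking.
    """
    n = x.shape[0]
    y = np.concatenate([x[:, 0], x[:, 1]])
    try:
        factor = cho_factor(V, lower=True)
    except np.linalg.LinAlgError as exc:
        raise SingularCovarianceError(str(exc)) from exc
    D = np.zeros((2 * n, 2))
    D[:n, 0] = 1.0
    D[n:, 1] = 1.0
    ViD = cho_solve(factor, D)
    A = D.T @ ViD
    b = ViD.T @ y
    a = np.linalg.solve(A, b)
    return float(a[0]), float(a[1])


def _loglik_from_V(V: np.ndarray, x: np.ndarray) -> tuple[float, tuple[float, float]]:
    n = x.shape[0]
    y = np.concatenate([x[:, 0], x[:, 1]])
    try:
        factor = cho_factor(V, lower=True)
    except np.linalg.LinAlgError as exc:
        raise SingularCovarianceError(str(exc)) from exc
    D = np.zeros((2 * n, 2))
    D[:n, 0] = 1.0
    D[n:, 1] = 1.0
    ViD = cho_solve(factor, D)
    A = D.T @ ViD
    a = np.linalg.solve(A, ViD.T @ y)
    resid = y - D @ a
    quad = float(resid @ cho_solve(factor, resid))
    logdet = 2.0 * float(np.sum(np.log(np.diag(factor[0]))))
    ll = -0.5 * (2 * n * LOG_2PI + logdet + quad)
    return ll, (float(a[0]), float(a[1]))


def loglik(
    tree: PaintedTree | SharedTimeMatrices,
    traits: pd.DataFrame,
    Rs: Mapping[str, RateMatrix],
    keep_covariance: bool = False,
) -> LikelihoodResult:
    """Log-likelihood (nats) of a trait table under per-regime rate matrices.

    ``tree`` may be a painted tree or a precomputed
    :class:`~bmhet.trees.SharedTimeMatrices` (useful when evaluating many
    parameter values on one tree).  Root states are profiled by GLS.
    """
    if isinstance(tree, SharedTimeMatrices):
        Cks = tree
    else:
        Cks = shared_time_matrices(tree)
    traits = trait_matrix(traits, list(Cks.taxa))
    x = traits.to_numpy()
    if not np.isfinite(x).all():
        raise ValueError("non-finite trait values")
    V = assemble_covariance(Cks, Rs)
    ll, roots = _loglik_from_V(V, x)
    return LikelihoodResult(ll, roots, V if keep_covariance else None)
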