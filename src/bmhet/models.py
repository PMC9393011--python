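"""The eight-model hierarchy for bivariate Brownian motion on painted trees.

Bivariate Brownian motion is governed by a 2x2 evolutionary rate matrix

    R = [[s1^2,        r*s1*s2],
         [r*s2*s1,     s2^2   ]]

where ``s1^2`` and ``s2^2`` are the instantaneous variances (rates) of the
two traits and ``r`` is their evolutionary correlation.  With regimes
painted on the tree, each of the three quantities may either be shared
across regimes or take a regime-specific value, giving eight nested models:

    code   rate 1     rate 2     correlation
    1      common     common     common
    2      varies     varies     common
    2b     varies     common     common
    2c     common     varies     common
    3      common     common     varies
    3b     varies     common     varies
    3c     common     varies     varies
    4      varies     varies     varies

Every model also estimates the two root states, so with K regimes the
parameter count is ``(K or 1) + (K or 1) + (K or 1) + 2`` according to the
pattern of varying slots (model 1 has 5 parameters for any K; model 4 has
3K + 2).

For numerical optimization the free parameters are carried in an
unconstrained vector: ``log sigma^2`` for rates and ``atanh(r)`` for
correlations, so that any real vector maps to a valid set of rate matrices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "MODEL_CODES",
    "RateMatrix",
    "ModelSpec",
    "correlation_from_covariance",
    "compose_R",
]

#: model code -> (rate1_varies, rate2_varies, corr_varies)
MODEL_CODES: dict[str, tuple[bool, bool, bool]] = {
    "1": (False, False, False),
    "2": (True, True, False),
    "2b": (True, False, False),
    "2c": (False, True, False),
    "3": (False, False, True),
    "3b": (True, False, True),
    "3c": (False, True, True),
    "4": (True, True, True),
}


def correlation_from_covariance(sigma12: float, sigma2_1: float, sigma2_2: float) -> float:
    """Evolutionary correlation r = sigma_12 / sqrt(sigma_1^2 sigma_2^2)."""
    if sigma2_1 <= 0 or sigma2_2 <= 0:
        raise ValueError("rates must be > 0")
    return sigma12 / math.sqrt(sigma2_1 * sigma2_2)


def compose_R(sigma2_1: float, sigma2_2: float, r: float) -> np.ndarray:
    """Assemble the 2x2 rate matrix from rates and correlation."""
    if sigma2_1 <= 0 or sigma2_2 <= 0:
        raise ValueError("rates must be > 0")
    if not -1.0 <= r <= 1.0:
        raise ValueError("correlation must be in [-1, 1]")
    cov = r * math.sqrt(sigma2_1) * math.sqrt(sigma2_2)
    return np.array([[sigma2_1, cov], [cov, sigma2_2]])


@dataclass(frozen=True)
class RateMatrix:
    """Per-regime Brownian rate matrix in (rate, rate, correlation) form."""

    sigma2_1: float
    sigma2_2: float
    r: float

    def __post_init__(self):
        if self.sigma2_1 <= 0 or self.sigma2_2 <= 0:
            raise ValueError("rates must be > 0")
        if not -1.0 < self.r < 1.0:
            raise ValueError("correlation must be in (-1, 1)")

    @property
    def matrix(self) -> np.ndarray:
        return compose_R(self.sigma2_1, self.sigma2_2, self.r)

    @property
    def covariance(self) -> float:
        """The instantaneous trait covariance (off-diagonal of R)."""
        return self.r * math.sqrt(self.sigma2_1 * self.sigma2_2)

    @classmethod
    def from_covariance(cls, sigma2_1: float, sigma2_2: float, sigma12: float):
        return cls(sigma2_1, sigma2_2,
                   correlation_from_covariance(sigma12, sigma2_1, sigma2_2))


@dataclass(frozen=True)
class ModelSpec:
    """One member of the eight-model hierarchy over a fixed regime set."""

    code: str
    regimes: tuple[str, ...]

    def __post_init__(self):
        if self.code not in MODEL_CODES:
            raise ValueError(
                f"unknown model code {self.code!r}; valid: {sorted(MODEL_CODES)}"
            )
        if len(self.regimes) < 1:
            raise ValueError("at least one regime is required")

    @property
    def flags(self) -> tuple[bool, bool, bool]:
        return MODEL_CODES[self.code]

    @property
    def rate1_varies(self) -> bool:
        return self.flags[0]

    @property
    def rate2_varies(self) -> bool:
        return self.flags[1]

    @property
    def corr_varies(self) -> bool:
        return self.flags[2]

    @property
    def K(self) -> int:
        return len(self.regimes)

    # -- parameter accounting ---------------------------------------------

    @property
    def n_free(self) -> int:
        """Free variance/correlation coordinates (excludes the 2 root states)."""
        K = self.K
        r1, r2, rc = self.flags
        return (K if r1 else 1) + (K if r2 else 1) + (K if rc else 1)

    @property
    def count_params(self) -> int:
        """Total estimated parameters, including the two root states."""
        return self.n_free + 2

    def slot_names(self) -> list[str]:
        """Names of the free slots in packing order."""
        names = []
        for varies, base in zip(self.flags, ("sigma2_1", "sigma2_2", "r")):
            if varies:
                names.extend(f"{base}[{g}]" for g in self.regimes)
            else:
                names.append(base)
        return names

    def nests_in(self, other: "ModelSpec") -> bool:
        """True if this model is a special case of ``other``."""
        return self.regimes == other.regimes and all(
            (not a) or b for a, b in zip(self.flags, other.flags)
        )

    # -- packing between RateMatrix maps and unconstrained vectors ---------

    def pack(self, rates: Mapping[str, RateMatrix]) -> np.ndarray:
        """Map per-regime rate matrices to the unconstrained vector.

        Shared slots take the value from the first regime (the caller is
        responsible for the map actually respecting the sharing pattern).
        """
        missing = [g for g in self.regimes if g not in rates]
        if missing:
            raise KeyError(f"missing regimes: {missing}")
        out: list[float] = []
        first = self.regimes[0]
        for varies, get in (
            (self.rate1_varies, lambda g: math.log(rates[g].sigma2_1)),
            (self.rate2_varies, lambda g: math.log(rates[g].sigma2_2)),
            (self.corr_varies, lambda g: math.atanh(rates[g].r)),
        ):
            if varies:
                out.extend(get(g) for g in self.regimes)
            else:
                out.append(get(first))
        return np.array(out)

    def expand(self, vector: Sequence[float]) -> dict[str, RateMatrix]:
        """Map an unconstrained vector back to per-regime rate matrices."""
        vector = np.asarray(vector, dtype=float)
        if vector.shape != (self.n_free,):
            raise ValueError(
                f"expected {self.n_free} free parameters for model {self.code} "
                f"with {self.K} regimes, got {vector.shape}"
            )
        pos = 0
        cols: list[np.ndarray] = []
        for varies in self.flags:
            width = self.K if varies else 1
            block = vector[pos : pos + width]
            cols.append(np.repeat(block, self.K) if width == 1 else block)
            pos += width
        s1 = np.exp(cols[0])
        s2 = np.exp(cols[1])
        # tanh saturates to +/-1 in floating point around |x| ~ 19; keep the
        # correlation strictly inside the open interval
        rr = np.clip(np.tanh(cols[2]), -1 + 1e-12, 1 - 1e-12)
        return {
            g: RateMatrix(s1[i], s2[i], rr[i]) for i, g in enumerate(self.regimes)
        }


def count_params(spec: ModelSpec, K: int | None = None) -> int:
    """Parameter count of a model (functional form of ``spec.count_params``)."""
    if K is not None and K != spec.K:
        spec = ModelSpec(spec.code, tuple(str(i) for i in range(K)))
    return spec.count_params


def all_specs(regimes: Sequence[str]) -> list[ModelSpec]:
    """All eight models over a regime set, in canonical code order."""
    return [ModelSpec(code, tuple(regimes)) for code in MODEL_CODES]
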