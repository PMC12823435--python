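"""C-alpha dispersion test for rare-variant count distributions.

The C-alpha test asks whether allele copies of rare variants split
between two groups (e.g. two disorders, or one disorder and controls)
according to a common binomial proportion ``p0``, or whether some units
(genes here) are systematically skewed toward one group — the signature
of unit-specific risk effects. For unit i with ``n_i`` total copies of
which ``y_i`` fall in group A:

    T = sum_i [ (y_i - n_i p0)^2 - n_i p0 (1 - p0) ]

Under the binomial null each term has mean zero; over-dispersion makes
T positive. The null variance is the exact sum over the binomial
support:

    c = sum_i sum_{u=0}^{n_i} [ (u - n_i p0)^2 - n_i p0 (1-p0) ]^2 Bin(u; n_i, p0)

and Z = T / sqrt(c) is compared with the upper tail of the standard
normal. Because the normal approximation is poor when copies are few,
a permutation p-value is computed alongside by permuting carrier group
labels: conditionally on the observed total number of group-A copies,
the permuted per-unit counts follow a multivariate hypergeometric
draw, re-scoring T each time. The permutation p uses the add-one
estimator, so its resolution is 1/(n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["CAlphaInput", "CAlphaResult", "calpha_T", "calpha_variance", "calpha_test"]


@dataclass
class CAlphaInput:
    """Per-unit copy counts for a two-group comparison.

    ``y`` — copies observed in group A per unit; ``n`` — total copies in
    both groups per unit; ``p0`` — expected group-A proportion (group A
    size / total sample size).
    """

    y: Sequence[int]
    n: Sequence[int]
    p0: float
    n_perm: int = 10_000
    seed: int | None = None

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=np.int64)
        n = np.asarray(self.n, dtype=np.int64)
        if y.shape != n.shape:
            raise ValueError("y and n must have equal length")
        if y.size == 0:
            raise ValueError("C-alpha requires at least one unit")
        if np.any(y < 0) or np.any(n < 0) or np.any(y > n):
            raise ValueError("need 0 <= y_i <= n_i for every unit")
        if not (0 < self.p0 < 1):
            raise ValueError("p0 must lie strictly in (0, 1)")
        self.y = y
        self.n = n


@dataclass
class CAlphaResult:
    T: float
    c: float
    Z: float
    p_asymptotic: float
    p_permutation: float
    n_perm: int


def calpha_T(input: CAlphaInput, y: np.ndarray | None = None) -> float:
    """The C-alpha statistic; ``y`` overrides the observed counts (used
    when re-scoring permutations)."""
    yy = input.y if y is None else np.asarray(y)
    n, p0 = input.n, input.p0
    return float(np.sum((yy - n * p0) ** 2 - n * p0 * (1 - p0)))


def calpha_variance(input: CAlphaInput) -> float:
    """Exact null variance of T under independent Binomial(n_i, p0)."""
    n, p0 = input.n, input.p0
    c = 0.0
    for n_i in np.asarray(n):
        if n_i == 0:
            continue
        u = np.arange(n_i + 1)
        term = (u - n_i * p0) ** 2 - n_i * p0 * (1 - p0)
        c += float(np.sum(term**2 * stats.binom.pmf(u, n_i, p0)))
    return c


def _permute_T(input: CAlphaInput, rng: np.random.Generator) -> np.ndarray:
    """Permutation null draws of T.

    Carrier labels are permuted across the two groups: conditionally on
    the observed total of group-A copies m = sum y_i, each permuted
    split is a multivariate hypergeometric allocation of m copies over
    units of sizes n_i.
    """
    n = np.asarray(input.n)
    m = int(np.sum(input.y))
    draws = rng.multivariate_hypergeometric(n, m, size=input.n_perm)
    p0 = input.p0
    return np.sum((draws - n * p0) ** 2 - n * p0 * (1 - p0), axis=1)


def calpha_test(input: CAlphaInput) -> CAlphaResult:
    """Full C-alpha test: statistic, exact variance, asymptotic and
    permutation p-values (upper tail; over-dispersion alternative)."""
    T = calpha_T(input)
    c = calpha_variance(input)
    if c <= 0:
        raise ValueError("degenerate input: null variance is zero (all n_i = 0?)")
    Z = T / np.sqrt(c)
    p_asym = float(stats.norm.sf(Z))
    rng = np.random.default_rng(input.seed)
    t_null = _permute_T(input, rng)
    p_perm = (1 + int(np.sum(t_null >= T))) / (input.n_perm + 1)
    return CAlphaResult(T=T, c=c, Z=float(Z), p_asymptotic=p_asym, p_permutation=float(p_perm), n_perm=input.n_perm)
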