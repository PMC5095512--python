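"""Third-order jackknife extrapolation of variant richness.

The jackknife baseline does not model the frequency distribution at all: it
predicts the number of distinct variants in ``N`` alleles directly as

    U(N) = D + g1(N, k) F1 + g2(N, k) F2 + g3(N, k) F3,

where ``F1, F2, F3`` count variants seen once, twice and three times among
the ``k`` sampled alleles, ``D`` is the observed number of distinct variants
and the ``g_m`` are coefficient functions satisfying the self-consistency
condition ``g_m(k, k) = 0`` (no extrapolation reproduces the data).

The coefficient rule is pluggable.  The shipped default assumes the
accumulation curve is a polynomial in ``1/M`` (sample size ``M``) up to third
order, and determines its four coefficients from the exact finite-difference
identities linking the curve to the low-order SFS counts:

    U(k) − U(k−1)                      =  F1 / C(k, 1)
    U(k) − 2U(k−1) + U(k−2)            = −F2 / C(k, 2)
    U(k) − 3U(k−1) + 3U(k−2) − U(k−3)  =  F3 / C(k, 3)

(these hold in expectation for any frequency distribution).  The default is
a reconstruction of the classical rule, exact for accumulation curves that
really are third-order polynomials in ``1/M``; only its contract properties
are relied on, not specific published coefficient values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .spectrum import SiteFrequencySpectrum

__all__ = [
    "JackknifeInput",
    "jackknife_predict",
    "default_coefficients",
    "JackknifeRichness",
]

CoefficientRule = Callable[[float, int], tuple[float, float, float]]


@dataclass(frozen=True)
class JackknifeInput:
    """Sufficient statistics for the jackknife: (F1, F2, F3, D, k, N)."""

    f1: int
    f2: int
    f3: int
    d: int
    k: int
    n: int

    def __post_init__(self) -> None:
        if min(self.f1, self.f2, self.f3) < 0:
            raise ValueError("F1, F2, F3 must be non-negative")
        if self.f1 + self.f2 + self.f3 > self.d:
            raise ValueError("F1 + F2 + F3 cannot exceed the distinct count D")
        if self.k < 3:
            raise ValueError("jackknife needs k >= 3")
        if self.n < self.k:
            raise ValueError("extrapolation only: need N >= k")

    @classmethod
    def from_sfs(cls, sfs: SiteFrequencySpectrum, n: int) -> "JackknifeInput":
        return cls(
            f1=sfs.f(1), f2=sfs.f(2), f3=sfs.f(3),
            d=sfs.total_variants, k=sfs.k, n=n,
        )


def default_coefficients(n: float, k: int) -> tuple[float, float, float]:
    """Coefficients ``(g1, g2, g3)`` of the polynomial-in-1/M reconstruction.

    Derived by fitting ``u(M) = a0 + a1 (k/M) + a2 (k/M)^2 + a3 (k/M)^3`` to
    the value ``D`` at ``M = k`` and the three backward differences implied by
    ``F1, F2, F3``, then evaluating at ``M = N``.  Linear in (D, F1, F2, F3),
    so it reduces to the ``D + Σ g_m F_m`` form; ``g_m(k, k) = 0`` because the
    interpolant passes through ``D`` at ``M = k`` exactly.
    """
    if k < 4:
        raise ValueError("default coefficient rule needs k >= 4")
    # basis scaled as (k/M)^j so matrix entries stay O(1)
    def basis(M: float) -> np.ndarray:
        t = k / M
        return np.array([1.0, t, t * t, t ** 3])

    f0, f1m, f2m, f3m = (basis(k - d) for d in range(4))
    A = np.vstack(
        [
            f0,
            f0 - f1m,
            f0 - 2 * f1m + f2m,
            f0 - 3 * f1m + 3 * f2m - f3m,
        ]
    )
    # prediction = fN @ A^-1 @ rhs with rhs = [D, F1/C(k,1), -F2/C(k,2), F3/C(k,3)].
    # The D-coefficient (first entry of the row) is identically 1: with all
    # F_m = 0 the four interpolation conditions force the constant curve D.
    row = np.linalg.solve(A.T, basis(float(n)))
    c1 = float(k)
    c2 = k * (k - 1) / 2.0
    c3 = k * (k - 1) * (k - 2) / 6.0
    return row[1] / c1, -row[2] / c2, row[3] / c3


def jackknife_predict(
    inp: JackknifeInput, coefficients: CoefficientRule = default_coefficients
) -> float:
    """Total distinct variants predicted at ``N = inp.n`` alleles.

    At ``N = k`` the prediction equals ``D`` exactly for any admissible
    coefficient rule (rules violating ``g_m(k, k) = 0`` beyond numerical
    tolerance are rejected).
    """
    if inp.n == inp.k:
        gk = coefficients(inp.k, inp.k)
        far = coefficients(2 * inp.k, inp.k)
        scale = max(1.0, max(abs(g) for g in far))
        if max(abs(g) for g in gk) > 1e-6 * scale:
            raise ValueError("coefficient rule violates self-consistency g_m(k, k) = 0")
        return float(inp.d)
    g1, g2, g3 = coefficients(inp.n, inp.k)
    return float(inp.d + g1 * inp.f1 + g2 * inp.f2 + g3 * inp.f3)


class JackknifeRichness(BaseEstimator):
    """Scikit-learn-style wrapper: fit on an SFS, predict distinct counts.

    Mirrors :class:`~unseenest.estimator.UnseenEst`'s predict interface so
    the two extrapolators can be compared side by side.
    """

    def __init__(self, coefficients: CoefficientRule = default_coefficients):
        self.coefficients = coefficients

    def fit(self, sfs: SiteFrequencySpectrum, y=None) -> "JackknifeRichness":
        self.f1_, self.f2_, self.f3_ = sfs.f(1), sfs.f(2), sfs.f(3)
        self.d_ = sfs.total_variants
        self.k_ = sfs.k
        return self

    def predict(self, cohort_sizes, ploidy: int = 2) -> np.ndarray:
        sizes = np.atleast_1d(np.asarray(cohort_sizes))
        return np.array([self.predict_unique(ploidy * int(s)) for s in sizes])

    def predict_unique(self, n_alleles: int) -> float:
        inp = JackknifeInput(
            f1=self.f1_, f2=self.f2_, f3=self.f3_, d=self.d_, k=self.k_, n=int(n_alleles)
        )
        return jackknife_predict(inp, self.coefficients)
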