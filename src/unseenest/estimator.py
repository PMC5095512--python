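"""UnseenEst: linear-programming recovery of the variant frequency histogram.

Given the observed SFS ``{F_i}`` of ``k`` alleles, the estimator searches for
a non-negative histogram ``h`` over a geometric frequency grid that minimises
the weighted L1 discrepancy between the expected and observed spectra,

    Σ_{i=1..i_fit} w_i · | Σ_j h_j · bin(x_j, k, i) − F_i |,

with the absolute values linearised through auxiliary variables.  Counts
above ``i_fit`` pin their variants' frequencies well, so those variants are
handled empirically at frequency ``i/k`` ("frequent part") rather than fitted.

Because the discrepancy objective alone leaves the total unseen mass
under-determined (many rare-tail shapes produce nearly identical spectra), a
second LP stage minimises the total mass ``T = Σ_j h_j`` subject to the
discrepancy staying within a small slack of the stage-1 optimum.  This
prefers the smallest variant inventory consistent with the data and makes the
returned histogram well defined.

Two numerical choices matter here.  The fitted grid is capped at ``i_fit/k``:
columns above it are essentially invisible to the fitted counts
(``bin(x, k, i) ≈ 0`` for ``i <= i_fit`` when ``x >> i_fit/k``), and keeping
them lets the solver park arbitrary mass on dead columns, corrupting the
mass-minimisation stage; the empirical frequent part covers that range
instead.  And the stage-2 slack is tiny by default (1e-6 relative), so the
returned histogram is an exact stage-1 optimum up to numerical tolerance —
its discrepancy is certifiably no worse than that of any feasible histogram,
including the true one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import linprog
from sklearn.base import BaseEstimator

from .spectrum import (
    FrequencyGrid,
    FrequencyHistogram,
    SiteFrequencySpectrum,
    build_grid,
    build_mixing_matrix,
    expected_unique,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FitConfig",
    "FitResult",
    "UnseenEst",
    "fit",
    "objective",
    "predict_discovery_curve",
    "fit_with_uncertainty",
]


@dataclass
class FitConfig:
    """Solver settings for the LP fit.

    Parameters
    ----------
    x_min_factor : r in x_min = 1/(r*k); unseen variants must be representable
        below 1/k, and r is the maximum extrapolation factor the grid supports.
    ratio : geometric grid spacing (uniform relative resolution).
    x_max : upper end of the fitted grid; additionally capped at i_fit/k
        (frequencies above it are represented by the empirical frequent
        part, not the LP).
    i_fit : largest occurrence count entering the LP; counts above it are
        placed in the frequent part at their empirical frequency i/k.
    weights : "inv_sqrt" for w_i = 1/sqrt(1 + F_i) (Poisson-scale variance
        stabilisation) or "uniform".
    mass_penalty : optional stage-1 additive penalty coefficient on Σ_j h_j.
    slack : stage-2 tolerance — total mass is minimised subject to
        discrepancy <= stage-1 optimum * (1 + slack); kept tiny so the
        returned histogram stays an exact optimum of the discrepancy.
    mass_cap : optional upper bound on total mass T (e.g. a genome-wide gene
        count for gene-level fits).
    lp_tol : numerical floor added to the stage-2 discrepancy bound.
    seed : seed for partition-based uncertainty resampling.
    """

    x_min_factor: float = 50.0
    ratio: float = 1.05
    x_max: float = 1.0
    i_fit: int = 50
    weights: str = "inv_sqrt"
    mass_penalty: float = 0.0
    slack: float = 1e-6
    mass_cap: float | None = None
    lp_tol: float = 1e-9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.i_fit < 1:
            raise ValueError("i_fit must be >= 1")
        if self.mass_penalty < 0:
            raise ValueError("mass_penalty must be >= 0")
        if self.slack < 0 or self.lp_tol <= 0:
            raise ValueError("slack must be >= 0 and lp_tol > 0")
        if self.weights not in ("inv_sqrt", "uniform"):
            raise ValueError(f"unknown weights mode {self.weights!r}")


@dataclass
class FitResult:
    """A fitted histogram with its achieved discrepancy and solver diagnostics."""

    histogram: FrequencyHistogram
    objective_value: float
    diagnostics: dict


def _weights(F: np.ndarray, mode: str) -> np.ndarray:
    if mode == "uniform":
        return np.ones_like(F, dtype=float)
    return 1.0 / np.sqrt(1.0 + F)


def _fit_weights_and_range(sfs: SiteFrequencySpectrum, config: FitConfig) -> tuple[int, np.ndarray, np.ndarray]:
    """Effective fitted range, observed counts F[1..i_fit] and weights."""
    i_fit = min(config.i_fit, sfs.k)
    if i_fit < config.i_fit:
        logger.warning("i_fit lowered from %d to k=%d", config.i_fit, sfs.k)
    F = sfs.to_array(i_fit)[1:]
    return i_fit, F, _weights(F, config.weights)


class UnseenEst(BaseEstimator):
    """Linear-programming estimator of the variant frequency histogram.

    After :meth:`fit` on a :class:`SiteFrequencySpectrum`, exposes

    - ``histogram_`` : the fitted :class:`FrequencyHistogram` (grid mass plus
      the empirical frequent part),
    - ``objective_value_`` : the weighted L1 discrepancy achieved by the
      returned histogram,
    - ``diagnostics_`` : solver status, per-count residuals and stage
      objectives,

    and :meth:`predict` maps cohort sizes (individuals) to expected numbers
    of distinct variants via the discovery curve ``U(ploidy * individuals)``.
    """

    def __init__(
        self,
        x_min_factor: float = 50.0,
        ratio: float = 1.05,
        x_max: float = 1.0,
        i_fit: int = 50,
        weights: str = "inv_sqrt",
        mass_penalty: float = 0.0,
        slack: float = 1e-6,
        mass_cap: float | None = None,
        lp_tol: float = 1e-9,
        seed: int = 0,
    ):
        self.x_min_factor = x_min_factor
        self.ratio = ratio
        self.x_max = x_max
        self.i_fit = i_fit
        self.weights = weights
        self.mass_penalty = mass_penalty
        self.slack = slack
        self.mass_cap = mass_cap
        self.lp_tol = lp_tol
        self.seed = seed

    def _config(self) -> FitConfig:
        return FitConfig(**self.get_params())

    # -- fitting ----------------------------------------------------------

    def fit(self, sfs: SiteFrequencySpectrum, y=None) -> "UnseenEst":
        config = self._config()
        k = sfs.k
        i_fit, F, w = _fit_weights_and_range(sfs, config)

        frequent = tuple(
            (i / k, float(sfs.counts[i])) for i in sorted(sfs.counts) if i > i_fit
        )

        x_max = min(config.x_max, i_fit / k)
        x_min = min(1.0 / (config.x_min_factor * k), x_max)
        grid = build_grid(x_min, x_max, config.ratio)

        if sfs.total_variants == 0:
            logger.warning("empty SFS: returning zero histogram")
            self.histogram_ = FrequencyHistogram(grid, np.zeros(len(grid)))
            self.objective_value_ = 0.0
            self.diagnostics_ = {
                "status": "optimal",
                "i_fit": i_fit,
                "stage1_objective": 0.0,
                "residuals": np.zeros(i_fit),
                "grid_size": len(grid),
            }
            self.result_ = FitResult(self.histogram_, 0.0, self.diagnostics_)
            return self

        B = build_mixing_matrix(grid, k, i_fit).entries[1:, :]  # rows i = 1..i_fit

        # The frequent part also leaks expected counts into the fitted range;
        # subtract that contribution so the grid only explains the remainder.
        F_adj = F.copy()
        if frequent:
            fx = np.array([x for x, _ in frequent])
            fc = np.array([c for _, c in frequent])
            ii = np.arange(1, i_fit + 1)[:, None]
            from scipy import stats as _st

            F_adj = np.clip(F - _st.binom.pmf(ii, k, fx[None, :]) @ fc, 0.0, None)

        h, diag = self._solve(B, F_adj, w, config)
        hist = FrequencyHistogram(grid, h, frequent_part=frequent)
        self.histogram_ = hist
        self.objective_value_ = objective(hist, sfs, config)
        diag.update({"i_fit": i_fit, "grid_size": len(grid)})
        self.diagnostics_ = diag
        self.result_ = FitResult(hist, self.objective_value_, diag)
        return self

    def _solve(self, B: np.ndarray, F: np.ndarray, w: np.ndarray, config: FitConfig):
        m, n = B.shape
        # variables z = [h (n), e (m)]; e_i >= |(Bh)_i - F_i|
        A_res = np.block(
            [[B, -np.eye(m)], [-B, -np.eye(m)]]
        )
        b_res = np.concatenate([F, -F])
        rows = [A_res]
        rhs = [b_res]
        if config.mass_cap is not None:
            cap_row = np.concatenate([np.ones(n), np.zeros(m)])[None, :]
            rows.append(cap_row)
            rhs.append(np.array([config.mass_cap]))
        A_ub = np.vstack(rows)
        b_ub = np.concatenate(rhs)

        c1 = np.concatenate([np.full(n, config.mass_penalty), w])
        res1 = linprog(c1, A_ub=A_ub, b_ub=b_ub, bounds=(0, None), method="highs")
        if res1.status != 0:
            raise RuntimeError(f"stage-1 LP failed: {res1.message} (status {res1.status})")
        opt1 = float(res1.fun)

        # stage 2: minimise total mass among near-optimal fits; the bound gets
        # a small absolute floor so HiGHS's feasibility tolerance cannot make
        # the stage-1 vertex infeasible
        bound = opt1 * (1.0 + config.slack) + max(config.lp_tol, 1e-7 * (1.0 + opt1))
        A_ub2 = np.vstack([A_ub, c1[None, :]])
        b_ub2 = np.concatenate([b_ub, [bound]])
        c2 = np.concatenate([np.ones(n), np.zeros(m)])
        res2 = linprog(c2, A_ub=A_ub2, b_ub=b_ub2, bounds=(0, None), method="highs")
        if res2.status == 0:
            h = res2.x[:n]
        else:
            logger.warning(
                "stage-2 LP did not converge (%s); keeping the stage-1 optimum",
                res2.message,
            )
            h = res1.x[:n]
        neg = h < 0
        if np.any(neg):
            worst = h[neg].min()
            if worst < -config.lp_tol:
                logger.warning("clipping negative masses (min %.3e) to zero", worst)
            h = np.clip(h, 0.0, None)
        residuals = B @ h - F
        return h, {
            "status": "optimal",
            "stage1_objective": opt1,
            "stage2_total_mass": float(h.sum()),
            "residuals": residuals,
        }

    # -- prediction -------------------------------------------------------

    def predict(self, cohort_sizes, ploidy: int = 2) -> np.ndarray:
        """Expected distinct variants at each cohort size (in individuals)."""
        self._check_fitted()
        sizes = np.atleast_1d(np.asarray(cohort_sizes))
        return np.array([expected_unique(self.histogram_, ploidy * int(s)) for s in sizes])

    def predict_unique(self, n_alleles) -> float:
        """Discovery curve evaluated directly at an allele count."""
        self._check_fitted()
        return expected_unique(self.histogram_, n_alleles)

    def _check_fitted(self) -> None:
        if not hasattr(self, "histogram_"):
            raise RuntimeError("estimator is not fitted; call fit() first")


def fit(sfs: SiteFrequencySpectrum, config: FitConfig | None = None) -> FitResult:
    """Fit the LP estimator and return the :class:`FitResult`."""
    config = config or FitConfig()
    est = UnseenEst(**config.__dict__)
    est.fit(sfs)
    return est.result_


def objective(
    h: FrequencyHistogram, sfs: SiteFrequencySpectrum, config: FitConfig | None = None
) -> float:
    """Weighted L1 discrepancy ``Σ_{i=1..i_fit} w_i |E[F_i] − F_i]`` of a histogram.

    Pure function of the histogram and the observed SFS; used to verify
    solver optimality against caller-supplied feasible histograms.
    """
    config = config or FitConfig()
    i_fit, F, w = _fit_weights_and_range(sfs, config)
    from .spectrum import expected_sfs as _expected_sfs

    E = _expected_sfs(h, sfs.k, i_fit)[1:]
    return float(np.sum(w * np.abs(E - F)))


def predict_discovery_curve(
    fit_result: FitResult, cohort_sizes: Sequence[int], ploidy: int = 2
) -> list[tuple[int, float]]:
    """``[(individuals, expected distinct variants), ...]`` from a fitted histogram."""
    out = []
    for s in cohort_sizes:
        if s < 0:
            raise ValueError("cohort sizes must be >= 0")
        out.append((int(s), expected_unique(fit_result.histogram, ploidy * int(s))))
    return out


def fit_with_uncertainty(
    data,
    cohort_sizes: Sequence[int],
    n_partitions: int = 10,
    config: FitConfig | None = None,
    ploidy: int = 2,
    k: int | None = None,
):
    """Partition-based mean discovery curve with a standard-deviation band.

    ``data`` is either a sequence of :class:`SiteFrequencySpectrum` (one per
    partition, ``n_partitions`` ignored) or an array of per-variant allele
    counts together with ``k``, in which case the ``k`` alleles are randomly
    split into ``n_partitions`` disjoint groups (each variant's count divided
    by multivariate hypergeometric draws) and each group's SFS is fitted
    independently.  The uncertainty band is the standard deviation of the
    per-partition predictions — no parametric confidence interval is used.

    Returns ``(sizes, mean_curve, sd_curve, per_partition_curves)``.
    """
    config = config or FitConfig()
    if n_partitions < 2:
        raise ValueError("n_partitions must be >= 2")

    if len(data) > 0 and isinstance(data[0], SiteFrequencySpectrum):
        sfs_list = list(data)
    else:
        if k is None:
            raise ValueError("k is required when passing per-variant allele counts")
        from .cohort import split_alleles

        sfs_list = split_alleles(np.asarray(data), k, n_partitions, seed=config.seed)

    curves = []
    for idx, part in enumerate(sfs_list):
        if part.total_variants == 0:
            logger.warning("partition %d contains no variants; skipped", idx)
            continue
        res = fit(part, config)
        curves.append([expected_unique(res.histogram, ploidy * int(s)) for s in cohort_sizes])
    if len(curves) < 2:
        raise RuntimeError("fewer than 2 usable partitions")
    arr = np.asarray(curves)
    return (
        np.asarray(list(cohort_sizes)),
        arr.mean(axis=0),
        arr.std(axis=0, ddof=1),
        arr,
    )
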