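"""Site-frequency spectra, frequency histograms and the binomial observation model.

A cohort of ``k`` sampled alleles observes each population variant of
frequency ``x`` in ``i`` alleles with probability ``bin(x, k, i)`` — the
binomial pmf.  The observed data are summarised by the site-frequency
spectrum (SFS) ``{F_i}``: the number of variants seen in exactly ``i`` of the
``k`` alleles.  The quantity of interest is the frequency histogram ``h(x)``,
the number of distinct variants at each population frequency ``x``, including
variants with ``F_i = 0`` (unseen in the cohort).

This module provides the data containers plus the forward model: the mixing
matrix ``B[i, j] = bin(x_j, k, i)``, the expected SFS of a histogram, and the
discovery curve ``U(N) = Σ_j h_j (1 − (1 − x_j)^N)`` — the expected number of
distinct variants found in a cohort of ``N`` alleles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SiteFrequencySpectrum",
    "FrequencyGrid",
    "FrequencyHistogram",
    "MixingMatrix",
    "build_grid",
    "binomial_kernel",
    "build_mixing_matrix",
    "expected_sfs",
    "expected_unique",
    "read_sfs",
    "write_sfs",
    "read_histogram",
    "write_histogram",
]

# Poisson approximation policy for very large cohorts: bin(x, k, i) is
# replaced by Poisson(k*x) when k exceeds K_EXACT_MAX and k*x <= LAMBDA_SWITCH.
LAMBDA_SWITCH = 10.0
K_EXACT_MAX = 10_000


@dataclass(frozen=True)
class SiteFrequencySpectrum:
    """Observed SFS: ``counts[i]`` variants seen in exactly ``i`` of ``k`` alleles.

    ``F_0`` is never stored — unobserved variants are what the estimator
    infers.
    """

    k: int
    counts: Mapping[int, int]
    label: str = ""

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be a positive integer, got {self.k}")
        clean: dict[int, int] = {}
        for i, f in self.counts.items():
            i = int(i)
            if not 1 <= i <= self.k:
                raise ValueError(f"occurrence count {i} outside [1, k={self.k}]")
            if f < 0 or f != int(f):
                raise ValueError(f"F_{i} must be a non-negative integer, got {f}")
            if f > 0:
                clean[i] = int(f)
        object.__setattr__(self, "counts", clean)

    @property
    def total_variants(self) -> int:
        """Number of distinct observed variants, ``D = Σ_i F_i``."""
        return int(sum(self.counts.values()))

    def f(self, i: int) -> int:
        return int(self.counts.get(i, 0))

    def to_array(self, i_max: int) -> np.ndarray:
        """SFS as a dense vector ``F[0..i_max]`` (``F[0] = 0`` by definition)."""
        out = np.zeros(i_max + 1)
        for i, f in self.counts.items():
            if i <= i_max:
                out[i] = f
        return out


@dataclass(frozen=True)
class FrequencyGrid:
    """Strictly increasing frequencies in ``(0, 1]`` (geometric by default)."""

    points: np.ndarray
    x_min: float | None = None
    ratio: float | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 1 or len(pts) == 0:
            raise ValueError("grid needs at least one point")
        if pts[0] <= 0 or pts[-1] > 1 + 1e-12:
            raise ValueError("grid points must lie in (0, 1]")
        if np.any(np.diff(pts) <= 0):
            raise ValueError("grid points must be strictly increasing")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class FrequencyHistogram:
    """Number of distinct variants ``mass[j]`` at each grid frequency.

    ``frequent_part`` holds ``(frequency, count)`` pairs for variants treated
    empirically outside the LP (occurrence counts above the fitted range).
    Mass is an unnormalised variant count, not a fraction, so the expected
    SFS and the discovery curve need no separate total-variant symbol.
    """

    grid: FrequencyGrid
    mass: np.ndarray
    frequent_part: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        m = np.asarray(self.mass, dtype=float)
        if m.shape != (len(self.grid),):
            raise ValueError("mass must have one entry per grid point")
        if not np.all(np.isfinite(m)) or np.any(m < 0):
            raise ValueError("histogram masses must be finite and >= 0")
        object.__setattr__(self, "mass", m)
        fp = tuple((float(x), float(c)) for x, c in self.frequent_part)
        for x, c in fp:
            if not 0 < x <= 1:
                raise ValueError(f"frequent-part frequency {x} outside (0, 1]")
            if not (np.isfinite(c) and c >= 0):
                raise ValueError("frequent-part counts must be finite and >= 0")
        object.__setattr__(self, "frequent_part", fp)

    @property
    def total(self) -> float:
        """Total number of variants ``T`` (grid mass plus frequent part)."""
        return float(self.mass.sum() + sum(c for _, c in self.frequent_part))

    def all_points(self) -> tuple[np.ndarray, np.ndarray]:
        """Concatenated ``(frequencies, masses)`` over grid and frequent part."""
        if self.frequent_part:
            fx = np.array([x for x, _ in self.frequent_part])
            fc = np.array([c for _, c in self.frequent_part])
            return np.concatenate([self.grid.points, fx]), np.concatenate([self.mass, fc])
        return self.grid.points, self.mass


@dataclass(frozen=True)
class MixingMatrix:
    """``entries[i, j] = bin(x_j, k, i)`` for rows ``i = 0..i_max``."""

    entries: np.ndarray
    k: int
    grid: FrequencyGrid

    @property
    def i_max(self) -> int:
        return self.entries.shape[0] - 1


def build_grid(x_min: float, x_max: float = 1.0, ratio: float = 1.05) -> FrequencyGrid:
    """Geometric frequency grid ``x_min, x_min*ratio, ...`` capped at ``x_max``.

    ``x_max`` is appended when the geometric sequence does not land on it
    exactly.  ``x_min == x_max`` degenerates to a single-point grid.
    """
    if not 0 < x_min <= x_max <= 1:
        raise ValueError(f"need 0 < x_min <= x_max <= 1, got x_min={x_min}, x_max={x_max}")
    if ratio <= 1:
        raise ValueError(f"ratio must be > 1, got ratio={ratio}")
    if x_min == x_max:
        return FrequencyGrid(np.array([x_min]), x_min=x_min, ratio=ratio)
    n = int(math.floor(math.log(x_max / x_min) / math.log(ratio) * (1 + 1e-12)))
    pts = x_min * ratio ** np.arange(n + 1)
    if pts[-1] < x_max * (1 - 1e-9):
        pts = np.append(pts, x_max)
    else:
        pts[-1] = min(pts[-1], x_max)
    return FrequencyGrid(pts, x_min=x_min, ratio=ratio)


def binomial_kernel(x, k: int, i, approx: bool = False):
    """``bin(x, k, i)``: probability a frequency-``x`` variant is seen in ``i`` of ``k`` alleles.

    With ``approx=True`` the Poisson(``k*x``) pmf is used instead — accurate in
    the rare-variant regime (``k*x`` small, ``k`` large) and numerically robust
    at very large ``k``.
    """
    x_arr = np.asarray(x, dtype=float)
    i_arr = np.asarray(i)
    if np.any(x_arr < 0) or np.any(x_arr > 1):
        raise ValueError("frequency x must lie in [0, 1]")
    if np.any(i_arr < 0) or np.any(i_arr > k):
        raise ValueError(f"occurrence count i must lie in [0, k={k}]")
    if approx:
        out = stats.poisson.pmf(i_arr, k * x_arr)
    else:
        out = stats.binom.pmf(i_arr, k, x_arr)
    if np.ndim(out) == 0:
        return float(out)
    return out


def build_mixing_matrix(
    grid: FrequencyGrid, k: int, i_max: int, approx: bool | str = "auto"
) -> MixingMatrix:
    """Mixing matrix ``B[i, j] = bin(x_j, k, i)`` for ``i = 0..i_max``.

    ``approx="auto"`` switches individual entries to the Poisson kernel when
    ``k > 10,000`` and ``k * x_j <= 10`` (rare regime at biobank-scale ``k``).
    """
    if i_max > k:
        raise ValueError(f"i_max={i_max} exceeds k={k}")
    x = grid.points
    ii = np.arange(i_max + 1)[:, None]
    if approx == "auto":
        exact = stats.binom.pmf(ii, k, x[None, :])
        if k > K_EXACT_MAX:
            use_pois = (k * x <= LAMBDA_SWITCH)[None, :] & np.ones_like(ii, dtype=bool)
            pois = stats.poisson.pmf(ii, k * x[None, :])
            entries = np.where(use_pois, pois, exact)
        else:
            entries = exact
    elif approx:
        entries = stats.poisson.pmf(ii, k * x[None, :])
    else:
        entries = stats.binom.pmf(ii, k, x[None, :])
    return MixingMatrix(np.asarray(entries, dtype=float), k=k, grid=grid)


def expected_sfs(h: FrequencyHistogram, k: int, i_max: int | None = None) -> np.ndarray:
    """Expected SFS ``E[F_i] = Σ_j h_j bin(x_j, k, i)`` for ``i = 0..i_max``.

    With ``i_max = k`` the entries sum to the total mass ``T`` (conservation).
    The frequent part contributes through the same binomial kernel.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if i_max is None:
        i_max = k
    x, m = h.all_points()
    if len(x) == 0:
        return np.zeros(i_max + 1)
    ii = np.arange(i_max + 1)[:, None]
    B = stats.binom.pmf(ii, k, x[None, :])
    return B @ m


def expected_unique(h: FrequencyHistogram, N) -> float:
    """Discovery curve ``U(N) = Σ_j h_j (1 − (1 − x_j)^N)``.

    The expected number of distinct variants observed in a cohort of ``N``
    sampled alleles; ``U(0) = 0`` and ``U(N) → T`` as ``N → ∞``.
    """
    if N < 0:
        raise ValueError("N must be >= 0")
    if N == 0:
        return 0.0
    x, m = h.all_points()
    if len(x) == 0:
        return 0.0
    # -expm1(N*log1p(-x)) = 1 - (1-x)^N, stable for tiny x; x == 1 gives 1.
    with np.errstate(divide="ignore", invalid="ignore"):
        p = -np.expm1(N * np.log1p(-x))
    p = np.where(x >= 1.0, 1.0, p)
    return float(np.dot(m, p))


# --------------------------------------------------------------------------
# Plain-text serialisation
#
# SFS dialect:        "#k=<alleles>" comment, then "count\tnum_variants".
# Histogram dialect:  "#T=<total>" comment, then "frequency\tmass\tsource"
#                     with source in {grid, frequent}.
# --------------------------------------------------------------------------


def write_sfs(sfs: SiteFrequencySpectrum, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#k={sfs.k}\n")
        if sfs.label:
            fh.write(f"#label={sfs.label}\n")
        fh.write("count\tnum_variants\n")
        for i in sorted(sfs.counts):
            fh.write(f"{i}\t{sfs.counts[i]}\n")


def read_sfs(path) -> SiteFrequencySpectrum:
    k = None
    label = ""
    counts: dict[int, int] = {}
    header_seen = False
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("k="):
                k = int(body[2:])
            elif body.startswith("label="):
                label = body[6:]
            continue
        if not header_seen and line.split("\t")[0] == "count":
            header_seen = True
            continue
        i_str, f_str = line.split("\t")[:2]
        counts[int(i_str)] = int(f_str)
    if k is None:
        raise ValueError(f"missing '#k=' comment in SFS file {path}")
    return SiteFrequencySpectrum(k=k, counts=counts, label=label)


def write_histogram(h: FrequencyHistogram, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#T={h.total!r}\n")
        if h.grid.x_min is not None and h.grid.ratio is not None:
            fh.write(f"#grid=x_min:{h.grid.x_min!r},ratio:{h.grid.ratio!r}\n")
        fh.write("frequency\tmass\tsource\n")
        for x, m in zip(h.grid.points, h.mass):
            fh.write(f"{float(x)!r}\t{float(m)!r}\tgrid\n")
        for x, c in h.frequent_part:
            fh.write(f"{float(x)!r}\t{float(c)!r}\tfrequent\n")


def read_histogram(path) -> FrequencyHistogram:
    xs: list[float] = []
    ms: list[float] = []
    freq: list[tuple[float, float]] = []
    x_min = ratio = None
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("grid="):
                for part in body[5:].split(","):
                    key, val = part.split(":")
                    if key == "x_min":
                        x_min = float(val)
                    elif key == "ratio":
                        ratio = float(val)
            continue
        cols = line.split("\t")
        if cols[0] == "frequency":
            continue
        x, m, source = float(cols[0]), float(cols[1]), cols[2]
        if source == "frequent":
            freq.append((x, m))
        else:
            xs.append(x)
            ms.append(m)
    grid = FrequencyGrid(np.array(xs), x_min=x_min, ratio=ratio)
    return FrequencyHistogram(grid=grid, mass=np.array(ms), frequent_part=tuple(freq))
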