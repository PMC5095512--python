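"""Allele-count resampling: downsampling, census-weighted cohorts, partitions.

Three related tools built on the hypergeometric law (sampling alleles without
replacement from a larger called set):

- :func:`downsample_count` — project a single site's allele count onto a
  smaller number of sampled alleles;
- :func:`census_matched_sfs` — synthesise the SFS of a cohort whose ancestry
  proportions match configurable demographic weights (e.g. a national
  census), by downsampling each ancestry group to its weighted share;
- :func:`split_alleles` / :func:`validate_by_partition` — the validation
  protocol: randomly partition all alleles into disjoint groups, fit the
  estimator on one group's SFS (a small fraction of the data), predict the
  full cohort, and report the spread of predictions across groups as the
  uncertainty band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .spectrum import SiteFrequencySpectrum, expected_unique
from .variant_io import ClassFilter, VariantRecord

logger = logging.getLogger(__name__)

__all__ = [
    "CensusSpec",
    "downsample_count",
    "census_matched_sfs",
    "split_allele_counts",
    "split_alleles",
    "validate_by_partition",
    "PartitionValidationReport",
]


@dataclass(frozen=True)
class CensusSpec:
    """Target demography: ancestry weights, cohort size, ploidy.

    The default weights shipped with the CLI are documented placeholders —
    any real-cohort claim must supply the demography actually intended.
    """

    weights: Mapping[str, float]
    total_individuals: int
    ploidy: int = 2

    def __post_init__(self) -> None:
        w = dict(self.weights)
        if any(v < 0 for v in w.values()):
            raise ValueError("census weights must be non-negative")
        if abs(sum(w.values()) - 1.0) > 1e-9:
            raise ValueError("census weights must sum to 1")
        if self.total_individuals <= 0 or self.ploidy < 1:
            raise ValueError("total_individuals and ploidy must be positive")
        object.__setattr__(self, "weights", w)

    @property
    def total_alleles(self) -> int:
        return self.total_individuals * self.ploidy


def downsample_count(ac: int, an: int, n_target: int, mode: str = "sampled",
                     seed: int | None = None, rng: np.random.Generator | None = None):
    """Allele count after drawing ``n_target`` of ``an`` alleles without replacement.

    ``sampled`` draws from Hypergeometric(ngood=ac, nbad=an-ac, n=n_target);
    ``expected`` returns the mean ``ac * n_target / an`` (variance-free, for
    deterministic pipelines and tests).
    """
    if not 0 <= ac <= an:
        raise ValueError(f"need 0 <= ac={ac} <= an={an}")
    if n_target > an:
        raise ValueError(f"n_target={n_target} exceeds an={an}")
    if mode == "expected":
        return ac * n_target / an
    if mode != "sampled":
        raise ValueError(f"unknown mode {mode!r}")
    if rng is None:
        rng = np.random.default_rng(seed)
    if ac == 0 or n_target == 0:
        return 0
    return int(rng.hypergeometric(ac, an - ac, n_target))


def census_matched_sfs(
    records: Iterable[VariantRecord],
    census: CensusSpec,
    filt: ClassFilter | None = None,
    seed: int = 0,
    mode: str = "sampled",
    label: str = "census-matched",
) -> SiteFrequencySpectrum:
    """SFS of a synthetic cohort matching the census ancestry proportions.

    Each population is downsampled to its weighted allele share
    ``round(weight * ploidy * total)``; per-record counts are then summed
    across populations.  If some population cannot supply its share, the
    cohort is scaled down to the binding constraint with a warning.  Records
    whose summed downsampled count reaches 0 drop out — they become part of
    the "unseen" mass at the reduced cohort size.
    """
    filt = filt or ClassFilter()
    recs = [r for r in records if filt.matches(r)]
    pops = [p for p, w in census.weights.items() if w > 0]
    for r in recs:
        for p in pops:
            if p not in r.an:
                raise ValueError(f"population {p!r} absent from record {r.chrom}:{r.pos}")

    available = {p: min(r.an[p] for r in recs) for p in pops} if recs else {}
    total = census.total_individuals
    if recs:
        binding = min(
            int(available[p] / (census.weights[p] * census.ploidy)) for p in pops
        )
        if binding < total:
            logger.warning(
                "census cohort scaled down from %d to %d individuals "
                "(insufficient alleles in some population)", total, binding,
            )
            total = binding
    targets = {p: int(round(census.weights[p] * census.ploidy * total)) for p in pops}
    k = sum(targets.values())

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    counts: dict[int, int] = {}
    for r in recs:
        summed = 0.0
        for p in pops:
            summed += downsample_count(r.ac[p], r.an[p], targets[p], mode=mode, rng=rng)
        i = int(round(summed))
        if i > 0:
            counts[i] = counts.get(i, 0) + 1
    return SiteFrequencySpectrum(k=k, counts=counts, label=label)


def _group_sizes(k: int, n_groups: int) -> np.ndarray:
    """k alleles into n_groups: the remainder goes one-per-group to the first groups."""
    base = k // n_groups
    sizes = np.full(n_groups, base, dtype=int)
    sizes[: k % n_groups] += 1
    return sizes


def split_allele_counts(
    counts: np.ndarray, k: int, n_groups: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Divide each variant's allele count across disjoint allele groups.

    Returns ``(matrix, group_sizes)`` where ``matrix[v, g]`` is variant ``v``'s
    count in group ``g`` — a multivariate hypergeometric draw with the group
    sizes as colours, so each variant's counts sum back to its total exactly.
    """
    counts = np.asarray(counts, dtype=int)
    if n_groups < 2:
        raise ValueError("n_groups must be >= 2")
    if n_groups > k:
        raise ValueError(f"n_groups={n_groups} exceeds k={k}")
    if np.any(counts < 0) or np.any(counts > k):
        raise ValueError("allele counts must lie in [0, k]")
    sizes = _group_sizes(k, n_groups)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    matrix = np.empty((len(counts), n_groups), dtype=int)
    for v, ac in enumerate(counts):
        matrix[v] = rng.multivariate_hypergeometric(sizes, int(ac))
    return matrix, sizes


def split_alleles(
    counts: np.ndarray, k: int, n_groups: int, seed: int = 0
) -> list[SiteFrequencySpectrum]:
    """Per-group SFS after randomly partitioning the ``k`` alleles."""
    matrix, sizes = split_allele_counts(counts, k, n_groups, seed=seed)
    out = []
    for g in range(n_groups):
        col = matrix[:, g]
        ii, ff = np.unique(col[col > 0], return_counts=True)
        out.append(
            SiteFrequencySpectrum(
                k=int(sizes[g]),
                counts=dict(zip(ii.tolist(), ff.tolist())),
                label=f"partition-{g}",
            )
        )
    return out


@dataclass
class PartitionValidationReport:
    """Results of the partition-and-extrapolate validation protocol."""

    n_groups: int
    group_sizes: np.ndarray
    predictions: np.ndarray          # per-group predicted distinct count at full k
    observed_distinct: int
    observed_sfs: SiteFrequencySpectrum
    extra_curves: dict = field(default_factory=dict)

    @property
    def mean_prediction(self) -> float:
        return float(self.predictions.mean())

    @property
    def sd_prediction(self) -> float:
        return float(self.predictions.std(ddof=1))

    @property
    def relative_error(self) -> float:
        """(mean prediction − observed) / observed."""
        return (self.mean_prediction - self.observed_distinct) / self.observed_distinct


def validate_by_partition(
    counts: np.ndarray,
    k: int,
    n_groups: int = 10,
    config=None,
    seed: int | None = None,
    extra_sizes: Sequence[int] | None = None,
) -> PartitionValidationReport:
    """Train on one allele partition, predict the whole cohort, repeat.

    ``counts`` are per-variant allele counts among all ``k`` alleles (zeros
    allowed and ignored — only observed variants enter the SFS).  With the
    default ``n_groups=10`` each fit sees 10% of the alleles and is asked to
    predict the distinct-variant count of the full cohort; the report carries
    each group's prediction, their mean and standard deviation, and the
    observed full-cohort value for comparison.
    """
    from .estimator import FitConfig, fit as lp_fit

    config = config or FitConfig()
    if seed is None:
        seed = config.seed
    counts = np.asarray(counts, dtype=int)
    parts = split_alleles(counts, k, n_groups, seed=seed)
    sizes = np.array([p.k for p in parts])

    preds = []
    extras: dict[int, list[float]] = {int(s): [] for s in (extra_sizes or [])}
    for part in parts:
        if part.total_variants == 0:
            logger.warning("partition with no variants skipped")
            continue
        res = lp_fit(part, config)
        preds.append(expected_unique(res.histogram, k))
        for s in extras:
            extras[s].append(expected_unique(res.histogram, s))
    if len(preds) < 2:
        raise RuntimeError("fewer than 2 usable partitions")

    obs = counts[counts > 0]
    ii, ff = np.unique(obs, return_counts=True)
    observed_sfs = SiteFrequencySpectrum(k=k, counts=dict(zip(ii.tolist(), ff.tolist())))
    return PartitionValidationReport(
        n_groups=n_groups,
        group_sizes=sizes,
        predictions=np.asarray(preds),
        observed_distinct=int(len(obs)),
        observed_sfs=observed_sfs,
        extra_curves={s: np.asarray(v) for s, v in extras.items()},
    )
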