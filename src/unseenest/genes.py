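"""Gene-level loss-of-function frequency estimation.

Instead of counting variants, count genes: ``F_i`` becomes the number of
genes carrying at least one LoF variant in exactly ``i`` of the ``k``
sampled alleles.  Fitting the same LP to this gene SFS yields a histogram
whose mass counts GENES by their LoF allele frequency — the basis for
intolerance binning (how many genes have LoF frequency < 1e-5?) and for
projecting how many genes will have ``>= t`` LoF alleles in larger cohorts.

A gene's allele count is approximated as the sum of its sites' LoF allele
counts, capped at ``k``: rare LoF alleles essentially never co-occur on one
haplotype and sites-only data carries no phase, so the sum is the natural
estimate of the number of LoF-carrying alleles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .estimator import FitConfig, fit as lp_fit
from .spectrum import FrequencyHistogram, SiteFrequencySpectrum, expected_unique
from .variant_io import VariantRecord

logger = logging.getLogger(__name__)

__all__ = [
    "GeneLofSpectrum",
    "build_gene_spectrum",
    "fit_gene_histogram",
    "bin_genes",
    "genes_with_at_least",
]


@dataclass(frozen=True)
class GeneLofSpectrum:
    """Per-gene aggregated LoF allele counts, reducible to a gene SFS."""

    k: int
    gene_counts: dict[str, int]

    def __post_init__(self) -> None:
        for g, c in self.gene_counts.items():
            if not 1 <= c <= self.k:
                raise ValueError(f"gene {g}: count {c} outside [1, k={self.k}]")

    @property
    def sfs(self) -> SiteFrequencySpectrum:
        counts: dict[int, int] = {}
        for c in self.gene_counts.values():
            counts[c] = counts.get(c, 0) + 1
        return SiteFrequencySpectrum(k=self.k, counts=counts, label="gene-lof")

    @property
    def n_genes(self) -> int:
        return len(self.gene_counts)


def build_gene_spectrum(
    records: Iterable[VariantRecord],
    k: int,
    populations: Sequence[str] | None = None,
    stats_out: dict | None = None,
) -> GeneLofSpectrum:
    """Aggregate (already LoF-filtered) records into per-gene allele counts.

    ``gene_count(g) = min(k, Σ_sites ac)``; records without a gene label are
    counted and skipped.
    """
    counters = stats_out if stats_out is not None else {}
    counters.setdefault("no_gene_label", 0)
    totals: dict[str, int] = {}
    for r in records:
        if not r.gene:
            counters["no_gene_label"] += 1
            continue
        totals[r.gene] = totals.get(r.gene, 0) + r.pooled_ac(populations)
    gene_counts = {g: min(k, c) for g, c in totals.items() if c > 0}
    if counters["no_gene_label"]:
        logger.info("skipped %d records without gene labels", counters["no_gene_label"])
    return GeneLofSpectrum(k=k, gene_counts=gene_counts)


def fit_gene_histogram(
    spectrum: GeneLofSpectrum, config: FitConfig | None = None
) -> FrequencyHistogram:
    """LP fit of the gene SFS; the returned histogram's mass counts genes.

    ``config.mass_cap`` can bound the total at a genome-wide gene count.
    """
    return lp_fit(spectrum.sfs, config).histogram


def bin_genes(h: FrequencyHistogram, edges: Sequence[float]) -> tuple[list[str], np.ndarray]:
    """Histogram mass per LoF-frequency bin.

    ``edges = (e1 < e2 < ...)`` in (0, 1) produce the half-open bins
    ``[0, e1), [e1, e2), ..., [e_last, 1]``; bin totals sum to ``T``.
    Returns ``(labels, counts)``.
    """
    edges = list(edges)
    if not edges:
        raise ValueError("need at least one bin edge")
    if any(not 0 < e < 1 for e in edges) or any(
        b <= a for a, b in zip(edges, edges[1:])
    ):
        raise ValueError("edges must be strictly increasing within (0, 1)")
    x, m = h.all_points()
    bounds = [0.0, *edges, np.inf]
    labels = [f"<{edges[0]:g}"]
    labels += [f"{a:g}-{b:g}" for a, b in zip(edges, edges[1:])]
    labels.append(f">={edges[-1]:g}")
    counts = np.array(
        [m[(x >= lo) & (x < hi)].sum() for lo, hi in zip(bounds, bounds[1:])]
    )
    return labels, counts


def genes_with_at_least(h: FrequencyHistogram, n_alleles: int, t: int = 1) -> float:
    """Expected number of genes with at least ``t`` LoF alleles among ``n_alleles``.

    ``Σ_j h_j · P(Binomial(n_alleles, x_j) >= t)``; at ``t = 1`` this is the
    discovery curve ``U(n_alleles)`` (same stable complement formula is used
    so the reduction is exact), and for fixed ``t`` it is non-decreasing in
    ``n_alleles``, saturating at the total mass ``T``.
    """
    if t < 1:
        raise ValueError("t must be >= 1")
    if n_alleles < t:
        raise ValueError(f"t={t} exceeds n_alleles={n_alleles}")
    if t == 1:
        return expected_unique(h, n_alleles)
    x, m = h.all_points()
    if len(x) == 0:
        return 0.0
    p = stats.binom.sf(t - 1, n_alleles, x)
    return float(np.dot(m, p))
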