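"""Synthetic cohorts: true frequency histograms, binomial sampling, fixture VCFs.

Scenarios define a true population frequency histogram for ``T`` variants
(or genes), from which cohorts of ``k`` alleles are drawn under the binomial
observation model.  The generator also serialises minimal annotated
sites-only VCFs (per-population AC/AN, a VEP-style CSQ string with a LOFTEE
confidence subfield, and a trinucleotide CONTEXT tag) so that the whole
VCF → SFS → fit pipeline is testable without any external download.

Shipped frequency models
------------------------
``pointmass``     all ``T`` variants at one frequency.
``mixture``       explicit list of ``(frequency, fraction_of_T)`` components.
``neutral_like``  mass ∝ 1/x on a geometric grid — the flat-per-decade shape
                  of a constant-size neutral coalescent; stands in for
                  synonymous-like variation.
``beta``          Beta(a, b) density discretised onto the grid; with a heavy
                  low-frequency skew (default a=0.5, b=50) it stands in for
                  deleterious, loss-of-function-like variation that segregates
                  comparatively rarely.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .spectrum import (
    FrequencyGrid,
    FrequencyHistogram,
    SiteFrequencySpectrum,
    build_grid,
)

__all__ = [
    "SimScenario",
    "SampledCohort",
    "make_true_histogram",
    "sample_cohort",
    "write_fixture_vcf",
    "lof_like_scenario",
    "neutral_like_scenario",
]

DEFAULT_ANNOTATION_PROFILE = {"synonymous": 0.35, "missense": 0.55, "lof": 0.10}


@dataclass
class SimScenario:
    """Parameters of one synthetic study condition."""

    model: str = "neutral_like"
    T: int = 10_000
    k: int = 2_000
    seed: int = 0
    freq_range: tuple[float, float] = (1e-5, 1.0)
    ratio: float = 1.05
    point_x: float = 0.01
    components: tuple[tuple[float, float], ...] = ((1e-3, 0.5), (1e-2, 0.5))
    beta_a: float = 0.5
    beta_b: float = 50.0
    populations: Mapping[str, float] | None = None
    annotation_profile: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ANNOTATION_PROFILE)
    )
    lof_hc_fraction: float = 0.8
    cpg_fraction: float = 0.2
    transition_fraction: float = 0.7
    n_genes: int = 200

    def __post_init__(self) -> None:
        if self.model not in ("pointmass", "mixture", "neutral_like", "beta"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.T <= 0:
            raise ValueError("T must be > 0")
        lo, hi = self.freq_range
        if not 0 < lo <= hi <= 1:
            raise ValueError("freq_range must satisfy 0 < lo <= hi <= 1")
        frac_sum = sum(self.annotation_profile.values())
        if abs(frac_sum - 1.0) > 1e-9:
            raise ValueError("annotation_profile fractions must sum to 1")
        if self.populations is not None:
            if abs(sum(self.populations.values()) - 1.0) > 1e-9:
                raise ValueError("population weights must sum to 1")


def neutral_like_scenario(T: int = 50_000, k: int = 2_000, seed: int = 0) -> SimScenario:
    """Synonymous-like condition: mass ∝ 1/x over (1e-5, 1]."""
    return SimScenario(model="neutral_like", T=T, k=k, seed=seed)


def lof_like_scenario(T: int = 50_000, k: int = 2_000, seed: int = 0) -> SimScenario:
    """Deleterious-variation condition: Beta(0.5, 5000), heavy rare skew.

    The shape parameters put the bulk of variants below frequency 1e-3
    (mean 1e-4), mirroring how strongly deleterious loss-of-function
    variation segregates in large healthy cohorts.
    """
    return SimScenario(model="beta", T=T, k=k, seed=seed, beta_a=0.5, beta_b=5000.0)


def make_true_histogram(scenario: SimScenario) -> FrequencyHistogram:
    """True histogram of the scenario; deterministic, total mass exactly ``T``."""
    lo, hi = scenario.freq_range
    if scenario.model == "pointmass":
        grid = FrequencyGrid(np.array([scenario.point_x]))
        return FrequencyHistogram(grid, np.array([float(scenario.T)]))
    if scenario.model == "mixture":
        comps = sorted(scenario.components)
        xs = np.array([x for x, _ in comps])
        fr = np.array([f for _, f in comps])
        if abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError("mixture fractions must sum to 1")
        return FrequencyHistogram(FrequencyGrid(xs), scenario.T * fr)
    grid = build_grid(lo, hi, scenario.ratio)
    x = grid.points
    edges = np.concatenate([[lo], np.sqrt(x[:-1] * x[1:]), [hi]])
    if scenario.model == "neutral_like":
        # density ∝ 1/x (constant-size coalescent) integrated per grid cell
        w = np.log(edges[1:] / edges[:-1])
    else:  # beta: probability mass per grid cell from cdf differences
        cdf = stats.beta.cdf(edges, scenario.beta_a, scenario.beta_b)
        w = np.diff(cdf)
        if w.sum() <= 0:
            raise ValueError("beta model has no mass inside freq_range")
    mass = scenario.T * w / w.sum()
    return FrequencyHistogram(grid, mass)


def _expand_variant_frequencies(h: FrequencyHistogram) -> np.ndarray:
    """Per-variant true frequencies; histogram masses rounded to integer counts.

    Largest-remainder rounding keeps the variant total exactly ``round(T)``.
    """
    x, m = h.all_points()
    base = np.floor(m).astype(int)
    deficit = int(round(m.sum())) - int(base.sum())
    if deficit > 0:
        order = np.argsort(-(m - base))
        base[order[:deficit]] += 1
    return np.repeat(x, base)


@dataclass
class SampledCohort:
    """One realised cohort: per-variant truth and observation."""

    scenario: SimScenario
    freqs: np.ndarray          # true frequency per variant (length T)
    counts: np.ndarray         # observed allele count per variant (length T)
    k: int

    @property
    def sfs(self) -> SiteFrequencySpectrum:
        seen = self.counts[self.counts > 0]
        ii, ff = np.unique(seen, return_counts=True)
        return SiteFrequencySpectrum(
            k=self.k, counts=dict(zip(ii.tolist(), ff.tolist())),
            label=f"simulated:{self.scenario.model}",
        )

    @property
    def n_observed(self) -> int:
        return int(np.count_nonzero(self.counts))

    @property
    def n_unseen(self) -> int:
        return int(len(self.counts) - self.n_observed)


def sample_cohort(
    h_true: FrequencyHistogram, k: int, seed: int = 0, scenario: SimScenario | None = None
) -> SampledCohort:
    """Draw one cohort of ``k`` alleles: count_v ~ Binomial(k, x_v) per variant."""
    freqs = _expand_variant_frequencies(h_true)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    counts = rng.binomial(k, freqs)
    scen = scenario or SimScenario(model="pointmass", T=max(1, len(freqs)), k=k, seed=seed)
    return SampledCohort(scenario=scen, freqs=freqs, counts=counts, k=k)


def simulate_scenario(scenario: SimScenario) -> tuple[FrequencyHistogram, SampledCohort]:
    """Convenience: true histogram plus one sampled cohort at the scenario's k."""
    h = make_true_histogram(scenario)
    return h, sample_cohort(h, scenario.k, seed=scenario.seed, scenario=scenario)


# --------------------------------------------------------------------------
# Fixture VCF writer
# --------------------------------------------------------------------------

_CSQ_FIELDS = ("Allele", "Consequence", "SYMBOL", "Gene", "LoF")

_CLASS_TEMPLATES = {
    # (ref, alt, context) per mutation class; contexts chosen so the CpG rule
    # fires only for the CpG class.
    "CpG_transition": ("C", "T", "ACG"),
    "nonCpG_transition": ("A", "G", "CAT"),
    "transversion": ("A", "T", "CAT"),
}

_CONSEQUENCE_TERMS = {
    "synonymous": "synonymous_variant",
    "missense": "missense_variant",
    "lof": "stop_gained",
}


def _deterministic_labels(n: int, fractions: Mapping[str, float]) -> list[str]:
    """Assign class labels with exact quotas (largest remainder), interleaved."""
    keys = sorted(fractions)
    quota = {c: int(np.floor(fractions[c] * n)) for c in keys}
    rem = n - sum(quota.values())
    order = sorted(keys, key=lambda c: -(fractions[c] * n - quota[c]))
    for c in order[:rem]:
        quota[c] += 1
    labels: list[str] = []
    pools = {c: quota[c] for c in keys}
    while len(labels) < n:
        for c in keys:
            if pools[c] > 0:
                labels.append(c)
                pools[c] -= 1
    return labels[:n]


def write_fixture_vcf(cohort: SampledCohort, scenario: SimScenario, path) -> None:
    """Serialise the observed variants of a cohort as an annotated sites VCF.

    Per-population AC/AN are realised by multivariate hypergeometric division
    of each variant's total allele count across populations (so population
    counts always sum back to the pooled count).  Annotations follow the
    scenario's profile with exact class quotas.
    """
    rng = np.random.default_rng(np.random.SeedSequence((scenario.seed, 0xFACE)))
    obs_idx = np.nonzero(cohort.counts > 0)[0]
    n = len(obs_idx)
    pops = dict(scenario.populations) if scenario.populations else {"ALL": 1.0}
    pop_names = sorted(pops)
    # integer per-population allele numbers summing to k
    sizes = np.array([pops[p] * cohort.k for p in pop_names])
    an_pop = np.floor(sizes).astype(int)
    for i in np.argsort(-(sizes - an_pop))[: cohort.k - an_pop.sum()]:
        an_pop[i] += 1

    consequences = _deterministic_labels(n, scenario.annotation_profile)
    mut_fracs = {
        "CpG_transition": scenario.cpg_fraction,
        "nonCpG_transition": max(0.0, scenario.transition_fraction - scenario.cpg_fraction),
        "transversion": 1.0 - scenario.transition_fraction,
    }
    mut_classes = _deterministic_labels(n, mut_fracs)
    n_lof = sum(1 for c in consequences if c == "lof")
    hc_labels = iter(_deterministic_labels(max(n_lof, 1), {
        "HC": scenario.lof_hc_fraction, "LC": 1.0 - scenario.lof_hc_fraction,
    }))

    lines = []
    lines.append("##fileformat=VCFv4.2")
    lines.append('##contig=<ID=1,length=100000000>')
    lines.append('##INFO=<ID=AC,Number=A,Type=Integer,Description="Alternate allele count">')
    lines.append('##INFO=<ID=AN,Number=1,Type=Integer,Description="Total called alleles">')
    for p in pop_names:
        lines.append(f'##INFO=<ID=AC_{p},Number=A,Type=Integer,Description="Alt allele count in {p}">')
        lines.append(f'##INFO=<ID=AN_{p},Number=1,Type=Integer,Description="Called alleles in {p}">')
    lines.append('##INFO=<ID=CONTEXT,Number=1,Type=String,Description="Reference trinucleotide context">')
    lines.append(
        '##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence annotations. '
        f'Format: {"|".join(_CSQ_FIELDS)}">'
    )
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")

    for row, v in enumerate(obs_idx):
        ac_total = int(cohort.counts[v])
        pos = 1000 + 100 * row
        ref, alt, context = _CLASS_TEMPLATES[mut_classes[row]]
        cons = consequences[row]
        term = _CONSEQUENCE_TERMS[cons]
        lof_flag = next(hc_labels) if cons == "lof" else ""
        gene_idx = row % scenario.n_genes
        gene = f"GENE{gene_idx:04d}"
        if len(pop_names) == 1:
            ac_split = np.array([ac_total])
        else:
            ac_split = rng.multivariate_hypergeometric(an_pop, ac_total)
        info = [f"AC={ac_total}", f"AN={cohort.k}"]
        for p, ac_p, an_p in zip(pop_names, ac_split, an_pop):
            info.append(f"AC_{p}={int(ac_p)}")
            info.append(f"AN_{p}={int(an_p)}")
        info.append(f"CONTEXT={context}")
        info.append(f"CSQ={alt}|{term}|{gene}|ENSG{gene_idx:011d}|{lof_flag}")
        lines.append(
            f"1\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t{';'.join(info)}"
        )

    Path(path).write_text("\n".join(lines) + "\n")
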