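"""Build site-frequency spectra from annotated sites-only VCFs.

Consumes VCFs that already carry VEP-style CSQ consequence annotations (with
a LOFTEE confidence subfield) and per-population AC/AN counts in INFO — the
layout of public aggregate releases.  Genotypes are never read; this module
only parses, classifies and filters pre-annotated allele counts.

Loss-of-function here means a single-nucleotide substitution that introduces
a stop codon or disrupts a splice donor/acceptor site; by default only
high-confidence (LOFTEE ``HC``) calls pass the LoF filter.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .spectrum import SiteFrequencySpectrum

logger = logging.getLogger(__name__)

__all__ = [
    "VariantRecord",
    "ClassFilter",
    "LOF_CONSEQUENCES",
    "read_sites_vcf",
    "classify_mutation",
    "sfs_from_records",
    "load_bed_mask",
]

BASES = {"A", "C", "G", "T"}
PURINES = {"A", "G"}

LOF_CONSEQUENCES = {"stop_gained", "splice_donor_variant", "splice_acceptor_variant"}
MISSENSE_CONSEQUENCES = {"missense_variant"}
SYNONYMOUS_CONSEQUENCES = {"synonymous_variant"}


@dataclass
class VariantRecord:
    """One biallelic SNV with per-population allele counts and class labels."""

    chrom: str
    pos: int            # 1-based, as in VCF
    ref: str
    alt: str
    ac: dict[str, int]
    an: dict[str, int]
    consequence: str = "other"          # synonymous | missense | lof | other
    lof_confidence: str | None = None   # HC | LC | None
    mutation_class: str = "unknown"
    gene: str | None = None

    def __post_init__(self) -> None:
        if self.ref not in BASES or self.alt not in BASES or self.ref == self.alt:
            raise ValueError(f"ref/alt must be distinct single bases, got {self.ref}>{self.alt}")
        for p, a in self.ac.items():
            n = self.an.get(p, 0)
            if not 0 <= a <= n:
                raise ValueError(f"population {p}: need 0 <= ac={a} <= an={n}")

    def pooled_ac(self, populations: Sequence[str] | None = None) -> int:
        pops = populations or list(self.ac)
        return int(sum(self.ac[p] for p in pops))

    def pooled_an(self, populations: Sequence[str] | None = None) -> int:
        pops = populations or list(self.an)
        return int(sum(self.an[p] for p in pops))


def classify_mutation(ref: str, alt: str, context: str | None = None) -> str:
    """Mutation class by the purine/pyrimidine rule plus CpG context.

    A CpG transition is a C→T change whose reference trinucleotide places the
    C in a CG dinucleotide — or, by reverse-complement symmetry, a G→A change
    preceded by C.  Without context a C→T / G→A transition is ``unknown``
    (the CpG call needs the neighbouring base); other transitions and all
    transversions need no context.
    """
    if ref not in BASES or alt not in BASES or ref == alt:
        raise ValueError(f"invalid substitution {ref}>{alt}")
    transition = (ref in PURINES) == (alt in PURINES)
    if not transition:
        return "transversion"
    if (ref, alt) not in (("C", "T"), ("G", "A")):
        return "nonCpG_transition"
    if context is None or len(context) != 3 or context[1] != ref:
        return "unknown"
    if ref == "C" and context[2] == "G":
        return "CpG_transition"
    if ref == "G" and context[0] == "C":
        return "CpG_transition"
    return "nonCpG_transition"


def _consequence_category(csq_terms: str) -> str:
    terms = set(csq_terms.split("&"))
    if terms & LOF_CONSEQUENCES:
        return "lof"
    if terms & MISSENSE_CONSEQUENCES:
        return "missense"
    if terms & SYNONYMOUS_CONSEQUENCES:
        return "synonymous"
    return "other"


def _csq_format_from_header(vcf) -> list[str] | None:
    try:
        desc = vcf.get_header_type("CSQ")["Description"]
    except KeyError:
        return None
    m = re.search(r"Format:\s*([\w|]+)", desc)
    if not m:
        return None
    return m.group(1).split("|")


def read_sites_vcf(
    path,
    csq_spec: Sequence[str] | None = None,
    populations: Sequence[str] | None = None,
    stats: dict | None = None,
) -> list[VariantRecord]:
    """Parse a sites VCF into :class:`VariantRecord` objects.

    Multi-allelic sites are split into one record per alternate allele.
    Indels and non-SNV alleles are skipped (SNV discovery only) and counted
    in ``stats``; records whose CSQ cannot be interpreted are kept with
    consequence ``other``.  When ``populations`` is given, AC_<pop>/AN_<pop>
    INFO fields are required and records missing one are skipped.
    Otherwise plain AC/AN are read under the population name ``ALL``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    csq_fields = list(csq_spec) if csq_spec else _csq_format_from_header(vcf)
    counters = stats if stats is not None else {}
    for key in ("records", "skipped_non_snv", "skipped_missing_counts", "malformed_csq"):
        counters.setdefault(key, 0)

    records: list[VariantRecord] = []
    for var in vcf:
        alts = var.ALT or []
        for alt_idx, alt in enumerate(alts):
            if len(var.REF) != 1 or len(alt) != 1 or var.REF not in BASES or alt not in BASES:
                counters["skipped_non_snv"] += 1
                continue
            ac: dict[str, int] = {}
            an: dict[str, int] = {}
            ok = True
            pop_keys = (
                [(p, f"AC_{p}", f"AN_{p}") for p in populations]
                if populations
                else [("ALL", "AC", "AN")]
            )
            for pop, ac_key, an_key in pop_keys:
                ac_val = var.INFO.get(ac_key)
                an_val = var.INFO.get(an_key)
                if ac_val is None or an_val is None:
                    ok = False
                    break
                if isinstance(ac_val, tuple):
                    ac_val = ac_val[alt_idx]
                ac[pop] = int(ac_val)
                an[pop] = int(an_val)
            if not ok:
                counters["skipped_missing_counts"] += 1
                continue

            consequence, lof_conf, gene = "other", None, None
            csq_raw = var.INFO.get("CSQ")
            if csq_raw and csq_fields:
                entry = _pick_csq_entry(str(csq_raw), csq_fields, alt)
                if entry is None:
                    counters["malformed_csq"] += 1
                else:
                    consequence = _consequence_category(entry.get("Consequence", ""))
                    lof = entry.get("LoF", "")
                    lof_conf = lof if lof in ("HC", "LC") else None
                    gene = entry.get("SYMBOL") or entry.get("Gene") or None
            elif csq_raw:
                counters["malformed_csq"] += 1

            context = var.INFO.get("CONTEXT")
            records.append(
                VariantRecord(
                    chrom=var.CHROM,
                    pos=var.POS,
                    ref=var.REF,
                    alt=alt,
                    ac=ac,
                    an=an,
                    consequence=consequence,
                    lof_confidence=lof_conf,
                    mutation_class=classify_mutation(var.REF, alt, context),
                    gene=gene,
                )
            )
            counters["records"] += 1
    if counters["skipped_non_snv"]:
        logger.info("skipped %d non-SNV alleles", counters["skipped_non_snv"])
    return records


def _pick_csq_entry(csq_raw: str, fields: Sequence[str], alt: str) -> dict | None:
    entries = []
    for chunk in csq_raw.split(","):
        vals = chunk.split("|")
        if len(vals) != len(fields):
            continue
        entries.append(dict(zip(fields, vals)))
    if not entries:
        return None
    for e in entries:
        if e.get("Allele") == alt:
            return e
    return entries[0]


def load_bed_mask(path) -> dict[str, IntervalTree]:
    """Read a BED coverage mask into per-chromosome interval trees.

    BED is 0-based half-open; :meth:`ClassFilter.in_mask` converts VCF's
    1-based positions at the boundary.
    """
    trees: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            trees.setdefault(chrom, IntervalTree()).addi(int(start), int(end))
    return trees


@dataclass
class ClassFilter:
    """Selects records by consequence, LoF confidence, mutation class, mask."""

    consequence: str | None = None
    lof_confidence: str | None = None
    mutation_class: str | set | None = None
    populations: Sequence[str] | None = None
    mask: Mapping[str, IntervalTree] | None = None

    def __post_init__(self) -> None:
        if self.lof_confidence is not None and self.consequence not in (None, "lof"):
            raise ValueError("a LoF-confidence requirement implies consequence='lof'")
        if self.lof_confidence is not None:
            self.consequence = "lof"

    def in_mask(self, record: VariantRecord) -> bool:
        if self.mask is None:
            return True
        tree = self.mask.get(record.chrom)
        return bool(tree is not None and tree.overlaps(record.pos - 1))

    def matches(self, record: VariantRecord) -> bool:
        if self.consequence is not None and record.consequence != self.consequence:
            return False
        if self.lof_confidence is not None and record.lof_confidence != self.lof_confidence:
            return False
        if self.mutation_class is not None:
            allowed = (
                {self.mutation_class}
                if isinstance(self.mutation_class, str)
                else set(self.mutation_class)
            )
            if record.mutation_class not in allowed:
                return False
        return self.in_mask(record)


def sfs_from_records(
    records: Iterable[VariantRecord],
    filt: ClassFilter | None = None,
    populations: Sequence[str] | None = None,
    nominal_an: int | None = None,
    an_floor: float = 0.8,
    seed: int = 0,
    downsample_mode: str = "expected",
    label: str = "",
) -> SiteFrequencySpectrum:
    """Bin filtered records into an SFS: ``F_i`` = passing records with ``ac = i``.

    Real call sets have per-site missingness, so AN varies; the SFS type needs
    one ``k``.  Policy: ``k`` is ``nominal_an`` (default: the modal pooled AN
    of the selection); records with ``an > k`` are hypergeometrically
    downsampled to ``k`` alleles and records with ``an < an_floor * k`` are
    excluded — echoing the at-least-80%-of-individuals coverage rule of large
    exome releases.  Records with (downsampled) ``ac = 0`` drop out: they are
    exactly the "unseen" set the estimator later infers.
    """
    filt = filt or ClassFilter()
    pops = populations or (filt.populations if filt.populations else None)
    selected = [r for r in records if filt.matches(r)]
    if not selected:
        logger.warning("no records pass the filter; returning empty SFS")
        return SiteFrequencySpectrum(k=nominal_an or 1, counts={}, label=label)

    ans = np.array([r.pooled_an(pops) for r in selected])
    acs = np.array([r.pooled_ac(pops) for r in selected])
    if nominal_an is None:
        vals, cnt = np.unique(ans, return_counts=True)
        k = int(vals[np.argmax(cnt)])
    else:
        k = int(nominal_an)

    from .cohort import downsample_count

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    counts: dict[int, int] = {}
    for ac, an in zip(acs, ans):
        if an < an_floor * k:
            continue
        if an > k:
            ac = downsample_count(int(ac), int(an), k, mode=downsample_mode, rng=rng)
            ac = int(round(ac))
        i = int(ac)
        if i > 0:
            counts[i] = counts.get(i, 0) + 1
    return SiteFrequencySpectrum(k=k, counts=counts, label=label)
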