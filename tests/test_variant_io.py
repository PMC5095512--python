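from collections import Counter

import numpy as np
import pytest

import unseenest as u
from unseenest.variant_io import (
    ClassFilter,
    VariantRecord,
    classify_mutation,
    load_bed_mask,
    read_sites_vcf,
    sfs_from_records,
)

VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=1,length=1000000>
##INFO=<ID=AC,Number=A,Type=Integer,Description="Alt allele count">
##INFO=<ID=AN,Number=1,Type=Integer,Description="Total alleles">
##INFO=<ID=CSQ,Number=.,Type=String,Description="Format: Allele|Consequence|SYMBOL|Gene|LoF">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(tmp_path, body, name="t.vcf"):
    p = tmp_path / name
    p.write_text(VCF_HEADER + body)
    return p


class TestClassifyMutation:
    def test_definitional_cases(self):
        assert classify_mutation("C", "T", "ACG") == "CpG_transition"
        assert classify_mutation("G", "A", "CGA") == "CpG_transition"  # revcomp symmetry
        assert classify_mutation("A", "G") == "nonCpG_transition"
        assert classify_mutation("A", "T") == "transversion"
        assert classify_mutation("C", "T") == "unknown"  # CpG call needs context
        assert classify_mutation("C", "T", "ACA") == "nonCpG_transition"

    def test_exhaustive_truth_table(self):
        # independent enumeration of all 12 substitutions x 16 contexts
        purines = {"A", "G"}
        bases = "ACGT"
        for ref in bases:
            for alt in bases:
                if ref == alt:
                    continue
                for left in bases:
                    for right in bases:
                        ctx = left + ref + right
                        got = classify_mutation(ref, alt, ctx)
                        if (ref in purines) != (alt in purines):
                            want = "transversion"
                        elif (ref, alt) == ("C", "T") and right == "G":
                            want = "CpG_transition"
                        elif (ref, alt) == ("G", "A") and left == "C":
                            want = "CpG_transition"
                        else:
                            want = "nonCpG_transition"
                        assert got == want, (ref, alt, ctx)

    def test_invalid_bases_rejected(self):
        with pytest.raises(ValueError):
            classify_mutation("N", "A")
        with pytest.raises(ValueError):
            classify_mutation("A", "A")


class TestReadSitesVcf:
    def test_fixture_round_trip(self, annotated_vcf):
        path, scen, cohort = annotated_vcf
        stats = {}
        recs = read_sites_vcf(path, populations=["AFR", "EUR"], stats=stats)
        assert stats["records"] == cohort.n_observed
        observed = np.sort(cohort.counts[cohort.counts > 0])
        parsed = np.sort([r.pooled_ac() for r in recs])
        np.testing.assert_array_equal(observed, parsed)
        # exact class quotas by construction
        frac = Counter(r.consequence for r in recs)
        n = len(recs)
        for cls, f in scen.annotation_profile.items():
            assert abs(frac[cls] - f * n) <= 1

    def test_multiallelic_split(self, tmp_path):
        p = write_vcf(tmp_path, "1\t100\t.\tA\tC,T\t.\tPASS\tAC=3,5;AN=100\n")
        recs = read_sites_vcf(p)
        assert [(r.alt, r.ac["ALL"]) for r in recs] == [("C", 3), ("T", 5)]
        assert all(r.an["ALL"] == 100 for r in recs)

    def test_indels_skipped_with_counter(self, tmp_path):
        rows = [f"1\t{100+i}\t.\tA\tG\t.\tPASS\tAC=1;AN=10\n" for i in range(10)]
        rows.append("1\t200\t.\tA\tAT\t.\tPASS\tAC=1;AN=10\n")
        rows.append("1\t201\t.\tAG\tA\t.\tPASS\tAC=1;AN=10\n")
        stats = {}
        recs = read_sites_vcf(write_vcf(tmp_path, "".join(rows)), stats=stats)
        assert len(recs) == 10
        assert stats["skipped_non_snv"] == 2

    def test_missing_population_counts_skipped(self, tmp_path):
        p = write_vcf(tmp_path, "1\t100\t.\tA\tG\t.\tPASS\tAC=1;AN=10\n")
        stats = {}
        recs = read_sites_vcf(p, populations=["NFE"], stats=stats)
        assert recs == [] and stats["skipped_missing_counts"] == 1

    def test_malformed_csq_kept_as_other(self, tmp_path):
        p = write_vcf(tmp_path, "1\t100\t.\tA\tG\t.\tPASS\tAC=1;AN=10;CSQ=garbage\n")
        stats = {}
        recs = read_sites_vcf(p, stats=stats)
        assert len(recs) == 1 and recs[0].consequence == "other"
        assert stats["malformed_csq"] == 1

    def test_lof_consequence_and_confidence(self, tmp_path):
        body = (
            "1\t100\t.\tA\tG\t.\tPASS\tAC=1;AN=10;CSQ=G|stop_gained|X|E1|HC\n"
            "1\t200\t.\tA\tG\t.\tPASS\tAC=1;AN=10;CSQ=G|splice_donor_variant|X|E1|LC\n"
            "1\t300\t.\tA\tG\t.\tPASS\tAC=1;AN=10;CSQ=G|missense_variant|X|E1|\n"
        )
        recs = read_sites_vcf(write_vcf(tmp_path, body))
        assert [r.consequence for r in recs] == ["lof", "lof", "missense"]
        assert [r.lof_confidence for r in recs] == ["HC", "LC", None]


class TestFilters:
    def test_contradictory_selector_rejected(self):
        with pytest.raises(ValueError):
            ClassFilter(consequence="missense", lof_confidence="HC")

    def test_lof_confidence_implies_lof(self):
        f = ClassFilter(lof_confidence="HC")
        assert f.consequence == "lof"

    def test_filter_monotonicity(self, annotated_vcf):
        path, _, _ = annotated_vcf
        recs = read_sites_vcf(path, populations=["AFR", "EUR"])
        base = sfs_from_records(recs, ClassFilter(consequence="lof"), nominal_an=200)
        tighter = sfs_from_records(recs, ClassFilter(lof_confidence="HC"), nominal_an=200)
        for i, f in tighter.counts.items():
            assert f <= base.counts.get(i, 0) + 0  # never increases any F_i
        assert tighter.total_variants <= base.total_variants

    def test_bed_mask_coordinate_convention(self, tmp_path):
        # BED 0-based half-open [999, 1000) covers exactly VCF pos 1000
        bed = tmp_path / "mask.bed"
        bed.write_text("1\t999\t1000\n")
        mask = load_bed_mask(bed)
        f = ClassFilter(mask=mask)
        rec = lambda pos: VariantRecord("1", pos, "A", "G", {"ALL": 1}, {"ALL": 10})
        assert f.matches(rec(1000))
        assert not f.matches(rec(999))
        assert not f.matches(rec(1001))


class TestSfsFromRecords:
    def test_simple_binning(self):
        recs = [
            VariantRecord("1", 1, "A", "G", {"ALL": 1}, {"ALL": 100}),
            VariantRecord("1", 2, "A", "G", {"ALL": 1}, {"ALL": 100}),
            VariantRecord("1", 3, "A", "G", {"ALL": 2}, {"ALL": 100}),
        ]
        sfs = sfs_from_records(recs)
        assert sfs.k == 100 and sfs.counts == {1: 2, 2: 1}

    def test_pooled_populations_sum_counts(self):
        recs = [
            VariantRecord("1", 1, "A", "G", {"p1": 2, "p2": 3}, {"p1": 50, "p2": 50})
        ]
        sfs = sfs_from_records(recs, nominal_an=100)
        assert sfs.counts == {5: 1}

    def test_low_call_rate_records_excluded(self):
        recs = [
            VariantRecord("1", 1, "A", "G", {"ALL": 1}, {"ALL": 100}),
            VariantRecord("1", 2, "A", "G", {"ALL": 1}, {"ALL": 70}),  # < 0.8 * 100
        ]
        sfs = sfs_from_records(recs, nominal_an=100)
        assert sfs.total_variants == 1

    def test_high_an_downsampled(self):
        recs = [VariantRecord("1", 1, "A", "G", {"ALL": 50}, {"ALL": 200})]
        sfs = sfs_from_records(recs, nominal_an=100, downsample_mode="expected")
        assert sfs.counts == {25: 1}

    def test_empty_selection_gives_empty_sfs(self):
        sfs = sfs_from_records([], ClassFilter(consequence="lof"), nominal_an=10)
        assert sfs.total_variants == 0

    def test_matches_simulation_bookkeeping(self, annotated_vcf):
        path, scen, cohort = annotated_vcf
        recs = read_sites_vcf(path, populations=["AFR", "EUR"])
        sfs = sfs_from_records(recs, nominal_an=scen.k)
        assert sfs.counts == cohort.sfs.counts


class TestVariantRecordInvariants:
    def test_ac_beyond_an_rejected(self):
        with pytest.raises(ValueError):
            VariantRecord("1", 1, "A", "G", {"ALL": 11}, {"ALL": 10})

    def test_non_snv_rejected(self):
        with pytest.raises(ValueError):
            VariantRecord("1", 1, "A", "A", {"ALL": 1}, {"ALL": 10})
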