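"""Read-pair and SNP quality filters, VCF input, positional annotation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import sweepscan as sw
from sweepscan.errors import AnnotationError, InputError
from sweepscan.sim import GeneModel

from conftest import build_table, random_table

Q40 = chr(40 + 33)
Q2 = chr(2 + 33)


def read(seq, qual=None):
    return seq, qual if qual is not None else Q40 * len(seq)


class TestReadPairFilter:
    def test_many_ambiguous_bases_drop_the_pair(self):
        seq = "N" * 16 + "A" * 84
        dec = sw.filter_read_pair(read(seq), read("A" * 100))
        assert not dec.keep and dec.reason == "ambiguous_bases"

    def test_clean_pair_is_kept(self):
        dec = sw.filter_read_pair(read("ACGT" * 25), read("TGCA" * 25), adapter="GGGGCCCCGGGGCCCC")
        assert dec.keep and dec.reason is None

    def test_low_quality_majority_drops_the_pair(self):
        qual = Q2 * 60 + Q40 * 40
        dec = sw.filter_read_pair(read("A" * 100), read("A" * 100, qual))
        assert not dec.keep and dec.reason == "low_quality"

    def test_adapter_alignment_drops_the_pair(self):
        adapter = "AGATCGGAAGAGC"
        seq = "T" * 50 + adapter + "T" * 37
        dec = sw.filter_read_pair(read(seq), read("C" * 100), adapter=adapter)
        assert not dec.keep and dec.reason == "adapter"

    def test_short_or_mismatched_adapter_hit_is_ignored(self):
        adapter = "AGATCGGAAGAGC"
        seq = "T" * 90 + adapter[:10]  # only 10 nt align; rule needs > 10
        dec = sw.filter_read_pair(read(seq), read("C" * 100), adapter=adapter)
        assert dec.keep

    def test_decision_is_symmetric_in_mates(self):
        bad = read("N" * 20 + "A" * 80)
        good = read("A" * 100)
        assert sw.filter_read_pair(bad, good).keep == sw.filter_read_pair(good, bad).keep

    def test_length_mismatch_is_an_input_error(self):
        with pytest.raises(InputError):
            sw.filter_read_pair(("ACGT", "!!!"), read("ACGT"))


VCF_3SITES = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=10000>
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS MQ">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2
chr1\t100\t.\tA\tG\t.\tPASS\tMQ=35.00\tGT:DP\t0|1:7\t1|1:9
chr1\t250\t.\tC\tT\t.\tPASS\tMQ=18.50\tGT:DP\t0|0:4\t0|1:3
chr1\t900\t.\tG\tC\t.\tPASS\tMQ=42.00\tGT:DP\t.|.:2\t0|1:8
"""


class TestReadVcf:
    def popmap(self, tmp_path):
        p = tmp_path / "popmap.tsv"
        p.write_text("s1\tfocal\ns2\tcontrol\n")
        return p

    def test_hand_parsed_fixture(self, tmp_path):
        vcf = tmp_path / "t.vcf"
        vcf.write_text(VCF_3SITES)
        t = sw.read_vcf(vcf, self.popmap(tmp_path))
        assert t.n_sites == 3 and t.n_samples == 2
        assert list(t.pos) == [100, 250, 900]
        assert list(t.ref) == ["A", "C", "G"]
        assert t.mq[1] == pytest.approx(18.5)
        assert t.gt[0, 0].tolist() == [0, 1]
        assert t.gt[2, 0].tolist() == [-1, -1]
        assert t.dp[1].tolist() == [4, 3]
        assert t.n_skipped == 0

    def test_multiallelic_record_skipped(self, tmp_path):
        body = VCF_3SITES.replace("chr1\t250\t.\tC\tT", "chr1\t250\t.\tC\tA,T")
        vcf = tmp_path / "t.vcf"
        vcf.write_text(body)
        t = sw.read_vcf(vcf, self.popmap(tmp_path))
        assert t.n_sites == 2
        assert t.n_skipped == 1

    def test_header_only_vcf_gives_empty_table(self, tmp_path):
        vcf = tmp_path / "t.vcf"
        vcf.write_text("".join(l + "\n" for l in VCF_3SITES.splitlines()[:6]))
        t = sw.read_vcf(vcf, self.popmap(tmp_path))
        assert t.n_sites == 0

    def test_sample_missing_from_popmap_is_an_error(self, tmp_path):
        vcf = tmp_path / "t.vcf"
        vcf.write_text(VCF_3SITES)
        pm = tmp_path / "bad.tsv"
        pm.write_text("s1\tfocal\n")
        with pytest.raises(InputError):
            sw.read_vcf(vcf, pm)


class TestRemoveProximal:
    def test_pair_closer_than_spacing_both_removed(self):
        assert sw.remove_proximal(np.array([100, 104]), 5).size == 0

    def test_pair_at_exact_spacing_both_kept(self):
        assert sw.remove_proximal(np.array([100, 105]), 5).tolist() == [0, 1]

    def test_chain_removed_wholesale(self):
        kept = sw.remove_proximal(np.array([100, 104, 108, 200]), 5)
        assert kept.tolist() == [3]

    def test_unsorted_input_rejected(self):
        with pytest.raises(InputError):
            sw.remove_proximal(np.array([100, 90]), 5)

    def test_matches_all_pairs_oracle(self, rng):
        for _ in range(50):
            pos = np.unique(rng.integers(1, 500, size=30))
            kept = sw.remove_proximal(pos, 5)
            bad = {
                i
                for i in range(len(pos))
                for j in range(len(pos))
                if i != j and abs(int(pos[i]) - int(pos[j])) < 5
            }
            assert set(kept.tolist()) == set(range(len(pos))) - bad

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.integers(1, 1000), min_size=0, max_size=40, unique=True))
    def test_survivors_are_spaced(self, positions):
        pos = np.array(sorted(positions))
        kept = pos[sw.remove_proximal(pos, 5)]
        assert np.all(np.diff(kept) >= 5)


def straight_line_filter(table, thr):
    """Independent rule-by-rule re-implementation of the SNP filters."""
    survivors = []
    for i in range(table.n_sites):
        dp = [d for d in table.dp[i] if d >= 0]
        if dp and np.mean(dp) < thr.min_depth:
            continue
        if np.isfinite(table.mq[i]) and table.mq[i] < thr.min_rms_mq:
            continue
        miss = sum(1 for g in table.gt[i] if g[0] < 0 or g[1] < 0)
        if miss / table.n_samples > thr.max_miss_ratio:
            continue
        alleles = [a for g in table.gt[i] for a in g if a >= 0]
        if alleles:
            p = sum(alleles) / len(alleles)
            if min(p, 1 - p) < thr.min_maf:
                continue
        survivors.append(i)
    pos = [int(table.pos[i]) for i in survivors]
    final = []
    for k, i in enumerate(survivors):
        near = any(
            abs(pos[k] - pos[j]) < thr.min_spacing_bp
            for j in range(len(pos))
            if j != k
        )
        if not near:
            final.append(i)
    return final


class TestSnpFilters:
    def test_low_mapping_quality_site_removed(self):
        gt = np.tile([[0, 1], [0, 0]], (1, 1, 1)).reshape(1, 2, 2)
        t = build_table(gt, mq=[19.0])
        out, report = sw.apply_snp_filters(t)
        assert out.n_sites == 0
        assert dict(report.removed)["mapping_quality"] == 1

    def test_missingness_just_over_threshold_removed(self):
        gt = np.zeros((1, 13, 2), dtype=np.int8)
        gt[0, :7, 1] = 1  # keep MAF high
        gt[0, :3] = -1  # 3/13 = 0.231 missing
        t = build_table(gt)
        out, report = sw.apply_snp_filters(t)
        assert out.n_sites == 0
        assert dict(report.removed)["missingness"] == 1

    def test_matches_straight_line_oracle(self, rng):
        thr = sw.FilterThresholds()
        for trial in range(10):
            t = random_table(rng, n_sites=50, n_samples=13, miss_frac=0.15, pos_step=12)
            t.mq[rng.random(t.n_sites) < 0.2] = 15.0
            t.dp[rng.random(t.dp.shape) < 0.2] = 1
            out, report = sw.apply_snp_filters(t, thr)
            expect = straight_line_filter(t, thr)
            assert out.pos.tolist() == [int(t.pos[i]) for i in expect]
            assert report.n_output == len(expect)

    def test_filtering_is_idempotent(self, rng):
        t = random_table(rng, n_sites=60, n_samples=8, miss_frac=0.1, pos_step=10)
        once, _ = sw.apply_snp_filters(t)
        twice, report = sw.apply_snp_filters(once)
        assert twice.pos.tolist() == once.pos.tolist()
        assert all(n == 0 for _, n in report.removed)


def _make_gene(start=2001, strand="+", cds=None):
    cds = cds or ((2001, 2060), (2301, 2360))
    return GeneModel("geneX", "chr1", cds[0][0], cds[-1][1], strand, tuple(cds))


def _ref_with(gene_seq_at, length=5000, base="A"):
    ref = list(base * length)
    for pos, b in gene_seq_at.items():
        ref[pos - 1] = b
    return "".join(ref)


class TestAnnotation:
    def table_at(self, positions, ref, alts=None):
        n = len(positions)
        gt = np.zeros((n, 2, 2), dtype=np.int8)
        gt[:, 0, 1] = 1
        refs = [ref[p - 1] for p in positions]
        alts = alts or ["G" if r != "G" else "C" for r in refs]
        return build_table(gt, pos=positions, ref=refs, alt=alts)

    def test_upstream_site_on_plus_strand(self):
        gene = _make_gene()
        ref = _ref_with({})
        df = sw.annotate_sites(self.table_at([1501], ref), [gene], ref)
        assert df["category"].tolist() == ["upstream"]

    def test_synonymous_third_position(self):
        # CDS of AAA codons; third-position A->G keeps Lys (AAA -> AAG)
        gene = _make_gene(cds=((2001, 2060),))
        ref = _ref_with({})
        df = sw.annotate_sites(self.table_at([2003], ref, alts=["G"]), [gene], ref)
        assert df["category"].tolist() == ["exon_synonymous"]
        assert df["aa_change"].tolist() == ["K1K"]

    def test_nonsynonymous_first_position(self):
        gene = _make_gene(cds=((2001, 2060),))
        ref = _ref_with({})
        df = sw.annotate_sites(self.table_at([2001], ref, alts=["G"]), [gene], ref)
        assert df["category"].tolist() == ["exon_nonsynonymous"]

    def test_splice_beats_intron_at_boundary(self):
        gene = _make_gene()
        ref = _ref_with({})
        df = sw.annotate_sites(self.table_at([2061], ref), [gene], ref)
        assert df["category"].tolist() == ["splice_site"]

    def test_minus_strand_codons_are_reverse_complemented(self):
        # minus-strand CDS of TTT codons reads AAA (Lys) after revcomp;
        # genomic T->C at the CDS last base is the codon's first position
        gene = _make_gene(strand="-", cds=((2001, 2060),))
        ref = _ref_with({p: "T" for p in range(2001, 2061)})
        df = sw.annotate_sites(self.table_at([2060], ref, alts=["C"]), [gene], ref)
        assert df["category"].tolist() == ["exon_nonsynonymous"]

    def test_reference_mismatch_raises(self):
        gene = _make_gene()
        ref = _ref_with({})
        t = self.table_at([1501], ref)
        t.ref[0] = "C"  # reference has A there
        with pytest.raises(AnnotationError):
            sw.annotate_sites(t, [gene], ref)

    def test_every_site_gets_exactly_one_category(self):
        gene = _make_gene()
        ref = _ref_with({})
        positions = list(range(900, 3500, 7))
        df = sw.annotate_sites(self.table_at(positions, ref), [gene], ref)
        assert len(df) == len(positions)
        assert df["category"].isin(sw.variants.CATEGORIES).all()

    def test_categories_match_exhaustive_rule_evaluation(self):
        gene = _make_gene()
        ref = _ref_with({})
        positions = list(range(901, 3500, 3))
        df = sw.annotate_sites(self.table_at(positions, ref), [gene], ref)
        splice = set()
        for (s1, e1), (s2, _) in zip(gene.cds, gene.cds[1:]):
            splice |= {e1 + 1, e1 + 2, s2 - 2, s2 - 1}
        for pos, cat in zip(df["pos"], df["category"]):
            if pos in splice:
                expect = "splice_site"
            elif any(s <= pos <= e for s, e in gene.cds):
                expect = ("exon_synonymous", "exon_nonsynonymous")
            elif gene.start <= pos <= gene.end:
                expect = "intron"
            elif gene.start - 1000 <= pos < gene.start:
                expect = "upstream"
            elif gene.end < pos <= gene.end + 1000:
                expect = "downstream"
            else:
                expect = "intergenic"
            if isinstance(expect, tuple):
                assert cat in expect
            else:
                assert cat == expect


class TestSummaries:
    def test_tstv_counts_transitions_over_transversions(self):
        gt = np.zeros((3, 2, 2), dtype=np.int8)
        gt[:, 0, 1] = 1
        t = build_table(gt, ref=["A", "C", "A"], alt=["G", "T", "C"])
        assert sw.tstv(t) == pytest.approx(2.0)

    def test_tstv_undefined_without_transversions(self):
        gt = np.zeros((2, 2, 2), dtype=np.int8)
        gt[:, 0, 1] = 1
        t = build_table(gt, ref=["A", "C"], alt=["G", "T"])
        assert np.isnan(sw.tstv(t))

    def test_tstv_empty_table_is_an_error(self):
        t = build_table(np.zeros((0, 2, 2), dtype=np.int8), pos=[])
        with pytest.raises(InputError):
            sw.tstv(t)

    def test_tstv_matches_per_site_classification(self, rng):
        bases = np.array(list("ACGT"))
        n = 200
        ref = bases[rng.integers(0, 4, n)]
        alt = np.array([
            rng.choice([b for b in "ACGT" if b != r]) for r in ref
        ])
        gt = np.zeros((n, 2, 2), dtype=np.int8)
        gt[:, 0, 1] = 1
        pos = np.arange(1, n + 1) * 10
        t = build_table(gt, pos=pos, ref=ref, alt=alt)
        transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
        ts = sum((r, a) in transitions for r, a in zip(ref, alt))
        tv = n - ts
        got = sw.tstv(t)
        if tv == 0:
            assert np.isnan(got)
        else:
            assert got == pytest.approx(ts / tv)

    def test_het_counts_direct_and_brute_force(self, rng):
        gt = np.array([
            [[0, 1], [0, 0]],
            [[1, 0], [-1, -1]],
            [[1, 1], [-1, -1]],
        ], dtype=np.int8)
        t = build_table(gt)
        counts = sw.het_counts(t)
        assert counts["s01"] == 2
        assert counts["s02"] == 0
        big = random_table(rng, n_sites=100, n_samples=6, miss_frac=0.2)
        got = sw.het_counts(big)
        for s_i, name in enumerate(big.samples):
            expect = sum(
                1
                for i in range(big.n_sites)
                if big.gt[i, s_i, 0] >= 0
                and big.gt[i, s_i, 1] >= 0
                and big.gt[i, s_i, 0] != big.gt[i, s_i, 1]
            )
            assert got[name] == expect
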