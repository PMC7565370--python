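"""Variant data model, quality filters and positional annotation.

The quality filters mirror a conventional population-resequencing QC
chain: read pairs are dropped when either mate is ambiguous (>10% N),
low quality (>50% of bases below Q5) or adapter-contaminated (an
ungapped adapter alignment longer than 10 nt with at most 10%
mismatches); called SNPs are kept when site depth >= 3 (mean per-sample
depth by default), RMS mapping quality >= 20, missingness <= 0.2 and
MAF >= 0.01, and any run of sites spaced closer than 5 bp is removed
wholesale.  Positional categories follow the precedence
splice > exon > intron > upstream/downstream > intergenic, with exonic
SNPs classified synonymous/nonsynonymous by codon translation under the
standard genetic code.

Genotypes are treated as unphased for all diversity and Fst work; phase
is demanded (and verified) only when haplotypes are extracted for
LD/XP-EHH via :meth:`VariantTable.to_haplotypes`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .errors import AnnotationError, InputError
from .sim import GeneModel

logger = logging.getLogger(__name__)

__all__ = [
    "VariantTable",
    "FilterThresholds",
    "ReadFilterThresholds",
    "FilterReport",
    "ReadPairDecision",
    "filter_read_pair",
    "read_vcf",
    "read_popmap",
    "read_gff3",
    "apply_snp_filters",
    "remove_proximal",
    "annotate_sites",
    "tstv",
    "het_counts",
    "CATEGORIES",
]

CATEGORIES = (
    "splice_site",
    "exon_synonymous",
    "exon_nonsynonymous",
    "intron",
    "upstream",
    "downstream",
    "intergenic",
)

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass
class VariantTable:
    """Biallelic SNP sites with genotypes, depths and site metadata.

    ``gt`` is (n_sites, n_samples, 2) with allele codes 0/1 and -1 for
    missing; a genotype with any missing allele counts as missing.
    ``dp`` uses -1 for missing depth and ``mq`` NaN for missing mapping
    quality.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    mq: np.ndarray
    gt: np.ndarray
    dp: np.ndarray
    phased: np.ndarray
    samples: list[str]
    populations: np.ndarray
    n_skipped: int = 0

    def __post_init__(self) -> None:
        n_sites = len(self.pos)
        if self.gt.shape != (n_sites, len(self.samples), 2):
            raise InputError("genotype array shape inconsistent with table")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if len(p) > 1 and np.any(np.diff(p) <= 0):
                raise InputError(f"positions not strictly increasing on {c}")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def subset(self, mask: np.ndarray) -> "VariantTable":
        return VariantTable(
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            ref=self.ref[mask],
            alt=self.alt[mask],
            mq=self.mq[mask],
            gt=self.gt[mask],
            dp=self.dp[mask],
            phased=self.phased[mask],
            samples=list(self.samples),
            populations=self.populations.copy(),
            n_skipped=0,
        )

    def sample_indices(self, population: Optional[str] = None) -> np.ndarray:
        if population is None:
            return np.arange(self.n_samples)
        idx = np.nonzero(self.populations == population)[0]
        if idx.size == 0:
            raise InputError(f"unknown population label: {population!r}")
        return idx

    def missing_mask(self) -> np.ndarray:
        """(n_sites, n_samples) True where the genotype is missing."""
        return (self.gt < 0).any(axis=2)

    def allele_stats(self, population: Optional[str] = None):
        """Per-site (alt allele count, non-missing allele count)."""
        idx = self.sample_indices(population)
        g = self.gt[:, idx, :]
        ok = g >= 0
        return (g == 1).sum(axis=(1, 2)), ok.sum(axis=(1, 2))

    def maf(self, population: Optional[str] = None) -> np.ndarray:
        ac, an = self.allele_stats(population)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(an > 0, ac / np.maximum(an, 1), np.nan)
        return np.minimum(p, 1 - p)

    def to_haplotypes(self, population: Optional[str] = None) -> np.ndarray:
        """Phased haplotype matrix (2 * n_samples, n_sites); -1 = missing.

        Raises InputError when any non-missing genotype is unphased,
        since haplotype statistics are meaningless on unphased data.
        """
        idx = self.sample_indices(population)
        g = self.gt[:, idx, :]
        nonmissing = (g >= 0).all(axis=2)
        het = nonmissing & (g[:, :, 0] != g[:, :, 1])
        if np.any(het & ~self.phased[:, idx]):
            raise InputError("unphased heterozygous genotypes: phase required")
        out = np.empty((2 * idx.size, self.n_sites), dtype=np.int8)
        out[0::2] = g[:, :, 0].T
        out[1::2] = g[:, :, 1].T
        return out


# ---------------------------------------------------------------------------
# Read-pair filter
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReadFilterThresholds:
    max_n_fraction: float = 0.10
    low_quality_phred: int = 5
    max_low_quality_fraction: float = 0.50
    min_adapter_overlap: int = 11  # "> 10 nt aligned"
    max_adapter_mismatch_fraction: float = 0.10


@dataclass(frozen=True)
class ReadPairDecision:
    keep: bool
    reason: Optional[str] = None


def _adapter_hit(seq: str, adapter: str, thresholds: ReadFilterThresholds) -> bool:
    """Ungapped scan of the adapter against the read at every offset."""
    if not adapter:
        return False
    r = np.frombuffer(seq.encode(), dtype=np.uint8)
    a = np.frombuffer(adapter.encode(), dtype=np.uint8)
    for off in range(-len(a) + 1, len(r)):
        lo, hi = max(0, off), min(len(r), off + len(a))
        overlap = hi - lo
        if overlap < thresholds.min_adapter_overlap:
            continue
        mism = int((r[lo:hi] != a[lo - off : hi - off]).sum())
        if mism <= thresholds.max_adapter_mismatch_fraction * overlap:
            return True
    return False


def filter_read_pair(
    read1: tuple[str, str],
    read2: tuple[str, str],
    adapter: str = "",
    thresholds: ReadFilterThresholds = ReadFilterThresholds(),
) -> ReadPairDecision:
    """Keep/drop decision for a read pair; symmetric in the two mates.

    Each read is a (sequence, Phred+33 quality string) tuple.  The pair is
    dropped if either mate has too many ambiguous bases, too many
    low-quality bases, or an adapter match; the reason names the first
    rule that fired.
    """
    for seq, qual in (read1, read2):
        if len(seq) != len(qual):
            raise InputError("sequence and quality strings differ in length")
    for rule in ("ambiguous_bases", "low_quality", "adapter"):
        for seq, qual in (read1, read2):
            n = len(seq)
            if n == 0:
                continue
            if rule == "ambiguous_bases":
                if seq.upper().count("N") / n > thresholds.max_n_fraction:
                    return ReadPairDecision(False, rule)
            elif rule == "low_quality":
                q = np.frombuffer(qual.encode(), dtype=np.uint8).astype(int) - 33
                if (q < thresholds.low_quality_phred).mean() > thresholds.max_low_quality_fraction:
                    return ReadPairDecision(False, rule)
            else:
                if _adapter_hit(seq, adapter, thresholds):
                    return ReadPairDecision(False, rule)
    return ReadPairDecision(True, None)


# ---------------------------------------------------------------------------
# VCF / popmap / GFF3 input
# ---------------------------------------------------------------------------


def read_popmap(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"],
                     dtype=str, comment="#")
    if df["sample"].duplicated().any():
        raise InputError("duplicate sample in population map")
    return dict(zip(df["sample"], df["population"]))


def read_vcf(vcf: str | Path, popmap: str | Path | dict[str, str]) -> VariantTable:
    """Load biallelic SNPs from a VCF; multiallelic/non-SNP records are
    skipped and counted in ``table.n_skipped``."""
    from cyvcf2 import VCF

    pops = popmap if isinstance(popmap, dict) else read_popmap(popmap)
    reader = VCF(str(vcf))
    samples = list(reader.samples)
    missing_from_map = [s for s in samples if s not in pops]
    if missing_from_map:
        raise InputError(f"samples absent from population map: {missing_from_map}")

    chroms, positions, refs, alts, mqs = [], [], [], [], []
    gts, dps, phased = [], [], []
    n_skipped = 0
    for v in reader:
        if (not v.is_snp) or len(v.ALT) != 1:
            n_skipped += 1
            continue
        chroms.append(v.CHROM)
        positions.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        mq = v.INFO.get("MQ")
        mqs.append(float(mq) if mq is not None else np.nan)
        row = np.full((len(samples), 2), -1, dtype=np.int8)
        ph = np.zeros(len(samples), dtype=bool)
        for s, g in enumerate(v.genotypes):
            a, b = g[0], g[1]
            row[s, 0] = a if a is not None and a >= 0 else -1
            row[s, 1] = b if b is not None and b >= 0 else -1
            ph[s] = bool(g[2])
        gts.append(row)
        dp = v.format("DP")
        if dp is None:
            dps.append(np.full(len(samples), -1, dtype=np.int32))
        else:
            d = dp.reshape(-1).astype(np.int64)
            d[d < 0] = -1
            dps.append(d.astype(np.int32))
        phased.append(ph)
    if n_skipped:
        logger.info("read_vcf: skipped %d non-SNP/multiallelic records", n_skipped)

    n = len(positions)
    table = VariantTable(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(positions, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        mq=np.array(mqs, dtype=np.float64),
        gt=np.array(gts, dtype=np.int8) if n else np.empty((0, len(samples), 2), np.int8),
        dp=np.array(dps, dtype=np.int32) if n else np.empty((0, len(samples)), np.int32),
        phased=np.array(phased, dtype=bool) if n else np.empty((0, len(samples)), bool),
        samples=samples,
        populations=np.array([pops[s] for s in samples], dtype=object),
        n_skipped=n_skipped,
    )
    return table


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Gene models (gene span + CDS segments) from a GFF3 file."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for g in db.features_of_type("gene", order_by="start"):
        cds = [
            (c.start, c.end)
            for c in db.children(g, featuretype="CDS", order_by="start")
        ]
        if not cds:
            continue
        genes.append(
            GeneModel(
                gene_id=g.id,
                chrom=g.seqid,
                start=g.start,
                end=g.end,
                strand=g.strand,
                cds=tuple(cds),
            )
        )
    return genes


# ---------------------------------------------------------------------------
# SNP filters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FilterThresholds:
    """SNP quality-filter settings (defaults follow the standard chain)."""

    min_depth: float = 3.0
    min_rms_mq: float = 20.0
    max_miss_ratio: float = 0.2
    min_maf: float = 0.01
    min_spacing_bp: int = 5
    depth_mode: str = "mean"  # or "per_sample_min"

    def __post_init__(self) -> None:
        if not 0 <= self.max_miss_ratio <= 1:
            raise InputError("max_miss_ratio must lie in [0, 1]")
        if not 0 <= self.min_maf <= 0.5:
            raise InputError("min_maf must lie in [0, 0.5]")
        if min(self.min_depth, self.min_rms_mq, self.min_spacing_bp) < 0:
            raise InputError("thresholds must be non-negative")
        if self.depth_mode not in ("mean", "per_sample_min"):
            raise InputError("depth_mode must be 'mean' or 'per_sample_min'")


@dataclass
class FilterReport:
    """Sites removed per rule, in application order."""

    n_input: int
    removed: list[tuple[str, int]] = field(default_factory=list)

    @property
    def n_output(self) -> int:
        return self.n_input - sum(n for _, n in self.removed)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.removed, columns=["rule", "removed_count"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def remove_proximal(positions: np.ndarray, min_spacing: int) -> np.ndarray:
    """Indices of sites whose nearest neighbour is >= min_spacing bp away.

    Any site closer than ``min_spacing`` to a neighbour is removed, so a
    chain of closely spaced sites is removed in its entirety.
    """
    positions = np.asarray(positions)
    if len(positions) > 1 and np.any(np.diff(positions) <= 0):
        raise InputError("positions must be sorted strictly increasing")
    if len(positions) == 0:
        return np.empty(0, dtype=np.int64)
    gaps = np.diff(positions)
    close = gaps < min_spacing
    bad = np.zeros(len(positions), dtype=bool)
    bad[:-1] |= close
    bad[1:] |= close
    return np.nonzero(~bad)[0]


def apply_snp_filters(
    table: VariantTable, thresholds: FilterThresholds = FilterThresholds()
) -> tuple[VariantTable, FilterReport]:
    """Apply depth, mapping-quality, missingness, MAF and spacing rules.

    Rules run in that order; a site with a missing metric (no DP or no MQ)
    cannot be assessed by that rule and passes it.  The returned report
    counts removals per rule sequentially, and the whole operation is
    idempotent.
    """
    report = FilterReport(n_input=table.n_sites)
    t = table

    dp = t.dp.astype(np.float64)
    dp[dp < 0] = np.nan
    with np.errstate(invalid="ignore"):
        if thresholds.depth_mode == "mean":
            depth_stat = np.nanmean(dp, axis=1) if t.n_sites else np.empty(0)
        else:
            depth_stat = np.nanmin(dp, axis=1) if t.n_sites else np.empty(0)
    keep = ~(depth_stat < thresholds.min_depth)  # NaN passes
    report.removed.append(("depth", int((~keep).sum())))
    t = t.subset(keep)

    keep = ~(t.mq < thresholds.min_rms_mq)
    report.removed.append(("mapping_quality", int((~keep).sum())))
    t = t.subset(keep)

    miss = t.missing_mask().mean(axis=1) if t.n_sites else np.empty(0)
    keep = miss <= thresholds.max_miss_ratio
    report.removed.append(("missingness", int((~keep).sum())))
    t = t.subset(keep)

    maf = t.maf()
    keep = ~(maf < thresholds.min_maf)  # NaN (no data) passes
    report.removed.append(("maf", int((~keep).sum())))
    t = t.subset(keep)

    keep = np.zeros(t.n_sites, dtype=bool)
    for c in np.unique(t.chrom):
        on_c = np.nonzero(t.chrom == c)[0]
        retained = remove_proximal(t.pos[on_c], thresholds.min_spacing_bp)
        keep[on_c[retained]] = True
    report.removed.append(("spacing", int((~keep).sum())))
    t = t.subset(keep)
    return t, report


# ---------------------------------------------------------------------------
# Positional annotation
# ---------------------------------------------------------------------------


def _splice_positions(gene: GeneModel) -> set[int]:
    out: set[int] = set()
    for (s1, e1), (s2, _) in zip(gene.cds, gene.cds[1:]):
        intron_start, intron_end = e1 + 1, s2 - 1
        if intron_end < intron_start:
            continue
        out.update(range(intron_start, min(intron_start + 2, intron_end + 1)))
        out.update(range(max(intron_end - 1, intron_start), intron_end + 1))
    return out


def _codon_change(
    gene: GeneModel, pos: int, ref: str, alt: str, reference: str
) -> tuple[str, str]:
    """Classify an exonic SNP; returns (category, aa_change)."""
    cds_seq = "".join(reference[s - 1 : e] for s, e in gene.cds)
    acc = 0
    for s, e in gene.cds:
        if s <= pos <= e:
            cds_index = acc + (pos - s)
            break
        acc += e - s + 1
    else:  # pragma: no cover - guarded by caller
        raise AnnotationError(f"position {pos} not in CDS of {gene.gene_id}")
    if gene.strand == "-":
        cds_seq = str(Seq(cds_seq).reverse_complement())
        cds_index = len(cds_seq) - 1 - cds_index
        ref = str(Seq(ref).complement())
        alt = str(Seq(alt).complement())
    if cds_seq[cds_index] != ref:
        raise AnnotationError(
            f"reference allele mismatch at {pos} in {gene.gene_id}"
        )
    codon_i = cds_index // 3
    codon = cds_seq[3 * codon_i : 3 * codon_i + 3]
    within = cds_index % 3
    mutated = codon[:within] + alt + codon[within + 1 :]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(mutated).translate())
    category = "exon_synonymous" if aa_ref == aa_alt else "exon_nonsynonymous"
    return category, f"{aa_ref}{codon_i + 1}{aa_alt}"


def annotate_sites(
    table: VariantTable,
    genes: Sequence[GeneModel],
    reference: str,
    flank: int = 1000,
    splice_margin: int = 2,
    strict: bool = True,
) -> pd.DataFrame:
    """Assign one positional category per site.

    Precedence across overlapping features is splice > exon > intron >
    upstream > downstream > intergenic; the splice region is the first and
    last ``splice_margin`` bp of each intron, and up/downstream flanks
    extend ``flank`` bp from the annotated gene span on the appropriate
    strand side.  A ref-allele/reference mismatch raises AnnotationError
    (or is recorded as category 'error' with ``strict=False``).
    """
    rank = {c: i for i, c in enumerate(CATEGORIES)}
    splice_sets = [(_splice_positions(g), g) for g in genes]
    rows = []
    for i in range(table.n_sites):
        pos = int(table.pos[i])
        chrom = table.chrom[i]
        ref, alt = table.ref[i], table.alt[i]
        if pos <= len(reference) and reference[pos - 1] != ref:
            msg = f"ref allele {ref} at {chrom}:{pos} does not match reference"
            if strict:
                raise AnnotationError(msg)
            rows.append((chrom, pos, "error", None))
            continue
        best = ("intergenic", None)
        for (splice, g) in splice_sets:
            if g.chrom != chrom:
                continue
            cand: Optional[tuple[str, Optional[str]]] = None
            if pos in splice:
                cand = ("splice_site", None)
            elif any(s <= pos <= e for s, e in g.cds):
                cand = _codon_change(g, pos, ref, alt, reference)
            elif g.start <= pos <= g.end:
                cand = ("intron", None)
            else:
                up = (g.strand == "+" and g.start - flank <= pos < g.start) or (
                    g.strand == "-" and g.end < pos <= g.end + flank
                )
                down = (g.strand == "+" and g.end < pos <= g.end + flank) or (
                    g.strand == "-" and g.start - flank <= pos < g.start
                )
                if up:
                    cand = ("upstream", None)
                elif down:
                    cand = ("downstream", None)
            if cand is not None and rank[cand[0]] < rank[best[0]]:
                best = cand
        rows.append((chrom, pos, best[0], best[1]))
    return pd.DataFrame(rows, columns=["chrom", "pos", "category", "aa_change"])


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------


def tstv(table: VariantTable) -> float:
    """Transition/transversion ratio; NaN (with a warning) if no
    transversions are present."""
    if table.n_sites == 0:
        raise InputError("ts/tv undefined on an empty table")
    pairs = list(zip(table.ref, table.alt))
    ts = sum((r, a) in _TRANSITIONS for r, a in pairs)
    tv = len(pairs) - ts
    if tv == 0:
        logger.warning("ts/tv undefined: no transversions observed")
        return float("nan")
    return ts / tv


def het_counts(table: VariantTable) -> pd.Series:
    """Heterozygous genotype count per sample (missing excluded)."""
    g = table.gt
    ok = (g >= 0).all(axis=2)
    het = ok & (g[:, :, 0] != g[:, :, 1])
    return pd.Series(het.sum(axis=0), index=table.samples, name="n_het")
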