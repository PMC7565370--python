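"""End-to-end orchestration: simulate/load -> filter -> annotate -> scan.

``run_scan`` drives the whole analysis from a single RunConfig and
writes a reproducible report bundle: filtered VCF, filter report,
window-scan TSVs, XP-EHH tables, candidate-region BEDs and gene lists,
the candidate-set Venn partition, enrichment tables and a JSON manifest
recording the seed, parameter defaults and derived percentile cutoffs.
Identical config and seed produce byte-identical bundles (no timestamps
enter any output file).
"""

from __future__ import annotations

import contextlib
import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diversity import LDConfig, WindowScheme, half_decay_distance, ld_decay
from .enrichment import enrich, read_term_map
from .errors import ComputationError, InputError, SweepscanError
from .sim import (
    SimulationConfig,
    make_annotation_and_terms,
    make_reference,
    simulate_cohort,
    write_cohort,
    write_gff3,
    write_term_map,
)
from .sweep import fst_pi_scan, intersect_gene_sets, merge_and_map
from .variants import (
    FilterThresholds,
    annotate_sites,
    apply_snp_filters,
    het_counts,
    read_gff3,
    read_vcf,
    tstv,
)
from .xpehh import GeneticMap, xpehh_scan, xpehh_windows

logger = logging.getLogger("sweepscan")

__all__ = ["RunConfig", "RunResult", "run_scan"]


@dataclass
class RunConfig:
    """Configuration of a full scan run.

    Exactly one of ``simulation`` or ``vcf``+``popmap`` must be given.
    Window schemes default to 40 kb / 20 kb (Fst and diversity ratio) and
    10 kb / 5 kb (XP-EHH) with the top 5% of each ranking as outliers.
    """

    output_dir: str | Path = "sweepscan_out"
    seed: int = 0
    simulation: Optional[SimulationConfig] = None
    vcf: Optional[str] = None
    popmap: Optional[str] = None
    gff3: Optional[str] = None
    genetic_map: Optional[str] = None
    term_map: Optional[str] = None
    reference_fasta: Optional[str] = None
    sequence_length: Optional[int] = None
    focal: str = "focal"
    control: str = "control"
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    fst_scheme: WindowScheme = field(default_factory=lambda: WindowScheme(40_000, 20_000))
    xpehh_scheme: WindowScheme = field(default_factory=lambda: WindowScheme(10_000, 5_000))
    quantile: float = 0.95
    ld: LDConfig = field(default_factory=LDConfig)
    enrichment_alpha: float = 0.05
    enrichment_correction: str = "none"
    n_genes: int = 12
    n_terms: int = 8
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        sim_mode = self.simulation is not None
        file_mode = self.vcf is not None or self.popmap is not None
        if sim_mode == file_mode:
            raise InputError(
                "exactly one of a simulation block or vcf+popmap paths is required"
            )
        if file_mode and (self.vcf is None or self.popmap is None):
            raise InputError("file mode needs both vcf and popmap")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "simulation" in raw and raw["simulation"] is not None:
            sim = dict(raw["simulation"])
            if "sweep" in sim and sim["sweep"] is not None:
                from .sim import SweepSpec

                sim["sweep"] = SweepSpec(**sim["sweep"])
            for key in ("pop_sizes", "migration_rates", "sample_sizes"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            if "epochs" in sim:
                sim["epochs"] = tuple(
                    tuple(tuple(e) for e in pop) for pop in sim["epochs"]
                )
            raw["simulation"] = SimulationConfig(**sim)
        if "thresholds" in raw:
            raw["thresholds"] = FilterThresholds(**raw["thresholds"])
        for key in ("fst_scheme", "xpehh_scheme"):
            if key in raw:
                raw[key] = WindowScheme(**raw[key])
        if "ld" in raw:
            raw["ld"] = LDConfig(**raw["ld"])
        return cls(**raw)


@dataclass
class RunResult:
    output_dir: Path
    manifest: dict
    files: dict[str, Path]


@contextlib.contextmanager
def _stage(name: str):
    logger.info("stage: %s", name)
    try:
        yield
    except SweepscanError as exc:
        raise type(exc)(f"[{name}] {exc}") from exc
    except Exception as exc:  # pragma: no cover - defensive
        raise ComputationError(f"[{name}] {exc}") from exc


def _setup_logging(out: Path, level: str) -> logging.Handler:
    # fixed format without timestamps so run.log is reproducible
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("sweepscan")
    root.setLevel(level)
    root.addHandler(handler)
    return handler


def _write_filtered_vcf(src: Path, kept: set[tuple[str, int]], dest: Path) -> None:
    """Copy the source VCF keeping headers and surviving records verbatim."""
    with open(src) as fin, open(dest, "w") as fout:
        for line in fin:
            if line.startswith("#"):
                fout.write(line)
                continue
            chrom, pos = line.split("\t", 2)[:2]
            if (chrom, int(pos)) in kept:
                fout.write(line)


def _read_fasta_first(path: str | Path) -> str:
    seq = []
    with open(path) as fh:
        started = False
        for line in fh:
            if line.startswith(">"):
                if started:
                    break
                started = True
                continue
            seq.append(line.strip())
    return "".join(seq)


def _regions_bed(regions, path: Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.n_windows}\n")


def _gene_list(regions, path: Path) -> list[str]:
    genes = sorted({g for r in regions for g in r.genes})
    path.write_text("".join(f"{g}\n" for g in genes))
    return genes


def run_scan(config: RunConfig) -> RunResult:
    """Execute the full pipeline and write the report bundle."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(out, config.log_level)
    files: dict[str, Path] = {}
    manifest: dict = {
        "tool": "sweepscan",
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "fst_window_bp": config.fst_scheme.width,
            "fst_step_bp": config.fst_scheme.step,
            "xpehh_window_bp": config.xpehh_scheme.width,
            "xpehh_step_bp": config.xpehh_scheme.step,
            "quantile": config.quantile,
            "thresholds": dataclasses.asdict(config.thresholds),
            "ld": dataclasses.asdict(config.ld),
        },
    }
    try:
        # ------------------------------------------------ inputs
        with _stage("inputs"):
            if config.simulation is not None:
                sim = dataclasses.replace(config.simulation, seed=config.seed)
                reference = make_reference(sim.sequence_length, seed=config.seed + 11)
                genes, term_map = make_annotation_and_terms(
                    sim.sequence_length, config.n_genes, config.n_terms,
                    seed=config.seed + 13, chrom=sim.chrom,
                )
                cohort, truth = simulate_cohort(sim)
                inputs = out / "inputs"
                paths = write_cohort(cohort, truth, inputs, reference=reference,
                                     depth_mean=sim.depth_mean, site_mq=sim.site_mq)
                write_gff3(genes, inputs / "annotation.gff3")
                write_term_map(term_map, inputs / "term_map.tsv")
                with open(inputs / "reference.fa", "w") as fh:
                    fh.write(f">{sim.chrom}\n")
                    for i in range(0, len(reference), 80):
                        fh.write(reference[i : i + 80] + "\n")
                vcf_path = paths["vcf"]
                popmap_path = paths["popmap"]
                gmap = GeneticMap.from_tsv(paths["genetic_map"])
                length = sim.sequence_length
                chrom = sim.chrom
                manifest["simulation"] = {
                    "sequence_length": sim.sequence_length,
                    "sample_sizes": list(sim.sample_sizes),
                    "split_generation": sim.split_generation,
                    "sweep": dataclasses.asdict(sim.sweep) if sim.sweep else None,
                }
                files.update(paths)
            else:
                vcf_path = Path(config.vcf)
                popmap_path = Path(config.popmap)
                genes = read_gff3(config.gff3) if config.gff3 else []
                term_map = read_term_map(config.term_map) if config.term_map else {}
                reference = (
                    _read_fasta_first(config.reference_fasta)
                    if config.reference_fasta
                    else None
                )
                gmap = None
                length = config.sequence_length

        # ------------------------------------------------ variants & filters
        with _stage("filter"):
            table = read_vcf(vcf_path, popmap_path)
            chrom = str(table.chrom[0]) if table.n_sites else "chr1"
            if length is None:
                length = int(table.pos.max()) if table.n_sites else 0
            if gmap is None:
                if config.genetic_map:
                    gmap = GeneticMap.from_tsv(config.genetic_map)
                else:
                    gmap = GeneticMap.constant(length)
            filtered, report = apply_snp_filters(table, config.thresholds)
            report.write_tsv(out / "filter_report.tsv")
            files["filter_report"] = out / "filter_report.tsv"
            kept = set(zip(filtered.chrom.tolist(), filtered.pos.tolist()))
            _write_filtered_vcf(vcf_path, kept, out / "filtered.vcf")
            files["filtered_vcf"] = out / "filtered.vcf"
            summary = {
                "n_sites_raw": table.n_sites,
                "n_sites_filtered": filtered.n_sites,
                "n_records_skipped": table.n_skipped,
                "tstv": tstv(filtered) if filtered.n_sites else None,
                "het_counts": het_counts(filtered).to_dict(),
            }
            manifest["variants"] = summary

        # ------------------------------------------------ annotation
        if genes and reference is not None:
            with _stage("annotate"):
                ann = annotate_sites(filtered, genes, reference)
                ann.to_csv(out / "annotation.tsv", sep="\t", index=False)
                files["annotation"] = out / "annotation.tsv"
                manifest["annotation_categories"] = (
                    ann["category"].value_counts().to_dict()
                )

        # ------------------------------------------------ LD decay
        with _stage("ld"):
            ld_summary = {}
            for pop in (config.focal, config.control):
                haps = filtered.to_haplotypes(pop)
                curve = ld_decay(haps, filtered.pos, config.ld)
                curve.to_frame().to_csv(out / f"ld_{pop}.tsv", sep="\t", index=False)
                files[f"ld_{pop}"] = out / f"ld_{pop}.tsv"
                try:
                    half = half_decay_distance(curve)
                except InputError:
                    half = None
                ld_summary[pop] = {"half_decay_bp": half}
            manifest["ld"] = ld_summary

        # ------------------------------------------------ Fst - pi scan
        with _stage("fst_pi_scan"):
            scan, z_cut, r_cut = fst_pi_scan(
                filtered, length, focal=config.focal, control=config.control,
                scheme=config.fst_scheme, quantile=config.quantile,
            )
            scan.insert(0, "chrom", chrom)
            scan.to_csv(out / "fst_pi_scan.tsv", sep="\t", index=False)
            files["fst_pi_scan"] = out / "fst_pi_scan.tsv"
            regions = merge_and_map(scan[scan["joint"]], genes, chrom=chrom)
            _regions_bed(regions, out / "fst_pi_regions.bed")
            fstpi_genes = _gene_list(regions, out / "fst_pi_genes.tsv")
            files["fst_pi_regions"] = out / "fst_pi_regions.bed"
            files["fst_pi_genes"] = out / "fst_pi_genes.tsv"
            manifest["fst_pi"] = {
                "z_fst_cutoff": z_cut,
                "log2_ratio_cutoff": r_cut,
                "n_joint_windows": int(scan["joint"].sum()),
                "n_regions": len(regions),
                "n_genes": len(fstpi_genes),
            }

        # ------------------------------------------------ XP-EHH
        with _stage("xpehh"):
            fh_haps = filtered.to_haplotypes(config.focal)
            ch_haps = filtered.to_haplotypes(config.control)
            records = xpehh_scan(fh_haps, ch_haps, filtered.pos, gmap, chrom=chrom)
            records.to_csv(out / "xpehh.tsv", sep="\t", index=False)
            files["xpehh"] = out / "xpehh.tsv"
            win, xp_cut, xp_regions = xpehh_windows(
                records, length, scheme=config.xpehh_scheme,
                quantile=config.quantile, genes=genes, chrom=chrom,
            )
            win.insert(0, "chrom", chrom)
            win.to_csv(out / "xpehh_windows.tsv", sep="\t", index=False)
            _regions_bed(xp_regions, out / "xpehh_regions.bed")
            xp_genes = _gene_list(xp_regions, out / "xpehh_genes.tsv")
            files["xpehh_windows"] = out / "xpehh_windows.tsv"
            files["xpehh_regions"] = out / "xpehh_regions.bed"
            files["xpehh_genes"] = out / "xpehh_genes.tsv"
            manifest["xpehh"] = {
                "cutoff": xp_cut,
                "n_cores": len(records),
                "n_outlier_windows": int(win["outlier"].sum()),
                "n_genes": len(xp_genes),
            }

        # ------------------------------------------------ intersection
        with _stage("intersect"):
            a_only, shared, b_only = intersect_gene_sets(fstpi_genes, xp_genes)
            pd.DataFrame(
                {
                    "set": ["fst_pi_only", "shared", "xpehh_only"],
                    "count": [len(a_only), len(shared), len(b_only)],
                    "genes": [
                        ",".join(sorted(a_only)),
                        ",".join(sorted(shared)),
                        ",".join(sorted(b_only)),
                    ],
                }
            ).to_csv(out / "venn.tsv", sep="\t", index=False)
            files["venn"] = out / "venn.tsv"
            manifest["venn"] = {
                "fst_pi_only": len(a_only),
                "shared": len(shared),
                "xpehh_only": len(b_only),
            }

        # ------------------------------------------------ enrichment
        if term_map and genes:
            with _stage("enrich"):
                background = [g.gene_id for g in genes]
                for name, cand in (("fst_pi", fstpi_genes), ("xpehh", xp_genes)):
                    res = enrich(cand, background, term_map,
                                 alpha=config.enrichment_alpha,
                                 correction=config.enrichment_correction)
                    res.to_csv(out / f"enrichment_{name}.tsv", sep="\t", index=False)
                    files[f"enrichment_{name}"] = out / f"enrichment_{name}.tsv"
                    manifest[f"enrichment_{name}"] = {
                        "n_terms_tested": len(res),
                        "n_significant": int(res["significant"].sum()),
                    }

        with _stage("manifest"):
            with open(out / "manifest.json", "w") as fh:
                json.dump(manifest, fh, indent=2, sort_keys=True)
                fh.write("\n")
            files["manifest"] = out / "manifest.json"
    finally:
        logging.getLogger("sweepscan").removeHandler(handler)
        handler.close()
    return RunResult(output_dir=out, manifest=manifest, files=files)
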