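"""End-to-end report over a set of annotated plastomes.

Runs structure detection, codon-usage statistics, the three
evolutionary-force diagnostics, SSR scanning, and (optionally) pairwise
Ka/Ks, writing one TSV per result table. Per-genome failures are
isolated: a genome that cannot be parsed or analysed is reported and the
remaining genomes still complete.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional

import pandas as pd

from . import codon_usage as cu
from . import diagnostics as dx
from . import kaks as kk
from . import plastome_io as pio
from . import ssr

log = logging.getLogger("plastocodon")


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    inputs: list[str] = field(default_factory=list)
    out_dir: str = "plastocodon_out"
    ssr_thresholds: dict[int, int] = field(
        default_factory=lambda: dict(ssr.DEFAULT_THRESHOLDS)
    )
    min_ir: int = 10_000
    min_gene_codons: int = 30
    coa_pooled: bool = True
    pr2_fourfold_only: bool = False
    enc_per: str = "genome"  # genome (concatenated CDS) | gene
    enc_curve_variant: str = "standard"
    run_kaks: bool = False
    kaks_reference: Optional[str] = None
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if cfg.enc_per not in ("genome", "gene"):
            raise ValueError("enc_per must be 'genome' or 'gene'")
        if cfg.enc_curve_variant not in ("standard", "printed"):
            raise ValueError("enc_curve_variant must be 'standard' or 'printed'")
        return cfg


@dataclass
class ReportBundle:
    out_dir: Path
    n_processed: int
    n_failed: int
    failures: dict[str, str]
    tables: dict[str, pd.DataFrame]

    @property
    def ok(self) -> bool:
        return self.n_failed == 0 and self.n_processed > 0


def load_genome(path: str | Path) -> pio.PlastidGenome:
    path = Path(path)
    if path.suffix.lower() in (".gb", ".gbk", ".gbff", ".genbank"):
        return pio.parse_genbank(path)
    if path.suffix.lower() in (".fa", ".fasta", ".fna"):
        gff = path.with_suffix(".gff3")
        if not gff.exists():
            gff = path.with_suffix(".gff")
        if not gff.exists():
            raise pio.ParseError(f"{path}: no companion GFF3 file found")
        return pio.parse_fasta_gff3(path, gff)
    # default to GenBank
    return pio.parse_genbank(path)


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute every stage and write the TSV bundle to ``config.out_dir``."""
    if not config.inputs:
        raise ValueError("empty input set")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    genomes: list[pio.PlastidGenome] = []
    failures: dict[str, str] = {}
    for p in config.inputs:
        try:
            genomes.append(load_genome(p))
        except Exception as exc:  # isolation contract: keep going
            log.error("parse %s: %s", p, exc)
            failures[str(p)] = str(exc)

    tables: dict[str, pd.DataFrame] = {}
    qc_frames = []
    gene_counts_all: list[tuple[str, list[tuple[str, cu.CodonCounts]]]] = []
    genome_counts: list[tuple[str, cu.CodonCounts]] = []
    all_loci: list[ssr.SSRLocus] = []
    region_tables = []
    cds_by_genome: dict[str, list[tuple[str, str]]] = {}

    analysed: list[pio.PlastidGenome] = []
    for g in genomes:
        try:
            qc_frames.append(pio.cds_qc(g))
            records = pio.extract_cds(g)
            gene_counts = [
                (f"{g.id}:{r.gene_name}", cu.count_codons(r.sequence, r.gene_name))
                for r in records
            ]
            gene_counts_all.append((g.id, gene_counts))
            genome_counts.append(
                (g.id, cu.concat_counts((c for _, c in gene_counts), source=g.id))
            )
            cds_by_genome[g.id] = [
                (r.gene_name, r.sequence.rstrip()) for r in records
            ]
            loci = ssr.scan_ssrs(g, thresholds=config.ssr_thresholds)
            annotation = pio.classify_regions(g)
            labeled, density = ssr.classify_ssr_regions(loci, annotation)
            density.insert(0, "genome", g.id)
            region_tables.append(density)
            all_loci.extend(labeled)
            analysed.append(g)
        except Exception as exc:
            log.error("stage failure for %s: %s", g.id, exc)
            failures[g.id] = str(exc)

    tables["structure"] = pio.structure_table(analysed, min_ir=config.min_ir)
    tables["summary"] = tables["structure"][
        ["genome", "species", "length", "gc_percent", "n_cds", "n_rrna", "n_trna", "n_features"]
    ]
    tables["cds_qc"] = (
        pd.concat(qc_frames, ignore_index=True) if qc_frames else pd.DataFrame()
    )

    entries = (
        genome_counts
        if config.enc_per == "genome"
        else [gc for _, lst in gene_counts_all for gc in lst]
    )
    tables["codon_usage"] = cu.codon_usage_table(entries) if entries else pd.DataFrame()
    tables["rscu_matrix"] = (
        cu.rscu_matrix(genome_counts).reset_index(names="genome")
        if genome_counts
        else pd.DataFrame()
    )

    tables["neutrality"] = dx.neutrality_table(
        gene_counts_all, min_codons=config.min_gene_codons
    )
    all_gene_counts = [gc for _, lst in gene_counts_all for gc in lst]
    tables["pr2"] = dx.pr2_table(
        all_gene_counts,
        min_codons=config.min_gene_codons,
        fourfold_only=config.pr2_fourfold_only,
    )

    coa_entries = [
        (label, counts)
        for label, counts in all_gene_counts
        if counts.n_codons >= config.min_gene_codons
    ]
    def _coa_frames(entries, scope: str):
        res = dx.coa(cu.rscu_matrix(entries))
        rows = pd.DataFrame(
            res.row_coords[:, :2], index=list(res.row_labels), columns=["axis1", "axis2"]
        ).reset_index(names="gene")
        cols = pd.DataFrame(
            res.col_coords[:, :2], index=list(res.col_labels), columns=["axis1", "axis2"]
        ).reset_index(names="codon")
        inertia = pd.DataFrame(
            {
                "axis": range(1, len(res.inertia_fraction) + 1),
                "inertia_fraction": res.inertia_fraction,
            }
        )
        for frame in (rows, cols, inertia):
            frame.insert(0, "scope", scope)
        return rows, cols, inertia

    if coa_entries:
        if config.coa_pooled:
            frames = [_coa_frames(coa_entries, "pooled")]
        else:
            frames = [
                _coa_frames(
                    [e for e in per_genome if e[1].n_codons >= config.min_gene_codons],
                    gid,
                )
                for gid, per_genome in gene_counts_all
                if sum(
                    1 for e in per_genome if e[1].n_codons >= config.min_gene_codons
                )
                >= 2
            ]
        if frames:
            tables["coa_rows"] = pd.concat([f[0] for f in frames], ignore_index=True)
            tables["coa_cols"] = pd.concat([f[1] for f in frames], ignore_index=True)
            tables["coa_inertia"] = pd.concat([f[2] for f in frames], ignore_index=True)

    tables["ssrs"] = ssr.loci_table(all_loci)
    tables["ssr_summary"] = ssr.ssr_summary(all_loci)
    tables["ssr_regions"] = (
        pd.concat(region_tables, ignore_index=True) if region_tables else pd.DataFrame()
    )
    if all_loci:
        tables["ssr_matrix"] = ssr.ssr_presence_matrix(all_loci).reset_index(
            names="motif"
        )

    if config.run_kaks and len(cds_by_genome) >= 2:
        pairs, skipped = kk.homolog_pairs(
            cds_by_genome, reference=config.kaks_reference
        )
        results = [kk.ng86(p) for p in pairs]
        tables["kaks"] = kk.kaks_table(results)
        tables["selection_summary"] = kk.classify_selection(results)
        for line in skipped:
            log.info("kaks skipped: %s", line)

    for name, df in tables.items():
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False, float_format="%.6g")

    return ReportBundle(
        out_dir=out,
        n_processed=len(analysed),
        n_failed=len(failures),
        failures=failures,
        tables=tables,
    )
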