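"""Perfect microsatellite (SSR) detection and cross-species summaries.

A reported locus is a maximal perfect tandem repeat of a *primitive* 1–6 bp
motif meeting a per-unit-length minimum copy number. The default
thresholds are 10 copies for mononucleotides, 5 for dinucleotides, 4 for
trinucleotides and 3 for tetra- through hexanucleotides. Partial trailing
units never count toward copies; N breaks any repeat; the scan is linear
along the input orientation (no origin wrap), matching common scanners.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .genetics import is_primitive, revcomp
from .plastome_io import PlastidGenome, RegionAnnotation

DEFAULT_THRESHOLDS: dict[int, int] = {1: 10, 2: 5, 3: 4, 4: 3, 5: 3, 6: 3}

CATEGORY_NAMES = {1: "Mono", 2: "Di", 3: "Tri", 4: "Tetra", 5: "Penta", 6: "Hexa"}


@dataclass(frozen=True)
class SSRLocus:
    """One perfect tandem repeat, 1-based inclusive coordinates."""

    motif: str
    copies: int
    start: int
    end: int
    genome: str = ""
    region: Optional[str] = None  # CDS | intron | IGS once classified

    @property
    def unit(self) -> int:
        return len(self.motif)

    @property
    def category(self) -> str:
        return CATEGORY_NAMES[self.unit]

    @property
    def canonical_motif(self) -> str:
        """Lexicographically minimal rotation of the motif."""
        m = self.motif
        return min(m[i:] + m[:i] for i in range(len(m)))

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def canonical_with_revcomp(motif: str) -> str:
    """Minimal rotation over the motif and its reverse complement
    (optional strand-merging canonicalization)."""
    rc = revcomp(motif)
    return min(
        min(m[i:] + m[:i] for i in range(len(m))) for m in (motif, rc)
    )


def scan_ssrs(
    genome: Union[PlastidGenome, str],
    thresholds: Optional[Mapping[int, int]] = None,
    genome_id: str = "",
) -> list[SSRLocus]:
    """All maximal perfect tandem repeats with primitive 1–6 bp motifs.

    For each unit length k the sequence is compared against itself at lag
    k; every maximal run of agreement of total length T >= 2k yields a
    candidate with ``copies = T // k`` and the leftmost phase as motif.
    Non-primitive motifs are skipped (their repeats are reported at the
    primitive unit length); duplicate spans keep the smallest unit.
    """
    if isinstance(genome, PlastidGenome):
        seq = genome.sequence
        genome_id = genome_id or genome.id
    else:
        seq = genome.upper()
    thr = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)

    n = len(seq)
    loci: list[SSRLocus] = []
    seen_spans: dict[tuple[int, int], int] = {}
    for k in sorted(thr):
        min_copies = thr[k]
        if min_copies < 2 or n < k * 2:
            continue
        i = 0
        limit = n - k
        while i < limit:
            if seq[i] != seq[i + k] or seq[i] == "N":
                i += 1
                continue
            run_start = i
            while i < limit and seq[i] == seq[i + k] and seq[i] != "N":
                i += 1
            total = (i - run_start) + k  # matched region length incl. lag
            copies = total // k
            if copies < min_copies:
                continue
            motif = seq[run_start : run_start + k]
            if "N" in motif or not is_primitive(motif):
                continue
            start = run_start + 1
            end = run_start + copies * k
            span = (start, end)
            if span in seen_spans:  # same repeat found at a larger unit
                continue
            seen_spans[span] = k
            loci.append(
                SSRLocus(motif=motif, copies=copies, start=start, end=end, genome=genome_id)
            )
    loci.sort(key=lambda l: (l.start, l.unit))
    return loci


def classify_ssr_regions(
    loci: Sequence[SSRLocus], annotation: RegionAnnotation
) -> tuple[list[SSRLocus], pd.DataFrame]:
    """Label each locus by the region containing its midpoint and tabulate
    the share of loci per region (CDS / intron / IGS)."""
    labeled = [replace(l, region=annotation.label_at(l.midpoint)) for l in loci]
    counts = {"CDS": 0, "intron": 0, "IGS": 0}
    for l in labeled:
        counts[l.region] += 1
    total = max(sum(counts.values()), 1)
    table = pd.DataFrame(
        [
            {"region": r, "n_loci": c, "percent": 100.0 * c / total}
            for r, c in counts.items()
        ]
    )
    return labeled, table


def ssr_presence_matrix(
    loci: Iterable[SSRLocus], merge_revcomp: bool = False
) -> pd.DataFrame:
    """Canonical-motif x genome presence/absence (1/0) matrix.

    Motifs are canonicalized by minimal rotation; ``merge_revcomp``
    additionally merges a motif with its reverse complement. Row means
    give per-motif conservation across genomes.
    """
    cells: dict[str, dict[str, int]] = {}
    genomes: list[str] = []
    for l in loci:
        key = canonical_with_revcomp(l.motif) if merge_revcomp else l.canonical_motif
        if l.genome not in genomes:
            genomes.append(l.genome)
        cells.setdefault(key, {})[l.genome] = 1
    matrix = pd.DataFrame(
        [[cells[m].get(g, 0) for g in genomes] for m in sorted(cells)],
        index=sorted(cells),
        columns=genomes,
        dtype=int,
    )
    return matrix


def motif_conservation(matrix: pd.DataFrame) -> pd.Series:
    """Per-motif conservation percentage (row mean of the 0/1 matrix)."""
    return 100.0 * matrix.mean(axis=1)


def ssr_summary(loci: Iterable[SSRLocus]) -> pd.DataFrame:
    """Per-genome counts by unit-length category plus overall percentages."""
    rows = [
        {"genome": l.genome, "category": l.category, "unit": l.unit} for l in loci
    ]
    if not rows:
        return pd.DataFrame(columns=["genome", *CATEGORY_NAMES.values(), "total"])
    df = pd.DataFrame(rows)
    pivot = (
        df.pivot_table(index="genome", columns="category", values="unit", aggfunc="count")
        .reindex(columns=list(CATEGORY_NAMES.values()))
        .fillna(0)
        .astype(int)
    )
    pivot["total"] = pivot.sum(axis=1)
    return pivot.reset_index()


def loci_table(loci: Iterable[SSRLocus]) -> pd.DataFrame:
    """One row per locus, TSV-ready."""
    return pd.DataFrame(
        [
            {
                "genome": l.genome,
                "motif": l.motif,
                "canonical_motif": l.canonical_motif,
                "unit": l.unit,
                "category": l.category,
                "copies": l.copies,
                "start": l.start,
                "end": l.end,
                "region": l.region or "",
            }
            for l in loci
        ]
    )


def loci_to_bed(loci: Iterable[SSRLocus]) -> pd.DataFrame:
    """BED-style frame (0-based half-open; conversion happens only here)."""
    return pd.DataFrame(
        [
            {
                "chrom": l.genome,
                "start": l.start - 1,
                "end": l.end,
                "name": f"{l.motif}x{l.copies}",
            }
            for l in loci
        ]
    )
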