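"""Plastome input, CDS extraction, and quadripartite structure detection.

Plastid genomes arrive as annotated GenBank flat files (or FASTA + GFF3).
This module turns them into :class:`PlastidGenome` objects, splices coding
sequences out of (possibly multi-exon, possibly minus-strand, possibly
origin-wrapping) feature locations, labels every base as CDS / intron /
intergenic spacer, and locates the canonical quadripartite layout
(LSC + IRb + SSC + IRa) by exact inverted-repeat search.

Coordinates are 1-based inclusive (GenBank convention) throughout; the
only conversions happen at serialization boundaries (e.g. BED export).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from Bio import SeqIO

from .genetics import STOP_CODONS, has_internal_stop, revcomp

VALID_BASES = set("ACGTN")

# region labels (RegionAnnotation array codes)
IGS, INTRON, CDS = 0, 1, 2
REGION_NAMES = {IGS: "IGS", INTRON: "intron", CDS: "CDS"}


class ParseError(ValueError):
    """A genome file could not be turned into a PlastidGenome."""


class NoInvertedRepeatError(ValueError):
    """No inverted repeat of the required length exists in the genome."""


@dataclass(frozen=True)
class GeneFeature:
    """One annotated feature; multi-exon locations keep one part per exon.

    ``parts`` are (start, end, strand) with 1-based inclusive coordinates
    in genomic order as written in the source file; strand is +1/-1.
    """

    gene_name: str
    kind: str  # CDS | tRNA | rRNA | other
    parts: tuple[tuple[int, int, int], ...]
    product: Optional[str] = None

    def __post_init__(self):
        if not self.parts:
            raise ValueError(f"feature {self.gene_name}: empty location")

    @property
    def strand(self) -> int:
        return self.parts[0][2]

    @property
    def spliced_length(self) -> int:
        return sum(e - s + 1 for s, e, _ in self.parts)

    def span(self) -> tuple[int, int]:
        return min(p[0] for p in self.parts), max(p[1] for p in self.parts)


@dataclass
class PlastidGenome:
    """A circular plastid genome: sequence plus typed gene features."""

    id: str
    species: str
    sequence: str
    circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ParseError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ParseError(f"{self.id}: invalid characters {sorted(bad)!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def gc(self) -> float:
        s = self.sequence
        return (s.count("G") + s.count("C")) / len(s)

    def slice(self, start: int, end: int) -> str:
        """1-based inclusive slice; wraps the origin when start > end."""
        if start <= end:
            return self.sequence[start - 1 : end]
        return self.sequence[start - 1 :] + self.sequence[:end]

    def gene_counts(self) -> dict[str, int]:
        """Feature tallies by kind, as annotated (IR duplicates included)."""
        out: dict[str, int] = {}
        for f in self.features:
            out[f.kind] = out.get(f.kind, 0) + 1
        out["total"] = len(self.features)
        return out


@dataclass(frozen=True)
class QuadripartiteStructure:
    """LSC / SSC / IRa / IRb intervals on the circle, 1-based inclusive.

    Intervals with start > end wrap the origin. IRb is the repeat copy
    encountered first along the input orientation; ``ira`` is its exact
    reverse complement.
    """

    lsc: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]
    irb: tuple[int, int]
    genome_length: int

    def _ilen(self, iv: tuple[int, int]) -> int:
        s, e = iv
        return e - s + 1 if s <= e else self.genome_length - s + 1 + e

    @property
    def ir_length(self) -> int:
        return self._ilen(self.ira)

    @property
    def lsc_length(self) -> int:
        return self._ilen(self.lsc)

    @property
    def ssc_length(self) -> int:
        return self._ilen(self.ssc)


@dataclass
class RegionAnnotation:
    """Per-base CDS / intron / IGS labels over a genome (dense array)."""

    codes: np.ndarray  # uint8, values in {IGS, INTRON, CDS}, length = genome

    def label_at(self, pos: int) -> str:
        """Label of 1-based position *pos*."""
        return REGION_NAMES[int(self.codes[pos - 1])]

    def counts(self) -> dict[str, int]:
        return {
            name: int(np.sum(self.codes == code))
            for code, name in REGION_NAMES.items()
        }

    def rle(self) -> list[tuple[int, int, str]]:
        """Run-length encoding as (start, end, label), 1-based inclusive."""
        codes = self.codes
        breaks = np.flatnonzero(np.diff(codes)) + 1
        starts = np.concatenate(([0], breaks))
        ends = np.concatenate((breaks, [len(codes)]))
        return [
            (int(s) + 1, int(e), REGION_NAMES[int(codes[s])])
            for s, e in zip(starts, ends)
        ]


# ---------------------------------------------------------------------------
# parsing

_KIND_MAP = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}
# feature types that describe the same gene at another level; skipped rather
# than collected under `other`
_SKIP_TYPES = {"gene", "source", "exon", "intron", "misc_feature"}


def _feature_name(qualifiers: dict, default: str) -> str:
    for key in ("gene", "locus_tag", "Name", "ID"):
        if key in qualifiers:
            v = qualifiers[key]
            return v[0] if isinstance(v, list) else v
    return default


def parse_genbank(path: str | Path) -> PlastidGenome:
    """Parse a GenBank flat file into a :class:`PlastidGenome`.

    join()/complement() locations are resolved into ordered parts;
    duplicate gene copies in IRa/IRb stay separate features. Unknown
    feature kinds are collected under ``other``.
    """
    path = Path(path)
    try:
        record = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    seq = str(record.seq).upper()
    if not seq:
        raise ParseError(f"{path}: record has no ORIGIN sequence")

    features: list[GeneFeature] = []
    warnings: list[str] = []
    for i, feat in enumerate(record.features):
        if feat.type in _SKIP_TYPES:
            continue
        kind = _KIND_MAP.get(feat.type)
        if kind is None:
            kind = "other"
            warnings.append(f"feature {i}: unknown kind {feat.type!r} -> other")
        parts = tuple(
            (int(p.start) + 1, int(p.end), int(p.strand or 1))
            for p in feat.location.parts
        )
        product = feat.qualifiers.get("product", [None])[0]
        features.append(
            GeneFeature(
                gene_name=_feature_name(feat.qualifiers, f"feature_{i}"),
                kind=kind,
                parts=parts,
                product=product,
            )
        )

    circular = record.annotations.get("topology", "circular") == "circular"
    species = record.annotations.get("organism", record.description or record.id)
    genome = PlastidGenome(
        id=record.id or path.stem,
        species=species,
        sequence=seq,
        circular=circular,
        features=features,
    )
    genome.parse_warnings = warnings  # type: ignore[attr-defined]
    return genome


def _parse_gff_attributes(text: str) -> dict[str, str]:
    out = {}
    for chunk in text.strip().split(";"):
        if "=" in chunk:
            k, v = chunk.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def parse_fasta_gff3(fasta_path: str | Path, gff_path: str | Path) -> PlastidGenome:
    """Assemble a PlastidGenome from a FASTA sequence and a GFF3 feature table.

    Only ``CDS``, ``tRNA`` and ``rRNA`` rows are mapped to typed features;
    multi-row CDS sharing a Parent (or ID) become one multi-part feature.
    """
    record = SeqIO.read(str(fasta_path), "fasta")
    seq = str(record.seq).upper()

    groups: dict[tuple[str, str], dict] = {}
    order: list[tuple[str, str]] = []
    with open(gff_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                continue
            ftype = cols[2]
            if ftype not in _KIND_MAP:
                continue
            attrs = _parse_gff_attributes(cols[8])
            key_id = attrs.get("Parent") or attrs.get("ID") or f"row{len(order)}"
            key = (ftype, key_id)
            start, end = int(cols[3]), int(cols[4])
            strand = -1 if cols[6] == "-" else 1
            if key not in groups:
                groups[key] = {
                    "name": attrs.get("gene") or attrs.get("Name") or key_id,
                    "kind": _KIND_MAP[ftype],
                    "parts": [],
                    "product": attrs.get("product"),
                }
                order.append(key)
            groups[key]["parts"].append((start, end, strand))

    features = [
        GeneFeature(
            gene_name=groups[k]["name"],
            kind=groups[k]["kind"],
            parts=tuple(sorted(groups[k]["parts"])),
            product=groups[k]["product"],
        )
        for k in order
    ]
    return PlastidGenome(
        id=record.id, species=record.description, sequence=seq, features=features
    )


# ---------------------------------------------------------------------------
# CDS extraction

@dataclass(frozen=True)
class CDSRecord:
    """A spliced coding sequence plus its QC flag (None = clean)."""

    gene_name: str
    sequence: str
    flag: Optional[str] = None  # "length_not_multiple_of_3" | "internal_stop"


def splice(genome: PlastidGenome, feature: GeneFeature) -> str:
    """Spliced sequence of *feature*: per-part slice, minus-strand parts
    reverse-complemented, minus-strand multi-part genes read 3'→5' in
    genomic order (GenBank ``complement(join(...))`` semantics)."""
    pieces = []
    for s, e, strand in feature.parts:
        seg = genome.slice(s, e)
        pieces.append(revcomp(seg) if strand == -1 else seg)
    if all(p[2] == -1 for p in feature.parts) and len(feature.parts) > 1:
        pieces = pieces[::-1]
    return "".join(pieces)


def extract_cds(
    genome: PlastidGenome, *, drop_flagged: bool = True
) -> list[CDSRecord]:
    """Spliced coding sequences of every CDS feature.

    Sequences whose length is not a multiple of 3, or that contain an
    internal stop under the plastid code, are flagged; with
    ``drop_flagged`` (default) they are excluded, matching their exclusion
    from all codon statistics. Use :func:`cds_qc` for the full table.
    """
    out = []
    for feat in genome.features:
        if feat.kind != "CDS":
            continue
        seq = splice(genome, feat)
        flag = None
        if len(seq) % 3:
            flag = "length_not_multiple_of_3"
        elif has_internal_stop(seq):
            flag = "internal_stop"
        rec = CDSRecord(feat.gene_name, seq, flag)
        if flag is None or not drop_flagged:
            out.append(rec)
    return out


def cds_qc(genome: PlastidGenome) -> pd.DataFrame:
    """QC table over all CDS features: gene, length, flag, included."""
    rows = []
    for rec in extract_cds(genome, drop_flagged=False):
        rows.append(
            {
                "genome": genome.id,
                "gene": rec.gene_name,
                "length": len(rec.sequence),
                "flag": rec.flag or "",
                "included": rec.flag is None,
            }
        )
    return pd.DataFrame(rows, columns=["genome", "gene", "length", "flag", "included"])


# ---------------------------------------------------------------------------
# quadripartite structure

def _maximal_inverted_matches(seq: str, k: int) -> list[tuple[int, int, int]]:
    """Maximal exact matches between *seq* and its reverse complement.

    Returns (i, j, L): seq[i:i+L] == rc[j:j+L], 0-based, found by k-mer
    anchoring on shared diagonals followed by mismatch-free extension.
    """
    rc = revcomp(seq)
    n = len(seq)
    index: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)

    # group anchors by diagonal (i - j); on a diagonal, anchor starts that
    # are contiguous belong to the same maximal match
    diagonals: dict[int, set[int]] = {}
    for j in range(n - k + 1):
        for i in index.get(rc[j : j + k], ()):
            diagonals.setdefault(i - j, set()).add(j)

    matches = []
    for d, js in diagonals.items():
        js_sorted = sorted(js)
        run_start = js_sorted[0]
        prev = js_sorted[0]
        runs = []
        for j in js_sorted[1:]:
            if j != prev + 1:
                runs.append((run_start, prev))
                run_start = j
            prev = j
        runs.append((run_start, prev))
        for j0, j1 in runs:
            i0 = j0 + d
            L = (j1 - j0) + k
            # extend in case the run edge fell between k-mer starts
            while i0 > 0 and j0 > 0 and seq[i0 - 1] == rc[j0 - 1]:
                i0 -= 1
                j0 -= 1
                L += 1
            while i0 + L < n and j0 + L < n and seq[i0 + L] == rc[j0 + L]:
                L += 1
            matches.append((i0, j0, L))
    return matches


def detect_quadripartite(
    genome: PlastidGenome, min_ir: int = 10_000, seed_k: int = 25
) -> QuadripartiteStructure:
    """Locate LSC/SSC/IRa/IRb by exact inverted-repeat search.

    Finds the longest pair of disjoint, exactly reverse-complementary
    segments of length >= *min_ir* (k-mer anchoring + maximal extension),
    then names the larger single-copy arc LSC. Intervals are reported in
    the input orientation, 1-based inclusive; the arc crossing the origin
    wraps (start > end).

    Raises :class:`NoInvertedRepeatError` if no such pair exists.
    """
    n = len(genome)
    if n <= 2 * min_ir:
        raise NoInvertedRepeatError(
            f"{genome.id}: genome length {n} <= 2*min_ir ({2 * min_ir})"
        )
    seq = genome.sequence
    best = None
    for i, j, L in _maximal_inverted_matches(seq, seed_k):
        if L < min_ir:
            continue
        # segment A = seq[i, i+L); its partner in seq coordinates:
        a0, a1 = i, i + L  # half-open
        b0, b1 = n - (j + L), n - j
        if a0 >= b0:  # each pair appears twice; keep A before B
            continue
        if a1 > b0:  # overlapping copies (palindrome core): trim to disjoint
            overlap = a1 - b0
            L2 = L - overlap
            if L2 < min_ir:
                continue
            a1, b0 = a0 + L2, b1 - L2
            L = L2
        if best is None or L > best[4]:
            best = (a0, a1, b0, b1, L)

    if best is None:
        raise NoInvertedRepeatError(
            f"{genome.id}: no inverted repeat of length >= {min_ir}"
        )
    a0, a1, b0, b1, L = best
    irb = (a0 + 1, a1)  # 1-based inclusive
    ira = (b0 + 1, b1)
    assert genome.slice(*irb) == revcomp(genome.slice(*ira))

    # the two single-copy arcs: between A and B, and B wrapping to A
    arc1 = (a1 + 1, b0)  # may be empty if a1 == b0
    arc2_start = (b1 % n) + 1
    arc2_end = a0 if a0 > 0 else n
    arc2 = (arc2_start, arc2_end)

    def arc_len(iv):
        s, e = iv
        return e - s + 1 if s <= e else n - s + 1 + e

    l1, l2 = arc_len(arc1), arc_len(arc2)
    if l1 >= l2:
        lsc, ssc = arc1, arc2
    else:
        lsc, ssc = arc2, arc1
    struct = QuadripartiteStructure(
        lsc=lsc, ssc=ssc, ira=ira, irb=irb, genome_length=n
    )
    assert struct.lsc_length + struct.ssc_length + 2 * struct.ir_length == n
    return struct


# ---------------------------------------------------------------------------
# region classification

def classify_regions(genome: PlastidGenome) -> RegionAnnotation:
    """Label every base CDS, intron, or IGS (precedence CDS > intron > IGS).

    A base is CDS if covered by any CDS part; else intron if it falls in
    an inter-part gap of any multi-part gene; else intergenic spacer.
    """
    n = len(genome)
    codes = np.zeros(n, dtype=np.uint8)  # IGS

    def mark(start: int, end: int, code: int):
        if start <= end:
            codes[start - 1 : end] = np.maximum(codes[start - 1 : end], code)
        else:  # wraps origin
            codes[start - 1 :] = np.maximum(codes[start - 1 :], code)
            codes[:end] = np.maximum(codes[:end], code)

    for feat in genome.features:
        if len(feat.parts) > 1:
            parts = sorted(feat.parts)
            for (s1, e1, _), (s2, e2, _) in zip(parts, parts[1:]):
                if e1 + 1 <= s2 - 1:
                    mark(e1 + 1, s2 - 1, INTRON)
    for feat in genome.features:
        if feat.kind == "CDS":
            for s, e, _ in feat.parts:
                mark(s, e, CDS)
    return RegionAnnotation(codes=codes)


def structure_table(
    genomes: Iterable[PlastidGenome], min_ir: int = 10_000
) -> pd.DataFrame:
    """One row per genome: id, species, length, GC%, region lengths, gene
    counts by kind. Genomes without a detectable IR get NA region lengths."""
    rows = []
    for g in genomes:
        counts = g.gene_counts()
        row = {
            "genome": g.id,
            "species": g.species,
            "length": len(g),
            "gc_percent": round(100 * g.gc, 2),
            "n_cds": counts.get("CDS", 0),
            "n_trna": counts.get("tRNA", 0),
            "n_rrna": counts.get("rRNA", 0),
            "n_features": counts["total"],
        }
        try:
            st = detect_quadripartite(g, min_ir=min_ir)
            row.update(
                lsc_length=st.lsc_length,
                ssc_length=st.ssc_length,
                ir_length=st.ir_length,
            )
        except NoInvertedRepeatError:
            row.update(lsc_length=pd.NA, ssc_length=pd.NA, ir_length=pd.NA)
        rows.append(row)
    return pd.DataFrame(rows)
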