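"""Genetic-code helpers shared by all analysis stages.

The plastid (bacterial/plant-plastid) genetic code, NCBI translation
table 11, is fixed package-wide. Synonymous families are built from the
Biopython codon table so the codon→amino-acid map is never hand-typed;
six-fold families (Leu, Ser, Arg) are treated as single families, the
CodonW convention.
"""

from __future__ import annotations

from functools import lru_cache

from Bio.Data.CodonTable import unambiguous_dna_by_id

TABLE_ID = 11

_table = unambiguous_dna_by_id[TABLE_ID]

#: codon (DNA, upper) -> one-letter amino acid, sense codons only
CODON_TO_AA: dict[str, str] = dict(_table.forward_table)

#: the three stop codons of table 11
STOP_CODONS: frozenset[str] = frozenset(_table.stop_codons)

SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

#: amino acid -> sorted tuple of synonymous codons
FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in CODON_TO_AA.items():
    FAMILIES.setdefault(_aa, ())
FAMILIES = {
    aa: tuple(sorted(c for c, a in CODON_TO_AA.items() if a == aa))
    for aa in FAMILIES
}

#: degeneracy (family size) per amino acid
DEGENERACY: dict[str, int] = {aa: len(cods) for aa, cods in FAMILIES.items()}

#: the 59 codons that carry synonymous-choice information:
#: all sense codons minus the single-codon families (ATG/Met, TGG/Trp)
INFORMATIVE_CODONS: tuple[str, ...] = tuple(
    c for c in SENSE_CODONS if DEGENERACY[CODON_TO_AA[c]] > 1
)

assert len(SENSE_CODONS) == 61 and len(INFORMATIVE_CODONS) == 59

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N preserved)."""
    return seq.translate(COMPLEMENT)[::-1]


def codons_of(seq: str) -> list[str]:
    """Frame-0 triplets of *seq*; raises if length is not a multiple of 3."""
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} not a multiple of 3")
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


@lru_cache(maxsize=None)
def is_primitive(motif: str) -> bool:
    """True if *motif* is not an integer power of a shorter string."""
    n = len(motif)
    for p in range(1, n):
        if n % p == 0 and motif == motif[:p] * (n // p):
            return False
    return True


def translate(seq: str) -> str:
    """Translate a frame-0 coding sequence; '*' marks stops, 'X' ambiguous."""
    out = []
    for c in codons_of(seq.upper()):
        if c in STOP_CODONS:
            out.append("*")
        else:
            out.append(CODON_TO_AA.get(c, "X"))
    return "".join(out)


def has_internal_stop(seq: str) -> bool:
    """True if any codon before the last is a stop codon."""
    cods = codons_of(seq.upper())
    return any(c in STOP_CODONS for c in cods[:-1])
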