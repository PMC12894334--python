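"""Pairwise Ka/Ks estimation (Nei–Gojobori 1986 counting) and selection
classification.

For each codon the number of synonymous sites is the sum over the three
positions of the fraction of single-base changes (to sense codons; stop
changes are ignored) that preserve the amino acid; site totals are
averaged over the two sequences. Observed differences are resolved over
all minimal mutational pathways with equal weights, skipping pathways
that pass through a stop codon. Proportions are corrected for multiple
hits with Jukes–Cantor, d = -(3/4) ln(1 - (4/3) p), and omega = Ka/Ks.

Genes are binned into three selection regimes at the conventional
thresholds: strong purifying (omega < 0.5), relaxed purifying
(0.5 <= omega <= 1.0), and positive (omega > 1.0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from typing import Iterable, Optional, Sequence

import pandas as pd

from .genetics import CODON_TO_AA, STOP_CODONS, codons_of

_BASES = "ACGT"

STRONG_PURIFYING = "strong_purifying"
RELAXED_PURIFYING = "relaxed_purifying"
POSITIVE = "positive"
UNDEFINED = "undefined"


class PairError(ValueError):
    """A sequence pair violates the codon-alignment contract."""


@dataclass(frozen=True)
class CodonAlignmentPair:
    """Two aligned, gap-stripped coding sequences of equal length."""

    gene: str
    seq_a: str
    seq_b: str
    species_a: str = ""
    species_b: str = ""
    n_dropped_columns: int = 0  # codon columns removed for gaps/N

    def __post_init__(self):
        if len(self.seq_a) != len(self.seq_b):
            raise PairError(f"{self.gene}: unequal lengths")
        if len(self.seq_a) % 3:
            raise PairError(f"{self.gene}: length not a multiple of 3")


def make_pair(
    gene: str,
    seq_a: str,
    seq_b: str,
    species_a: str = "",
    species_b: str = "",
) -> CodonAlignmentPair:
    """Build a clean pair from aligned sequences.

    Codon columns containing gaps, N, or a stop codon in either sequence
    are removed (the count is recorded on the pair). Input lengths must
    match and be multiples of 3.
    """
    a, b = seq_a.upper(), seq_b.upper()
    if len(a) != len(b):
        raise PairError(f"{gene}: aligned lengths differ ({len(a)} vs {len(b)})")
    if len(a) % 3:
        raise PairError(f"{gene}: aligned length {len(a)} not a multiple of 3")
    keep_a, keep_b = [], []
    dropped = 0
    for ca, cb in zip(codons_of(a), codons_of(b)):
        bad = (
            any(ch not in _BASES for ch in ca + cb)
            or ca in STOP_CODONS
            or cb in STOP_CODONS
        )
        if bad:
            dropped += 1
            continue
        keep_a.append(ca)
        keep_b.append(cb)
    return CodonAlignmentPair(
        gene=gene,
        seq_a="".join(keep_a),
        seq_b="".join(keep_b),
        species_a=species_a,
        species_b=species_b,
        n_dropped_columns=dropped,
    )


@dataclass(frozen=True)
class KaKsResult:
    gene: str
    ka: Optional[float]
    ks: Optional[float]
    ratio: Optional[float]
    category: str
    n_syn_sites: float
    n_nonsyn_sites: float
    syn_differences: float
    nonsyn_differences: float
    n_codons: int


@lru_cache(maxsize=None)
def _syn_sites(codon: str) -> float:
    """Synonymous sites of one sense codon (stop changes ignored)."""
    aa = CODON_TO_AA[codon]
    total = 0.0
    for pos in range(3):
        syn = 0
        sense = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            sense += 1
            if CODON_TO_AA[alt] == aa:
                syn += 1
        if sense:
            total += syn / sense
    return total


@lru_cache(maxsize=None)
def _pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two sense codons,
    averaged with equal weights over all minimal mutational pathways.

    Pathways passing through a stop codon are excluded; if every pathway
    is blocked, all pathways are used with stop steps counted as
    nonsynonymous.
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return (0.0, 0.0)

    def walk(order: tuple[int, ...], allow_stops: bool):
        syn = nonsyn = 0.0
        cur = codon_a
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                if not allow_stops:
                    return None
                nonsyn += 1.0
            elif cur in STOP_CODONS:
                nonsyn += 1.0
            elif CODON_TO_AA[cur] == CODON_TO_AA[nxt]:
                syn += 1.0
            else:
                nonsyn += 1.0
            cur = nxt
        return syn, nonsyn

    results = [r for o in permutations(diff_pos) if (r := walk(o, False)) is not None]
    if not results:
        results = [walk(o, True) for o in permutations(diff_pos)]
    syn = sum(r[0] for r in results) / len(results)
    nonsyn = sum(r[1] for r in results) / len(results)
    return (syn, nonsyn)


def _jukes_cantor(p: float) -> Optional[float]:
    """JC69 distance; None when p >= 3/4 (correction undefined)."""
    if p < 0:
        raise ValueError("proportion < 0")
    if p == 0.0:
        return 0.0
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


def ng86(pair: CodonAlignmentPair) -> KaKsResult:
    """NG86 Ka, Ks, and omega for one codon-aligned pair.

    Site counts are averaged over the two sequences and satisfy
    S + N = 3 * n_codons. ks = 0 with ka > 0, p >= 3/4, or identical
    sequences all yield an undefined ratio (category ``undefined``).
    """
    cods_a = codons_of(pair.seq_a)
    cods_b = codons_of(pair.seq_b)
    n_codons = len(cods_a)
    if n_codons == 0:
        return KaKsResult(pair.gene, None, None, None, UNDEFINED, 0.0, 0.0, 0.0, 0.0, 0)

    S = 0.0
    Sd = Nd = 0.0
    for ca, cb in zip(cods_a, cods_b):
        if ca in STOP_CODONS or cb in STOP_CODONS:
            raise PairError(f"{pair.gene}: internal stop codon in aligned pair")
        S += (_syn_sites(ca) + _syn_sites(cb)) / 2.0
        s, ns = _pathway_differences(ca, cb)
        Sd += s
        Nd += ns
    N = 3.0 * n_codons - S

    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    ks = _jukes_cantor(ps)
    ka = _jukes_cantor(pn)

    if ka is None or ks is None or ks == 0.0:
        ratio = None
    else:
        ratio = ka / ks

    if ratio is None:
        category = UNDEFINED
    elif ratio < 0.5:
        category = STRONG_PURIFYING
    elif ratio <= 1.0:
        category = RELAXED_PURIFYING
    else:
        category = POSITIVE

    return KaKsResult(
        gene=pair.gene,
        ka=ka,
        ks=ks,
        ratio=ratio,
        category=category,
        n_syn_sites=S,
        n_nonsyn_sites=N,
        syn_differences=Sd,
        nonsyn_differences=Nd,
        n_codons=n_codons,
    )


def classify_selection(results: Iterable[KaKsResult]) -> pd.DataFrame:
    """Counts and percentages per selection regime.

    Pairs with an undefined ratio are excluded from the percentage
    denominator and reported in their own row (percent = NaN).
    """
    tallies = {STRONG_PURIFYING: 0, RELAXED_PURIFYING: 0, POSITIVE: 0, UNDEFINED: 0}
    for r in results:
        tallies[r.category] += 1
    defined = sum(v for k, v in tallies.items() if k != UNDEFINED)
    rows = []
    for cat in (STRONG_PURIFYING, RELAXED_PURIFYING, POSITIVE):
        pct = 100.0 * tallies[cat] / defined if defined else math.nan
        rows.append({"category": cat, "n": tallies[cat], "percent": pct})
    rows.append({"category": UNDEFINED, "n": tallies[UNDEFINED], "percent": math.nan})
    return pd.DataFrame(rows)


def homolog_pairs(
    cds_by_genome: dict[str, Sequence[tuple[str, str]]],
    reference: Optional[str] = None,
) -> tuple[list[CodonAlignmentPair], list[str]]:
    """Pair homologous CDS by identical gene name across genomes.

    ``reference=None`` forms all genome pairs per gene; otherwise every
    genome is paired against the reference only. Only equal-length CDS
    pairs are formed (positional codon mapping); skipped combinations are
    returned as log lines.
    """
    pairs: list[CodonAlignmentPair] = []
    skipped: list[str] = []
    genomes = list(cds_by_genome)
    by_gene: dict[str, dict[str, str]] = {}
    for genome_id, records in cds_by_genome.items():
        for gene, seq in records:
            by_gene.setdefault(gene, {}).setdefault(genome_id, seq)

    for gene, per_genome in sorted(by_gene.items()):
        if reference is not None:
            if reference not in per_genome:
                continue
            combos = [
                (reference, g) for g in genomes if g != reference and g in per_genome
            ]
        else:
            present = [g for g in genomes if g in per_genome]
            combos = [
                (g1, g2)
                for i, g1 in enumerate(present)
                for g2 in present[i + 1 :]
            ]
        for g1, g2 in combos:
            a, b = per_genome[g1], per_genome[g2]
            if len(a) != len(b):
                skipped.append(f"{gene}: {g1} vs {g2} lengths differ ({len(a)} vs {len(b)})")
                continue
            try:
                pairs.append(make_pair(gene, a, b, species_a=g1, species_b=g2))
            except PairError as exc:
                skipped.append(str(exc))
    return pairs, skipped


def pair_from_fasta(path) -> CodonAlignmentPair:
    """Read one aligned pair from a FASTA file holding exactly two records.

    Record ids become the species labels; the file stem names the gene.
    Gap/N/stop codon columns are dropped as in :func:`make_pair`.
    """
    from pathlib import Path

    from Bio import SeqIO

    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise PairError(f"{path}: expected exactly 2 records, found {len(records)}")
    a, b = records
    return make_pair(
        gene=path.stem,
        seq_a=str(a.seq),
        seq_b=str(b.seq),
        species_a=a.id,
        species_b=b.id,
    )


def kaks_table(results: Iterable[KaKsResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "ka": r.ka,
                "ks": r.ks,
                "ratio": r.ratio,
                "category": r.category,
                "n_syn_sites": r.n_syn_sites,
                "n_nonsyn_sites": r.n_nonsyn_sites,
                "n_codons": r.n_codons,
            }
            for r in results
        ]
    )
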