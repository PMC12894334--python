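"""Synthetic plastomes and homolog pairs with exact ground truth.

Every pipeline stage is verifiable without any real accession: the
generator emits an annotated circular genome with a planted quadripartite
layout (LSC + IRb + SSC + IRa, IRa an exact reverse complement of IRb),
protein-coding genes drawn codon-by-codon from controllable per-family
codon probabilities (or a third-position GC target), SSR loci planted at
known coordinates in CDS / intron / IGS, and a truth table that can be
re-checked against the emitted sequence by direct string comparison.

Intergenic filler is built under an online run-length constraint so that
no unplanned tandem repeat can reach the reporting thresholds, and every
planted repeat is flanked by non-extending guard bases; a final
verification scan asserts that the scanner's output over the whole genome
equals the planted truth exactly.

A single integer seed drives one named pseudo-random stream
(`numpy.random.Generator`); all stochastic operations take the stream
explicitly, so outputs are byte-identical across reruns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .genetics import CODON_TO_AA, FAMILIES, STOP_CODONS, revcomp
from .kaks import CodonAlignmentPair, make_pair
from .plastome_io import GeneFeature, PlastidGenome
from .ssr import DEFAULT_THRESHOLDS, SSRLocus, scan_ssrs

_BASES = "ACGT"
_GUARD_LEN = 10


class SpecError(ValueError):
    """The synthetic-genome spec cannot be realized as requested."""


@dataclass
class SyntheticGenomeSpec:
    """Parameters of one synthetic plastome.

    ``family_probs`` maps amino acid -> probability per synonymous codon
    (aligned with the sorted codon order of the family); unspecified
    families use equal probabilities. ``gc3_target`` instead biases every
    family's third position toward the requested GC fraction. Planted
    SSRs are (motif, copies, region) with region in {CDS, intron, IGS}.
    """

    seed: int = 0
    lsc_len: int = 87_000
    ssc_len: int = 16_000
    ir_len: int = 26_000
    n_genes: int = 40
    gene_length_codons: int = 250
    family_probs: Optional[dict[str, Sequence[float]]] = None
    gc3_target: Optional[float] = None
    planted_ssrs: list[tuple[str, int, str]] = field(default_factory=list)
    intergenic_at_fraction: float = 0.7
    minus_strand_fraction: float = 0.3
    intron_len: int = 120
    genome_id: str = "synthetic"
    species: str = "synthetic plastome"

    def __post_init__(self):
        if min(self.lsc_len, self.ssc_len, self.ir_len) <= 0:
            raise SpecError("region lengths must be positive")
        if self.lsc_len < self.ssc_len:
            raise SpecError("LSC must be at least as long as SSC")
        for motif, copies, region in self.planted_ssrs:
            if not 1 <= len(motif) <= 6:
                raise SpecError(f"motif {motif!r}: unit length must be 1-6")
            if region not in ("CDS", "intron", "IGS"):
                raise SpecError(f"unknown SSR region {region!r}")
            if copies < DEFAULT_THRESHOLDS[len(motif)]:
                raise SpecError(
                    f"motif {motif!r}: {copies} copies below reporting threshold"
                )


@dataclass
class TruthTable:
    """Realized coordinates of everything the generator planted."""

    spec: SyntheticGenomeSpec
    lsc: tuple[int, int]
    irb: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]
    genes: list[dict] = field(default_factory=list)  # name, strand, parts, cds
    ssrs: list[SSRLocus] = field(default_factory=list)

    def validate(self, genome: PlastidGenome) -> None:
        """Re-check every truth coordinate against the emitted sequence."""
        assert genome.slice(*self.irb) == revcomp(genome.slice(*self.ira))
        for g in self.genes:
            from .plastome_io import splice

            feat = next(f for f in genome.features if f.gene_name == g["name"])
            assert splice(genome, feat) == g["cds"], g["name"]
        for l in self.ssrs:
            seg = genome.slice(l.start, l.end)
            assert seg == l.motif * l.copies, (l.motif, l.start)


# ---------------------------------------------------------------------------
# constrained random sequence


class _FillerWriter:
    """Emits random bases while forbidding any lag-k agreement run long
    enough to complete a reportable repeat (k = 1..6), including runs that
    would continue pre-existing context."""

    def __init__(self, rng: np.random.Generator, at_fraction: float, context: str = ""):
        self.rng = rng
        self.p = np.array(
            [
                at_fraction / 2,
                (1 - at_fraction) / 2,
                (1 - at_fraction) / 2,
                at_fraction / 2,
            ]
        )
        self.tail = context[-64:]

    # forbid run[k] >= k * (threshold(k) - 1): a matched run of that length
    # spans threshold copies, so staying strictly below keeps every window
    # under-threshold regardless of phase
    _LIMITS = {k: k * (t - 1) for k, t in DEFAULT_THRESHOLDS.items()}

    def _violates(self, tail: str) -> bool:
        n = len(tail)
        for k, limit in self._LIMITS.items():
            if n < k + 1:
                continue
            run = 0
            for i in range(n - 1, k - 1, -1):
                if tail[i] == tail[i - k] and tail[i] != "N":
                    run += 1
                    if run >= limit:
                        return True
                else:
                    break
        return False

    def emit(self, length: int) -> str:
        out = []
        for _ in range(length):
            order = self.rng.permutation(4)
            # try bases in a random order biased by composition
            u = self.rng.random()
            first = int(np.searchsorted(np.cumsum(self.p), u))
            candidates = [first] + [int(b) for b in order if int(b) != first]
            for b in candidates:
                base = _BASES[b]
                if not self._violates(self.tail + base):
                    break
            else:  # all four blocked (cannot happen with these limits)
                base = _BASES[candidates[-1]]
            out.append(base)
            self.tail = (self.tail + base)[-64:]
        return "".join(out)


def _nonextending_guard(
    rng: np.random.Generator, motif: str, side: str, at_fraction: float
) -> str:
    """Guard flank for a planted repeat: its boundary base breaks the
    repeat's phase so the locus cannot extend into the guard."""
    w = _FillerWriter(rng, at_fraction)
    guard = w.emit(_GUARD_LEN)
    if side == "right":
        forbidden = motif[0]  # next base that would continue the repeat
        if guard[0] == forbidden:
            repl = next(b for b in _BASES if b != forbidden)
            guard = repl + guard[1:]
    else:
        forbidden = motif[-1]  # previous base that would extend leftward
        if guard[-1] == forbidden:
            repl = next(b for b in _BASES if b != forbidden)
            guard = guard[:-1] + repl
    return guard


# ---------------------------------------------------------------------------
# codon sampling


def _family_distributions(
    spec: SyntheticGenomeSpec,
) -> dict[str, np.ndarray]:
    """Per-family codon probability vectors from the spec."""
    dists: dict[str, np.ndarray] = {}
    for aa, codons in FAMILIES.items():
        k = len(codons)
        if spec.family_probs and aa in spec.family_probs:
            p = np.asarray(spec.family_probs[aa], dtype=float)
            if len(p) != k or abs(p.sum() - 1.0) > 1e-9 or np.any(p < 0):
                raise SpecError(f"family {aa}: invalid probability vector")
        elif spec.gc3_target is not None:
            g = spec.gc3_target
            w = np.array([g if c[2] in "GC" else (1 - g) for c in codons])
            if w.sum() == 0:
                w = np.ones(k)
            p = w / w.sum()
        else:
            p = np.full(k, 1.0 / k)
        dists[aa] = p
    return dists


def random_cds(
    rng: np.random.Generator,
    n_codons: int,
    family_probs: Optional[dict[str, Sequence[float]]] = None,
    gc3_target: Optional[float] = None,
    include_stop: bool = False,
) -> str:
    """A random coding sequence: ATG + codons drawn per family.

    Amino acids are drawn with probability proportional to family size
    (uniform over the 61 sense codons when families are unbiased), then
    the codon from the family's probability vector.
    """
    spec = SyntheticGenomeSpec(
        family_probs=family_probs, gc3_target=gc3_target
    )
    dists = _family_distributions(spec)
    aas = sorted(FAMILIES)
    aa_weights = np.array([len(FAMILIES[a]) for a in aas], dtype=float)
    aa_weights /= aa_weights.sum()
    out = ["ATG"]
    for _ in range(n_codons - 1):
        aa = aas[rng.choice(len(aas), p=aa_weights)]
        codons = FAMILIES[aa]
        out.append(codons[rng.choice(len(codons), p=dists[aa])])
    if include_stop:
        out.append("TAA")
    return "".join(out)


def _ssr_cds_block(motif: str, copies: int) -> tuple[str, int]:
    """Codon-aligned block embedding motif*copies inside a CDS.

    Tries all three frame offsets (left-padding with phase-breaking
    bases), pads to a codon boundary on the right likewise, and returns
    (block, offset-of-repeat-within-block). Raises when every frame puts
    a stop codon inside the block.
    """
    repeat = motif * copies

    def pad_char(next_in_phase: str) -> str:
        return next(b for b in "GC" + _BASES if b != next_in_phase)

    for left in range(3):
        lpad = "".join(
            pad_char(motif[-1 - i % len(motif)]) for i in range(left)
        )[::-1]
        block = lpad + repeat
        phase = len(repeat) % len(motif)
        while len(block) % 3:
            block += pad_char(motif[phase % len(motif)])
            phase += 1
        if all(
            block[i : i + 3] not in STOP_CODONS for i in range(0, len(block), 3)
        ):
            return block, left
    raise SpecError(f"motif {motif!r} x {copies} places a stop codon in every frame")


# ---------------------------------------------------------------------------
# genome assembly


@dataclass
class _Segment:
    kind: str  # filler | gene_part | ssr | guard
    text: str
    meta: dict = field(default_factory=dict)


class _TruthMismatch(Exception):
    pass


def make_plastome(spec: SyntheticGenomeSpec) -> tuple[PlastidGenome, TruthTable]:
    """Generate a synthetic plastome and its exact truth table.

    Deterministic under ``spec.seed``. The assembly is verified by a full
    scanner pass against the planted truth; in the rare event that a
    segment junction completes an unplanned repeat, the build is retried
    on a derived substream (still a pure function of the seed). Raises
    :class:`SpecError` when the requested content does not fit the region
    sizes.
    """
    last = None
    for attempt in range(20):
        try:
            return _build_plastome(spec, np.random.default_rng([spec.seed, attempt]))
        except _TruthMismatch as exc:
            last = exc
    raise SpecError(f"seed {spec.seed}: could not realize planted SSR truth ({last})")


def _build_plastome(
    spec: SyntheticGenomeSpec, rng: np.random.Generator
) -> tuple[PlastidGenome, TruthTable]:
    at = spec.intergenic_at_fraction
    dists = _family_distributions(spec)
    aas = sorted(FAMILIES)
    aa_weights = np.array([len(FAMILIES[a]) for a in aas], dtype=float)
    aa_weights /= aa_weights.sum()

    igs_ssrs = [(m, c) for m, c, r in spec.planted_ssrs if r == "IGS"]
    intron_ssrs = [(m, c) for m, c, r in spec.planted_ssrs if r == "intron"]
    cds_ssrs = [(m, c) for m, c, r in spec.planted_ssrs if r == "CDS"]
    if len(intron_ssrs) + len(cds_ssrs) > spec.n_genes:
        raise SpecError("more CDS/intron SSRs than genes to host them")

    def sample_codons(n: int) -> str:
        out = []
        for _ in range(n):
            aa = aas[rng.choice(len(aas), p=aa_weights)]
            codons = FAMILIES[aa]
            out.append(codons[rng.choice(len(codons), p=dists[aa])])
        return "".join(out)

    # --- design genes -----------------------------------------------------
    gene_plans = []  # dicts: name, strand, intron_ssr, cds_ssr
    for i in range(spec.n_genes):
        gene_plans.append(
            {
                "name": f"gene{i + 1:03d}",
                "strand": -1 if rng.random() < spec.minus_strand_fraction else 1,
                "intron_ssr": intron_ssrs[i] if i < len(intron_ssrs) else None,
                "cds_ssr": (
                    cds_ssrs[i - len(intron_ssrs)]
                    if len(intron_ssrs) <= i < len(intron_ssrs) + len(cds_ssrs)
                    else None
                ),
            }
        )

    def build_gene_cds(plan) -> str:
        """Biological coding sequence (ATG ... stop-free body + TAA)."""
        body_codons = spec.gene_length_codons - 2  # minus start + stop
        if plan["cds_ssr"]:
            motif, copies = plan["cds_ssr"]
            block, rep_off = _ssr_cds_block(motif, copies)
            n_block = len(block) // 3
            if n_block + 4 > body_codons:
                raise SpecError(f"gene too short to host CDS SSR {motif!r}")
            left = sample_codons(2)
            if rep_off == 0:  # block starts with the repeat itself
                while left[-1] == motif[-1]:  # would extend the run leftward
                    left = sample_codons(2)
            right = sample_codons(body_codons - n_block - 2)
            if (len(block) - rep_off) == len(motif) * copies:  # no right pad
                while right[0] == motif[0]:  # would extend the run rightward
                    right = sample_codons(body_codons - n_block - 2)
            body = left + block + right
            plan["cds_ssr_offset"] = 3 + len(left) + rep_off  # nt offset in cds
        else:
            body = sample_codons(body_codons)
        return "ATG" + body + "TAA"

    # --- assemble LSC as segments ----------------------------------------
    segments: list[_Segment] = []

    def add_filler(length: int, context: str):
        w = _FillerWriter(rng, at, context)
        segments.append(_Segment("filler", w.emit(length)))

    def current_tail() -> str:
        return "".join(s.text for s in segments)[-64:]

    # fixed content first, to size the fillers
    gene_blocks: list[list[_Segment]] = []
    fixed_len = 0
    for plan in gene_plans:
        cds = build_gene_cds(plan)
        while True:  # resample genes that contain an accidental repeat
            hits = scan_ssrs(cds if plan["strand"] == 1 else revcomp(cds))
            expected = 1 if plan["cds_ssr"] else 0
            if len(hits) == expected:
                break
            cds = build_gene_cds(plan)
        plan["cds"] = cds
        block: list[_Segment] = []
        genomic = cds if plan["strand"] == 1 else revcomp(cds)
        if plan["intron_ssr"]:
            motif, copies = plan["intron_ssr"]
            half = len(genomic) // 6 * 3
            exon1, exon2 = genomic[:half], genomic[half:]
            gl = _nonextending_guard(rng, motif, "left", at)
            gr = _nonextending_guard(rng, motif, "right", at)
            pad = max(spec.intron_len - 2 * _GUARD_LEN - len(motif) * copies, 0)
            wpad = _FillerWriter(rng, at).emit(pad)
            block.append(_Segment("gene_part", exon1, {"plan": plan, "part": 0}))
            block.append(_Segment("guard", gl))
            block.append(
                _Segment("ssr", motif * copies, {"motif": motif, "copies": copies, "region": "intron"})
            )
            block.append(_Segment("guard", gr + wpad))
            block.append(_Segment("gene_part", exon2, {"plan": plan, "part": 1}))
        else:
            block.append(_Segment("gene_part", genomic, {"plan": plan, "part": 0}))
        gene_blocks.append(block)
        fixed_len += sum(len(s.text) for s in block)

    igs_blocks: list[list[_Segment]] = []
    for motif, copies in igs_ssrs:
        gl = _nonextending_guard(rng, motif, "left", at)
        gr = _nonextending_guard(rng, motif, "right", at)
        blk = [
            _Segment("guard", gl),
            _Segment("ssr", motif * copies, {"motif": motif, "copies": copies, "region": "IGS"}),
            _Segment("guard", gr),
        ]
        igs_blocks.append(blk)
        fixed_len += sum(len(s.text) for s in blk)

    n_slots = spec.n_genes + len(igs_blocks) + 1  # filler slots between blocks
    free = spec.lsc_len - fixed_len
    if free < n_slots * 20:
        raise SpecError(
            f"LSC too small: {free} bp of filler for {n_slots} slots (need >= {n_slots * 20})"
        )
    base_fill = free // n_slots
    extra = free - base_fill * n_slots

    blocks = []
    order = gene_blocks + igs_blocks
    # interleave IGS-SSR blocks between gene blocks deterministically
    if igs_blocks:
        order = []
        gi, si = 0, 0
        step = max(len(gene_blocks) // (len(igs_blocks) + 1), 1)
        for idx, gb in enumerate(gene_blocks):
            order.append(gb)
            if si < len(igs_blocks) and (idx + 1) % step == 0:
                order.append(igs_blocks[si])
                si += 1
        while si < len(igs_blocks):
            order.append(igs_blocks[si])
            si += 1

    for i, block in enumerate(order):
        fill = base_fill + (1 if i < extra else 0)
        add_filler(fill, current_tail())
        segments.extend(block)
    add_filler(spec.lsc_len - sum(len(s.text) for s in segments), current_tail())
    lsc_seq = "".join(s.text for s in segments)
    assert len(lsc_seq) == spec.lsc_len

    # --- IRb, SSC ---------------------------------------------------------
    irb_seq = _FillerWriter(rng, at, lsc_seq[-64:]).emit(spec.ir_len)
    ssc_seq = _FillerWriter(rng, at, irb_seq[-64:]).emit(spec.ssc_len)
    ira_seq = revcomp(irb_seq)

    # junction guards: keep the IR pair non-extendable on either side
    n = spec.lsc_len + 2 * spec.ir_len + spec.ssc_len
    if lsc_seq[-1] == revcomp(lsc_seq[0]):
        repl = next(b for b in _BASES if b != lsc_seq[-1] and b != revcomp(lsc_seq[0]))
        lsc_seq = lsc_seq[:-1] + repl
        segments[-1].text = segments[-1].text[:-1] + repl
    if ssc_seq[0] == revcomp(ssc_seq[-1]):
        repl = next(b for b in _BASES if b != ssc_seq[0] and b != revcomp(ssc_seq[-1]))
        ssc_seq = repl + ssc_seq[1:]

    sequence = lsc_seq + irb_seq + ssc_seq + ira_seq
    assert len(sequence) == n

    # --- coordinates and truth -------------------------------------------
    truth = TruthTable(
        spec=spec,
        lsc=(1, spec.lsc_len),
        irb=(spec.lsc_len + 1, spec.lsc_len + spec.ir_len),
        ssc=(spec.lsc_len + spec.ir_len + 1, spec.lsc_len + spec.ir_len + spec.ssc_len),
        ira=(spec.lsc_len + spec.ir_len + spec.ssc_len + 1, n),
    )

    features: list[GeneFeature] = []
    pos = 1
    gene_parts: dict[str, list[tuple[int, int, int]]] = {}
    for seg in segments:
        seg_start, seg_end = pos, pos + len(seg.text) - 1
        if seg.kind == "gene_part":
            plan = seg.meta["plan"]
            gene_parts.setdefault(plan["name"], []).append(
                (seg_start, seg_end, plan["strand"])
            )
        elif seg.kind == "ssr":
            truth.ssrs.append(
                SSRLocus(
                    motif=seg.meta["motif"],
                    copies=seg.meta["copies"],
                    start=seg_start,
                    end=seg_end,
                    genome=spec.genome_id,
                    region=seg.meta["region"],
                )
            )
        pos = seg_end + 1

    for plan in gene_plans:
        parts = tuple(sorted(gene_parts[plan["name"]]))
        features.append(GeneFeature(gene_name=plan["name"], kind="CDS", parts=parts))
        truth.genes.append(
            {
                "name": plan["name"],
                "strand": plan["strand"],
                "parts": parts,
                "cds": plan["cds"],
            }
        )
        if plan["cds_ssr"]:
            motif, copies = plan["cds_ssr"]
            off = plan["cds_ssr_offset"]
            if plan["strand"] == 1:
                s = parts[0][0] + off
            else:  # repeat sits in the reverse-complement strand copy
                s_end = parts[-1][1] - off
                s = s_end - len(motif) * copies + 1
                motif = revcomp(motif)
                # reported motif is the leftmost phase on the plus strand
                copies_span = copies * len(motif)
                seg_text = sequence[s - 1 : s - 1 + copies_span]
                motif = seg_text[: len(motif)]
            truth.ssrs.append(
                SSRLocus(
                    motif=motif,
                    copies=copies,
                    start=s,
                    end=s + len(motif) * copies - 1,
                    genome=spec.genome_id,
                    region="CDS",
                )
            )

    genome = PlastidGenome(
        id=spec.genome_id,
        species=spec.species,
        sequence=sequence,
        circular=True,
        features=features,
    )

    # --- final verification ----------------------------------------------
    truth.ssrs.sort(key=lambda l: (l.start, l.unit))
    found = scan_ssrs(genome)
    expected = {(l.motif, l.copies, l.start, l.end) for l in truth.ssrs}
    got = {(l.motif, l.copies, l.start, l.end) for l in found}
    if expected != got:
        raise _TruthMismatch(
            f"missing {expected - got}, extra {got - expected}"
        )
    truth.validate(genome)
    return genome, truth


def to_genbank(genome: PlastidGenome, path: str | Path) -> None:
    """Write a PlastidGenome as a GenBank flat file."""
    record = SeqRecord(
        Seq(genome.sequence),
        id=genome.id,
        name=genome.id[:16],
        description=genome.species,
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if genome.circular else "linear",
            "organism": genome.species,
        },
    )
    for feat in genome.features:
        locs = [
            FeatureLocation(s - 1, e, strand=st) for s, e, st in feat.parts
        ]
        location = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        qualifiers = {"gene": [feat.gene_name]}
        if feat.product:
            qualifiers["product"] = [feat.product]
        record.features.append(
            SeqFeature(location, type=feat.kind, qualifiers=qualifiers)
        )
    SeqIO.write(record, str(path), "genbank")


# ---------------------------------------------------------------------------
# homolog-pair simulation


def make_homolog_pair(
    cds: str,
    t: float,
    omega: float,
    seed: int,
) -> tuple[CodonAlignmentPair, dict]:
    """Diverge a coding sequence under a prescribed Ka/Ks.

    Single-nucleotide mutations are proposed as a Poisson process with
    expectation *t* proposals per codon; acceptance odds are 1 : *omega*
    for synonymous : nonsynonymous proposals (for omega <= 1 every
    synonymous proposal is accepted, for omega > 1 every nonsynonymous
    one), and proposals creating a stop codon are always rejected.
    Returns the aligned pair plus the realized truth (accepted
    synonymous / nonsynonymous counts).
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if omega <= 0:
        raise ValueError("omega must be > 0")
    rng = np.random.default_rng(seed)
    seq = cds.upper()
    if len(seq) % 3:
        raise ValueError("cds length must be a multiple of 3")
    cods = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if cods and cods[-1] in STOP_CODONS:
        cods = cods[:-1]
    if any(c in STOP_CODONS or "N" in c for c in cods):
        raise ValueError("cds must be stop-free and unambiguous")
    n_codons = len(cods)

    derived = list(cods)
    n_events = rng.poisson(t * n_codons)
    syn_accepted = nonsyn_accepted = 0
    for _ in range(n_events):
        site = int(rng.integers(0, 3 * n_codons))
        ci, pos = divmod(site, 3)
        codon = derived[ci]
        old = codon[pos]
        alternatives = [b for b in _BASES if b != old]
        new = alternatives[int(rng.integers(0, 3))]
        candidate = codon[:pos] + new + codon[pos + 1 :]
        if candidate in STOP_CODONS:
            continue
        # acceptance odds syn : nonsyn are 1 : omega for any omega > 0
        if CODON_TO_AA[candidate] == CODON_TO_AA[codon]:
            if rng.random() < min(1.0, 1.0 / omega):
                derived[ci] = candidate
                syn_accepted += 1
        elif rng.random() < min(1.0, omega):
            derived[ci] = candidate
            nonsyn_accepted += 1

    ancestral = "".join(cods)
    evolved = "".join(derived)
    pair = make_pair("simulated", ancestral, evolved, "ancestor", "derived")
    truth = {
        "n_codons": n_codons,
        "proposals": int(n_events),
        "syn_accepted": syn_accepted,
        "nonsyn_accepted": nonsyn_accepted,
        "omega": omega,
        "t": t,
    }
    return pair, truth
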