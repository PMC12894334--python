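"""Parsing, CDS splicing, region labelling, and IR detection."""

import numpy as np
import pytest

from plastocodon.genetics import revcomp
from plastocodon.plastome_io import (
    GeneFeature,
    NoInvertedRepeatError,
    PlastidGenome,
    classify_regions,
    detect_quadripartite,
    extract_cds,
    parse_fasta_gff3,
    parse_genbank,
    splice,
)
from plastocodon.simulate import to_genbank


def _write_genbank(tmp_path, name, length, seq, feature_lines):
    """Handwritten minimal GenBank flat file."""
    lines = [
        f"LOCUS       {name}{str(length).rjust(28 - len(name))} bp    DNA     circular PLN 01-JAN-2024",
        f"DEFINITION  test record {name}.",
        f"ACCESSION   {name}",
        f"VERSION     {name}.1",
        "FEATURES             Location/Qualifiers",
    ]
    lines += feature_lines
    lines.append("ORIGIN")
    for i in range(0, len(seq), 60):
        chunk = seq[i : i + 60].lower()
        blocks = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
        lines.append(f"{i + 1:>9} {blocks}")
    lines.append("//")
    path = tmp_path / f"{name}.gb"
    path.write_text("\n".join(lines) + "\n")
    return path


def test_parse_minimal_record_with_one_cds(tmp_path):
    seq = "ATGTAAGGCCGGCCGGCCAAATTTCCCGGG"
    path = _write_genbank(
        tmp_path,
        "MINI",
        len(seq),
        seq,
        ["     CDS             1..6", '                     /gene="tiny"'],
    )
    g = parse_genbank(path)
    assert g.sequence == seq
    assert len(g) == len(seq)
    cds = [f for f in g.features if f.kind == "CDS"]
    assert len(cds) == 1
    assert cds[0].gene_name == "tiny"
    assert cds[0].parts == ((1, 6, 1),)


def test_origin_wrapping_join_splices_to_manual_concatenation(tmp_path):
    # CDS = last 3 bases + first 3 bases of the circle
    seq = "ATGCCCGGGTTTAAACCCGGGTTTAAATAA"
    path = _write_genbank(
        tmp_path,
        "WRAP",
        len(seq),
        seq,
        [
            "     CDS             join(28..30,1..3)",
            '                     /gene="wrap"',
        ],
    )
    g = parse_genbank(path)
    feat = next(f for f in g.features if f.gene_name == "wrap")
    assert len(feat.parts) == 2
    # oracle: manual splice of the two intervals
    assert splice(g, feat) == seq[27:30] + seq[0:3]


def test_minus_strand_splice_is_reverse_complement(tmp_path):
    seq = "TTACATAACATGGGCCCGGGCCCGGGCCC"
    path = _write_genbank(
        tmp_path,
        "MINUS",
        len(seq),
        seq,
        [
            "     CDS             complement(1..9)",
            '                     /gene="neg"',
        ],
    )
    g = parse_genbank(path)
    feat = next(f for f in g.features if f.gene_name == "neg")
    assert splice(g, feat) == revcomp(seq[0:9])  # hand oracle


def test_extract_cds_flags_bad_frames_and_internal_stops():
    g = PlastidGenome(
        id="x",
        species="x",
        sequence="ATGTTATAA" + "ATGTT" + "ATGTAATTGTAA" + "C" * 10,
        features=[
            GeneFeature("good", "CDS", ((1, 9, 1),)),
            GeneFeature("badframe", "CDS", ((10, 14, 1),)),
            GeneFeature("internalstop", "CDS", ((15, 26, 1),)),
        ],
    )
    clean = extract_cds(g)
    assert [c.gene_name for c in clean] == ["good"]
    assert clean[0].sequence == "ATGTTATAA"
    flagged = {c.gene_name: c.flag for c in extract_cds(g, drop_flagged=False)}
    assert flagged["badframe"] == "length_not_multiple_of_3"
    assert flagged["internalstop"] == "internal_stop"


def test_extract_cds_matches_truth_on_synthetic_genome(small_genome):
    genome, truth = small_genome
    by_name = {c.gene_name: c.sequence for c in extract_cds(genome)}
    for gene in truth.genes:
        assert by_name[gene["name"]] == gene["cds"]


def test_extract_cds_invariant_under_genome_reverse_complement(small_genome):
    genome, _ = small_genome
    n = len(genome)
    mirrored = PlastidGenome(
        id=genome.id,
        species=genome.species,
        sequence=revcomp(genome.sequence),
        features=[
            GeneFeature(
                f.gene_name,
                f.kind,
                tuple(sorted((n - e + 1, n - s + 1, -st) for s, e, st in f.parts)),
            )
            for f in genome.features
        ],
    )
    a = sorted((c.gene_name, c.sequence) for c in extract_cds(genome))
    b = sorted((c.gene_name, c.sequence) for c in extract_cds(mirrored))
    assert a == b


class TestClassifyRegions:
    def test_single_cds_splits_cds_and_igs(self):
        g = PlastidGenome(
            id="x", species="x", sequence="A" * 1000,
            features=[GeneFeature("g", "CDS", ((1, 300, 1),))],
        )
        counts = classify_regions(g).counts()
        assert counts == {"IGS": 700, "intron": 0, "CDS": 300}

    def test_gap_between_parts_is_intron(self):
        g = PlastidGenome(
            id="x", species="x", sequence="A" * 300,
            features=[GeneFeature("g", "CDS", ((1, 100, 1), (201, 300, 1)))],
        )
        ann = classify_regions(g)
        assert ann.label_at(150) == "intron"
        assert ann.counts() == {"IGS": 0, "intron": 100, "CDS": 200}

    def test_precedence_against_per_base_oracle(self, rng):
        n = 500
        feats = [
            GeneFeature("cds1", "CDS", ((50, 150, 1),)),
            GeneFeature("trna1", "tRNA", ((100, 130, 1), (160, 200, 1))),
            GeneFeature("cds2", "CDS", ((180, 280, -1), (340, 400, -1))),
        ]
        g = PlastidGenome(id="x", species="x", sequence="A" * n, features=feats)
        ann = classify_regions(g)
        # brute-force per-base labeler
        for pos in range(1, n + 1):
            in_cds = any(
                f.kind == "CDS" and any(s <= pos <= e for s, e, _ in f.parts)
                for f in feats
            )
            in_gap = any(
                len(f.parts) > 1
                and min(p[0] for p in f.parts) <= pos <= max(p[1] for p in f.parts)
                and not any(s <= pos <= e for s, e, _ in f.parts)
                for f in feats
            )
            expected = "CDS" if in_cds else ("intron" if in_gap else "IGS")
            assert ann.label_at(pos) == expected, pos

    def test_labels_partition_genome(self, small_genome):
        genome, _ = small_genome
        counts = classify_regions(genome).counts()
        assert sum(counts.values()) == len(genome)


class TestDetectQuadripartite:
    def test_recovers_planted_lengths_exactly(self, small_genome):
        genome, truth = small_genome
        st = detect_quadripartite(genome, min_ir=2000)
        assert (st.lsc_length, st.ssc_length, st.ir_length) == (
            truth.spec.lsc_len,
            truth.spec.ssc_len,
            truth.spec.ir_len,
        )
        assert st.irb == truth.irb and st.ira == truth.ira
        assert st.lsc_length + st.ssc_length + 2 * st.ir_length == len(genome)
        assert st.lsc_length >= st.ssc_length

    def test_no_ir_raises_structured_error(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=50_000))
        g = PlastidGenome(id="r", species="r", sequence=seq)
        with pytest.raises(NoInvertedRepeatError):
            detect_quadripartite(g, min_ir=2000)

    @pytest.mark.parametrize("rotation", [500, 4000, 8000])
    def test_rotation_within_lsc_preserves_region_lengths(self, small_genome, rotation):
        genome, truth = small_genome
        s = genome.sequence
        rotated = PlastidGenome(
            id="rot", species="rot", sequence=s[rotation:] + s[:rotation]
        )
        st = detect_quadripartite(rotated, min_ir=2000)
        assert (st.lsc_length, st.ssc_length, st.ir_length) == (
            truth.spec.lsc_len,
            truth.spec.ssc_len,
            truth.spec.ir_len,
        )

    def test_reverse_complement_preserves_region_lengths(self, small_genome):
        genome, truth = small_genome
        rc = PlastidGenome(id="rc", species="rc", sequence=revcomp(genome.sequence))
        st = detect_quadripartite(rc, min_ir=2000)
        assert (st.lsc_length, st.ssc_length, st.ir_length) == (
            truth.spec.lsc_len,
            truth.spec.ssc_len,
            truth.spec.ir_len,
        )


def test_fasta_gff3_agrees_with_genbank(tmp_path, small_genome):
    genome, _ = small_genome
    gb = tmp_path / "syn.gb"
    to_genbank(genome, gb)
    fasta = tmp_path / "syn.fasta"
    fasta.write_text(f">{genome.id} {genome.species}\n{genome.sequence}\n")
    rows = ["##gff-version 3"]
    for i, f in enumerate(genome.features):
        for s, e, st in f.parts:
            strand = "+" if st == 1 else "-"
            rows.append(
                f"{genome.id}\tsyn\t{f.kind}\t{s}\t{e}\t.\t{strand}\t0\t"
                f"ID=f{i};gene={f.gene_name}"
            )
    (tmp_path / "syn.gff3").write_text("\n".join(rows) + "\n")

    from_gb = parse_genbank(gb)
    from_gff = parse_fasta_gff3(fasta, tmp_path / "syn.gff3")
    assert from_gff.sequence == from_gb.sequence
    assert sorted((f.gene_name, f.kind, f.parts) for f in from_gff.features) == sorted(
        (f.gene_name, f.kind, f.parts) for f in from_gb.features
    )
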