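"""SSR scanner vs brute force, thresholds, regions, presence matrix."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plastocodon.genetics import is_primitive, revcomp
from plastocodon.ssr import (
    DEFAULT_THRESHOLDS,
    classify_ssr_regions,
    motif_conservation,
    scan_ssrs,
    ssr_presence_matrix,
)


def brute_force_ssrs(seq, thresholds=DEFAULT_THRESHOLDS):
    """Exhaustive O(n^2 * 6) reference scanner (independent oracle)."""
    n = len(seq)
    found = {}
    for k, thr in thresholds.items():
        for start in range(n - 2 * k + 1):
            motif = seq[start : start + k]
            if "N" in motif or not is_primitive(motif):
                continue
            # maximal on the left: the lag-k agreement must not extend back
            if start > 0 and seq[start - 1] == seq[start - 1 + k] and seq[start - 1] != "N":
                continue
            copies = 1
            while seq[start + copies * k : start + (copies + 1) * k] == motif:
                copies += 1
            if copies < thr:
                continue
            span = (start + 1, start + copies * k)
            if span not in found or k < found[span][0]:
                found[span] = (k, motif, copies)
    return {
        (motif, copies, s, e) for (s, e), (k, motif, copies) in found.items()
    }


def as_set(loci):
    return {(l.motif, l.copies, l.start, l.end) for l in loci}


class TestThresholdEdges:
    def test_mono_at_and_below_threshold(self):
        flank = "GCGTACGGTC"
        assert as_set(scan_ssrs(flank + "A" * 10 + flank)) == {("A", 10, 11, 20)}
        assert scan_ssrs(flank + "A" * 9 + flank) == []

    def test_di_at_and_below_threshold(self):
        flank = "GCGCGTACGG"  # careful: no AT phase continuation
        assert scan_ssrs("CCGGC" + "AT" * 4 + "CCGGC") == []
        loci = scan_ssrs("CCGGC" + "AT" * 5 + "CCGGC")
        assert as_set(loci) == {("AT", 5, 6, 15)}

    def test_partial_trailing_unit_not_counted(self):
        loci = scan_ssrs("CCGGC" + "AAT" * 4 + "AA" + "GGCCG")
        [l] = loci
        assert (l.motif, l.copies) == ("AAT", 4)
        assert l.end - l.start + 1 == 12

    def test_non_primitive_motifs_suppressed(self):
        loci = scan_ssrs("CCGGC" + "A" * 12 + "GGCCG")
        assert len(loci) == 1 and loci[0].motif == "A"

    def test_n_breaks_repeats(self):
        assert scan_ssrs("CG" + "A" * 6 + "N" + "A" * 6 + "GC") == []


class TestOracleEquivalence:
    def test_planted_fixture_matches_truth_and_oracle(self, small_genome):
        genome, truth = small_genome
        loci = scan_ssrs(genome)
        assert as_set(loci) == as_set(truth.ssrs)
        assert as_set(loci) == brute_force_ssrs(genome.sequence)

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_random_sequences_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        # AT-rich composition makes repeats frequent
        seq = "".join(rng.choice(list("ACGT"), size=2000, p=[0.35, 0.15, 0.15, 0.35]))
        assert as_set(scan_ssrs(seq)) == brute_force_ssrs(seq)

    def test_reported_loci_satisfy_invariants(self, small_genome):
        genome, _ = small_genome
        for l in scan_ssrs(genome):
            assert is_primitive(l.motif)
            assert l.copies >= DEFAULT_THRESHOLDS[l.unit]
            assert l.end - l.start + 1 == l.copies * l.unit
            assert genome.slice(l.start, l.end) == l.motif * l.copies

    def test_reverse_complement_preserves_category_counts(self, small_genome):
        genome, _ = small_genome
        fwd = scan_ssrs(genome.sequence)
        rev = scan_ssrs(revcomp(genome.sequence))
        count = lambda loci: sorted((l.unit, l.copies) for l in loci)
        assert count(fwd) == count(rev)


class TestRegions:
    def test_midpoint_rule_and_density_truth(self, small_genome):
        genome, truth = small_genome
        from plastocodon.plastome_io import classify_regions

        ann = classify_regions(genome)
        labeled, density = classify_ssr_regions(scan_ssrs(genome), ann)
        got = {(l.motif, l.start): l.region for l in labeled}
        for planted in truth.ssrs:
            assert got[(planted.motif, planted.start)] == planted.region
        assert density["percent"].sum() == pytest.approx(100.0)
        expected_counts = {"CDS": 0, "intron": 0, "IGS": 0}
        for planted in truth.ssrs:
            expected_counts[planted.region] += 1
        table = dict(zip(density["region"], density["n_loci"]))
        assert table == expected_counts

    def test_locus_straddling_boundary_uses_midpoint(self):
        from plastocodon.plastome_io import GeneFeature, PlastidGenome, classify_regions

        seq = "GCGTC" + "A" * 10 + "GCGCGTTGCC" * 10
        g = PlastidGenome(
            id="x", species="x", sequence=seq,
            features=[GeneFeature("g", "CDS", ((1, 8, 1),))],
        )
        [locus] = scan_ssrs(g)
        labeled, _ = classify_ssr_regions([locus], classify_regions(g))
        # midpoint of 6..15 is 10 -> outside the CDS (1..8) -> IGS
        assert labeled[0].region == "IGS"


class TestPresenceMatrix:
    def test_single_genome(self):
        loci = scan_ssrs("GCGTC" + "A" * 10 + "CCGTG" + "AT" * 5 + "GGCTC", genome_id="g1")
        m = ssr_presence_matrix(loci)
        assert m.shape == (2, 1)
        assert set(m.index) == {"A", "AT"}
        assert (m.values == 1).all()

    def test_conservation_across_genomes(self):
        s_shared = "GCGTC" + "A" * 10 + "GCGTC"
        s_private = "GCGTC" + "A" * 10 + "CCGTG" + "AATAT" * 3 + "GGCTC"
        loci = scan_ssrs(s_shared, genome_id="g1") + scan_ssrs(s_private, genome_id="g2")
        m = ssr_presence_matrix(loci)
        cons = motif_conservation(m)
        assert cons["A"] == 100.0
        assert cons[min(("AATAT"[i:] + "AATAT"[:i]) for i in range(5))] == 50.0

    def test_planted_design_across_genomes(self):
        from plastocodon.simulate import SyntheticGenomeSpec, make_plastome

        shared = ("AAG", 5, "IGS")
        loci = []
        privates = [("AACC", 4, "IGS"), ("AGGAT", 3, "IGS"), ("ACGTC", 3, "IGS")]
        for i in range(3):
            spec = SyntheticGenomeSpec(
                seed=100 + i, lsc_len=4000, ssc_len=800, ir_len=1000,
                n_genes=3, gene_length_codons=80,
                planted_ssrs=[shared, privates[i]],
                genome_id=f"g{i}",
            )
            genome, _ = make_plastome(spec)
            loci.extend(scan_ssrs(genome))
        m = ssr_presence_matrix(loci)
        cons = motif_conservation(m)
        assert cons["AAG"] == 100.0
        for motif, _, _ in privates:
            canon = min(motif[i:] + motif[:i] for i in range(len(motif)))
            assert cons[canon] == pytest.approx(100 / 3)
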