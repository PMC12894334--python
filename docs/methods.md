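# Methods

This note records the models, conventions, and numerical choices behind
each analysis stage, what the synthetic-data generator does and does not
emulate, and the design decisions taken where more than one defensible
convention exists.

## Genetic code and coordinates

All codon statistics use the plant-plastid genetic code (NCBI translation
table 11), whose sense-codon→amino-acid map matches the standard code:
9 two-fold families, isoleucine as the single three-fold family, 5
four-fold families, and leucine/serine/arginine as six-fold families.
Six-fold families are treated as single families (the CodonW convention),
not split 2+4. Codons containing N are excluded from every count; stop
codons are tracked separately and never enter `n_codons`. The 59
"informative" codons are the 61 sense codons minus AUG and UGG, whose
single-codon families carry no synonymous choice.

Coordinates are 1-based inclusive (GenBank convention) everywhere inside
the library; the only conversion is the 0-based half-open BED export.

## Quadripartite structure

`detect_quadripartite` indexes every k-mer (default k = 25) of the
sequence, streams the k-mers of the reverse complement, groups hits by
diagonal, merges contiguous runs, and extends each run to a maximal
mismatch-free match. The longest pair of disjoint, exactly
reverse-complementary segments of length ≥ `min_ir` (default 10 kb)
becomes IRb/IRa; the larger single-copy arc is the LSC. When no such pair
exists the genome is reported as non-quadripartite via a structured
error, never guessed.

Choices and limits:

* IR identity is exact. Real IR pairs occasionally differ by a few
  single-nucleotide variants; a mismatch-tolerant mode is future work.
* The scan is linear in the input orientation. Region *lengths* are
  invariant under rotation provided the rotation point does not fall
  inside an IR copy (the tests rotate within the LSC); full circular
  anchoring was not needed for genomes deposited in the conventional
  LSC-first orientation.
* Plastomes occur as two SSC-orientation isomers; the structure is
  reported in input orientation with no canonical flipping.

## CDS extraction and region labels

`join()`/`complement()` locations are resolved into ordered parts;
minus-strand parts are reverse-complemented, and an all-minus multi-part
feature is spliced in 3'→5' genomic order, matching
`complement(join(...))` semantics. Sequences whose spliced length is not
a multiple of 3, or that contain an internal stop, are flagged and
excluded from codon statistics but surfaced in a QC table — never
silently dropped.

Every base is labelled CDS if covered by any CDS part, else intron if it
lies in an inter-part gap of a multi-part gene, else intergenic spacer,
with precedence CDS > intron > IGS on overlap. The three labels always
partition the genome exactly.

Gene counts are reported as annotated, including IR duplicates; published
per-accession totals vary by annotation convention, so counts are
reported but never asserted as invariants.

## Codon-usage statistics

RSCU(c) = count(c)/(T/k) for a codon in a k-fold family with family total
T > 0; families with T = 0 are *missing*, not zero — the distinction
matters when averaging profiles. In full tables AUG and UGG are reported
as exactly 1; the 59-dimensional analysis vector excludes them (missing
families are filled with 0 only when a dense matrix is required, e.g. for
correspondence analysis).

ENC uses F = (n·Σp²−1)/(n−1) per family with n ≥ 2 observations, class
means over the observed families of each degeneracy, and
ENC = 2 + 9/F₂ + 1/F₃ + 5/F₄ + 3/F₆ clamped to [20, 61]. When isoleucine
is unobserved, F₃ is imputed as (F₂+F₄)/2 (Wright's prescription; the
imputation is flagged on the result). If any class mean is missing or
non-positive the ENC is undefined (NaN) rather than extrapolated.

GC3s is the G+C fraction at third positions of codons whose family has
at least two synonyms (AUG, UGG, stops excluded); on a sequence of only
four-fold-family codons it equals GC3 exactly, which the tests assert.

Two forms of the expected-ENC curve are provided:
`standard` = 2 + s + 29/(s²+(1−s)²), and a `printed` variant without the
linear term that appears in some published figure captions. The default
is the standard form; at s = 0.5 they evaluate to 60.5 and 60.0.

Species-level statistics are computed on concatenated CDS per genome;
gene-level values feed the diagnostics. Both modes are exposed
(`enc_per="genome"|"gene"` in the pipeline) because published work is
often silent about which was used.

## Diagnostics

The neutrality fit is closed-form OLS (slope = cov/var) of GC12 on GC3;
fits require ≥ 3 genes and positive GC3 variance, otherwise a structured
"undefined" result is returned. PR2 tallies third-position bases over all
sense codons by default; a four-fold-only mode implements the classical
definition restricted to fully degenerate families. Zero denominators
yield missing ratios, never 0/0 artifacts.

Correspondence analysis is the classical chi-square-metric SVD: with
P = X/ΣX and marginals r, c, the matrix
S = D_r^{−1/2}(P − rcᵀ)D_c^{−1/2} is decomposed; principal coordinates
are D^{−1/2}·U·Σ (rows) and D^{−1/2}·V·Σ (columns); axis i explains
σ_i²/Σσ² of the inertia. All-zero rows are dropped with a record;
all-zero columns get zero coordinates; singular values below
max(m,n)·ε·max(1, σ₁) are treated as exact zeros, so a rank-one
(independence) matrix reports zero total inertia instead of noise. Axis
signs follow a fixed convention — the largest-magnitude column coordinate
on each axis is positive — so outputs are deterministic. COA runs on the
RSCU matrix (rows weighted by row sums as in standard CA); a count-based
alternative is available by passing raw counts. Pooled (all species'
genes in one matrix) and per-species modes are both supported; the
pooled mode is the default. Genes shorter than 30 codons are excluded
from the diagnostics by default to avoid degenerate ratios (threshold
configurable).

## SSR scanning

For each unit length k the sequence is compared with itself at lag k;
every maximal agreement run of total length T ≥ 2k yields a candidate
with copies = ⌊T/k⌋ and the leftmost phase as the motif. Motifs must be
primitive (not a power of a shorter string), partial trailing units never
count toward copies, N breaks any run, and duplicate spans keep the
smallest unit. Default thresholds are {1:10, 2:5, 3:4, 4:3, 5:3, 6:3}
copies and fully configurable. The scanner is validated against an
exhaustive O(n²·6) brute-force oracle on random and planted fixtures.

Loci are assigned to CDS/intron/IGS by the region containing their
midpoint — a documented rule, since densities are not reproducible
without one. Motifs are canonicalized by minimal rotation and are *not*
merged with reverse complements by default (an optional strand-merging
canonicalization exists), matching how published motif heatmaps list
plain motifs. Compound/interrupted repeats are out of scope: only perfect
repeats are modelled.

## Ka/Ks (NG86)

Synonymous sites per codon are Σ over positions of (synonymous changes) /
(changes to sense codons) — mutations to stops are ignored in site
counting, the original counting convention. Site totals are averaged over
the two sequences and satisfy S + N = 3·codons exactly. Observed
differences are averaged with equal weights over all d! minimal pathways,
excluding pathways through stop codons (falling back to all pathways,
stop steps counted nonsynonymous, in the rare case every pathway is
blocked). Proportions are Jukes–Cantor corrected; p ≥ 3/4 makes the
correction undefined and the result is reported as undefined rather than
clamped. ω is undefined when Ks = 0; undefined results are excluded from
category percentages and tallied separately. Category thresholds are
exactly 0.5 and 1.0.

NG86 was chosen as the fully specifiable baseline estimator; model-mixed
estimators (γ-series, model averaging) are out of scope, and an ω > 1
call is a signal of relaxed constraint or possible positive selection,
not proof of adaptive evolution.

Homologs are paired by identical gene name across genomes, either all
pairs per gene or all-vs-reference. Codon alignment is positional and
only equal-length CDS pairs are formed; columns containing gaps, N, or a
stop in either sequence are removed with a count.

## Synthetic data

The generator emulates the features each stage consumes: a circular
~10–160 kb genome assembled as LSC + IRb + SSC + IRa with IRa an exact
reverse complement of IRb; plus- and minus-strand genes (default 30%
minus) drawn codon-by-codon from per-family probability vectors or a GC3
target (within-family weight g for G/C-ending codons, 1−g otherwise);
introns; and planted SSRs in CDS, intron, or IGS. Intergenic filler is
sampled base-by-base under an online constraint that forbids any lag-k
agreement run long enough to complete a reportable repeat, planted
repeats get phase-breaking guard bases on both sides, and a final
full-genome scan asserts that the scanner output equals the planted
truth exactly (re-trying on a derived substream in the rare case a
junction completes an unplanned repeat — still a pure function of the
seed, so output is byte-identical across reruns).

Defaults follow the scale of real plastome studies: intergenic AT
fraction 0.7 (plastomes are AT-rich, ~62% AT overall), genes of 250
codons, IRs of tens of kilobases at full scale. Tests and the acceptance
script use a scaled-down genome (LSC 9 kb, SSC 1.6 kb, IR 2.5 kb, 8 genes
of 120 codons) — the same construction at a size where the exhaustive
SSR oracle and repeated simulation remain cheap.

What the generator does **not** emulate: IR expansion/contraction and
gene-order evolution, indels and alignment uncertainty, near-identical
(SNV-bearing) IRs, compound SSRs, sequencing error, and real codon-usage
covariance structure across genes. Passing tests therefore demonstrate
algorithmic correctness on clean inputs with known truth, not robustness
to annotation noise in real accessions.

Homolog pairs are diverged by proposing Poisson(t·codons) single-base
mutations (t = expected proposals per codon) with acceptance odds
1 : ω for synonymous : nonsynonymous proposals — for ω ≤ 1 every
synonymous proposal is accepted, for ω > 1 every nonsynonymous one — and
stop-creating proposals always rejected, so the instantaneous
nonsynonymous/synonymous rate ratio equals ω for any ω > 0. Realized
accepted counts are recorded as truth.

## Reproducibility and problem sizes

One integer seed drives a single `numpy.random.Generator` stream per
operation; all stochastic functions take the stream or seed explicitly.
The acceptance script exercises: 100 random 2 kb sequences plus a
12-locus planted genome for scanner/oracle equivalence; 10,000-codon
genes for the ENC/RSCU closed-form limits and RSCU recovery; a 4×5
matrix against a dense eigensolver for CA; 50 seeds × 500 codons per ω ∈
{0.2, 0.7, 1.0, 1.5} for NG86 recovery; 50 simulated species × 20 genes
for the null neutrality slope; and exact planted-structure recovery with
rotation/reverse-complement invariance. These sizes keep the whole run
in a few seconds while leaving Monte-Carlo standard errors well inside
the asserted 3σ bands.

Report tables round to 4 decimals (TSV `%.6g`); all test comparisons use
numeric tolerances, never string equality.
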