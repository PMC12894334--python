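"""Codon-usage statistics: counts, RSCU, positional GC, GC3s, and ENC.

All statistics run on frame-0 coding sequences under the plastid genetic
code. Codons containing N are excluded from every count; stop codons are
tracked but never enter n_codons. Statistics are available per gene and
per genome (concatenated CDS) — the per-genome convention is what the
species-level summaries use; gene-level values feed the diagnostic plots.

RSCU(c) for a codon c in a k-fold synonymous family with family total T
is count(c) / (T / k): 1 means no preference. Wright's effective number
of codons summarises bias on a 20 (one codon per amino acid) to 61
(uniform usage) scale from the family "homozygosities"

    F = (n * sum(p_i^2) - 1) / (n - 1),    ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6

averaged within each degeneracy class (9 two-fold families, Ile as the
single three-fold, 5 four-fold, 3 six-fold).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .genetics import (
    CODON_TO_AA,
    DEGENERACY,
    FAMILIES,
    INFORMATIVE_CODONS,
    STOP_CODONS,
    codons_of,
)

#: degeneracy class -> amino acids, fixed by translation table 11
DEGENERACY_CLASSES: dict[int, tuple[str, ...]] = {
    k: tuple(sorted(aa for aa, d in DEGENERACY.items() if d == k))
    for k in (2, 3, 4, 6)
}
# 9 two-fold, Ile alone three-fold, 5 four-fold, Leu/Ser/Arg six-fold
assert tuple(map(len, (DEGENERACY_CLASSES[k] for k in (2, 3, 4, 6)))) == (9, 1, 5, 3)

_GC = frozenset("GC")


@dataclass
class CodonCounts:
    """Sense-codon tallies for one gene or one genome."""

    counts: dict[str, int]
    stop_counts: dict[str, int] = field(default_factory=dict)
    source: str = ""

    @property
    def n_codons(self) -> int:
        return sum(self.counts.values())

    def family_total(self, aa: str) -> int:
        return sum(self.counts.get(c, 0) for c in FAMILIES[aa])

    def __add__(self, other: "CodonCounts") -> "CodonCounts":
        counts = dict(self.counts)
        for c, v in other.counts.items():
            counts[c] = counts.get(c, 0) + v
        stops = dict(self.stop_counts)
        for c, v in other.stop_counts.items():
            stops[c] = stops.get(c, 0) + v
        return CodonCounts(counts, stops, source=self.source or other.source)


@dataclass(frozen=True)
class RSCUProfile:
    """RSCU over the 59 informative codons (all sense codons minus the
    single-codon families AUG/Met and UGG/Trp).

    Families with zero observations are *missing*: their codons are absent
    from ``rscu`` and the amino acids listed in ``missing_families``.
    """

    rscu: dict[str, float]
    missing_families: frozenset[str]

    def to_vector(self, fill_missing: float = 0.0) -> np.ndarray:
        """59-vector in fixed codon order; missing families filled."""
        return np.array(
            [self.rscu.get(c, fill_missing) for c in INFORMATIVE_CODONS]
        )

    def full_table(self) -> pd.DataFrame:
        """All 61 sense codons (AUG and UGG reported as exactly 1)."""
        rows = []
        for codon in sorted(CODON_TO_AA):
            aa = CODON_TO_AA[codon]
            if DEGENERACY[aa] == 1:
                val: float = 1.0
            else:
                val = self.rscu.get(codon, math.nan)
            rows.append({"codon": codon, "amino_acid": aa, "rscu": val})
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class CompositionStats:
    gc: float
    gc1: float
    gc2: float
    gc3: float
    gc3s: float  # nan when no synonymously degenerate codon observed
    a3: int
    t3: int
    g3: int
    c3: int
    n_codons: int

    @property
    def gc12(self) -> float:
        return (self.gc1 + self.gc2) / 2.0


@dataclass(frozen=True)
class ENCStats:
    f2: float
    f3: float
    f4: float
    f6: float
    enc: float  # nan when undefined
    n_families_used: dict[int, int]
    f3_imputed: bool = False


def count_codons(cds: str, source: str = "") -> CodonCounts:
    """Tally frame-0 codons of a coding sequence.

    The terminal stop is tracked separately; codons containing N are
    skipped. An internal stop raises — such sequences must be filtered
    upstream (see ``plastome_io.extract_cds``).
    """
    cods = codons_of(cds.upper())
    counts: dict[str, int] = {}
    stops: dict[str, int] = {}
    for i, c in enumerate(cods):
        if "N" in c:
            continue
        if c in STOP_CODONS:
            if i != len(cods) - 1:
                raise ValueError(
                    f"{source or 'sequence'}: internal stop codon {c} at codon {i + 1}"
                )
            stops[c] = stops.get(c, 0) + 1
        else:
            counts[c] = counts.get(c, 0) + 1
    return CodonCounts(counts=counts, stop_counts=stops, source=source)


def concat_counts(counts: Iterable[CodonCounts], source: str = "") -> CodonCounts:
    """Pool several genes' counts (the per-genome concatenated-CDS mode)."""
    total = CodonCounts({}, {}, source=source)
    for c in counts:
        total = total + c
    total.source = source
    return total


def rscu(counts: CodonCounts) -> RSCUProfile:
    """Relative synonymous codon usage: observed / expected-under-equal-use.

    For codon c in a k-fold family with family total T > 0,
    RSCU(c) = count(c) / (T / k); families with T = 0 are missing.
    """
    values: dict[str, float] = {}
    missing = set()
    for aa, codons in FAMILIES.items():
        k = len(codons)
        if k == 1:
            continue
        total = sum(counts.counts.get(c, 0) for c in codons)
        if total == 0:
            missing.add(aa)
            continue
        expected = total / k
        for c in codons:
            values[c] = counts.counts.get(c, 0) / expected
    return RSCUProfile(rscu=values, missing_families=frozenset(missing))


def composition(counts_or_cds: Union[CodonCounts, str]) -> CompositionStats:
    """Overall and positional GC content plus third-position base tallies.

    gc1/gc2/gc3 are taken over all sense codons; gc3s over third positions
    of codons whose family has >= 2 synonyms (Met, Trp, stops excluded).
    """
    counts = (
        counts_or_cds
        if isinstance(counts_or_cds, CodonCounts)
        else count_codons(counts_or_cds)
    )
    n = counts.n_codons
    if n == 0:
        raise ValueError("composition undefined on empty codon counts")

    pos_gc = [0, 0, 0]
    third = {"A": 0, "C": 0, "G": 0, "T": 0}
    gc_total = 0
    syn3_gc = 0
    syn3_n = 0
    for codon, c in counts.counts.items():
        for i in range(3):
            if codon[i] in _GC:
                pos_gc[i] += c
                gc_total += c
        third[codon[2]] += c
        if DEGENERACY[CODON_TO_AA[codon]] >= 2:
            syn3_n += c
            if codon[2] in _GC:
                syn3_gc += c
    return CompositionStats(
        gc=gc_total / (3 * n),
        gc1=pos_gc[0] / n,
        gc2=pos_gc[1] / n,
        gc3=pos_gc[2] / n,
        gc3s=(syn3_gc / syn3_n) if syn3_n else math.nan,
        a3=third["A"],
        t3=third["T"],
        g3=third["G"],
        c3=third["C"],
        n_codons=n,
    )


def _family_homozygosity(counts: CodonCounts, aa: str) -> Optional[float]:
    """F = (n * sum p_i^2 - 1) / (n - 1) for one family, None if n < 2."""
    obs = [counts.counts.get(c, 0) for c in FAMILIES[aa]]
    n = sum(obs)
    if n < 2:
        return None
    sum_p2 = sum((x / n) ** 2 for x in obs)
    return (n * sum_p2 - 1.0) / (n - 1.0)


def enc(counts: CodonCounts) -> ENCStats:
    """Wright's effective number of codons from family homozygosities.

    F for each degeneracy class is the mean over families with >= 2
    observations. A missing three-fold class (Ile unobserved) is imputed
    as (F2 + F4)/2, Wright's prescription; if any required class mean is
    otherwise missing or non-positive the ENC is undefined (nan). The
    result is clamped to [20, 61].
    """
    class_means: dict[int, float] = {}
    n_used: dict[int, int] = {}
    for k, aas in DEGENERACY_CLASSES.items():
        fs = [f for aa in aas if (f := _family_homozygosity(counts, aa)) is not None]
        n_used[k] = len(fs)
        if fs:
            class_means[k] = float(np.mean(fs))

    f3_imputed = False
    if 3 not in class_means and 2 in class_means and 4 in class_means:
        class_means[3] = (class_means[2] + class_means[4]) / 2.0
        f3_imputed = True

    nan = math.nan
    if any(k not in class_means for k in (2, 3, 4, 6)) or any(
        class_means[k] <= 0 for k in (2, 3, 4, 6)
    ):
        return ENCStats(
            f2=class_means.get(2, nan),
            f3=class_means.get(3, nan),
            f4=class_means.get(4, nan),
            f6=class_means.get(6, nan),
            enc=nan,
            n_families_used=n_used,
            f3_imputed=f3_imputed,
        )
    value = (
        2.0
        + 9.0 / class_means[2]
        + 1.0 / class_means[3]
        + 5.0 / class_means[4]
        + 3.0 / class_means[6]
    )
    value = min(61.0, max(20.0, value))
    return ENCStats(
        f2=class_means[2],
        f3=class_means[3],
        f4=class_means[4],
        f6=class_means[6],
        enc=value,
        n_families_used=n_used,
        f3_imputed=f3_imputed,
    )


def expected_enc_curve(gc3s: float, variant: str = "standard") -> float:
    """Wright's expected ENC when usage is driven by GC3s alone.

    ``standard``: 2 + s + 29/(s^2 + (1-s)^2).
    ``printed``:  2 +     29/(s^2 + (1-s)^2) — a published variant of the
    curve that drops the linear term; both are provided for comparison.
    """
    if not 0.0 < gc3s < 1.0:
        raise ValueError(f"gc3s must be in (0, 1), got {gc3s}")
    s = gc3s
    base = 29.0 / (s * s + (1.0 - s) * (1.0 - s))
    if variant == "standard":
        return 2.0 + s + base
    if variant == "printed":
        return 2.0 + base
    raise ValueError(f"unknown variant {variant!r}")


# ---------------------------------------------------------------------------
# tabular aggregation

def codon_usage_table(
    entries: Sequence[tuple[str, CodonCounts]]
) -> pd.DataFrame:
    """One row per (label, counts): n_codons, GC, GC1–GC3, GC12, GC3s, ENC."""
    rows = []
    for label, counts in entries:
        comp = composition(counts)
        e = enc(counts)
        rows.append(
            {
                "label": label,
                "n_codons": counts.n_codons,
                "gc": comp.gc,
                "gc1": comp.gc1,
                "gc2": comp.gc2,
                "gc3": comp.gc3,
                "gc12": comp.gc12,
                "gc3s": comp.gc3s,
                "enc": e.enc,
            }
        )
    return pd.DataFrame(rows).round(4)


def rscu_matrix(entries: Sequence[tuple[str, CodonCounts]]) -> pd.DataFrame:
    """Labels x 59 informative codons; missing families filled with 0."""
    data = {
        label: rscu(counts).to_vector(fill_missing=0.0) for label, counts in entries
    }
    return pd.DataFrame.from_dict(
        data, orient="index", columns=list(INFORMATIVE_CODONS)
    )
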