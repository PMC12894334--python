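"""Evolutionary-force diagnostics over gene-level codon statistics.

Three classical analyses that together separate mutational pressure from
selection as drivers of codon usage:

* **neutrality plot** — OLS regression of GC12 (mean GC of codon positions
  1–2) on GC3 across genes; slope near 1 implicates mutation pressure,
  near 0 selection.
* **PR2 plot** — within-gene parity at the third codon position,
  A3/(A3+T3) vs G3/(G3+C3); (0.5, 0.5) is the mutation–selection
  equilibrium.
* **correspondence analysis** — chi-square-metric decomposition of the
  gene x 59-codon RSCU matrix into axes ordered by explained inertia.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .codon_usage import CodonCounts, composition
from .genetics import CODON_TO_AA, DEGENERACY


@dataclass(frozen=True)
class NeutralityFit:
    """OLS fit of GC12 on GC3 for one species' genes."""

    slope: float
    intercept: float
    r2: float
    n_genes: int
    species: str = ""
    defined: bool = True


@dataclass(frozen=True)
class PR2Point:
    """Third-position parity ratios for one gene (None = zero denominator)."""

    gene: str
    g3_ratio: Optional[float]
    a3_ratio: Optional[float]
    functional_category: str = ""


@dataclass(frozen=True)
class COAResult:
    row_coords: np.ndarray  # rows x axes, principal coordinates
    col_coords: np.ndarray  # cols x axes
    inertia_fraction: np.ndarray
    total_inertia: float
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    dropped_rows: tuple[str, ...] = ()


def neutrality_fit(
    points: Sequence[tuple[float, float]], species: str = ""
) -> NeutralityFit:
    """Ordinary least squares of GC12 on GC3 over (gc3, gc12) gene points.

    Requires >= 3 finite points with var(GC3) > 0; otherwise returns an
    undefined fit (``defined=False``) rather than raising.
    """
    pts = [(x, y) for x, y in points if math.isfinite(x) and math.isfinite(y)]
    n = len(pts)
    if n < 3:
        return NeutralityFit(math.nan, math.nan, math.nan, n, species, defined=False)
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0.0:
        return NeutralityFit(math.nan, math.nan, math.nan, n, species, defined=False)
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    syy = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if syy == 0.0 else (sxy * sxy) / (sxx * syy)
    return NeutralityFit(slope, intercept, r2, n, species)


def pr2(
    counts: CodonCounts,
    gene: str = "",
    functional_category: str = "",
    fourfold_only: bool = False,
) -> PR2Point:
    """Parity-rule-2 point for one gene.

    Third-position base tallies run over all sense codons by default;
    ``fourfold_only`` restricts them to codons of four-fold degenerate
    families (the classical PR2 definition). A zero denominator yields a
    missing ratio for that axis.
    """
    a3 = t3 = g3 = c3 = 0
    for codon, n in counts.counts.items():
        if fourfold_only and DEGENERACY[CODON_TO_AA[codon]] != 4:
            continue
        base = codon[2]
        if base == "A":
            a3 += n
        elif base == "T":
            t3 += n
        elif base == "G":
            g3 += n
        elif base == "C":
            c3 += n
    g_ratio = g3 / (g3 + c3) if (g3 + c3) > 0 else None
    a_ratio = a3 / (a3 + t3) if (a3 + t3) > 0 else None
    return PR2Point(
        gene=gene or counts.source,
        g3_ratio=g_ratio,
        a3_ratio=a_ratio,
        functional_category=functional_category,
    )


def coa(
    matrix: pd.DataFrame | np.ndarray,
    n_axes: Optional[int] = None,
) -> COAResult:
    """Classical correspondence analysis of a non-negative matrix.

    With correspondence matrix P = X / sum(X), row/column marginals r, c,
    the standardized residuals S = D_r^{-1/2} (P - r c^T) D_c^{-1/2} are
    decomposed by SVD; principal coordinates are the D^{-1/2}-scaled
    singular vectors times their singular values, and axis i explains
    sigma_i^2 / sum(sigma^2) of the total inertia (the chi-square statistic
    over sum(X)).

    All-zero rows are dropped (recorded in ``dropped_rows``); all-zero
    columns are kept out of the decomposition and given zero coordinates.
    A rank-one (independent) matrix yields zero total inertia, not an
    exception. Axis signs follow a fixed convention: the largest-magnitude
    column coordinate on each axis is positive.
    """
    if isinstance(matrix, pd.DataFrame):
        row_labels = tuple(map(str, matrix.index))
        col_labels = tuple(map(str, matrix.columns))
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        row_labels = tuple(f"r{i}" for i in range(X.shape[0]))
        col_labels = tuple(f"c{j}" for j in range(X.shape[1]))
    if np.any(X < 0) or not np.all(np.isfinite(X)):
        raise ValueError("correspondence analysis requires a finite non-negative matrix")

    row_keep = X.sum(axis=1) > 0
    dropped = tuple(lbl for lbl, k in zip(row_labels, row_keep) if not k)
    row_labels = tuple(lbl for lbl, k in zip(row_labels, row_keep) if k)
    X = X[row_keep]
    col_keep = X.sum(axis=0) > 0

    n_rows, n_cols_all = X.shape
    n_cols = int(col_keep.sum())
    max_axes = max(min(n_rows - 1, n_cols - 1), 0)
    if n_axes is None:
        n_axes = max_axes
    n_axes = min(n_axes, max_axes)

    if n_rows == 0 or n_cols == 0 or max_axes == 0:
        return COAResult(
            row_coords=np.zeros((n_rows, 0)),
            col_coords=np.zeros((n_cols_all, 0)),
            inertia_fraction=np.zeros(0),
            total_inertia=0.0,
            row_labels=row_labels,
            col_labels=col_labels,
            dropped_rows=dropped,
        )

    Xk = X[:, col_keep]
    P = Xk / Xk.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sigma, Vt = np.linalg.svd(S, full_matrices=False)
    sigma = sigma[:max_axes]
    U = U[:, :max_axes]
    V = Vt.T[:, :max_axes]

    # numerically-zero axes carry no information; P is normalized so the
    # singular values are O(1) at most and an absolute floor is safe
    tol = max(S.shape) * np.finfo(float).eps * max(1.0, sigma[0] if sigma.size else 0.0)
    sigma = np.where(sigma > tol, sigma, 0.0)
    total_inertia = float(np.sum(sigma**2))
    fractions = (
        sigma**2 / total_inertia if total_inertia > 0 else np.zeros_like(sigma)
    )

    row_coords = (U / np.sqrt(r)[:, None]) * sigma
    col_coords_kept = (V / np.sqrt(c)[:, None]) * sigma

    # sign convention: largest-|.| column coordinate positive on each axis
    for j in range(col_coords_kept.shape[1]):
        col = col_coords_kept[:, j]
        if col.size and col[np.argmax(np.abs(col))] < 0:
            col_coords_kept[:, j] *= -1
            row_coords[:, j] *= -1

    col_coords = np.zeros((n_cols_all, row_coords.shape[1]))
    col_coords[col_keep] = col_coords_kept

    return COAResult(
        row_coords=row_coords[:, :n_axes],
        col_coords=col_coords[:, :n_axes],
        inertia_fraction=fractions[:n_axes],
        total_inertia=total_inertia,
        row_labels=row_labels,
        col_labels=col_labels,
        dropped_rows=dropped,
    )


# ---------------------------------------------------------------------------
# tabular drivers

def neutrality_table(
    per_species_counts: Sequence[tuple[str, Sequence[tuple[str, CodonCounts]]]],
    min_codons: int = 30,
) -> pd.DataFrame:
    """Per-species neutrality fits from gene-level codon counts.

    Genes with fewer than *min_codons* codons are excluded (logged via the
    returned n_genes column being smaller than the input).
    """
    rows = []
    for species, genes in per_species_counts:
        pts = []
        for _, counts in genes:
            if counts.n_codons < min_codons:
                continue
            comp = composition(counts)
            pts.append((comp.gc3, comp.gc12))
        fit = neutrality_fit(pts, species)
        rows.append(
            {
                "species": species,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r2": fit.r2,
                "n_genes": fit.n_genes,
                "defined": fit.defined,
            }
        )
    return pd.DataFrame(rows)


def pr2_table(
    genes: Sequence[tuple[str, CodonCounts]],
    min_codons: int = 30,
    fourfold_only: bool = False,
) -> pd.DataFrame:
    """PR2 points for every gene with at least *min_codons* codons."""
    rows = []
    for gene, counts in genes:
        if counts.n_codons < min_codons:
            continue
        p = pr2(counts, gene=gene, fourfold_only=fourfold_only)
        rows.append(
            {
                "gene": p.gene,
                "g3_ratio": p.g3_ratio,
                "a3_ratio": p.a3_ratio,
                "functional_category": p.functional_category,
            }
        )
    return pd.DataFrame(rows, columns=["gene", "g3_ratio", "a3_ratio", "functional_category"])
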