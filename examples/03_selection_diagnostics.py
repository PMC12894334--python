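"""Neutrality plot, PR2 parity, and correspondence analysis.

Genes are simulated so that GC3 varies while GC12 does not depend on it:
the neutrality regression slope should sit near 0 (the selection-dominated
limit), PR2 points should scatter around the (0.5, 0.5) equilibrium, and
the COA axes report how much codon-usage variation each direction explains.
"""

import numpy as np

from plastocodon import composition, count_codons, pr2, random_cds
from plastocodon.codon_usage import rscu_matrix
from plastocodon.diagnostics import coa, neutrality_fit

rng = np.random.default_rng(1)

genes = []
for i in range(40):
    g3 = rng.uniform(0.25, 0.75)
    genes.append((f"gene{i:02d}", count_codons(random_cds(rng, 200, gc3_target=g3))))

pts = []
for _, counts in genes:
    comp = composition(counts)
    pts.append((comp.gc3, comp.gc12))
fit = neutrality_fit(pts, species="simulated")
print(f"neutrality plot: slope {fit.slope:+.4f}, R^2 {fit.r2:.4f}, n={fit.n_genes}")
print("  (slope near 0 = selection-dominated; near 1 = mutation-dominated)")

ratios = [pr2(c, gene=g) for g, c in genes[:5]]
print("\nPR2 points (first five genes; equilibrium is 0.5, 0.5):")
for p in ratios:
    print(f"  {p.gene}: G3/(G3+C3) = {p.g3_ratio:.3f}, A3/(A3+T3) = {p.a3_ratio:.3f}")

res = coa(rscu_matrix(genes))
print("\ncorrespondence analysis of the gene x 59-codon RSCU matrix:")
for i, frac in enumerate(res.inertia_fraction[:2], start=1):
    print(f"  axis {i}: {100 * frac:.2f}% of total inertia")
print(f"  total inertia: {res.total_inertia:.4f}")
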