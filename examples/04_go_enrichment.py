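"""GO-term over-representation of a candidate gene list.

Builds a small gene->term annotation, plants a functional theme among
the candidate genes, and tests every term by the upper-tail
hypergeometric with Bonferroni correction over the terms tested.
"""

import pandas as pd

from foundersweep.enrich import enrich

rows = []
for i in range(200):
    rows.append((f"gene{i:03d}", f"GO:{i % 12:04d}"))
for g in ("gene000", "gene012", "gene024", "gene036"):
    rows.append((g, "GO:muscle"))
annotation = pd.DataFrame(rows, columns=["gene_id", "term_id"])

candidates = {"gene000", "gene012", "gene024", "gene036", "gene101"}
results = enrich(candidates, annotation)

print(f"{'term':>10}  k/K (candidates/universe with term)   p_raw     p_adj")
for r in results[:5]:
    print(f"{r.term:>10}  {r.k}/{r.K:<3} of n={r.n}, N={r.N}          "
          f"{r.p_raw:9.2e} {r.p_adj:9.2e}")
print(
    "\nThe planted term covers 4 of 5 candidates but only 4 of 200 universe\n"
    "genes, so it tops the ranking after Bonferroni; the positional terms\n"
    "behave like null annotations (adjusted P near 1)."
)
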