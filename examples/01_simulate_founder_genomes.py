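"""Simulate native and introduced genomes under the founder model.

Generates diploid genotypes for 8 native + 8 introduced individuals
under the fitted demography (native size 35,000; founded 50 generations
ago at ~14 individuals, grown to ~1,290) and prints the summary
statistics that characterise a founder event: the introduced population
keeps only part of the native diversity, and its site-frequency
spectrum is shifted toward intermediate frequencies (positive Tajima's
D) because rare alleles are the first casualties of a bottleneck.
"""

import numpy as np

import foundersweep as fs

model = fs.DemographicModel(N1=35_000, N2b=14.4, N2f=1290.0, T=50, mu=1e-8)
table = fs.simulate_genome(model, {"chr1": 500_000}, seed=1)
windows = fs.sliding_windows({"chr1": 500_000})

for pop in ("introduced", "native"):
    other = "native" if pop == "introduced" else "introduced"
    stats = fs.window_stats(table, windows, pop, other)
    full = [w for w in stats if not w.window.partial]
    pi = np.mean([w.pi_10kb for w in full])
    theta = np.mean([w.theta_w_10kb for w in full])
    d = np.mean([w.tajima_d for w in full if w.tajima_d is not None])
    fst = np.mean([w.fst for w in full if w.fst is not None])
    print(
        f"{pop:>10}:  pi/10kb = {pi:5.2f}   theta_W/10kb = {theta:5.2f}   "
        f"Tajima's D = {d:+5.2f}   FST = {fst:5.3f}"
    )

print(
    "\nThe introduced sample shows reduced diversity (pi and theta below the\n"
    "native values), a positive mean Tajima's D (the bottleneck signature),\n"
    "and clear differentiation from the source (FST > 0)."
)
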