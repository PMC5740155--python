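# Methods

## Demographic model

Two demes, no migration.  The native deme has constant diploid
effective size `N1`; the introduced deme split from it `T` generations
ago at size `N2b` and changed exponentially to its present size `N2f`.
Backward in time its size is `N2(t) = N2f * exp(-g t)` with
`g = ln(N2f/N2b) / T`, so the parameter space includes post-introduction
decline (`N2b > N2f`).  Defaults follow the study system the package
was built around: `N1 = 35,000` (from native diversity 14.0 per 10 kb
via `theta = 4 N mu` at `mu = 1e-8`), `T = 50` generations (historical
record of the introduction), samples of 8 diploids (16 chromosomes) per
population, and the fitted values `N2b = 14.4`, `N2f = 1,290` wherever
a concrete introduced-deme model is needed.  `mu` is configurable over
`1e-9 .. 1e-7`; estimates are reported for `1e-8`.

## Coalescent simulator (synthetic data)

Continuous-time two-deme Kingman coalescent.  Within the introduction
epoch the two demes coalesce independently; waiting times in the
exponentially changing deme come from exact inversion of the integrated
hazard `C(k,2) exp(g t) / (2 N2f)` (no generation stepping, no Euler
discretisation).  At `t = T` all surviving introduced lineages join the
native deme.  Mutation is infinite-sites: Poisson counts with mean
`mu * L * branch length`, uniform positions, positional collisions
dropped.  One master seed drives everything; per-replicate streams are
drawn from the shared `numpy` Generator in a fixed order, so every
output is reproducible bit-for-bit.

**Recombination.**  A region is simulated as independent equal-length
blocks, one genealogy per block — an approximation that captures the
variance-reducing effect of recombination without an ancestral
recombination graph.  The default granularity is 4 blocks per 10 kb
window (2.5 kb blocks), used coherently by both the genome generator
and the null calibration.  Justification: at `r ~ 1e-8` per bp the
expected number of ancestral breakpoints between two introduced
lineages across 10 kb is about `2 * r * L * E[pairwise coalescence
time] ~ 10`, so four independent blocks is conservative.  A strictly
non-recombining mode (`n_blocks = 1`, `rho = 0`) is available; note
that under the severe founder bottleneck it produces very heavy-tailed
window-statistic nulls (whole windows descending from a single
pre-introduction lineage), which depresses outlier-scan power.

**Sweep planting.**  A completed hard sweep is overlaid on the
introduced haplotypes by a star-genealogy approximation with
per-lineage recombination escape: each haplotype draws an exponential
escape distance (mean `width`, default 30 kb) on each side of the sweep
centre and copies a single donor haplotype at all closer sites; escaped
segments keep their own alleles.  This produces the canonical
signature — a core of near-zero diversity with donor alleles at or near
fixation, flanked by an excess of low-frequency variants (negative
Tajima's D).  Swept segments accumulate private mutations for `tau`
generations (default 25, completion midway through the epoch).  The
30 kb escape scale yields visible footprints of order 100–150 kb,
matching the spatial scale at which window scans of this design detect
candidates (single significant 10 kb windows inspected with ±50 kb
flanks).  What the generator does **not** emulate: gene conversion,
mutation-rate and recombination-rate heterogeneity, background
selection, soft sweeps from multiple origins, linkage across block
boundaries, and sequencing/genotyping error beyond uniform missingness
and synthetic QUAL/DP fields — so passing power tests bound performance
under idealised, not real, data.

## Expected joint AFS and the composite likelihood

Cell `(i, j)` of the expected joint AFS is `mu * total_sites * E[branch
length subtending i native and j introduced lineages]`.  The
expectation is computed without simulating topology: within a deme with
`k` surviving ancestors of `n` tips, the subtended-tip distribution is
the exchangeable-composition law `P(i | k, n) = C(n-i-1, k-2) /
C(n-1, k-1)`, and after the merge the constant-size phase is exact
given the surviving counts `(k1, k2)` (level durations
`E[T_m] = 4 N1 / (m (m-1))`, ancestor-composition and hypergeometric
type-splitting laws; precomputed tables per `(k1, k2)`).  Two routes to
the remaining randomness — the lineage-count trajectory through the
introduction epoch:

* `method="exact"` (default): the trajectory is a pure-death process
  with rates `C(k,2)` on the coalescent-intensity time scale
  `tau(t) = ∫ dt / (2 N(t))`; occupancy times and the endpoint law are
  computed by matrix exponentials of the bidiagonal generator under
  96-node Gauss–Legendre quadrature.  The result is deterministic.
* `method="mc"`: the trajectory is simulated (`n_mc` replicates,
  Rao-Blackwellised over topology); a shared seed across grid points
  gives common-random-numbers surfaces.

The exact route exists because the composite-likelihood ridge is
defined at a resolution of 2 log-likelihood units: with
raw-genealogy Monte Carlo the surface noise at the study's information
content is orders of magnitude larger than that, and even the
Rao-Blackwellised sampler needs prohibitive replicate counts.  The
three routes (exact, MC, and the independent msprime simulator) agree
to ~0.3% per cell in the test suite.

Model comparison uses the Poisson random-field composite
log-likelihood `sum k ln(lambda) - lambda - ln(k!)` over unmasked cells
(corners `(0,0)` and `(n1,n2)` masked; after folding, the mirror half
too).  Expected cells that are exactly zero with positive observed
counts are floored at a relative pseudo-mass of `1e-10` of the total so
Monte-Carlo zeros cannot produce infinities.  The spectrum is folded
(minor-allele, total-count convention with half-weight on the boundary
diagonal) by default because ancestral-state polarisation is usually
unavailable; unfolded spectra are supported.

**Grid search.**  25 × 25 log-spaced points over `N2b in [2, 1000]`,
`N2f in [35, 35000]`, then two 5 × 5 refinement passes spanning the
cells neighbouring the incumbent maximum.  The ridge diagnostic
collects all evaluated points within `delta_ll <= 2` of the maximum;
because `N2b` and `N2f` are strongly confounded (a smaller founding
size trades against faster growth at nearly constant total coalescent
intensity), the ridge — not the point estimate — is the scientifically
meaningful answer.

**Recovery experiment.**  `self_consistency_recovery` generates a
Monte-Carlo observed spectrum under the fitted model and re-fits it.
The observed spectrum's polymorphic mass is scaled to ~1.21 million
sites, the size of the real joint-AFS analysis, because the upper bound
the ridge places on the founder size is a function of the data's
information content: at the model-implied neutral mass (~6,000
polymorphic sites for the same number of genomic sites) the
`delta_ll <= 2` ridge honestly extends to founder sizes near 100–160,
whereas at the analysis scale it stays below ~50.  Observed-spectrum
`n_mc = 100,000` keeps the observation noise well inside the ridge
curvature at that scale.

## Variant filters

Retention requires, in attribution order: biallelic SNP; `QUAL > 10`
(strict); per-site mean depth `<= 100`; Hardy–Weinberg exact
(Levene/Haldane conditional) `P >= 0.01` in **every** population.
Per-population testing avoids conflating the Wahlund effect of
structure with genotyping error.  The separate high-coverage region
mask (depth > 1,000) used for read-level preprocessing is a distinct
option, not part of the SNP filter.  Filtering is idempotent and the
retained set is order-independent; only the per-rule attribution
depends on the fixed order.

## Outlier scan

Null distributions of `D`, `pi` (per 10 kb) and `FST` come from
simulating windows under the fitted model (default 10,000 replicates at
desk scale; the procedure supports the 10⁶ replicates of a full-scale
run).  Thresholds are order statistics (the `floor(alpha*R)`-th most
extreme stored value); empirical P-values use the add-one rule
`(1 + #more-extreme) / (R + 1)` so a Monte-Carlo P is never zero.  A
window is a candidate iff all three one-tailed P-values are `< 0.05`
**and** `D < 0` **and** `FST > 0`.  No multiple-testing correction is
applied across windows — this deliberately mirrors the per-window
`P < 0.05` criterion of the original design and is documented loudly:
with ~10⁵ windows genome-wide the per-statistic false-positive count is
large, and only the joint three-statistic requirement (and downstream
replication) controls it.  Partial trailing windows and windows with
undefined `D` or `FST` are never called.  Candidate genes are genes
whose body overlaps a called window by at least 1 bp (half-open
intervals); the ±50 kb flanking convention is treated as a plotting
aid, not an overlap rule.  Per-statistic FST defaults to Weir &
Cockerham (1984) ratio-of-averages on allele counts (appropriate for
small per-population sample sizes); the Hudson estimator is selectable.

## CLR sweep scan

Nielsen-style escape mixture: a lineage at distance `d` from a sweep of
strength `alpha` escapes with `p_e = 1 - exp(-alpha d)`; non-escaping
lineages collapse onto the sweeping haplotype, and the transformed
spectrum is the binomial mixture over escape counts of hypergeometric
subsamples of the genome-wide background spectrum.
`Lambda = 2 (max_alpha sum ln P_sweep - sum ln P_bg) >= 0` because the
background is nested at the `alpha d -> inf` boundary.  The `alpha`
grid is 40 log-spaced values over `1e-6 .. 1e-2` per bp (footprints
~100 bp to ~1 Mb).  The background spectrum spans classes `0..n`
(empty classes floored at a 0.5-count pseudo-mass): sites fixed in the
scanned population while variable elsewhere are precisely the strongest
sweep evidence, whereas sites invariant across the entire dataset are
ignored everywhere (making `Lambda` invariant to their injection).
The genome grid defaults to one point per 10 kb — `floor(genome
length / 10^4)` points, 108,164 for a 1,081,644,591 bp genome — with
the top 0.1% of `Lambda` flagged.  For genome scans, site distances are
collapsed into ~100 log-spaced bins per grid point (each bin scored at
its mean distance); the binning error on `Lambda` is a few percent,
far below the neutral spread, and exact per-site evaluation remains
available via `clr_at_position`.

## GO enrichment

Upper-tail hypergeometric per term (log-gamma arithmetic via
`scipy.stats.hypergeom`), universe = all genes in the user-supplied
`gene -> term` annotation, Bonferroni over the terms actually tested;
terms annotating no candidate are excluded from both testing and the
correction denominator.  No GO-DAG parent propagation is performed.

## Numerical and degenerate-input conventions

* Tajima's `D` is undefined at `S = 0` (returned as `None`/NaN and
  excluded from nulls with the exclusion counted); for `n = 2` the
  numerator vanishes identically and 0 is returned.
* `FST` is undefined when no site varies in the pooled sample.
* Windows are 0-based half-open internally; files use the native
  1-based conventions of VCF/GFF.
* Window `pi` is normalised by callable sites (the assembled-site
  count), reported per 10 kb as `x 1e4`.
* `D` constants are computed from the nominal sample size (2 x
  individuals); with missing data the per-site `pi` terms remain
  unbiased but `D` is approximate.

## Known limitations

The block-recombination approximation has no linkage across block
boundaries; sweep planting is a star approximation, not a structured
coalescent; the demographic fit ignores linkage entirely (composite
likelihood), so its ridge understates uncertainty on real data; and
the mean of Tajima's `D` under the exact neutral coalescent is slightly
negative at this study's `theta` (~-0.09 at `4 N mu L = 14`, `n = 16`;
confirmed independently with msprime/tskit), a property of the
statistic worth remembering when interpreting "D centred on zero" as a
neutrality diagnostic.
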