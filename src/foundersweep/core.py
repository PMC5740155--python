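"""Core population-genetic containers and summary statistics.

Diploid genotype data flow through :class:`GenotypeTable`; windowed summary
statistics (segregating sites, nucleotide diversity, Watterson's theta,
Tajima's D, FST) are computed from per-site allele counts so the same code
path serves both VCF-derived and simulated data.

Conventions: positions are 1-based bp (VCF convention) inside
:class:`Site`; windows are 0-based half-open internally and converted back
to 1-based only on file output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

MISSING = -1

__all__ = [
    "MISSING",
    "Site",
    "GenotypeTable",
    "Window",
    "WindowStats",
    "JointSFS",
    "site_allele_counts",
    "nucleotide_diversity",
    "watterson_theta",
    "harmonic_number",
    "tajimas_d",
    "fst_window",
    "sliding_windows",
    "window_stats",
    "joint_sfs",
    "sfs_1d",
]


@dataclass
class Site:
    """One biallelic (or to-be-filtered) SNP record.

    ``genotypes`` holds the alt-allele count per diploid individual
    (0, 1, 2) with :data:`MISSING` (-1) for no-calls.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    qual: float
    depth: float
    genotypes: np.ndarray

    @property
    def is_biallelic_snp(self) -> bool:
        return (
            len(self.ref) == 1
            and "," not in self.alt
            and len(self.alt) == 1
            and self.ref != self.alt
        )


@dataclass
class GenotypeTable:
    """Per-site diploid genotypes plus a sample -> population map."""

    sites: list[Site]
    samples: list[str]
    populations: dict[str, list[int]]  # population id -> sample indices

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for pop, idx in self.populations.items():
            if seen & set(idx):
                raise ValueError(f"population {pop!r} overlaps another population")
            seen |= set(idx)
            if any(i < 0 or i >= len(self.samples) for i in idx):
                raise ValueError(f"population {pop!r} has out-of-range sample index")
        last: dict[str, int] = {}
        for s in self.sites:
            if len(s.genotypes) != len(self.samples):
                raise ValueError(f"site {s.chrom}:{s.pos} genotype length mismatch")
            if s.chrom in last and s.pos <= last[s.chrom]:
                raise ValueError(f"positions not strictly increasing at {s.chrom}:{s.pos}")
            last[s.chrom] = s.pos

    def pop_indices(self, population: str) -> list[int]:
        try:
            return self.populations[population]
        except KeyError:
            raise KeyError(f"unknown population {population!r}") from None

    def chrom_sites(self, chrom: str) -> list[Site]:
        return [s for s in self.sites if s.chrom == chrom]

    @property
    def chroms(self) -> list[str]:
        out: list[str] = []
        for s in self.sites:
            if not out or out[-1] != s.chrom:
                if s.chrom in out:
                    raise ValueError("sites not grouped by chromosome")
                out.append(s.chrom)
        return out


@dataclass(frozen=True)
class Window:
    """Half-open genomic interval [start, end) with a callable-site count."""

    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    callable_sites: int
    partial: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class WindowStats:
    window: Window
    S: int
    pi_site: float
    pi_10kb: float
    theta_w_10kb: float
    tajima_d: float | None
    fst: float | None


# ---------------------------------------------------------------------------
# allele counting


def site_allele_counts(
    table: GenotypeTable, window: Window, population: str
) -> list[tuple[int, int]]:
    """Per-site (called chromosomes, alt-allele count) for one population.

    One entry per site with ``window.start < pos-1 < window.end`` on the
    window's chromosome (0-based half-open on the 0-based position).
    All-missing sites yield ``(0, 0)``.
    """
    idx = table.pop_indices(population)
    out: list[tuple[int, int]] = []
    for s in table.sites:
        if s.chrom != window.chrom:
            continue
        p0 = s.pos - 1
        if not (window.start <= p0 < window.end):
            continue
        g = s.genotypes[idx]
        called = g[g != MISSING]
        out.append((2 * len(called), int(called.sum())))
    return out


# ---------------------------------------------------------------------------
# diversity statistics


def nucleotide_diversity(
    counts: list[tuple[int, int]], callable_sites: int
) -> float:
    """Per-site nucleotide diversity (pi).

    Unbiased per-site heterozygosity 2*a*(n-a)/(n*(n-1)) summed over sites
    and divided by the number of callable sites.  Sites with fewer than two
    called chromosomes are skipped.
    """
    if callable_sites <= 0:
        raise ValueError("callable_sites must be positive")
    return _pi_total(counts) / callable_sites


def _pi_total(counts) -> float:
    tot = 0.0
    for n, a in counts:
        if n >= 2:
            tot += 2.0 * a * (n - a) / (n * (n - 1))
    return tot


def harmonic_number(n_minus_1: int) -> float:
    """a1 = sum_{i=1}^{n-1} 1/i, the Watterson normaliser."""
    return sum(1.0 / i for i in range(1, n_minus_1 + 1))


def watterson_theta(S: int, n: int) -> float:
    """Watterson's theta for the whole window (not per site): S / a1(n)."""
    if n < 2:
        raise ValueError("need at least 2 chromosomes")
    if S < 0:
        raise ValueError("negative segregating-site count")
    if S == 0:
        return 0.0
    return S / harmonic_number(n - 1)


def tajimas_d(S: int, pi_total: float, n: int) -> float | None:
    """Tajima's D from segregating sites and total pairwise diversity.

    Returns None (undefined) when S = 0.  For n = 2 the numerator is
    identically zero and 0.0 is returned.
    """
    if n < 2:
        raise ValueError("need at least 2 chromosomes")
    if S == 0:
        return None
    a1 = harmonic_number(n - 1)
    if n == 2:
        return 0.0
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return 0.0
    return (pi_total - S / a1) / math.sqrt(var)


# ---------------------------------------------------------------------------
# FST


def fst_window(
    counts_pop1: list[tuple[int, int]],
    counts_pop2: list[tuple[int, int]],
    estimator: str = "wc",
) -> float | None:
    """Multi-site FST between two populations (ratio of averages).

    ``counts_popX`` are per-site (called chromosomes, alt count) pairs at
    the same sites in the same order.  Default is the Weir & Cockerham
    (1984) variance-component estimator on allele counts; ``estimator=
    "hudson"`` selects 1 - Hw/Hb.  Returns None when no site is variable
    in the pooled sample (or no usable site exists).
    """
    if len(counts_pop1) != len(counts_pop2):
        raise ValueError("count lists must align site-for-site")
    c1 = np.asarray(counts_pop1, dtype=float).reshape(-1, 2)
    c2 = np.asarray(counts_pop2, dtype=float).reshape(-1, 2)
    return _fst_arrays(c1[:, 0], c1[:, 1], c2[:, 0], c2[:, 1], estimator)


def _fst_arrays(n1, a1, n2, a2, estimator: str = "wc") -> float | None:
    if estimator not in ("wc", "hudson"):
        raise ValueError(f"unknown estimator {estimator!r}")
    ok = (n1 >= 2) & (n2 >= 2)
    n1, a1, n2, a2 = n1[ok], a1[ok], n2[ok], a2[ok]
    if len(n1) == 0 or not np.any((a1 + a2 > 0) & (a1 + a2 < n1 + n2)):
        return None
    p1, p2 = a1 / n1, a2 / n2
    if estimator == "wc":
        a, b = _wc_components(n1, p1, n2, p2)
        den = float((a + b).sum())
        if den == 0.0:
            return None
        return float(a.sum()) / den
    hw = 0.5 * (2 * p1 * (1 - p1) * n1 / (n1 - 1) + 2 * p2 * (1 - p2) * n2 / (n2 - 1))
    hb = p1 * (1 - p2) + p2 * (1 - p1)
    den = float(hb.sum())
    if den == 0.0:
        return None
    return 1.0 - float(hw.sum()) / den


def _wc_components(n1, p1, n2, p2):
    # Weir & Cockerham 1984 components for allele-count (haploid-unit) data,
    # r = 2 populations: a = between-population, b = within-population.
    # Accepts scalars or aligned arrays.
    r = 2
    nbar = (n1 + n2) / 2.0
    nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    pq = pbar * (1 - pbar)
    a = (nbar / nc) * (s2 - (pq - s2 * (r - 1) / r) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pq - s2 * (r - 1) / r)
    return a, b


# ---------------------------------------------------------------------------
# windows


def sliding_windows(
    chrom_lengths: dict[str, int], window_size: int = 10_000, step: int = 5_000
) -> list[Window]:
    """Sliding windows [k*step, k*step + window_size) per chromosome.

    Trailing windows extending past the chromosome end are clipped and
    flagged ``partial``; callable_sites defaults to the window's span
    (fully-assembled assumption, override downstream if known).
    """
    if step > window_size:
        raise ValueError("step must not exceed window_size")
    if window_size % step != 0:
        raise ValueError("window_size must be a multiple of step")
    out: list[Window] = []
    for chrom, length in chrom_lengths.items():
        k = 0
        while k * step < length:
            start = k * step
            end = start + window_size
            if end > length:
                out.append(Window(chrom, start, length, length - start, partial=True))
            else:
                out.append(Window(chrom, start, end, window_size))
            k += 1
    return out


def window_stats(
    table: GenotypeTable,
    windows: list[Window],
    scan_pop: str,
    other_pop: str | None = None,
    fst_estimator: str = "wc",
) -> list[WindowStats]:
    """Per-window S, pi, Watterson's theta, Tajima's D (scan population)
    and FST between scan and other population.

    Vectorised: per-chromosome position/genotype arrays are built once
    and windows slice them by binary search.
    """
    n_chrom = 2 * len(table.pop_indices(scan_pop))
    i1 = np.asarray(table.pop_indices(scan_pop))
    i2 = np.asarray(table.pop_indices(other_pop)) if other_pop is not None else None
    # per-chromosome arrays
    arrays: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {w.chrom for w in windows}:
        cs = table.chrom_sites(chrom)
        pos0 = np.array([s.pos - 1 for s in cs], dtype=np.int64)
        G = (
            np.stack([s.genotypes for s in cs])
            if cs
            else np.zeros((0, len(table.samples)), dtype=np.int8)
        )
        arrays[chrom] = (pos0, G)

    def pop_counts(G, idx):
        g = G[:, idx]
        miss = (g == MISSING).sum(axis=1)
        n = 2 * (g.shape[1] - miss)
        a = g.sum(axis=1) + miss  # MISSING is -1: add back one per no-call
        return n.astype(float), a.astype(float)

    out: list[WindowStats] = []
    for w in windows:
        pos0, G = arrays[w.chrom]
        lo = np.searchsorted(pos0, w.start, side="left")
        hi = np.searchsorted(pos0, w.end, side="left")
        Gw = G[lo:hi]
        n, a = pop_counts(Gw, i1)
        ok = n >= 2
        S = int(((a > 0) & (a < n) & ok).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            terms = np.where(ok, 2.0 * a * (n - a) / np.maximum(n * (n - 1), 1), 0.0)
        pi_tot = float(terms.sum())
        callable_sites = max(w.callable_sites, 1)
        pi_site = pi_tot / callable_sites
        theta = watterson_theta(S, n_chrom) / callable_sites * 1e4
        d = tajimas_d(S, pi_tot, n_chrom)
        fst = None
        if i2 is not None:
            n2, a2 = pop_counts(Gw, i2)
            fst = _fst_arrays(n, a, n2, a2, fst_estimator)
        out.append(
            WindowStats(
                window=w,
                S=S,
                pi_site=pi_site,
                pi_10kb=pi_site * 1e4,
                theta_w_10kb=theta,
                tajima_d=d,
                fst=fst,
            )
        )
    return out


# ---------------------------------------------------------------------------
# site-frequency spectra


@dataclass
class JointSFS:
    """(n1+1) x (n2+1) joint allele-frequency spectrum.

    ``mask`` marks cells excluded from all likelihood sums: at minimum the
    monomorphic corners (0,0) and (n1,n2); after folding also the mirror
    half of the spectrum.
    """

    data: np.ndarray
    mask: np.ndarray = field(default=None)  # True = masked
    folded: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.mask is None:
            self.mask = np.zeros(self.data.shape, dtype=bool)
            self.mask[0, 0] = True
            self.mask[-1, -1] = True
        if self.mask.shape != self.data.shape:
            raise ValueError("mask/data shape mismatch")

    @property
    def n1(self) -> int:
        return self.data.shape[0] - 1

    @property
    def n2(self) -> int:
        return self.data.shape[1] - 1

    def total(self) -> float:
        """Mass in unmasked cells."""
        return float(self.data[~self.mask].sum())

    def fold(self) -> "JointSFS":
        """Fold onto minor-allele classes (total-count convention).

        Each cell is combined with its mirror (n1-i, n2-j); cells whose
        total allele count exceeds (n1+n2)/2 are masked, and cells exactly
        on the boundary keep half of the combined mass.
        """
        if self.folded:
            return self
        ntot = self.n1 + self.n2
        d = self.data + self.data[::-1, ::-1]
        m = self.mask | self.mask[::-1, ::-1]
        i = np.arange(self.n1 + 1)[:, None]
        j = np.arange(self.n2 + 1)[None, :]
        tot = i + j
        d = np.where(tot * 2 == ntot, 0.5 * d, d)
        m = m | (tot * 2 > ntot)
        return JointSFS(d, m, folded=True)


def joint_sfs(
    table: GenotypeTable,
    pop1: str,
    pop2: str,
    fold: bool = True,
    project_to: tuple[int, int] | None = None,
) -> JointSFS:
    """Observed joint AFS of two populations.

    Cell [i][j] counts sites with alt count i in pop1 and j in pop2.
    By default sites with any missing call in either population are
    dropped.  ``project_to=(m1, m2)`` instead hypergeometrically projects
    every site down to m1/m2 chromosomes (sites with fewer called
    chromosomes than the projection size are still dropped), spreading
    each site's unit mass over the projected cells.
    """
    i1 = table.pop_indices(pop1)
    i2 = table.pop_indices(pop2)
    if set(i1) & set(i2):
        raise ValueError("populations overlap")
    n1, n2 = 2 * len(i1), 2 * len(i2)
    m1, m2 = project_to if project_to is not None else (n1, n2)
    if m1 > n1 or m2 > n2 or m1 < 1 or m2 < 1:
        raise ValueError("projection sizes must be in [1, sample size]")
    arr = np.zeros((m1 + 1, m2 + 1))
    for s in table.sites:
        g1 = s.genotypes[i1]
        g2 = s.genotypes[i2]
        c1 = g1[g1 != MISSING]
        c2 = g2[g2 != MISSING]
        nc1, nc2 = 2 * len(c1), 2 * len(c2)
        if project_to is None:
            if nc1 < n1 or nc2 < n2:
                continue
            arr[int(c1.sum()), int(c2.sum())] += 1
        else:
            if nc1 < m1 or nc2 < m2:
                continue
            w1 = _project_weights(nc1, int(c1.sum()), m1)
            w2 = _project_weights(nc2, int(c2.sum()), m2)
            arr += np.outer(w1, w2)
    sfs = JointSFS(arr)
    return sfs.fold() if fold else sfs


def _project_weights(n: int, a: int, m: int) -> np.ndarray:
    """Hypergeometric weights for projecting a alt alleles of n down to m."""
    from scipy.stats import hypergeom

    k = np.arange(m + 1)
    return hypergeom.pmf(k, n, a, m)


def sfs_1d(counts: list[tuple[int, int]], n: int, fold: bool = False) -> np.ndarray:
    """1-D site-frequency spectrum over classes 0..n from per-site counts.

    Sites with missing calls (called chromosomes != n) are dropped.
    Folded spectra map class k onto min(k, n-k).
    """
    out = np.zeros(n + 1)
    for nc, a in counts:
        if nc != n:
            continue
        k = min(a, n - a) if fold else a
        out[k] += 1
    return out
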