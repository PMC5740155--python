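"""Two-deme coalescent simulator for founder/expansion demography.

The model: a native deme of constant diploid size N1; an introduced deme
founded T generations ago at size N2b that changed exponentially to its
present size N2f (the backward-time size is N2(t) = N2f * exp(-g*t) with
g = ln(N2f/N2b)/T, so decline after introduction, N2b > N2f, is allowed).
No migration.  Looking backward, the two demes coalesce independently
until t = T, when every surviving introduced lineage joins the native
deme.

Mutation is infinite-sites: Poisson numbers of mutations proportional to
branch length in generations, uniform positions along the region.  Times
are continuous (exact inversion of the integrated coalescent hazard
through the exponential epoch); nothing is discretised to generations.

Recombination within a region is approximated by partitioning it into
independent equal-length blocks, one genealogy per block (``rho`` chooses
the number of blocks); the default is a single non-recombining block,
which gives conservatively wide null distributions for 10 kb windows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import (
    MISSING,
    GenotypeTable,
    Site,
    Window,
    fst_window,
    tajimas_d,
    _pi_total,
)

__all__ = [
    "DemographicModel",
    "HaplotypeMatrix",
    "simulate_region",
    "simulate_null_windows",
    "plant_sweep",
    "haplotypes_to_genotypes",
    "simulate_genome",
]


@dataclass(frozen=True)
class DemographicModel:
    """Four demographic parameters plus the mutation rate.

    N1: native diploid effective size (constant).
    N2b: introduced effective size at founding.
    N2f: introduced effective size at present.
    T: generations since the introduction.
    mu: mutation rate per site per generation.
    """

    N1: float
    N2b: float
    N2f: float
    T: float
    mu: float

    def __post_init__(self) -> None:
        if min(self.N1, self.N2b, self.N2f) < 1:
            raise ValueError("population sizes must be >= 1")
        if self.T <= 0:
            raise ValueError("T must be positive")
        if self.mu < 0:
            raise ValueError("mu must be non-negative")

    @property
    def g(self) -> float:
        """Backward-time exponential rate of the introduced deme."""
        return math.log(self.N2f / self.N2b) / self.T


@dataclass
class HaplotypeMatrix:
    """0/1 haplotypes at segregating sites in a region of length L bp."""

    L: int
    positions: np.ndarray  # increasing ints in [0, L)
    matrix: np.ndarray  # (n_haplotypes, n_sites) uint8
    pop_labels: np.ndarray  # per-haplotype population name

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.positions):
            raise ValueError("matrix/positions mismatch")
        if len(self.pop_labels) != self.matrix.shape[0]:
            raise ValueError("pop_labels length mismatch")

    def pop_rows(self, population: str) -> np.ndarray:
        return self.matrix[np.asarray(self.pop_labels) == population]


# ---------------------------------------------------------------------------
# genealogy engine


def _exp_epoch_time(rng, k: int, N2f: float, g: float, t0: float) -> float:
    """Next coalescence time in the exponentially changing introduced deme.

    Hazard at backward time t is C(k,2) / (2 * N2f * exp(-g*t)).  Returns
    math.inf when the drawn integrated hazard is never reached.
    """
    if k < 2:
        return math.inf
    rate0 = k * (k - 1) / 2.0 / (2.0 * N2f)
    e = rng.exponential()
    if g == 0.0:
        return t0 + e / rate0
    arg = math.exp(g * t0) + g * e / rate0
    if arg <= 0.0:
        return math.inf
    return math.log(arg) / g


def _const_time(rng, k: int, N: float, t0: float) -> float:
    if k < 2:
        return math.inf
    rate = k * (k - 1) / 2.0 / (2.0 * N)
    return t0 + rng.exponential() / rate


def _genealogy(rng: np.random.Generator, n1: int, n2: int, model: DemographicModel):
    """Simulate one genealogy; yield (tip_bitmask, branch_length) branches.

    Tips 0..n1-1 are native (deme 1), n1..n1+n2-1 introduced (deme 2).
    Branch lengths are in generations.
    """
    g = model.g
    # (mask, birth_time) per active lineage, per deme
    d1 = [(1 << i, 0.0) for i in range(n1)]
    d2 = [(1 << (n1 + i), 0.0) for i in range(n2)]
    branches: list[tuple[int, float]] = []
    t = 0.0
    while t < model.T and (len(d1) > 1 or len(d2) > 1):
        t1 = _const_time(rng, len(d1), model.N1, t)
        t2 = _exp_epoch_time(rng, len(d2), model.N2f, g, t)
        tn = min(t1, t2)
        if tn >= model.T:
            break
        t = tn
        deme = d1 if t1 <= t2 else d2
        i, j = rng.choice(len(deme), size=2, replace=False)
        (ma, ba), (mb, bb) = deme[i], deme[j]
        branches.append((ma, t - ba))
        branches.append((mb, t - bb))
        merged = (ma | mb, t)
        for k in sorted((i, j), reverse=True):
            deme.pop(k)
        deme.append(merged)
    # introduction event: all introduced lineages join the native deme
    t = model.T
    pool = d1 + d2
    while len(pool) > 1:
        t = _const_time(rng, len(pool), model.N1, t)
        i, j = rng.choice(len(pool), size=2, replace=False)
        (ma, ba), (mb, bb) = pool[i], pool[j]
        branches.append((ma, t - ba))
        branches.append((mb, t - bb))
        merged = (ma | mb, t)
        for k in sorted((i, j), reverse=True):
            pool.pop(k)
        pool.append(merged)
    return branches


def _drop_mutations(rng, branches, mu: float, L: int, n_hap: int):
    """Infinite-sites mutations on a genealogy -> (positions, matrix)."""
    pos: list[int] = []
    cols: list[int] = []  # tip bitmasks, parallel to pos
    for mask, length in branches:
        nm = rng.poisson(mu * L * length)
        if nm:
            for p in rng.integers(0, L, size=nm):
                pos.append(int(p))
                cols.append(mask)
    if not pos:
        return np.empty(0, dtype=np.int64), np.zeros((n_hap, 0), dtype=np.uint8)
    order = np.argsort(pos, kind="stable")
    # drop positional collisions (rare for L >> S) to honour infinite sites
    out_pos: list[int] = []
    out_cols: list[int] = []
    last = -1
    for k in order:
        if pos[k] != last:
            out_pos.append(pos[k])
            out_cols.append(cols[k])
            last = pos[k]
    mat = np.zeros((n_hap, len(out_pos)), dtype=np.uint8)
    for j, mask in enumerate(out_cols):
        for i in range(n_hap):
            if mask >> i & 1:
                mat[i, j] = 1
    return np.asarray(out_pos, dtype=np.int64), mat


def simulate_region(
    model: DemographicModel,
    n1: int,
    n2: int,
    L: int,
    rho: float = 0.0,
    seed: int | np.random.Generator | None = None,
    pop_names: tuple[str, str] = ("native", "introduced"),
) -> HaplotypeMatrix:
    """Simulate haplotypes for one region of L bp.

    n1/n2 are sampled chromosome counts from the native and introduced
    demes.  ``rho`` (scaled recombination 4*N1*r*L) sets the number of
    independently simulated blocks, 1 + round(rho) capped at the site
    scale; rho = 0 gives a single genealogy for the region.
    """
    if n1 < 0 or n2 < 0 or n1 + n2 < 2:
        raise ValueError("need at least 2 sampled chromosomes")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_blocks = max(1, 1 + int(round(rho))) if rho > 0 else 1
    n_blocks = min(n_blocks, max(1, L // 100))
    edges = np.linspace(0, L, n_blocks + 1).astype(np.int64)
    all_pos: list[np.ndarray] = []
    all_mat: list[np.ndarray] = []
    n_hap = n1 + n2
    for b in range(n_blocks):
        bl = int(edges[b + 1] - edges[b])
        branches = _genealogy(rng, n1, n2, model)
        p, m = _drop_mutations(rng, branches, model.mu, bl, n_hap)
        all_pos.append(p + edges[b])
        all_mat.append(m)
    positions = np.concatenate(all_pos)
    matrix = np.concatenate(all_mat, axis=1) if all_mat else np.zeros((n_hap, 0))
    labels = np.array([pop_names[0]] * n1 + [pop_names[1]] * n2)
    return HaplotypeMatrix(L=L, positions=positions, matrix=matrix, pop_labels=labels)


# ---------------------------------------------------------------------------
# per-window null statistics


def _stats_from_haps(haps: HaplotypeMatrix, scan_pop: str, other_pop: str):
    """(tajima_d, pi_10kb, fst, S) of the scan population for one window."""
    scan = haps.pop_rows(scan_pop)
    other = haps.pop_rows(other_pop)
    n = scan.shape[0]
    a = scan.sum(axis=0)
    counts = [(n, int(x)) for x in a]
    seg = int(((a > 0) & (a < n)).sum())
    pi_tot = _pi_total(counts)
    pi_10kb = pi_tot / haps.L * 1e4
    d = tajimas_d(seg, pi_tot, n)
    no = other.shape[0]
    ao = other.sum(axis=0)
    fst = fst_window(counts, [(no, int(x)) for x in ao])
    return d, pi_10kb, fst, seg


def simulate_null_windows(
    model: DemographicModel,
    n_reps: int,
    n1: int = 16,
    n2: int = 16,
    L: int = 10_000,
    seed: int | None = None,
    scan_pop: str = "introduced",
    n_blocks: int = 4,
):
    """Null distribution of (Tajima's D, pi per 10 kb, FST) per window.

    Each replicate simulates both demes jointly for one window of L bp;
    D and pi are computed on the scanned (introduced) sample, FST between
    the samples.  Replicates with no segregating site in the scanned
    sample carry undefined (NaN) D.  Returns a record array with fields
    tajima_d, pi_10kb, fst, S.

    ``n_blocks`` independent genealogy blocks per window model
    within-window recombination; the default (4 blocks of 2.5 kb) is
    conservative against the ~10 expected ancestral recombination
    breakpoints per 10 kb between two introduced lineages at r ~ 1e-8
    per bp (pairwise coalescent depth ~ pi / (4*mu) generations).
    Set ``n_blocks=1`` for a strictly non-recombining null.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    other = "native" if scan_pop == "introduced" else "introduced"
    out = np.zeros(
        n_reps,
        dtype=[("tajima_d", float), ("pi_10kb", float), ("fst", float), ("S", int)],
    )
    for r in range(n_reps):
        haps = simulate_region(model, n1, n2, L, rho=n_blocks - 1, seed=rng)
        d, pi, fst, S = _stats_from_haps(haps, scan_pop, other)
        out[r] = (
            np.nan if d is None else d,
            pi,
            np.nan if fst is None else fst,
            S,
        )
    return out


# ---------------------------------------------------------------------------
# sweep planting


def plant_sweep(
    haps: HaplotypeMatrix,
    center: int,
    tau: float,
    mu: float,
    width: float = 30_000.0,
    seed: int | np.random.Generator | None = None,
    population: str = "introduced",
) -> HaplotypeMatrix:
    """Overlay a completed hard sweep on the introduced haplotypes.

    Star-genealogy approximation with per-lineage recombination escape:
    every introduced haplotype draws an exponential escape distance
    (mean ``width``) on each side of ``center`` and copies the single
    donor haplotype at all sites closer than that; escaped segments keep
    their own alleles, which produces the canonical post-sweep excess of
    low-frequency variants (negative Tajima's D) flanking a core of
    near-zero diversity.  Swept segments then accumulate private
    mutations for ``tau`` generations.  ``width = 0`` returns the input
    unchanged.

    The default escape scale (30 kb, giving a visible footprint of
    roughly 100-150 kb once all lineages have escaped) matches the
    spatial scale of sweep signals detectable in window scans of this
    design: candidate regions are single 10 kb windows examined with
    +-50 kb flanks, i.e. signals of order 10^2 kb.  ``tau`` defaults to
    25 generations (sweep completion midway through the introduction
    epoch).
    """
    if not (0 <= center < haps.L):
        raise ValueError("sweep center outside the region")
    return _plant_sweep_impl(haps, float(center), tau, mu, width, seed, population)


def _plant_sweep_impl(
    haps: HaplotypeMatrix,
    center: float,
    tau: float,
    mu: float,
    width: float,
    seed,
    population: str,
    escape: tuple[np.ndarray, np.ndarray] | None = None,
) -> HaplotypeMatrix:
    # center may lie outside [0, L) when the footprint of a sweep centred
    # in a neighbouring block spills into this one
    if width <= 0:
        return haps
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sel = np.flatnonzero(np.asarray(haps.pop_labels) == population)
    mat = haps.matrix.copy()
    donor = sel[0]
    # per-lineage recombination escape: lineage i carries the sweeping
    # haplotype out to an exponential distance on each side of the centre
    if escape is None:
        d_left = rng.exponential(width, size=len(sel))
        d_right = rng.exponential(width, size=len(sel))
        d_left[0] = d_right[0] = np.inf  # the donor IS the sweeping haplotype
    else:
        d_left, d_right = escape
    offset = haps.positions - center  # signed distance
    for ii, h in enumerate(sel):
        if h == donor:
            continue
        swept = ((offset < 0) & (-offset < d_left[ii])) | (
            (offset >= 0) & (offset < d_right[ii])
        )
        mat[h, swept] = mat[donor, swept]
    # private post-sweep mutations accumulate on each swept segment
    new_pos: list[int] = []
    new_cols: list[np.ndarray] = []
    n_hap = mat.shape[0]
    for ii, h in enumerate(sel):
        lo = max(0.0, center - d_left[ii])
        hi = min(float(haps.L), center + d_right[ii])
        seg = max(0.0, hi - lo)
        nm = rng.poisson(mu * tau * seg)
        for _ in range(nm):
            p = int(rng.uniform(lo, hi))
            col = np.zeros(n_hap, dtype=np.uint8)
            col[h] = 1
            new_pos.append(p)
            new_cols.append(col)
    positions = np.concatenate([haps.positions, np.asarray(new_pos, dtype=np.int64)])
    matrix = (
        np.concatenate([mat, np.stack(new_cols, axis=1)], axis=1) if new_cols else mat
    )
    # re-sort, drop duplicate positions and monomorphic columns
    order = np.argsort(positions, kind="stable")
    positions = positions[order]
    matrix = matrix[:, order]
    keep = np.ones(len(positions), dtype=bool)
    keep[1:] &= positions[1:] != positions[:-1]
    tot = matrix.sum(axis=0)
    keep &= (tot > 0) & (tot < matrix.shape[0])
    return HaplotypeMatrix(
        L=haps.L,
        positions=positions[keep],
        matrix=matrix[:, keep],
        pop_labels=haps.pop_labels,
    )


# ---------------------------------------------------------------------------
# genotype assembly


def haplotypes_to_genotypes(
    haps: HaplotypeMatrix,
    missing_rate: float = 0.0,
    seed: int | np.random.Generator | None = None,
    chrom: str = "chr1",
    qual_range: tuple[float, float] = (20.0, 60.0),
    depth_range: tuple[float, float] = (10.0, 50.0),
    pos_offset: int = 0,
) -> GenotypeTable:
    """Pair haplotypes in order into diploids and emit a GenotypeTable.

    Synthetic per-site QUAL and mean-depth fields are drawn uniformly
    from the configured ranges so that the filtering rules are
    exercisable on simulated data.  ``missing_rate`` applies i.i.d. per
    genotype call.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = np.asarray(haps.pop_labels)
    if len(labels) % 2:
        raise ValueError("odd haplotype count cannot be paired into diploids")
    samples: list[str] = []
    populations: dict[str, list[int]] = {}
    pairs: list[tuple[int, int]] = []
    for i in range(0, len(labels), 2):
        if labels[i] != labels[i + 1]:
            raise ValueError("haplotype pair spans two populations")
        pop = str(labels[i])
        idx = len(samples)
        samples.append(f"{pop}_{sum(1 for s in samples if s.startswith(pop))}")
        populations.setdefault(pop, []).append(idx)
        pairs.append((i, i + 1))
    sites: list[Site] = []
    nsite = haps.matrix.shape[1]
    quals = rng.uniform(*qual_range, size=nsite)
    depths = rng.uniform(*depth_range, size=nsite)
    for j in range(nsite):
        g = np.array(
            [haps.matrix[a, j] + haps.matrix[b, j] for a, b in pairs], dtype=np.int8
        )
        if missing_rate > 0:
            g[rng.random(len(g)) < missing_rate] = MISSING
        sites.append(
            Site(
                chrom=chrom,
                pos=pos_offset + int(haps.positions[j]) + 1,
                ref="A",
                alt="T",
                qual=float(quals[j]),
                depth=float(depths[j]),
                genotypes=g,
            )
        )
    return GenotypeTable(sites=sites, samples=samples, populations=populations)


# ---------------------------------------------------------------------------
# whole-genome synthesis


def simulate_genome(
    model: DemographicModel,
    chrom_lengths: dict[str, int],
    n1: int = 16,
    n2: int = 16,
    block_size: int = 2_500,
    sweeps: list[dict] | None = None,
    missing_rate: float = 0.0,
    seed: int | None = None,
    sweep_tau: float = 25.0,
    sweep_width: float = 30_000.0,
) -> GenotypeTable:
    """Simulate a multi-chromosome diploid genotype table.

    Each chromosome is built from independent ``block_size`` genealogies
    (2.5 kb default, emulating within-window recombination at the same
    granularity as the null calibration).
    ``sweeps`` is a list of {"chrom": ..., "center": bp} dicts; each sweep
    is planted on the haplotypes of the blocks within its footprint
    before genotype assembly.
    """
    rng = np.random.default_rng(seed)
    sweeps = sweeps or []
    # one set of escape distances per sweep, shared across blocks so the
    # spatial escape pattern is coherent along the chromosome
    sweep_escapes = []
    for sw in sweeps:
        w = sw.get("width", sweep_width)
        dl = rng.exponential(w, size=n2 if n2 else 1)
        dr = rng.exponential(w, size=n2 if n2 else 1)
        dl[0] = dr[0] = np.inf
        sweep_escapes.append((dl, dr))
    all_sites: list[Site] = []
    samples = None
    populations = None
    for chrom, length in chrom_lengths.items():
        chrom_sweeps = [(s, sweep_escapes[i]) for i, s in enumerate(sweeps) if s["chrom"] == chrom]
        start = 0
        while start < length:
            bl = min(block_size, length - start)
            haps = simulate_region(model, n1, n2, bl, seed=rng)
            for sw, esc in chrom_sweeps:
                c_local = sw["center"] - start
                w = sw.get("width", sweep_width)
                if -8 * w <= c_local <= bl + 8 * w:
                    haps = _plant_sweep_impl(
                        haps,
                        center=float(c_local),
                        tau=sw.get("tau", sweep_tau),
                        mu=model.mu,
                        width=w,
                        seed=rng,
                        population="introduced",
                        escape=esc,
                    )
            t = haplotypes_to_genotypes(
                haps, missing_rate=missing_rate, seed=rng, chrom=chrom, pos_offset=start
            )
            if samples is None:
                samples, populations = t.samples, t.populations
            all_sites.extend(t.sites)
            start += bl
    return GenotypeTable(sites=all_sites, samples=samples or [], populations=populations or {})
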