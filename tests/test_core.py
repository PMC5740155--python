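"""Summary statistics against independent oracles and their invariants."""

import math
from itertools import combinations

import numpy as np
import pytest

from foundersweep.core import (
    JointSFS,
    Window,
    fst_window,
    harmonic_number,
    joint_sfs,
    nucleotide_diversity,
    site_allele_counts,
    sliding_windows,
    tajimas_d,
    watterson_theta,
    window_stats,
)
from foundersweep.simulate import DemographicModel, simulate_region

from conftest import make_table


# ---------------------------------------------------------------------------
# allele counting


class TestSiteAlleleCounts:
    def test_basic_counting(self):
        t = make_table([[0, 2], [1, 1], [-1, -1]])
        w = Window("chr1", 0, 100, 100)
        assert site_allele_counts(t, w, "pop1") == [(4, 2), (4, 2), (0, 0)]

    def test_empty_window(self):
        t = make_table([[0, 2]])
        assert site_allele_counts(t, Window("chr1", 1000, 2000, 1000), "pop1") == []

    def test_unknown_population(self):
        t = make_table([[0, 2]])
        with pytest.raises(KeyError):
            site_allele_counts(t, Window("chr1", 0, 100, 100), "nope")


# ---------------------------------------------------------------------------
# diversity


class TestNucleotideDiversity:
    def test_two_haplotypes_fraction(self):
        # two haplotypes differing at 3 of 10 callable sites -> pi = 0.3
        counts = [(2, 1)] * 3 + [(2, 0)] * 7
        assert nucleotide_diversity(counts, 10) == pytest.approx(0.3)

    def test_monomorphic(self):
        assert nucleotide_diversity([(16, 0)] * 5, 100) == 0.0

    def test_zero_callable_is_error(self):
        with pytest.raises(ValueError):
            nucleotide_diversity([(2, 1)], 0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_equals_exhaustive_pairwise_differences(self, seed):
        """pi must equal the mean per-site difference fraction over all
        haplotype pairs (exhaustive oracle, <= 8 haplotypes x <= 50 sites)."""
        rng = np.random.default_rng(seed)
        n_hap, n_sites, L = 8, 50, 1000
        mat = rng.integers(0, 2, size=(n_hap, n_sites))
        mat = mat[:, (mat.sum(0) > 0) & (mat.sum(0) < n_hap)]
        counts = [(n_hap, int(c)) for c in mat.sum(axis=0)]
        pi = nucleotide_diversity(counts, L)
        diffs = [
            (mat[a] != mat[b]).sum() / L for a, b in combinations(range(n_hap), 2)
        ]
        assert pi == pytest.approx(np.mean(diffs), rel=1e-12)


class TestWattersonTheta:
    def test_n2(self):
        assert watterson_theta(5, 2) == pytest.approx(5.0)

    def test_zero_sites(self):
        assert watterson_theta(0, 16) == 0.0

    def test_against_series(self):
        a1 = sum(1.0 / i for i in range(1, 16))
        assert watterson_theta(20, 16) == pytest.approx(20.0 / a1)

    def test_small_n_error(self):
        with pytest.raises(ValueError):
            watterson_theta(3, 1)


def _tajima_oracle(S, pi_total, n):
    """Independent transcription of the 1989 constants."""
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (pi_total - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


class TestTajimasD:
    def test_n2_degenerates_to_zero(self):
        assert tajimas_d(7, 7.0, 2) == 0.0

    def test_no_segregating_sites_undefined(self):
        assert tajimas_d(0, 0.0, 16) is None

    @pytest.mark.parametrize(
        "S,pi_total,n", [(20, 15.0, 16), (5, 1.2, 8), (44, 60.0, 32)]
    )
    def test_against_independent_constants(self, S, pi_total, n):
        assert tajimas_d(S, pi_total, n) == pytest.approx(
            _tajima_oracle(S, pi_total, n), rel=1e-12
        )


def _wc_single_locus_oracle(n1, a1, n2, a2):
    """Literal Weir & Cockerham (1984) variance components, one locus,
    two populations of allele counts."""
    r = 2
    p1, p2 = a1 / n1, a2 / n2
    nbar = (n1 + n2) / 2
    nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2)
    return a / (a + b)


class TestFst:
    def test_fixed_difference_is_one(self):
        assert fst_window([(16, 16)], [(16, 0)]) == pytest.approx(1.0)

    def test_shared_monomorphism_undefined(self):
        assert fst_window([(16, 0)] * 3, [(16, 0)] * 3) is None

    def test_single_locus_variance_component_oracle(self):
        assert fst_window([(16, 8)], [(16, 2)]) == pytest.approx(
            _wc_single_locus_oracle(16, 8, 16, 2), rel=1e-12
        )

    def test_hudson_estimator_selectable(self):
        val = fst_window([(16, 8)], [(16, 2)], estimator="hudson")
        hw = 0.5 * (2 * 0.5 * 0.5 * 16 / 15 + 2 * 0.125 * 0.875 * 16 / 15)
        hb = 0.5 * 0.875 + 0.125 * 0.5
        assert val == pytest.approx(1 - hw / hb)

    @pytest.mark.parametrize("seed", [0, 5])
    def test_invariant_to_allele_relabel_and_site_order(self, seed):
        rng = np.random.default_rng(seed)
        c1 = [(16, int(a)) for a in rng.integers(0, 17, size=20)]
        c2 = [(16, int(a)) for a in rng.integers(0, 17, size=20)]
        base = fst_window(c1, c2)
        flipped = fst_window([(n, n - a) for n, a in c1], [(n, n - a) for n, a in c2])
        perm = rng.permutation(20)
        shuffled = fst_window([c1[i] for i in perm], [c2[i] for i in perm])
        assert base == pytest.approx(flipped)
        assert base == pytest.approx(shuffled)


# ---------------------------------------------------------------------------
# windows


class TestSlidingWindows:
    def test_basic_starts(self):
        ws = sliding_windows({"c": 25_000})
        assert [w.start for w in ws if not w.partial] == [0, 5_000, 10_000, 15_000]

    def test_short_chrom_single_partial(self):
        ws = sliding_windows({"c": 9_999}, 10_000, 10_000)
        assert len(ws) == 1 and ws[0].partial and ws[0].end == 9_999

    def test_partials_flagged(self):
        ws = sliding_windows({"c": 12_000})
        assert [w.partial for w in ws] == [False, True, True]

    def test_step_larger_than_window_rejected(self):
        with pytest.raises(ValueError):
            sliding_windows({"c": 100}, 10, 20)

    def test_genome_window_count_convention(self):
        # non-overlapping 10 kb windows over the 1.08 Gb genome
        ws = sliding_windows({"genome": 1_081_644_591}, 10_000, 10_000)
        assert sum(1 for w in ws if not w.partial) == 108_164


# ---------------------------------------------------------------------------
# joint SFS


class TestJointSFS:
    def test_single_site_cell(self):
        g1 = [[1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 1]]
        t = make_table(
            g1, populations={"p1": list(range(8)), "p2": list(range(8, 16))}
        )
        sfs = joint_sfs(t, "p1", "p2", fold=False)
        assert sfs.data[1, 1] == 1 and sfs.data.sum() == 1

    def test_monomorphic_site_masked(self):
        t = make_table(
            [[0] * 16], populations={"p1": list(range(8)), "p2": list(range(8, 16))}
        )
        sfs = joint_sfs(t, "p1", "p2", fold=False)
        assert sfs.total() == 0 and sfs.mask[0, 0]

    def test_population_overlap_rejected(self):
        t = make_table([[0, 1, 2, 0]])
        t.populations = {"a": [0, 1], "b": [1, 2]}
        with pytest.raises(ValueError):
            joint_sfs(t, "a", "b")

    def test_fold_mirror_identity(self):
        rng = np.random.default_rng(0)
        arr = rng.integers(0, 9, size=(9, 9)).astype(float)
        a = JointSFS(arr.copy()).fold()
        b = JointSFS(arr[::-1, ::-1].copy()).fold()
        assert np.allclose(a.data[~a.mask], b.data[~b.mask])

    def test_unmasked_mass_counts_polymorphic_sites(self, fitted_model):
        haps = simulate_region(fitted_model, 8, 8, 50_000, seed=3)
        from foundersweep.simulate import haplotypes_to_genotypes

        t = haplotypes_to_genotypes(haps, seed=1)
        sfs = joint_sfs(t, "native", "introduced", fold=True)
        assert sfs.total() == haps.matrix.shape[1]

    def test_projection_preserves_mass(self):
        g = [[0, 1, -1, 0], [2, 1, 1, 0]]
        t = make_table(g, populations={"p1": [0, 1], "p2": [2, 3]})
        sfs = joint_sfs(t, "p1", "p2", fold=False, project_to=(2, 2))
        assert sfs.data.sum() == pytest.approx(2.0)


def test_window_stats_consistency(fitted_model):
    """The vectorised window pipeline must agree with the scalar ops."""
    haps = simulate_region(fitted_model, 16, 16, 20_000, seed=7)
    from foundersweep.simulate import haplotypes_to_genotypes

    t = haplotypes_to_genotypes(haps, seed=1)
    wins = sliding_windows({"chr1": 20_000})
    stats = window_stats(t, wins, "introduced", "native")
    w = stats[0]
    counts = site_allele_counts(t, w.window, "introduced")
    counts_o = site_allele_counts(t, w.window, "native")
    S = sum(1 for n, a in counts if 0 < a < n)
    assert w.S == S
    assert w.pi_site == pytest.approx(
        nucleotide_diversity(counts, w.window.callable_sites)
    )
    assert w.fst == pytest.approx(fst_window(counts, counts_o))
    pi_total = w.pi_site * w.window.callable_sites
    assert w.tajima_d == pytest.approx(tajimas_d(S, pi_total, 16))
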