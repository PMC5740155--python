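"""Coalescent generator: analytic neutral expectations, exchangeability,
sweep planting, genotype assembly, and an msprime cross-check."""

import numpy as np
import pytest

from foundersweep.core import harmonic_number, _pi_total, tajimas_d
from foundersweep.simulate import (
    DemographicModel,
    HaplotypeMatrix,
    haplotypes_to_genotypes,
    plant_sweep,
    simulate_genome,
    simulate_null_windows,
    simulate_region,
)


@pytest.fixture(scope="module")
def constant_model():
    return DemographicModel(N1=35_000, N2b=35_000, N2f=35_000, T=1e-9, mu=1e-8)


class TestModel:
    def test_growth_rate_sign_free(self):
        grow = DemographicModel(N1=100, N2b=10, N2f=1000, T=50, mu=0)
        decline = DemographicModel(N1=100, N2b=1000, N2f=10, T=50, mu=0)
        assert grow.g > 0 > decline.g

    @pytest.mark.parametrize(
        "bad", [dict(N2b=0.5), dict(T=0), dict(mu=-1e-9), dict(N1=0)]
    )
    def test_invalid_model_rejected(self, bad):
        kw = dict(N1=100, N2b=10, N2f=100, T=50, mu=1e-8)
        kw.update(bad)
        with pytest.raises(ValueError):
            DemographicModel(**kw)


class TestSimulateRegion:
    def test_zero_mutation_rate(self):
        m = DemographicModel(N1=1000, N2b=10, N2f=100, T=50, mu=0.0)
        h = simulate_region(m, 4, 4, 10_000, seed=1)
        assert h.matrix.shape == (8, 0)

    def test_deterministic_under_seed(self, fitted_model):
        a = simulate_region(fitted_model, 8, 8, 10_000, seed=42)
        b = simulate_region(fitted_model, 8, 8, 10_000, seed=42)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.matrix, b.matrix)

    def test_columns_are_segregating(self, fitted_model):
        h = simulate_region(fitted_model, 8, 8, 50_000, seed=2)
        tot = h.matrix.sum(axis=0)
        assert np.all((tot > 0) & (tot < 16))

    def test_too_few_samples_rejected(self, fitted_model):
        with pytest.raises(ValueError):
            simulate_region(fitted_model, 1, 0, 1000)

    def test_single_deme_neutral_segregating_sites(self, constant_model):
        """Constant size, one deme: E[S] = 4*N*mu*L*a1(n), E[pi] = 4*N*mu."""
        rng = np.random.default_rng(9)
        R, L, n = 1500, 10_000, 16
        S = np.zeros(R)
        pi = np.zeros(R)
        for r in range(R):
            h = simulate_region(constant_model, n, 0, L, seed=rng)
            a = h.matrix.sum(axis=0)
            S[r] = len(a)
            pi[r] = _pi_total([(n, int(x)) for x in a]) / L
        eS = 4 * 35_000 * 1e-8 * L * harmonic_number(n - 1)
        assert abs(S.mean() - eS) < 3 * S.std() / np.sqrt(R)
        assert abs(pi.mean() - 4 * 35_000 * 1e-8) < 3 * pi.std() / np.sqrt(R)

    def test_exchangeable_demes_have_zero_mean_fst(self, constant_model):
        sims = simulate_null_windows(constant_model, 1500, seed=4, n_blocks=1)
        fst = sims["fst"][~np.isnan(sims["fst"])]
        assert abs(fst.mean()) < 3 * fst.std() / np.sqrt(len(fst))

    def test_mean_s_matches_msprime(self, fitted_model):
        """Independent-simulator oracle for the two-deme founder model."""
        import msprime

        rng = np.random.default_rng(10)
        R, L = 800, 10_000
        mine = np.array(
            [
                simulate_region(fitted_model, 16, 16, L, seed=rng).matrix.shape[1]
                for _ in range(R)
            ]
        )
        dem = msprime.Demography()
        dem.add_population(name="native", initial_size=35_000)
        dem.add_population(name="intro", initial_size=1290, growth_rate=fitted_model.g)
        dem.add_population(name="anc", initial_size=35_000)
        dem.add_population_split(time=50, derived=["native", "intro"], ancestral="anc")
        theirs = []
        for ts in msprime.sim_ancestry(
            samples={"native": 8, "intro": 8},
            demography=dem,
            ploidy=2,
            sequence_length=L,
            num_replicates=R,
            random_seed=11,
        ):
            mts = msprime.sim_mutations(ts, rate=1e-8, discrete_genome=False)
            theirs.append(mts.num_sites)
        theirs = np.array(theirs)
        se = np.sqrt(mine.var() / R + np.var(theirs) / R)
        assert abs(mine.mean() - theirs.mean()) < 3 * se


class TestNullWindows:
    def test_empty_run_rejected(self, fitted_model):
        with pytest.raises(ValueError):
            simulate_null_windows(fitted_model, 0)

    def test_deterministic(self, fitted_model):
        a = simulate_null_windows(fitted_model, 50, seed=5)
        b = simulate_null_windows(fitted_model, 50, seed=5)
        assert np.array_equal(a, b)

    def test_bottleneck_skews_tajima_d_positive(self, fitted_model):
        sims = simulate_null_windows(fitted_model, 600, seed=6)
        d = sims["tajima_d"]
        assert np.nanmean(d) > 0.3

    def test_introduced_diversity_below_native(self, fitted_model):
        intro = simulate_null_windows(fitted_model, 400, seed=7)
        native = simulate_null_windows(fitted_model, 400, seed=7, scan_pop="native")
        assert intro["pi_10kb"].mean() < native["pi_10kb"].mean()

    def test_exchangeability_within_deme(self, fitted_model):
        """Permuting haplotypes within a deme leaves window statistics
        unchanged (statistics depend on counts only)."""
        h = simulate_region(fitted_model, 8, 8, 10_000, seed=8)
        rng = np.random.default_rng(0)
        perm = np.concatenate([rng.permutation(8), 8 + rng.permutation(8)])
        hp = HaplotypeMatrix(
            L=h.L,
            positions=h.positions,
            matrix=h.matrix[perm],
            pop_labels=np.asarray(h.pop_labels)[perm],
        )
        for pop in ("native", "introduced"):
            a0 = h.pop_rows(pop).sum(axis=0)
            a1 = hp.pop_rows(pop).sum(axis=0)
            assert np.array_equal(a0, a1)


class TestPlantSweep:
    def test_complete_sweep_erases_diversity(self, fitted_model):
        h = simulate_region(fitted_model, 8, 8, 10_000, seed=9)
        swept = plant_sweep(h, 5_000, tau=0.0, mu=1e-8, width=1e12, seed=1)
        intro = swept.pop_rows("introduced")
        assert np.all(intro == intro[0])

    def test_zero_width_is_identity(self, fitted_model):
        h = simulate_region(fitted_model, 8, 8, 10_000, seed=9)
        assert plant_sweep(h, 5_000, tau=5.0, mu=1e-8, width=0.0, seed=1) is h

    def test_center_outside_region_rejected(self, fitted_model):
        h = simulate_region(fitted_model, 8, 8, 10_000, seed=9)
        with pytest.raises(ValueError):
            plant_sweep(h, 20_000, tau=5.0, mu=1e-8, seed=1)

    def test_lowers_central_diversity(self, fitted_model):
        """Introduced pi at the sweep centre below the flank in >= 95% of
        replicates."""
        rng = np.random.default_rng(12)
        wins = 0
        R = 400
        for _ in range(R):
            h = simulate_region(fitted_model, 0, 16, 200_000, rho=19, seed=rng)
            swept = plant_sweep(h, 100_000, tau=25.0, mu=1e-8, seed=rng)
            intro = swept.pop_rows("introduced")
            a = intro.sum(axis=0)
            seg = (a > 0) & (a < 16)
            center = seg & (np.abs(swept.positions - 100_000) < 15_000)
            flank = seg & (np.abs(swept.positions - 100_000) > 70_000)
            pi_c = _pi_total([(16, int(x)) for x in a[center]])
            pi_f = _pi_total([(16, int(x)) for x in a[flank]])
            if pi_c < pi_f:
                wins += 1
        assert wins / R >= 0.95


class TestGenotypeAssembly:
    def test_alt_counts_preserved(self, fitted_model):
        h = simulate_region(fitted_model, 8, 8, 20_000, seed=13)
        t = haplotypes_to_genotypes(h, missing_rate=0.0, seed=1)
        for j, s in enumerate(t.sites):
            assert s.genotypes.sum() == h.matrix[:, j].sum()

    def test_full_missingness(self, fitted_model):
        h = simulate_region(fitted_model, 8, 8, 20_000, seed=13)
        t = haplotypes_to_genotypes(h, missing_rate=1.0, seed=1)
        assert all((s.genotypes == -1).all() for s in t.sites)

    def test_vcf_round_trip(self, fitted_model, tmp_path):
        from foundersweep.io import read_vcf, write_vcf

        h = simulate_region(fitted_model, 8, 8, 20_000, seed=14)
        t = haplotypes_to_genotypes(h, missing_rate=0.1, seed=2)
        p = tmp_path / "rt.vcf"
        write_vcf(t, p)
        back = read_vcf(p, popmap={s: p_ for p_, idx in t.populations.items() for s in [t.samples[i] for i in idx]})
        assert len(back.sites) == len(t.sites)
        for a, b in zip(t.sites, back.sites):
            assert np.array_equal(a.genotypes, b.genotypes)
            assert (a.chrom, a.pos, a.ref, a.alt) == (b.chrom, b.pos, b.ref, b.alt)


class TestSimulateGenome:
    def test_positions_strictly_increasing(self, fitted_model):
        t = simulate_genome(fitted_model, {"c1": 30_000, "c2": 20_000}, seed=15)
        for chrom in ("c1", "c2"):
            pos = [s.pos for s in t.chrom_sites(chrom)]
            assert pos == sorted(pos) and len(set(pos)) == len(pos)

    def test_deterministic(self, fitted_model):
        a = simulate_genome(fitted_model, {"c1": 30_000}, seed=16)
        b = simulate_genome(fitted_model, {"c1": 30_000}, seed=16)
        assert len(a.sites) == len(b.sites)
        assert all(
            np.array_equal(x.genotypes, y.genotypes) for x, y in zip(a.sites, b.sites)
        )
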