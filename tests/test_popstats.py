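"""Diversity, neutrality and divergence statistics against independent
oracles (brute force, textbook formulas, published golden cells)."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

import milletpop.popstats as ps


def random_matrix(rng, n, L, states=4):
    return rng.integers(0, states, size=(n, L)).astype(np.int8)


class TestDiversity:
    def test_two_sequences_one_difference(self):
        G = np.zeros((2, 100), np.int8)
        G[1, 17] = 1
        assert ps.nucleotide_diversity(G, L=100) == pytest.approx(0.01)

    def test_identical_sequences_have_zero_diversity(self):
        G = np.ones((8, 50), np.int8)
        assert ps.nucleotide_diversity(G, L=50) == 0.0
        assert ps.segregating_sites(G) == 0

    def test_pairwise_diversity_matches_brute_force(self, rng):
        G = random_matrix(rng, 10, 200)
        total = 0
        for i, j in itertools.combinations(range(10), 2):
            total += int((G[i] != G[j]).sum())
        expected = total / (10 * 9 / 2)
        assert ps.mean_pairwise_differences(G) == pytest.approx(expected)

    def test_singletons_counted_per_lone_state(self):
        # column with counts (1, n-1) -> 1 singleton; (1, 1, n-2) -> 2
        G = np.zeros((6, 2), np.int8)
        G[0, 0] = 1
        G[0, 1] = 1
        G[1, 1] = 2
        assert ps.singleton_count(G) == 3


class TestWatterson:
    def test_published_golden_cells(self):
        # per-site Watterson theta reconstructed from printed (S, n, L)
        assert round(ps.watterson_theta(27, 29, 1014), 4) == 0.0068
        assert round(ps.watterson_theta(6, 50, 1005), 4) == 0.0013

    def test_no_segregating_sites_gives_zero(self):
        assert ps.watterson_theta(0, 20, 500) == 0.0


class TestTajimasD:
    def test_zero_when_pi_equals_watterson_expectation(self):
        a1 = ps.harmonic(12)
        D = ps.tajimas_D(n=12, S=7, pi_total=7 / a1)
        assert D == pytest.approx(0.0, abs=1e-12)

    def test_printed_row_reconstruction(self):
        # n=29, S=10, per-site pi=0.0014 over 732 bp -> printed -1.9503;
        # the 4-d.p. rounding of pi bounds the reconstruction error
        D = ps.tajimas_D(n=29, S=10, pi_total=0.0014 * 732)
        assert D == pytest.approx(-1.9503, abs=0.1)

    def test_matches_textbook_formula_on_random_data(self, rng):
        # independent re-derivation from Tajima (1989) constants
        for _ in range(20):
            G = random_matrix(rng, rng.integers(5, 15), 40, states=2)
            n = G.shape[0]
            S = ps.segregating_sites(G)
            if S == 0:
                continue
            pi = ps.mean_pairwise_differences(G)
            a1 = sum(1 / i for i in range(1, n))
            a2 = sum(1 / i**2 for i in range(1, n))
            b1 = (n + 1) / (3 * (n - 1))
            b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
            c1, c2 = b1 - 1 / a1, b2 - (n + 2) / (a1 * n) + a2 / a1**2
            expect = (pi - S / a1) / np.sqrt(
                c1 / a1 * S + c2 / (a1**2 + a2) * S * (S - 1))
            assert ps.tajimas_D(G) == pytest.approx(expect, abs=1e-12)

    def test_undefined_without_segregating_sites(self):
        assert np.isnan(ps.tajimas_D(np.zeros((6, 10), np.int8)))

    def test_beta_approximation_p_value_is_two_tailed(self):
        p0 = ps.tajima_p_value(0.0, 20)
        assert 0.5 < p0 <= 1.0
        assert ps.tajima_p_value(-2.2, 20) < 0.05


class TestFuLi:
    def test_intermediate_frequency_variants_give_positive_Dstar(self):
        G = np.zeros((10, 6), np.int8)
        G[:5] = 1  # all variants at frequency 5/10, no singletons
        Dstar, Fstar = ps.fu_li_tests(G)
        assert Dstar > 0 and Fstar > 0

    def test_all_singletons_give_negative_Dstar(self):
        G = np.zeros((10, 6), np.int8)
        for j in range(6):
            G[j, j] = 1
        Dstar, Fstar = ps.fu_li_tests(G)
        assert Dstar < 0 and Fstar < 0

    def test_printed_row_reconstruction(self):
        # printed D* = -2.8589 / F* = -3.0169 for n=29, S=10; a singleton
        # count of 8 (recovered by inverting the printed D*) reproduces both
        Dstar, Fstar = ps.fu_li_tests(n=29, S=10, eta_s=8,
                                      pi_total=0.0014 * 732)
        assert Dstar == pytest.approx(-2.8589, abs=0.01)
        assert Fstar == pytest.approx(-3.0169, abs=0.05)

    def test_matches_independent_formula_evaluation(self, rng):
        # second implementation straight from the 1993 expressions
        for _ in range(15):
            n = int(rng.integers(5, 25))
            G = random_matrix(rng, n, 30, states=2)
            S = ps.segregating_sites(G)
            if S == 0:
                continue
            eta_s = ps.singleton_count(G)
            pi = ps.mean_pairwise_differences(G)
            a = sum(1 / i for i in range(1, n))
            b = sum(1 / i**2 for i in range(1, n))
            a1 = a + 1 / n
            c = 2 * (n * a - 2 * (n - 1)) / ((n - 1) * (n - 2))
            d = c + (n - 2) / (n - 1) ** 2 + 2 / (n - 1) * (
                1.5 - (2 * a1 - 3) / (n - 2) - 1 / n)
            vD = ((n / (n - 1)) ** 2 * b + a**2 * d
                  - 2 * n * a * (a + 1) / (n - 1) ** 2) / (a**2 + b)
            uD = (n / (n - 1)) * (a - n / (n - 1)) - vD
            Dstar = ((n / (n - 1)) * S - a * eta_s) / np.sqrt(
                uD * S + vD * S**2)
            vF = ((2 * n**3 + 110 * n**2 - 255 * n + 153)
                  / (9 * n**2 * (n - 1)) + 2 * (n - 1) * a / n**2
                  - 8 * b / n) / (a**2 + b)
            uF = ((4 * n**2 + 19 * n + 3 - 12 * (n + 1) * a1)
                  / (3 * n * (n - 1))) / a - vF
            Fstar = (pi - (n - 1) / n * eta_s) / np.sqrt(uF * S + vF * S**2)
            got_D, got_F = ps.fu_li_tests(G)
            assert got_D == pytest.approx(Dstar, abs=1e-12)
            assert got_F == pytest.approx(Fstar, abs=1e-12)


class TestHaplotypes:
    def test_identical_rows(self):
        G = np.ones((7, 20), np.int8)
        assert ps.haplotype_stats(G) == (1, 0.0)

    def test_all_distinct_rows(self):
        G = np.eye(10, dtype=np.int8)
        hap, hdiv = ps.haplotype_stats(G)
        assert hap == 10
        assert hdiv == pytest.approx(1.0)

    def test_invariant_to_sample_order(self, rng):
        G = random_matrix(rng, 12, 25)
        perm = rng.permutation(12)
        assert ps.haplotype_stats(G) == ps.haplotype_stats(G[perm])


class TestRm:
    @staticmethod
    def oracle(G):
        """Weighted-interval-scheduling DP over incompatible pairs —
        an independent algorithm for the maximum disjoint-interval count."""
        from milletpop.popstats import _incompatible_intervals
        iv = sorted(set(_incompatible_intervals(G, None)),
                    key=lambda p: p[1])
        best = 0
        ends = []
        counts = []
        for lo, hi in iv:
            prev = 0
            for e, c in zip(ends, counts):
                if e <= lo and c > prev:
                    prev = c
            ends.append(hi)
            counts.append(prev + 1)
            best = max(best, prev + 1)
        return best

    def test_trivial_cases(self):
        G = np.zeros((8, 3), np.int8)
        G[0, 0] = 1
        assert ps.min_recombination_Rm(G) == 0  # one segregating site
        four = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], np.int8)
        assert ps.min_recombination_Rm(four) == 1

    def test_matches_interval_dp_oracle_on_random_matrices(self, rng):
        for _ in range(60):
            G = random_matrix(rng, 8, 20, states=2)
            assert ps.min_recombination_Rm(G) == self.oracle(G)


class TestTwoPopulations:
    def test_fixed_differences_give_fst_one(self):
        G = np.zeros((8, 10), np.int8)
        G[4:] = 1
        pops = np.array(["wild"] * 4 + ["cultivated"] * 4)
        assert ps.fst(G, pops) == pytest.approx(1.0)

    def test_label_shuffle_centres_fst_at_zero(self, rng):
        G = random_matrix(rng, 20, 60, states=2)
        vals = []
        for _ in range(200):
            labels = np.array(["wild"] * 10 + ["cultivated"] * 10)
            rng.shuffle(labels)
            vals.append(ps.fst(G, labels))
        assert abs(np.mean(vals)) < 0.02

    def test_panmictic_pool_gives_near_zero_fst(self):
        # single-population coalescent sample split arbitrarily in two
        from milletpop.coalescent import simulate_standard_fast
        vals = []
        for i in range(30):
            hm = simulate_standard_fast(50, 80.0, 0.0, 1000.0, seed=500 + i)
            pops = np.array(["wild"] * 25 + ["cultivated"] * 25)
            vals.append(ps.fst(hm.genotypes, pops))
        assert abs(np.mean(vals)) < 0.05

    def test_partition_classifies_and_sums(self, rng):
        G = np.array([
            [0, 0, 0, 1],
            [0, 1, 0, 1],
            [1, 1, 0, 0],
            [1, 1, 0, 1],
        ], np.int8)
        pops = np.array(["wild", "wild", "cultivated", "cultivated"])
        shared, fixed, wsp, csp = ps.polymorphism_partition(G, pops)
        assert (shared, fixed, wsp, csp) == (0, 1, 1, 1)
        # bookkeeping identity on random data
        G = random_matrix(rng, 16, 80, states=2)
        pops = np.array(["wild"] * 8 + ["cultivated"] * 8)
        shared, fixed, wsp, csp = ps.polymorphism_partition(G, pops)
        seg_union = int((G != G[0]).any(axis=0).sum())
        assert shared + fixed + wsp + csp == seg_union

    def test_ks_divergence_direct_count(self):
        G = np.zeros((6, 500), np.int8)
        G[3:, :5] = 1  # two fixed haplotypes differing at 5 of 500 sites
        pops = np.array(["wild"] * 3 + ["cultivated"] * 3)
        assert ps.ks_divergence(G, pops, L=500) == pytest.approx(0.01)
        assert ps.ks_divergence(G, pops, L=500) == pytest.approx(
            ps.ks_divergence(G[::-1], pops[::-1], L=500))


class TestSFS:
    def test_single_singleton(self):
        G = np.zeros((10, 1), np.int8)
        G[0, 0] = 1
        out = ps.sfs(G, outgroup=np.zeros(1, np.int8))
        assert out.polarized and out.counts[0] == 1 and out.counts.sum() == 1

    def test_polarized_total_equals_biallelic_count(self, rng):
        G = random_matrix(rng, 12, 50, states=2)
        outgroup = G[0].copy()
        out = ps.sfs(G, outgroup=outgroup)
        counts, _ = np.unique(G, axis=0, return_counts=True)
        n_biallelic = sum(
            1 for j in range(50) if len(np.unique(G[:, j])) == 2)
        assert out.counts.sum() == n_biallelic

    def test_folded_when_no_outgroup(self):
        G = np.zeros((10, 2), np.int8)
        G[:3, 0] = 1
        G[:7, 1] = 1
        out = ps.sfs(G)
        assert not out.polarized
        assert out.counts[2] == 2  # both sites have minor count 3

    def test_neutral_spectrum_tracks_one_over_i(self):
        from milletpop.coalescent import simulate_standard_fast
        n = 10
        total = np.zeros(n - 1)
        for i in range(1500):
            hm = simulate_standard_fast(n, 2.0, 0.0, 100.0, seed=9000 + i)
            out = ps.sfs(hm.genotypes,
                         outgroup=np.zeros(hm.genotypes.shape[1], np.int8))
            total += out.counts
        expect = total.sum() * (1 / np.arange(1, n)) / sum(1 / np.arange(1, n))
        # 3 sigma under Poisson-ish counting error, coarse but seeded
        assert np.all(np.abs(total - expect) < 5 * np.sqrt(expect))


class TestCorrelation:
    def test_limits(self):
        x = np.array([1.0, 2, 3, 4])
        r, p = ps.theta_ks_correlation(x, 2 * x)
        assert r == pytest.approx(1.0)
        r, _ = ps.theta_ks_correlation(x, -3 * x)
        assert r == pytest.approx(-1.0)

    def test_matches_manual_formula(self, rng):
        x, y = rng.normal(size=9), rng.normal(size=9)
        r, p = ps.theta_ks_correlation(x, y)
        rr = np.corrcoef(x, y)[0, 1]
        tt = rr * np.sqrt(7 / (1 - rr**2))
        assert r == pytest.approx(rr)
        assert p == pytest.approx(2 * sps.t.sf(abs(tt), 7), rel=1e-6)

    def test_exclusion_set(self):
        x = np.array([1.0, 2, 3, 100])
        y = np.array([2.0, 4, 6, -50])
        r, _ = ps.theta_ks_correlation(x, y, exclude={"out"},
                                       loci=["a", "b", "c", "out"])
        assert r == pytest.approx(1.0)


class TestHKA:
    def test_proportional_data_has_near_zero_chi2(self):
        # polymorphism exactly proportional to divergence at every locus
        theta = np.array([4.0, 8.0, 2.0])
        nA = nB = 20
        aA = sum(1 / i for i in range(1, nA))
        T, f = 3.0, 1.0
        SA = theta * aA
        SB = f * theta * aA
        D = theta * (T + (1 + f) / 2)
        res = ps.hka_multilocus(SA, SB, D, nA, nB)
        assert res.chi2 == pytest.approx(0.0, abs=1e-8)
        assert res.theta == pytest.approx(theta, rel=1e-4)
        assert res.components.sum() == pytest.approx(res.chi2)

    def test_symmetric_two_locus_toy(self):
        res = ps.hka_multilocus([10, 10], [10, 10], [10, 10], 20, 20)
        assert res.components[0] == pytest.approx(res.components[1])

    def test_matches_grid_search_oracle(self):
        SA = np.array([12.0, 5.0])
        SB = np.array([6.0, 9.0])
        D = np.array([15.0, 8.0])
        res = ps.hka_multilocus(SA, SB, D, 16, 24)
        aA = sum(1 / i for i in range(1, 16))
        aB = sum(1 / i for i in range(1, 24))

        def resid(th1, th2, T, f):
            th = np.array([th1, th2])
            dscale = T + (1 + f) / 2
            r = [SA.sum() - (th * aA).sum(),
                 SB.sum() - f * (th * aB).sum(),
                 D.sum() - (th * dscale).sum(),
                 (SA[1] + SB[1] + D[1]) - th[1] * (aA + f * aB + dscale)]
            return sum(x * x for x in r)

        # coarse grid refined around the package solution
        best = None
        for th1 in np.linspace(1, 8, 24):
            for th2 in np.linspace(1, 8, 24):
                for T in np.linspace(0.5, 6, 24):
                    for f in np.linspace(0.2, 3, 24):
                        v = resid(th1, th2, T, f)
                        if best is None or v < best[0]:
                            best = (v, th1, th2, T, f)
        assert res.theta[0] == pytest.approx(best[1], abs=0.35)
        assert res.theta[1] == pytest.approx(best[2], abs=0.35)
        assert res.T == pytest.approx(best[3], abs=0.35)
        # the package's least-squares solve should fit at least as well
        assert resid(res.theta[0], res.theta[1], res.T, res.f) <= best[0] + 1e-9

    def test_degenerate_all_monomorphic_is_an_error(self):
        with pytest.raises(ValueError):
            ps.hka_multilocus([0, 0], [0, 0], [3, 3], 10, 10)


class TestInvariants:
    def test_statistics_invariant_to_orderings(self, rng):
        G = random_matrix(rng, 10, 40)
        rperm = rng.permutation(10)
        cperm = rng.permutation(40)
        assert ps.segregating_sites(G) == ps.segregating_sites(G[rperm])
        assert ps.mean_pairwise_differences(G) == pytest.approx(
            ps.mean_pairwise_differences(G[:, cperm]))

    def test_monomorphic_column_changes_nothing_but_length(self, rng):
        G = random_matrix(rng, 8, 30, states=2)
        G2 = np.hstack([G, np.ones((8, 1), np.int8)])
        assert ps.segregating_sites(G) == ps.segregating_sites(G2)
        assert ps.mean_pairwise_differences(G) == pytest.approx(
            ps.mean_pairwise_differences(G2))
        assert ps.haplotype_stats(G)[1] == pytest.approx(
            ps.haplotype_stats(G2)[1])

    def test_estimator_consistency_on_simulations(self):
        # mean pi and mean Watterson theta within 3 SE of truth, 2000 reps
        from milletpop.coalescent import simulate_standard_fast, summarize
        theta = 5.0
        n, L, reps = 20, 800.0, 2000
        pis, thetas = [], []
        a1 = sum(1 / i for i in range(1, n))
        for i in range(reps):
            hm = simulate_standard_fast(n, theta, 0.0, L, seed=31000 + i)
            s = summarize(hm)
            pis.append(s["pi"] * L)
            thetas.append(s["S"] / a1)
        for est in (pis, thetas):
            se = np.std(est) / np.sqrt(reps)
            assert abs(np.mean(est) - theta) < 3 * se + 1e-9
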