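"""Coalescent engines: theory checks, limits, determinism, and the
fast-engine vs msprime cross-validation."""

import numpy as np
import pytest
from scipy.stats import ks_2samp

import milletpop as mp
from milletpop.coalescent import (CULT, WILD, DemographicModel, LocusSpec,
                                  coalescent_to_generations,
                                  generations_to_coalescent,
                                  simulate_bottleneck,
                                  simulate_bottleneck_panel_fast,
                                  simulate_standard, simulate_standard_fast,
                                  summarize)

NA = 2.1e5


class TestStandardModel:
    def test_zero_theta_means_zero_sites(self):
        hm = simulate_standard(10, 0.0, 0.0, 500, seed=1)
        assert hm.genotypes.shape[1] == 0
        hm = simulate_standard_fast(10, 0.0, 0.0, 500, seed=1)
        assert hm.genotypes.shape[1] == 0

    @pytest.mark.parametrize("engine", ["msprime", "fast"])
    def test_watterson_and_pairwise_expectations(self, engine):
        theta, n, reps = 4.0, 25, 3000
        a1 = sum(1 / i for i in range(1, n))
        S, pi = [], []
        if engine == "msprime":
            it = simulate_standard(n, theta, theta, 1000, seed=3,
                                   num_replicates=reps)
        else:
            it = (simulate_standard_fast(n, theta, theta, 1000, seed=50_000 + i)
                  for i in range(reps))
        for hm in it:
            s = summarize(hm)
            S.append(s["S"])
            pi.append(s["pi"] * 1000)
        for est, truth in ((S, theta * a1), (pi, theta)):
            se = np.std(est) / np.sqrt(reps)
            assert abs(np.mean(est) - truth) < 3 * se

    def test_positions_strictly_increasing_and_columns_polymorphic(self):
        hm = simulate_standard_fast(12, 8.0, 4.0, 800, seed=9)
        assert np.all(np.diff(hm.positions) > 0)
        assert np.all((hm.genotypes.sum(0) > 0)
                      & (hm.genotypes.sum(0) < 12))

    def test_fixed_seed_is_bit_identical(self):
        a = simulate_standard_fast(15, 6.0, 3.0, 700, seed=77)
        b = simulate_standard_fast(15, 6.0, 3.0, 700, seed=77)
        assert np.array_equal(a.genotypes, b.genotypes)
        assert np.array_equal(a.positions, b.positions)
        c = simulate_standard(15, 6.0, 3.0, 700, seed=78)
        d = simulate_standard(15, 6.0, 3.0, 700, seed=78)
        assert np.array_equal(c.genotypes, d.genotypes)


class TestTimeScaling:
    def test_conversion_round_trips(self):
        for t in (0.0, 137.5, 8000.0, 2.3e6):
            tau = generations_to_coalescent(t, NA)
            assert coalescent_to_generations(tau, NA) == pytest.approx(
                t, abs=1e-9 * max(t, 1))


class TestBottleneckModel:
    def spec(self, n_wild=20, n_cult=30, L=600):
        return LocusSpec("X", L, L, n_wild, n_cult)

    def test_inconsistent_times_rejected(self):
        with pytest.raises(ValueError):
            DemographicModel(N_a=NA, t2=1000, d=2000, k=1.0)

    def test_severe_bottleneck_reduces_cultivated_diversity(self):
        model = DemographicModel.from_theta(
            0.006, rho_over_theta=1.0, t2=8000, d=1000, k=0.1)
        Sw, Sc = [], []
        for i in range(800):
            hm = simulate_bottleneck_panel_fast(model, [self.spec()],
                                                seed=2000 + i)[0]
            Sw.append(summarize(hm, WILD)["S"])
            Sc.append(summarize(hm, CULT)["S"])
        assert np.mean(Sc) < 0.8 * np.mean(Sw)

    def test_no_bottleneck_limit_equalizes_diversity(self):
        # huge k (no founder loss) and an old split with no migration:
        # both populations show wild-level diversity
        model = DemographicModel.from_theta(
            0.006, rho_over_theta=0.0, t2=4 * NA, d=100, k=1e4)
        Sw, Sc = [], []
        for i in range(600):
            hm = simulate_bottleneck_panel_fast(model, [self.spec()],
                                                seed=4000 + i)[0]
            Sw.append(summarize(hm, WILD)["S"])
            Sc.append(summarize(hm, CULT)["S"])
        assert np.mean(Sc) == pytest.approx(np.mean(Sw), rel=0.1)

    def test_recent_split_behaves_panmictic(self):
        from milletpop.popstats import fst
        model = DemographicModel.from_theta(
            0.006, rho_over_theta=0.0, t2=2.0, d=1.0, k=5.0,
            m12=0.0, m21=0.0)
        vals = []
        for i in range(300):
            hm = simulate_bottleneck_panel_fast(model, [self.spec()],
                                                seed=6000 + i)[0]
            if hm.genotypes.shape[1] == 0:
                continue
            pops = np.where(hm.pops == WILD, "wild", "cultivated")
            vals.append(fst(hm.genotypes, pops))
        assert abs(np.mean(vals)) < 0.05

    def test_wild_marginal_matches_standard_model(self):
        # isolated populations (no migration, deep split): the wild sample's
        # S distribution must match the constant-size model (two-sample KS)
        model = DemographicModel.from_theta(
            0.006, rho_over_theta=1.0, t2=12000, d=1000, k=1.0)
        theta_loc = model.theta_site * 600
        S_b = []
        for i in range(2000):
            hm = simulate_bottleneck_panel_fast(
                model.with_(m12=0.0, m21=0.0), [self.spec()],
                seed=8000 + i)[0]
            S_b.append(summarize(hm, WILD)["S"])
        S_s = [summarize(simulate_standard_fast(
            20, theta_loc, theta_loc, 600, seed=30000 + i))["S"]
            for i in range(2000)]
        assert ks_2samp(S_b, S_s).pvalue > 0.01


class TestEngineCrossValidation:
    """The numba Hudson engine against msprime on the same demography."""

    def test_two_population_summaries_agree(self):
        model = DemographicModel(N_a=NA, mu=7e-9, rho_over_theta=1.0,
                                 t2=8000, d=1000, k=0.6, m12=5.0, m21=5.0)
        spec = LocusSpec("X", 800, 800, 25, 40)
        ms = {"Sw": [], "Sc": [], "pw": [], "pc": []}
        for hm in simulate_bottleneck(model, spec, seed=17,
                                      num_replicates=1200):
            w, c = summarize(hm, WILD), summarize(hm, CULT)
            ms["Sw"].append(w["S"])
            ms["Sc"].append(c["S"])
            ms["pw"].append(w["pi"])
            ms["pc"].append(c["pi"])
        fast = {"Sw": [], "Sc": [], "pw": [], "pc": []}
        for i in range(1200):
            hm = simulate_bottleneck_panel_fast(model, [spec],
                                                seed=7000 + i)[0]
            w, c = summarize(hm, WILD), summarize(hm, CULT)
            fast["Sw"].append(w["S"])
            fast["Sc"].append(c["S"])
            fast["pw"].append(w["pi"])
            fast["pc"].append(c["pi"])
        for key in ms:
            assert ks_2samp(ms[key], fast[key]).pvalue > 0.005, key


class TestSummarize:
    def test_trivial_monomorphic_matrix(self):
        hm = mp.HaplotypeMatrix(np.zeros((8, 0), np.int8), np.empty(0),
                                np.zeros(8, np.int8), 500.0)
        s = summarize(hm)
        assert (s["S"], s["Hap"], s["Hdiv"]) == (0, 1, 0.0)

    def test_cross_path_equality_with_alignment_statistics(self, tmp_path):
        """The simulation summary equals the observed-data pipeline run on
        the same matrix rendered as a FASTA alignment."""
        from milletpop.synthetic import realize_nucleotides
        hm = simulate_standard_fast(12, 8.0, 4.0, 400, seed=21)
        seq, _, _ = realize_nucleotides(
            hm, 400, np.random.default_rng(0))
        with open(tmp_path / "m.fasta", "w") as fh:
            for i in range(12):
                fh.write(f">s{i}\n{seq[i].tobytes().decode()}\n")
        with open(tmp_path / "pop.tsv", "w") as fh:
            for i in range(12):
                fh.write(f"s{i}\twild\n")
        aln = mp.read_alignment(tmp_path / "m.fasta",
                                popmap_path=tmp_path / "pop.tsv")
        fa = mp.filter_sites(aln)
        s_sim = summarize(hm)
        assert mp.segregating_sites(fa, "wild") == s_sim["S"]
        assert mp.nucleotide_diversity(fa, "wild") == pytest.approx(
            s_sim["pi"])
        hap, hdiv = mp.haplotype_stats(fa, "wild")
        assert (hap, hdiv) == (s_sim["Hap"], pytest.approx(s_sim["Hdiv"]))

    def test_invariant_to_row_order_within_population(self):
        hm = simulate_standard_fast(14, 6.0, 2.0, 500, seed=33)
        perm = np.random.default_rng(0).permutation(14)
        hm2 = mp.HaplotypeMatrix(hm.genotypes[perm], hm.positions,
                                 hm.pops[perm], hm.L)
        a, b = summarize(hm), summarize(hm2)
        assert a == b
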