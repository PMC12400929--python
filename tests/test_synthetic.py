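import numpy as np
import pandas as pd
import pytest
from scipy.integrate import solve_ivp

from halovar.synthetic import (
    EcologyParams,
    PAPER_ANI_TARGETS,
    heaps_presence,
    simulate_ecology,
    simulate_genomovar_genomes,
    simulate_reads,
    simulate_viral_contigs,
    star_rates_from_ani,
)


class TestGenomeSimulator:
    def test_zero_divergence_gives_identical_genomes(self):
        targets = pd.DataFrame(100.0, index=["a", "b"], columns=["a", "b"])
        genomes, truth = simulate_genomovar_genomes(
            ancestor_len=60_000,
            n_genomovars=2,
            strains_per_genomovar=2,
            ani_targets=targets,
            shared_fraction_target=100.0,
            strain_divergence=0.0,
            strain_gene_loss=0.0,
            seed=0,
        )
        assert len({g.sequence for g in genomes}) == 1
        assert truth.realized_identity(genomes[0].id, genomes[-1].id) == 100.0

    def test_two_genomovar_target_ani_realized(self):
        """Planted substitutions reproduce a 99.0% pairwise ANI target
        within 0.1 points on 200 kb genomes (counted from the truth)."""
        targets = pd.DataFrame([[100.0, 99.0], [99.0, 100.0]], index=["a", "b"], columns=["a", "b"])
        _, truth = simulate_genomovar_genomes(
            ancestor_len=200_000, n_genomovars=2, strains_per_genomovar=1,
            ani_targets=targets, seed=5,
        )
        assert truth.realized_identity("a_s1", "b_s1") == pytest.approx(99.0, abs=0.1)

    def test_paper_targets_realized_within_fit_tolerance(self, four_genomovar_panel):
        _, truth = four_genomovar_panel
        for a, b in [("Hqrw1", "Hqrw2"), ("Hqrw1", "Hqrw4"), ("Hqrw2", "Hqrw3")]:
            target = truth.ani_targets.loc[a, b]
            realized = truth.realized_identity(f"{a}_s1", f"{b}_s1")
            # the published target matrix is star-additive only to ~0.08
            assert realized == pytest.approx(target, abs=0.2)

    def test_within_genomovar_ani_above_cut(self, four_genomovar_panel):
        _, truth = four_genomovar_panel
        assert truth.realized_identity("Hqrw1_s1", "Hqrw1_s2") > 99.6

    def test_shared_fraction_target_exact(self):
        genomes, truth = simulate_genomovar_genomes(
            ancestor_len=200_000, strains_per_genomovar=1, shared_fraction_target=85.0,
            strain_gene_loss=0.0, seed=7,
        )
        one_gene_pct = 100.0 / len(truth.gene_inventory["Hqrw1_s1"])
        for a, b in [("Hqrw1_s1", "Hqrw2_s1"), ("Hqrw3_s1", "Hqrw4_s1")]:
            assert truth.shared_fraction(a, b) == pytest.approx(85.0, abs=one_gene_pct)

    def test_non_embeddable_targets_rejected(self):
        bad = pd.DataFrame(
            [[100.0, 99.9, 98.0], [99.9, 100.0, 99.9], [98.0, 99.9, 100.0]],
            index=list("abc"), columns=list("abc"),
        )
        with pytest.raises(ValueError, match="triple"):
            simulate_genomovar_genomes(n_genomovars=3, ani_targets=bad)

    def test_star_rates_reproduce_additive_distances(self):
        d = np.array([0.3, 0.4, 0.5, 0.8])
        ani = 100.0 - (d[:, None] + d[None, :])
        np.fill_diagonal(ani, 100.0)
        fitted = star_rates_from_ani(ani)
        assert np.allclose(fitted, d, atol=1e-9)


class TestReadSimulator:
    def test_error_free_reads_are_exact_substrings(self):
        genomes, _ = simulate_genomovar_genomes(
            ancestor_len=60_000, n_genomovars=1, strains_per_genomovar=1, seed=1
        )
        reads, truth = simulate_reads(genomes, [1.0], n_reads=200, err_rate=0.0, seed=2)
        seq = genomes[0].sequence
        for (rid, read), row in zip(reads, truth.itertuples()):
            assert seq[row.start : row.start + 150] == read

    def test_source_counts_match_multinomial(self):
        genomes, _ = simulate_genomovar_genomes(
            ancestor_len=60_000, n_genomovars=3, strains_per_genomovar=1, seed=1
        )
        n = 30_000
        weights = np.array([0.6, 0.3, 0.1])
        _, truth = simulate_reads(genomes, weights, n_reads=n, seed=3)
        counts = truth.genome.value_counts()
        lens = np.array([len(g) for g in genomes], dtype=float)
        p = weights * lens / (weights * lens).sum()
        for genome, pi in zip(genomes, p):
            sd = np.sqrt(n * pi * (1 - pi))
            assert abs(counts[genome.id] - n * pi) < 3 * sd

    def test_error_rate_gives_expected_mismatches(self):
        genomes, _ = simulate_genomovar_genomes(
            ancestor_len=60_000, n_genomovars=1, strains_per_genomovar=1, seed=1
        )
        n = 20_000
        _, truth = simulate_reads(genomes, [1.0], n_reads=n, err_rate=0.01, seed=4)
        expected = 150 * 0.01
        sd = np.sqrt(expected / n)  # CLT on the mean
        assert truth.n_errors.mean() == pytest.approx(expected, abs=4 * sd)

    def test_bad_inputs_rejected(self):
        genomes, _ = simulate_genomovar_genomes(
            ancestor_len=60_000, n_genomovars=1, strains_per_genomovar=1, seed=1
        )
        with pytest.raises(ValueError):
            simulate_reads(genomes, [1.0], n_reads=0)
        with pytest.raises(ValueError):
            simulate_reads(genomes, [0.0], n_reads=10)


class TestEcology:
    def test_zero_infection_decouples_hosts_and_viruses(self):
        p = EcologyParams(infection=0.0, immigration=0.0, noise_sd=0.0)
        eco = simulate_ecology(regime="D20", params=p, seed=0)
        # viruses decay to zero without hosts to infect
        assert eco.cohort_true.iloc[:, -1].max() < 1e-10
        # hosts follow bounded logistic growth
        assert (eco.host_true.to_numpy() >= 0).all()
        assert eco.host_true.to_numpy().sum(axis=0).max() <= EcologyParams().K * 1.05

    def test_trajectories_nonnegative_and_reproducible(self):
        a = simulate_ecology(seed=11)
        b = simulate_ecology(seed=11)
        assert (a.virus_abundance.to_numpy() >= 0).all()
        assert (a.host_abundance.to_numpy() >= 0).all()
        pd.testing.assert_frame_equal(a.virus_abundance, b.virus_abundance)
        pd.testing.assert_frame_equal(a.host_abundance, b.host_abundance)

    def test_cohort_members_mutually_correlated(self):
        eco = simulate_ecology(seed=3, noise_sd=0.2)
        for cohort in set(eco.cohort_membership.values()):
            members = [v for v, c in eco.cohort_membership.items() if c == cohort]
            X = np.log(eco.virus_abundance.loc[members].to_numpy() + 1e-12)
            cc = np.corrcoef(X)
            off = cc[np.triu_indices(len(members), k=1)]
            assert off.min() >= 0.8

    def test_intense_disturbance_suppresses_salt_loving_genomovar(self):
        """Under the D13 regime the genomovar with negative growth below
        ~32% salts declines from the first to the last quarter."""
        eco = simulate_ecology(regime="D13", seed=0, noise_sd=0.0)
        h1 = eco.host_true.loc["Hqrw1"].to_numpy()
        q = len(h1) // 4
        assert h1[-q:].mean() < h1[:q].mean()

    def test_single_pair_matches_reference_ode_solver(self):
        """One host, one cohort, constant salinity: the daily Euler update
        tracks a reference ODE integration and the virus lags the host."""
        p = EcologyParams(
            rmax=(0.15,), opt_s=(36.0,), w_s=(10.0,), opt_t=(22.0,), w_t=(50.0,),
            H0=(10.0,), V0=5.0, infection=1e-3, burst=8.0, decay=0.15,
            immigration=0.0, T_days=300, n_samples=300, dilution_interval=10_000,
            t_amp=0.0, votus_per_cohort=(3,), noise_sd=0.0,
        )
        eco = simulate_ecology(regime="D20", params=p, seed=0)
        r = 0.15  # constant environment at the optimum
        def rhs(t, y):
            H, V = y
            return [r * H * (1 - H / p.K) - p.infection * H * V,
                    p.burst * p.infection * H * V - p.decay * V]
        ref = solve_ivp(rhs, (0, 299), [10.0, 5.0], t_eval=np.arange(300), rtol=1e-8)
        H_e = eco.host_true.iloc[0].to_numpy()
        H_r = ref.y[0]
        assert np.corrcoef(H_e, H_r)[0, 1] > 0.9
        # predator follows prey: host-virus cross-correlation peaks at a
        # positive lag in both integrators
        V_e = eco.cohort_true.iloc[0].to_numpy()
        def best_lag(h, v, max_lag=60):
            cors = [np.corrcoef(h[: len(h) - k], v[k:])[0, 1] for k in range(max_lag)]
            return int(np.argmax(cors)), max(cors)
        lag_e, cor_e = best_lag(H_e, V_e)
        lag_r, cor_r = best_lag(H_r, ref.y[1])
        assert cor_e > 0.5 and cor_r > 0.5
        assert lag_e > 0 and abs(lag_e - lag_r) <= 10

    def test_overflow_reported_with_timepoint(self):
        p = EcologyParams(infection=5.0, burst=1e6, decay=0.0)
        with pytest.raises(ValueError, match="day"):
            simulate_ecology(params=p, seed=0)


class TestViralContigs:
    def test_variants_and_decoys(self):
        contigs, truth = simulate_viral_contigs(["v1", "v2"], variants_per_votu=2, n_short=3, seed=0)
        assert len(contigs) == 2 * 3 + 3
        assert sum(1 for c in contigs if len(c) < 5000) >= 3
        assert set(truth.values()) == {"v1", "v2"}


class TestHeapsPresence:
    def test_expected_curve_is_power_law(self):
        M = heaps_presence(0.5, n_genomes=40, seed=0)
        # expected rarefaction at k = N equals scale * N^gamma
        assert M.shape[1] == pytest.approx(500 * 40 ** 0.5, rel=0.02)
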