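import dataclasses

import numpy as np
import pytest
from scipy import stats

from phenocoop import abm
from phenocoop.fixation import FixationQuery, fixation_probability
from phenocoop.model_core import ModelParams, Strain, payoff_diff_phenotype


class TestComputePayoffs:
    def test_small_subpopulation_pays_only_capacitor_cost(self, study_params):
        # 4 individuals on one phenotype with g = 5: no games anywhere
        pop = abm.Population(
            phenotype=np.array([1, 1, 1, 1]),
            strategy=np.array([1, 1, 0, 1]),
            K=np.array([2, 3, 1, 5]),
        )
        np.testing.assert_allclose(
            abm.compute_payoffs(pop, study_params), -study_params.theta * pop.K
        )

    def test_pure_cooperator_subpopulation(self, study_params):
        n = 10
        pop = abm.Population(
            phenotype=np.ones(n, dtype=int),
            strategy=np.ones(n, dtype=int),
            K=np.full(n, 4),
        )
        expected = study_params.chi(n) * (study_params.r - 1) - study_params.theta * 4
        np.testing.assert_allclose(abm.compute_payoffs(pop, study_params), expected)

    def test_two_phenotype_population_matches_pairwise_formulas(self, study_params):
        # i mutants (C, K=3) on phenotype 2 vs N - i residents (D, K=1) on
        # phenotype 1 must reproduce the analytic two-subpopulation payoffs
        N = study_params.N
        for i in (2, 5, 17, 35):
            pop = abm.Population(
                phenotype=np.array([2] * i + [1] * (N - i)),
                strategy=np.array([1] * i + [0] * (N - i)),
                K=np.array([3] * i + [1] * (N - i)),
            )
            payoffs = abm.compute_payoffs(pop, study_params)
            P_A, P_B = payoff_diff_phenotype(i, 1, 0, 3, 1, study_params)
            np.testing.assert_allclose(payoffs[:i], P_A)
            np.testing.assert_allclose(payoffs[i:], P_B)

    def test_sampled_payoffs_are_unbiased(self, study_params):
        # the game-sampling realization must average to the expected payoffs
        N = study_params.N
        pop = abm.Population(
            phenotype=np.array([1] * 12 + [2] * 20 + [3] * 8),
            strategy=np.array([1, 0] * 6 + [1] * 15 + [0] * 5 + [0] * 8),
            K=np.array([3] * 12 + [5] * 20 + [4] * 8),
        )
        expected = abm.compute_payoffs(pop, study_params)
        total = np.zeros(N)
        n_draws = 20000
        members = np.empty(N, dtype=np.int64)
        out = np.empty(N)
        np.random.seed(2024)
        for _ in range(n_draws):
            abm._sampled_payoffs(
                pop.phenotype.astype(np.int64), pop.strategy.astype(np.int64),
                pop.K.astype(np.int64), N, study_params.g, study_params.r,
                study_params.c, study_params.theta, study_params.chi_slope,
                study_params.M, out, members,
            )
            total += out
        np.testing.assert_allclose(total / n_draws, expected, atol=0.05)


class TestMoranStep:
    def test_population_size_and_capacitor_invariants(self, small_params, rng):
        pop = abm.Population.random(small_params, rng)
        for _ in range(500):
            abm.moran_step(pop, small_params, rng)
        assert len(pop.phenotype) == small_params.N
        assert np.all(pop.phenotype >= 1)
        assert np.all(pop.phenotype <= pop.K)
        assert np.all(pop.K <= small_params.M)
        assert pop.step_count == 500

    def test_no_mutation_monomorphic_state_absorbing(self, small_params, rng):
        params = dataclasses.replace(small_params, mu=0.0)
        pop = abm.Population.monomorphic(Strain(1, 3), 2, params)
        for _ in range(200):
            abm.moran_step(pop, params, rng)
        assert np.all(pop.strategy == 1)
        assert np.all(pop.K == 3)
        assert np.all(pop.phenotype == 2)

    def test_full_mutation_draws_match_stated_scheme(self):
        # with mu = 1 every replacement is a fresh mutant, so the standing
        # population is an iid sample of the mutation scheme: strategy and
        # volume jointly uniform, phenotype uniform inside the capacitor
        params = ModelParams(N=20, mu=1.0, M=5, beta=0.1, g=3, r=2.0)
        rng = np.random.default_rng(31)
        pop = abm.Population.random(params, rng)
        strat_K = np.zeros((2, params.M))
        pheno_given_K3 = np.zeros(3)
        n_snapshots = 1500
        for _ in range(n_snapshots):
            for _ in range(3 * params.N):
                abm.moran_step(pop, params, rng)
            for s, k, h in zip(pop.strategy, pop.K, pop.phenotype):
                strat_K[s, k - 1] += 1
                if k == 3:
                    pheno_given_K3[h - 1] += 1
        counts = strat_K.ravel()
        chi2 = stats.chisquare(counts).statistic
        # 10 uniform cells; snapshots are slightly correlated, so test at a
        # conservative threshold far in the tail of chi2(9)
        assert chi2 / counts.sum() < 0.01
        p_pheno = stats.chisquare(pheno_given_K3).pvalue
        assert p_pheno > 1e-4


class TestRun:
    def test_neutral_symmetric_mutation_half_cooperators(self):
        params = ModelParams(beta=0.0, mu=0.5)
        s = abm.run(params, n_steps=400_000, burn_in=40_000, seed=9)
        assert s.mean_cooperator_fraction == pytest.approx(0.5, abs=0.01)

    def test_neutral_strain_occupancy_uniform(self):
        # theta = beta = 0: all strains equivalent, so mean volume per
        # strategy matches the uniform mean (M + 1) / 2 and cooperators are
        # half the population
        params = ModelParams(beta=0.0, theta=0.0, mu=0.5, M=10)
        s = abm.run(params, n_steps=600_000, burn_in=60_000, seed=4)
        assert s.mean_cooperator_fraction == pytest.approx(0.5, abs=0.01)
        assert s.mean_K_by_strategy["C"] == pytest.approx(5.5, abs=0.1)
        assert s.mean_K_by_strategy["D"] == pytest.approx(5.5, abs=0.1)

    def test_seeded_runs_bit_reproducible(self, small_params):
        a = abm.run(small_params, n_steps=50_000, burn_in=5_000, seed=12)
        b = abm.run(small_params, n_steps=50_000, burn_in=5_000, seed=12)
        assert a.mean_cooperator_fraction == b.mean_cooperator_fraction
        assert a.mean_K_by_strategy == b.mean_K_by_strategy
        assert a.state_occupancy == b.state_occupancy
        c = abm.run(small_params, n_steps=50_000, burn_in=5_000, seed=13)
        assert c.mean_cooperator_fraction != a.mean_cooperator_fraction

    def test_occupancy_fractions_well_formed(self, small_params):
        s = abm.run(small_params, n_steps=60_000, burn_in=10_000, seed=2)
        for strat in ("C", "D"):
            total = sum(v for k, v in s.state_occupancy.items() if k.startswith(strat))
            assert 0.0 <= total <= 1.0 + 1e-12

    def test_trajectory_written_and_consistent(self, small_params, tmp_path):
        import pandas as pd

        path = tmp_path / "traj.tsv"
        abm.run(small_params, n_steps=20_000, burn_in=0, seed=5, thin=1000,
                traj_path=str(path))
        df = pd.read_csv(path, sep="\t")
        assert list(df.columns) == [
            "step", "n_cooperators", "mean_K_C", "mean_K_D", "n_subpopulations"
        ]
        assert len(df) == 20
        assert df["n_cooperators"].between(0, small_params.N).all()
        assert df["n_subpopulations"].between(1, small_params.N).all()

    def test_rejects_bad_step_counts(self, small_params):
        with pytest.raises(ValueError):
            abm.run(small_params, n_steps=100, burn_in=100, seed=1)


class TestFixationAgainstAnalytics:
    @pytest.mark.parametrize(
        "mutant,resident,same",
        [
            (Strain(1, 3), Strain(0, 2), True),
            (Strain(1, 3), Strain(0, 2), False),
            (Strain(0, 2), Strain(1, 4), False),
        ],
    )
    def test_empirical_fixation_matches_analytic(self, small_params, mutant, resident, same):
        # expected-payoff mode uses the exact payoff functions of the
        # analytic Moran chain, so the empirical frequency is an unbiased
        # estimate of the product-formula fixation probability
        rho = fixation_probability(FixationQuery(mutant, resident, same, small_params))
        n_reps = 20_000
        freq = abm.simulate_pairwise_fixation(
            mutant, resident, same, small_params, n_reps=n_reps, seed=314,
        )
        se = np.sqrt(rho * (1 - rho) / n_reps)
        assert abs(freq - rho) < 3 * se
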