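import math

import numpy as np
import pytest

import beaconkit as bk
from beaconkit import attack_sim as sim
from beaconkit.errors import DomainError


class TestSimulatePopulation:
    def test_seed_determinism(self):
        a = bk.simulate_population(10, 100, (0.5, 0.5), f_min=0.001, seed=7)
        b = bk.simulate_population(10, 100, (0.5, 0.5), f_min=0.001, seed=7)
        assert np.array_equal(a.genotypes, b.genotypes)
        assert np.array_equal(a.frequencies, b.frequencies)

    def test_truncation_collapse_at_half(self):
        population = bk.simulate_population(10, 50, f_min=0.5, seed=1)
        assert np.all(population.frequencies == 0.5)

    def test_mean_dosage_within_binomial_error(self):
        population = bk.simulate_population(10_000, 3, f_min=0.5, seed=2)
        mean_dosage = population.genotypes.mean(axis=0)
        sd_of_mean = math.sqrt(2 * 0.5 * 0.5 / 10_000)
        assert np.all(np.abs(mean_dosage - 1.0) < 3 * sd_of_mean)

    def test_frequency_bounds_and_dtype(self):
        population = bk.simulate_population(50, 500, f_min=0.01, seed=3)
        assert population.frequencies.min() >= 0.01
        assert population.frequencies.max() <= 0.5
        assert set(np.unique(population.genotypes)) <= {0, 1, 2}

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_individuals": 0, "n_snps": 10},
            {"n_individuals": 10, "n_snps": 0},
            {"n_individuals": 10, "n_snps": 10, "afs_shape": (0.0, 1.0)},
            {"n_individuals": 10, "n_snps": 10, "f_min": 0.0},
            {"n_individuals": 10, "n_snps": 10, "f_min": 0.6},
        ],
    )
    def test_degenerate_parameters_rejected(self, kwargs):
        with pytest.raises(DomainError):
            bk.simulate_population(**kwargs)


def _crafted_population(genotypes, frequencies=None):
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n, m = genotypes.shape
    return sim.SyntheticPopulation(
        n_individuals=n,
        n_snps=m,
        frequencies=np.asarray(frequencies if frequencies is not None else [0.1] * m),
        genotypes=genotypes,
        seed=0,
    )


class TestBeaconOracle:
    def test_single_member_direct_readout(self):
        population = _crafted_population([[2, 0, 1]])
        oracle = bk.beacon_from_population(population, [0])
        assert [oracle.query_site(i) for i in range(3)] == [True, False, True]

    def test_empty_membership_answers_all_no(self):
        population = _crafted_population([[2, 0, 1], [1, 1, 0]])
        oracle = bk.beacon_from_population(population, [])
        assert not oracle.presence.any()

    def test_matches_bruteforce_or_over_random_instances(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            population = bk.simulate_population(20, 80, seed=int(rng.integers(1e6)))
            members = rng.choice(20, size=7, replace=False)
            oracle = bk.beacon_from_population(population, members)
            brute = np.zeros(80, dtype=bool)
            for member in members:  # brute-force OR over member dosages
                brute |= population.genotypes[member] > 0
            assert np.array_equal(oracle.presence, brute)

    def test_member_ids_validated(self):
        population = _crafted_population([[1, 0]])
        with pytest.raises(DomainError):
            bk.beacon_from_population(population, [5])


class TestStatistics:
    def test_lrt_single_query_hand_values(self):
        # yes: ln((1-1e-6)/0.75); no: ln(1e-6/0.25) at f=0.5, N=1
        assert bk.lrt_statistic([True], [0.5], 1, 1e-6) == pytest.approx(
            0.28768, abs=1e-5
        )
        assert bk.lrt_statistic([False], [0.5], 1, 1e-6) == pytest.approx(
            -12.429, abs=1e-3
        )

    def test_lrt_empty_sum_is_zero(self):
        assert bk.lrt_statistic([], [], 5, 1e-6) == 0.0

    def test_lrt_requires_positive_mismatch_rate_for_no_responses(self):
        with pytest.raises(DomainError):
            bk.lrt_statistic([True, False], [0.1, 0.1], 10, 0.0)

    def test_lrt_agrees_with_bruteforce_per_term_evaluation(self):
        rng = np.random.default_rng(13)
        for _ in range(200):
            n_members = int(rng.integers(1, 40))
            delta = 10.0 ** -rng.integers(2, 8)
            k = int(rng.integers(1, 30))
            f = rng.uniform(0.001, 0.5, size=k)
            x = rng.integers(0, 2, size=k).astype(bool)
            expected = 0.0
            for fi, xi in zip(f, x):  # independent scalar-math oracle
                p_out = 1.0 - (1.0 - fi) ** (2 * n_members)
                p_in = 1.0 - delta * (1.0 - fi) ** (2 * (n_members - 1))
                if xi:
                    expected += math.log(p_in / p_out)
                else:
                    # (1-Pin)/(1-Pout) = delta*(1-f)^{2(N-1)} / (1-f)^{2N},
                    # which is delta/(1-f)^2 exactly (avoids underflow)
                    expected += math.log(delta) - 2 * math.log(1.0 - fi)
            got = bk.lrt_statistic(x, f, n_members, delta)
            assert got == pytest.approx(expected, rel=1e-9)

    def test_count_statistic_is_the_mean(self):
        rng = np.random.default_rng(14)
        assert bk.count_statistic([True] * 100) == 1.0
        assert bk.count_statistic([False] * 7) == 0.0
        for _ in range(50):
            x = rng.integers(0, 2, size=int(rng.integers(1, 500))).astype(bool)
            assert bk.count_statistic(x) == pytest.approx(x.mean())

    def test_count_statistic_needs_queries(self):
        with pytest.raises(DomainError):
            bk.count_statistic([])


class TestRunAttack:
    def test_config_guards(self):
        with pytest.raises(DomainError):
            sim.AttackConfig(n_queries=0)
        with pytest.raises(DomainError):
            sim.AttackConfig(attack_kind="telepathy")
        with pytest.raises(DomainError):
            sim.AttackConfig(mismatch_rate=0.0)

    def test_population_must_fit_beacon_plus_targets(self):
        population = bk.simulate_population(10, 50, seed=4)
        config = sim.AttackConfig(beacon_size=10, n_replicates=2, n_queries=5)
        with pytest.raises(DomainError, match="too small"):
            bk.run_attack(population, config)

    def test_same_seed_reproduces_statistics_exactly(self):
        population = bk.simulate_population(120, 800, seed=6)
        config = sim.AttackConfig(
            attack_kind=sim.FREQUENCY_AWARE_LRT,
            n_queries=100,
            beacon_size=20,
            n_replicates=30,
            seed=42,
        )
        a, b = bk.run_attack(population, config), bk.run_attack(population, config)
        assert np.array_equal(a.statistics_members, b.statistics_members)
        assert np.array_equal(a.statistics_nonmembers, b.statistics_nonmembers)
        assert a.power == b.power

    def test_truncation_warns(self):
        population = bk.simulate_population(60, 100, seed=6)
        config = sim.AttackConfig(
            n_queries=10_000, beacon_size=10, n_replicates=5, seed=1
        )
        with pytest.warns(UserWarning, match="truncated"):
            bk.run_attack(population, config)

    def test_achieved_fpr_never_exceeds_alpha(self):
        population = bk.simulate_population(200, 1000, seed=8)
        for kind in (sim.FREQUENCY_AWARE_LRT, sim.FREQUENCY_AGNOSTIC_COUNT):
            config = sim.AttackConfig(
                attack_kind=kind,
                n_queries=50,
                beacon_size=25,
                n_replicates=60,
                seed=2,
            )
            result = bk.run_attack(population, config)
            assert result.achieved_fpr <= config.fpr_target

    def test_result_frame_shape(self):
        population = bk.simulate_population(120, 500, seed=6)
        config = sim.AttackConfig(n_queries=40, beacon_size=20, n_replicates=10, seed=3)
        frame = sim.attack_result_frame(bk.run_attack(population, config))
        assert list(frame.columns) == [
            "replicate",
            "member_statistic",
            "nonmember_statistic",
        ]
        assert len(frame) == 10


class TestQueriesNeeded:
    def test_trivially_separable_setting_needs_few_queries(self):
        population = bk.simulate_population(300, 4000, seed=9)
        config = sim.AttackConfig(
            attack_kind=sim.FREQUENCY_AWARE_LRT,
            n_queries=50,
            beacon_size=1,
            n_replicates=100,
            seed=9,
            freq_range=(0.001, 0.05),
        )
        needed = bk.queries_needed(population, config, power_goal=0.95)
        assert needed is not None and needed <= 50

    def test_null_calibrated_setting_never_reaches_the_goal(self):
        population = bk.simulate_population(300, 2000, seed=2)
        config = sim.AttackConfig(
            attack_kind=sim.FREQUENCY_AWARE_LRT,
            n_queries=100,
            beacon_size=50,
            n_replicates=100,
            seed=9,
            null_calibration=True,
        )
        sweep = bk.sweep_queries_needed(population, config, power_goal=0.95)
        assert sweep.n_queries is None
        assert sweep.power_at_cap < 0.95

    def test_power_goal_domain(self):
        population = bk.simulate_population(50, 100, seed=2)
        config = sim.AttackConfig(beacon_size=5, n_replicates=5, n_queries=10, seed=1)
        with pytest.raises(DomainError):
            bk.sweep_queries_needed(population, config, power_goal=1.5)


class TestEvaluateDefense:
    def test_infinite_threshold_reproduces_unmetered_attack_exactly(
        self, mid_population
    ):
        config = sim.AttackConfig(
            attack_kind=sim.FREQUENCY_AGNOSTIC_COUNT,
            n_queries=500,
            beacon_size=100,
            n_replicates=40,
            seed=17,
        )
        comparison = bk.evaluate_defense(
            mid_population, config, threshold_bits=math.inf
        )
        assert np.array_equal(
            comparison.defended.statistics_members,
            comparison.undefended.statistics_members,
        )
        assert np.array_equal(
            comparison.defended.statistics_nonmembers,
            comparison.undefended.statistics_nonmembers,
        )
        assert comparison.defended.power == comparison.undefended.power

    def test_budget_collapses_a_powerful_attack(self, mid_population):
        """Where the unmetered yes-count attack is near-perfect (100-member
        beacon, 5,000 queries), a 30-bit budget leaves it powerless: only a
        handful of common-allele queries get answered before lockout."""
        config = sim.AttackConfig(
            attack_kind=sim.FREQUENCY_AGNOSTIC_COUNT,
            n_queries=5000,
            beacon_size=100,
            n_replicates=150,
            seed=4,
        )
        comparison = bk.evaluate_defense(mid_population, config, threshold_bits=30.0)
        assert comparison.undefended.power >= 0.95
        assert comparison.defended.power < comparison.undefended.power
        assert comparison.defended.power <= 0.2
        max_answered = int(
            max(
                comparison.answered_members.max(),
                comparison.answered_nonmembers.max(),
            )
        )
        assert max_answered <= math.ceil(30.0 / comparison.policy.min_cost)


class TestWriteVcf:
    def test_empty_membership_writes_header_only(self, tmp_path):
        population = bk.simulate_population(5, 20, seed=1)
        path = sim.write_vcf(population, [], tmp_path / "empty.vcf")
        body = [
            line
            for line in path.read_text().splitlines()
            if line and not line.startswith("#")
        ]
        assert body == []
        assert bk.ingest_vcf(path, "d", "SYNTH").record_count == 0

    def test_site_count_matches_segregating_sites(self, tmp_path):
        population = bk.simulate_population(30, 250, seed=5)
        members = range(12)
        path = sim.write_vcf(population, members, tmp_path / "m.vcf")
        segregating = int((population.genotypes[:12] > 0).any(axis=0).sum())
        index = bk.ingest_vcf(path, "d", "SYNTH")
        assert index.record_count == segregating
        assert index.sample_total == 12
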