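import numpy as np
import pytest

from mhcrq._kernels import encounter_kernel
from mhcrq.engine import (
    EncounterLedger,
    _encounter_step,
    _infection_counts,
    _select_parents,
    assign_encounters,
    encounter_credit,
    host_fitness,
    reproduce_hosts,
    run_pathogen_generation,
    run_simulation,
)
from mhcrq.populations import (
    AlleleRegistry,
    HostPopulation,
    PathogenSpeciesPop,
    ScenarioConfig,
    init_populations,
)
from mhcrq.recognition import MatchRule, recognition_lut


def _host_pop(seq_pairs, registry=None):
    seqs = np.asarray(seq_pairs, dtype=np.uint32)
    registry = registry or AlleleRegistry()
    ids = np.asarray(
        [[registry.register(int(s), None, 0) for s in pair] for pair in seq_pairs],
        dtype=np.int64,
    )
    return HostPopulation(seqs=seqs, origin_ids=ids), registry


class TestEncounterCredit:
    RULE = MatchRule(8, 4)
    GOOD = 0b11110000   # presents the attacker below
    BAD = 0b01010101    # does not
    ATTACKER = np.array([0b11110000, 0b00000001], dtype=np.uint32)

    @pytest.mark.parametrize(
        "pair, mode, expected",
        [
            ((GOOD, BAD), "dominant", 1.0),
            ((GOOD, BAD), "additive", 0.5),
            ((GOOD, GOOD), "dominant", 1.0),   # presenting homozygote
            ((GOOD, GOOD), "additive", 1.0),   # both copies count
            ((BAD, BAD), "dominant", 0.0),
            ((BAD, BAD), "additive", 0.0),
        ],
    )
    def test_credit_values(self, pair, mode, expected):
        assert encounter_credit(pair, self.ATTACKER, mode, self.RULE) == expected

    def test_heterozygote_both_presenting_additive(self):
        other_good = 0b00001111
        attacker = np.array([0b11110000, 0b00001111], dtype=np.uint32)
        assert encounter_credit((self.GOOD, other_good), attacker, "additive", self.RULE) == 1.0

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            encounter_credit((0, 0), self.ATTACKER, "codominant", self.RULE)

    def test_dominant_credit_never_below_additive(self, rng):
        rule = MatchRule(16, 7)
        for _ in range(100):
            pair = tuple(int(x) for x in rng.integers(0, 2**16, 2))
            attacker = rng.integers(0, 2**16, 20).astype(np.uint32)
            dom = encounter_credit(pair, attacker, "dominant", rule)
            add = encounter_credit(pair, attacker, "additive", rule)
            assert dom >= add


class TestEncounterKernel:
    def test_jitted_kernel_matches_numpy_path(self, rng):
        """The jitted hot loop and the plain numpy implementation agree exactly."""
        rule = MatchRule(16, 7)
        lut = recognition_lut(rule)
        n_species, n, n_ant = 4, 12, 5
        stacked = rng.integers(0, 2**16, (n_species, n, n_ant)).astype(np.uint32)
        host_seqs = rng.integers(0, 2**16, (n, 2)).astype(np.uint32)
        attackers = rng.integers(0, n, (n_species, n))
        for mode in ("dominant", "additive"):
            credits_np, pres_any = _encounter_step(host_seqs, stacked, attackers, mode, lut)
            counts_np = _infection_counts(attackers, pres_any)
            credits_jit, counts_jit = encounter_kernel(
                stacked,
                attackers,
                np.ascontiguousarray(host_seqs[:, 0]),
                np.ascontiguousarray(host_seqs[:, 1]),
                lut,
                mode == "dominant",
            )
            np.testing.assert_array_equal(credits_jit, credits_np)
            np.testing.assert_array_equal(counts_jit, counts_np)

    def test_credits_match_scalar_op(self, rng):
        rule = MatchRule(16, 7)
        lut = recognition_lut(rule)
        stacked = rng.integers(0, 2**16, (3, 6, 4)).astype(np.uint32)
        host_seqs = rng.integers(0, 2**16, (6, 2)).astype(np.uint32)
        attackers = rng.integers(0, 6, (3, 6))
        for mode in ("dominant", "additive"):
            credits, _ = _encounter_step(host_seqs, stacked, attackers, mode, lut)
            for h in range(6):
                expected = sum(
                    encounter_credit(
                        tuple(host_seqs[h]), stacked[s, attackers[s, h]], mode, rule
                    )
                    for s in range(3)
                )
                assert credits[h] == pytest.approx(expected)


class TestPathogenSelection:
    def test_all_fitness_on_one_individual(self, rng):
        counts = np.array([[0, 5, 0]])
        parents, n_fb = _select_parents(counts, selection=True, rng=rng)
        assert (parents == 1).all() and n_fb == 0

    def test_zero_fitness_species_falls_back_to_uniform(self, rng):
        counts = np.zeros((2, 50), dtype=np.int64)
        counts[1, 3] = 4
        parents, n_fb = _select_parents(counts, selection=True, rng=rng)
        assert n_fb == 1
        assert np.unique(parents[0]).size > 1  # uniform, not stuck
        assert (parents[1] == 3).all()

    def test_selection_off_ignores_counts(self, rng):
        counts = np.array([[0, 1000, 0, 0]])
        parents, _ = _select_parents(counts, selection=False, rng=rng)
        # uniform resampling: every parent index appears over many draws
        draws = [_select_parents(counts, False, rng)[0] for _ in range(50)]
        assert np.unique(np.concatenate(draws)).size == 4

    def test_proportional_sampling_frequencies(self, rng):
        counts = np.array([[1, 3, 0, 0]])
        samples = np.concatenate(
            [_select_parents(counts, True, rng)[0].ravel() for _ in range(2000)]
        )
        freq1 = (samples == 1).mean()
        assert freq1 == pytest.approx(0.75, abs=0.02)
        assert not (samples == 2).any()


class TestEncountersAndGenerationCycle:
    def test_assign_encounters_uniform_with_replacement(self, rng):
        hosts, _ = _host_pop([[1, 2]] * 30)
        pops = [PathogenSpeciesPop(0, np.zeros((10, 2), dtype=np.uint32))]
        draws = np.concatenate(
            [assign_encounters(hosts, pops, rng).attackers.ravel() for _ in range(200)]
        )
        counts = np.bincount(draws, minlength=10)
        from scipy.stats import chisquare

        assert chisquare(counts).pvalue > 1e-4
        assert draws.size > np.unique(draws).size  # replacement: repeats happen

    def test_run_pathogen_generation_credits_and_resampling(self, rng):
        rule = MatchRule(8, 8)  # recognition only on exact antigen match
        allele = 0b10101010
        hosts, _ = _host_pop([[allele, allele]] * 4)
        # individual 0 is presented (antigen == allele), individual 1 is not
        antigens = np.array([[allele], [0b01010101]], dtype=np.uint32)
        pops = [PathogenSpeciesPop(0, antigens.copy())]
        config = ScenarioConfig(
            scenario="HA+RQ", n_hosts=4, n_species=1, antigens_per_pathogen=1,
            rule=rule, mu_pathogen=0.0,
        )
        ledger = EncounterLedger(attackers=np.array([[0, 0, 1, 1]]))
        credits, n_fb = run_pathogen_generation(hosts, pops, ledger, config, rng)
        np.testing.assert_array_equal(credits, [1.0, 1.0, 0.0, 0.0])
        assert n_fb == 0
        # only the infecting individual (index 1) leaves offspring
        assert (pops[0].antigens == 0b01010101).all()

    def test_host_fitness_normalisation(self):
        fitness = host_fitness(np.array([500.0, 250.0, 0.0]), n_species=50,
                               pathogen_generations=10)
        np.testing.assert_allclose(fitness, [1.0, 0.5, 0.0])
        with pytest.raises(ValueError):
            host_fitness(np.array([501.0]), 50, 10)


class TestReproduction:
    def test_single_fit_parent_in_every_pair(self, rng):
        hosts, registry = _host_pop([[1, 2], [3, 4], [5, 6], [7, 8]])
        fitness = np.array([0.0, 1.0, 0.0, 0.0])
        config = ScenarioConfig(scenario="DRIFT", n_hosts=4, host_site_mutation_rate=0.0)
        child = reproduce_hosts(hosts, fitness, config, registry, rng)
        # every offspring inherits one allele from host 1 ({3, 4})
        assert all(len({3, 4} & set(pair)) >= 1 for pair in child.seqs.tolist())

    def test_mendelian_segregation(self, rng):
        n = 3000
        hosts, registry = _host_pop([[11, 22]] * n)
        config = ScenarioConfig(scenario="DRIFT", n_hosts=n, host_site_mutation_rate=0.0)
        child = reproduce_hosts(hosts, np.ones(n), config, registry, rng)
        freq = (child.seqs == 11).mean()
        se = 0.5 / np.sqrt(2 * n)
        assert abs(freq - 0.5) < 4 * se

    def test_population_size_conserved_and_generation_advances(self, rng):
        hosts, registry = _host_pop([[1, 2]] * 10)
        config = ScenarioConfig(scenario="DRIFT", n_hosts=10)
        child = reproduce_hosts(hosts, np.ones(10), config, registry, rng)
        assert child.n_hosts == 10 and child.generation == hosts.generation + 1


class TestRunSimulation:
    def test_zero_recorded_generations(self):
        config = ScenarioConfig(scenario="DRIFT", n_hosts=10, burn_in=5,
                                recorded_generations=0, seed=1)
        result = run_simulation(config)
        assert result.summaries.empty
        assert result.final_hosts.generation == 5

    def test_same_seed_bitwise_identical(self, tiny_run):
        rerun = run_simulation(tiny_run.config)
        assert rerun.summaries.equals(tiny_run.summaries)
        assert rerun.registry.sequences == tiny_run.registry.sequences
        np.testing.assert_array_equal(rerun.final_hosts.seqs, tiny_run.final_hosts.seqs)

    def test_fitness_bounds_and_sizes(self, tiny_run):
        s = tiny_run.summaries
        assert s["mean_fitness"].between(0, 1).all()
        assert s["observed_heterozygosity"].between(0, 1).all()
        assert (s["n_distinct_alleles"] >= 1).all()
        assert tiny_run.final_hosts.n_hosts == tiny_run.config.n_hosts
        for pop in tiny_run.final_pathogens:
            assert pop.n_individuals == tiny_run.config.n_hosts

    def test_drift_without_mutation_loses_variants(self):
        config = ScenarioConfig(
            scenario="DRIFT", n_hosts=30, host_site_mutation_rate=0.0,
            burn_in=0, recorded_generations=120, seed=7,
        )
        richness = run_simulation(config).summaries["n_distinct_alleles"].to_numpy()
        assert (np.diff(richness) <= 0).all()
        assert richness[-1] < richness[0]

    def test_drift_fitness_constant(self):
        config = ScenarioConfig(scenario="DRIFT", n_hosts=20, burn_in=0,
                                recorded_generations=10, seed=3)
        assert (run_simulation(config).summaries["mean_fitness"] == 1.0).all()

    def test_pathogen_selection_lowers_host_fitness(self):
        """Adapting pathogens (selection on) depress host fitness relative to
        pathogen drift at otherwise identical dominant-resistance settings."""
        base = dict(n_hosts=60, n_species=20, antigens_per_pathogen=10,
                    mu_pathogen=5e-3, burn_in=30, recorded_generations=50, seed=11)
        with_rq = run_simulation(ScenarioConfig(scenario="HA+RQ", **base))
        without = run_simulation(ScenarioConfig(scenario="HA", **base))
        assert (
            with_rq.summaries["mean_fitness"].mean()
            < without.summaries["mean_fitness"].mean()
        )

    def test_fitness_window_last_generation_only(self):
        config = ScenarioConfig(
            scenario="HA+RQ", n_hosts=20, n_species=5, antigens_per_pathogen=5,
            burn_in=0, recorded_generations=15, seed=5, fitness_window="last",
        )
        s = run_simulation(config).summaries
        assert s["mean_fitness"].between(0, 1).all()
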