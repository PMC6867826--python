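"""Unit and property tests for the lineage-based Wright-Fisher engine."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mutsim import (
    ConfigurationError,
    DegeneratePopulationError,
    DfeSpec,
    OutcomeStatus,
    Population,
    SimParams,
    lineage_fitness,
    mean_fitness,
    mutate,
    resample,
    run_until_absorption,
    step,
)
from mutsim.experiments import derive_seed


def make_pop(sizes, n_ben, n_del, muts, params):
    n_ben = np.asarray(n_ben, dtype=np.int64)
    n_del = np.asarray(n_del, dtype=np.int64)
    return Population(
        generation=0,
        N=int(np.sum(sizes)),
        n_ben=n_ben,
        n_del=n_del,
        is_mutator=np.asarray(muts, dtype=bool),
        fitness=np.asarray(lineage_fitness(n_ben, n_del, params), dtype=float),
        size=np.asarray(sizes, dtype=np.int64),
    )


class TestLineageFitness:
    @pytest.mark.parametrize(
        "n_ben,n_del,expected",
        [(0, 0, 1.0), (2, 1, 1.1), (0, 12, 0.0), (1, 0, 1.1), (0, 1, 0.9)],
    )
    def test_additive_with_zero_floor(self, n_ben, n_del, expected, std_params):
        assert lineage_fitness(n_ben, n_del, std_params) == pytest.approx(expected)

    def test_deleterious_sign_convention(self, std_params):
        # s_del is stored negative; deleterious mutations must *decrease* fitness
        assert lineage_fitness(0, 1, std_params) < 1.0

    def test_rejects_negative_counts(self, std_params):
        with pytest.raises(ValueError):
            lineage_fitness(-1, 0, std_params)

    def test_rejects_locus_overflow(self, std_params):
        with pytest.raises(ValueError):
            lineage_fitness(60, 60, std_params)  # L = 99


class TestMeanFitness:
    def test_single_lineage(self, std_params):
        pop = make_pop([100], [0], [0], [False], std_params)
        assert mean_fitness(pop) == pytest.approx(1.0)

    def test_equal_split_is_arithmetic_mean(self, std_params):
        pop = make_pop([50, 50], [0, 1], [0, 0], [False, False], std_params)
        assert mean_fitness(pop) == pytest.approx(1.05)

    def test_weighted_mean(self, std_params):
        # sizes (90, 10) with w = (1.0, 2.0) -> 1.1
        pop = make_pop([90, 10], [0, 10], [0, 0], [False, False], std_params)
        assert mean_fitness(pop) == pytest.approx(1.1)

    def test_all_zero_fitness_is_degenerate(self, std_params):
        pop = make_pop([100], [0], [12], [False], std_params)
        with pytest.raises(DegeneratePopulationError):
            mean_fitness(pop)


class TestResample:
    def test_single_lineage_is_fixed_point(self, std_params, rng):
        pop = make_pop([100], [0], [0], [True], std_params)
        out = resample(pop, rng)
        assert out.size.tolist() == [100]

    def test_conserves_population_size_and_prunes(self, std_params, rng):
        pop = make_pop([60, 30, 10], [0, 1, 2], [0, 0, 0],
                       [False, True, False], std_params)
        for _ in range(200):
            out = resample(pop, rng)
            assert out.total_size() == 100
            assert (out.size > 0).all()

    def test_expected_offspring_counts(self, std_params, rng):
        """Empirical mean sizes match N * f_i * w_i / w_bar over 1e4 draws."""
        pop = make_pop([50, 50], [0, 1], [0, 0], [False, True], std_params)
        sel = np.empty(10_000)
        for i in range(10_000):
            out = resample(pop, rng)
            fit = out.size[out.is_mutator]
            sel[i] = fit[0] if fit.size else 0
        expected = 100 * 0.5 * 1.1 / 1.05  # ~52.38
        se = np.sqrt(expected * (1 - expected / 100) / 10_000)
        assert abs(sel.mean() - expected) < 3 * se

    def test_neutral_expected_offspring_counts(self, std_params, rng):
        pop = make_pop([50, 50], [0, 0], [0, 0], [False, True], std_params)
        sel = np.empty(10_000)
        for i in range(10_000):
            out = resample(pop, rng)
            fit = out.size[out.is_mutator]
            sel[i] = fit[0] if fit.size else 0
        se = np.sqrt(100 * 0.25 / 10_000)
        assert abs(sel.mean() - 50.0) < 3 * se

    def test_degenerate_population_propagates(self, std_params, rng):
        pop = make_pop([100], [0], [12], [False], std_params)
        with pytest.raises(DegeneratePopulationError):
            resample(pop, rng)


class TestMutate:
    def test_zero_rates_identity(self, constant_dfe, rng):
        params = SimParams(N=100, U_ben=0.0, U_del=0.0, s_ben=0.1, s_del=-0.1,
                           m_fold=1, x0=0.5)
        pop = Population.initial(params)
        out = mutate(pop, params, constant_dfe, rng)
        assert out is pop

    def test_poisson_mean_of_new_mutants(self, constant_dfe, rng):
        """Fresh N=1e4 population at U_tot=1e-2: ~100 mutants per call."""
        params = SimParams(N=10_000, U_ben=1e-3, U_del=9e-3, s_ben=0.1,
                           s_del=-0.1, m_fold=1, x0=1.0)
        total, calls, lam = 0, 300, 100.0
        for _ in range(calls):
            out = mutate(Population.initial(params), params, constant_dfe, rng)
            wild = out.size[(out.n_ben == 0) & (out.n_del == 0)].sum()
            total += params.N - wild
        se = np.sqrt(lam * calls)  # Poisson variance
        assert abs(total - lam * calls) < 3 * se

    def test_mutator_rate_is_m_fold_higher(self, constant_dfe, rng):
        """m_fold = 100 multiplies the Poisson mean 100-fold for mutators."""
        params = SimParams(N=10_000, U_ben=1e-6, U_del=1e-4, s_ben=0.1,
                           s_del=-0.1, m_fold=100, x0=1.0)
        total, calls = 0, 300
        lam = params.N * (params.U_ben + params.U_del) * params.m_fold  # ~101
        for _ in range(calls):
            out = mutate(Population.initial(params), params, constant_dfe, rng)
            wild = out.size[(out.n_ben == 0) & (out.n_del == 0)].sum()
            total += params.N - wild
        assert abs(total - lam * calls) < 3 * np.sqrt(lam * calls)

    def test_conserves_population_size(self, std_params, constant_dfe, rng):
        pop = Population.initial(std_params)
        for _ in range(50):
            pop = mutate(pop, std_params, constant_dfe, rng)
            assert pop.total_size() == std_params.N

    def test_saturated_lineage_ignores_mutations(self, constant_dfe, rng):
        params = SimParams(N=100, U_ben=0.5, U_del=0.5, s_ben=0.1, s_del=-0.1,
                           m_fold=1, x0=1.0, L=2)
        pop = make_pop([100], [1], [1], [True], params)
        out = mutate(pop, params, constant_dfe, rng)
        assert out.size.tolist() == [100]
        assert out.n_ben.tolist() == [1] and out.n_del.tolist() == [1]

    def test_mutator_flag_inherited(self, std_params, constant_dfe, rng):
        params = SimParams(N=1000, U_ben=0.05, U_del=0.05, s_ben=0.1,
                           s_del=-0.1, m_fold=1, x0=1.0)
        pop = Population.initial(params)
        out = mutate(pop, params, constant_dfe, rng)
        assert out.is_mutator.all()

    def test_exponential_mode_founds_distinct_lineages(self, rng):
        params = SimParams(N=1000, U_ben=0.05, U_del=0.05, s_ben=0.1,
                           s_del=-0.1, m_fold=1, x0=1.0, dfe_mode="exponential")
        dfe = DfeSpec(mode="exponential")
        out = mutate(Population.initial(params), params, dfe, rng)
        mutants = out.size[(out.n_ben + out.n_del) > 0]
        assert (mutants == 1).all()  # every mutant is its own size-1 lineage
        assert out.total_size() == 1000
        assert (out.fitness >= 0).all()


class TestStepAndRun:
    def test_step_increments_generation_and_conserves(self, std_params,
                                                      constant_dfe, rng):
        pop = Population.initial(std_params)
        out = step(pop, std_params, constant_dfe, rng)
        assert out.generation == 1
        assert out.total_size() == std_params.N

    def test_x0_one_fixes_at_generation_zero(self, std_params, constant_dfe):
        params = SimParams(**{**std_params.__dict__, "x0": 1.0})
        traj = run_until_absorption(params, constant_dfe, seed=1)
        assert traj.outcome.status is OutcomeStatus.FIXED
        assert traj.outcome.generations_elapsed == 0

    def test_no_mutators_is_configuration_error(self, std_params):
        params = SimParams(**{**std_params.__dict__, "x0": 0.0})
        with pytest.raises(ConfigurationError):
            run_until_absorption(params, None, seed=1)

    def test_absorption_at_zero_is_permanent(self, std_params, constant_dfe, rng):
        """Once the modifier is lost, mutation at fitness loci cannot revive it."""
        pop = make_pop([100], [0], [0], [False], std_params)
        for _ in range(100):
            pop = step(pop, std_params, constant_dfe, rng)
            assert pop.mutator_frequency == 0.0

    def test_trajectory_is_bit_reproducible(self, std_params, constant_dfe):
        a = run_until_absorption(std_params, constant_dfe, seed=derive_seed(0, 3))
        b = run_until_absorption(std_params, constant_dfe, seed=derive_seed(0, 3))
        assert a.outcome == b.outcome
        np.testing.assert_array_equal(a.freq, b.freq)

    def test_record_off_keeps_outcome_and_final_state(self, std_params, constant_dfe):
        traj = run_until_absorption(std_params, constant_dfe, seed=derive_seed(0, 3),
                                    record=False)
        assert traj.freq is None
        assert traj.final_freq in (0.0, 1.0)

    def test_neutral_fixation_probability_equals_frequency(self, neutral_params):
        """Strictly neutral modifier: Pfix(x0) = x0 (martingale absorption)."""
        n_reps, x0 = 3000, 0.1
        fixed = sum(
            run_until_absorption(neutral_params, None, seed=derive_seed(0, r),
                                 record=False).outcome.status is OutcomeStatus.FIXED
            for r in range(n_reps)
        )
        se = np.sqrt(x0 * (1 - x0) / n_reps)
        assert abs(fixed / n_reps - x0) < 3 * se

    def test_censoring_reported_not_absorbed(self, std_params, constant_dfe):
        params = SimParams(**{**std_params.__dict__, "x0": 0.5,
                              "U_ben": 0.0, "U_del": 0.0, "max_generations": 3})
        traj = run_until_absorption(params, None, seed=derive_seed(0, 0))
        if traj.outcome.status is OutcomeStatus.CENSORED:
            assert 0.0 < traj.final_freq < 1.0
            assert traj.outcome.generations_elapsed == 3

    def test_exponential_dfe_runs_to_absorption(self):
        params = SimParams(N=500, U_ben=1e-3, U_del=1e-2, s_ben=0.1, s_del=-0.1,
                           m_fold=10, x0=0.2, dfe_mode="exponential")
        traj = run_until_absorption(params, DfeSpec(mode="exponential"),
                                    seed=derive_seed(0, 0))
        assert traj.outcome.status in (OutcomeStatus.FIXED, OutcomeStatus.LOST)


@st.composite
def small_params(draw):
    N = draw(st.integers(10, 150))
    x0 = draw(st.floats(0.05, 0.95))
    if int(round(x0 * N)) == 0:
        x0 = 1.0 / N
    return SimParams(
        N=N,
        U_ben=draw(st.floats(0.0, 0.02)),
        U_del=draw(st.floats(0.0, 0.05)),
        s_ben=draw(st.floats(0.01, 0.5)),
        s_del=-draw(st.floats(0.0, 0.3)),
        m_fold=draw(st.floats(1.0, 100.0)),
        x0=x0,
        L=draw(st.integers(2, 99)),
    )


class TestInvariants:
    @given(params=small_params(), seed=st.integers(0, 2**20))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_conservation_bounds_and_locus_cap(self, params, seed):
        """After every generation: sizes sum to N exactly, the modifier
        frequency is a valid frequency, and no lineage exceeds L mutations."""
        rng = np.random.default_rng(seed)
        dfe = DfeSpec()
        pop = Population.initial(params)
        for _ in range(25):
            pop = step(pop, params, dfe, rng)
            assert pop.total_size() == params.N
            assert 0.0 <= pop.mutator_frequency <= 1.0
            assert (pop.n_ben + pop.n_del <= params.L).all()
            assert (pop.size >= 1).all()
            if pop.mutator_frequency in (0.0, 1.0):
                break

    @given(seed=st.integers(0, 2**20))
    @settings(max_examples=10, deadline=None, derandomize=True)
    def test_merged_representation_has_unique_classes(self, seed):
        """Class merging is a representation change: after any number of steps
        each (n_ben, n_del, is_mutator) class appears at most once."""
        params = SimParams(N=100, U_ben=1e-4, U_del=1e-2, s_ben=0.1,
                           s_del=-0.1, m_fold=10, x0=0.1)
        rng = np.random.default_rng(seed)
        pop = Population.initial(params)
        for _ in range(20):
            pop = step(pop, params, DfeSpec(), rng)
        keys = {
            (int(b), int(d), bool(m))
            for b, d, m in zip(pop.n_ben, pop.n_del, pop.is_mutator)
        }
        assert len(keys) == pop.size.shape[0]


class TestSimParamsValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"N": 1},
            {"U_ben": -1e-6},
            {"s_ben": 0.0},
            {"s_del": 0.1},
            {"m_fold": 0.5},
            {"x0": 1.5},
            {"L": 0},
            {"dfe_mode": "gamma"},
            {"max_generations": 0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        base = dict(N=100, U_ben=1e-6, U_del=1e-4, s_ben=0.1, s_del=-0.1,
                    m_fold=100, x0=0.1)
        with pytest.raises(ConfigurationError):
            SimParams(**{**base, **kwargs})
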