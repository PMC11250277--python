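"""Tumor simulator: per-step dynamics, outcome bookkeeping and the
distributional guarantees the growth experiments rely on."""

import math

import numpy as np
import pytest
from scipy import stats

from msidyn.switching import (
    Population,
    SimParams,
    Trajectory,
    growth_time,
    ms_shannon,
    simulate_tumor,
    step_population,
)


def make_pop(n, **overrides):
    pop = Population(
        high=np.zeros(n, dtype=bool),
        n_antigens=np.zeros(n, dtype=np.int32),
        escaped=np.zeros(n, dtype=bool),
        lethal=np.zeros(n, dtype=bool),
        ms_state=np.zeros(n, dtype=np.int32),
    )
    for k, v in overrides.items():
        setattr(pop, k, v)
    return pop


class TestStepPopulation:
    def test_no_switching_keeps_regimes_fixed(self):
        params = SimParams(beta=0.0, founder_regime="basal")
        rng = np.random.default_rng(0)
        pop = Population.founders(params)
        for _ in range(15):
            pop = step_population(pop, params, rng)
            assert pop.high.sum() == 0

    def test_pure_birth_death_offspring_mean(self):
        # all-escaped, all probabilities zero: Galton-Watson with mean 2(1-d0)
        params = SimParams(p_antigen=0, p_escape=0, p_lethal=0, p_ms=0,
                           beta=0, d0=0.2, n0=10_000, n_detect=10**9)
        pop = make_pop(10_000, escaped=np.ones(10_000, dtype=bool))
        rng = np.random.default_rng(1)
        out = step_population(pop, params, rng)
        mean_offspring = len(out) / len(pop)
        se = 2 * math.sqrt(0.2 * 0.8 / 10_000)  # binomial survival SE
        assert abs(mean_offspring - 2 * 0.8) < 3 * se

    def test_lethal_cells_die_with_certainty(self):
        params = SimParams()
        pop = make_pop(500, lethal=np.ones(500, dtype=bool))
        out = step_population(pop, params, np.random.default_rng(2))
        assert len(out) == 0

    def test_mean_mutations_per_division_matches_regime(self):
        # with p_antigen=1 every new mutation is counted in n_antigens, so the
        # first-generation antigen burden reads out K ~ Poisson(mu)
        for regime, mu in (("basal", 6.0), ("high", 120.0)):
            params = SimParams(p_antigen=1.0, p_escape=0, p_lethal=0, p_ms=0,
                               d0=0.0, founder_regime=regime)
            pop = Population.founders(params)
            out = step_population(pop, params, np.random.default_rng(3))
            se = math.sqrt(mu / len(out))
            assert abs(out.n_antigens.mean() - mu) < 3 * se

    def test_mutation_counts_are_poisson(self):
        params = SimParams(p_antigen=1.0, p_escape=0, p_lethal=0, p_ms=0,
                           d0=0.0, n0=5_000, founder_regime="basal")
        pop = Population.founders(params)
        out = step_population(pop, params, np.random.default_rng(4))
        counts = out.n_antigens
        kmax = 15
        obs = np.bincount(np.minimum(counts, kmax), minlength=kmax + 1)
        pmf = stats.poisson.pmf(np.arange(kmax), 6.0)
        expected = np.append(pmf, 1 - pmf.sum()) * len(counts)
        keep = expected > 5
        chi2, p = stats.chisquare(obs[keep], expected[keep] * obs[keep].sum()
                                  / expected[keep].sum())
        assert p > 0.01

    def test_ms_walk_is_symmetric(self):
        params = SimParams(p_antigen=0, p_escape=0, p_lethal=0, p_ms=0.5,
                           d0=0.0, n0=2_000, founder_regime="high")
        pop = Population.founders(params)
        rng = np.random.default_rng(5)
        pop.escaped[:] = True
        for _ in range(3):
            pop = step_population(pop, params, rng)
            pop = Population(pop.high[:2000], pop.n_antigens[:2000],
                             pop.escaped[:2000], pop.lethal[:2000],
                             pop.ms_state[:2000])
        # ~0.5*120*3 = 180 expected hits per lineage; mean displacement 0
        se = math.sqrt(pop.ms_state.astype(float).var() / len(pop))
        assert abs(pop.ms_state.mean()) < 3 * se + 1e-9

    def test_escape_flag_is_permanent(self):
        params = SimParams(p_antigen=0, p_escape=0, p_lethal=0, p_ms=0, d0=0.3)
        pop = make_pop(1000, escaped=np.ones(1000, dtype=bool))
        rng = np.random.default_rng(6)
        for _ in range(5):
            pop = step_population(pop, params, rng)
            assert pop.escaped.all()


class TestSimulateTumor:
    def test_detection_at_time_zero_boundary(self):
        params = SimParams(n0=100, n_detect=100)
        outcome, _ = simulate_tumor(params, seed=0)
        assert outcome.status == "detected"
        assert outcome.t_final == 0
        assert outcome.growth_time == 0

    def test_bit_reproducible(self):
        params = SimParams(founder_regime="high", n_detect=2_000)
        o1, t1 = simulate_tumor(params, seed=33)
        o2, t2 = simulate_tumor(params, seed=33)
        assert o1 == o2
        assert t1.total == t2.total and t1.escaped == t2.escaped

    def test_no_selection_allows_detection_without_escape(self):
        params = SimParams(s=0.0, founder_regime="high", n_detect=5_000)
        detected_unescaped = 0
        for seed in range(8):
            outcome, traj = simulate_tumor(params, seed=seed)
            assert outcome.status == "detected"
            if traj.escaped[-1] < 20:
                detected_unescaped += 1
        assert detected_unescaped >= 6

    def test_eliminated_has_no_growth_time(self):
        params = SimParams(founder_regime="high", n0=2, n_detect=10_000)
        for seed in range(30):
            outcome, _ = simulate_tumor(params, seed=seed)
            if outcome.status == "eliminated":
                assert outcome.growth_time is None
                assert outcome.n_final == 0
                return
        pytest.fail("no eliminated lineage among 30 tiny founders")


class TestDiversityAndGrowthTime:
    def test_shannon_closed_forms(self):
        assert ms_shannon(make_pop(10)) == 0.0
        pop = make_pop(10, ms_state=np.array([0] * 5 + [-1] * 5, dtype=np.int32))
        assert ms_shannon(pop) == pytest.approx(math.log(2))
        pop = make_pop(10, ms_state=np.array([0] * 7 + [1] * 2 + [-1],
                                             dtype=np.int32))
        expected = -(0.7 * math.log(0.7) + 0.2 * math.log(0.2)
                     + 0.1 * math.log(0.1))
        assert ms_shannon(pop) == pytest.approx(expected)
        assert expected == pytest.approx(0.8018, abs=5e-5)

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            ms_shannon(make_pop(0))

    def test_growth_time_definition(self):
        traj = Trajectory()
        traj.escaped = [5, 12, 19, 25, 60] + [100] * 35 + [5000]
        traj.total = [0] * len(traj.escaped)
        assert len(traj.escaped) == 41  # detection at t = 40
        assert growth_time(traj) == 38  # last below-20 step is t = 2

    def test_growth_time_when_escape_established_from_start(self):
        traj = Trajectory()
        traj.escaped = [25, 40, 80, 200]
        traj.total = [0] * 4
        assert growth_time(traj) == 3  # start 0, t_final 3

    def test_growth_time_bounded_by_duration(self):
        params = SimParams(founder_regime="high", n_detect=2_000)
        for seed in range(300):
            outcome, _ = simulate_tumor(params, seed=seed)
            if outcome.status == "detected":
                assert 0 <= outcome.growth_time <= outcome.t_final
                return
        pytest.fail("no detected tumor in 300 tries")
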