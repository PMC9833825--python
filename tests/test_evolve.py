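import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from dupdiv.config import preset
from dupdiv.evolve import (
    ExtinctPopulationError,
    PopulationState,
    SerialProtocol,
    TauLeapError,
    Trajectory,
    bottleneck,
    deterministic_trajectory,
    grow_day,
    mutation_flows,
    run_experiment,
    run_replicate,
    solve_day_duration,
)
from dupdiv.model_core import AlleleParams, Environment, MutationRates

from conftest import make_state

ZERO = MutationRates(0.0, 0.0, 0.0)


class TestSolveDayDuration:
    def test_single_class_closed_form(self, low_demand_env, alleles):
        """One class growing from K/820 to K takes exactly ln(820)/r hours."""
        proto = SerialProtocol(carrying_capacity=1e8)
        env = Environment(demand=1.0, r0=0.2, rmax=0.7)  # ancestral at plateau: r = 0.7
        state = make_state(**{"1_0": 1e8 / 820})
        t = solve_day_duration(state, env, alleles, proto)
        assert t == pytest.approx(math.log(820) / 0.7, rel=1e-9)

    def test_zero_growth_returns_zero(self, alleles):
        env = Environment(demand=4.0, r0=0.0, rmax=0.9, cost_per_copy=0.9)
        # with r0=0 and E/D = 1/4, ancestral still grows; use a costly class at rate 0
        state = make_state(**{"20_0": 1e3})
        assert solve_day_duration(state, env, alleles, SerialProtocol()) == 0.0

    def test_two_class_root_matches_grid_search(self, alleles):
        """The bisection agrees with a brute-force dense scan of the root."""
        proto = SerialProtocol(carrying_capacity=1e8)
        # engineer rates r(1,0)=0.5 and r(1,1)=1.0 via a custom environment
        env = Environment(demand=40.0, r0=0.5 - 0.0125, rmax=1.0, cost_per_copy=0.0)
        state = make_state(**{"1_0": 1e5, "1_1": 1e2})
        from dupdiv.model_core import growth_rate_grid

        r = growth_rate_grid(20, env, alleles)
        r1, r2 = r[0, 0], r[0, 1]

        def f(t):
            return 1e5 * math.exp(r1 * t) + 1e2 * math.exp(r2 * t) - 1e8

        grid = np.linspace(0.0, 100.0, 2_000_001)
        vals = 1e5 * np.exp(r1 * grid) + 1e2 * np.exp(r2 * grid) - 1e8
        bracket = int(np.argmax(vals > 0))
        t_oracle = brentq(f, grid[bracket - 1], grid[bracket])
        t = solve_day_duration(state, env, alleles, proto)
        assert t == pytest.approx(t_oracle, rel=1e-8)


class TestMutationFlows:
    def test_zero_rates_identity(self):
        state = make_state(**{"1_0": 1e6, "4_1": 1e3})
        out = mutation_flows(state, ZERO, 1.0, np.random.default_rng(0))
        np.testing.assert_array_equal(out.counts, state.counts)

    def test_duplication_poisson_mean(self):
        """Mean flow into (2,0) over seeds matches the Poisson mean of 1000."""
        rates = MutationRates(mu_dup=1e-3, mu_step=0.0, mu_pm=0.0)
        n_seeds = 300
        flows = []
        for s in range(n_seeds):
            out = mutation_flows(make_state(**{"1_0": 1e6}), rates, 1.0, np.random.default_rng(s))
            flows.append(out.counts[1, 0])
        se = math.sqrt(1000 / n_seeds)
        assert abs(np.mean(flows) - 1000) < 3 * se

    def test_deletion_target_follows_m_over_k(self):
        """Deletions from (4,1) land in (3,0) three quarters of the time."""
        rates = MutationRates(mu_dup=0.0, mu_step=1e-3, mu_pm=0.0)
        rng = np.random.default_rng(42)
        down = same = 0
        state = make_state(**{"4_1": 4e6})  # mean deletions per call: 4e6*1e-3*3 = 12000
        for _ in range(3):
            out = mutation_flows(state, rates, 1.0, rng)
            same += out.counts[2, 1]
            down += out.counts[2, 0]
        total = down + same
        p_hat = down / total
        assert abs(p_hat - 0.25) < 3 * math.sqrt(0.25 * 0.75 / total)

    def test_duplication_copies_allele_state(self):
        """(1,1) duplicates to (2,2): a tandem duplication copies its allele."""
        rates = MutationRates(mu_dup=1e-2, mu_step=0.0, mu_pm=0.0)
        out = mutation_flows(make_state(**{"1_1": 1e6}), rates, 1.0, None)
        assert out.counts[1, 2] == pytest.approx(1e4)
        assert out.counts[1, 0] == 0.0

    def test_tau_leap_violation_raises(self):
        rates = MutationRates(mu_dup=0.0, mu_step=0.9, mu_pm=0.0)
        with pytest.raises(TauLeapError):
            mutation_flows(make_state(**{"4_0": 1e3}), rates, 1.0, np.random.default_rng(0))

    @given(seed=st.integers(0, 10_000))
    @settings(deadline=None, max_examples=25)
    def test_conservation(self, seed):
        """Total abundance is conserved through any mutation step."""
        rng = np.random.default_rng(seed)
        counts = np.zeros((8, 9))
        for k in range(1, 9):
            for m in range(0, k + 1):
                counts[k - 1, m] = rng.integers(0, 10_000)
        state = PopulationState(counts)
        rates = MutationRates(mu_dup=1e-3, mu_step=1e-2, mu_pm=1e-5)
        out = mutation_flows(state, rates, 1.0, rng)
        assert out.total == pytest.approx(state.total, rel=1e-9)


class TestGrowDay:
    def test_reaches_capacity_without_mutation(self, low_demand_env, alleles, small_protocol):
        state = make_state(**{"1_0": small_protocol.bottleneck_size})
        out = grow_day(state, low_demand_env, alleles, ZERO, small_protocol, None)
        assert out.total == pytest.approx(small_protocol.carrying_capacity, rel=1e-6)

    def test_selection_increases_fitter_class(self, low_demand_env, alleles, small_protocol):
        state = make_state(**{"1_0": 1000, "4_0": 10})
        out = grow_day(state, low_demand_env, alleles, ZERO, small_protocol, None)
        assert out.frequencies()[3, 0] > 10 / 1010

    def test_neutral_frequencies_unchanged(self, alleles, small_protocol):
        # all occupied classes at the plateau with zero copy cost -> equal rates
        env = Environment(demand=0.5, r0=0.2, rmax=0.9, cost_per_copy=0.0)
        state = make_state(**{"1_0": 500, "3_0": 250, "2_1": 250})
        out = grow_day(state, env, alleles, ZERO, small_protocol, None)
        np.testing.assert_allclose(out.frequencies(), state.frequencies(), atol=1e-12)


class TestBottleneck:
    def test_unit_dilution_is_identity(self):
        proto = SerialProtocol(dilution_factor=1.0000001, carrying_capacity=1e6)
        state = make_state(**{"1_0": 8.2e5})
        out = bottleneck(state, proto, np.random.default_rng(0))
        assert out.total == 8.2e5

    def test_single_class_deterministic_size(self):
        proto = SerialProtocol(dilution_factor=820.0, carrying_capacity=8.2e7)
        out = bottleneck(make_state(**{"4_0": 8.2e7}), proto, np.random.default_rng(1))
        assert out.total == 1e5
        assert out.counts[3, 0] == 1e5

    def test_minority_class_binomial_mean(self):
        proto = SerialProtocol(dilution_factor=820.0, carrying_capacity=8.2e7)
        state = make_state(**{"1_0": 8.2e7 * 0.99, "2_0": 8.2e7 * 0.01})
        n_seeds = 200
        counts = [
            bottleneck(state, proto, np.random.default_rng(s)).counts[1, 0] for s in range(n_seeds)
        ]
        se = math.sqrt(1e5 * 0.01 * 0.99 / n_seeds)
        assert abs(np.mean(counts) - 1000) < 3 * se

    def test_extinction_raises(self):
        proto = SerialProtocol(dilution_factor=820.0, carrying_capacity=1e6)
        with pytest.raises(ExtinctPopulationError):
            bottleneck(make_state(**{"1_0": 100}), proto, np.random.default_rng(0))


class TestRunReplicate:
    def test_zero_rates_stay_ancestral(self, small_protocol):
        cfg = preset("low", "IS+", protocol=small_protocol, rates=ZERO)
        traj = run_replicate(cfg, 7)
        assert len(traj.states) == small_protocol.n_days + 1
        for st in traj.states:
            assert st.counts[0, 0] == st.total

    def test_same_seed_bit_identical(self, small_protocol):
        cfg = preset("low", "IS+", protocol=small_protocol)
        t1 = run_replicate(cfg, 11)
        t2 = run_replicate(cfg, 11)
        for a, b in zip(t1.states, t2.states):
            np.testing.assert_array_equal(a.counts, b.counts)

    def test_experiment_seed_fanout(self, small_protocol):
        cfg = preset("low", "IS+", protocol=small_protocol)
        trajs = run_experiment(cfg, 3, base_seed=5)
        lone = run_replicate(cfg, 6)
        np.testing.assert_array_equal(trajs[1].final().counts, lone.final().counts)

    def test_unreachable_capacity_truncates_day(self, alleles):
        # every class effectively at rate ~0 except a crawl that cannot reach 1e8
        env = Environment(demand=1e9, r0=1e-5, rmax=2e-5, cost_per_copy=0.0)
        proto = SerialProtocol(carrying_capacity=1e8, n_days=1)
        cfg = preset("low", "IS+", protocol=proto, environment=env, rates=ZERO)
        traj = run_replicate(cfg, 0)
        assert traj.warnings and "truncated" in traj.warnings[0]

    def test_trajectory_tidy_frame(self, small_protocol):
        cfg = preset("low", "IS+", protocol=small_protocol, rates=ZERO)
        df = run_replicate(cfg, 1).to_frame()
        assert list(df.columns) == ["replicate", "day", "k", "m", "count"]
        assert set(df["day"]) == set(range(small_protocol.n_days + 1))


class TestDeterministicOracle:
    def test_zero_rates_constant_frequencies(self, small_protocol):
        cfg = preset("low", "IS+", protocol=small_protocol, rates=ZERO)
        det = deterministic_trajectory(cfg)
        f0 = det.states[0].frequencies()
        for st in det.states:
            np.testing.assert_allclose(st.frequencies(), f0, atol=1e-12)

    def test_two_type_takeover_matches_independent_recursion(self, alleles):
        """Deterministic selection matches a per-day closed-form recursion.

        With two types at rates r1 < r2 and no mutation, one day maps the
        mutant frequency p to p*w/(p*w + 1 - p) with w = exp((r2-r1)*T) and
        T the day duration; T is recomputed independently by scalar root
        finding on the capacity equation.
        """
        env = Environment(demand=4.0, r0=0.2, rmax=0.9, cost_per_copy=0.01)
        proto = SerialProtocol(carrying_capacity=1e6, n_days=8)
        cfg = preset("low", "IS+", protocol=proto, environment=env, rates=ZERO)
        # seed the deterministic run manually: 99% ancestral, 1% (4,0)
        from dupdiv.evolve import _run

        inoculum = make_state(**{"1_0": 0.99 * proto.bottleneck_size, "4_0": 0.01 * proto.bottleneck_size})
        r1, r2 = 0.375, 0.87
        k_cap, dil = proto.carrying_capacity, proto.dilution_factor
        n1, n2 = inoculum.counts[0, 0], inoculum.counts[3, 0]
        p = n2 / (n1 + n2)
        total = n1 + n2
        expected = [p]
        for _ in range(proto.n_days):
            t = brentq(
                lambda t: total * ((1 - p) * math.exp(r1 * t) + p * math.exp(r2 * t)) - k_cap,
                0.0,
                60.0,
                rtol=1e-14,
            )
            w = math.exp((r2 - r1) * t)
            p = p * w / (p * w + 1 - p)
            expected.append(p)
            total = k_cap / dil
        # package recursion
        states = [inoculum]
        cur = inoculum
        for _ in range(proto.n_days):
            grown = grow_day(cur, env, alleles, ZERO, proto, None)
            states.append(grown)
            cur = bottleneck(grown, proto, None)
        observed = [st.counts[3, 0] / st.total for st in states]
        np.testing.assert_allclose(observed, expected, rtol=1e-6)

    def test_neutral_martingale_under_bottleneck(self):
        """With equal rates and no mutation, mean sampled frequency is unbiased."""
        env = Environment(demand=0.5, r0=0.2, rmax=0.9, cost_per_copy=0.0)
        proto = SerialProtocol(carrying_capacity=1e6, n_days=4)
        cfg = preset("low", "IS+", protocol=proto, environment=env, rates=ZERO)
        from dupdiv.evolve import _run

        freqs = []
        for s in range(150):
            rng = np.random.default_rng(s)
            cur = make_state(**{"1_0": 0.7 * proto.bottleneck_size, "2_0": 0.3 * proto.bottleneck_size})
            for _ in range(proto.n_days):
                grown = grow_day(cur, env, AlleleParams(), ZERO, proto, rng)
                cur = bottleneck(grown, proto, rng)
            freqs.append(cur.counts[1, 0] / cur.total)
        # 4 rounds of multinomial sampling at N=1220: se ~ sqrt(4*p*q/N)/sqrt(150)
        se = math.sqrt(4 * 0.3 * 0.7 / 1220) / math.sqrt(150)
        assert abs(np.mean(freqs) - 0.3) < 3 * se
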