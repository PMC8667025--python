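"""Stepping engines: exactness contracts, distributional law, audit counts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from presynmc import (ConfigurationError, ContractError, Environment, RNGAudit,
                      StateCounts, StateFractions, run_ensemble, simulate,
                      step_gaussian, step_multinomial, step_ode, step_standard,
                      transition_matrix)
from presynmc.engines import sample_flow_matrix

P_TWO = np.array([[0.999, 0.001], [0.0005, 0.9995]])
PERMUTE = np.array([[0.0, 1.0], [1.0, 0.0]])

STEP_FNS = {"standard": step_standard, "multinomial": step_multinomial}


@pytest.mark.parametrize("engine", ["standard", "multinomial"])
class TestCountEngineContracts:
    def test_identity_matrix_is_a_noop(self, engine, rng):
        audit = RNGAudit()
        counts = StateCounts(np.array([7, 0, 3]))
        out = STEP_FNS[engine](counts, np.eye(3), rng, audit)
        assert np.array_equal(out.counts, counts.counts)
        if engine == "standard":
            assert audit.uniform_draws == 10  # one per particle, always
        else:
            assert audit.multinomial_component_draws == 0  # single-outcome rows

    def test_permutation_matrix_swaps_deterministically(self, engine, rng):
        out = STEP_FNS[engine](StateCounts(np.array([5, 3])), PERMUTE, rng)
        assert np.array_equal(out.counts, [3, 5])

    def test_total_conserved_exactly(self, engine, rng, vdcc):
        P = transition_matrix(vdcc, Environment(0.0, 1e-7), 1e-6)
        counts = StateCounts(np.array([20, 10, 5, 0, 30]))
        for _ in range(200):
            counts = STEP_FNS[engine](counts, P, rng)
            assert counts.total == 65
            assert (counts.counts >= 0).all()

    def test_invalid_matrix_rejected(self, engine, rng):
        bad = np.array([[0.6, 0.6], [0.5, 0.5]])
        with pytest.raises(ContractError):
            STEP_FNS[engine](StateCounts(np.array([1, 1])), bad, rng)


@given(c0=st.integers(0, 50), c1=st.integers(0, 50), c2=st.integers(0, 50),
       p01=st.floats(0.0, 0.4), p02=st.floats(0.0, 0.4),
       p10=st.floats(0.0, 0.9), p21=st.floats(0.0, 0.9))
@settings(max_examples=60)
def test_conservation_over_random_chains(c0, c1, c2, p01, p02, p10, p21):
    """Both count engines conserve the total for arbitrary stochastic rows."""
    P = np.array([[1 - p01 - p02, p01, p02],
                  [p10, 1 - p10, 0.0],
                  [0.0, p21, 1 - p21]])
    counts = StateCounts(np.array([c0, c1, c2]))
    rng = np.random.default_rng(7)
    for engine in ("standard", "multinomial"):
        out = STEP_FNS[engine](counts, P, rng)
        assert out.total == counts.total
        assert (out.counts >= 0).all()


class TestSamplingLaw:
    def test_standard_engine_matches_binomial_law(self):
        """Symmetric 2-state row: state-0 occupancy after one step from
        (100, 0) is Binomial(100, 1/2); chi-square at alpha=0.01."""
        P = np.array([[0.5, 0.5], [0.5, 0.5]])
        rng = np.random.default_rng(2021)
        reps = 10_000
        outcomes = np.empty(reps, dtype=int)
        start = StateCounts(np.array([100, 0]))
        for r in range(reps):
            outcomes[r] = step_standard(start, P, rng).counts[0]
        edges = np.array([0, 40, 45, 48, 50, 52, 55, 60, 101])
        observed = np.histogram(outcomes, bins=edges)[0]
        cdf = stats.binom(100, 0.5).cdf
        expected = reps * np.diff(cdf(edges - 1e-9))
        expected *= observed.sum() / expected.sum()
        _, p = stats.chisquare(observed, expected)
        assert p > 0.01

    def test_engines_agree_in_law_on_rare_transitions(self):
        """One step of the 65-particle two-state chain: the number leaving
        state 0 is Binomial(65, 0.001) under both engines; two-sample
        chi-square at alpha=0.01 over 10,000 repetitions."""
        reps = 10_000
        start = StateCounts(np.array([65, 0]))
        moved = {}
        for engine, seed in (("standard", 11), ("multinomial", 12)):
            rng = np.random.default_rng(seed)
            moved[engine] = np.array(
                [STEP_FNS[engine](start, P_TWO, rng).counts[1] for _ in range(reps)])
        table = np.array([
            [np.sum(moved[e] == 0), np.sum(moved[e] == 1), np.sum(moved[e] >= 2)]
            for e in ("standard", "multinomial")])
        table = table[:, table.sum(axis=0) > 0]
        _, p, _, _ = stats.chi2_contingency(table)
        assert p > 0.01


class TestGaussianEngine:
    def test_zero_noise_reproduces_the_deterministic_update(self, rng, vdcc):
        P = transition_matrix(vdcc, Environment(0.0, 1e-7), 1e-6)
        start = StateCounts(np.array([30, 10, 10, 10, 5]))
        frac = step_gaussian(start, P, rng, noise_scale=0.0)
        ode = step_ode(start.fractions(), P)
        assert np.allclose(frac.fractions, ode.fractions, atol=1e-12)

    def test_no_noise_at_occupancy_boundaries(self, rng):
        """The spread n_i(n-n_i) vanishes at n_i = 0 and n_i = n, so a
        fully-occupied state under an identity matrix stays put."""
        out = step_gaussian(StateCounts(np.array([50, 0])), np.eye(2), rng)
        assert np.allclose(out.counts_scale(), [50, 0], atol=1e-12)

    def test_large_population_tracks_the_mean(self, two_state):
        P = transition_matrix(two_state, Environment(0.0, 1e-7), 1e-6)
        n = 10**6
        rng = np.random.default_rng(3)
        state = StateCounts(np.array([n, 0]))
        frac = state.fractions()
        gauss = state
        for _ in range(500):
            gauss = step_gaussian(gauss, P, rng)
            frac = step_ode(frac, P)
        assert np.allclose(gauss.fractions, frac.fractions, atol=1e-3)

    def test_clamping_visible_at_small_n_negligible_at_large_n(self):
        """The central-limit approximation audibly breaks at n=5 (clamp events
        are common) but not at n=1e5 (< 1e-4 per state-step).  The chain's
        stationary state puts ~0.5 particle in state 0, where the Gaussian
        tail regularly crosses zero when n is small."""
        P = np.array([[0.05, 0.95], [0.10, 0.90]])
        steps = 2000
        rates = {}
        for n in (5, 100_000):
            rng = np.random.default_rng(4)
            audit = RNGAudit()
            state = StateCounts(np.array([n, 0]))
            out = step_gaussian(state, P, rng, audit)
            for _ in range(steps - 1):
                out = step_gaussian(out, P, rng, audit)
            rates[n] = audit.gaussian_clamp_events / (steps * 2)
        assert rates[5] > 0.01
        assert rates[100_000] < 1e-4


class TestOdeEngine:
    def test_two_state_relaxation_matches_closed_form(self):
        """Symmetric 1000/s chain from (1,0): f0(t) = 1/2 + exp(-2000 t)/2."""
        P = np.array([[1 - 1e-3, 1e-3], [1e-3, 1 - 1e-3]])
        f = StateFractions(np.array([1.0, 0.0]), 1)
        worst = 0.0
        for k in range(1, 1001):
            f = step_ode(f, P)
            exact = 0.5 + 0.5 * np.exp(-2000.0 * k * 1e-6)
            worst = max(worst, abs(f.fractions[0] - exact) / exact)
        assert worst < 1e-2

    def test_stationary_vector_is_a_fixed_point(self, two_state):
        P = transition_matrix(two_state, Environment(0.0, 1e-7), 1e-6)
        pi = np.array([1 / 3, 2 / 3])  # k10/(k01+k10), k01/(k01+k10)
        out = step_ode(StateFractions(pi, 1), P)
        assert np.allclose(out.fractions, pi, atol=1e-15)

    def test_mass_conserved_over_long_runs(self, vdcc):
        res = simulate(vdcc, "ode", Environment(-20.0, 1e-7),
                       StateCounts.single_state(5, 0, 65), 0.01, 1e-6)
        totals = res.states.sum(axis=1)
        assert np.abs(totals - 65).max() < 1e-9


class TestSimulate:
    def test_identical_seeds_identical_trajectories(self, vdcc):
        from presynmc import make_action_potential
        ap = make_action_potential(duration_s=2e-3)
        kw = dict(duration_s=2e-3, dt_s=1e-6, seed=42)
        a = simulate(vdcc, "multinomial", ap, StateCounts.single_state(5, 0, 65), **kw)
        b = simulate(vdcc, "multinomial", ap, StateCounts.single_state(5, 0, 65), **kw)
        assert np.array_equal(a.states, b.states)
        assert a.audit.to_dict() == b.audit.to_dict()

    def test_resting_voltage_keeps_channels_near_closed_steady_state(self, vdcc):
        from presynmc import constant_trace
        res = simulate(vdcc, "multinomial", constant_trace(-70.0, 0.01, 1e-6),
                       StateCounts.single_state(5, 0, 65), 0.01, 1e-6, seed=5)
        open_frac = res.states[:, 4] / 65
        assert open_frac.max() <= 3 / 65  # stray openings only

    def test_zero_rate_scheme_constant_under_every_engine(self):
        from presynmc import build_vdcc_scheme
        scheme = build_vdcc_scheme(
            [{"alpha0": 0, "v_alpha": 50, "beta0": 0, "v_beta": 50}] * 4)
        start = StateCounts(np.array([10, 20, 5, 0, 30]))
        for engine in ("standard", "multinomial", "ode"):
            res = simulate(scheme, engine, Environment(-70.0, 1e-7), start,
                           1e-3, 1e-6, seed=1)
            assert np.allclose(res.states, res.states[0], atol=1e-9)
        # the Gaussian engine's spread vanishes only at the occupancy
        # boundaries, so its zero-rate trajectory is constant from a
        # single-state start
        res = simulate(scheme, "gaussian", Environment(-70.0, 1e-7),
                       StateCounts.single_state(5, 0, 65), 1e-3, 1e-6, seed=1)
        assert np.allclose(res.states, res.states[0], atol=1e-9)

    def test_audit_laws(self, vdcc):
        env = Environment(-10.0, 1e-7)
        start = StateCounts.single_state(5, 0, 65)
        T = 1000
        std = simulate(vdcc, "standard", env, start, T * 1e-6, 1e-6, seed=1)
        assert std.audit.uniform_draws == 65 * T
        multi = simulate(vdcc, "multinomial", env, start, T * 1e-6, 1e-6, seed=1)
        bound = int(vdcc.branch_counts.sum()) * T
        assert multi.audit.multinomial_component_draws <= bound <= \
            vdcc.max_branch * vdcc.s * T
        gauss = simulate(vdcc, "gaussian", env, start, T * 1e-6, 1e-6, seed=1)
        assert gauss.audit.normal_draws == 5 * T
        ode = simulate(vdcc, "ode", env, start, T * 1e-6, 1e-6)
        assert ode.audit.total_draws == 0

    def test_short_stimulus_rejected(self, vdcc):
        from presynmc import constant_trace
        with pytest.raises(ConfigurationError, match="stimulus"):
            simulate(vdcc, "ode", constant_trace(-70.0, 1e-3, 1e-6),
                     StateCounts.single_state(5, 0, 65), 5e-3, 1e-6)


class TestEnsemble:
    def test_single_run_has_zero_sd(self, two_state):
        ens = run_ensemble(two_state, "multinomial", Environment(0.0, 1e-7),
                           StateCounts(np.array([50, 0])), 1e-3, 1e-6, n_runs=1)
        assert np.all(ens.sd == 0.0)

    def test_fixed_base_seed_reproduces_bit_exactly(self, two_state):
        args = (two_state, "standard", Environment(0.0, 1e-7),
                StateCounts(np.array([20, 0])), 5e-4, 1e-6)
        a = run_ensemble(*args, n_runs=8, base_seed=99, keep_runs=True)
        b = run_ensemble(*args, n_runs=8, base_seed=99, keep_runs=True)
        assert np.array_equal(a.runs, b.runs)

    def test_ensemble_mean_approaches_the_deterministic_trajectory(self, two_state):
        """CLT over runs: the multinomial ensemble mean deviates from the
        Euler mean by less than 4 standard errors at the final timepoint."""
        env = Environment(0.0, 1e-7)
        start = StateCounts(np.array([65, 0]))
        ens = run_ensemble(two_state, "multinomial", env, start, 1e-3, 1e-6,
                           n_runs=1000, base_seed=17)
        ode = simulate(two_state, "ode", env, start, 1e-3, 1e-6)
        se = ens.sd[-1] / np.sqrt(ens.n_runs)
        dev = np.abs(ens.mean[-1] - ode.states[-1])
        assert np.all(dev <= 4 * np.maximum(se, 1e-12))
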