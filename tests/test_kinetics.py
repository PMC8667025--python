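"""Scheme construction and transition-probability matrices."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from presynmc import (ConfigurationError, Environment, KineticScheme, KineticState,
                      RateKind, RateLaw, TimestepTooLargeError, Transition,
                      build_calbindin_scheme, build_vdcc_scheme, export_edge_list,
                      load_scheme, save_scheme, transition_matrix)
from presynmc.kinetics import (default_calbindin_params, default_vdcc_params,
                               max_admissible_dt, scheme_from_dict, scheme_to_dict)

ENV_REST = Environment(membrane_voltage=-70.0, free_calcium=1e-7)


class TestVdccScheme:
    def test_structure(self, vdcc):
        assert vdcc.s == 5
        assert vdcc.state_names == ["C0", "C1", "C2", "C3", "O"]
        assert len(vdcc.transitions) == 8
        assert vdcc.max_branch == 2
        assert list(vdcc.branch_counts) == [1, 2, 2, 2, 1]

    def test_forward_edges_grow_with_depolarization_backward_shrink(self, vdcc):
        dt = 1e-6
        voltages = [-90.0, -50.0, -10.0, 30.0]
        mats = [transition_matrix(vdcc, Environment(v, 1e-7), dt) for v in voltages]
        for i in range(4):
            fwd = [P[i, i + 1] for P in mats]
            bwd = [P[i + 1, i] for P in mats]
            assert np.all(np.diff(fwd) > 0), f"alpha step {i} not increasing in V"
            assert np.all(np.diff(bwd) < 0), f"beta step {i} not decreasing in V"

    def test_hyperpolarized_limit_closes_the_chain(self, vdcc):
        p01 = [transition_matrix(vdcc, Environment(v, 1e-7), 1e-8)[0, 1]
               for v in (-40.0, -80.0, -120.0, -200.0)]
        assert np.all(np.diff(p01) < 0)
        P = transition_matrix(vdcc, Environment(-200.0, 1e-7), 1e-8)
        assert P[0, 0] == pytest.approx(1.0, abs=1e-5)

    def test_missing_parameter_names_the_step(self):
        params = default_vdcc_params()
        del params[2]["beta0"]
        with pytest.raises(ConfigurationError, match="C2<->C3"):
            build_vdcc_scheme(params)

    def test_all_zero_rates_give_identity_matrix(self):
        params = [{"alpha0": 0.0, "v_alpha": 50.0, "beta0": 0.0, "v_beta": 50.0}
                  for _ in range(4)]
        scheme = build_vdcc_scheme(params)
        for dt in (1e-6, 1e-3, 1.0):
            assert np.array_equal(transition_matrix(scheme, ENV_REST, dt), np.eye(5))

    def test_degenerate_two_state_chain(self):
        """C0 <-> O with huge voltage scales behaves as constant 1000/s rates."""
        scheme = KineticScheme(
            [KineticState("C0", 0), KineticState("O", 1)],
            [Transition(0, 1, RateLaw(RateKind.VOLTAGE_EXP, 1000.0, voltage_scale=1e9)),
             Transition(1, 0, RateLaw(RateKind.VOLTAGE_EXP, 1000.0, voltage_scale=-1e9))])
        assert scheme.s == 2
        assert list(scheme.branch_counts) == [1, 1]
        P = transition_matrix(scheme, ENV_REST, 1e-6)
        assert P[0, 1] == pytest.approx(1e-3, rel=1e-6)
        assert P[1, 0] == pytest.approx(1e-3, rel=1e-6)


class TestCalbindinScheme:
    def test_structure(self, calbindin):
        assert calbindin.s == 9
        assert len(calbindin.transitions) == 24
        b = calbindin.branch_counts
        # corners of the 3x3 occupancy grid branch 2 ways, edges 3, center 4
        by_name = dict(zip(calbindin.state_names, b))
        assert {by_name[n] for n in ("H0M0", "H0M2", "H2M0", "H2M2")} == {2}
        assert {by_name[n] for n in ("H0M1", "H1M0", "H1M2", "H2M1")} == {3}
        assert by_name["H1M1"] == 4

    def test_zero_calcium_blocks_binding_only(self, calbindin):
        P = transition_matrix(calbindin, Environment(0.0, 0.0), 1e-6)
        i, j = calbindin.index_of("H0M0"), calbindin.index_of("H1M0")
        assert P[i, j] == 0.0
        assert P[j, i] > 0.0  # unbinding proceeds

    def test_binding_probability_linear_in_calcium(self, calbindin):
        i, j = calbindin.index_of("H0M0"), calbindin.index_of("H1M0")
        p1 = transition_matrix(calbindin, Environment(0.0, 1e-6), 1e-6)[i, j]
        p3 = transition_matrix(calbindin, Environment(0.0, 3e-6), 1e-6)[i, j]
        assert p3 == pytest.approx(3 * p1, rel=1e-12)

    def test_detailed_balance_on_the_four_cycle(self, calbindin):
        """Independent sites: clockwise and counterclockwise rate products match
        around H0M0 -> H1M0 -> H1M1 -> H0M1 -> H0M0 at fixed calcium."""
        env = Environment(0.0, 1e-6)
        rates = {}
        for tr in calbindin.transitions:
            key = (calbindin.state_names[tr.source], calbindin.state_names[tr.target])
            rates[key] = tr.law.evaluate(env)
        cw = (rates[("H0M0", "H1M0")] * rates[("H1M0", "H1M1")]
              * rates[("H1M1", "H0M1")] * rates[("H0M1", "H0M0")])
        ccw = (rates[("H0M0", "H0M1")] * rates[("H0M1", "H1M1")]
               * rates[("H1M1", "H1M0")] * rates[("H1M0", "H0M0")])
        assert cw == pytest.approx(ccw, rel=1e-12)

    def test_negative_rates_rejected(self):
        params = default_calbindin_params()
        params["high"]["k_on"] = -1.0
        with pytest.raises(ConfigurationError):
            build_calbindin_scheme(params)


class TestTransitionMatrix:
    def test_two_state_exact_values(self, two_state):
        P = transition_matrix(two_state, ENV_REST, 1e-6)
        assert np.allclose(P, [[0.999, 0.001], [0.0005, 0.9995]], atol=1e-15)

    @pytest.mark.parametrize("voltage", [-90.0, -70.0, -20.0, 0.0, 30.0])
    @pytest.mark.parametrize("calcium", [0.0, 1e-7, 1e-5])
    def test_rows_stochastic_everywhere(self, vdcc, calbindin, voltage, calcium):
        env = Environment(voltage, calcium)
        for scheme in (vdcc, calbindin):
            P = transition_matrix(scheme, env, 1e-6)
            assert np.all(P >= 0) and np.all(P <= 1)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)

    def test_offdiagonal_homogeneous_in_dt(self, vdcc):
        env = Environment(-20.0, 1e-7)
        P1 = transition_matrix(vdcc, env, 1e-6)
        P2 = transition_matrix(vdcc, env, 2e-6)
        off = ~np.eye(5, dtype=bool)
        assert np.allclose(P2[off], 2 * P1[off], rtol=1e-12)

    def test_timestep_too_large_reports_state_and_bound(self, two_state):
        dt_max = max_admissible_dt(two_state, ENV_REST)
        assert dt_max == pytest.approx(1e-3)
        with pytest.raises(TimestepTooLargeError) as exc:
            transition_matrix(two_state, ENV_REST, 2e-3)
        assert exc.value.state_name == "A"
        assert exc.value.dt_max == pytest.approx(1e-3)

    @given(dt=st.floats(1e-8, 9e-4), k01=st.floats(0.0, 1000.0),
           k10=st.floats(0.0, 1000.0))
    def test_row_sums_invariant_over_rates(self, dt, k01, k10):
        scheme = KineticScheme(
            [KineticState("A", 0), KineticState("B", 1)],
            [Transition(0, 1, RateLaw(RateKind.CONSTANT, k01)),
             Transition(1, 0, RateLaw(RateKind.CONSTANT, k10))])
        P = transition_matrix(scheme, ENV_REST, dt)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
        assert np.all((P >= 0) & (P <= 1))


class TestSchemeIO:
    def test_yaml_roundtrip_preserves_matrix(self, tmp_path, vdcc, calbindin):
        env = Environment(-10.0, 2e-6)
        for scheme in (vdcc, calbindin):
            path = tmp_path / f"{scheme.name}.yaml"
            save_scheme(scheme, path)
            loaded = load_scheme(path)
            assert loaded.state_names == scheme.state_names
            assert np.allclose(transition_matrix(loaded, env, 1e-6),
                               transition_matrix(scheme, env, 1e-6))

    def test_dict_roundtrip(self, calbindin):
        again = scheme_from_dict(scheme_to_dict(calbindin))
        assert len(again.transitions) == 24

    def test_edge_list_export(self, vdcc):
        text = export_edge_list(vdcc)
        lines = text.strip().splitlines()
        assert lines[0].split("\t") == ["source", "target", "kind", "base_rate", "scale"]
        assert len(lines) == 1 + 8
        assert any(line.startswith("C3\tO\tvoltage_exp") for line in lines)

    def test_invalid_schemes_rejected(self):
        with pytest.raises(ConfigurationError):  # duplicate edge
            KineticScheme([KineticState("A", 0), KineticState("B", 1)],
                          [Transition(0, 1, RateLaw(RateKind.CONSTANT, 1.0)),
                           Transition(0, 1, RateLaw(RateKind.CONSTANT, 2.0))])
        with pytest.raises(ConfigurationError):  # disconnected
            KineticScheme([KineticState("A", 0), KineticState("B", 1),
                           KineticState("C", 2)],
                          [Transition(0, 1, RateLaw(RateKind.CONSTANT, 1.0))])
        with pytest.raises(ConfigurationError):  # self loop
            Transition(1, 1, RateLaw(RateKind.CONSTANT, 1.0))
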