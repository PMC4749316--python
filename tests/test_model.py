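"""Unit and property tests for the core model equations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import avianlung as al
from avianlung.model import CONFIG_KEYS, ParameterError, regime_for_label

# strategy for physically admissible resistances/compliances (log-uniform-ish)
pos = st.floats(min_value=0.05, max_value=200.0, allow_nan=False)
state_val = st.floats(min_value=-5.0, max_value=5.0, allow_nan=False)


def _random_params(rng: np.random.Generator) -> al.ModelParameters:
    """Random positive parameter set satisfying the valving ordering."""
    R1_insp = rng.uniform(0.2, 10.0)
    R2_exp = rng.uniform(0.2, 10.0)
    cfg = dict(
        P_atm=1033.6,
        R_T=rng.uniform(0.5, 30.0),
        R_P=rng.uniform(0.5, 10.0),
        R1_insp=R1_insp,
        R2_exp=R2_exp,
        R2_insp=R1_insp * rng.uniform(1.0, 150.0),
        R1_exp=R2_exp * rng.uniform(1.0, 30.0),
        gamma=rng.uniform(0.2, 5.0),
        C_tot=rng.uniform(50.0, 1000.0),
        V1_res=105.6,
        V2_res=103.6,
        P_c=1033.6,
        P_amp=rng.uniform(0.1, 2.0),
        T=rng.uniform(1.0, 6.0),
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return al.resolve_parameters(cfg)


class TestResolveParameters:
    def test_table_defaults_linkage(self, default_params):
        p = default_params
        assert p.R_T == pytest.approx(10.0)  # 2 * 1 + 8
        assert p.C1 * 1e3 == pytest.approx(258.5, abs=0.05)
        assert p.C2 * 1e3 == pytest.approx(191.5, abs=0.05)
        assert p.R2_insp == pytest.approx(100.0)
        assert p.R1_exp == pytest.approx(50.0)

    def test_symmetric_compliance_split(self):
        cfg = al.preset_config("default")
        cfg["gamma"] = 1.0
        p = al.resolve_parameters(cfg)
        assert p.C1 == pytest.approx(p.C2) == pytest.approx(0.225)

    def test_split_compliances_accepted(self):
        cfg = al.preset_config("default")
        del cfg["gamma"], cfg["C_tot"]
        cfg["C1"] = 270.0
        cfg["C2"] = 180.0
        p = al.resolve_parameters(cfg)
        assert p.gamma == pytest.approx(1.5)
        assert p.C_tot == pytest.approx(0.45)

    def test_conflicting_inputs_rejected(self):
        cfg = al.preset_config("default")
        cfg["C1"] = 200.0  # inconsistent with C_tot=450, gamma=1.35
        cfg["C2"] = 250.0
        with pytest.raises(ParameterError, match="over-determined"):
            al.resolve_parameters(cfg)

    def test_missing_key_named_in_error(self):
        cfg = al.preset_config("default")
        del cfg["P_amp"]
        with pytest.raises(ParameterError, match="P_amp"):
            al.resolve_parameters(cfg)

    def test_unknown_key_rejected(self):
        cfg = al.preset_config("default")
        cfg["R_bogus"] = 1.0
        with pytest.raises(ParameterError, match="R_bogus"):
            al.resolve_parameters(cfg)

    def test_non_positive_rejected(self):
        cfg = al.preset_config("default")
        cfg["R_P"] = -2.5
        with pytest.raises(ParameterError, match="R_P"):
            al.resolve_parameters(cfg)

    def test_idempotent(self, default_params):
        again = al.resolve_parameters(default_params.to_config())
        for name in ("R_T", "R1_exp", "R2_insp", "C1", "C2", "gamma", "V1_res"):
            assert getattr(again, name) == pytest.approx(getattr(default_params, name), rel=1e-12)


class TestForcing:
    @pytest.mark.parametrize(
        "frac, expected",
        [(0.0, -0.5), (0.25, 0.0), (0.5, +0.5)],  # offsets from P_c in units of P_amp
    )
    def test_extremes_and_node(self, default_params, frac, expected):
        p = default_params
        assert al.external_pressure(frac * p.T, p) == pytest.approx(
            p.P_c + expected * p.P_amp, abs=1e-12
        )

    def test_period_and_range(self, default_params):
        p = default_params
        t = np.linspace(0, p.T, 4001)
        vals = al.external_pressure(t, p)
        assert np.ptp(vals) == pytest.approx(p.P_amp, rel=1e-6)
        assert al.external_pressure(t + p.T, p) == pytest.approx(vals, abs=1e-12)

    def test_rate_matches_finite_difference(self, default_params):
        p = default_params
        h = 1e-6
        fd = (al.external_pressure(0.3 + h, p) - al.external_pressure(0.3 - h, p)) / (2 * h)
        assert al.external_pressure_rate(0.3, p) == pytest.approx(fd, rel=1e-6)
        assert al.external_pressure_rate(0.0, p) == pytest.approx(0.0, abs=1e-15)
        assert al.external_pressure_rate(p.T / 4, p) == pytest.approx(p.P_amp * np.pi / p.T)


class TestRegimes:
    @pytest.mark.parametrize(
        "regime, expected",
        [
            (al.REGION_1, (1.0, 100.0)),
            (al.REGION_23, (50.0, 100.0)),
            (al.REGION_4, (50.0, 5.0)),
        ],
    )
    def test_branch_selection(self, default_params, regime, expected):
        assert al.regime_resistances(regime, default_params) == pytest.approx(expected)

    def test_unreachable_combination_rejected(self):
        with pytest.raises(ParameterError):
            al.FlowRegime("insp", "exp")

    def test_label_mapping(self):
        assert al.REGION_1.label == "1"
        assert al.REGION_23.label == "23"
        assert al.REGION_4.label == "4"
        assert regime_for_label("2") == al.REGION_23


class TestFlows:
    def test_equilibrium_is_quiescent(self, default_params):
        f = al.compute_flows(0.0, 0.0, al.REGION_1, default_params)
        assert f.q_T == f.q_1 == f.q_2 == f.q_P == 0.0
        assert f.P_J == pytest.approx(default_params.P_atm)

    def test_against_junction_linear_system(self, default_params):
        """Closed-form flows must solve the 3x3 junction balance directly."""
        p = default_params
        rng = np.random.default_rng(42)
        for regime in (al.REGION_1, al.REGION_23, al.REGION_4):
            R1, R2 = al.regime_resistances(regime, p)
            for _ in range(20):
                x1, x2 = rng.uniform(-1, 1, 2)
                P1, P2 = x1 + p.P_atm, x2 + p.P_atm
                # unknowns (q1, q2, P_J): junction mass balance + two branch laws
                M = np.array([[p.R_T, -p.R_T, 1.0], [-R1, 0.0, 1.0], [0.0, R2, 1.0]])
                b = np.array([p.P_atm, P1, P2])
                q1, q2, PJ = np.linalg.solve(M, b)
                f = al.compute_flows(x1, x2, regime, p)
                assert f.q_1 == pytest.approx(q1, rel=1e-9, abs=1e-12)
                assert f.q_2 == pytest.approx(q2, rel=1e-9, abs=1e-12)
                assert f.P_J == pytest.approx(PJ, rel=1e-12)
                assert f.q_T == pytest.approx((p.P_atm - PJ) / p.R_T, rel=1e-9, abs=1e-12)

    def test_worked_example_region1(self, default_params):
        f = al.compute_flows(-0.1, -0.05, al.REGION_1, default_params)
        assert f.q_T == pytest.approx(10.05 / 1110, rel=1e-9)
        assert f.q_1 == pytest.approx(10.5 / 1110, rel=1e-9)
        assert f.q_2 == pytest.approx(0.45 / 1110, rel=1e-9)
        assert f.q_P == pytest.approx(-0.02, rel=1e-12)

    @settings(max_examples=200, derandomize=True)
    @given(x1=state_val, x2=state_val, seed=st.integers(0, 2**31 - 1))
    def test_junction_conservation_property(self, x1, x2, seed):
        """q_T + q_2 = q_1 for every state, regime and positive parameter set."""
        p = _random_params(np.random.default_rng(seed))
        for regime in (al.REGION_1, al.REGION_23, al.REGION_4):
            f = al.compute_flows(x1, x2, regime, p)
            assert f.q_T + f.q_2 == pytest.approx(f.q_1, rel=1e-12, abs=1e-15)


class TestDerivative:
    def test_equilibrium_fixed_point(self, default_params):
        d = al.state_derivative(0.0, (0.0, 0.0), al.REGION_1, default_params)
        assert d == pytest.approx((0.0, 0.0), abs=1e-15)

    def test_flow_form_equals_matrix_form(self):
        """dx_i/dt from the branch flows must equal the matrix right-hand side."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            p = _random_params(rng)
            regime = (al.REGION_1, al.REGION_23, al.REGION_4)[rng.integers(3)]
            x1, x2 = rng.uniform(-1, 1, 2)
            t = rng.uniform(0, p.T)
            f = al.compute_flows(x1, x2, regime, p)
            rate = al.external_pressure_rate(t, p)
            flow_form = np.array(
                [(f.q_1 - f.q_P) / p.C1 + rate, (f.q_P - f.q_2) / p.C2 + rate]
            )
            matrix_form = al.state_derivative(t, (x1, x2), regime, p)
            np.testing.assert_allclose(matrix_form, flow_form, rtol=1e-12, atol=1e-14)

    def test_equal_pressures_have_no_parabronchial_coupling(self, default_params):
        f = al.compute_flows(0.3, 0.3, al.REGION_1, default_params)
        assert f.q_P == 0.0


class TestVolumes:
    def test_resting_volumes_at_equilibrium(self, default_params):
        p = default_params
        # at t = T/4 the forcing equals P_c = P_atm, so x = 0 gives V_res
        V1, V2 = al.airsac_volumes(0.0, 0.0, p.T / 4, p)
        assert V1 == pytest.approx(105.6, abs=1e-9)
        assert V2 == pytest.approx(103.6, abs=1e-9)

    def test_forcing_offset_at_t0(self, default_params):
        p = default_params
        V1, _ = al.airsac_volumes(0.0, 0.0, 0.0, p)
        assert V1 == pytest.approx(105.6 + 258.5106382978723 * 0.25, rel=1e-9)

    def test_rigid_sac_limit(self):
        cfg = al.preset_config("default")
        cfg["C_tot"] = 1e-9
        p = al.resolve_parameters(cfg)
        V1, V2 = al.airsac_volumes(0.5, -0.5, 0.0, p)
        assert V1 == pytest.approx(105.6, abs=1e-6)
        assert V2 == pytest.approx(103.6, abs=1e-6)

    def test_negative_volume_warns(self, default_params):
        with pytest.warns(UserWarning, match="non-positive"):
            al.airsac_volumes(-1e4, 0.0, 0.0, default_params)


class TestClassifyRegion:
    def test_inspiratory_state(self, default_params):
        label, signs = al.classify_region(-0.2, -0.1, default_params)
        assert label == "1"
        assert signs["q_1"] > 0 and signs["q_T"] > 0

    def test_expiratory_state(self, default_params):
        label, signs = al.classify_region(0.1, 0.2, default_params)
        assert label == "4"
        assert signs["q_2"] > 0

    def test_equilibrium_tie_break(self, default_params):
        label, signs = al.classify_region(0.0, 0.0, default_params)
        assert label == "1"
        assert signs == {"q_T": 0.0, "q_1": 0.0, "q_2": 0.0}

    def test_labels_match_flow_signs(self, default_params):
        """Region label must agree with the branch-flow signs it implies."""
        rng = np.random.default_rng(3)
        for _ in range(200):
            x1, x2 = rng.uniform(-0.5, 0.5, 2)
            label, signs = al.classify_region(x1, x2, default_params)
            if label == "1":
                assert signs["q_1"] >= 0
            elif label == "4":
                assert signs["q_2"] > 0
            else:
                assert signs["q_1"] < 0 and signs["q_2"] <= 0
                assert (signs["q_T"] > 0) == (label == "2")


def test_config_keys_cover_presets():
    for preset in al.PRESETS:
        assert set(al.preset_config(preset)) <= CONFIG_KEYS
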