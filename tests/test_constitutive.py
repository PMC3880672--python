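"""Energy, Cauchy stress, consistency conditions, and the stress oracle."""
import numpy as np
import pytest

import resmyo as rm
from resmyo.constitutive import numerical_energy_gradient
from resmyo.errors import ConfigurationError, InvalidInputError

from conftest import random_frame, random_isochoric_F, random_sym

IDENTITY = rm.make_deformation(np.eye(3))
FRAME = rm.FibreFrame.canonical()


class TestEnergy:
    def test_baseline_identity(self, params):
        inv = rm.invariants(IDENTITY, FRAME)
        assert rm.energy("baseline", params, inv) == pytest.approx(
            params.a / (2 * params.b))

    def test_simple_identity_adds_half_trace(self, params):
        tau = np.diag([1.0, 2.0, 3.0])
        inv = rm.invariants(IDENTITY, FRAME, tau)
        W = rm.energy("simple", params, inv)
        assert W == pytest.approx(params.a / (2 * params.b) + 3.0)

    def test_extended_identity_residual_part(self, params):
        # I6 = I7 = tr tau = 6 at identity -> residual part (1/4 + 1/8) * 6
        tau = np.diag([1.0, 2.0, 3.0])
        inv = rm.invariants(IDENTITY, FRAME, tau)
        W = rm.energy("extended", params, inv)
        assert W - params.a / (2 * params.b) == pytest.approx(2.25)

    def test_unknown_model_rejected(self, params):
        with pytest.raises(ConfigurationError):
            rm.energy("exotic", params, rm.invariants(IDENTITY, FRAME))

    def test_tension_switch_continuity(self, params):
        """Energy and stress are continuous across I4f = 1."""
        eps = 1e-8
        Ws, sigs = [], []
        for lam2 in (1.0 - eps, 1.0, 1.0 + eps):
            lam = np.sqrt(lam2)
            F = np.diag([lam, 1 / lam, 1.0])
            state = rm.make_deformation(F)
            Ws.append(rm.energy("baseline", params,
                                rm.invariants(state, FRAME)))
            sigs.append(rm.cauchy_stress("baseline", params, state,
                                         FRAME).sigma_hat)
        assert abs(Ws[2] - Ws[0]) < 1e-6
        assert np.max(np.abs(sigs[2] - sigs[0])) < 1e-6


class TestCauchyStress:
    def test_unloaded_configuration_returns_tau(self, params):
        """sigma(F=I, p=a) = tau exactly, for both residual models."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            tau = random_sym(rng)
            for model in ("simple", "extended"):
                res = rm.cauchy_stress(model, params, IDENTITY, FRAME, tau,
                                       p=params.a)
                assert np.max(np.abs(res.sigma - tau)) < 1e-14

    def test_zero_tau_models_coincide(self, params):
        rng = np.random.default_rng(12)
        F = random_isochoric_F(rng)
        state = rm.make_deformation(F)
        frame = random_frame(rng)
        z = np.zeros((3, 3))
        sb = rm.cauchy_stress("baseline", params, state, frame).sigma_hat
        ss = rm.cauchy_stress("simple", params, state, frame, z).sigma_hat
        se = rm.cauchy_stress("extended", params, state, frame, z).sigma_hat
        assert np.allclose(sb, ss, atol=1e-14)
        assert np.allclose(sb, se, atol=1e-14)

    def test_missing_tau_is_configuration_error(self, params):
        with pytest.raises(ConfigurationError):
            rm.cauchy_stress("simple", params, IDENTITY, FRAME)

    def test_symmetry(self, params):
        rng = np.random.default_rng(13)
        state = rm.make_deformation(random_isochoric_F(rng))
        res = rm.cauchy_stress("extended", params, state, random_frame(rng),
                               random_sym(rng))
        assert np.max(np.abs(res.sigma - res.sigma.T)) < 1e-10

    def test_traction_condition_sets_pressure(self, params):
        rng = np.random.default_rng(14)
        state = rm.make_deformation(random_isochoric_F(rng))
        n = np.array([0.0, 0.0, 1.0])
        res = rm.cauchy_stress("baseline", params, state, FRAME,
                               traction=(n, -0.4))
        assert n @ res.sigma @ n == pytest.approx(-0.4, abs=1e-12)

    @pytest.mark.parametrize("model", ["baseline", "simple", "extended"])
    def test_finite_difference_oracle(self, params, model):
        """Analytic stress equals central-difference F dW/dF."""
        rng = np.random.default_rng(2024)
        worst = 0.0
        for _ in range(40):
            F = random_isochoric_F(rng)
            frame = random_frame(rng)
            tau = None if model == "baseline" else random_sym(rng)
            state = rm.make_deformation(F)
            sig = rm.cauchy_stress(model, params, state, frame, tau).sigma_hat
            ref = numerical_energy_gradient(model, params, F, frame, tau)
            worst = max(worst, np.max(np.abs(sig - ref))
                        / max(np.max(np.abs(ref)), 1.0))
        assert worst < 1e-6

    def test_simple_extended_converge_as_tau_shrinks(self, params):
        """|sigma_simple - sigma_extended| = O(|tau| |B - I|): halving tau
        halves the gap (it is exactly linear in tau)."""
        rng = np.random.default_rng(15)
        F = random_isochoric_F(rng)
        state = rm.make_deformation(F)
        frame = random_frame(rng)
        tau0 = random_sym(rng)
        gaps = []
        for t in (1.0, 0.5, 0.25, 0.125):
            ss = rm.cauchy_stress("simple", params, state, frame, t * tau0)
            se = rm.cauchy_stress("extended", params, state, frame, t * tau0)
            gaps.append(np.max(np.abs(ss.sigma_hat - se.sigma_hat)))
        for g1, g2 in zip(gaps, gaps[1:]):
            assert g2 == pytest.approx(g1 / 2, rel=1e-9)

    def test_full_invariant_mode_matches_extended_when_W8_zero(self, params):
        rng = np.random.default_rng(16)
        state = rm.make_deformation(random_isochoric_F(rng))
        frame = random_frame(rng)
        tau = random_sym(rng)
        full = rm.cauchy_stress_full(params, state, frame, tau,
                                     W6=0.25, W7=0.125)
        ext = rm.cauchy_stress("extended", params, state, frame, tau)
        assert np.allclose(full.sigma_hat, ext.sigma_hat, atol=1e-13)

    def test_full_invariant_mode_enforces_consistency(self, params):
        with pytest.raises(ConfigurationError):
            rm.cauchy_stress_full(params, IDENTITY, FRAME, np.eye(3),
                                  W6=0.5, W7=0.1)


class TestConsistencyConstants:
    def test_simple(self, params):
        cc = rm.consistency_constants("simple", params)
        assert cc["W6"] == 0.5 and cc["W7"] == 0.0
        assert 2 * (cc["W6"] + 2 * cc["W7"]) == 1.0

    def test_extended(self, params):
        cc = rm.consistency_constants("extended", params)
        assert (cc["W6"], cc["W7"]) == (0.25, 0.125)
        assert 2 * (cc["W6"] + 2 * cc["W7"]) == 1.0

    @pytest.mark.parametrize("model", ["simple", "extended"])
    def test_quadratic_terms_vanish(self, params, model):
        cc = rm.consistency_constants(model, params)
        assert cc["W8"] + 2 * cc["W9"] == 0.0
        assert cc["p_r"] == params.a == 2 * cc["W1"]


class TestReducedForms:
    def test_identity_gives_trace(self, params):
        inv = rm.invariants(IDENTITY, FRAME)
        assert rm.reduced_I6(0.1, -0.2, 0.05, inv) == pytest.approx(-0.05)

    def test_isotropic_tau_gives_t_I1(self):
        rng = np.random.default_rng(17)
        state = rm.make_deformation(random_isochoric_F(rng))
        inv = rm.invariants(state, FRAME)
        t = 0.3
        assert rm.reduced_I6(t, t, t, inv) == pytest.approx(t * inv.I1)

    def test_matches_direct_trace(self):
        rng = np.random.default_rng(18)
        comps = (-0.1, 0.02, 0.05)
        for _ in range(20):
            frame = random_frame(rng)
            state = rm.make_deformation(random_isochoric_F(rng))
            inv = rm.invariants(state, frame)
            tau = rm.ResidualStressTensor.from_principal(*comps, frame)
            I6_direct, I7_direct, _, _ = rm.residual_invariants(state, tau.tau)
            assert rm.reduced_I6(*comps, inv) == pytest.approx(I6_direct,
                                                               abs=1e-10)
            assert rm.reduced_I7(*comps, inv) == pytest.approx(I7_direct,
                                                               abs=1e-10)

    def test_non_principal_rejected(self):
        inv = rm.invariants(IDENTITY, FRAME)
        tau = rm.ResidualStressTensor.from_matrix(np.full((3, 3), 0.1))
        with pytest.raises(InvalidInputError):
            rm.reduced_I6_from_tensor(tau, inv)


class TestMaterialParams:
    def test_default_values_load(self, params):
        assert params.a == pytest.approx(0.236)
        assert params.b_fs == pytest.approx(11.3)

    def test_negative_rejected(self):
        with pytest.raises(ConfigurationError):
            rm.MaterialParams(a=-1, b=1, a_f=1, b_f=1, a_s=1, b_s=1,
                              a_fs=1, b_fs=1)

    def test_strict_parse_rejects_unknown_keys(self):
        good = {k: 1.0 for k in
                ("a", "b", "a_f", "b_f", "a_s", "b_s", "a_fs", "b_fs")}
        rm.MaterialParams.from_mapping(good)
        with pytest.raises(ConfigurationError):
            rm.MaterialParams.from_mapping({**good, "c": 2.0})
        with pytest.raises(ConfigurationError):
            rm.MaterialParams.from_mapping({"a": 1.0})
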