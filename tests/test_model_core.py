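"""Parameter presets, the right-hand side, and cost transforms."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phagecomm.model_core import (
    CommunityParams,
    CommunityState,
    apply_cost,
    jacobian,
    preset_params,
    rhs,
    rhs_array,
)


class TestPresets:
    def test_competition_preset(self, competition):
        assert competition.R == 2.0
        assert competition.kappa_E == competition.kappa_S == 0.0
        assert competition.beta_ES == competition.beta_SE == 1.0

    def test_mutualism_preset(self, mutualism):
        assert mutualism.R == 1.0
        assert mutualism.kappa_E == mutualism.kappa_S == 1.0
        assert mutualism.beta_ES == mutualism.beta_SE == 0.0

    @pytest.mark.parametrize("mode", ["competition", "mutualism"])
    def test_shared_defaults(self, mode):
        p = preset_params(mode)
        assert p.mu_E == p.mu_S == 0.5
        assert p.gamma_EG == p.gamma_SG == p.gamma_SP == 20.0
        assert p.sigma_EG == p.sigma_SG == p.sigma_SP == 0.001
        assert p.delta_E == p.delta_S == p.delta_G == p.delta_P == 0.03
        assert p.alpha_ES == p.alpha_SE == 1.0

    def test_negative_parameter_rejected(self):
        with pytest.raises(ValueError):
            CommunityParams(mu_E=-0.1)


class TestRhs:
    def test_origin_is_fixed_for_any_params(self, competition, mutualism):
        for p in (competition, mutualism, apply_cost(mutualism, "mortality", 3.0)):
            assert np.all(rhs(CommunityState(0, 0, 0, 0), p) == 0.0)

    def test_competition_hand_value(self, competition):
        # mu*E*(R - E - S) - delta*E = 0.5*(2-2) - 0.03 = -0.03, same for S
        d = rhs(CommunityState(1.0, 1.0, 0.0, 0.0), competition)
        assert d == pytest.approx([-0.03, -0.03, 0.0, 0.0])

    def test_mutualism_symmetric_equilibrium(self, mutualism, mutualism_prey_roots):
        _, x = mutualism_prey_roots
        d = rhs(CommunityState(x, x, 0.0, 0.0), mutualism)
        assert np.abs(d).max() < 1e-9

    def test_zero_kappa_gate_is_identity_even_at_zero_partner(self, competition):
        # with S = 0 the 0/0 gate must resolve to 1: plain logistic growth
        d = rhs(CommunityState(0.5, 0.0, 0.0, 0.0), competition)
        expected = 0.5 * 0.5 * (2.0 - 0.5) - 0.03 * 0.5
        assert d[0] == pytest.approx(expected)

    def test_negative_state_rejected(self, mutualism):
        with pytest.raises(ValueError):
            rhs(CommunityState(-0.1, 0.1, 0.0, 0.0), mutualism)

    def test_reduces_to_lotka_volterra_when_kappa_zero(self, competition):
        rng = np.random.default_rng(7)
        for _ in range(20):
            E, S, G, P = rng.uniform(0.01, 2.0, size=4)
            d = rhs_array(np.array([E, S, G, P]), competition)
            lv_dE = 0.5 * E * (2 - E - S) - 0.001 * G * E - 0.03 * E
            lv_dS = 0.5 * S * (2 - S - E) - 0.001 * P * S - 0.001 * G * S - 0.03 * S
            assert d[0] == pytest.approx(lv_dE, rel=1e-12)
            assert d[1] == pytest.approx(lv_dS, rel=1e-12)

    @given(
        x=st.floats(1e-6, 5.0),
        g=st.floats(0.0, 100.0),
        mode=st.sampled_from(["competition", "mutualism"]),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_symmetry_preserved_on_symmetric_states(self, x, g, mode):
        """E <-> S swap symmetry: symmetric params + E=S, P=0 give dE = dS."""
        p = preset_params(mode)
        d = rhs_array(np.array([x, x, g, 0.0]), p)
        assert d[0] == pytest.approx(d[1], rel=1e-12, abs=1e-15)


class TestApplyCost:
    def test_burst_cost(self, competition):
        q = apply_cost(competition, "burst", 5.0)
        assert q.gamma_SP == 100.0
        assert q.gamma_SG == q.gamma_EG == 20.0
        assert competition.gamma_SP == 20.0  # input untouched

    def test_identity_ratio_is_noop(self, mutualism):
        q = apply_cost(mutualism, "burst", 1.0)
        assert q == mutualism

    def test_mortality_cost(self, mutualism):
        q = apply_cost(mutualism, "mortality", 1.0)
        assert q.delta_E == q.delta_S == q.delta_G == q.delta_P == 0.0067
        q2 = apply_cost(mutualism, "mortality", 3.0)
        assert q2.delta_G == pytest.approx(3 * 0.0067)
        assert q2.delta_P == 0.0067

    @pytest.mark.parametrize("kind", ["burst", "attachment", "mortality"])
    def test_composition_is_idempotent(self, mutualism, kind):
        """Cost is absolute w.r.t. the generalist baseline, not cumulative."""
        once = apply_cost(mutualism, kind, 4.0)
        twice = apply_cost(apply_cost(mutualism, kind, 2.5), kind, 4.0)
        assert once == twice

    def test_unknown_kind_rejected(self, mutualism):
        with pytest.raises(ValueError):
            apply_cost(mutualism, "latency", 2.0)


class TestJacobian:
    @pytest.mark.parametrize("mode", ["competition", "mutualism"])
    def test_matches_central_differences(self, mode):
        p = preset_params(mode)
        rng = np.random.default_rng(11)
        h = 1e-6
        for _ in range(10):
            y = rng.uniform(0.01, 2.0, size=4)
            y[2:] *= 50
            J = jacobian(y, p)
            Jfd = np.empty((4, 4))
            for i in range(4):
                yp, ym = y.copy(), y.copy()
                yp[i] += h
                ym[i] -= h
                Jfd[:, i] = (rhs_array(yp, p) - rhs_array(ym, p)) / (2 * h)
            assert np.abs(J - Jfd).max() < 1e-5


class TestSerialization:
    def test_roundtrip_json_yaml(self, tmp_path, competition):
        for ext in ("json", "yaml"):
            f = tmp_path / f"params.{ext}"
            competition.to_file(f)
            assert CommunityParams.from_file(f) == competition

    def test_toml_read(self, tmp_path, mutualism):
        f = tmp_path / "params.toml"
        lines = [f"{k} = {v}" for k, v in mutualism.to_dict().items()]
        f.write_text("\n".join(lines) + "\n")
        assert CommunityParams.from_file(f) == mutualism

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            CommunityParams.from_dict({"mu_X": 1.0})

    def test_all_fields_serialized(self, competition):
        assert set(competition.to_dict()) == {
            f.name for f in dataclasses.fields(CommunityParams)
        }
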