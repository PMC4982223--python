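"""Rate laws, drift consistency, and parameter-set validation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gliodiff.deterministic import basal_steady_state, steady_state
from gliodiff.model import (
    N_PARAMS,
    PARAM_NAMES,
    SPECIES,
    ParameterSet,
    StateError,
    default_parameters,
    degradation_rates,
    differentiation_gate,
    drift,
    hill_activation,
    load_parameters,
    michaelis_menten,
    production_rates,
    save_parameters,
    validate_state,
)
from gliodiff.model import ParameterError


@pytest.mark.parametrize(
    "S,V,K,expected",
    [(1.0, 2.0, 1.0, 1.0), (0.0, 5.0, 1.0, 0.0), (3.0, 4.0, 1.0, 3.0)],
)
def test_michaelis_menten_values(S, V, K, expected):
    assert michaelis_menten(S, V, K) == pytest.approx(expected)


def test_michaelis_menten_rejects_negative_input():
    with pytest.raises(ParameterError):
        michaelis_menten(-1.0, 1.0, 1.0)


@given(
    S=st.floats(0, 1e3),
    V=st.floats(0, 1e2),
    K=st.floats(1e-6, 1e3),
)
@settings(max_examples=100, deadline=None)
def test_michaelis_menten_bounded_by_v(S, V, K):
    assert 0.0 <= michaelis_menten(S, V, K) <= V


class TestHillActivation:
    def test_half_maximal_at_k_for_kn_variant(self):
        assert hill_activation(0.5, 1.0, 0.5, 4.0) == pytest.approx(0.5)

    def test_saturates_at_v(self):
        assert hill_activation(1e9, 3.0, 0.5, 4.0) == pytest.approx(3.0, rel=1e-6)

    def test_shifted_k_variant(self):
        # denominator K + S^n, as used for the drug input and the
        # aGSK3b arm of GFAP production
        assert hill_activation(1.0, 1.0, 1.0, 2.0, shifted_K=True) == pytest.approx(0.5)

    def test_rejects_exponent_below_one(self):
        with pytest.raises(ParameterError):
            hill_activation(1.0, 1.0, 1.0, 0.5)


@pytest.mark.parametrize(
    "cyclin,expected", [(0.89, 0.0), (0.0, 1.0), (1.78, 0.0), (0.445, 0.5)]
)
def test_differentiation_gate(cyclin, expected):
    assert differentiation_gate(cyclin, 0.89) == pytest.approx(expected)


def test_differentiation_gate_rejects_nonpositive_ceiling():
    with pytest.raises(ParameterError):
        differentiation_gate(0.1, 0.0)


class TestDrift:
    def test_pka_balance_at_zero_dose(self, params):
        p = params.with_updates(a1=0.1, d1=0.5)
        y = np.zeros(10)
        y[0] = 0.2
        assert drift(y, 0.0, p)[0] == pytest.approx(0.0, abs=1e-12)

    def test_pka_steady_state_closed_form(self):
        # with n1 = 1 the PKA equation is linear with steady state
        # (a1 + V1*CT/(K1+CT)) / d1
        p = default_parameters().with_updates(a1=0.1, V1=1.0, K1=5.0, n1=1.0, d1=0.5)
        y = np.zeros(10)
        y[0] = (0.1 + 1.0 * 10.0 / 15.0) / 0.5
        assert y[0] == pytest.approx(1.5333333333)
        assert drift(y, 10.0, p)[0] == pytest.approx(0.0, abs=1e-12)

    def test_vanishes_at_fixed_point(self, params, basal):
        y = steady_state(params, basal, CT=0.0)
        assert np.max(np.abs(drift(y, 0.0, params))) < 1e-8

    def test_production_minus_degradation_identity(self, params, basal):
        rng = np.random.default_rng(0)
        y = rng.uniform(0.0, 0.9, size=(50, 10))
        f = drift(y, 7.0, params)
        assert np.allclose(
            f, production_rates(y, 7.0, params) - degradation_rates(y, 7.0, params),
            atol=1e-14,
        )

    def test_gfap_production_zero_above_ceiling(self, params, basal):
        y = basal.copy()
        y[SPECIES.index("CyclinD1")] = params.C * 1.5
        assert production_rates(y, 10.0, params)[9] == 0.0

    def test_rejects_pgsk3b_above_total_pool(self, params):
        y = np.full(10, 0.1)
        y[4] = params.GSK3bT * 1.5
        with pytest.raises(StateError):
            drift(y, 0.0, params)


def test_upstream_cascade_matches_sequential_closed_forms(params):
    """The drug-free cascade is feed-forward: each steady state follows
    from the previous one by solving a single rate balance."""
    y = basal_steady_state(params)
    p = params
    pka = p.a1 / p.d1
    creb = p.V2 * pka / (p.K2 + pka) / p.d2
    pi3k = 1.0 / (1.0 + pka / p.K3) / p.d3
    akt = p.V4 * pi3k / (p.K4 + pi3k) / p.d4
    il6 = p.V7 * pka / (p.K7 + pka) / p.d7
    jak2 = p.V8 * il6 / (p.K8 + il6) / p.d8
    stat3 = p.V9 * jak2 / (p.K9 + jak2) / p.d9
    expected = {"PKA": pka, "CREB": creb, "PI3K": pi3k, "AKT": akt,
                "IL6": il6, "JAK2": jak2, "STAT3": stat3}
    for name, value in expected.items():
        assert y[SPECIES.index(name)] == pytest.approx(value, abs=1e-8), name


class TestParameterSet:
    def test_has_exactly_39_parameters(self, params):
        assert N_PARAMS == 39
        assert params.as_array().shape == (39,)

    def test_array_round_trip(self, params):
        assert ParameterSet.from_array(params.as_array()) == params

    def test_rejects_negative_rate(self, params):
        with pytest.raises(ParameterError, match="d6"):
            params.with_updates(d6=-1.0)

    def test_rejects_hill_exponent_below_one(self, params):
        with pytest.raises(ParameterError, match="n2"):
            params.with_updates(n2=0.5)

    @pytest.mark.parametrize("suffix", ["yaml", "json"])
    def test_file_round_trip(self, params, tmp_path, suffix):
        path = tmp_path / f"params.{suffix}"
        save_parameters(params, path)
        assert load_parameters(path) == params

    def test_missing_parameter_named_in_error(self, params, tmp_path):
        path = tmp_path / "params.yaml"
        save_parameters(params, path)
        text = path.read_text()
        path.write_text("\n".join(l for l in text.splitlines() if not l.startswith("K6a:")))
        with pytest.raises(ParameterError, match="K6a"):
            load_parameters(path)


class TestStateValidation:
    def test_accepts_basal_state(self, params, basal):
        validate_state(basal, params)

    @pytest.mark.parametrize(
        "mutate",
        [
            lambda y: y[:9],  # wrong length
            lambda y: np.where(np.arange(10) == 3, -0.1, y),  # negative
            lambda y: np.where(np.arange(10) == 2, np.nan, y),  # non-finite
        ],
    )
    def test_rejects_invalid_states(self, params, basal, mutate):
        with pytest.raises(StateError):
            validate_state(mutate(basal.copy()), params)
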