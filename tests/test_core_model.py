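"""Core scheme, rate evaluation, generator and detailed-balance tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from navfit.core_model import (
    N_INDEPENDENT_RATES,
    PARAM_NAMES,
    RATE_LABELS,
    ChannelScheme,
    RateParams,
    build_generator,
    cycle_residuals,
    default_scheme,
    equilibrium_distribution,
    eval_rates,
)
from navfit.errors import (
    DetailedBalanceError,
    EquilibriumError,
    ParameterDomainError,
    SchemeDefinitionError,
)

from conftest import random_positive_params


class TestRateEvaluation:
    def test_alpha11_is_reciprocal_prefactor_at_zero_mV(self, true_params):
        p = RateParams.from_dict({**true_params.to_dict(), "a11_v1": 1.0})
        assert eval_rates(p, 0.0).a11 == pytest.approx(1.0)

    def test_beta2_follows_reversibility_formula(self, true_params):
        # b2 = a13*a2*a3/(b13*b3) must hold exactly for any V
        for V in (-120.0, -60.0, 0.0, 40.0):
            r = eval_rates(true_params, V)
            assert r.b2 == pytest.approx(r.a13 * r.a2 * r.a3 / (r.b13 * r.b3), rel=1e-12)

    def test_unit_multipliers_collapse_onto_alpha11(self, true_params):
        p = RateParams.from_dict({**true_params.to_dict(), "a12": 1.0, "a13": 1.0})
        for V in (-100.0, -30.0, 20.0):
            r = eval_rates(p, V)
            assert r.a12 == r.a11 == r.a13

    def test_nonpositive_parameter_rejected(self, true_params):
        bad = true_params.to_dict()
        bad["a3_v1"] = 0.0
        with pytest.raises(ParameterDomainError, match="a3_v1"):
            RateParams.from_dict(bad)

    def test_unknown_and_missing_keys_rejected(self, true_params):
        with pytest.raises(ParameterDomainError, match="bogus"):
            RateParams.from_dict({**true_params.to_dict(), "bogus": 1.0})
        short = true_params.to_dict()
        short.pop("b12")
        with pytest.raises(ParameterDomainError, match="b12"):
            RateParams.from_dict(short)

    def test_extreme_voltage_does_not_overflow(self, true_params):
        # the exponential cap keeps rates finite even far outside the
        # physiological range explored by the optimizer
        r = eval_rates(true_params, -2000.0)
        assert all(math.isfinite(v) for v in r.to_dict().values())

    @settings(max_examples=25, deadline=None)
    @given(V=st.floats(-140, 60), seed=st.integers(0, 10_000))
    def test_rates_positive_for_positive_params(self, V, seed):
        params = random_positive_params(np.random.default_rng(seed))
        r = eval_rates(params, V)
        assert all(v > 0 for v in r.to_dict().values())


class TestGenerator:
    def test_column_sums_vanish_across_voltages(self, true_params, scheme):
        for V in np.linspace(-140, 60, 21):
            Q = build_generator(scheme, eval_rates(true_params, V))
            assert np.abs(Q.sum(axis=0)).max() < 1e-12

    def test_two_state_toy_matrix(self):
        toy = ChannelScheme(states=("A", "B"), edges=(("A", "B", "k1"), ("B", "A", "k2")),
                            conducting_states=("A",))
        Q = build_generator(toy, {"k1": 3.0, "k2": 1.0})
        assert np.allclose(Q, [[-3.0, 1.0], [3.0, -1.0]])

    def test_full_scheme_has_ten_reversible_edges(self, true_params, scheme):
        # hand-enumerated topology: 4 horizontal pairs, 3 vertical pairs,
        # opening, open-inactivation, slow-inactivation = 10 reversible edges
        expected_pairs = {
            frozenset(p)
            for p in [
                ("IC3", "IC2"), ("IC2", "IF"), ("C3", "C2"), ("C2", "C1"),
                ("C1", "O"), ("IC3", "C3"), ("IC2", "C2"), ("IF", "C1"),
                ("O", "IF"), ("O", "IS"),
            ]
        }
        assert {frozenset(p) for p in scheme.undirected_pairs()} == expected_pairs
        Q = build_generator(scheme, eval_rates(true_params, -20.0))
        off = Q - np.diag(np.diag(Q))
        assert np.count_nonzero(off) == 20

    def test_unresolved_label_raises(self, scheme):
        partial = {k: 1.0 for k in RATE_LABELS if k != "bx"}
        with pytest.raises(SchemeDefinitionError, match="bx"):
            build_generator(scheme, partial)

    def test_scheme_requires_reverse_edges(self):
        with pytest.raises(SchemeDefinitionError, match="reverse"):
            ChannelScheme(states=("A", "B"), edges=(("A", "B", "k"),))


class TestEquilibrium:
    def test_two_state_closed_form(self):
        toy = ChannelScheme(states=("A", "B"), edges=(("A", "B", "a"), ("B", "A", "b")),
                            conducting_states=("A",))
        Q = build_generator(toy, {"a": 3.0, "b": 1.0})
        pi = equilibrium_distribution(Q)
        assert pi == pytest.approx([0.25, 0.75])

    def test_matches_long_time_propagation(self, true_params, scheme):
        from scipy.linalg import expm

        Q = build_generator(scheme, eval_rates(true_params, -100.0))
        pi = equilibrium_distribution(Q)
        p0 = np.zeros(8)
        p0[0] = 1.0
        # propagate 1e6 ms in doubling steps
        M = expm(Q * 1e6)
        assert np.abs(M @ p0 - pi).max() < 1e-6

    def test_full_scheme_is_a_distribution(self, true_params, scheme):
        Q = build_generator(scheme, eval_rates(true_params, -100.0))
        pi = equilibrium_distribution(Q)
        assert pi.min() >= 0
        assert pi.sum() == pytest.approx(1.0, abs=1e-12)

    def test_reducible_generator_rejected(self):
        Q = np.zeros((2, 2))  # two disconnected states: 2-dim null space
        with pytest.raises(EquilibriumError):
            equilibrium_distribution(Q)


class TestDetailedBalance:
    def test_constructed_beta2_closes_every_cycle(self, true_params, scheme):
        for V in (-120.0, -40.0, 10.0):
            res = cycle_residuals(scheme, eval_rates(true_params, V))
            assert len(res) == 3  # cycle basis of the 8-state graph
            assert max(abs(r) for _, r in res) < 1e-10

    def test_doubled_beta2_breaks_open_loop_only(self, true_params, scheme):
        rates = eval_rates(true_params, -20.0).to_dict()
        rates["b2"] *= 2.0
        broken = [
            (cyc, r) for cyc, r in cycle_residuals(scheme, rates) if abs(r) > 1e-10
        ]
        assert len(broken) == 1
        cyc, r = broken[0]
        assert set(cyc) == {"C1", "O", "IF"}
        assert abs(abs(r) - math.log(2.0)) < 1e-12

    def test_four_cycle_against_brute_force_product(self):
        rng = np.random.default_rng(7)
        k = rng.uniform(0.1, 10.0, size=8)
        square = ChannelScheme(
            states=("A", "B", "C", "D"),
            edges=(
                ("A", "B", "k0"), ("B", "A", "k1"),
                ("B", "C", "k2"), ("C", "B", "k3"),
                ("C", "D", "k4"), ("D", "C", "k5"),
                ("D", "A", "k6"), ("A", "D", "k7"),
            ),
            conducting_states=("A",),
        )
        rates = {f"k{i}": float(k[i]) for i in range(8)}
        (cycle, r), = cycle_residuals(square, rates)
        # brute force: walk the returned cycle and multiply
        fwd = rev = 1.0
        n = len(cycle)
        lab = {(f, t): l for f, t, l in square.edges}
        for i in range(n):
            a, b = cycle[i], cycle[(i + 1) % n]
            fwd *= rates[lab[(a, b)]]
            rev *= rates[lab[(b, a)]]
        assert r == pytest.approx(math.log(fwd / rev), rel=1e-12)

    def test_zero_rate_on_cycle_is_undefined(self, scheme, true_params):
        rates = eval_rates(true_params, -20.0).to_dict()
        rates["b2"] = 0.0
        with pytest.raises(DetailedBalanceError):
            cycle_residuals(scheme, rates)

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000), V=st.floats(-120, 40))
    def test_detailed_balance_holds_for_random_parameters(self, seed, V):
        params = random_positive_params(np.random.default_rng(seed))
        res = cycle_residuals(default_scheme(), eval_rates(params, V))
        assert max(abs(r) for _, r in res) < 1e-10


def test_structural_counts():
    """16 free parameters and 11 independent rate constants in the scheme."""
    assert len(PARAM_NAMES) == 16
    assert N_INDEPENDENT_RATES == 11
    assert len(RATE_LABELS) == 12
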