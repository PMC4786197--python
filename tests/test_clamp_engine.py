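"""Clamp-engine tests: propagation accuracy, protocol semantics, limits."""

import numpy as np
import pytest

from navfit.clamp_engine import (
    ChannelModel,
    Readout,
    Segment,
    SegmentSolution,
    VoltageProtocol,
    propagate,
    run_protocol,
)
from navfit.core_model import ChannelScheme, build_generator
from navfit.drug_extension import DrugScalars, DrugSpec
from navfit.errors import ProtocolDefinitionError
from navfit.protocols import drug_free_protocols


def _two_state_Q(a, b):
    toy = ChannelScheme(states=("A", "B"), edges=(("A", "B", "a"), ("B", "A", "b")),
                        conducting_states=("A",))
    return build_generator(toy, {"a": a, "b": b})


class TestPropagate:
    def test_single_state_is_constant(self):
        t, P = propagate(np.zeros((1, 1)), [1.0], duration=5.0, sample_dt=1.0)
        assert np.allclose(P, 1.0)

    def test_two_state_closed_form(self):
        a, b = 0.7, 0.3
        Q = _two_state_Q(a, b)
        p0 = np.array([1.0, 0.0])
        t, P = propagate(Q, p0, duration=20.0, sample_dt=0.1)
        pi = np.array([b, a]) / (a + b)
        expected = pi[:, None] + (p0 - pi)[:, None] * np.exp(-(a + b) * t)
        assert np.abs(P - expected).max() < 1e-8

    def test_conservation_along_trace(self, model):
        Q = model.generator(-30.0)
        p0 = model.equilibrium(-100.0)
        t, P = propagate(Q, p0, duration=50.0, sample_dt=0.5)
        assert np.abs(P.sum(axis=0) - 1.0).max() < 1e-6
        assert P.min() > -1e-10

    def test_expm_matches_fine_step_euler_integration(self, model):
        """Matrix-exponential step vs brute-force fine-step integration."""
        rng = np.random.default_rng(11)
        for _ in range(5):
            V = float(rng.uniform(-80, 20))
            hold = float(rng.uniform(-120, -90))
            Q = model.generator(V)
            p0 = model.equilibrium(hold)
            dur = float(rng.uniform(1.0, 5.0))
            _, P = propagate(Q, p0, duration=dur, sample_dt=dur)
            # explicit RK4 at dt=1e-4 ms as the independent oracle
            dt = 1e-4
            n = int(dur // dt)
            steps = [dt] * n + [dur - n * dt]
            p = p0.copy()
            for h in steps:
                if h <= 0:
                    continue
                k1 = Q @ p
                k2 = Q @ (p + 0.5 * h * k1)
                k3 = Q @ (p + 0.5 * h * k2)
                k4 = Q @ (p + h * k3)
                p = p + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
            assert np.abs(P[:, -1] - p).max() < 1e-6


class TestSegmentSolution:
    def test_matches_expm_pointwise(self, model):
        Q = model.generator(-20.0)
        p0 = model.equilibrium(-100.0)
        from scipy.linalg import expm

        sol = SegmentSolution(Q, p0)
        for t in (0.01, 0.5, 3.0, 24.0):
            assert np.abs(sol(t) - expm(Q * t) @ p0).max() < 1e-10

    def test_dense_sampling_consistent_with_point_eval(self, model):
        Q = model.generator(-40.0)
        p0 = model.equilibrium(-100.0)
        sol = SegmentSolution(Q, p0)
        grid = np.linspace(0, 10, 23)
        P = sol.sample(grid)
        for j in (0, 7, 22):
            assert np.abs(P[:, j] - sol(grid[j])).max() < 1e-10


class TestRunProtocol:
    def test_fully_available_limit(self, model, registry):
        # prepulse to a very hyperpolarized level leaves all channels available
        from dataclasses import replace

        ssa = replace(registry["SSA"], sweep=(-150.0, -40.0))
        res = run_protocol(model, ssa)
        assert res[0].value == pytest.approx(1.0, abs=1e-6)
        assert res[1].value < 0.05

    def test_recovery_saturates_at_long_intervals(self, model, registry):
        from dataclasses import replace

        rfi = replace(registry["RFI"], sweep=(10_000.0,))
        res = run_protocol(model, rfi)
        assert res[0].value == pytest.approx(1.0, abs=1e-3)

    def test_sweep_order_independence(self, model, registry):
        from dataclasses import replace

        rfi = registry["RFI"]
        fwd = run_protocol(model, rfi)
        perm = (3, 0, 5, 1, 6, 2, 4)
        rev = run_protocol(model, replace(rfi, sweep=tuple(rfi.sweep[i] for i in perm)))
        for i, j in enumerate(perm):
            assert rev[i].value == pytest.approx(fwd[j].value, rel=1e-12)

    def test_sample_dt_refinement_leaves_readouts_unchanged(self, model, registry):
        # readouts come from the analytic solution, so halving the sampling
        # step only changes the bracketing, not the value
        for name in ("SSA", "TAU50", "RFI"):
            coarse = run_protocol(model, registry[name], sample_dt=0.05)
            fine = run_protocol(model, registry[name], sample_dt=0.025)
            for a, b in zip(coarse, fine):
                assert abs(a.value - b.value) < 1e-6

    def test_unknown_statistic_rejected(self):
        with pytest.raises(ProtocolDefinitionError):
            VoltageProtocol(
                name="bad", holding=-100.0,
                segments=(Segment(level="sweep", duration=1.0, record=True, tag="test"),),
                sweep=(0.0,),
                readout=Readout(statistic="no-such-stat"),
            )

    def test_train_period_must_exceed_pulse(self):
        with pytest.raises(ProtocolDefinitionError, match="period"):
            VoltageProtocol(
                name="bad", holding=-100.0,
                segments=(Segment(level=-20.0, duration=50.0, repeat=5, period=25.0),),
                sweep=(1.0,),
                sweep_kind="pulse_index",
                readout=Readout(statistic="pulse_ratio"),
            )

    def test_occupancies_remain_distributions(self, model, registry):
        res = run_protocol(model, registry["ACT"], keep_traces=True)
        for r in res:
            assert np.abs(r.trace.sum(axis=0) - 1.0).max() < 1e-6
            assert r.trace.min() > -1e-10


class TestDrugProtocols:
    def test_zero_concentration_matches_drug_free(self, true_params, registry):
        """Extended model at zero drug reproduces drug-free readouts."""
        plain = ChannelModel(true_params)
        zero = ChannelModel(true_params, drug=DrugSpec(concentration=0.0),
                            scalars=DrugScalars())
        for name in ("SSA", "ACT", "RFI", "TAU50"):
            a = run_protocol(plain, registry[name])
            b = run_protocol(zero, registry[name])
            for ra, rb in zip(a, b):
                assert abs(ra.value - rb.value) < 1e-8

    def test_huge_kd_means_no_block(self, true_params, registry):
        # vanishing affinity (huge Kd everywhere): the last-to-first pulse
        # ratio of the train approaches the drug-free value
        weak = DrugSpec(concentration=10e-6, kd0_charged_open=1.0,
                        kd_neutral_open=1.0, kd_neutral_closed=1.0,
                        kd_neutral_inactivated=1.0)
        scal = DrugScalars(ki_on=1e-3, ki_off=5500.0)
        drugged = ChannelModel(true_params, drug=weak, scalars=scal)
        plain = ChannelModel(true_params)
        udb = registry["UDB"]
        a = run_protocol(drugged, udb)
        b = run_protocol(plain, udb)
        for ra, rb in zip(a, b):
            assert ra.value == pytest.approx(rb.value, abs=1e-3)

    def test_use_dependence_accumulates_with_pulse_number(self, true_params, registry):
        m = ChannelModel(true_params, drug=DrugSpec(concentration=100e-6),
                         scalars=DrugScalars())
        res = run_protocol(m, registry["UDB"])
        vals = [r.value for r in res]
        assert all(a >= b - 1e-9 for a, b in zip(vals, vals[1:]))  # monotone block
        assert vals[-1] < 0.6  # substantial block at 100 uM

    def test_tonic_block_increases_with_concentration(self, true_params, registry):
        tb = registry["TB"]
        ratios = []
        for conc in (1e-6, 10e-6, 100e-6):
            m = ChannelModel(true_params, drug=DrugSpec(concentration=conc),
                             scalars=DrugScalars())
            ratios.append(run_protocol(m, tb)[0].value)
        assert ratios[0] > ratios[1] > ratios[2]
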