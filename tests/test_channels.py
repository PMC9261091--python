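"""Gating kinetics, modifiers and Ca²⁺ pool dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from assrnet.channels import (
    CHANNEL_NAMES,
    CalciumPool,
    ChannelSpec,
    GateSpec,
    IDENTITY_MODIFIER,
    KineticModifier,
    TauSpec,
    channel_current,
    load_channel_table,
    steady_state,
    time_constant,
    update_calcium,
)

VGRID = np.linspace(-120.0, 60.0, 181)


def _all_gates(*tables):
    out = []
    for table in tables:
        for name, chan in table.items():
            for gate in chan.gates:
                out.append((f"{name}.{gate.name}", gate))
    return out


class TestSteadyState:
    def test_midpoint_is_half_for_every_gate(self, l5pc_channels, fs_channels):
        for label, gate in _all_gates(l5pc_channels, fs_channels):
            val = steady_state(gate, IDENTITY_MODIFIER, gate.v_half)
            assert val == pytest.approx(0.5), label

    def test_bounded_and_monotone(self, l5pc_channels):
        for label, gate in _all_gates(l5pc_channels):
            vals = steady_state(gate, IDENTITY_MODIFIER, VGRID)
            assert np.all((vals >= 0) & (vals <= 1)), label
            diffs = np.diff(vals)
            if gate.slope_k > 0:
                assert np.all(diffs > 0), label
            else:
                assert np.all(diffs < 0), label

    def test_rejects_non_finite_voltage(self, l5pc_channels):
        gate = l5pc_channels["NaT"].gates[0]
        with pytest.raises(ValueError):
            steady_state(gate, IDENTITY_MODIFIER, np.nan)

    @settings(deadline=None, max_examples=50)
    @given(dv=st.floats(-25, 25), v=st.floats(-100, 40))
    def test_shift_equals_translation(self, dv, v):
        """dv_shift = d evaluated at v must equal the unshifted gate at v − d."""
        gate = GateSpec("m", v_half=-40.0, slope_k=6.0, tau=TauSpec(1.0, 2.0, -50.0, 25.0))
        mod = KineticModifier(dv_shift=dv)
        assert steady_state(gate, mod, v) == pytest.approx(
            steady_state(gate, IDENTITY_MODIFIER, v - dv), rel=1e-12)
        assert time_constant(gate, mod, v) == pytest.approx(
            time_constant(gate, IDENTITY_MODIFIER, v - dv), rel=1e-12)

    def test_activation_left_shift_raises_curve_pointwise(self, l5pc_channels):
        # oracle: direct evaluation of the shifted and unshifted sigmoids
        gate = next(g for g in l5pc_channels["CaHVA"].gates if g.name == "m")
        shifted = steady_state(gate, KineticModifier(dv_shift=-3.0), VGRID)
        base = steady_state(gate, IDENTITY_MODIFIER, VGRID)
        assert np.all(shifted >= base)
        assert np.any(shifted > base + 1e-4)


class TestTimeConstant:
    def test_identity_and_scaling(self, l5pc_channels):
        for label, gate in _all_gates(l5pc_channels):
            base = time_constant(gate, IDENTITY_MODIFIER, VGRID)
            assert np.all(base > 0), label
            doubled = time_constant(gate, KineticModifier(tau_factor=2.0), VGRID)
            np.testing.assert_allclose(doubled, 2.0 * base, rtol=1e-12)

    def test_invalid_tau_factor_rejected(self):
        with pytest.raises(ValueError):
            KineticModifier(tau_factor=0.0)


class TestModifier:
    def test_identity_flags(self):
        assert IDENTITY_MODIFIER.is_identity
        assert not KineticModifier(dv_shift=1.0).is_identity

    @settings(deadline=None, max_examples=50)
    @given(
        a=st.tuples(st.floats(-10, 10), st.floats(0.5, 2), st.floats(0.5, 2),
                    st.floats(0.1, 3)),
        b=st.tuples(st.floats(-10, 10), st.floats(0.5, 2), st.floats(0.5, 2),
                    st.floats(0.1, 3)),
    )
    def test_composition_adds_shifts_multiplies_factors(self, a, b):
        ma, mb = KineticModifier(*a), KineticModifier(*b)
        c = ma.compose(mb)
        assert c.dv_shift == pytest.approx(ma.dv_shift + mb.dv_shift)
        assert c.slope_factor == pytest.approx(ma.slope_factor * mb.slope_factor)
        assert c.tau_factor == pytest.approx(ma.tau_factor * mb.tau_factor)
        assert c.g_factor == pytest.approx(ma.g_factor * mb.g_factor)

    def test_sequential_shifts_translate_by_their_sum(self, l5pc_channels):
        gate = l5pc_channels["Ih"].gates[0]
        ma = KineticModifier(dv_shift=-4.0)
        mb = KineticModifier(dv_shift=2.5)
        comp = ma.compose(mb)
        np.testing.assert_allclose(
            steady_state(gate, comp, VGRID),
            steady_state(gate, IDENTITY_MODIFIER, VGRID + 1.5),
            rtol=1e-12,
        )


class TestChannelCurrent:
    def test_closed_gates_and_zero_g_factor(self, l5pc_channels):
        chan = l5pc_channels["NaT"].with_gbar(0.1)
        states = [0.0] * len(chan.gates)
        assert channel_current(chan, states, -20.0) == 0.0
        dead = chan.with_modifier(KineticModifier(g_factor=0.0))
        assert channel_current(dead, [0.5] * len(chan.gates), -20.0) == 0.0

    def test_leak_vanishes_at_reversal(self, l5pc_channels):
        leak = l5pc_channels["leak"].with_gbar(1e-4)
        assert channel_current(leak, [], leak.reversal) == 0.0

    def test_sk_requires_calcium(self, l5pc_channels):
        sk = l5pc_channels["SK"].with_gbar(1e-3)
        with pytest.raises(ValueError):
            channel_current(sk, [], -60.0, ca=None)
        pool = CalciumPool(concentration=1e-2)
        assert channel_current(sk, [], -60.0, ca=pool) > 0  # outward above E_K

    def test_out_of_range_gate_state_rejected(self, l5pc_channels):
        chan = l5pc_channels["NaT"].with_gbar(0.1)
        with pytest.raises(ValueError):
            channel_current(chan, [1.5, 0.2], -20.0)

    def test_exactly_eleven_channel_classes(self, l5pc_channels):
        assert set(CHANNEL_NAMES) == set(l5pc_channels)
        assert len(CHANNEL_NAMES) == 11
        with pytest.raises(ValueError):
            ChannelSpec(name="KCa_bogus", gates=(), gbar=0.0, reversal=-85.0)


class TestCalciumPool:
    def test_rest_is_fixed_point(self):
        pool = CalciumPool()
        out = update_calcium(pool, i_ca=0.0, dt=0.025)
        assert out.concentration == pytest.approx(pool.rest)

    def test_exponential_relaxation_matches_closed_form(self):
        pool = CalciumPool(concentration=5e-4, rest=1e-4, decay_tau=80.0)
        p = pool
        dt = 0.025
        for _ in range(int(round(pool.decay_tau / dt))):
            p = update_calcium(p, 0.0, dt)
        excess0 = pool.concentration - pool.rest
        expected = pool.rest + excess0 * np.exp(-1.0)
        assert p.concentration == pytest.approx(expected, rel=0.01)

    def test_constant_current_reaches_analytic_steady_state(self):
        pool = CalciumPool(rest=1e-4, decay_tau=40.0, influx_scale=5e-3)
        i_ca = -0.02  # inward
        p = pool
        prev = p.concentration
        rising = True
        for k in range(20000):
            p = update_calcium(p, i_ca, 0.025)
            rising &= p.concentration >= prev - 1e-15
            prev = p.concentration
        target = pool.rest - pool.influx_scale * i_ca * pool.decay_tau
        assert rising
        assert p.concentration == pytest.approx(target, rel=1e-4)

    def test_dt_must_be_positive(self):
        with pytest.raises(ValueError):
            update_calcium(CalciumPool(), 0.0, dt=0.0)


class TestChannelTable:
    def test_bundled_tables_parse(self, l5pc_channels, fs_channels):
        assert {"NaT", "Kv3", "leak"} <= set(fs_channels)
        assert l5pc_channels["CaHVA"].is_ca_channel
        assert l5pc_channels["SK"].ca_half == pytest.approx(4.3e-4)

    def test_unknown_channel_rejected_with_line_number(self, tmp_path):
        bad = tmp_path / "bad.tsv"
        bad.write_text(
            "channel\tgate\tparameter\tvalue\n"
            "NaQ\tm\tv_half\t-40\n"
        )
        with pytest.raises(ValueError, match="bad.tsv:2"):
            load_channel_table(bad)

    def test_missing_reversal_rejected(self, tmp_path):
        bad = tmp_path / "bad2.tsv"
        bad.write_text(
            "channel\tgate\tparameter\tvalue\n"
            "NaT\tm\tv_half\t-40\n"
            "NaT\tm\tslope_k\t6\n"
            "NaT\tm\ttau_base\t0.1\n"
        )
        with pytest.raises(ValueError, match="reversal"):
            load_channel_table(bad)
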