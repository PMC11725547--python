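"""Reduced-order trap filling: ramp, conservation, events, saturation."""

import numpy as np
import pytest

from trapcolor import RampSchedule, TrapSpec, ramp_fraction, saturation_time, simulate_trap
from trapcolor.trap_sim import read_trace_csv, write_trace_csv


RAMP = RampSchedule(t_start=1.0, t_full=3.0, phi_final=0.2)


def inflow_integral_ul(trace):
    q_ul_s = trace.q_ul_min / 60.0
    dt = trace.time_s[1] - trace.time_s[0]
    return float(np.sum(q_ul_s * trace.vof_in[:-1] * dt))


def outflow_integral_ul(trace):
    q_ul_s = trace.q_ul_min / 60.0
    dt = trace.time_s[1] - trace.time_s[0]
    return float(np.sum(q_ul_s * trace.vof_out[1:] * dt))


class TestRamp:
    def test_zero_before_start(self):
        assert ramp_fraction(1.0, RAMP) == 0.0
        assert ramp_fraction(0.0, RAMP) == 0.0

    def test_full_value_after_ramp(self):
        assert ramp_fraction(3.0, RAMP) == RAMP.phi_final
        assert ramp_fraction(10.0, RAMP) == RAMP.phi_final

    def test_smoothstep_midpoint(self):
        # 3u^2 - 2u^3 at u = 1/2 is exactly 1/2
        assert ramp_fraction(2.0, RAMP) == pytest.approx(0.5 * RAMP.phi_final, abs=1e-15)

    def test_monotone_and_continuous(self):
        t = np.linspace(0, 5, 5001)
        phi = ramp_fraction(t, RAMP)
        assert np.all(np.diff(phi) >= 0)
        assert np.max(np.abs(np.diff(phi))) < 1e-3  # no jumps at grid scale

    def test_invalid_schedules_rejected(self):
        with pytest.raises(ValueError):
            RampSchedule(t_start=3.0, t_full=3.0)
        with pytest.raises(ValueError):
            RampSchedule(phi_final=1.5)


class TestSimulateTrap:
    def test_no_air_no_events(self, fast_trap):
        trace = simulate_trap(50.0, RampSchedule(phi_final=0.0), fast_trap)
        assert np.all(trace.v_air_ul == 0.0)
        assert trace.tep is None and trace.cep is None
        assert saturation_time(trace) is None

    def test_air_volume_conserved(self, fast_trap):
        trace = simulate_trap(50.0, RAMP, fast_trap, t_end=30.0)
        total_in = inflow_integral_ul(trace)
        assert total_in > 0
        balance = trace.v_air_ul[-1] + outflow_integral_ul(trace)
        assert abs(balance - total_in) <= 1e-6 * total_in

    def test_trapped_volume_monotone_and_bounded(self, fast_trap):
        trace = simulate_trap(100.0, RAMP, fast_trap, t_end=30.0)
        assert np.all(np.diff(trace.v_air_ul) >= 0)
        assert trace.v_air_ul.max() <= trace.capacity_ul * (1 + 1e-12)
        assert np.all(trace.vof_out >= 0) and np.all(trace.vof_out <= RAMP.phi_final)

    def test_euler_refinement(self, fast_trap):
        coarse = simulate_trap(50.0, RAMP, fast_trap, dt=0.01, t_end=10.0)
        fine = simulate_trap(50.0, RAMP, fast_trap, dt=0.005, t_end=10.0)
        assert abs(fine.v_air_ul[-1] - coarse.v_air_ul[-1]) < 0.01 * fine.v_air_ul[-1]

    def test_unstable_dt_rejected(self):
        tiny = TrapSpec(capacity_ul=0.01)
        with pytest.raises(ValueError, match="unstable"):
            simulate_trap(150.0, RAMP, tiny, dt=0.5, t_end=10.0)

    def test_events_ordered(self, fast_trap):
        trace = simulate_trap(50.0, RAMP, fast_trap, t_end=30.0)
        assert trace.tep is not None and trace.cep is not None
        assert trace.tep <= trace.cep

    def test_events_strictly_decreasing_in_flow_rate(self, fast_trap):
        teps, ceps = [], []
        for q in (50.0, 100.0, 150.0):
            trace = simulate_trap(q, RAMP, fast_trap, t_end=60.0)
            teps.append(trace.tep)
            ceps.append(trace.cep)
        assert teps[0] > teps[1] > teps[2]
        assert ceps[0] > ceps[1] > ceps[2]

    def test_highest_flow_saturates_fastest(self, fast_trap):
        sats = [
            saturation_time(simulate_trap(q, RAMP, fast_trap, t_end=60.0))
            for q in (50.0, 100.0, 150.0)
        ]
        assert sats[0] > sats[1] > sats[2]


class TestSaturation:
    def test_closed_form_saturation_time(self, fast_trap):
        # analytic integral oracle: with constant phi after t_full and the
        # smoothstep contributing phi*(t_full-t_start)/2, capacity is hit at
        # t = t_full + (capacity - ramp_integral) / (Q*phi)
        q = 50.0
        trace = simulate_trap(q, RAMP, fast_trap, dt=0.001, t_end=30.0)
        q_ul_s = q / 60.0
        expected = RAMP.t_full + (fast_trap.capacity - q_ul_s * RAMP.ramp_integral) / (
            q_ul_s * RAMP.phi_final
        )
        got = saturation_time(trace)
        assert got == pytest.approx(expected, abs=0.01)

    def test_doubling_flow_at_least_halves_fill_time(self, fast_trap):
        t1 = saturation_time(simulate_trap(50.0, RAMP, fast_trap, t_end=60.0))
        t2 = saturation_time(simulate_trap(100.0, RAMP, fast_trap, t_end=60.0))
        assert t2 - RAMP.t_full <= 0.5 * (t1 - RAMP.t_full) + 0.02


class TestTraceCsv:
    def test_round_trip(self, tmp_path, fast_trap):
        trace = simulate_trap(50.0, RAMP, fast_trap, t_end=20.0)
        p = tmp_path / "trace.csv"
        write_trace_csv(trace, p)
        back = read_trace_csv(p, capacity_ul=trace.capacity_ul)
        np.testing.assert_allclose(back.v_air_ul, trace.v_air_ul, atol=1e-9)
        np.testing.assert_allclose(back.time_s, trace.time_s, atol=1e-9)
        assert back.tep == pytest.approx(trace.tep, abs=1e-9)
        assert back.cep == pytest.approx(trace.cep, abs=1e-9)
        assert p.read_text().splitlines()[0] == "time_s,v_air_ul,vof_in,vof_out"


def test_default_capacity_is_cylinder_volume():
    spec = TrapSpec(diameter_mm=2.0, height_mm=4.0)
    assert spec.capacity == pytest.approx(np.pi * 1.0**2 * 4.0)
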