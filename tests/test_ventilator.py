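import numpy as np
import pytest

import pvasync as pv
from pvasync.subject import SubjectParams
from pvasync.ventilator import (
    CycleOrigin,
    Mode,
    Phase,
    VentilatorEngine,
    VentSettings,
    VentState,
    compute_p01,
    flow_trigger_check,
    phase_durations,
    pressure_target,
)


class TestPhaseDurations:
    @pytest.mark.parametrize(
        "kwargs, ti, te",
        [
            ({"rr_set": 30.0, "ie_ratio": 1.0}, 1.0, 1.0),
            ({"rr_set": 20.0, "ie_ratio": 1.0}, 1.5, 1.5),
            # bench auto-trigger cycle: RR 45 with explicit Ti 0.7
            ({"rr_set": 45.0, "tinsp": 0.7}, 0.7, 60.0 / 45.0 - 0.7),
        ],
    )
    def test_values(self, kwargs, ti, te):
        s = VentSettings(**kwargs)
        got_ti, got_te = phase_durations(s)
        assert got_ti == pytest.approx(ti)
        assert got_te == pytest.approx(te)
        assert got_ti + got_te == pytest.approx(s.period)


class TestPressureTarget:
    def test_linear_midpoint(self):
        s = VentSettings(peep=10.0, pinsp=20.0, ramp_time=0.9)
        assert pressure_target(0.45, s) == pytest.approx(15.0)

    def test_plateau_after_ramp(self):
        s = VentSettings(peep=10.0, pinsp=20.0, ramp_time=0.2)
        assert pressure_target(0.2, s) == 20.0
        assert pressure_target(0.9, s) == 20.0

    def test_square_profile_at_zero_ramp(self):
        s = VentSettings(peep=10.0, pinsp=20.0, ramp_time=0.0)
        assert pressure_target(1e-9, s) == 20.0


class TestFlowTrigger:
    def setup_method(self):
        self.s = VentSettings(trigger_flow=3.0)

    def _state(self, phase, elapsed):
        st = VentState()
        st.phase = phase
        st.phase_elapsed = elapsed
        return st

    def test_strict_threshold(self):
        st = self._state(Phase.EXPIRATION, 0.5)
        assert not flow_trigger_check(2.9, self.s, st)
        assert flow_trigger_check(3.5, self.s, st)

    def test_refractory_blocks(self):
        st = self._state(Phase.EXPIRATION, 0.1)
        assert not flow_trigger_check(10.0, self.s, st)

    def test_no_trigger_during_hold(self):
        st = self._state(Phase.HOLD_EXP, 2.0)
        assert not flow_trigger_check(10.0, self.s, st)


def _passive_engine(settings, fs=100.0):
    subject = SubjectParams(effort_amplitude_Pmax=0.0, neural_RR=1e-9 or 1)
    return VentilatorEngine(settings, SubjectParams(effort_amplitude_Pmax=0.0), fs=fs)


class TestModeEquivalence:
    def test_pc_plateau_reaches_pinsp(self):
        eng = _passive_engine(VentSettings(mode=Mode.PC_AC, peep=10.0, pinsp=20.0))
        paws = []
        for i in range(600):
            paw, _ = eng.step(0.0)
            paws.append(paw)
        # end-inspiratory pressure of the 3rd cycle
        assert max(paws[400:500]) == pytest.approx(20.0, abs=0.2)

    def test_ippv_delivers_set_volume(self):
        s = VentSettings(mode=Mode.IPPV, peep=10.0, vt_target=0.350, insp_flow=35.0,
                         rr_set=40.0)
        eng = _passive_engine(s)
        flows = []
        for i in range(450):
            _, f = eng.step(0.0)
            flows.append(f)
        flows = np.asarray(flows)
        vt = np.sum(np.clip(flows[:150], 0, None)) * eng.dt
        assert vt == pytest.approx(0.350, rel=0.02)
        # constant-flow phase lasts vt/flow = 0.350/(35/60) = 0.6 s per cycle
        assert np.sum(flows[:150] > 0.5) * eng.dt == pytest.approx(0.6, abs=0.03)

    def test_passive_cycles_are_timed_on_grid(self):
        eng = _passive_engine(VentSettings(mode=Mode.PC_AC, rr_set=30.0))
        for _ in range(2000):
            eng.step(0.0)
        starts = [c["t_start"] for c in eng.cycle_log]
        assert all(c["origin"] == "TIMED" for c in eng.cycle_log)
        assert np.allclose(np.diff(starts), 2.0, atol=2 * eng.dt)


class TestHolds:
    def test_end_inspiratory_hold_flat_without_effort(self):
        eng = _passive_engine(VentSettings(mode=Mode.PC_AC, peep=10.0, pinsp=20.0))
        eng.request_hold("end_inspiratory", 1.0)
        paws = []
        for _ in range(400):
            paw, flow = eng.step(0.0)
            paws.append(paw)
            if eng.state.phase is Phase.HOLD_INSP:
                assert flow == 0.0
        hold = eng.hold_log[0]
        i0 = int(hold["t_start"] * eng.fs)
        seg = paws[i0 + 2 : i0 + 98]
        assert np.ptp(seg) < 0.2  # plateau held constant

    def test_end_expiratory_hold_drops_by_pmus(self):
        # subject effort of 5 cmH2O against closed valves at PEEP 10:
        # recorded Paw falls to ~5 cmH2O while flow stays at zero
        eng = VentilatorEngine(
            VentSettings(mode=Mode.PC_AC, peep=10.0, pinsp=20.0),
            SubjectParams(effort_amplitude_Pmax=5.0, neural_Ti=0.5),
        )
        eng.request_hold("end_expiratory", 1.2)
        paw_min = np.inf
        for i in range(500):
            t = eng.t
            pmus = 5.0 * np.sin(np.pi * min((t - 2.2) / 0.5, 1.0)) if 2.2 < t < 3.2 else 0.0
            paw, flow = eng.step(max(pmus, 0.0))
            if eng.state.phase is Phase.HOLD_EXP:
                assert flow == 0.0
                paw_min = min(paw_min, paw)
        # Paw drops by the effort amplitude below its pre-hold static level
        assert paw_min == pytest.approx(10.0 - 5.0, abs=0.6)

    def test_hold_requires_positive_duration(self):
        eng = _passive_engine(VentSettings())
        with pytest.raises(ValueError):
            eng.request_hold("end_expiratory", 0.0)
        with pytest.raises(ValueError):
            eng.request_hold("sideways", 1.0)


class TestRunCycle:
    def test_advances_exactly_one_cycle(self):
        eng = _passive_engine(VentSettings(mode=Mode.PC_AC, rr_set=30.0))
        ts, paws, flows = eng.run_cycle(lambda t: 0.0, max_t=10.0)
        start_idx = eng.state.cycle_index
        ts2, _, _ = eng.run_cycle(lambda t: 0.0, max_t=10.0)
        assert eng.state.cycle_index == start_idx + 1
        assert ts2[0] > ts[-1] - 1e-9


class TestP01:
    def _record(self, paw, flow, fs=100.0):
        n = len(paw)
        return pv.WaveformRecord(fs=fs, t=np.arange(n) / fs, flow=np.asarray(flow),
                                 paw=np.asarray(paw), peso=np.zeros(n))

    def test_linear_ramp_gives_slope_times_100ms(self):
        t = np.arange(200) / 100.0
        paw = 10.0 - np.clip(t - 0.5, 0, None) * 25.0  # 25 cmH2O/s drop
        rec = self._record(paw, np.zeros_like(paw))
        assert compute_p01(rec, 0.4, 0.5) == pytest.approx(2.5, abs=0.03)

    def test_no_effort_gives_zero(self):
        paw = np.full(100, 10.0)
        rec = self._record(paw, np.zeros_like(paw))
        assert compute_p01(rec, 0.1, 0.3) == 0.0

    def test_completed_step_measured_fully(self):
        paw = np.full(200, 10.0)
        paw[55:] = 6.0  # 4 cmH2O drop finished within 100 ms
        rec = self._record(paw, np.zeros_like(paw))
        assert compute_p01(rec, 0.4, 0.5) == pytest.approx(4.0)

    def test_unoccluded_window_rejected(self):
        paw = np.full(100, 10.0)
        flow = np.full(100, 5.0)
        rec = self._record(paw, flow)
        with pytest.raises(ValueError):
            compute_p01(rec, 0.1, 0.3)


class TestSettingsValidation:
    def test_ramp_must_fit_inspiration(self):
        with pytest.raises(ValueError):
            VentSettings(rr_set=30.0, ramp_time=1.2)

    def test_pinsp_below_peep_rejected(self):
        with pytest.raises(ValueError):
            VentSettings(mode=Mode.PC_AC, peep=10.0, pinsp=8.0)

    def test_ippv_volume_must_be_deliverable(self):
        with pytest.raises(ValueError):
            VentilatorEngine(
                VentSettings(mode=Mode.IPPV, vt_target=0.8, insp_flow=35.0, rr_set=40.0),
                SubjectParams(),
            )
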