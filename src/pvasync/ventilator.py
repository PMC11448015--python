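"""Phase-machine model of the mechanical ventilator.

Covers the pressure-controlled modes used in the experiments (BIPAP,
pressure assist-control) and volume-controlled IPPV:

* pressure delivery with a linear rise (ramp) from PEEP to the
  inspiratory target, tracked through a first-order servo with a 20 ms
  time constant;
* flow triggering with a refractory period at the start of expiration;
* time cycling from the set rate and I:E ratio, with per-cycle overrides
  (inspiratory time, ramp, shortened period) used by the asynchrony
  induction controller;
* end-expiratory / end-inspiratory hold manoeuvres during which both
  valves are closed, flow is zero and the airway pressure equals the
  subject's alveolar pressure.

Expiration is passive through the airway resistance (no separate
expiratory-valve model).  All pressures are cmH2O; flows are L/min at the
configuration surface and L/s internally.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

from .subject import SubjectParams, SubjectState, alveolar_pressure, step_mechanics

__all__ = [
    "Mode",
    "Phase",
    "CycleOrigin",
    "VentSettings",
    "VentState",
    "CycleOverrides",
    "VentilatorEngine",
    "phase_durations",
    "pressure_target",
    "flow_trigger_check",
    "compute_p01",
]

SERVO_TAU = 0.020  # s, first-order pressure-tracking time constant
REARM_DELAY = 0.35  # s between the end of a hold and an overdue timed breath


class Mode(str, enum.Enum):
    BIPAP = "BIPAP"
    IPPV = "IPPV"
    PC_AC = "PC_AC"


class Phase(str, enum.Enum):
    INSPIRATION = "INSPIRATION"
    EXPIRATION = "EXPIRATION"
    HOLD_EXP = "HOLD_EXP"
    HOLD_INSP = "HOLD_INSP"


class CycleOrigin(str, enum.Enum):
    TIMED = "TIMED"
    SUBJECT_TRIGGERED = "SUBJECT_TRIGGERED"


@dataclass(frozen=True)
class VentSettings:
    """Ventilator configuration.

    ``pinsp`` is the inspiratory pressure target of the PC modes (P_high);
    ``vt_target``/``insp_flow`` apply to IPPV.  ``tinsp`` overrides the
    I:E-derived inspiratory time when set.  ``trigger_refractory`` is the
    initial part of expiration during which subject triggering is not
    honoured (prevents double counting of the same effort).
    """

    mode: Mode = Mode.PC_AC
    peep: float = 10.0            # cmH2O
    pinsp: float = 20.0           # cmH2O, PC modes
    vt_target: float = 0.350      # L, IPPV
    insp_flow: float = 35.0       # L/min constant delivery flow, IPPV
    rr_set: float = 30.0          # min^-1
    ie_ratio: float = 1.0         # Ti : Te
    tinsp: float | None = None    # s, explicit inspiratory time override
    ramp_time: float = 0.2        # s, pressure rise time
    trigger_flow: float = 3.0     # L/min flow-trigger threshold
    trigger_refractory: float = 0.3  # s of expiration with triggering disabled
    hold_rearm: float = REARM_DELAY  # s from hold release to an overdue timed
                                     # breath (0 for manual-release holds)

    def __post_init__(self) -> None:
        if self.peep < 0:
            raise ValueError("peep must be >= 0")
        if self.rr_set <= 0:
            raise ValueError("rr_set must be > 0")
        if self.ramp_time < 0:
            raise ValueError("ramp_time must be >= 0")
        if self.trigger_flow <= 0:
            raise ValueError("trigger_flow must be > 0")
        if self.mode in (Mode.BIPAP, Mode.PC_AC) and self.pinsp < self.peep:
            raise ValueError("pinsp must be >= peep in pressure-controlled modes")
        ti, _ = phase_durations(self)
        if self.ramp_time >= ti:
            raise ValueError("ramp_time must be shorter than the inspiratory time")

    @property
    def period(self) -> float:
        return 60.0 / self.rr_set

    @property
    def trigger_flow_ls(self) -> float:
        return self.trigger_flow / 60.0

    @property
    def insp_flow_ls(self) -> float:
        return self.insp_flow / 60.0

    def with_(self, **kwargs) -> "VentSettings":
        return replace(self, **kwargs)


def phase_durations(settings: VentSettings) -> tuple[float, float]:
    """(Ti, Te) from rate and I:E ratio; ``tinsp`` takes precedence for Ti."""
    period = 60.0 / settings.rr_set
    if settings.tinsp is not None:
        ti = settings.tinsp
    else:
        ti = period * settings.ie_ratio / (1.0 + settings.ie_ratio)
    return ti, period - ti


def pressure_target(t_in_insp: float, settings: VentSettings, ramp_time: float | None = None) -> float:
    """PC-mode pressure target: linear ramp from PEEP to Pinsp, then constant."""
    ramp = settings.ramp_time if ramp_time is None else ramp_time
    if ramp <= 0 or t_in_insp >= ramp:
        return settings.pinsp
    frac = max(t_in_insp, 0.0) / ramp
    return settings.peep + (settings.pinsp - settings.peep) * frac


def flow_trigger_check(subject_flow: float, settings: VentSettings, state: "VentState") -> bool:
    """True iff inspiratory flow reaches the trigger threshold during the
    armed part of expiration.  ``subject_flow`` is in L/min."""
    if state.phase is not Phase.EXPIRATION:
        return False
    if state.phase_elapsed < settings.trigger_refractory:
        return False
    return subject_flow >= settings.trigger_flow


@dataclass
class CycleOverrides:
    """Per-cycle parameter alterations set by the induction controller."""

    ramp_time: float | None = None      # DT: prolonged pressure ramp
    tinsp: float | None = None          # AT: shortened inspiratory time
    period: float | None = None         # AT: shortened timed-cycle period of the
                                        # *preceding* cycle (early mandatory start)
    exp_hold: float | None = None       # IE: end-expiratory hold duration
    force_timed: bool = False           # AT: suppress triggering before onset
    pinsp: float | None = None          # bench regression: per-cycle Pinsp


@dataclass
class VentState:
    phase: Phase = Phase.EXPIRATION
    phase_elapsed: float = 0.0
    cycle_index: int = -1
    cycle_origin: CycleOrigin = CycleOrigin.TIMED
    active_overrides: CycleOverrides = field(default_factory=CycleOverrides)


class VentilatorEngine:
    """Sample-stepping ventilator coupled to a virtual subject.

    The engine owns the phase machine and the delivered airway pressure;
    the caller provides the subject's muscle pressure sample by sample and
    the engine advances the subject mechanics accordingly.
    """

    def __init__(
        self,
        settings: VentSettings,
        subject_params: SubjectParams,
        fs: float = 100.0,
        overrides: dict[int, CycleOverrides] | None = None,
    ):
        if settings.mode is Mode.IPPV:
            ti, _ = phase_durations(settings)
            if settings.vt_target <= 0 or settings.insp_flow <= 0:
                raise ValueError("IPPV requires positive vt_target and insp_flow")
            if settings.vt_target / settings.insp_flow_ls > ti:
                raise ValueError("vt_target not deliverable within the inspiratory time")
        self.settings = settings
        self.subject_params = subject_params
        self.fs = fs
        self.dt = 1.0 / fs
        self.overrides = overrides or {}

        self.state = VentState()
        self.subject = SubjectState()
        self.paw = settings.peep
        self.t = 0.0

        ti, _ = phase_durations(settings)
        self._ti_cur = ti
        self._ramp_cur = settings.ramp_time
        self._pinsp_cur = settings.pinsp
        self._cycle_start = 0.0
        self._deadline = 0.0  # next timed inspiration, absolute s
        self._trig_suppressed_until = -np.inf
        self._armed_exp_hold: float | None = None  # pending hold duration
        self._hold_end = 0.0
        self._delivered_vt = 0.0
        self._manual_hold: tuple[str, float] | None = None

        # logs
        self.cycle_log: list[dict] = []
        self.hold_log: list[dict] = []

    # -- manoeuvres -------------------------------------------------------

    def request_hold(self, kind: str, duration: float) -> None:
        """Queue a hold manoeuvre at the next matching phase boundary."""
        if duration <= 0:
            raise ValueError("hold duration must be > 0")
        if kind not in ("end_expiratory", "end_inspiratory"):
            raise ValueError(f"unknown hold kind: {kind}")
        self._manual_hold = (kind, duration)

    # -- phase machine ----------------------------------------------------

    def _cycle_overrides(self, idx: int) -> CycleOverrides:
        return self.overrides.get(idx, CycleOverrides())

    def _start_inspiration(self, origin: CycleOrigin) -> None:
        st = self.state
        st.cycle_index += 1
        st.cycle_origin = origin
        st.phase = Phase.INSPIRATION
        st.phase_elapsed = 0.0
        self._cycle_start = self.t
        ov = self._cycle_overrides(st.cycle_index)
        st.active_overrides = ov
        base_ti, _ = phase_durations(self.settings)
        self._ti_cur = ov.tinsp if ov.tinsp is not None else base_ti
        self._ramp_cur = ov.ramp_time if ov.ramp_time is not None else self.settings.ramp_time
        self._pinsp_cur = ov.pinsp if ov.pinsp is not None else self.settings.pinsp
        self._delivered_vt = 0.0
        self._deadline = self.t + self.settings.period
        self.cycle_log.append(
            {
                "cycle_index": st.cycle_index,
                "t_start": self.t,
                "origin": origin.value,
                "ramp_time": self._ramp_cur,
                "ti": self._ti_cur,
            }
        )
        # An early-mandatory (auto-trigger) modification of the *next* cycle
        # shortens this cycle's timed period and disarms the trigger so the
        # ventilator fires before the subject's expected effort.
        nxt = self._cycle_overrides(st.cycle_index + 1)
        if nxt.period is not None:
            self._deadline = self.t + nxt.period
        if nxt.force_timed:
            self._trig_suppressed_until = self._deadline

    def _start_expiration(self) -> None:
        st = self.state
        st.phase = Phase.EXPIRATION
        st.phase_elapsed = 0.0
        ov = st.active_overrides
        if ov.exp_hold is not None:
            # Arm an automatic end-expiratory hold: the valves close on the
            # next trigger-level inspiratory flow (i.e. on the subject's
            # effort) or, failing that, at the timed deadline.
            self._armed_exp_hold = ov.exp_hold
            self._trig_suppressed_until = np.inf
        if self._manual_hold and self._manual_hold[0] == "end_expiratory":
            self._armed_exp_hold = self._manual_hold[1]
            self._trig_suppressed_until = np.inf
            self._manual_hold = None

    def _begin_exp_hold(self, duration: float) -> None:
        st = self.state
        st.phase = Phase.HOLD_EXP
        st.phase_elapsed = 0.0
        self._hold_end = self.t + duration
        self._armed_exp_hold = None
        self.hold_log.append(
            {"kind": "end_expiratory", "t_start": self.t, "duration": duration,
             "cycle_index": st.cycle_index}
        )

    def step(self, pmus: float) -> tuple[float, float]:
        """Advance one sample; returns (paw, flow_ls) at the new time."""
        st = self.state
        s = self.settings
        prev_flow = self.subject.flow

        if st.phase is Phase.INSPIRATION:
            if st.phase_elapsed >= self._ti_cur:
                if self._manual_hold and self._manual_hold[0] == "end_inspiratory":
                    dur = self._manual_hold[1]
                    self._manual_hold = None
                    st.phase = Phase.HOLD_INSP
                    st.phase_elapsed = 0.0
                    self._hold_end = self.t + dur
                    self.hold_log.append(
                        {"kind": "end_inspiratory", "t_start": self.t,
                         "duration": dur, "cycle_index": st.cycle_index}
                    )
                else:
                    self._start_expiration()
        elif st.phase is Phase.HOLD_INSP:
            if self.t >= self._hold_end:
                self._start_expiration()
                self._deadline = max(self._deadline, self.t + s.hold_rearm)
        elif st.phase is Phase.HOLD_EXP:
            if self.t >= self._hold_end:
                st.phase = Phase.EXPIRATION
                # resume with the refractory period already spent: the hold
                # itself blocked any re-trigger
                st.phase_elapsed = s.trigger_refractory
                self._trig_suppressed_until = -np.inf
                # a timed breath whose deadline elapsed during the hold is
                # delivered promptly once the valves re-open
                self._deadline = max(self._deadline, self.t + s.hold_rearm)

        if st.phase is Phase.EXPIRATION:
            armed = self._armed_exp_hold is not None
            triggerable = (
                st.phase_elapsed >= s.trigger_refractory
                and self.t >= self._trig_suppressed_until
            )
            effort_flow = prev_flow >= s.trigger_flow_ls
            if armed and st.phase_elapsed >= s.trigger_refractory and effort_flow:
                self._begin_exp_hold(self._armed_exp_hold)
            elif armed and self.t >= self._deadline:
                self._begin_exp_hold(self._armed_exp_hold)
            elif triggerable and effort_flow:
                self._start_inspiration(CycleOrigin.SUBJECT_TRIGGERED)
            elif self.t >= self._deadline:
                self._start_inspiration(CycleOrigin.TIMED)

        # --- delivery + mechanics at the (possibly new) phase -------------
        dt = self.dt
        subj = self.subject
        pp = self.subject_params
        subj.pmus = pmus

        if st.phase in (Phase.HOLD_EXP, Phase.HOLD_INSP):
            self.paw = alveolar_pressure(subj, s.peep, pp)
            step_mechanics(subj, self.paw, s.peep, dt, pp, occluded=True)
        elif st.phase is Phase.INSPIRATION and s.mode is Mode.IPPV:
            if self._delivered_vt < s.vt_target:
                f = s.insp_flow_ls
                step_mechanics(subj, 0.0, s.peep, dt, pp, forced_flow=f)
                self._delivered_vt += f * dt
                self.paw = alveolar_pressure(subj, s.peep, pp) + pp.resistance_R * f
            else:
                # inspiratory pause at the delivered volume, valves closed
                self.paw = alveolar_pressure(subj, s.peep, pp)
                step_mechanics(subj, self.paw, s.peep, dt, pp, occluded=True)
        else:
            if st.phase is Phase.INSPIRATION:
                target = self._pc_target(st.phase_elapsed)
            else:
                target = s.peep
            self.paw += (target - self.paw) * min(1.0, dt / SERVO_TAU)
            step_mechanics(subj, self.paw, s.peep, dt, pp)

        self.t += dt
        st.phase_elapsed += dt
        return self.paw, subj.flow

    def _pc_target(self, t_in_insp: float) -> float:
        ramp = self._ramp_cur
        if ramp <= 0 or t_in_insp >= ramp:
            return self._pinsp_cur
        return self.settings.peep + (self._pinsp_cur - self.settings.peep) * t_in_insp / ramp

    def run_cycle(self, pmus_of_t, max_t: float | None = None):
        """Advance until the next cycle begins (or ``max_t``); returns the
        delivered (t, paw, flow) samples of the interval."""
        start_idx = self.state.cycle_index
        ts, paws, flows = [], [], []
        limit = np.inf if max_t is None else max_t
        while self.state.cycle_index == start_idx and self.t < limit:
            paw, flow = self.step(float(pmus_of_t(self.t)))
            ts.append(self.t)
            paws.append(paw)
            flows.append(flow)
        return np.asarray(ts), np.asarray(paws), np.asarray(flows)


def compute_p01(record, occlusion_onset: float, effort_onset: float) -> float:
    """Airway occlusion pressure P0.1: Paw drop over the first 100 ms of an
    inspiratory effort made against closed valves.

    ``record`` must expose uniformly sampled ``t``, ``paw`` and ``flow``
    (L/min) arrays.  Raises if the 100 ms window is not occluded.
    """
    t = np.asarray(record.t)
    paw = np.asarray(record.paw)
    flow = np.asarray(record.flow)
    if effort_onset < occlusion_onset:
        raise ValueError("effort must start at or after the occlusion onset")
    win = (t >= effort_onset) & (t <= effort_onset + 0.1)
    if not win.any():
        raise ValueError("window outside record")
    if np.max(np.abs(flow[win])) > 1e-6:
        raise ValueError("P0.1 window is not occluded (non-zero flow)")
    fs = 1.0 / np.median(np.diff(t))
    i0 = int(np.searchsorted(t, effort_onset))
    i1 = min(len(t) - 1, i0 + int(round(0.1 * fs)))
    return float(paw[i0] - paw[i1])
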