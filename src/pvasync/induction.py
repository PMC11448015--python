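"""Cycle-by-cycle induction of subject-ventilator asynchrony.

The controller schedules three kinds of per-cycle ventilator-parameter
modifications, each designed to provoke one asynchrony type in an
otherwise synchronous closed loop:

* **IE** (ineffective effort): an automatic end-expiratory hold is armed
  for the target cycle.  The valves close on the subject's next
  inspiratory-flow excursion (or at the timed deadline if no effort
  arrives) and stay closed for ``k_hold`` times a reference time
  (inspiratory time by default).  The effort is thus spent against a
  closed valve: oesophageal and airway pressure dip, flow stays at zero,
  and no assisted cycle follows.
* **AT** (auto-triggering): the preceding cycle's timed period is
  shortened to 60 / (RR * rr_multiplier) with triggering disarmed, so a
  mandatory inspiration (with a shortened inspiratory time) starts before
  the subject's expected effort — a machine cycle without a preceding
  pressure dip.
* **DT** (double-triggering): the pressure ramp is prolonged for three
  consecutive cycles.  Slow pressurization lets the subject's effort
  complete while the airway pressure is still rising, producing two flow
  humps within one machine inspiration (the "M" shape of breath
  stacking).

Modifications are drawn without index collisions at a configurable
fraction of breaths per type (default 5%, aiming at a gross asynchrony
index near 25% when DT clusters are counted cycle-wise: 5% + 5% + 3x5%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .record import WaveformRecord
from .subject import SubjectParams, effort_onset_times, pmus_waveform
from .ventilator import (
    CycleOrigin,
    CycleOverrides,
    Mode,
    VentilatorEngine,
    VentSettings,
    phase_durations,
)

__all__ = [
    "ModificationEvent",
    "InductionSchedule",
    "SchedulingError",
    "build_schedule",
    "induce_ie",
    "induce_at",
    "induce_dt",
    "run_experiment",
    "SimulationResult",
]


class SchedulingError(RuntimeError):
    """Raised when the requested event density cannot be packed."""


@dataclass
class ModificationEvent:
    """One scheduled per-cycle parameter alteration."""

    sva_type: str                      # "IE" | "AT" | "DT"
    target_cycles: list[int]
    params: dict = field(default_factory=dict)
    applied: bool = False

    def __post_init__(self) -> None:
        if self.sva_type not in ("IE", "AT", "DT"):
            raise ValueError(f"unknown sva_type: {self.sva_type}")
        tc = self.target_cycles
        if any(b - a != 1 for a, b in zip(tc, tc[1:])):
            raise ValueError("target_cycles must be strictly increasing and consecutive")


@dataclass
class InductionSchedule:
    fraction_per_type: float
    dt_cluster_len: int
    min_gap: int
    seed: int
    events: list[ModificationEvent] = field(default_factory=list)

    def events_by_type(self, sva_type: str) -> list[ModificationEvent]:
        return [e for e in self.events if e.sva_type == sva_type]

    @property
    def asynchronous_cycles(self) -> set[int]:
        out: set[int] = set()
        for e in self.events:
            out.update(e.target_cycles)
        return out


def induce_ie(
    cycle_idx: int,
    settings: VentSettings,
    k_hold: float = 1.5,
    reference: str = "inspiratory_time",
    hold_duration: float | None = None,
) -> ModificationEvent:
    """End-expiratory hold of ``k_hold`` x reference time at ``cycle_idx``.

    ``hold_duration`` (s) overrides the multiplier when given (the bench
    tests used a fixed one-second hold).
    """
    if k_hold <= 0:
        raise ValueError("k_hold must be > 0")
    if hold_duration is None:
        ti, te = phase_durations(settings)
        ref = ti if reference == "inspiratory_time" else te
        hold_duration = k_hold * ref
    return ModificationEvent(
        "IE", [cycle_idx], {"hold_duration": float(hold_duration)}
    )


def induce_at(
    cycle_idx: int,
    settings: VentSettings,
    rr_multiplier: float = 1.5,
    tinsp_override: float = 0.5,
) -> ModificationEvent:
    """Early mandatory cycle at ``cycle_idx``: period 60/(RR*multiplier),
    inspiratory time ``tinsp_override``, triggering disarmed beforehand."""
    if rr_multiplier <= 1:
        raise ValueError("rr_multiplier must be > 1")
    period = 60.0 / (settings.rr_set * rr_multiplier)
    return ModificationEvent(
        "AT",
        [cycle_idx],
        {"period": period, "tinsp_override": float(tinsp_override)},
    )


def default_dt_ramp(settings: VentSettings) -> float:
    """Prolonged-ramp default: 2 s where the inspiratory time allows it,
    otherwise 90% of the inspiratory time."""
    ti, _ = phase_durations(settings)
    return 2.0 if ti > 2.0 else 0.9 * ti


def induce_dt(
    start_cycle_idx: int,
    settings: VentSettings,
    ramp_override: float | None = None,
    n_consecutive: int = 3,
) -> ModificationEvent:
    """Prolong the pressure ramp for ``n_consecutive`` cycles."""
    if n_consecutive < 1:
        raise ValueError("n_consecutive must be >= 1")
    if ramp_override is None:
        ramp_override = default_dt_ramp(settings)
    if ramp_override <= settings.ramp_time:
        raise ValueError("ramp_override must exceed the baseline ramp_time")
    ti, _ = phase_durations(settings)
    if ramp_override >= ti:
        raise ValueError("ramp_override must be shorter than the inspiratory time")
    cycles = list(range(start_cycle_idx, start_cycle_idx + n_consecutive))
    return ModificationEvent("DT", cycles, {"ramp_override": float(ramp_override)})


def build_schedule(
    n_cycles: int,
    fraction_per_type: float = 0.05,
    min_gap: int = 2,
    seed: int = 0,
    settings: VentSettings | None = None,
    dt_cluster_len: int = 3,
    ie_kwargs: dict | None = None,
    at_kwargs: dict | None = None,
    dt_kwargs: dict | None = None,
    types: tuple[str, ...] = ("IE", "AT", "DT"),
) -> InductionSchedule:
    """Draw ``round(fraction * n_cycles)`` events per type without index
    collisions, honouring ``min_gap`` free cycles between events.

    Reproducible under ``seed``.  Raises :class:`SchedulingError` when the
    requested density cannot be packed.
    """
    if n_cycles < 20:
        raise ValueError("n_cycles must be >= 20")
    if not (0 <= fraction_per_type <= 0.35):
        raise ValueError("fraction_per_type out of range")
    if min_gap < 1:
        raise ValueError("min_gap must be >= 1")
    settings = settings or VentSettings()
    rng = np.random.default_rng(seed)
    n_per_type = int(round(fraction_per_type * n_cycles))

    lengths = {"IE": 1, "AT": 1, "DT": dt_cluster_len}
    wanted = [(typ, lengths[typ]) for typ in types for _ in range(n_per_type)]
    if not wanted:
        return InductionSchedule(fraction_per_type, dt_cluster_len, min_gap, seed, [])

    # Block allocation: events in random order with the mandatory min_gap
    # between them, the spare cycles spread multinomially over the slots.
    # The first cycles stay pristine so classification context exists.
    order = rng.permutation(len(wanted))
    wanted = [wanted[i] for i in order]
    k = len(wanted)
    lead, tail = 3, 2
    consumed = lead + tail + sum(length for _, length in wanted) + min_gap * (k - 1)
    spare = n_cycles - consumed
    if spare < 0:
        raise SchedulingError(
            f"infeasible packing: {k} events need {consumed} cycles, have {n_cycles}"
        )
    extra = rng.multinomial(spare, np.full(k + 1, 1.0 / (k + 1)))
    placements: list[tuple[str, int, int]] = []
    pos = lead + int(extra[0])
    for j, (typ, length) in enumerate(wanted):
        placements.append((typ, pos, length))
        pos += length + min_gap + int(extra[j + 1])
    ie_kwargs = ie_kwargs or {}
    at_kwargs = at_kwargs or {}
    dt_kwargs = dt_kwargs or {}
    events = []
    for typ, start, length in placements:
        if typ == "IE":
            events.append(induce_ie(start, settings, **ie_kwargs))
        elif typ == "AT":
            events.append(induce_at(start, settings, **at_kwargs))
        else:
            events.append(induce_dt(start, settings, n_consecutive=length, **dt_kwargs))
    return InductionSchedule(
        fraction_per_type=fraction_per_type,
        dt_cluster_len=dt_cluster_len,
        min_gap=min_gap,
        seed=seed,
        events=events,
    )


def _overrides_from_schedule(schedule: InductionSchedule) -> dict[int, CycleOverrides]:
    out: dict[int, CycleOverrides] = {}
    for ev in schedule.events:
        if ev.sva_type == "IE":
            (k,) = ev.target_cycles
            out[k] = CycleOverrides(exp_hold=ev.params["hold_duration"])
        elif ev.sva_type == "AT":
            (k,) = ev.target_cycles
            out[k] = CycleOverrides(
                period=ev.params["period"],
                tinsp=ev.params["tinsp_override"],
                force_timed=True,
            )
        else:
            for k in ev.target_cycles:
                out[k] = CycleOverrides(ramp_time=ev.params["ramp_override"])
    return out


@dataclass
class SimulationResult:
    record: WaveformRecord
    cycles: pd.DataFrame       # ground truth per machine cycle
    events: pd.DataFrame       # applied modification events
    holds: pd.DataFrame        # hold manoeuvre intervals

    @property
    def truth_labels(self) -> pd.Series:
        return self.cycles.set_index("cycle_index")["sva_truth"]


def run_experiment(
    subject_params: SubjectParams,
    vent_settings: VentSettings,
    schedule: InductionSchedule | None,
    duration: float,
    seed: int = 0,
    fs: float = 100.0,
) -> SimulationResult:
    """Closed-loop simulation of subject + ventilator + induction schedule.

    Returns the uniformly sampled waveform record (flow L/min, Paw and
    Peso cmH2O, Ppl as Peso without the cardiac artifact) together with
    per-cycle ground truth.  Bit-identical under a fixed seed.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    n = int(round(duration * fs))
    onsets = effort_onset_times(subject_params, duration, seed=seed)
    pmus = pmus_waveform(onsets, n, fs, subject_params)

    overrides = _overrides_from_schedule(schedule) if schedule else {}
    engine = VentilatorEngine(vent_settings, subject_params, fs=fs, overrides=overrides)

    paw = np.empty(n)
    flow = np.empty(n)
    volume = np.empty(n)
    for i in range(n):
        paw[i], flow[i] = engine.step(pmus[i])
        volume[i] = engine.subject.lung_volume_V

    t = np.arange(n) / fs
    ppl = (
        subject_params.peso_baseline
        + subject_params.chestwall_E * volume
        - pmus
    )
    peso = ppl + subject_params.cardiac_artifact_amp * np.sin(
        2.0 * np.pi * subject_params.f_cardiac * t
    )

    record = WaveformRecord(
        fs=fs,
        t=t,
        flow=flow * 60.0,
        paw=paw,
        peso=peso,
        ppl=ppl,
        meta={
            "mode": vent_settings.mode.value,
            "peep": vent_settings.peep,
            "pinsp": vent_settings.pinsp,
            "rr_set": vent_settings.rr_set,
            "seed": seed,
            "duration": duration,
        },
    )

    cycles = pd.DataFrame(engine.cycle_log)
    truth = {}
    if schedule:
        starts = np.array([c["t_start"] for c in engine.cycle_log])
        holds_by_cycle = {h["cycle_index"]: h for h in engine.hold_log}
        for ev in schedule.events:
            for k in ev.target_cycles:
                truth[k] = ev.sva_type
            ev.applied = any(k <= engine.state.cycle_index for k in ev.target_cycles)
            if ev.sva_type == "IE" and ev.applied:
                # ground truth from simulator internals: the hold induced an
                # ineffective effort only if an effort fell into it and no
                # inspiration started until well after the effort released
                (k,) = ev.target_cycles
                hold = holds_by_cycle.get(k)
                if hold is None:
                    truth[k] = "NORMAL"
                    continue
                h0, h1 = hold["t_start"], hold["t_start"] + hold["duration"]
                dip_dur = subject_params.neural_Ti * (
                    1.0 + 0.5 * np.log(max(subject_params.effective_pmax / 2.0, 1.001))
                )
                ineffective = False
                for o in onsets[(onsets >= h0 - 0.15) & (onsets <= h1)]:
                    later = starts[starts > o]
                    nxt = later[0] if len(later) else np.inf
                    if nxt > o + dip_dur + 0.5:
                        ineffective = True
                if not ineffective:
                    truth[k] = "NORMAL"
    if len(cycles):
        cycles["sva_truth"] = [
            truth.get(k, "NORMAL") for k in cycles["cycle_index"]
        ]
    events_rows = []
    if schedule:
        for i, ev in enumerate(schedule.events):
            for name, value in ev.params.items():
                events_rows.append(
                    {
                        "event_id": i,
                        "sva_type": ev.sva_type,
                        "cycle_indices": ";".join(map(str, ev.target_cycles)),
                        "param_name": name,
                        "param_value": value,
                        "applied": ev.applied,
                    }
                )
    events = pd.DataFrame(
        events_rows,
        columns=["event_id", "sva_type", "cycle_indices", "param_name", "param_value", "applied"],
    )
    holds = pd.DataFrame(
        engine.hold_log, columns=["kind", "t_start", "duration", "cycle_index"]
    )
    return SimulationResult(record=record, cycles=cycles, events=events, holds=holds)
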