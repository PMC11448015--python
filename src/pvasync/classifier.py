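"""Rule-based offline classification of subject-ventilator asynchrony.

Re-implements, as explicit waveform rules, the manual flowchart used to
annotate the recordings: cycles are segmented from the flow signal,
inspiratory efforts are detected as oesophageal-pressure dips, and every
cycle is labelled NORMAL / IE / AT / DT:

* an **effort** is a contiguous dip of Peso at least ``theta_dip`` below
  its local (rolling-median) baseline lasting at least 100 ms;
* an effort is **rewarded** when any segmented inspiration starts between
  shortly before the dip begins and shortly after it ends — an unrewarded
  effort marks its enclosing cycle as **IE** (the effort met closed or
  untriggered valves: pressure dip with no flow response);
* a machine inspiration with no effort dip anywhere near its onset is
  **AT** (mandatory delivery without a preceding pressure drop);
* two inspiratory flow humps inside one machine inspiration (the "M"
  shape of breath stacking), or two machine inspirations separated by
  less than half the running-mean inspiratory time without considerable
  intervening expiration, are **DT**.

Label priority is DT > IE > AT.  Classification is deterministic: the
same record always yields identical annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from scipy.signal import find_peaks

from .record import WaveformRecord

__all__ = [
    "ClassifierParams",
    "RespiratoryCycle",
    "EffortEvent",
    "CycleAnnotation",
    "AsynchronyReport",
    "segment_cycles",
    "detect_efforts",
    "count_flow_peaks",
    "classify_cycle",
    "classify_record",
    "compute_aix",
    "summarize_group",
]

LABELS = ("NORMAL", "IE", "AT", "DT", "OTHER")


@dataclass(frozen=True)
class ClassifierParams:
    """Thresholds of the rule cascade (the reference procedure was visual,
    so these quantify what an annotator judges by eye)."""

    theta_flow: float = 0.05     # L/s, inspiration on/off threshold
    flow_sustain: float = 0.05   # s a crossing must persist
    min_ti: float = 0.15         # s, shorter flow excursions are artifacts
    merge_gap: float = 0.30      # s, max zero-flow gap merged into one inspiration
    merge_exp_frac: float = 0.25  # max expired/inspired volume ratio for a merge
    theta_dip: float = 2.0       # cmH2O, effort-dip depth
    dip_min_dur: float = 0.10    # s
    baseline_win: float = 5.0    # s, rolling-median window for the Peso baseline
                                 # (long enough that a deep one-second effort
                                 # dip barely biases the local median)
    reward_pre: float = 0.50     # s before dip start an inspiration may begin
    reward_post: float = 0.50    # s after dip end an inspiration may begin
    at_pre: float = 0.30         # s, AT look-back around inspiration onset
    at_post: float = 0.35        # s, AT look-forward
    theta_peak_frac: float = 0.10  # flow-peak prominence, fraction of cycle peak
    peak_sep: float = 0.10       # s, min separation of counted flow peaks
    dt_interval_frac: float = 0.50  # DT: interval < frac * mean Ti
    dt_exp_frac: float = 0.25    # DT: expired volume < frac * preceding VT
    machine_paw_rise: float = 2.0  # cmH2O above PEEP marking a machine cycle
    ti_run_mean_n: int = 10      # machine cycles in the running mean Ti


@dataclass
class RespiratoryCycle:
    index: int
    t_insp_start: float
    t_insp_end: float
    t_exp_end: float
    vt_insp: float
    vt_exp: float
    machine_cycle: bool
    n_flow_peaks: int = 1

    def __post_init__(self) -> None:
        if not (self.t_insp_start < self.t_insp_end <= self.t_exp_end):
            raise ValueError("cycle boundaries must satisfy start < insp_end <= exp_end")

    @property
    def ti(self) -> float:
        return self.t_insp_end - self.t_insp_start


@dataclass
class EffortEvent:
    onset: float
    nadir_t: float
    end: float
    magnitude: float
    rewarded: bool = False


@dataclass
class CycleAnnotation:
    cycle_index: int
    label: str
    t_insp_start: float
    t_insp_end: float
    t_exp_end: float
    evidence: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label: {self.label}")


@dataclass
class AsynchronyReport:
    n_cycles: int
    counts: dict
    aix: float
    incidence: dict

    def to_dict(self) -> dict:
        return asdict(self)


def _sustained_mask(mask: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    """Runs of True at least ``min_len`` samples long, as (start, stop)."""
    if not mask.any():
        return []
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    runs = idx.reshape(-1, 2)
    return [(a, b) for a, b in runs if b - a >= min_len]


def segment_cycles(
    record: WaveformRecord,
    fs: float | None = None,
    params: ClassifierParams = ClassifierParams(),
) -> list[RespiratoryCycle]:
    """Segment respiratory cycles from the flow channel.

    Inspiration onset is an upward crossing of +theta_flow sustained for
    ``flow_sustain``; the end is the matching downward crossing.  Two
    inspiratory excursions separated by a short gap with negligible
    expired volume are merged into one inspiration (breath stacking keeps
    its "M" shape inside a single machine inspiration).  Cycles tile the
    record without gaps: cycle i spans [insp_start_i, insp_start_{i+1}).
    """
    fs = fs or record.fs
    if fs < 50:
        raise ValueError("fs must be >= 50 Hz")
    flow = record.flow_ls
    t = record.t
    dt = 1.0 / fs
    segs = _sustained_mask(flow > params.theta_flow, max(1, int(round(params.flow_sustain * fs))))
    if not segs:
        return []

    # Merge across brief, low-volume gaps so a stacked second hump stays
    # inside one inspiration.  The airway pressure must still be elevated
    # in the gap (the machine is mid-insufflation); once Paw has returned
    # to PEEP, the next excursion is a new cycle, not a hump.
    peep_est = float(np.percentile(record.paw, 10))
    merged: list[list[int]] = []
    for a, b in segs:
        if merged:
            pa, pb = merged[-1]
            gap = (a - pb) * dt
            insp_vol = np.sum(np.clip(flow[pa:pb], 0, None)) * dt
            exp_vol = np.sum(np.clip(-flow[pb:a], 0, None)) * dt
            paw_gap = float(np.min(record.paw[pb:a])) if a > pb else np.inf
            if (
                gap < params.merge_gap
                and exp_vol < params.merge_exp_frac * max(insp_vol, 1e-9)
                and paw_gap > peep_est + params.machine_paw_rise
            ):
                merged[-1][1] = b
                continue
        merged.append([a, b])

    min_samples = int(round(params.min_ti * fs))
    merged = [(a, b) for a, b in merged if b - a >= min_samples]
    if not merged:
        return []

    peep_est = float(np.percentile(record.paw, 10))
    cycles = []
    for i, (a, b) in enumerate(merged):
        nxt = merged[i + 1][0] if i + 1 < len(merged) else len(flow)
        vt_insp = float(np.sum(np.clip(flow[a:b], 0, None)) * dt)
        vt_exp = float(np.sum(np.clip(-flow[b:nxt], 0, None)) * dt)
        machine = bool(np.max(record.paw[a:b]) >= peep_est + params.machine_paw_rise)
        cycles.append(
            RespiratoryCycle(
                index=i,
                t_insp_start=float(t[a]),
                t_insp_end=float(t[b - 1] + dt),
                t_exp_end=float(t[nxt - 1] + dt) if nxt > b else float(t[b - 1] + dt),
                vt_insp=vt_insp,
                vt_exp=vt_exp,
                machine_cycle=machine,
            )
        )
    return cycles


def detect_efforts(
    peso: np.ndarray,
    fs: float,
    params: ClassifierParams = ClassifierParams(),
) -> list[EffortEvent]:
    """Inspiratory efforts as contiguous Peso dips >= theta_dip below the
    local rolling-median baseline, lasting >= 100 ms.

    The dip threshold sits above the peak-to-peak cardiac artifact, which
    therefore produces no false efforts.
    """
    peso = np.asarray(peso, dtype=float)
    win = int(round(params.baseline_win * fs)) | 1
    baseline = median_filter(peso, size=win, mode="nearest")
    depth = baseline - peso
    min_len = max(1, int(round(params.dip_min_dur * fs)))
    events = []
    for a, b in _sustained_mask(depth >= params.theta_dip, min_len):
        seg = depth[a:b]
        nadir = a + int(np.argmax(seg))
        events.append(
            EffortEvent(
                onset=a / fs,
                nadir_t=nadir / fs,
                end=(b - 1) / fs,
                magnitude=float(seg.max()),
            )
        )
    return events


def _inspiration_peaks(
    cycle: RespiratoryCycle,
    record: WaveformRecord,
    params: ClassifierParams,
) -> tuple[int, int | None]:
    """(peak count, sample index of the inter-peak valley) for the cycle's
    inspiration.  The valley index (global, into the record) is reported
    only when two or more peaks are counted."""
    fs = record.fs
    a = int(round(cycle.t_insp_start * fs))
    b = int(round(cycle.t_insp_end * fs))
    seg = record.flow_ls[a:b]
    if len(seg) < 3:
        return 0, None
    peak_flow = float(np.max(seg))
    if peak_flow <= 0:
        return 0, None
    # pad with zeros so peak prominence is measured against sub-threshold
    # flow outside the inspiration, not against the segment edges; a
    # counted peak must still be an interior maximum (a rise cut off by
    # cycling is not a delivered flow hump)
    padded = np.concatenate(([0.0], seg, [0.0]))
    peaks, _ = find_peaks(
        padded,
        prominence=params.theta_peak_frac * peak_flow,
        distance=max(1, int(round(params.peak_sep * fs))),
    )
    peaks = peaks[(peaks > 1) & (peaks < len(padded) - 2)] - 1
    if len(peaks) < 2:
        # a monotone rise-fall profile has its maximum at an endpoint of
        # the plateau; count one even without an interior extremum
        return max(len(peaks), 1), None
    valley = int(peaks[0] + np.argmin(seg[peaks[0] : peaks[-1] + 1]))
    return len(peaks), a + valley


def count_flow_peaks(
    cycle: RespiratoryCycle,
    record: WaveformRecord,
    params: ClassifierParams = ClassifierParams(),
) -> int:
    """Local flow maxima within the inspiration with prominence at least
    ``theta_peak_frac`` of the cycle's peak flow and 100 ms separation."""
    n, _ = _inspiration_peaks(cycle, record, params)
    return n


def _occlusion_in_gap(
    record: WaveformRecord,
    t0: float,
    t1: float,
    peep_est: float,
    params: ClassifierParams,
    min_dur: float = 0.25,
    paw_dev: float = 1.5,
) -> bool:
    """Hold signature between two inspirations: a sustained run of zero
    flow while the airway pressure sits away from PEEP (closed valves
    with the subject pulling on, or relaxing against, the circuit)."""
    fs = record.fs
    a, b = int(round(t0 * fs)), int(round(t1 * fs))
    if b - a < 2:
        return False
    quiet = (np.abs(record.flow_ls[a:b]) < 0.5 * params.theta_flow) & (
        np.abs(record.paw[a:b] - peep_est) > paw_dev
    )
    return any(
        (j - i) >= int(round(min_dur * fs)) for i, j in _sustained_mask(quiet, 1)
    )


def _mean_ti(cycles: list[RespiratoryCycle], upto: int, n_run: int, fallback: float) -> float:
    tis = [c.ti for c in cycles[:upto] if c.machine_cycle][-n_run:]
    return float(np.mean(tis)) if tis else fallback


def classify_cycle(
    cycle: RespiratoryCycle,
    cycles: list[RespiratoryCycle],
    efforts: list[EffortEvent],
    record: WaveformRecord,
    params: ClassifierParams = ClassifierParams(),
) -> CycleAnnotation:
    """Label one cycle using its neighbours as context (first/last cycles
    use one-sided context).  Priority DT > IE > AT."""
    i = cycle.index
    evidence: dict = {}
    label = "NORMAL"
    peep_est = float(np.percentile(record.paw, 10))

    if cycle.machine_cycle:
        n_peaks, valley_idx = _inspiration_peaks(cycle, record, params)
    else:
        n_peaks, valley_idx = 1, None
    cycle.n_flow_peaks = n_peaks
    evidence["n_flow_peaks"] = n_peaks

    mean_ti = _mean_ti(cycles, i, params.ti_run_mean_n, cycle.ti)

    # --- DT: stacked inspirations --------------------------------------
    # Two flow humps within one machine inspiration mark ramp-prolongation
    # stacking only if the inter-hump valley falls while airway pressure
    # is still rising: an effort landing on an established pressure
    # plateau produces a second hump too, but no stacked delivery.
    dt_flag = False
    if cycle.machine_cycle and n_peaks >= 2 and valley_idx is not None:
        fs = record.fs
        a = int(round(cycle.t_insp_start * fs))
        b = int(round(cycle.t_insp_end * fs))
        plateau = float(np.max(record.paw[a:b]))
        paw_valley = float(record.paw[valley_idx])
        dt_flag = paw_valley < peep_est + 0.9 * (plateau - peep_est)
    if dt_flag:
        evidence["stacking"] = "within_inspiration"
    else:
        for j in (i - 1, i):  # stacking across the cycle boundary
            if 0 <= j < len(cycles) - 1:
                prev, nxt = cycles[j], cycles[j + 1]
                if not (prev.machine_cycle and nxt.machine_cycle):
                    continue
                interval = nxt.t_insp_start - prev.t_insp_end
                exp_frac = prev.vt_exp / max(prev.vt_insp, 1e-9)
                if (
                    interval < params.dt_interval_frac * mean_ti
                    and exp_frac < params.dt_exp_frac
                    and cycle.index in (prev.index, nxt.index)
                ):
                    dt_flag = True
                    evidence["stacking"] = "across_cycles"
                    evidence["inter_inspiration_interval"] = interval
                    evidence["expired_volume_fraction"] = exp_frac
                    break
    if dt_flag:
        label = "DT"

    # --- IE: unrewarded effort inside this cycle's span -----------------
    span_end = cycle.t_exp_end if i == len(cycles) - 1 else cycles[i + 1].t_insp_start
    unrewarded = [
        e
        for e in efforts
        if not e.rewarded and cycle.t_insp_start <= e.onset < span_end
    ]
    if i == 0:
        unrewarded += [e for e in efforts if not e.rewarded and e.onset < cycle.t_insp_start]
    if unrewarded and label == "NORMAL":
        label = "IE"
    if unrewarded:
        evidence["effort_dip_magnitude"] = max(e.magnitude for e in unrewarded)
        evidence["n_unrewarded_efforts"] = len(unrewarded)

    # --- AT: machine inspiration without a nearby effort dip ------------
    if cycle.machine_cycle:
        lo = cycle.t_insp_start - params.at_pre
        hi = cycle.t_insp_start + params.at_post
        pre_dip = any(e.onset <= hi and e.end >= lo for e in efforts)
        evidence["pre_inspiration_dip"] = pre_dip
        if not pre_dip and label == "NORMAL":
            # a mandatory breath resuming ventilation right after a hold
            # manoeuvre (zero flow with Paw pulled off PEEP in the
            # preceding gap) is not auto-triggering
            prev_end = cycles[i - 1].t_insp_end if i > 0 else 0.0
            if _occlusion_in_gap(record, prev_end, cycle.t_insp_start, peep_est, params):
                evidence["post_hold"] = True
            else:
                label = "AT"
    elif label == "NORMAL":
        label = "OTHER"  # effort-only excursion with a rewarded dip

    return CycleAnnotation(
        cycle_index=i,
        label=label,
        t_insp_start=cycle.t_insp_start,
        t_insp_end=cycle.t_insp_end,
        t_exp_end=cycle.t_exp_end,
        evidence=evidence,
    )


def _mark_rewarded(efforts: list[EffortEvent], cycles: list[RespiratoryCycle],
                   params: ClassifierParams) -> None:
    """An effort is rewarded when an inspiration starts near it, or when it
    begins during an ongoing inspiration (it rides the insufflation)."""
    starts = np.array([c.t_insp_start for c in cycles])
    ends = np.array([c.t_insp_end for c in cycles])
    for e in efforts:
        lo, hi = e.onset - params.reward_pre, e.end + params.reward_post
        near_start = bool(np.any((starts >= lo) & (starts <= hi)))
        inside = bool(np.any((starts <= e.onset) & (e.onset <= ends)))
        e.rewarded = near_start or inside


def classify_record(
    record: WaveformRecord,
    params: ClassifierParams = ClassifierParams(),
) -> tuple[pd.DataFrame, AsynchronyReport]:
    """Segment, detect efforts and label every cycle of a record.

    Returns the annotation table and the asynchrony report.
    """
    if record.peso is None:
        raise ValueError("classification requires the peso channel")
    cycles = segment_cycles(record, params=params)
    efforts = detect_efforts(record.peso, record.fs, params)
    _mark_rewarded(efforts, cycles, params)
    annotations = [
        classify_cycle(c, cycles, efforts, record, params) for c in cycles
    ]
    rows = []
    for ann in annotations:
        row = {
            "cycle_index": ann.cycle_index,
            "t_insp_start": ann.t_insp_start,
            "t_insp_end": ann.t_insp_end,
            "t_exp_end": ann.t_exp_end,
            "label": ann.label,
        }
        row.update(ann.evidence)
        rows.append(row)
    table = pd.DataFrame(rows)
    report = compute_aix(annotations)
    return table, report


def compute_aix(annotations) -> AsynchronyReport:
    """Asynchrony index: asynchronous cycles / all cycles, with per-type
    incidences.  Accepts CycleAnnotation lists or an annotation table."""
    if isinstance(annotations, pd.DataFrame):
        labels = list(annotations["label"])
    else:
        labels = [a.label for a in annotations]
    if not labels:
        raise ValueError("no annotated cycles")
    n = len(labels)
    counts = {lab: labels.count(lab) for lab in LABELS}
    async_n = counts["IE"] + counts["AT"] + counts["DT"]
    incidence = {lab: counts[lab] / n for lab in ("IE", "AT", "DT")}
    return AsynchronyReport(
        n_cycles=n, counts=counts, aix=async_n / n, incidence=incidence
    )


def summarize_group(values, group_keys=None) -> pd.DataFrame:
    """Median and [Q1-Q3] per group (linear-interpolation quartiles).

    ``values``: sequence of numbers, or mapping/frame with ``group_keys``.
    """
    if group_keys is None:
        frame = pd.DataFrame({"value": list(values)})
        frame["group"] = "all"
        keys = ["group"]
    else:
        frame = pd.DataFrame(values)
        keys = list(group_keys)
    out = (
        frame.groupby(keys)["value"]
        .agg(
            median="median",
            q1=lambda v: float(np.percentile(v, 25)),
            q3=lambda v: float(np.percentile(v, 75)),
            n="count",
        )
        .reset_index()
    )
    return out
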