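"""Built-in scenario catalogue and fixture generation.

Each scenario bundles subject parameters, ventilator settings and an
induction schedule reproducing one of the bench or pilot set-ups, or one
arm of the longitudinal study:

* ``bench_*`` — active-lung-simulator tests at PEEP 0 / Pinsp 5, RR 30
  (the failed Pinsp-to-zero attempt, the one-second expiratory hold, and
  the RR-x1.5 auto-trigger with 0.7 s inspiratory time);
* ``pilot_*`` — pig pilots: hold-duration titration at PEEP 10 /
  Pinsp 23 / RR 30, IE dose-response at PEEP 10 / Pinsp 20 / RR 40 in
  BIPAP and IPPV, and ramp-prolongation double-triggering at PEEP 5 /
  Pinsp 20 / RR 20;
* ``study_asy`` / ``study_syn`` — the longitudinal arms: pressure
  assist-control, PEEP 10, I:E 1:1, RR 30, flow trigger 3 L/min, with
  5%-per-type induction (DT as three-cycle clusters) or none.

The subject's intrinsic rate is set slightly above the ventilator rate so
that, absent modifications, every cycle is subject-triggered — the
synchronous baseline on which the induced events stand out.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .induction import (
    InductionSchedule,
    SimulationResult,
    build_schedule,
    run_experiment,
)
from .record import write_waveforms
from .subject import SubjectParams
from .ventilator import Mode, VentSettings

__all__ = ["ScenarioSpec", "make_scenario", "scenario_names", "run_scenario", "generate_fixture"]

# intrinsic effort rate / set rate: the subject leads the ventilator and
# re-entrains within a couple of breaths after a timing perturbation
NEURAL_RR_FACTOR = 1.1


def _subject(rr_set: float, **kwargs) -> SubjectParams:
    defaults = dict(neural_RR=rr_set * NEURAL_RR_FACTOR)
    defaults.update(kwargs)
    return SubjectParams(**defaults)


@dataclass
class ScenarioSpec:
    name: str
    subject_params: SubjectParams
    vent_settings: VentSettings
    duration: float = 600.0
    seed: int = 1
    fraction_per_type: float = 0.0
    types: tuple[str, ...] = ()
    ie_kwargs: dict = field(default_factory=dict)
    at_kwargs: dict = field(default_factory=dict)
    dt_kwargs: dict = field(default_factory=dict)
    expected: str = ""

    @property
    def expected_cycle_rate(self) -> float:
        """Breaths per minute of the closed loop: the subject leads the
        ventilator whenever its intrinsic rate is higher."""
        return max(self.vent_settings.rr_set, self.subject_params.effective_rr)

    def schedule(self, n_cycles: int | None = None, seed: int | None = None) -> InductionSchedule | None:
        if not self.types or self.fraction_per_type == 0:
            return None
        n = n_cycles or int(round(self.duration * self.expected_cycle_rate / 60.0))
        n = max(n, 20)
        return build_schedule(
            n,
            fraction_per_type=self.fraction_per_type,
            seed=self.seed if seed is None else seed,
            settings=self.vent_settings,
            ie_kwargs=self.ie_kwargs,
            at_kwargs=self.at_kwargs,
            dt_kwargs=self.dt_kwargs,
            types=self.types,
        )


def _catalogue() -> dict[str, ScenarioSpec]:
    bench_vent = VentSettings(mode=Mode.BIPAP, peep=0.0, pinsp=5.0, rr_set=30.0,
                              ie_ratio=1.0)
    # active lung simulator + spontaneous breathing module: short, fixed
    # programmed strokes, no cardiac artifact, no timing jitter
    bench_subject = _subject(30.0, rr_jitter_sd=0.0, neural_Ti=0.35,
                             effort_amplitude_Pmax=5.0,
                             cardiac_artifact_amp=0.0, peso_baseline=0.0)
    # pilot holds were operator-released: ventilation resumes immediately
    pilot2_vent = VentSettings(mode=Mode.BIPAP, peep=10.0, pinsp=23.0, rr_set=30.0,
                               hold_rearm=0.0)
    # The hold-titration pilot ran before the drive was titrated down to
    # P0.1 ~ 2.5 cmH2O: long, strong efforts, still pulling when a hold of
    # one inspiratory time ends (hence the post-hold triggered breath), and
    # a brisker intrinsic rate that re-entrains the loop quickly.
    hold_pilot_subject = _subject(
        30.0, neural_Ti=0.55, effort_amplitude_Pmax=12.0, neural_RR=36.0
    )
    pilot3_bipap = VentSettings(mode=Mode.BIPAP, peep=10.0, pinsp=20.0, rr_set=40.0)
    pilot3_ippv = VentSettings(mode=Mode.IPPV, peep=10.0, vt_target=0.350,
                               insp_flow=35.0, rr_set=40.0)
    dt_vent = VentSettings(mode=Mode.BIPAP, peep=5.0, pinsp=20.0, rr_set=20.0,
                           tinsp=2.0, ramp_time=0.2)
    study_vent = VentSettings(mode=Mode.PC_AC, peep=10.0, pinsp=20.0, rr_set=30.0,
                              trigger_flow=3.0, ramp_time=0.2)

    cat = {
        "bench_ie_pinsp_zero": ScenarioSpec(
            "bench_ie_pinsp_zero", bench_subject, bench_vent,
            expected="setting Pinsp to PEEP does NOT suppress the flow cycle "
                     "(pressure compensation); no IE results",
        ),
        "bench_ie_hold": ScenarioSpec(
            "bench_ie_hold", bench_subject, bench_vent,
            fraction_per_type=0.05, types=("IE",),
            ie_kwargs={"hold_duration": 1.0},
            expected="one-second expiratory holds: zero flow with a pressure "
                     "drop below baseline during the hold",
        ),
        "bench_at_rr": ScenarioSpec(
            "bench_at_rr", bench_subject, bench_vent,
            fraction_per_type=0.05, types=("AT",),
            at_kwargs={"tinsp_override": 0.7},
            expected="RR raised to 45/min for one cycle (Ti 0.7 s): mandatory "
                     "cycle without a preceding pressure dip",
        ),
        "pilot_hold_short": ScenarioSpec(
            "pilot_hold_short", hold_pilot_subject, pilot2_vent,
            fraction_per_type=0.05, types=("IE",),
            ie_kwargs={"k_hold": 1.0},
            expected="sub-threshold hold: ventilator delivers right after the "
                     "hold while the subject inhales (triggered breath, no IE)",
        ),
        "pilot_hold_long": ScenarioSpec(
            "pilot_hold_long", hold_pilot_subject, pilot2_vent,
            fraction_per_type=0.05, types=("IE",),
            ie_kwargs={"k_hold": 1.5},
            expected="hold of 1.5x inspiratory time: effort spent against "
                     "closed valves, IE",
        ),
        "pilot_dt_ramp": ScenarioSpec(
            "pilot_dt_ramp", _subject(20.0), dt_vent,
            fraction_per_type=0.05, types=("DT",),
            dt_kwargs={"ramp_override": 1.5},
            expected="ramp 1.5 s yields two flow peaks per inspiration; "
                     "ramp 0.2 s yields one",
        ),
        "pilot_ie_bipap": ScenarioSpec(
            "pilot_ie_bipap", _subject(40.0), pilot3_bipap,
            fraction_per_type=0.065, types=("IE",),
            expected="IE induction above 5% of cycles in BIPAP",
        ),
        "pilot_ie_ippv": ScenarioSpec(
            "pilot_ie_ippv", _subject(40.0), pilot3_ippv,
            fraction_per_type=0.065, types=("IE",),
            expected="IE induction above 5% of cycles in IPPV",
        ),
        "study_asy": ScenarioSpec(
            "study_asy", _subject(30.0), study_vent,
            fraction_per_type=0.05, types=("IE", "AT", "DT"),
            expected="5% per type, DT in three-cycle clusters: gross AIX near 25%",
        ),
        "study_syn": ScenarioSpec(
            "study_syn", _subject(30.0), study_vent,
            expected="no induced events: AIX 0",
        ),
    }
    for frac in (10, 20, 30):
        cat[f"pilot_dose_ie_{frac}"] = ScenarioSpec(
            f"pilot_dose_ie_{frac}", _subject(40.0), pilot3_bipap,
            fraction_per_type=frac / 100.0, types=("IE",),
            expected=f"pre-set IE incidence {frac}% recovered by the classifier",
        )
    return cat


def scenario_names() -> list[str]:
    return sorted(_catalogue())


def make_scenario(name: str) -> ScenarioSpec:
    """Look up a fully parameterized scenario by name."""
    cat = _catalogue()
    if name not in cat:
        raise KeyError(
            f"unknown scenario {name!r}; available: {', '.join(sorted(cat))}"
        )
    return cat[name]


def run_scenario(
    spec: ScenarioSpec,
    duration: float | None = None,
    seed: int | None = None,
    fs: float = 100.0,
) -> SimulationResult:
    duration = duration or spec.duration
    seed = spec.seed if seed is None else seed
    n_cycles = int(round(duration * spec.expected_cycle_rate / 60.0))
    schedule = spec.schedule(n_cycles=n_cycles, seed=seed)
    return run_experiment(
        spec.subject_params, spec.vent_settings, schedule, duration, seed=seed, fs=fs
    )


def generate_fixture(spec: ScenarioSpec, out_dir, duration: float | None = None,
                     seed: int | None = None, fs: float = 100.0) -> dict:
    """Run a scenario and write waveforms, ground truth and a run log."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result = run_scenario(spec, duration=duration, seed=seed, fs=fs)
    paths = {
        "waveforms": out_dir / f"{spec.name}_waveforms.csv",
        "truth_cycles": out_dir / f"{spec.name}_truth_cycles.csv",
        "truth_events": out_dir / f"{spec.name}_truth_events.csv",
        "log": out_dir / f"{spec.name}_run.json",
    }
    write_waveforms(result.record, paths["waveforms"])
    result.cycles.to_csv(paths["truth_cycles"], index=False)
    result.events.to_csv(paths["truth_events"], index=False)
    log = {
        "scenario": spec.name,
        "seed": spec.seed if seed is None else seed,
        "duration": duration or spec.duration,
        "fs": fs,
        "settings": result.record.meta,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    paths["log"].write_text(json.dumps(log, indent=2) + "\n", encoding="utf-8")
    return {k: str(v) for k, v in paths.items()}
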