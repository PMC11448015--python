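"""Virtual spontaneously breathing subject.

Stands in for the injured, lightly sedated animal (or an active lung
simulator with a spontaneous-breathing module): passive single-compartment
respiratory mechanics driven by the airway pressure the ventilator applies,
plus a stochastic inspiratory-effort generator producing the muscle
pressure waveform Pmus.

Model
-----
The passive side is the standard single-compartment equation of motion,

    Paw = PEEP + V/C + R * V'  - Pmus,

solved for flow,

    V' = (Paw - PEEP - V/C + Pmus) / R,

with volume V measured above the end-expiratory equilibrium at PEEP,
inspiratory flow positive, and Pmus >= 0 acting to *lower* alveolar (and
hence pleural/oesophageal) pressure.  Integration is explicit fixed-step at
the sampling interval.

The effort generator is an open-loop renewal process: inter-effort
intervals are Gaussian around 60 / (neural_RR * sedation_factor) with an
absolute floor of 0.5 s.  Each effort is a half-sine rise to the
sedation-scaled peak over the neural inspiratory time, followed by an
exponential relaxation with time constant neural_Ti / 2; support is
truncated at 3 * neural_Ti.  There is no chemoreflex feedback: effort
timing does not react to delivered volume or gas exchange.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SubjectParams",
    "SubjectState",
    "pmus_profile",
    "step_mechanics",
    "peso_signal",
    "effort_onset_times",
    "pmus_waveform",
]


@dataclass(frozen=True)
class SubjectParams:
    """Mechanics and effort-generator parameters of the virtual subject.

    Units: pressures cmH2O, volumes L, flows L/s, times s, rates min^-1.
    Defaults approximate a 40-58 kg pig after experimental lung injury
    ventilated at ~6 mL/kg.
    """

    resistance_R: float = 10.0       # airway resistance, cmH2O*s/L
    compliance_C: float = 0.030      # respiratory-system compliance, L/cmH2O
    chestwall_E: float = 5.0         # chest-wall elastance share, cmH2O/L
    effort_amplitude_Pmax: float = 6.5  # peak muscle pressure, cmH2O
                                        # (with neural_Ti 0.4 s this yields an
                                        # occlusion pressure P0.1 of ~2.5 cmH2O,
                                        # the drive level the protocol titrates to)
    neural_Ti: float = 0.4           # neural inspiratory time, s
    neural_RR: float = 32.0          # intrinsic effort rate, min^-1
    rr_jitter_sd: float = 0.1        # sd of inter-effort interval, s
    sedation_factor: float = 1.0     # in (0, 1]; scales Pmax and neural_RR
    peso_baseline: float = 5.0       # oesophageal pressure offset, cmH2O
    cardiac_artifact_amp: float = 0.5   # cardiogenic oscillation on Peso, cmH2O
    f_cardiac: float = 1.5           # cardiac oscillation frequency, Hz
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resistance_R <= 0:
            raise ValueError("resistance_R must be > 0")
        if self.compliance_C <= 0:
            raise ValueError("compliance_C must be > 0")
        if not (0 < self.sedation_factor <= 1):
            raise ValueError("sedation_factor must be in (0, 1]")
        if self.effort_amplitude_Pmax < 0:
            raise ValueError("effort_amplitude_Pmax must be >= 0")
        if self.rr_jitter_sd < 0:
            raise ValueError("rr_jitter_sd must be >= 0")
        if self.neural_RR > 0 and self.neural_Ti >= 60.0 / self.neural_RR:
            raise ValueError("neural_Ti must be shorter than the effort period")

    @property
    def effective_pmax(self) -> float:
        return self.effort_amplitude_Pmax * self.sedation_factor

    @property
    def effective_rr(self) -> float:
        return self.neural_RR * self.sedation_factor

    def with_(self, **kwargs) -> "SubjectParams":
        return replace(self, **kwargs)


@dataclass
class SubjectState:
    """Instantaneous state of the virtual subject."""

    lung_volume_V: float = 0.0   # volume above FRC at PEEP, L
    flow: float = 0.0            # airway flow, L/s, inspiratory positive
    pmus: float = 0.0            # current muscle pressure, cmH2O
    next_effort_onsets: list = field(default_factory=list)


def pmus_profile(t_rel, params: SubjectParams):
    """Muscle pressure at ``t_rel`` seconds after effort onset.

    Half-sine rise to the sedation-scaled peak over ``neural_Ti``, then
    exponential relaxation with time constant ``neural_Ti / 2``; zero
    beyond three neural inspiratory times.  Accepts scalars or arrays.
    """
    t = np.asarray(t_rel, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_rel must be >= 0")
    ti = params.neural_Ti
    peak = params.effective_pmax
    if peak == 0 or ti <= 0:
        out = np.zeros_like(t)
        return out if out.ndim else float(out)
    rise = peak * np.sin(0.5 * np.pi * np.minimum(t, ti) / ti)
    relax = peak * np.exp(-(t - ti) / (0.5 * ti))
    out = np.where(t <= ti, rise, relax)
    out = np.where(t >= 3.0 * ti, 0.0, out)
    return out if out.ndim else float(out)


def step_mechanics(
    state: SubjectState,
    paw: float,
    peep_ref: float,
    dt: float,
    params: SubjectParams,
    occluded: bool = False,
    forced_flow: float | None = None,
) -> SubjectState:
    """Advance the single-compartment mechanics by one step.

    ``occluded`` models closed ventilator valves (hold manoeuvre, plateau
    pause): flow is forced to zero and volume frozen.  ``forced_flow``
    models volume-controlled delivery: the given flow is imposed
    regardless of the pressure balance.
    """
    if not (dt > 0 and dt <= 0.02):
        raise ValueError("dt must be in (0, 0.02] s")
    if not np.isfinite([paw, peep_ref, state.lung_volume_V, state.pmus]).all():
        raise FloatingPointError("non-finite input to step_mechanics")
    if occluded:
        state.flow = 0.0
        return state
    if forced_flow is not None:
        state.flow = forced_flow
    else:
        recoil = state.lung_volume_V / params.compliance_C
        state.flow = (paw - peep_ref - recoil + state.pmus) / params.resistance_R
    state.lung_volume_V += state.flow * dt
    return state


def alveolar_pressure(state: SubjectState, peep_ref: float, params: SubjectParams) -> float:
    """Static alveolar pressure: recoil above PEEP minus muscle pressure.

    During an occlusion the airway pressure equals this value, so Paw
    drops by exactly Pmus relative to its pre-hold static level.
    """
    return peep_ref + state.lung_volume_V / params.compliance_C - state.pmus


def peso_signal(state: SubjectState, params: SubjectParams, t) -> float:
    """Oesophageal pressure: baseline + chest-wall recoil - Pmus + cardiac artifact."""
    return (
        params.peso_baseline
        + params.chestwall_E * state.lung_volume_V
        - state.pmus
        + params.cardiac_artifact_amp * np.sin(2.0 * np.pi * params.f_cardiac * np.asarray(t))
    )


def effort_onset_times(params: SubjectParams, duration: float, seed: int | None = None):
    """Effort onset times over ``[0, duration)``.

    Renewal process: first onset at t = 0, subsequent intervals Gaussian
    with mean 60 / (neural_RR * sedation_factor) and sd ``rr_jitter_sd``,
    truncated below at 0.5 s.  Deterministic under a fixed seed.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if params.effective_rr <= 0:
        return np.empty(0)
    rng = np.random.default_rng(params.seed if seed is None else seed)
    mean = 60.0 / params.effective_rr
    onsets = []
    t = 0.0
    while t < duration:
        onsets.append(t)
        step = mean if params.rr_jitter_sd == 0 else rng.normal(mean, params.rr_jitter_sd)
        t += max(0.5, step)
    return np.asarray(onsets)


def pmus_waveform(onsets, n_samples: int, fs: float, params: SubjectParams) -> np.ndarray:
    """Sampled Pmus trace from a list of effort onsets (contributions sum)."""
    pmus = np.zeros(n_samples)
    support = 3.0 * params.neural_Ti
    for onset in np.asarray(onsets, dtype=float):
        i0 = max(0, int(np.ceil(onset * fs)))
        i1 = min(n_samples, int(np.floor((onset + support) * fs)) + 1)
        if i0 >= i1:
            continue
        t_rel = np.arange(i0, i1) / fs - onset
        pmus[i0:i1] += pmus_profile(t_rel, params)
    return pmus
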