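"""Horse-race synthetic data generator with embedded ground truth.

Behaviour.  Go finishing times are ex-Gaussian (the standard RT model:
Gaussian mu/sigma plus an exponential tail tau), shifted additively by
flanker congruency and, optionally, by proactive slowing in
stop-expectation contexts.  On stop trials an independent stop process of
duration ``stop_latency_ms`` starts at the SSD and races the go process
(context independence holds by construction).  Writing g for the go
finishing (press) time, o = g - emg_onset_to_press_ms for the EMG onset
and s = ssd + stop_latency_ms for the stop finish:

* s <= o       -> NO_EMG successful stop (no muscle response initiated)
* o <  s <  g  -> PARTIAL: the burst is initiated then cancelled; its
                  envelope peaks at ssd + cancel_peak_latency_ms
* s >= g       -> FULL_PRESS failed stop (ties go to the press)

EMG traces.  The cued hand carries an amplitude-modulated broadband
carrier (envelope x white noise) on top of baseline noise; the non-cued
hand is baseline noise only.  Go bursts rise over ``burst_rise_ms`` from
onset o, hold until the press, and decay with time constant
``burst_fall_ms``.  Partial bursts are symmetric bumps centred on the
cancellation time ssd + cancel_peak_latency_ms (width ``burst_rise_ms``),
so their envelope peak is well-defined under any zero-phase smoothing;
their amplitude is a random fraction of the full-burst amplitude.
Because the observed cancellation latency (~155 ms) is shorter than the
behavioural stop latency (~250 ms), partial bursts are anchored to the
cancellation time rather than to the never-occurring press.

fNIRS.  Each event contributes a double-gamma HRF scaled by a
condition-specific HbO2 amplitude (HbR = -amplitude/3); concentrations
are pushed through the same MBLL forward model (shared extinction table)
that the analysis inverts, then mixed with sinusoidal physiological
noise (cardiac ~1 Hz, respiratory ~0.3 Hz, Mayer waves ~0.1 Hz), white
noise and transient motion spikes before exponentiation to intensities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .design import (
    Condition,
    Congruency,
    Hand,
    SessionDesign,
    StaircaseState,
    TrialSpec,
    generate_session,
    make_staircases,
    staircase_update,
)
from .emg import EMG_FS_HZ, EMGTrace, Phenotype
from .fnirs import Channel, Domain, FnirsEvent, HaemoSeries, default_montage
from .hemodynamics import FNIRS_FS_HZ, WAVELENGTHS_NM, extinction_matrix, hrf_kernel

__all__ = [
    "RaceModelParams",
    "HaemoSimParams",
    "SimulatedSession",
    "simulate_trial",
    "simulate_session",
    "simulate_fnirs",
]


@dataclass
class RaceModelParams:
    """Generator parameters for behaviour and EMG.

    Young-adult defaults; the older group is emulated by slower, more
    variable go parameters (e.g. mu=360, sigma=50, tau=110).
    """

    go_mu_ms: float = 300.0
    go_sigma_ms: float = 40.0
    go_tau_ms: float = 80.0
    stop_latency_ms: float = 250.0
    cancel_peak_latency_ms: float = 155.0
    emg_onset_to_press_ms: float = 100.0
    burst_amp: float = 1.0
    burst_rise_ms: float = 20.0
    burst_fall_ms: float = 60.0
    noise_sd: float = 0.02
    fs_emg: float = EMG_FS_HZ
    proactive_slow_ms: float = 0.0
    flanker_effect_ms: Mapping[Congruency, float] = field(
        default_factory=lambda: {
            Congruency.NONE: 0.0,
            Congruency.NEUTRAL: 0.0,
            Congruency.CONGRUENT: -8.0,
            Congruency.INCONGRUENT: 57.0,
        }
    )
    partial_amp_range: tuple[float, float] = (0.3, 0.8)
    choice_error_rate: float = 0.02
    go_omission_rate: float = 0.01
    deadline_ms: float = 1500.0
    trace_t0_s: float = -0.5
    trace_duration_s: float = 2.0

    def __post_init__(self) -> None:
        for name in ("go_tau_ms", "stop_latency_ms", "cancel_peak_latency_ms",
                     "emg_onset_to_press_ms", "burst_rise_ms", "burst_fall_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.fs_emg <= 0:
            raise ValueError("fs_emg must be positive")


def _draw_go_finish(params: RaceModelParams, spec: TrialSpec, rng: np.random.Generator) -> float:
    """Ex-Gaussian go finishing time with congruency and proactive shifts."""
    g = rng.normal(params.go_mu_ms, params.go_sigma_ms) + rng.exponential(params.go_tau_ms)
    g += params.flanker_effect_ms.get(spec.congruency, 0.0)
    if spec.condition in (Condition.SST, Condition.SSFT):
        g += params.proactive_slow_ms
    return float(max(g, 1.0))


def _go_burst_envelope(t_ms: np.ndarray, onset_ms: float, press_ms: float,
                       params: RaceModelParams) -> np.ndarray:
    """Raised-cosine rise from onset, plateau to the press, exponential decay."""
    rise_end = onset_ms + params.burst_rise_ms
    env = np.zeros_like(t_ms)
    rising = (t_ms >= onset_ms) & (t_ms < rise_end)
    env[rising] = 0.5 * (1 - np.cos(np.pi * (t_ms[rising] - onset_ms) / params.burst_rise_ms))
    plateau = (t_ms >= rise_end) & (t_ms <= press_ms)
    env[plateau] = 1.0
    falling = t_ms > press_ms
    env[falling] = np.exp(-(t_ms[falling] - press_ms) / params.burst_fall_ms)
    # truncate the exponential tail at 5 time constants
    env[t_ms > press_ms + 5 * params.burst_fall_ms] = 0.0
    return params.burst_amp * env


def _partial_burst_envelope(t_ms: np.ndarray, peak_ms: float, amp: float,
                            params: RaceModelParams) -> np.ndarray:
    """Symmetric Gaussian bump centred on the cancellation time (sigma =
    burst_rise_ms, support +/- 3.5 sigma)."""
    sigma = params.burst_rise_ms
    env = amp * np.exp(-0.5 * ((t_ms - peak_ms) / sigma) ** 2)
    env[np.abs(t_ms - peak_ms) > 3.5 * sigma] = 0.0
    return env


def _make_trace(env: Optional[np.ndarray], params: RaceModelParams, side: Hand,
                trial_id: int, rng: np.random.Generator) -> EMGTrace:
    n = int(round(params.trace_duration_s * params.fs_emg))
    raw = params.noise_sd * rng.standard_normal(n)
    if env is not None:
        raw = raw + env * rng.standard_normal(n)
    return EMGTrace(samples=raw, fs=params.fs_emg, t0_s=params.trace_t0_s,
                    side=side, trial_id=trial_id)


def simulate_trial(
    params: RaceModelParams,
    spec: TrialSpec,
    ssd_ms: Optional[float],
    rng: np.random.Generator,
    make_traces: bool = True,
) -> tuple[dict, dict[Hand, EMGTrace], dict]:
    """Simulate one trial: behaviour record, per-hand EMG traces (empty dict
    when ``make_traces`` is False) and the ground-truth record."""
    if spec.is_stop and ssd_ms is None:
        raise ValueError("stop trials require an SSD")

    g = _draw_go_finish(params, spec, rng)
    omitted = rng.random() < params.go_omission_rate
    choice_correct = rng.random() >= params.choice_error_rate
    onset = g - params.emg_onset_to_press_ms
    partial_amp = float(rng.uniform(*params.partial_amp_range)) * params.burst_amp

    responded = False
    rt: float = math.nan
    phenotype = Phenotype.NO_EMG
    stop_wins = False
    cancel_peak_ms = math.nan

    if not spec.is_stop:
        if not omitted and g <= params.deadline_ms:
            responded = True
            rt = g
            phenotype = Phenotype.FULL_PRESS
    else:
        s = ssd_ms + params.stop_latency_ms
        if omitted or g > params.deadline_ms:
            stop_wins, phenotype = True, Phenotype.NO_EMG
        elif s <= onset:
            stop_wins, phenotype = True, Phenotype.NO_EMG
        elif s < g:
            stop_wins, phenotype = True, Phenotype.PARTIAL
            cancel_peak_ms = ssd_ms + params.cancel_peak_latency_ms
        else:
            responded = True
            rt = g
            phenotype = Phenotype.FULL_PRESS

    record = {
        "trial_index": spec.trial_index,
        "condition": spec.condition.value,
        "congruency": spec.congruency.value,
        "hand": spec.hand.value,
        "is_stop": spec.is_stop,
        "practice": spec.practice,
        "fixation_s": spec.fixation_s,
        "ssd_ms": ssd_ms if spec.is_stop else math.nan,
        "responded": responded,
        "rt_ms": rt,
        "correct_choice": bool(choice_correct) if responded else True,
        "stop_success": stop_wins if spec.is_stop else math.nan,
    }
    truth = {
        "trial_index": spec.trial_index,
        "true_go_rt_ms": math.nan if omitted else g,
        "true_stop_wins": stop_wins if spec.is_stop else False,
        "true_phenotype": phenotype.value,
        "true_cancel_peak_ms": cancel_peak_ms,
        "true_emg_onset_ms": math.nan if phenotype is Phenotype.NO_EMG else onset,
    }

    traces: dict[Hand, EMGTrace] = {}
    if make_traces:
        n = int(round(params.trace_duration_s * params.fs_emg))
        t_ms = (params.trace_t0_s + np.arange(n) / params.fs_emg) * 1000.0
        env: Optional[np.ndarray] = None
        if phenotype is Phenotype.FULL_PRESS:
            env = _go_burst_envelope(t_ms, onset, g, params)
        elif phenotype is Phenotype.PARTIAL:
            env = _partial_burst_envelope(t_ms, cancel_peak_ms, partial_amp, params)
        for hand in Hand:
            traces[hand] = _make_trace(env if hand is spec.hand else None, params,
                                       hand, spec.trial_index, rng)
    return record, traces, truth


@dataclass
class SimulatedSession:
    """Trial table, per-trial cued-hand traces and ground truth for one
    session, with the realised staircase states."""

    condition: Condition
    trials: pd.DataFrame
    traces: dict[int, dict[Hand, EMGTrace]]
    truth: pd.DataFrame
    staircases: dict[tuple[Hand, Congruency], StaircaseState]
    seed: Optional[int] = None


def simulate_session(
    params: RaceModelParams,
    design: SessionDesign,
    rng: np.random.Generator,
    make_traces: bool = True,
    traces_for: str = "all",
    initial_ssd_ms: float = 200.0,
) -> SimulatedSession:
    """Simulate every trial of a session design, applying the staircase
    controller on stop trials (practice included, so the staircase warms up
    exactly as in the task; analyses exclude practice downstream).

    ``traces_for``: "all", "stop" (stop trials only) or "none" -- trace
    synthesis dominates runtime, so behaviour-only studies can skip it.
    """
    staircases = make_staircases(design.condition, initial_ssd_ms=initial_ssd_ms)
    records, truths = [], []
    traces: dict[int, dict[Hand, EMGTrace]] = {}
    for spec in design.trials:
        ssd = None
        key = (spec.hand, spec.congruency)
        if spec.is_stop:
            ssd = staircases[key].ssd_ms
        want_traces = make_traces and (
            traces_for == "all" or (traces_for == "stop" and spec.is_stop)
        )
        record, tr, truth = simulate_trial(params, spec, ssd, rng, make_traces=want_traces)
        if spec.is_stop:
            staircases[key] = staircase_update(staircases[key], bool(record["stop_success"]))
        records.append(record)
        truths.append(truth)
        if tr:
            traces[spec.trial_index] = tr
    return SimulatedSession(
        condition=design.condition,
        trials=pd.DataFrame(records),
        traces=traces,
        truth=pd.DataFrame(truths),
        staircases=staircases,
        seed=design.seed,
    )


@dataclass
class HaemoSimParams:
    """Forward-model parameters for the continuous fNIRS simulation.

    ``amplitude_by_condition`` maps an event condition label to the peak
    HbO2 change in uM; HbR follows at ``hbr_ratio`` times the HbO2
    amplitude.  Physiological oscillation amplitudes are in OD units.
    """

    amplitude_by_condition: Mapping[str, float] = field(
        default_factory=lambda: {"GO": 0.3, "STOP_SUCCESS": 0.5, "STOP_FAIL": 0.2}
    )
    default_amplitude_umol: float = 0.3
    hbr_ratio: float = -1.0 / 3.0
    hrf_kwargs: dict = field(default_factory=dict)
    cardiac_hz: float = 1.0
    resp_hz: float = 0.3
    mayer_hz: float = 0.1
    cardiac_amp_od: float = 0.005
    resp_amp_od: float = 0.008
    mayer_amp_od: float = 0.010
    white_noise_od: float = 0.002
    motion_spike_rate_per_min: float = 0.0
    motion_spike_amp_od: float = 0.3
    motion_spike_tau_s: float = 0.25
    fs: float = FNIRS_FS_HZ
    baseline_intensity: float = 2.0
    dpf: Mapping[int, float] = field(default_factory=lambda: {760: 6.0, 850: 5.2})
    wavelengths: tuple[int, ...] = WAVELENGTHS_NM
    montage: Optional[list[Channel]] = None

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.baseline_intensity <= 0:
            raise ValueError("fs and baseline intensity must be positive")
        if self.montage is None:
            self.montage = default_montage()


def simulate_fnirs(
    params: HaemoSimParams,
    events: Sequence[FnirsEvent],
    duration_s: float,
    rng: np.random.Generator,
) -> tuple[HaemoSeries, dict]:
    """Forward-simulate a raw-intensity series with embedded ground truth.

    Intensity = baseline * exp(-OD(t)) where OD combines the MBLL forward
    model of the HRF-convolved concentration regressors with sinusoidal
    physiological noise (random phase per channel), white noise and
    exponentially decaying motion spikes.  Returns the INTENSITY-domain
    series and a truth dict (per-event amplitudes, spike times).
    """
    n_t = int(round(duration_s * params.fs))
    for ev in events:
        if not (0 <= ev.time_s < duration_s):
            raise ValueError(f"event at {ev.time_s} s outside the {duration_s} s recording")
    channels = list(params.montage)
    n_ch = len(channels)
    n_wl = len(params.wavelengths)

    # concentration regressors (uM), shared across channels
    impulse_o = np.zeros(n_t)
    amp_of = {}
    for ev in events:
        amp = params.amplitude_by_condition.get(ev.condition, params.default_amplitude_umol)
        amp_of[ev] = amp
        impulse_o[int(round(ev.time_s * params.fs))] += amp
    h = hrf_kernel(params.fs, **params.hrf_kwargs)
    hbo2 = np.convolve(impulse_o, h)[:n_t]
    hbr = params.hbr_ratio * hbo2

    E = extinction_matrix(params.wavelengths)
    dpf = np.array([params.dpf[int(w)] for w in params.wavelengths])

    od = np.zeros((n_ch, n_wl, n_t))
    t = np.arange(n_t) / params.fs
    spike_times: list[float] = []
    n_spikes = rng.poisson(params.motion_spike_rate_per_min * duration_s / 60.0)
    spike_onsets = np.sort(rng.uniform(0, duration_s, size=n_spikes))
    spike_wave = np.zeros(n_t)
    for t0 in spike_onsets:
        spike_times.append(float(t0))
        i0 = int(round(t0 * params.fs))
        tail = np.exp(-(t[i0:] - t[i0]) / params.motion_spike_tau_s)
        spike_wave[i0:] += params.motion_spike_amp_od * tail * np.sign(rng.standard_normal())

    for i, ch in enumerate(channels):
        path_cm = (ch.separation_mm / 10.0) * dpf
        od_hrf = (E @ np.vstack([hbo2, hbr])) * path_cm[:, None]
        phases = rng.uniform(0, 2 * np.pi, size=3)
        physio = (
            params.cardiac_amp_od * np.sin(2 * np.pi * params.cardiac_hz * t + phases[0])
            + params.resp_amp_od * np.sin(2 * np.pi * params.resp_hz * t + phases[1])
            + params.mayer_amp_od * np.sin(2 * np.pi * params.mayer_hz * t + phases[2])
        )
        for w in range(n_wl):
            noise = params.white_noise_od * rng.standard_normal(n_t) if params.white_noise_od else 0.0
            od[i, w] = od_hrf[w] + physio + noise + spike_wave

    intensity = params.baseline_intensity * np.exp(-od)
    series = HaemoSeries(
        channels=channels,
        data=intensity,
        fs=params.fs,
        wavelengths=params.wavelengths,
        events=list(events),
        domain=Domain.INTENSITY,
    )
    truth = {
        "amplitudes_umol": {f"{ev.condition}|{ev.outcome}|{ev.time_s}": a for ev, a in amp_of.items()},
        "hbr_ratio": params.hbr_ratio,
        "spike_times_s": spike_times,
        "hrf_kwargs": dict(params.hrf_kwargs),
    }
    return series, truth
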