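"""Surface-EMG processing: bursts, partial responses and Cancel Time.

The chain mirrors standard first-dorsal-interosseous (FDI) stop-signal
analyses: a zero-phase 4th-order Butterworth band-pass (20-500 Hz),
full-wave rectification and a 10 Hz low-pass to obtain the envelope, a
single-threshold burst detector (3 SD above the quietest within-trial
baseline, bursts separated by <20 ms merged), selection of the
RT-generating burst (last burst starting after the go cue and at least
50 ms before the press), and partial-EMG (prEMG) qualification on stop
trials.  Cancel Time is the interval from stop-signal onset (SSD) to the
peak of the prEMG envelope -- a trial-level physiological measure of how
fast the motor command was cancelled.

Time convention: milliseconds relative to go-signal onset (t = 0); the
stop signal occurs at t = SSD.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import signal

from .design import Hand
from .errors import ProcessingError

__all__ = [
    "EMGTrace",
    "EMGBurst",
    "PrEMGEvent",
    "Phenotype",
    "bandpass",
    "envelope",
    "detect_bursts",
    "select_rt_burst",
    "detect_prEMG",
    "cancel_time",
    "normalise_profiles",
    "mean_profile",
    "classify_stop_trial",
    "process_trace",
]

EMG_FS_HZ = 2000.0
BANDPASS_LO_HZ = 20.0
BANDPASS_HI_HZ = 500.0
BANDPASS_ORDER = 4
ENVELOPE_LP_HZ = 10.0
BURST_THRESHOLD_SD = 3.0
BURST_MERGE_MS = 20.0
BASELINE_WINDOW_MS = 100.0
RT_BURST_MIN_LEAD_MS = 50.0
PREMG_AMP_FRACTION = 0.10


class Phenotype(str, enum.Enum):
    """Trichotomy of stop-trial muscle outcomes."""

    FULL_PRESS = "FULL_PRESS"  # go process won; button pressed (failed stop)
    PARTIAL = "PARTIAL"        # burst initiated then cancelled before the press
    NO_EMG = "NO_EMG"          # stopped before any muscle activity


@dataclass
class EMGTrace:
    """A per-trial EMG signal for one hand.

    ``t0_s`` is the time of the first sample relative to go-signal onset.
    """

    samples: np.ndarray
    fs: float = EMG_FS_HZ
    t0_s: float = 0.0
    side: Hand = Hand.RIGHT
    trial_id: int = -1

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ProcessingError("sampling rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ProcessingError("EMG samples must be finite")

    @property
    def times_ms(self) -> np.ndarray:
        return (self.t0_s + np.arange(self.samples.size) / self.fs) * 1000.0


@dataclass(frozen=True)
class EMGBurst:
    """A supra-threshold envelope burst (times in ms relative to go onset)."""

    onset_ms: float
    offset_ms: float
    peak_ms: float
    peak_amp: float


@dataclass(frozen=True)
class PrEMGEvent:
    """A qualified partial EMG response on a successful stop trial."""

    burst: EMGBurst
    ssd_ms: float
    cancel_time_ms: float
    peak_amp_norm: float


def bandpass(
    trace: EMGTrace,
    lo: float = BANDPASS_LO_HZ,
    hi: float = BANDPASS_HI_HZ,
    order: int = BANDPASS_ORDER,
) -> EMGTrace:
    """Zero-phase Butterworth band-pass; forward-backward filtering keeps
    burst onsets and peaks free of group delay."""
    nyq = trace.fs / 2.0
    if not (0 < lo < hi < nyq):
        raise ValueError(f"band [{lo}, {hi}] Hz invalid for fs={trace.fs} Hz (Nyquist {nyq} Hz)")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=trace.fs, output="sos")
    return replace(trace, samples=signal.sosfiltfilt(sos, trace.samples))


def envelope(trace: EMGTrace, lp: float = ENVELOPE_LP_HZ, order: int = BANDPASS_ORDER) -> EMGTrace:
    """Full-wave rectify then zero-phase low-pass; negative filter ripple is
    clipped to zero so the envelope is non-negative."""
    if not (0 < lp < trace.fs / 2.0):
        raise ValueError(f"low-pass cutoff {lp} Hz invalid for fs={trace.fs} Hz")
    sos = signal.butter(order, lp, btype="lowpass", fs=trace.fs, output="sos")
    env = signal.sosfiltfilt(sos, np.abs(trace.samples))
    return replace(trace, samples=np.clip(env, 0.0, None))


def _baseline_stats(env: np.ndarray, fs: float, window_ms: float) -> tuple[float, float]:
    """Mean and SD of the quietest window: the sliding window (length
    ``window_ms``) with the minimal mean envelope amplitude."""
    w = max(1, int(round(window_ms * fs / 1000.0)))
    if env.size < w:
        raise ProcessingError(f"trial of {env.size} samples shorter than the {window_ms} ms baseline window")
    c = np.concatenate(([0.0], np.cumsum(env)))
    means = (c[w:] - c[:-w]) / w
    start = int(np.argmin(means))
    seg = env[start : start + w]
    return float(seg.mean()), float(seg.std())


def detect_bursts(
    env_trace: EMGTrace,
    k: float = BURST_THRESHOLD_SD,
    merge_ms: float = BURST_MERGE_MS,
    baseline_window_ms: float = BASELINE_WINDOW_MS,
) -> list[EMGBurst]:
    """Single-threshold burst detection on the envelope.

    The threshold is baseline mean + ``k`` x baseline SD, with the baseline
    taken from the quietest ``baseline_window_ms`` window of the trial.
    Supra-threshold runs separated by less than ``merge_ms`` are merged; the
    burst peak is the envelope argmax within [onset, offset] (earliest
    sample on ties).  Crossings are resolved at the sample level only.
    """
    env = env_trace.samples
    times = env_trace.times_ms
    mean, sd = _baseline_stats(env, env_trace.fs, baseline_window_ms)
    thr = mean + k * sd

    above = env > thr
    if not above.any():
        return []
    padded = np.concatenate(([False], above, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1  # inclusive

    # merge runs whose below-threshold gap is shorter than merge_ms
    gap_samples = merge_ms * env_trace.fs / 1000.0
    merged: list[list[int]] = [[int(starts[0]), int(ends[0])]]
    for s, e in zip(starts[1:], ends[1:]):
        if (s - merged[-1][1] - 1) < gap_samples:
            merged[-1][1] = int(e)
        else:
            merged.append([int(s), int(e)])

    bursts = []
    for s, e in merged:
        seg = env[s : e + 1]
        p = s + int(np.argmax(seg))
        bursts.append(
            EMGBurst(onset_ms=float(times[s]), offset_ms=float(times[e]),
                     peak_ms=float(times[p]), peak_amp=float(env[p]))
        )
    return bursts


def select_rt_burst(
    bursts: Sequence[EMGBurst],
    press_ms: float,
    go_ms: float = 0.0,
    min_lead_ms: float = RT_BURST_MIN_LEAD_MS,
) -> Optional[EMGBurst]:
    """The RT-generating burst: the last burst whose onset falls (i) after
    the go signal and (ii) at least ``min_lead_ms`` before the button press.
    Returns None when no burst qualifies."""
    qualifying = [b for b in bursts if b.onset_ms > go_ms and b.onset_ms <= press_ms - min_lead_ms]
    return qualifying[-1] if qualifying else None


def detect_prEMG(
    bursts: Sequence[EMGBurst],
    ssd_ms: float,
    press_occurred: bool,
    ref_peak: float,
    go_ms: float = 0.0,
    amp_fraction: float = PREMG_AMP_FRACTION,
) -> Optional[PrEMGEvent]:
    """Qualify a partial EMG response on a stop trial.

    A trial with a press is a failed stop, never prEMG.  Otherwise the
    latest burst satisfying (i) onset after the go signal, (ii) peak after
    the SSD, and (iii) peak amplitude above ``amp_fraction`` of the
    reference go-trial peak, becomes the prEMG event.
    """
    if ref_peak <= 0 or not np.isfinite(ref_peak):
        raise ValueError(f"invalid reference peak amplitude {ref_peak}")
    if press_occurred:
        return None
    qualifying = [
        b
        for b in bursts
        if b.onset_ms > go_ms and b.peak_ms > ssd_ms and b.peak_amp > amp_fraction * ref_peak
    ]
    if not qualifying:
        return None
    burst = qualifying[-1]
    return PrEMGEvent(
        burst=burst,
        ssd_ms=float(ssd_ms),
        cancel_time_ms=cancel_time(burst, ssd_ms),
        peak_amp_norm=burst.peak_amp / ref_peak,
    )


def cancel_time(ev_burst: EMGBurst, ssd_ms: float) -> float:
    """Time from stop-signal onset to the prEMG envelope peak (strictly positive)."""
    ct = ev_burst.peak_ms - ssd_ms
    if ct <= 0:
        raise ProcessingError(
            f"burst peak at {ev_burst.peak_ms} ms precedes the stop signal at {ssd_ms} ms"
        )
    return float(ct)


def classify_stop_trial(
    bursts: Sequence[EMGBurst],
    press_occurred: bool,
    ssd_ms: float,
    ref_peak: float,
    amp_fraction: float = PREMG_AMP_FRACTION,
) -> tuple[Phenotype, Optional[PrEMGEvent]]:
    """Phenotype a stop trial: press -> FULL_PRESS; qualified prEMG ->
    PARTIAL; otherwise NO_EMG."""
    if press_occurred:
        return Phenotype.FULL_PRESS, None
    ev = detect_prEMG(bursts, ssd_ms, press_occurred, ref_peak, amp_fraction=amp_fraction)
    if ev is not None:
        return Phenotype.PARTIAL, ev
    return Phenotype.NO_EMG, None


def process_trace(trace: EMGTrace) -> tuple[EMGTrace, list[EMGBurst]]:
    """Band-pass, envelope and burst-detect one raw trace."""
    env = envelope(bandpass(trace))
    return env, detect_bursts(env)


def normalise_profiles(
    envelopes: Sequence[EMGTrace],
    crt_reference_trials: Sequence[tuple[EMGTrace, float]],
) -> tuple[list[EMGTrace], float]:
    """Normalise envelopes to the participant's mean RT-burst peak amplitude
    over successful CRT go trials.

    ``crt_reference_trials`` supplies (envelope, press_ms) pairs from
    successful CRT go trials; the reference scalar is the mean peak of their
    RT-generating bursts.  Returns the rescaled envelopes and the scalar.
    """
    peaks = []
    for env, press_ms in crt_reference_trials:
        burst = select_rt_burst(detect_bursts(env), press_ms=press_ms)
        if burst is not None:
            peaks.append(burst.peak_amp)
    if not peaks:
        raise ProcessingError("no CRT reference trial yielded an RT-generating burst")
    ref = float(np.mean(peaks))
    return [replace(e, samples=e.samples / ref) for e in envelopes], ref


def reference_peak(trials, traces) -> float:
    """Participant reference amplitude: mean RT-generating-burst peak over
    successful (correct, responded, non-practice) go trials of a session --
    the CRT session by convention.

    ``trials`` is the simulated/recorded trial table; ``traces`` maps
    trial_index -> {hand: EMGTrace} (cued hand used).
    """
    peaks = []
    ok = trials[
        (~trials["is_stop"])
        & trials["responded"]
        & trials["correct_choice"]
        & (~trials["practice"])
    ]
    for row in ok.itertuples():
        tr = traces.get(row.trial_index)
        if tr is None:
            continue
        env, bursts = process_trace(tr[Hand(row.hand)])
        burst = select_rt_burst(bursts, press_ms=row.rt_ms)
        if burst is not None:
            peaks.append(burst.peak_amp)
    if not peaks:
        raise ProcessingError("no reference go trial yielded an RT-generating burst")
    return float(np.mean(peaks))


def process_session_emg(trials, traces, ref_peak: float, amp_fraction: float = PREMG_AMP_FRACTION):
    """Per-trial EMG results for one session.

    Stop trials are phenotyped (FULL_PRESS / PARTIAL / NO_EMG) with Cancel
    Time on prEMG trials; go trials carry their RT-generating burst.
    Returns a tidy DataFrame (one row per trial that has a cued-hand trace).
    """
    import pandas as pd

    rows = []
    for row in trials.itertuples():
        tr = traces.get(row.trial_index)
        if tr is None:
            continue
        env, bursts = process_trace(tr[Hand(row.hand)])
        out = {
            "trial_index": row.trial_index,
            "is_stop": row.is_stop,
            "phenotype": None,
            "cancel_time_ms": np.nan,
            "premg_peak_ms": np.nan,
            "premg_peak_amp_norm": np.nan,
            "rt_burst_onset_ms": np.nan,
            "rt_burst_peak_amp": np.nan,
        }
        if row.is_stop:
            phenotype, ev = classify_stop_trial(
                bursts, bool(row.responded), float(row.ssd_ms), ref_peak, amp_fraction
            )
            out["phenotype"] = phenotype.value
            if ev is not None:
                out["cancel_time_ms"] = ev.cancel_time_ms
                out["premg_peak_ms"] = ev.burst.peak_ms
                out["premg_peak_amp_norm"] = ev.peak_amp_norm
        elif row.responded:
            burst = select_rt_burst(bursts, press_ms=row.rt_ms)
            if burst is not None:
                out["rt_burst_onset_ms"] = burst.onset_ms
                out["rt_burst_peak_amp"] = burst.peak_amp
        rows.append(out)
    return pd.DataFrame(rows)


class ProfileAlignment(str, enum.Enum):
    STOP_SIGNAL = "STOP_SIGNAL"
    PEAK = "PEAK"


def mean_profile(
    envelopes: Sequence[EMGTrace],
    align_times_ms: Sequence[float],
    align: ProfileAlignment | str = ProfileAlignment.STOP_SIGNAL,
    grid_ms: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Mean +/- 95% CI envelope over trials on a common aligned time base.

    Each trial's time axis is shifted so that its ``align_times_ms`` entry
    (stop-signal onset, or the trial's envelope peak) sits at t = 0, then
    trials are interpolated onto a shared grid and averaged pointwise.

    Returns ``(grid_ms, mean, ci_lo, ci_hi)``.
    """
    ProfileAlignment(align)  # validate
    if len(envelopes) < 2:
        raise ProcessingError("mean profile requires at least two trials")
    if len(envelopes) != len(align_times_ms):
        raise ProcessingError("one alignment time per trial required")
    shifted = [e.times_ms - a for e, a in zip(envelopes, align_times_ms)]
    if grid_ms is None:
        lo = max(t[0] for t in shifted)
        hi = min(t[-1] for t in shifted)
        if hi <= lo:
            raise ProcessingError("aligned trials share no common time support")
        step = 1000.0 / envelopes[0].fs
        grid_ms = np.arange(lo, hi + step / 2, step)
    stack = np.vstack([np.interp(grid_ms, t, e.samples) for t, e in zip(shifted, envelopes)])
    mean = stack.mean(axis=0)
    sem = stack.std(axis=0, ddof=1) / np.sqrt(stack.shape[0])
    return grid_ms, mean, mean - 1.96 * sem, mean + 1.96 * sem
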