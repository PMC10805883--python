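"""Event-related prefrontal fNIRS processing.

A simplified continuous-wave chain in the style of Homer3 block averaging:
channel pruning on raw intensities, conversion to optical density (OD),
windowed motion-artifact detection with targeted PCA correction, 0.5 Hz
low-pass, modified Beer-Lambert law (MBLL) inversion to HbO2/HbR/HbT
concentration changes, hemisphere averaging, stimulus-locked 10 s epochs
baselined over 0-2 s, and the peak HbO2 change in the 4-7 s window as the
per-event measure of neural activity.

Default thresholds follow the printed processing parameters: Prune
(dRange [1, 3], SNRthresh 2, SDrange [0, 45] mm), motion (tMotion 0.5 s,
tMask 1 s, STDEVthresh 9, AMPthresh 100), PCA (nSV 0.97, max 5
iterations).  Exact bit-parity with Homer3 is not a goal; the contract is
the parameterised behaviour implemented here.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal
from scipy.ndimage import binary_dilation, maximum_filter1d, minimum_filter1d

from .errors import ConfigurationError, ProcessingError
from .hemodynamics import (
    DPF_DEFAULT,
    FNIRS_FS_HZ,
    WAVELENGTHS_NM,
    extinction_matrix,
    hrf_kernel,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Hemisphere",
    "Domain",
    "Channel",
    "FnirsEvent",
    "HaemoSeries",
    "HaemoEpoch",
    "default_montage",
    "prune_channels",
    "to_optical_density",
    "detect_motion",
    "pca_motion_correct",
    "lowpass_haemo",
    "od_to_concentration",
    "hemisphere_average",
    "epoch_and_average",
    "peak_hbo2",
    "expected_epoch_peak_gain",
    "process_fnirs",
    "write_snirf",
    "read_snirf",
]

SPECIES = ("HbO2", "HbR", "HbT")

EPOCH_WINDOW_S = (0.0, 10.0)
BASELINE_WINDOW_S = (0.0, 2.0)
PEAK_WINDOW_S = (4.0, 7.0)
LOWPASS_CUTOFF_HZ = 0.5
LOWPASS_ORDER = 3


class Hemisphere(str, enum.Enum):
    LEFT = "LEFT"
    RIGHT = "RIGHT"
    MIDLINE = "MIDLINE"


class Domain(str, enum.Enum):
    INTENSITY = "INTENSITY"
    OD = "OD"
    CONC = "CONC"


@dataclass(frozen=True)
class Channel:
    source: int
    detector: int
    separation_mm: float
    hemisphere: Hemisphere
    label: str


@dataclass(frozen=True)
class FnirsEvent:
    time_s: float
    condition: str
    outcome: str = ""


@dataclass
class HaemoSeries:
    """Multi-channel optical / haemoglobin time series.

    ``data`` has shape (n_channels, n_wavelengths, n_time) in the INTENSITY
    and OD domains and (n_channels, 3 species, n_time) in the CONC domain
    (HbO2, HbR, HbT in micromolar).
    """

    channels: list[Channel]
    data: np.ndarray
    fs: float = FNIRS_FS_HZ
    wavelengths: tuple[int, ...] = WAVELENGTHS_NM
    events: list[FnirsEvent] = field(default_factory=list)
    domain: Domain = Domain.INTENSITY

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.fs <= 0:
            raise ProcessingError("sampling rate must be positive")
        if self.data.ndim != 3 or self.data.shape[0] != len(self.channels):
            raise ProcessingError("data must be (channel, wavelength/species, time)")

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_times) / self.fs

    def _flat(self) -> np.ndarray:
        """(channel x wavelength, time) view for channel-wise operations."""
        return self.data.reshape(-1, self.n_times)


def default_montage(
    n_per_hemisphere: int = 10, n_midline: int = 2, separation_mm: float = 30.0
) -> list[Channel]:
    """A prefrontal montage: ``n_per_hemisphere`` channels over each lateral
    PFC plus midline channels (excluded from hemisphere averages)."""
    channels = []
    idx = 1
    for hemi, n in ((Hemisphere.LEFT, n_per_hemisphere), (Hemisphere.RIGHT, n_per_hemisphere),
                    (Hemisphere.MIDLINE, n_midline)):
        for i in range(n):
            channels.append(
                Channel(source=idx, detector=idx, separation_mm=separation_mm,
                        hemisphere=hemi, label=f"{hemi.value[0]}{i + 1}")
            )
            idx += 1
    return channels


# ---------------------------------------------------------------------------
# pruning and optical density
# ---------------------------------------------------------------------------

def prune_channels(
    series: HaemoSeries,
    d_range: tuple[float, float] = (1.0, 3.0),
    snr_thresh: float = 2.0,
    sd_range_mm: tuple[float, float] = (0.0, 45.0),
) -> tuple[HaemoSeries, list[tuple[str, str]]]:
    """Drop channels with out-of-range raw intensity, low SNR (mean/SD of
    raw intensity, either wavelength) or out-of-range source-detector
    separation.  Returns the pruned series and a (label, reason) list."""
    if series.domain is not Domain.INTENSITY:
        raise ProcessingError("prune_channels expects the INTENSITY domain")
    removed: list[tuple[str, str]] = []
    keep: list[int] = []
    for i, ch in enumerate(series.channels):
        mean = series.data[i].mean(axis=1)
        sd = series.data[i].std(axis=1)
        snr = np.divide(mean, sd, out=np.full_like(mean, np.inf), where=sd > 0)
        if not (d_range[0] <= mean.min() and mean.max() <= d_range[1]):
            removed.append((ch.label, f"mean intensity outside [{d_range[0]}, {d_range[1]}]"))
        elif snr.min() < snr_thresh:
            removed.append((ch.label, f"SNR {snr.min():.2f} below {snr_thresh}"))
        elif not (sd_range_mm[0] <= ch.separation_mm <= sd_range_mm[1]):
            removed.append((ch.label, f"separation {ch.separation_mm} mm outside range"))
        else:
            keep.append(i)
    if not keep:
        raise ProcessingError("channel pruning removed every channel")
    pruned = replace(series, channels=[series.channels[i] for i in keep], data=series.data[keep])
    return pruned, removed


def to_optical_density(series: HaemoSeries) -> HaemoSeries:
    """OD(t) = -ln(I(t) / temporal mean I), per channel and wavelength."""
    if series.domain is not Domain.INTENSITY:
        raise ProcessingError("to_optical_density expects the INTENSITY domain")
    if np.any(series.data <= 0):
        bad = np.argwhere((series.data <= 0).any(axis=2))
        ch = series.channels[bad[0][0]].label
        raise ProcessingError(f"non-positive intensity in channel {ch}")
    mean = series.data.mean(axis=2, keepdims=True)
    od = -np.log(series.data / mean)
    return replace(series, data=od, domain=Domain.OD)


# ---------------------------------------------------------------------------
# motion artifacts
# ---------------------------------------------------------------------------

def detect_motion(
    od: HaemoSeries,
    t_motion_s: float = 0.5,
    t_mask_s: float = 1.0,
    stdev_thresh: float = 9.0,
    amp_thresh: float = 100.0,
) -> np.ndarray:
    """Boolean time mask of motion artifacts.

    A sample is flagged when, within any ``t_motion_s`` window covering it
    on any channel, the OD excursion (max - min) exceeds either
    ``stdev_thresh`` times that channel's SD of the OD first difference, or
    ``amp_thresh`` OD units.  Flags are dilated by ``t_mask_s`` per side.
    """
    if od.domain is not Domain.OD:
        raise ProcessingError("detect_motion expects the OD domain")
    y = od._flat()
    w = max(1, int(round(t_motion_s * od.fs)))
    excursion = maximum_filter1d(y, w, axis=1) - minimum_filter1d(y, w, axis=1)
    sd_diff = np.diff(y, axis=1).std(axis=1, ddof=0) if y.shape[1] > 1 else np.zeros(y.shape[0])
    flagged = (excursion > stdev_thresh * sd_diff[:, None]) | (excursion > amp_thresh)
    mask = flagged.any(axis=0)
    if mask.any():
        half = int(round(t_mask_s * od.fs))
        mask = binary_dilation(mask, structure=np.ones(2 * half + 1, dtype=bool))
    return mask


def _stitch_offsets(y: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Offset-correct so segment boundaries stay continuous after flagged
    segments were modified: each flagged run is shifted to join the sample
    preceding it, and each following clean segment is shifted to join the
    corrected run.  Within-segment shapes are untouched."""
    out = y.copy()
    n = mask.size
    runs = _runs(mask)
    for a, b in runs:  # inclusive run [a, b]
        if a > 0:
            out[:, a : b + 1] += (out[:, a - 1] - out[:, a])[:, None]
        if b + 1 < n:
            out[:, b + 1 :] += (out[:, b] - out[:, b + 1])[:, None]
    return out


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


def pca_motion_correct(
    od: HaemoSeries,
    mask: Optional[np.ndarray] = None,
    n_sv: float = 0.97,
    max_iter: int = 5,
    **detect_kwargs,
) -> tuple[HaemoSeries, dict]:
    """Targeted PCA motion correction, iterated at most ``max_iter`` times.

    Per iteration the flagged samples of all channels are concatenated,
    principal components are extracted, and the smallest leading set whose
    cumulative explained variance reaches ``n_sv`` is removed from the
    flagged samples only; the series is then offset-corrected for
    continuity and motion is re-detected.  An empty mask is the identity.
    """
    y = od._flat().copy()
    report = {"iterations": 0, "flagged_per_iter": [], "warnings": []}
    current = detect_motion(od, **detect_kwargs) if mask is None else np.asarray(mask, dtype=bool)
    for _ in range(max_iter):
        if not current.any():
            break
        report["iterations"] += 1
        report["flagged_per_iter"].append(int(current.sum()))
        n_flagged = int(current.sum())
        if n_flagged < y.shape[0]:
            msg = f"flagged segment ({n_flagged} samples) smaller than channel count; PCA skipped"
            logger.warning(msg)
            report["warnings"].append(msg)
            break
        seg = y[:, current]
        mu = seg.mean(axis=1, keepdims=True)
        segc = seg - mu
        u, s, vt = np.linalg.svd(segc, full_matrices=False)
        var = s**2
        total = var.sum()
        if total == 0:
            break
        frac = np.cumsum(var) / total
        k = int(np.searchsorted(frac, n_sv) + 1)
        k = min(k, s.size)
        artifact = (u[:, :k] * s[:k]) @ vt[:k]
        y[:, current] = mu + (segc - artifact)
        y = _stitch_offsets(y, current)
        corrected = replace(od, data=y.reshape(od.data.shape))
        current = detect_motion(corrected, **detect_kwargs)
    out = replace(od, data=y.reshape(od.data.shape))
    report["residual_flagged"] = int(current.sum())
    return out, report


# ---------------------------------------------------------------------------
# filtering and MBLL
# ---------------------------------------------------------------------------

def lowpass_haemo(
    od: HaemoSeries, cutoff_hz: float = LOWPASS_CUTOFF_HZ, order: int = LOWPASS_ORDER
) -> HaemoSeries:
    """Zero-phase Butterworth low-pass attenuating cardiac/respiratory bands
    while preserving the slow haemodynamic response (and DC exactly)."""
    if not (0 < cutoff_hz < od.fs / 2):
        raise ValueError(f"cutoff {cutoff_hz} Hz invalid for fs={od.fs}")
    sos = signal.butter(order, cutoff_hz, btype="lowpass", fs=od.fs, output="sos")
    return replace(od, data=signal.sosfiltfilt(sos, od.data, axis=2))


def od_to_concentration(
    od: HaemoSeries,
    dpf: Optional[dict[int, float]] = None,
    extinction: Optional[np.ndarray] = None,
) -> HaemoSeries:
    """Modified Beer-Lambert inversion to concentration changes (uM).

    Per channel: dC = E^-1 (dOD / (L * DPF)) with L the source-detector
    separation in cm and E the 2x2 extinction matrix; HbT = HbO2 + HbR is
    appended as a third species.
    """
    if od.domain is not Domain.OD:
        raise ProcessingError("od_to_concentration expects the OD domain")
    dpf = dict(DPF_DEFAULT) if dpf is None else dpf
    E = extinction_matrix(od.wavelengths) if extinction is None else np.asarray(extinction, float)
    if E.shape != (2, 2) or abs(np.linalg.det(E)) < 1e-12:
        raise ConfigurationError("extinction matrix must be 2x2 and invertible")
    dpf_vec = np.array([dpf[int(w)] for w in od.wavelengths])
    out = np.empty((len(od.channels), 3, od.n_times))
    for i, ch in enumerate(od.channels):
        path_cm = (ch.separation_mm / 10.0) * dpf_vec  # per wavelength
        scaled = od.data[i] / path_cm[:, None]
        conc = np.linalg.solve(E, scaled)
        out[i, 0] = conc[0]
        out[i, 1] = conc[1]
        out[i, 2] = conc[0] + conc[1]
    return replace(od, data=out, domain=Domain.CONC)


def hemisphere_average(conc: HaemoSeries) -> tuple[HaemoSeries, list[str]]:
    """Unweighted mean over surviving non-midline channels per hemisphere.

    Returns a two-"channel" regional series (labels LEFT / RIGHT) and the
    list of hemispheres with no surviving channels (flagged missing).
    """
    if conc.domain is not Domain.CONC:
        raise ProcessingError("hemisphere_average expects the CONC domain")
    regions = []
    data = []
    missing = []
    for hemi in (Hemisphere.LEFT, Hemisphere.RIGHT):
        idx = [i for i, ch in enumerate(conc.channels) if ch.hemisphere is hemi]
        if not idx:
            missing.append(hemi.value)
            continue
        regions.append(Channel(source=-1, detector=-1, separation_mm=np.nan,
                               hemisphere=hemi, label=hemi.value))
        data.append(conc.data[idx].mean(axis=0))
    if not regions:
        raise ProcessingError("no lateral channels survive for hemisphere averaging")
    return replace(conc, channels=regions, data=np.stack(data)), missing


# ---------------------------------------------------------------------------
# epoching and peak extraction
# ---------------------------------------------------------------------------

@dataclass
class HaemoEpoch:
    """A stimulus-locked mean epoch for one channel/region and group.

    ``series`` is (species, time) over [0, 10] s from stimulus onset,
    zeroed to the mean of the 0-2 s baseline; CI bands are pointwise 95%.
    """

    series: np.ndarray
    fs: float
    n_trials: int
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    window_s: tuple[float, float] = EPOCH_WINDOW_S
    baseline_s: tuple[float, float] = BASELINE_WINDOW_S

    @property
    def times_s(self) -> np.ndarray:
        return self.window_s[0] + np.arange(self.series.shape[1]) / self.fs


def _extract_epochs(
    conc: HaemoSeries,
    events: Sequence[FnirsEvent],
    window_s: tuple[float, float],
    baseline_s: tuple[float, float],
) -> tuple[dict[FnirsEvent, np.ndarray], list[FnirsEvent]]:
    n_win = int(round((window_s[1] - window_s[0]) * conc.fs)) + 1
    epochs: dict[FnirsEvent, np.ndarray] = {}
    dropped: list[FnirsEvent] = []
    t = np.arange(n_win) / conc.fs + window_s[0]
    base_idx = (t >= baseline_s[0]) & (t <= baseline_s[1])
    for ev in events:
        i0 = int(round((ev.time_s + window_s[0]) * conc.fs))
        if i0 < 0 or i0 + n_win > conc.n_times:
            logger.warning("event at %.1f s too close to recording edge; dropped", ev.time_s)
            dropped.append(ev)
            continue
        seg = conc.data[:, :, i0 : i0 + n_win].copy()
        seg -= seg[:, :, base_idx].mean(axis=2, keepdims=True)
        epochs[ev] = seg
    return epochs, dropped


def epoch_and_average(
    conc: HaemoSeries,
    events: Optional[Sequence[FnirsEvent]] = None,
    window_s: tuple[float, float] = EPOCH_WINDOW_S,
    baseline_s: tuple[float, float] = BASELINE_WINDOW_S,
) -> tuple[dict[tuple[str, str, str], HaemoEpoch], list[FnirsEvent]]:
    """Group events by (condition, outcome), average their baseline-zeroed
    epochs per channel, and return ``{(condition, outcome, channel_label):
    HaemoEpoch}`` plus the events dropped at the recording edge."""
    events = list(conc.events) if events is None else list(events)
    if not events:
        raise ProcessingError("no events to epoch")
    epochs, dropped = _extract_epochs(conc, events, window_s, baseline_s)
    groups: dict[tuple[str, str], list[np.ndarray]] = {}
    for ev, seg in epochs.items():
        groups.setdefault((ev.condition, ev.outcome), []).append(seg)
    out: dict[tuple[str, str, str], HaemoEpoch] = {}
    for (cond, outcome), segs in groups.items():
        stack = np.stack(segs)  # (trial, channel, species, time)
        mean = stack.mean(axis=0)
        if stack.shape[0] > 1:
            sem = stack.std(axis=0, ddof=1) / np.sqrt(stack.shape[0])
        else:
            sem = np.zeros_like(mean)
        for i, ch in enumerate(conc.channels):
            out[(cond, outcome, ch.label)] = HaemoEpoch(
                series=mean[i],
                fs=conc.fs,
                n_trials=stack.shape[0],
                ci_lo=mean[i] - 1.96 * sem[i],
                ci_hi=mean[i] + 1.96 * sem[i],
                window_s=window_s,
                baseline_s=baseline_s,
            )
    return out, dropped


def peak_hbo2(
    epoch: HaemoEpoch, window_s: tuple[float, float] = PEAK_WINDOW_S
) -> tuple[float, float]:
    """Signed maximum HbO2 change and its time within the 4-7 s window
    (bounds inclusive)."""
    t = epoch.times_s
    sel = (t >= window_s[0]) & (t <= window_s[1])
    if not sel.any():
        raise ProcessingError(f"peak window {window_s} outside the epoch span [{t[0]}, {t[-1]}] s")
    hbo2 = epoch.series[0, sel]
    i = int(np.argmax(hbo2))
    return float(hbo2[i]), float(t[sel][i])


def expected_epoch_peak_gain(
    fs: float = FNIRS_FS_HZ,
    window_s: tuple[float, float] = EPOCH_WINDOW_S,
    baseline_s: tuple[float, float] = BASELINE_WINDOW_S,
    peak_window_s: tuple[float, float] = PEAK_WINDOW_S,
    **hrf_kwargs,
) -> tuple[float, float]:
    """Noiseless epoch peak produced by a unit-amplitude event: the HRF is
    sampled, baseline-zeroed and peak-picked exactly like a real epoch.
    Returns (gain, peak_time_s); recovered amplitude = measured peak / gain.
    """
    h = hrf_kernel(fs, **hrf_kwargs)
    n_win = int(round((window_s[1] - window_s[0]) * fs)) + 1
    seg = h[:n_win]
    t = np.arange(n_win) / fs + window_s[0]
    base = seg[(t >= baseline_s[0]) & (t <= baseline_s[1])].mean()
    seg = seg - base
    sel = (t >= peak_window_s[0]) & (t <= peak_window_s[1])
    i = int(np.argmax(seg[sel]))
    return float(seg[sel][i]), float(t[sel][i])


# ---------------------------------------------------------------------------
# full chain and I/O
# ---------------------------------------------------------------------------

def process_fnirs(
    series: HaemoSeries,
    d_range: tuple[float, float] = (1.0, 3.0),
    snr_thresh: float = 2.0,
    sd_range_mm: tuple[float, float] = (0.0, 45.0),
    t_motion_s: float = 0.5,
    t_mask_s: float = 1.0,
    stdev_thresh: float = 9.0,
    amp_thresh: float = 100.0,
    n_sv: float = 0.97,
    max_iter: int = 5,
    lowpass_cutoff_hz: float = LOWPASS_CUTOFF_HZ,
    dpf: Optional[dict[int, float]] = None,
) -> dict:
    """Run the full chain on a raw-intensity series and extract peak HbO2
    per (condition, outcome, hemisphere).  Returns all intermediates plus a
    tidy ``peaks`` DataFrame."""
    pruned, removed = prune_channels(series, d_range, snr_thresh, sd_range_mm)
    od = to_optical_density(pruned)
    mask = detect_motion(od, t_motion_s, t_mask_s, stdev_thresh, amp_thresh)
    od_corr, pca_report = pca_motion_correct(
        od, mask, n_sv=n_sv, max_iter=max_iter,
        t_motion_s=t_motion_s, t_mask_s=t_mask_s,
        stdev_thresh=stdev_thresh, amp_thresh=amp_thresh,
    )
    od_filt = lowpass_haemo(od_corr, lowpass_cutoff_hz)
    conc = od_to_concentration(od_filt, dpf=dpf)
    regional, missing = hemisphere_average(conc)
    epochs, dropped = epoch_and_average(regional)
    rows = []
    for (cond, outcome, label), ep in sorted(epochs.items()):
        value, t_peak = peak_hbo2(ep)
        rows.append(
            {"condition": cond, "outcome": outcome, "hemisphere": label,
             "peak_hbo2_umol": value, "peak_time_s": t_peak, "n_trials": ep.n_trials}
        )
    return {
        "pruned": pruned,
        "removed_channels": removed,
        "motion_mask": mask,
        "pca_report": pca_report,
        "conc": conc,
        "regional": regional,
        "missing_hemispheres": missing,
        "epochs": epochs,
        "dropped_events": dropped,
        "peaks": pd.DataFrame(rows),
    }


def write_snirf(series: HaemoSeries, path) -> None:
    """Write a minimal SNIRF-layout HDF5 file (continuous-wave intensity)."""
    import h5py

    if series.domain is not Domain.INTENSITY:
        raise ProcessingError("SNIRF export expects raw intensities")
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        d1 = nirs.create_group("data1")
        flat = series._flat().T  # time x measurement
        d1.create_dataset("dataTimeSeries", data=flat)
        d1.create_dataset("time", data=series.times_s)
        m = 1
        for ci, ch in enumerate(series.channels):
            for wi in range(len(series.wavelengths)):
                ml = d1.create_group(f"measurementList{m}")
                ml.create_dataset("sourceIndex", data=ch.source)
                ml.create_dataset("detectorIndex", data=ch.detector)
                ml.create_dataset("wavelengthIndex", data=wi + 1)
                ml.create_dataset("dataType", data=1)
                ml.create_dataset("sourceDetectorSeparation", data=ch.separation_mm)
                ml.create_dataset("hemisphere", data=ch.hemisphere.value)
                ml.create_dataset("channelLabel", data=ch.label)
                m += 1
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.array(series.wavelengths, dtype=float))
        for i, ev in enumerate(series.events, start=1):
            st = nirs.create_group(f"stim{i}")
            st.create_dataset("name", data=f"{ev.condition}|{ev.outcome}")
            st.create_dataset("data", data=np.array([[ev.time_s, 0.0, 1.0]]))


def read_snirf(path) -> HaemoSeries:
    """Read the minimal SNIRF layout written by :func:`write_snirf`."""
    import h5py

    with h5py.File(path, "r") as f:
        nirs = f["nirs"]
        d1 = nirs["data1"]
        flat = np.asarray(d1["dataTimeSeries"]).T
        times = np.asarray(d1["time"])
        fs = 1.0 / float(np.mean(np.diff(times)))
        wavelengths = tuple(int(w) for w in np.asarray(nirs["probe"]["wavelengths"]))
        n_wl = len(wavelengths)
        mls = sorted((k for k in d1 if k.startswith("measurementList")),
                     key=lambda k: int(k.replace("measurementList", "")))
        channels = []
        for k in mls[::n_wl]:
            ml = d1[k]
            channels.append(
                Channel(
                    source=int(ml["sourceIndex"][()]),
                    detector=int(ml["detectorIndex"][()]),
                    separation_mm=float(ml["sourceDetectorSeparation"][()]),
                    hemisphere=Hemisphere(_h5str(ml["hemisphere"][()])),
                    label=_h5str(ml["channelLabel"][()]),
                )
            )
        events = []
        for k in sorted(k for k in nirs if k.startswith("stim")):
            name = _h5str(nirs[k]["name"][()])
            cond, _, outcome = name.partition("|")
            for row in np.atleast_2d(np.asarray(nirs[k]["data"])):
                events.append(FnirsEvent(time_s=float(row[0]), condition=cond, outcome=outcome))
        data = flat.reshape(len(channels), n_wl, -1)
    return HaemoSeries(channels=channels, data=data, fs=fs, wavelengths=wavelengths,
                       events=events, domain=Domain.INTENSITY)


def _h5str(v) -> str:
    return v.decode() if isinstance(v, bytes) else str(v)
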