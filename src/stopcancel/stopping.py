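"""Stop-signal summaries: integration-method SSRT, race-model validity,
prEMG proportions and per-cell stopping statistics.

Under the independent horse-race model, the latent stop-signal reaction
time (SSRT) is estimated with the integration method: go omissions are
replaced with the subject's slowest go RT, the augmented go-RT
distribution is sorted, and the RT at rank ceil(p_respond x N) marks the
point the stop process must beat; SSRT is that quantile minus the mean
realised SSD.  SSRT is reported only for cells satisfying the race-model
checks: mean failed-stop RT below mean go RT, and stop success within
25-75% (inclusive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import UndefinedSSRTError
from .emg import PrEMGEvent

__all__ = [
    "StopCell",
    "StopStats",
    "compute_ssrt_integration",
    "race_validity",
    "prEMG_proportion",
    "summarise_stopping",
    "SUCCESS_BAND",
]

#: inclusive stop-success band for race-model validity
SUCCESS_BAND = (0.25, 0.75)


@dataclass
class StopCell:
    """All stopping-relevant observations for one subject x congruency cell.

    ``label`` is "SST" for the no-flanker stop task, otherwise the SSFT
    congruency level.  ``stop_trials`` rows are (ssd_ms, responded, rt_ms,
    hand); go RTs are choice-error- and anticipation-screened.
    """

    subject: str
    label: str
    go_rts_ms: np.ndarray
    n_go_omissions: int
    stop_trials: pd.DataFrame  # columns: ssd_ms, responded, rt_ms, hand
    prEMG_events: list[PrEMGEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.go_rts_ms = np.asarray(self.go_rts_ms, dtype=float)
        if self.go_rts_ms.size and not np.all(self.go_rts_ms > 0):
            raise ValueError("go RTs must be positive")

    @property
    def p_respond(self) -> float:
        return float(self.stop_trials["responded"].mean())

    @property
    def mean_ssd_ms(self) -> float:
        """Mean realised SSD: per hand first, then averaged over hands."""
        by_hand = self.stop_trials.groupby("hand", observed=True)["ssd_ms"].mean()
        return float(by_hand.mean())


@dataclass
class StopStats:
    subject: str
    label: str
    ssrt_ms: Optional[float]
    p_respond: float
    mean_ssd_ms: float
    prEMG_proportion: float
    cancel_times_ms: np.ndarray
    race_rt_ok: bool
    success_in_band: bool

    @property
    def valid(self) -> bool:
        return self.race_rt_ok and self.success_in_band


def compute_ssrt_integration(
    go_rts_ms: Sequence[float],
    n_go_omissions: int,
    p_respond: float,
    mean_ssd_ms: float,
) -> float:
    """Integration-method SSRT with omission replacement.

    Go omissions are replaced with the slowest observed go RT; the augmented
    distribution is sorted ascending and the value at 1-based rank
    ceil(p_respond x N) is taken (ties inherit sorted order); SSRT is that
    value minus the mean SSD.
    """
    go = np.sort(np.asarray(go_rts_ms, dtype=float))
    if go.size == 0:
        raise UndefinedSSRTError("no go RTs available")
    if not (0.0 < p_respond < 1.0):
        raise UndefinedSSRTError(f"SSRT undefined for p_respond={p_respond}")
    if n_go_omissions < 0:
        raise ValueError("omission count cannot be negative")
    if n_go_omissions:
        go = np.sort(np.concatenate([go, np.full(n_go_omissions, go[-1])]))
    n = go.size
    rank = math.ceil(p_respond * n)
    rank = min(max(rank, 1), n)
    return float(go[rank - 1] - mean_ssd_ms)


def race_validity(cell: StopCell) -> dict[str, bool]:
    """Race-model validity flags for one cell.

    ``race_rt_ok``: mean failed-stop RT strictly below mean go RT (undefined
    without failed stops, in which case the cell is flagged invalid).
    ``success_in_band``: stop success within 25-75%, endpoints inclusive.
    """
    failed = cell.stop_trials.loc[cell.stop_trials["responded"], "rt_ms"].dropna()
    if failed.empty or cell.go_rts_ms.size == 0:
        race_rt_ok = False
    else:
        race_rt_ok = bool(failed.mean() < cell.go_rts_ms.mean())
    success = 1.0 - cell.p_respond
    success_in_band = bool(SUCCESS_BAND[0] <= success <= SUCCESS_BAND[1])
    return {"race_rt_ok": race_rt_ok, "success_in_band": success_in_band}


def prEMG_proportion(cell: StopCell) -> float:
    """Fraction of stop trials carrying a qualified partial EMG response."""
    n_stop = len(cell.stop_trials)
    if n_stop == 0:
        raise ValueError("prEMG proportion undefined without stop trials")
    return len(cell.prEMG_events) / n_stop


def cell_stats(cell: StopCell) -> tuple[StopStats, Optional[str]]:
    """StopStats for one cell plus an exclusion reason when SSRT is withheld."""
    flags = race_validity(cell)
    reason = None
    ssrt: Optional[float] = None
    if not flags["race_rt_ok"]:
        reason = "mean failed-stop RT not below mean go RT"
    elif not flags["success_in_band"]:
        reason = f"stop success {1 - cell.p_respond:.0%} outside 25-75% band"
    else:
        try:
            ssrt = compute_ssrt_integration(
                cell.go_rts_ms, cell.n_go_omissions, cell.p_respond, cell.mean_ssd_ms
            )
        except UndefinedSSRTError as exc:
            reason = str(exc)
    stats = StopStats(
        subject=cell.subject,
        label=cell.label,
        ssrt_ms=ssrt,
        p_respond=cell.p_respond,
        mean_ssd_ms=cell.mean_ssd_ms,
        prEMG_proportion=prEMG_proportion(cell),
        cancel_times_ms=np.array([ev.cancel_time_ms for ev in cell.prEMG_events]),
        race_rt_ok=flags["race_rt_ok"],
        success_in_band=flags["success_in_band"],
    )
    return stats, reason


def build_cells(
    subject: str,
    trials: pd.DataFrame,
    emg_results: Optional[pd.DataFrame] = None,
    anticipatory_ms: float = 150.0,
) -> list[StopCell]:
    """Assemble StopCells (hands pooled) from a session trial table.

    Cell labels: "SST" for the no-flanker stop task, else the SSFT
    congruency level.  Go RTs exclude practice, choice errors and
    anticipatory responses; omissions (non-practice, correct-by-default
    go trials without a press) are counted for replacement.  Cancel Times
    attach from ``emg_results`` (rows with a PARTIAL phenotype).
    """
    from .emg import EMGBurst, Phenotype  # local import to avoid cycles at module load

    test = trials[~trials["practice"]]
    stopper = test[test["condition"].isin(["SST", "SSFT"])]
    if stopper.empty:
        return []
    cells = []
    for (cond, cong), sub in stopper.groupby(["condition", "congruency"], observed=True):
        label = "SST" if cond == "SST" else cong
        go = sub[~sub["is_stop"]]
        go_kept = go[go["responded"] & go["correct_choice"] & (go["rt_ms"] >= anticipatory_ms)]
        n_omissions = int((~go["responded"]).sum())
        stop = sub[sub["is_stop"]][
            ["trial_index", "ssd_ms", "responded", "rt_ms", "hand"]
        ].reset_index(drop=True)
        events = []
        if emg_results is not None and not emg_results.empty:
            pr = emg_results[
                emg_results["trial_index"].isin(stop["trial_index"])
                & (emg_results["phenotype"] == Phenotype.PARTIAL.value)
            ]
            ssd_of = dict(zip(stop["trial_index"], stop["ssd_ms"]))
            for r in pr.itertuples():
                ssd = float(ssd_of[r.trial_index])
                burst = EMGBurst(onset_ms=np.nan, offset_ms=np.nan,
                                 peak_ms=r.premg_peak_ms, peak_amp=np.nan)
                events.append(
                    PrEMGEvent(burst=burst, ssd_ms=ssd, cancel_time_ms=r.cancel_time_ms,
                               peak_amp_norm=r.premg_peak_amp_norm)
                )
        cells.append(
            StopCell(
                subject=subject,
                label=label,
                go_rts_ms=go_kept["rt_ms"].to_numpy(),
                n_go_omissions=n_omissions,
                stop_trials=stop,
                prEMG_events=events,
            )
        )
    return cells


def summarise_stopping(cells: Sequence[StopCell]) -> tuple[pd.DataFrame, list[dict]]:
    """Tabulate StopStats over cells (hands pooled within each cell) and log
    every exclusion with its reason.  Deterministic given the input order."""
    rows = []
    exclusions: list[dict] = []
    for cell in cells:
        stats, reason = cell_stats(cell)
        rows.append(
            {
                "subject": stats.subject,
                "label": stats.label,
                "ssrt_ms": np.nan if stats.ssrt_ms is None else stats.ssrt_ms,
                "p_respond": stats.p_respond,
                "mean_ssd_ms": stats.mean_ssd_ms,
                "prEMG_proportion": stats.prEMG_proportion,
                "mean_cancel_time_ms": (
                    float(np.mean(stats.cancel_times_ms)) if stats.cancel_times_ms.size else np.nan
                ),
                "n_cancel_times": int(stats.cancel_times_ms.size),
                "race_rt_ok": stats.race_rt_ok,
                "success_in_band": stats.success_in_band,
            }
        )
        if reason is not None:
            exclusions.append({"subject": cell.subject, "label": cell.label, "reason": reason})
    return pd.DataFrame(rows), exclusions
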