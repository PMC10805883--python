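"""Go-trial screening and condition / flanker RT metrics.

Screening removes practice trials, incorrect left/right choices,
anticipatory responses (RT < 150 ms) and omissions; every exclusion is
logged with its reason.  Metrics are computed from subject-level means:
flanker congruency deltas (incongruent - neutral and congruent - neutral)
and proactive slowing (stop-context go RT minus the matched no-stop
baseline: SST vs CRT, SSFT vs the congruency-matched flanker-task cell).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import Condition, Congruency
from .errors import ProcessingError

__all__ = [
    "ANTICIPATORY_MS",
    "screen_go_trials",
    "flanker_deltas",
    "proactive_slowing",
]

ANTICIPATORY_MS = 150.0

_REQUIRED = ("subject", "condition", "congruency", "rt_ms", "correct_choice", "practice")


def screen_go_trials(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition go-trial records into (kept, excluded-with-reason).

    Exclusion reasons, in precedence order: practice trial, omission (no
    RT), incorrect choice, anticipatory (RT < 150 ms).  RT = 150 ms exactly
    is kept (the rule is strict).  Idempotent: screening the kept set again
    removes nothing.
    """
    missing = [c for c in _REQUIRED if c not in records.columns]
    if missing:
        raise ProcessingError(f"go records missing columns: {missing}")
    df = records.copy()
    reason = pd.Series(pd.NA, index=df.index, dtype="string")
    reason[df["practice"].astype(bool)] = "practice"
    omitted = df["rt_ms"].isna()
    reason[reason.isna() & omitted] = "omission"
    reason[reason.isna() & ~df["correct_choice"].astype(bool)] = "incorrect choice"
    reason[reason.isna() & (df["rt_ms"] < ANTICIPATORY_MS)] = "anticipatory (<150 ms)"
    excluded = df[reason.notna()].assign(reason=reason[reason.notna()])
    kept = df[reason.isna()]
    return kept, excluded


def flanker_deltas(kept: pd.DataFrame) -> pd.DataFrame:
    """Per subject x condition congruency means and deltas (ms).

    Deltas are differences of the same subject's condition means; a missing
    congruency level leaves the affected delta as NaN.  Only flanker-bearing
    conditions (FLANKER, SSFT go trials) contribute.
    """
    flanked = kept[kept["congruency"].isin(
        [Congruency.CONGRUENT.value, Congruency.INCONGRUENT.value, Congruency.NEUTRAL.value]
    )]
    if flanked.empty:
        raise ProcessingError("no flanker-bearing go trials to summarise")
    means = (
        flanked.groupby(["subject", "condition", "congruency"], observed=True)["rt_ms"]
        .mean()
        .unstack("congruency")
    )
    for level in (Congruency.CONGRUENT.value, Congruency.INCONGRUENT.value, Congruency.NEUTRAL.value):
        if level not in means.columns:
            means[level] = np.nan
    out = means.reset_index()
    out["delta_incongruent_neutral_ms"] = out[Congruency.INCONGRUENT.value] - out[Congruency.NEUTRAL.value]
    out["delta_congruent_neutral_ms"] = out[Congruency.CONGRUENT.value] - out[Congruency.NEUTRAL.value]
    return out


def proactive_slowing(kept: pd.DataFrame) -> pd.DataFrame:
    """Go-RT slowing in stop-expectation contexts, per subject (ms).

    SST is referenced to CRT; each SSFT congruency cell is referenced to the
    same congruency cell of the flanker task.  Rows with a missing reference
    carry NaN."""
    rows = []
    for subject, sub in kept.groupby("subject"):
        means = sub.groupby(["condition", "congruency"], observed=True)["rt_ms"].mean()

        def cell(cond: Condition, cong: Congruency) -> float:
            return float(means.get((cond.value, cong.value), np.nan))

        rows.append(
            {
                "subject": subject,
                "context": "SST_vs_CRT",
                "slowing_ms": cell(Condition.SST, Congruency.NONE) - cell(Condition.CRT, Congruency.NONE),
            }
        )
        for cong in (Congruency.CONGRUENT, Congruency.INCONGRUENT, Congruency.NEUTRAL):
            rows.append(
                {
                    "subject": subject,
                    "context": f"SSFT_vs_FLANKER_{cong.value}",
                    "slowing_ms": cell(Condition.SSFT, cong) - cell(Condition.FLANKER, cong),
                }
            )
    return pd.DataFrame(rows)
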