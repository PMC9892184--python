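"""Arrhythmic-score statistic and cohort responder tables.

The severity score of a challenge session is the mean of the three most
severe arrhythmic events inside the 1–3 h post-dose counting window,
padding with zeros when fewer than three events occurred.  The per-event
severity mapping of the cited canine scoring system is not printed in the
source study; the default table below is an explicit reconstruction that
reproduces the universal pre-block value 0.3 (one single ectopic beat:
(1+0+0)/3) and is consistent with the 3–5 range reported for sessions with
three or more runs of 2–4 ectopic beats.  It is fully configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import pandas as pd

from .holter import ArrhythmiaEvent


@dataclass(frozen=True)
class ScoreTable:
    """Event-kind -> severity-points mapping (a documented reconstruction)."""

    single_pvb: float = 1.0
    run_points: Mapping[int, float] = field(
        default_factory=lambda: {2: 3.0, 3: 4.0, 4: 5.0}
    )
    #: severity of a >=5-beat segment that does not meet the TdP definition
    non_tdp_tachycardia: float = 5.0
    #: TdP severity: per-episode beat count
    tdp_per_beat: bool = True

    def severity(self, event: ArrhythmiaEvent) -> float:
        if event.kind == "single_pvb":
            pts = self.single_pvb
        elif event.kind == "tdp":
            pts = float(event.n_beats) if self.tdp_per_beat else self.non_tdp_tachycardia
        elif event.n_beats in self.run_points:
            pts = float(self.run_points[event.n_beats])
        else:  # >=5-beat non-TdP tachycardia
            pts = self.non_tdp_tachycardia
        if pts < 0:
            raise ValueError("severity points must be non-negative")
        return pts


DEFAULT_SCORE_TABLE = ScoreTable()


def arrhythmic_score(
    events_in_window: Sequence[ArrhythmiaEvent],
    table: ScoreTable = DEFAULT_SCORE_TABLE,
) -> float:
    """Mean of the three largest per-event severities, zero-padded.

    Permutation-invariant in the event list; with k < 3 events it equals
    (sum of severities)/3 exactly.
    """
    sev = sorted((table.severity(e) for e in events_in_window), reverse=True)
    top3 = (sev + [0.0, 0.0, 0.0])[:3]
    return float(sum(top3) / 3.0)


def flag_runs_ge3(events_in_window: Sequence[ArrhythmiaEvent]) -> bool:
    """True iff the window holds >= 3 runs of 2–4 ectopic beats."""
    n = sum(1 for e in events_in_window if e.kind == "run" and 2 <= e.n_beats <= 4)
    return n >= 3


def has_tdp(events_in_window: Sequence[ArrhythmiaEvent]) -> bool:
    return any(e.kind == "tdp" for e in events_in_window)


def _fixture(name: str) -> pd.DataFrame:
    with resources.files("cavbmonkey.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_tdp_outcomes() -> pd.DataFrame:
    """Packaged transcription of the monthly TdP outcome table (10 animals).

    Columns: animal, month (-1 = pre-block week), outcome in
    {no_tdp, tdp, na, nr, not_done, autopsy}, and vehicle / moxifloxacin /
    reablation indicator columns.
    """
    return _fixture("table2_tdp_outcomes.csv")


def load_score_matrix() -> pd.DataFrame:
    """Packaged transcription of the monthly arrhythmic-score table.

    Columns: animal, month, score (blank where missing), runs_ge3 (>=3 run
    sets of 2–4 beats), tdp (TdP in the window) and status in
    {recorded, nr, na, not_done}.  Missing cells propagate as missing,
    never as zero.
    """
    df = _fixture("table3_scores.csv")
    bad = df[(df["status"] != "recorded") & df["score"].notna()]
    if len(bad):
        raise ValueError("score present in a cell flagged as not recorded")
    return df


def responder_counts(
    outcomes: pd.DataFrame | None = None,
    scores: pd.DataFrame | None = None,
) -> dict:
    """Cohort-level responder summary from the outcome/score tables.

    Returns the number of animals with >=1 and >=3 TdP months over the
    whole observation period, the number showing the arrhythmia "trigger"
    (>=3 run sets of 2–4 beats, or TdP) by 2 months after block, per-animal
    TdP totals, and the TdP 0–1 / TdP >=3 group label per animal.  An
    animal with exactly two TdP months has no defined group and raises.
    """
    out = load_tdp_outcomes() if outcomes is None else outcomes
    post = out[out["month"] > 0]
    tdp_totals = (
        (post.assign(is_tdp=post["outcome"].eq("tdp")))
        .groupby("animal")["is_tdp"]
        .sum()
        .astype(int)
    )
    # every cohort animal is counted, including those with all cells missing
    tdp_totals = tdp_totals.reindex(sorted(out["animal"].unique()), fill_value=0)
    groups = {}
    for animal, total in tdp_totals.items():
        if total >= 3:
            groups[int(animal)] = "TdP >=3"
        elif total <= 1:
            groups[int(animal)] = "TdP 0-1"
        else:
            raise ValueError(
                f"animal {animal} had exactly 2 TdP months; no group is defined"
            )
    sc = load_score_matrix() if scores is None else scores
    early = sc[sc["month"].isin([1, 2])]
    trig = (
        early.assign(trigger=early["runs_ge3"].astype(bool) | early["tdp"].astype(bool))
        .groupby("animal")["trigger"]
        .any()
    )
    return {
        "n_animals": int(tdp_totals.size),
        "n_tdp_ge1": int((tdp_totals >= 1).sum()),
        "n_tdp_ge3": int((tdp_totals >= 3).sum()),
        "n_trigger_by_month2": int(trig.sum()),
        "tdp_totals": {int(a): int(v) for a, v in tdp_totals.items()},
        "groups": groups,
    }


def score_sessions(
    session_events: Mapping[tuple, Sequence[ArrhythmiaEvent]],
    table: ScoreTable = DEFAULT_SCORE_TABLE,
) -> pd.DataFrame:
    """Score a mapping of (animal, month) -> windowed events into a long table."""
    rows = []
    for (animal, month), events in session_events.items():
        rows.append(
            {
                "animal": animal,
                "month": month,
                "score": arrhythmic_score(events, table),
                "runs_ge3": flag_runs_ge3(events),
                "tdp": has_tdp(events),
                "n_events": len(events),
            }
        )
    return pd.DataFrame(rows).sort_values(["animal", "month"]).reset_index(drop=True)
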