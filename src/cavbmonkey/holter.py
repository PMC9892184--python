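"""Classification of Holter beat-annotation streams into arrhythmia events.

The substrate is a beat stream: one row per heartbeat with a timestamp
(seconds from recording start), a rhythm label (``sinus``, ``escape`` or
``ectopic``), a signed morphology scalar standing in for QRS polarity/axis,
and an optional per-beat QT estimate in ms.  Torsade de pointes (TdP) is
recognised operationally as a run of six or more consecutive ectopic beats
whose morphology twists (changes sign) around the baseline and whose onset
is preceded by QT prolongation relative to the pre-dose baseline.

Events are counted inside a fixed challenge window, by default 1–3 h after
oral drug administration (around Tmax of dl-sotalol), matching the study
design this package analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

BEAT_LABELS = ("sinus", "escape", "ectopic")

#: counting window relative to dose time, seconds (half-open [lo, hi))
DEFAULT_WINDOW_S = (3600.0, 3 * 3600.0)

#: fractional QTc elevation over pre-dose baseline that counts as
#: "QT prolongation prior to onset" (the study states the criterion
#: qualitatively; the threshold is a documented operational choice)
DEFAULT_QT_PROLONGATION_FRACTION = 0.10

#: how far before episode onset (s) per-beat QT values are averaged
QT_LOOKBACK_S = 60.0


@dataclass(frozen=True)
class BeatAnnotation:
    """One time-stamped, labelled heartbeat."""

    t: float
    label: str
    morphology: float = 0.0
    qt_ms: float | None = None

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError(f"beat time must be non-negative, got {self.t}")
        if self.label not in BEAT_LABELS:
            raise ValueError(f"unknown beat label {self.label!r}")


@dataclass
class ArrhythmiaEvent:
    """A classified arrhythmia episode.

    ``kind`` is ``single_pvb``, ``run`` or ``tdp``.  Segments of >=5 beats
    that fail the TdP criteria (too short, monomorphic, or no preceding QT
    prolongation) are recorded as ``run`` with their beat count preserved,
    i.e. a non-TdP ventricular tachycardia.
    """

    kind: str
    onset_t: float
    n_beats: int
    duration_s: float
    polymorphic: bool = False
    qt_prolonged_before_onset: bool = False
    spontaneously_terminated: bool | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("single_pvb", "run", "tdp"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.n_beats < 1:
            raise ValueError("event must contain at least one beat")
        if self.duration_s < 0:
            raise ValueError("duration must be non-negative")
        if self.kind == "tdp" and self.n_beats < 6:
            raise ValueError("TdP requires >= 6 beats")


def beats_to_frame(beats: Iterable[BeatAnnotation] | pd.DataFrame) -> pd.DataFrame:
    """Normalise a beat stream to a DataFrame with columns t/label/morphology/qt_ms."""
    if isinstance(beats, pd.DataFrame):
        df = beats
        missing = {"t", "label"} - set(df.columns)
        if missing:
            raise ValueError(f"beat frame missing columns: {sorted(missing)}")
        df = df.copy()
        if "morphology" not in df:
            df["morphology"] = 0.0
        if "qt_ms" not in df:
            df["qt_ms"] = np.nan
        return df[["t", "label", "morphology", "qt_ms"]]
    rows = [(b.t, b.label, b.morphology, np.nan if b.qt_ms is None else b.qt_ms) for b in beats]
    return pd.DataFrame(rows, columns=["t", "label", "morphology", "qt_ms"])


def _require_sorted(t: np.ndarray) -> None:
    if t.size > 1 and np.any(np.diff(t) < 0):
        raise ValueError("beat stream must be sorted by time")


def segment_ectopic_runs(beats: Iterable[BeatAnnotation] | pd.DataFrame) -> list[pd.DataFrame]:
    """Split a sorted stream into maximal segments of consecutive ectopic beats.

    Every ectopic beat belongs to exactly one segment; segments are maximal,
    i.e. bounded by non-ectopic beats or the record edges.
    """
    df = beats_to_frame(beats)
    t = df["t"].to_numpy(dtype=float)
    _require_sorted(t)
    ect = (df["label"] == "ectopic").to_numpy()
    if not ect.any():
        return []
    # run-length encode the ectopic mask
    padded = np.concatenate(([False], ect, [False]))
    edges = np.flatnonzero(np.diff(padded.view(np.int8)))
    starts, stops = edges[0::2], edges[1::2]
    return [df.iloc[a:b] for a, b in zip(starts, stops)]


def _polymorphic(morphology: np.ndarray, min_sign_changes: int = 2) -> bool:
    s = np.sign(morphology[morphology != 0])
    if s.size < 2:
        return False
    return int(np.sum(s[1:] != s[:-1])) >= min_sign_changes


def qt_prolonged_before(
    beats: pd.DataFrame,
    onset_t: float,
    baseline_qt_ms: float,
    threshold_fraction: float = DEFAULT_QT_PROLONGATION_FRACTION,
    lookback_s: float = QT_LOOKBACK_S,
) -> bool:
    """True iff mean per-beat QT in the minute before ``onset_t`` exceeds
    the pre-dose baseline by more than ``threshold_fraction``."""
    if baseline_qt_ms <= 0 or np.isnan(baseline_qt_ms):
        return False
    t = beats["t"].to_numpy(dtype=float)
    qt = beats["qt_ms"].to_numpy(dtype=float)
    mask = (t >= onset_t - lookback_s) & (t < onset_t) & ~np.isnan(qt)
    if not mask.any():
        return False
    return float(np.mean(qt[mask])) > baseline_qt_ms * (1.0 + threshold_fraction)


def predose_baseline_qt(beats: pd.DataFrame, dose_time_s: float) -> float:
    """Session baseline: mean per-beat QT over all pre-dose beats with a QT value."""
    t = beats["t"].to_numpy(dtype=float)
    qt = beats["qt_ms"].to_numpy(dtype=float)
    mask = (t < dose_time_s) & ~np.isnan(qt)
    return float(np.mean(qt[mask])) if mask.any() else float("nan")


def classify_segment(
    segment: pd.DataFrame,
    *,
    context: pd.DataFrame | None = None,
    baseline_qt_ms: float = float("nan"),
    qt_threshold_fraction: float = DEFAULT_QT_PROLONGATION_FRACTION,
) -> ArrhythmiaEvent:
    """Classify one maximal ectopic segment.

    1 beat -> single premature ventricular beat; 2–4 beats -> run; >=6 beats
    that are polymorphic with QT prolongation before onset -> TdP; anything
    else (5 beats, or >=6 failing a TdP criterion) -> non-TdP tachycardia
    recorded as ``run`` with the beat count preserved.
    """
    if len(segment) == 0:
        raise ValueError("cannot classify an empty segment")
    t = segment["t"].to_numpy(dtype=float)
    n = len(segment)
    onset = float(t[0])
    duration = float(t[-1] - t[0])
    poly = _polymorphic(segment["morphology"].to_numpy(dtype=float))
    qt_ok = qt_prolonged_before(
        context if context is not None else segment,
        onset,
        baseline_qt_ms,
        qt_threshold_fraction,
    )
    if n == 1:
        kind = "single_pvb"
    elif n >= 6 and poly and qt_ok:
        kind = "tdp"
    else:
        kind = "run"
    return ArrhythmiaEvent(
        kind=kind,
        onset_t=onset,
        n_beats=n,
        duration_s=duration,
        polymorphic=poly,
        qt_prolonged_before_onset=qt_ok,
    )


def termination_flag(
    event: ArrhythmiaEvent,
    beats: Iterable[BeatAnnotation] | pd.DataFrame,
) -> bool:
    """Whether the episode ends with resumption of a non-ectopic rhythm.

    True iff at least one sinus/escape beat follows the last beat of the
    episode; an episode running to the end of the record (or degenerating)
    is not terminated.  The 15-s figure quoted for spontaneously terminated
    TdP is a report cutoff, not part of this flag.
    """
    df = beats_to_frame(beats)
    end_t = event.onset_t + event.duration_s
    after = df[(df["t"] > end_t) & (df["label"] != "ectopic")]
    return len(after) > 0


def detect_events(
    beats: Iterable[BeatAnnotation] | pd.DataFrame,
    dose_time_s: float,
    window_s: tuple[float, float] = DEFAULT_WINDOW_S,
    *,
    qt_threshold_fraction: float = DEFAULT_QT_PROLONGATION_FRACTION,
) -> tuple[list[ArrhythmiaEvent], list[ArrhythmiaEvent]]:
    """Classify all ectopic segments and split out those in the dose window.

    Returns ``(windowed_events, all_events)``.  The counting window is
    half-open, ``[dose + window_s[0], dose + window_s[1])``, by event onset.
    Events carry their spontaneous-termination flag.
    """
    df = beats_to_frame(beats)
    if len(df):
        rec_end = float(df["t"].iloc[-1])
        if dose_time_s < 0 or dose_time_s > rec_end:
            raise ValueError("dose time outside recording")
        if dose_time_s + window_s[0] >= rec_end:
            warnings.warn("challenge window lies outside the recording; no windowed events")
    baseline = predose_baseline_qt(df, dose_time_s)
    events = []
    for seg in segment_ectopic_runs(df):
        ev = classify_segment(
            seg,
            context=df,
            baseline_qt_ms=baseline,
            qt_threshold_fraction=qt_threshold_fraction,
        )
        ev.spontaneously_terminated = termination_flag(ev, df)
        events.append(ev)
    lo, hi = dose_time_s + window_s[0], dose_time_s + window_s[1]
    windowed = [e for e in events if lo <= e.onset_t < hi]
    return windowed, events


def events_to_frame(events: Sequence[ArrhythmiaEvent]) -> pd.DataFrame:
    """Tabulate events for CSV/JSON export."""
    return pd.DataFrame(
        [
            {
                "kind": e.kind,
                "onset_t": e.onset_t,
                "n_beats": e.n_beats,
                "duration_s": e.duration_s,
                "polymorphic": e.polymorphic,
                "qt_prolonged_before_onset": e.qt_prolonged_before_onset,
                "spontaneously_terminated": e.spontaneously_terminated,
            }
            for e in events
        ],
        columns=[
            "kind",
            "onset_t",
            "n_beats",
            "duration_s",
            "polymorphic",
            "qt_prolonged_before_onset",
            "spontaneously_terminated",
        ],
    )
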