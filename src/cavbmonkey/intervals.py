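"""ECG interval arithmetic and heart-rate correction of the QT interval.

Bazett's correction (QT/RR^0.5) is used for conscious recordings and
Fridericia's (QT/RR^0.33, exponent as conventionally printed rather than
1/3) for anesthetised ones, with RR in seconds.  The JT interval isolates
ventricular repolarisation as QT - QRS.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

FRIDERICIA_EXPONENT = 0.33


def rr_from_rate(rate_bpm):
    """RR interval in seconds from ventricular rate in beats/min."""
    rate = np.asarray(rate_bpm, dtype=float)
    if np.any(rate <= 0):
        raise ValueError("ventricular rate must be positive")
    out = 60.0 / rate
    return float(out) if out.ndim == 0 else out


def qtc_bazett(qt_ms, rr_s):
    """QTcB = QT / sqrt(RR), QT in ms, RR in s."""
    rr = np.asarray(rr_s, dtype=float)
    if np.any(rr <= 0):
        raise ValueError("RR interval must be positive")
    out = np.asarray(qt_ms, dtype=float) / np.sqrt(rr)
    return float(out) if out.ndim == 0 else out


def qtc_fridericia(qt_ms, rr_s):
    """QTcF = QT / RR^0.33, QT in ms, RR in s."""
    rr = np.asarray(rr_s, dtype=float)
    if np.any(rr <= 0):
        raise ValueError("RR interval must be positive")
    out = np.asarray(qt_ms, dtype=float) / rr**FRIDERICIA_EXPONENT
    return float(out) if out.ndim == 0 else out


def jt_interval(qt_ms, qrs_ms):
    """JT = QT - QRS (ms); requires QT >= QRS."""
    qt = np.asarray(qt_ms, dtype=float)
    qrs = np.asarray(qrs_ms, dtype=float)
    if np.any(qt < qrs):
        raise ValueError("QT must not be shorter than QRS")
    out = qt - qrs
    return float(out) if out.ndim == 0 else out


def derive_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Add rr_s, jt_ms, qtcb_ms and qtcf_ms columns to a long-format
    interval table (requires ventricular_rate, qt_ms, qrs_ms)."""
    out = df.copy()
    out["rr_s"] = rr_from_rate(out["ventricular_rate"].to_numpy())
    out["jt_ms"] = jt_interval(out["qt_ms"].to_numpy(), out["qrs_ms"].to_numpy())
    out["qtcb_ms"] = qtc_bazett(out["qt_ms"].to_numpy(), out["rr_s"].to_numpy())
    out["qtcf_ms"] = qtc_fridericia(out["qt_ms"].to_numpy(), out["rr_s"].to_numpy())
    return out


#: sign convention per variable for conscious-vs-anesthetised deltas:
#: rate and blood pressure are reported as decreases under anesthesia
#: (conscious - anesthetised), interval prolongations as increases
#: (anesthetised - conscious)
_DECREASE_VARS = ("ventricular_rate", "sbp", "dbp")
_INCREASE_VARS = ("qrs_ms", "jt_ms", "qt_ms")


def state_delta(conscious_row: pd.Series, anesthetized_row: pd.Series) -> dict:
    """Per-variable conscious/anesthetised differences for one animal-month.

    Rate and blood pressure are signed as decreases under anesthesia,
    interval variables as prolongations under anesthesia.
    """
    for key in ("animal", "month"):
        if key in conscious_row and key in anesthetized_row:
            if conscious_row[key] != anesthetized_row[key]:
                raise ValueError(f"state rows disagree on {key}")
    for key in ("state",):
        if conscious_row.get(key, "conscious") != "conscious":
            raise ValueError("first row must be the conscious measurement")
        if anesthetized_row.get(key, "anesthetized") != "anesthetized":
            raise ValueError("second row must be the anesthetised measurement")
    deltas = {}
    for var in _DECREASE_VARS:
        if var in conscious_row and var in anesthetized_row:
            deltas[f"{var}_decrease"] = float(conscious_row[var] - anesthetized_row[var])
    for var in _INCREASE_VARS:
        if var in conscious_row and var in anesthetized_row:
            deltas[f"{var}_prolongation"] = float(
                anesthetized_row[var] - conscious_row[var]
            )
    return deltas
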