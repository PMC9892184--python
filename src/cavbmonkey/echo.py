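"""Echocardiographic and radiographic derived indices.

M-mode left-ventricular volumes use the Teichholz formula
``V = 7.0/(2.4 + LVID) * LVID^3`` with LVID in cm and V in mL; stroke
volume and ejection fraction follow as SV = EDV - ESV and
EF% = SV/EDV * 100.  LV wall mass is the cubed-shell estimate
``[(IVSd + LVIDd + LVPWd)^3 - LVIDd^3] * 1.05`` g (myocardial density
1.05 g/mL).  Linear inputs are cm internally; source tables print mm, so
conversion helpers are provided and a unit guard rejects cm-field values
that look like mm.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: linear LV dimensions above this (cm) are almost certainly mm
UNIT_GUARD_CM = 15.0

MYOCARDIAL_DENSITY_G_PER_ML = 1.05


def mm_to_cm(value_mm):
    return np.asarray(value_mm, dtype=float) / 10.0


def _check_lvid(lvid_cm: np.ndarray) -> None:
    if np.any(lvid_cm <= 0):
        raise ValueError("LVID must be positive")
    if np.any(lvid_cm > UNIT_GUARD_CM):
        raise ValueError(
            f"LVID > {UNIT_GUARD_CM} cm: input looks like mm, convert to cm first"
        )


def teichholz_volume(lvid_cm):
    """Teichholz LV volume (mL) from an internal diameter (cm)."""
    lvid = np.asarray(lvid_cm, dtype=float)
    _check_lvid(lvid)
    out = 7.0 / (2.4 + lvid) * lvid**3
    return float(out) if out.ndim == 0 else out


def sv_ef(edv_ml, esv_ml):
    """(stroke volume mL, ejection fraction %) from LV volumes."""
    edv = np.asarray(edv_ml, dtype=float)
    esv = np.asarray(esv_ml, dtype=float)
    if np.any(edv <= 0):
        raise ValueError("EDV must be positive")
    if np.any(esv < 0) or np.any(esv > edv):
        raise ValueError("require 0 <= ESV <= EDV")
    sv = edv - esv
    ef = sv / edv * 100.0
    if sv.ndim == 0:
        return float(sv), float(ef)
    return sv, ef


def lv_wall_mass(ivsd_cm, lvidd_cm, lvpwd_cm):
    """LV wall mass (g) by the cubed-shell estimate; inputs in cm."""
    ivsd = np.asarray(ivsd_cm, dtype=float)
    lvidd = np.asarray(lvidd_cm, dtype=float)
    lvpwd = np.asarray(lvpwd_cm, dtype=float)
    if np.any(ivsd <= 0) or np.any(lvidd <= 0) or np.any(lvpwd <= 0):
        raise ValueError("all wall dimensions must be positive")
    _check_lvid(lvidd)
    out = ((ivsd + lvidd + lvpwd) ** 3 - lvidd**3) * MYOCARDIAL_DENSITY_G_PER_ML
    return float(out) if out.ndim == 0 else out


def cardiac_output(sv_ml, rate_bpm):
    """CO (L/min) = SV (mL) x ventricular rate (beats/min) / 1000.

    The derivation SV x rate is a reconstruction: the source tables report
    SV, rate and CO but not the operation linking them.
    """
    sv = np.asarray(sv_ml, dtype=float)
    rate = np.asarray(rate_bpm, dtype=float)
    if np.any(sv <= 0) or np.any(rate <= 0):
        raise ValueError("SV and rate must be positive")
    out = sv * rate / 1000.0
    return float(out) if out.ndim == 0 else out


def cardiothoracic_ratio(cardiac_diameter, thoracic_diameter):
    """CTR (%) = maximal horizontal cardiac / thoracic diameter x 100."""
    c = np.asarray(cardiac_diameter, dtype=float)
    th = np.asarray(thoracic_diameter, dtype=float)
    if np.any(c <= 0) or np.any(th <= c):
        raise ValueError("require 0 < cardiac < thoracic diameter")
    out = c / th * 100.0
    return float(out) if out.ndim == 0 else out


def derive_echo(df: pd.DataFrame, units: str = "cm") -> pd.DataFrame:
    """Add derived columns (edv/esv/sv/ef/co/lv_mass) to an echo table.

    Expects lvidd, lvids, lvpwd, ivsd and ventricular_rate columns; pass
    ``units="mm"`` when linear dimensions are in mm (as printed).
    """
    out = df.copy()
    cols = ["lvidd", "lvids", "lvpwd", "ivsd"] + (["lad"] if "lad" in df else [])
    if units == "mm":
        for c in cols:
            out[c] = mm_to_cm(out[c].to_numpy())
    elif units != "cm":
        raise ValueError("units must be 'cm' or 'mm'")
    out["edv_ml"] = teichholz_volume(out["lvidd"].to_numpy())
    out["esv_ml"] = teichholz_volume(out["lvids"].to_numpy())
    sv, ef = sv_ef(out["edv_ml"].to_numpy(), out["esv_ml"].to_numpy())
    out["sv_ml"], out["ef_pct"] = sv, ef
    out["lv_mass_g"] = lv_wall_mass(
        out["ivsd"].to_numpy(), out["lvidd"].to_numpy(), out["lvpwd"].to_numpy()
    )
    if "ventricular_rate" in out:
        out["co_l_min"] = cardiac_output(sv, out["ventricular_rate"].to_numpy())
    return out
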