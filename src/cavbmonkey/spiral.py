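"""Effective size of the heart for spiral-wave (reentry) rotation.

How many turns a reentrant spiral can complete before meeting a boundary
depends on the ratio of tissue size to the wavelength of the reentrant
wave.  The dimensionless index used here is

    I = (LV wall mass)^(1/3) / (period of spiral-wave rotation)
      = (LV wall mass)^(1/3) * rotation frequency,

with mass in g and frequency in Hz (the torsade-de-pointes undulation
frequency is taken as the rotation frequency).  Hearts with small I
terminate polymorphic tachycardia spontaneously; hearts with large I
sustain it and may degenerate into fibrillation.  Note the formula is
stated elsewhere as cube-root of mass divided by *wavelength*; the
published species values are only reproduced by the division-by-period
(multiplication-by-frequency) form implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (report convention)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SpeciesCardiacProfile:
    """LV wall mass and polymorphic-VT frequency range of one species/model."""

    species: str
    lv_mass_g: float
    tdp_frequency_range_hz: tuple[float, float]

    def __post_init__(self) -> None:
        if self.lv_mass_g <= 0:
            raise ValueError("LV mass must be positive")
        lo, hi = self.tdp_frequency_range_hz
        if not 0 < lo <= hi:
            raise ValueError("frequency range must satisfy 0 < low <= high")


#: the four published profiles: chronic AV-block monkey (echo-derived mass
#: at 7 months), chronic AV-block dog, normal adult human, intact NZW rabbit
REFERENCE_PROFILES = (
    SpeciesCardiacProfile("cavb_monkey", 11.4, (2.0, 5.0)),
    SpeciesCardiacProfile("cavb_dog", 75.4, (5.0, 6.0)),
    SpeciesCardiacProfile("human", 179.3, (3.0, 4.5)),
    SpeciesCardiacProfile("rabbit", 3.6, (3.0, 6.0)),
)

#: default reference threshold: the published lower bound of the dog/human
#: (TdP-sustaining) range
DEFAULT_TERMINATION_THRESHOLD = 17.2


def effective_size(mass_g: float, frequency_hz: float) -> float:
    """I = mass^(1/3) * frequency (dimensionless up to unit convention)."""
    if mass_g <= 0 or frequency_hz <= 0:
        raise ValueError("mass and frequency must be positive")
    return mass_g ** (1.0 / 3.0) * frequency_hz


def effective_size_range(profile: SpeciesCardiacProfile) -> tuple[float, float]:
    lo, hi = profile.tdp_frequency_range_hz
    return (
        effective_size(profile.lv_mass_g, lo),
        effective_size(profile.lv_mass_g, hi),
    )


def termination_propensity(
    i_range: tuple[float, float],
    threshold: float = DEFAULT_TERMINATION_THRESHOLD,
) -> str:
    """Label a heart's TdP fate from its effective-size range.

    Entirely below the sustaining reference threshold -> spontaneous
    termination expected; entirely at/above -> degeneration expected;
    straddling -> indeterminate.
    """
    lo, hi = i_range
    if lo > hi:
        raise ValueError("range low must not exceed high")
    if hi < threshold:
        return "self-terminating-like"
    if lo >= threshold:
        return "degenerating-like"
    return "indeterminate"


def species_table(
    profiles=REFERENCE_PROFILES,
    threshold: float = DEFAULT_TERMINATION_THRESHOLD,
) -> pd.DataFrame:
    """Effective-size comparison table, bounds rounded half-up to 1 decimal."""
    rows = []
    for p in profiles:
        i_lo, i_hi = effective_size_range(p)
        rows.append(
            {
                "species": p.species,
                "lv_mass_g": p.lv_mass_g,
                "freq_low_hz": p.tdp_frequency_range_hz[0],
                "freq_high_hz": p.tdp_frequency_range_hz[1],
                "I_low": round_half_up(i_lo, 1),
                "I_high": round_half_up(i_hi, 1),
                "termination_propensity": termination_propensity((i_lo, i_hi), threshold),
            }
        )
    return pd.DataFrame(rows)
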