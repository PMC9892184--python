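"""Recomputation of the study's countable published quantities.

Each target is computed from scratch by the package: the effective-size
indices from the published species profiles, the responder counts from the
packaged outcome/score transcriptions, the echo and Bazett chains from the
published basal means, and the baseline score from a one-beat session run
through the generator and classifier.
"""

from __future__ import annotations

from .echo import mm_to_cm, sv_ef, teichholz_volume
from .holter import detect_events
from .intervals import qtc_bazett, rr_from_rate
from .scoring import arrhythmic_score, responder_counts
from .spiral import REFERENCE_PROFILES, round_half_up, species_table
from .synthetic import CohortConfig, generate_beat_stream


def effective_size_targets() -> dict[str, float]:
    """Species-profile effective-size bounds (1 decimal, half-up)."""
    table = species_table(REFERENCE_PROFILES).set_index("species")
    return {
        "monkey_low": float(table.loc["cavb_monkey", "I_low"]),
        "dog_low": float(table.loc["cavb_dog", "I_low"]),
        "rabbit_high": float(table.loc["rabbit", "I_high"]),
        "human_high": float(table.loc["human", "I_high"]),
        "human_low": float(table.loc["human", "I_low"]),
        "monkey_high": float(table.loc["cavb_monkey", "I_high"]),
    }


def echo_chain_targets() -> dict[str, float]:
    """SV (mL) and EF (%) from the published basal LVIDd/LVIDs of
    17.4 / 12.7 mm via the Teichholz volume formula."""
    edv = teichholz_volume(mm_to_cm(17.4))
    esv = teichholz_volume(mm_to_cm(12.7))
    sv, ef = sv_ef(edv, esv)
    return {"sv_ml": sv, "ef_pct": ef}


def bazett_target() -> float:
    """QTcB (ms) from the published basal QT 167 ms at 231 beats/min."""
    return qtc_bazett(167.0, rr_from_rate(231.0))


def baseline_score_target(seed: int) -> float:
    """Arrhythmic score of a pre-block session (one single ectopic beat in
    the counting window), generated and classified end to end."""
    config = CohortConfig(n_animals=1, months=(-1,), seed=seed, recording_duration_h=6.0)
    session = generate_beat_stream(1, -1, config, susceptible=False)
    windowed, _ = detect_events(session.beats, session.dose_time_s)
    return round_half_up(arrhythmic_score(windowed), 1)


def compute_targets(seed: int = 1) -> dict[str, dict]:
    """All targets as {id: {value, n}}; values on the published scale."""
    ez = effective_size_targets()
    counts = responder_counts()
    chain = echo_chain_targets()
    out = {
        "t1": {"value": ez["monkey_low"], "n": 1},
        "t2": {"value": ez["dog_low"], "n": 1},
        "t3": {"value": ez["rabbit_high"], "n": 1},
        "t4": {"value": ez["human_high"], "n": 1},
        "t5": {"value": counts["n_tdp_ge1"], "n": counts["n_animals"]},
        "t6": {"value": counts["n_tdp_ge3"], "n": counts["n_animals"]},
        "t7": {"value": counts["n_trigger_by_month2"], "n": counts["n_animals"]},
        "t8": {"value": chain["sv_ml"], "n": 1},
        "t9": {"value": chain["ef_pct"], "n": 1},
        "t10": {"value": bazett_target(), "n": 1},
        "t11": {"value": baseline_score_target(seed), "n": 1},
    }
    return out
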