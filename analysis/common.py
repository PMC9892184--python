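"""Shared configuration of the analysis drivers.

One cohort definition used by every numbered script: 10 animals, the
challenge schedule through 7 months plus the 15-month follow-up, 6-h
Holter recordings (dose at 2 h, so the 1-3 h post-dose counting window is
fully contained) and the default physiological calibration.
"""

from pathlib import Path

from cavbmonkey.synthetic import CohortConfig

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

STUDY_SEED = 42

STUDY_CONFIG = CohortConfig(
    n_animals=10,
    months=(-1, 1, 2, 3, 4, 5, 6, 7, 15),
    seed=STUDY_SEED,
    recording_duration_h=6.0,
)
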