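"""Responder counts from the packaged study-table transcriptions.

Recomputes, from the monthly TdP-outcome and arrhythmic-score tables, the
study's headline counts: how many of the 10 animals developed TdP at
least once (6), at least three times (4), and how many showed the
arrhythmia "trigger" (>=3 run sets of 2-4 ectopic beats, or TdP) within
the first two months (8).
"""

import json

from common import RESULTS

from cavbmonkey.scoring import responder_counts


def main() -> None:
    counts = responder_counts()
    outdir = RESULTS
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "responder_counts.json", "w") as fh:
        json.dump(counts, fh, indent=1)

    print(f"animals with >=1 TdP over the observation period: {counts['n_tdp_ge1']}/10")
    print(f"animals with >=3 TdP: {counts['n_tdp_ge3']}/10 "
          f"({sorted(a for a, g in counts['groups'].items() if g == 'TdP >=3')})")
    print(f"animals with trigger arrhythmias by 2 months: {counts['n_trigger_by_month2']}/10")
    print(f"-> {outdir / 'responder_counts.json'}")


if __name__ == "__main__":
    main()
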