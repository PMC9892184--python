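"""Generate the synthetic study cohort.

Writes the full dataset (including the per-beat streams) under scratch/
and the compact tables (session index, measurement tables, PK profiles,
ground truth) under results/synthetic/.
"""

import shutil

from common import RESULTS, SCRATCH, STUDY_CONFIG

from cavbmonkey.synthetic import generate_cohort


def main() -> None:
    cohort = generate_cohort(STUDY_CONFIG)
    scratch_dir = SCRATCH / "synthetic"
    cohort.to_csv(scratch_dir)

    outdir = RESULTS / "synthetic"
    outdir.mkdir(parents=True, exist_ok=True)
    # beat streams and the per-event ground truth stay in scratch/ (large);
    # only the compact tables are published under results/
    for name in (
        "sessions.csv",
        "intervals.csv",
        "echo.csv",
        "neurohumoral.csv",
        "pk.csv",
        "config.json",
    ):
        shutil.copy(scratch_dir / name, outdir / name)

    n_sessions = len(cohort.sessions)
    n_beats = sum(len(s.beats) for s in cohort.sessions)
    n_tdp = sum(1 for s in cohort.sessions for e in s.ground_truth if e.kind == "tdp")
    susceptible = sorted(a for a, s in cohort.susceptibility.items() if s)
    print(f"cohort: {STUDY_CONFIG.n_animals} animals x {len(STUDY_CONFIG.months)} months "
          f"= {n_sessions} Holter sessions, {n_beats} beats")
    print(f"TdP-susceptible animals (seed {STUDY_CONFIG.seed}): {susceptible}")
    print(f"ground-truth TdP episodes: {n_tdp}")
    print(f"beat streams in {scratch_dir}, tables in {outdir}")


if __name__ == "__main__":
    main()
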