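"""Nonparametric statistics over the synthetic longitudinal tables.

Friedman + Dunn on the conscious QT trajectory (each month vs pre-block),
Wilcoxon signed-rank on the pre-block vs 1-month pairs, Mann-Whitney U
between TdP-susceptible and non-susceptible animals, the fold-change
flags of the packaged expression table, and physiological range checks
for the neurohumoral factors.
"""

import json

from common import RESULTS, STUDY_CONFIG

from cavbmonkey.scoring import _fixture
from cavbmonkey.stats import (
    flag_fold_table,
    friedman_dunn,
    mann_whitney_u,
    range_check,
    wilcoxon_signed_rank,
)
from cavbmonkey.synthetic import DEFAULT_TRAJECTORIES, generate_cohort


def main() -> None:
    cohort = generate_cohort(STUDY_CONFIG)
    outdir = RESULTS / "stats"
    outdir.mkdir(parents=True, exist_ok=True)
    summary = {}

    conscious = cohort.intervals[cohort.intervals["state"] == "conscious"]
    grid = conscious.pivot_table(index="animal", columns="month", values="qt_ms")

    fr = friedman_dunn(grid, reference=-1)
    summary["friedman_qt"] = {"chi2": fr.statistic, "p": fr.pvalue, "n": fr.n, "k": fr.k}
    sig = fr.comparisons[fr.comparisons["significant"]]["timepoint"].tolist()
    print(f"Friedman on conscious QT: chi2 = {fr.statistic:.1f}, p = {fr.pvalue:.2g}")
    print(f"  Dunn vs pre-block significant at months: {sig}")

    w, p_w = wilcoxon_signed_rank(grid[-1].to_numpy(), grid[1].to_numpy())
    summary["wilcoxon_qt_pre_vs_1mo"] = {"W": w, "p": p_w}
    print(f"Wilcoxon QT pre vs 1 month: W = {w}, p = {p_w:.4f}")

    susceptible = [a for a, s in cohort.susceptibility.items() if s]
    resistant = [a for a, s in cohort.susceptibility.items() if not s]
    qt1 = grid[1]
    u, p_u = mann_whitney_u(qt1.loc[susceptible], qt1.loc[resistant])
    summary["mannwhitney_qt_1mo_by_susceptibility"] = {"U": u, "p": p_u}
    print(f"Mann-Whitney QT at 1 month, susceptible ({len(susceptible)}) vs "
          f"resistant ({len(resistant)}): U = {u}, p = {p_u:.4f}")
    print("  (the generator gives both groups the same QT law, so this "
          "comparison should usually be null)")

    folds = flag_fold_table(_fixture("table4_fold_changes.csv"))
    folds.to_csv(outdir / "fold_change_flags.csv", index=False)
    flagged = folds[folds["flagged"]]
    print(f"expression fold changes flagged (>=2 or <=0.5): {len(flagged)} "
          f"of {len(folds)} entries")

    aldo = cohort.neurohumoral.groupby("month")["aldosterone"].mean()
    lo, hi = DEFAULT_TRAJECTORIES["aldosterone:conscious"].physiological_range
    checks = {int(m): range_check(v, lo, hi) for m, v in aldo.items()}
    summary["aldosterone_range_checks"] = checks
    n_out = sum(1 for v in checks.values() if v != "within")
    print(f"aldosterone monthly means outside the {lo}-{hi} ng/dL "
          f"physiological range: {n_out}/{len(checks)} months")

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    print(f"-> {outdir}")


if __name__ == "__main__":
    main()
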