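# Methods

This note documents the models, operational definitions, parameter choices
and numerical conventions of the `cavbmonkey` package, and what its
synthetic data do and do not establish about real recordings.

## The model system

Radiofrequency ablation of the atrioventricular (AV) node leaves the
ventricles paced by a slow idioventricular escape rhythm. In the cynomolgus
monkey the conscious rate falls from a (stress-elevated) sinus rate of about
231 beats/min to about 111 beats/min, and to about 52 beats/min under
ketamine/xylazine anesthesia. Chronic bradycardia-driven volume load then
remodels the heart — dilation, hypertrophy, interstitial fibrosis, reduced
repolarization reserve — until an I_Kr blocker (10 mg/kg oral *dl*-sotalol
in the study design emulated here) can trigger torsade de pointes (TdP).
The package's job is the quantitative side of such a study: classifying and
scoring the arrhythmias, deriving the remodeling indices, summarising the
pharmacokinetics, and running the nonparametric statistics.

## Holter event classification

A beat stream is a sorted table `(t, label, morphology, qt_ms)`; waveform
delineation is out of scope, so morphology is a signed scalar standing in
for QRS polarity/axis and `qt_ms` is accepted as given.

* **Segmentation.** Maximal runs of consecutive `ectopic` beats; every
  ectopic beat belongs to exactly one segment, so beat counts are conserved.
* **Classification.** 1 beat → `single_pvb`; 2–4 beats → `run`; ≥ 6 beats
  that are polymorphic *and* preceded by QT prolongation → `tdp`. Five-beat
  segments, and longer segments failing either TdP criterion, are non-TdP
  ventricular tachycardias recorded as `run` with the beat count preserved
  (the ≥6-beat TdP definition deliberately excludes them from TdP counts).
* **Polymorphism proxy.** ≥ 2 sign changes of the morphology scalar within
  the episode. The generator encodes "twisting QRS" as alternating-sign
  morphology, so the proxy is exact on synthetic data; on real annotations
  it inherits whatever axis/polarity measure is mapped onto the scalar.
* **QT prolongation before onset.** The mean per-beat QT in the 60 s before
  episode onset must exceed the session's pre-dose baseline mean by more
  than 10%. The defining criterion is qualitative ("QT prolongation prior
  to onset"); the +10%/60 s operationalization is this package's choice and
  both knobs are arguments.
* **Counting window.** Half-open `[dose + 1 h, dose + 3 h)` by episode
  onset, approximating the absorption peak of an oral dose given ~2 h into
  the recording; half-openness prevents double counting at the boundaries.
  Enlarging the window can only add events.
* **Spontaneous termination.** An episode is terminated iff a non-ectopic
  beat follows its last beat; episodes running to the end of the record are
  not. The 15-s figure often quoted for self-terminating TdP is a reporting
  cutoff, not part of the flag.

## Arrhythmic score

Score = mean of the three largest per-event severities in the window,
padding with zeros (k < 3 events ⇒ sum/3 exactly). Severity ties are broken
by onset for reporting order only; the value is permutation-invariant and
monotone in each severity. The severity table of the canine scoring system
the study adapted is not published, so the default here is an explicit
reconstruction: single ectopic beat = 1; runs of 2/3/4 beats = 3/4/5; TdP =
its beat count; ≥5-beat non-TdP tachycardia = 5 (the largest non-TdP
severity). This reproduces the universal pre-block cell value 0.3 (one
single beat) and the 3–5 score range of sessions with ≥3 run-sets, and is
fully configurable (`ScoreTable`). Cells recorded as n/r or n/a propagate
as missing, never as 0. Responder grouping: "TdP ≥3" vs "TdP 0–1"; a total
of exactly 2 has no defined group and raises.

## Remodeling indices

Teichholz volume `V = 7.0/(2.4+LVID)·LVID³` with LVID in **cm** (tables
print mm; a guard rejects cm-field values > 15, which are almost certainly
mm). SV = EDV − ESV, EF% = SV/EDV·100, LV wall mass
`[(IVSd+LVIDd+LVPWd)³ − LVIDd³]·1.05` g, CTR% = cardiac/thoracic
diameter·100. CO = SV·rate/1000 L/min is a reconstruction — the source
design reports SV, rate and CO but not the operation (the published basal
SV 4.98 mL and CO 0.64 L/min imply ~128 beats/min at the echo session).
Evaluating the nonlinear Teichholz chain at the cohort-mean diameters gives
SV 5.00 mL / EF 56.1% against published means of 4.98 / 55.7 — the ~0.5%
residual is the mean-of-a-nonlinear-function effect, since the study
averaged per-animal values.

Rate corrections: Bazett QTcB = QT/RR^0.5 (conscious), Fridericia
QTcF = QT/RR^0.33 (anesthetized), RR in s. The Fridericia exponent is
stored as the conventional printed 0.33, not 1/3 (the difference is < 0.5%
over RR 0.3–1.2 s). Corrections are applied per animal and then averaged,
matching the study's convention; hence cohort-level checks use ~1%
tolerances while row-level arithmetic is exact. The published 1-month QTcB
(304 ms) is not reproducible from the published QT/rate means alone
(319.6 ms) because the per-animal data are unpublished; no guess is made.
State deltas are signed as the study phrases them: rate and blood pressure
as decreases under anesthesia, interval changes as prolongations.

## Effective size of the heart

`I = ∛(LV wall mass) × TdP frequency` (mass in g, frequency in Hz), i.e.
cube-root size divided by the rotation period. The abstract-style phrasing
"∛mass / wavelength" is dimensionally different; the published species
values (monkey 4.5–11.2, dog 21.1–25.3, human 17.2–25.4, rabbit 4.6–9.2
from masses 11.4/75.4/179.3/3.6 g and frequencies 2–5/5–6/3–4.5/3–6 Hz)
are reproduced only by the frequency form, which is therefore implemented.
Two published bounds deviate slightly from the formula: the human lower
bound prints 17.2 but computes 16.9, and the monkey upper bound prints 11.2
but computes 11.25 (→ 11.3 under half-up rounding); both are asserted as
small discrepancies rather than forced. Report rounding is decimal half-up
to 1 decimal. Termination propensity compares a species' range to a
reference threshold (default 17.2, the bottom of the dog/human band):
entirely below → self-terminating-like, entirely at/above →
degenerating-like, straddling → indeterminate.

## Pharmacokinetics

NCA is deliberately minimal for 4-point profiles: Cmax and Tmax from the
observed samples (earliest on ties) and linear-trapezoid AUC over the
observed span (1–8 h) with **no** extrapolation to t = 0 or infinity — the
study design reports AUC from four samples without stating any
back-extrapolation, so none is invented; the synthetic sampled AUC
(~18 µg·h/mL) is accordingly below the model's full AUC (21).

The synthetic model is one-compartment first-order absorption,
`C(t) = D·ka/(ka−ke)·(e^(−ke·t) − e^(−ka·t))`. Defaults ke = 0.51 /h,
ka = 0.755 /h, D = 10.71 µg/mL were solved from the published 1-month
summary via Cmax = D·e^(−ke·Tmax), AUC∞ = D/ke and
Tmax = ln(ka/ke)/(ka−ke), giving Tmax 1.60 h, AUC∞ 21 µg·h/mL and a
sparse-sampled Cmax of 4.61 µg/mL (within the expected sparse-sampling
bias of the published 4.74). `ka = ke` is rejected rather than handled by
the limiting form. The least-squares fit reports the absorption-dominant
labelling of the flip-flop-symmetric parameter pair.

## Statistics

All tests two-sided at p < 0.05; listwise deletion of animals with missing
cells within each test (the study's n shrinks from 10 to 8 over time).

* **Friedman + Dunn.** Chi-square on within-animal ranks (scipy, with tie
  correction; a fully tied grid is returned as statistic 0). Dunn's test
  against the reference timepoint uses z = (R̄_i − R̄_ref)/√(k(k+1)/(6n))
  with Bonferroni adjustment over the comparisons actually made — the
  adjustment variant is unstated in the source design, so plain Bonferroni
  is used and documented.
* **Wilcoxon signed-rank.** Zero differences dropped; exact distribution
  for n ≤ 25 untied differences, normal approximation otherwise (scipy
  backend; the exact mode is validated in-tree against full 2^n sign
  enumeration).
* **Mann–Whitney U.** U counts pairs with a > b plus half the ties. For
  pooled n ≤ 12 (the study's 4-vs-6 grouping) the two-sided p is exact by
  complete enumeration of labelings, counting those at least as deviant
  from n_a·n_b/2 — correct under ties, where the textbook no-tie exact
  distribution is not. Larger samples use the tie-corrected normal
  approximation.
* **Fold changes.** Reported to 2 decimals (half-up); the ≥2 / ≤0.5 flag is
  applied to the *rounded* value so a fold printing as exactly 2.00 is
  flagged, matching the published expression table.
* **Range checks** are boundary-inclusive.

## Synthetic cohort generator

The generator's defaults are the study conditions: 10 animals; challenge
months pre-block (coded −1) and 1–10, 12, 13, 15; dose 2 h into a 24-h
recording; sinus/escape rates 231/111 (conscious) and 52 (anesthetized)
beats/min; TdP episodes of ≥6 beats at 2–5 Hz lasting ≤15 s; 40% of
animals TdP-prone (4/10 reached ≥3 TdP).

* **Rhythm.** Jittered regular trains (3% interval CV at `noise_scale` 1;
  exactly regular when noise-free). Ectopic events are placed in the
  counting window with ≥25-s separation; base beats within ±0.3 s of an
  episode are removed so each episode forms one maximal ectopic segment.
  Singles and runs carry constant negative morphology (monomorphic), TdP
  beats alternate sign. Pre-block sessions contain exactly one single
  ectopic beat in the window — the origin of the universal 0.3 pre-block
  score. Post-block sessions draw Poisson singles/runs (4 events/h in the
  window), a sparse pre-dose background (0.05/h), and, in susceptible
  animals, Poisson(1) TdP episodes per session.
* **QT.** Per-beat QT = state baseline (167 ms sinus, 235 ms escape)
  × a piecewise-linear drug effect (ramp to +20% over the first post-dose
  hour, plateau to hour 3, washout by hour 6) × 1% beat noise. The +20%
  peak clears the classifier's +10% criterion throughout the window.
* **Measurement tables.** Each variable follows
  `value = mean_m · exp(σ_m(ρ·z_a + √(1−ρ²)·z_am) − σ_m²/2)` with
  σ_m = √ln(1+cv_m²), cv_m = sd_m/mean_m and sd = s.e.m.·√n from the
  published mean ± s.e.m. (n = 10 through 7 months, 8 after). The lognormal
  keeps positive physiology positive, hits the target mean and s.d.
  exactly, and the shared per-animal z_a (ρ = 0.5) gives paired tests real
  within-animal correlation — the correlation structure is a modeling
  choice, as none is published. Anchors between the published pre-block and
  1-month values are interpolated linearly toward 15-month values chosen to
  follow the reported qualitative trends. Cross-variable correlations are
  not modeled; where a draw would violate LVIDs < LVIDd the systolic value
  is capped at 0.95·LVIDd.
* **Reproducibility.** Every (purpose, animal, month) tuple seeds its own
  child stream of the root seed, so identical configs are byte-identical
  and adding an animal never perturbs the others.

What passing tests show — and don't. The classifier recovers the
generator's ground truth exactly on noise-free streams because generator
and classifier share the operational event definitions; this validates the
logic, not robustness to annotation error, QT-measurement difficulty during
bradycardic escape rhythm, or morphology proxies on real leads. Likewise
the measurement tables reproduce published first and second moments, not
real cross-variable physiology.

## Problem sizes

The analysis drivers and the acceptance run use 6-h recordings (dose at
2 h, so the full counting window plus pre-dose baseline are contained) and
months through 7 plus 15 — about 4 million synthetic beats per cohort —
which this package treats as its standard desk-scale configuration; the
generator's 24-h default remains available. The Monte-Carlo checks use 200
replicate cohorts (susceptibility binomial law) and 1000 replicate
trajectories (s.e.m. calibration within 10%).

## Known limitations

* The severity table is a reconstruction; TdP-containing published score
  cells (13.0, 26.3, 44.0, …) cannot be reproduced without the unpublished
  per-episode beat counts, and are not attempted.
* Published per-month significance patterns are likewise out of reach
  without per-animal raw data; the statistics are validated against
  enumeration oracles instead.
* Beat streams are annotation-level; no waveform synthesis, no
  ventricular-fibrillation discrimination (the model species shows none).
* PK is racemate-level, one-compartment, and sampled at the study's four
  time points; enantiomer kinetics and assay chemistry are out of scope.
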