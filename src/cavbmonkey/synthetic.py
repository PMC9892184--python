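"""Synthetic study-cohort generator.

Emulates the data structure of a chronic atrioventricular (AV) block
monkey proarrhythmia study: monthly 24-h Holter challenge sessions with an
oral IKr-blocker dose, longitudinal ECG-interval / echocardiographic /
neurohumoral measurement tables, and sparse plasma concentration-time
profiles.  Everything downstream (event classification, scoring, interval
and echo arithmetic, NCA, nonparametric statistics) is testable against
the generator's stored ground truth without any external data.

Rhythm calibration follows the published cohort means: conscious sinus
rate ~231 bpm before block, conscious idioventricular escape ~111 bpm and
anesthetised escape ~52 bpm after block.  Drug-triggered ectopy is
confined to a 1-3 h post-dose window (around Tmax); torsade-de-pointes
episodes have >= 6 polymorphic beats at 2-5 Hz and last at most 15 s, the
published envelope of spontaneously terminating episodes.  Measurement
noise is derived from printed s.e.m. values (s.d. = s.e.m. x sqrt(n)) with
a lognormal per-animal random effect so that paired longitudinal tests are
meaningful.

Reproducibility: one root seed; every (animal, month, purpose) draws from
its own child stream, so adding an animal or month never perturbs the
others, and identical configs yield byte-identical output.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import pk as pkmod
from .echo import derive_echo
from .holter import ArrhythmiaEvent, DEFAULT_WINDOW_S
from .intervals import derive_intervals

#: challenge schedule (months after block; -1 encodes the pre-block week)
CHALLENGE_MONTHS = (-1, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 13, 15)

# child-stream tags
_TAG_SUSCEPTIBILITY = 1
_TAG_BEATS = 2
_TAG_TRAJ_ANIMAL = 3
_TAG_TRAJ_RESID = 4
_TAG_PK = 5


def _rng(seed: int, *keys: int) -> np.random.Generator:
    """Child generator for a (seed, purpose, animal, ...) key tuple."""
    return np.random.default_rng(np.random.SeedSequence([int(seed)] + [int(k) & 0xFFFFFFFF for k in keys]))


def _var_key(name: str) -> int:
    return zlib.crc32(name.encode())


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition parameters of the synthetic cohort."""

    n_animals: int = 10
    months: tuple = CHALLENGE_MONTHS
    seed: int = 0
    conscious_sinus_rate: float = 231.0
    conscious_escape_rate: float = 111.0
    anesthetized_escape_rate: float = 52.0
    #: fraction of animals carrying high TdP susceptibility (4/10 reached
    #: >=3 TdP in the study)
    tdp_prone_fraction: float = 0.4
    #: drug-triggered ectopic events (singles/runs) per hour inside the
    #: 1-3 h post-dose window
    ectopy_rate_per_h: float = 4.0
    #: mean TdP episodes per susceptible post-block session
    tdp_episode_rate: float = 1.0
    tdp_beat_frequency_hz: tuple = (2.0, 5.0)
    max_tdp_duration_s: float = 15.0
    #: spontaneous single ectopics per hour outside the window
    background_ectopy_rate_per_h: float = 0.05
    recording_duration_h: float = 24.0
    dose_time_h: float = 2.0
    #: pre-block sinus and post-block escape per-beat QT baselines (ms)
    sinus_qt_ms: float = 167.0
    escape_qt_ms: float = 235.0
    #: peak fractional QT prolongation after the dose
    drug_qt_peak_fraction: float = 0.20
    #: global multiplier on all stochastic spreads; 0 -> noise-free streams
    noise_scale: float = 1.0
    #: share of measurement s.d. carried by the per-animal random effect
    animal_effect_rho: float = 0.5

    def __post_init__(self) -> None:
        if self.n_animals <= 0:
            raise ValueError("n_animals must be positive")
        if len(self.months) == 0:
            raise ValueError("month list must not be empty")
        if any(b <= a for a, b in zip(self.months, self.months[1:])):
            raise ValueError("months must be strictly increasing")
        if not 0.0 <= self.tdp_prone_fraction <= 1.0:
            raise ValueError("tdp_prone_fraction must be in [0, 1]")
        for name in (
            "conscious_sinus_rate",
            "conscious_escape_rate",
            "anesthetized_escape_rate",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.ectopy_rate_per_h < 0 or self.tdp_episode_rate < 0:
            raise ValueError("event rates must be non-negative")
        lo, hi = self.tdp_beat_frequency_hz
        if not 0 < lo <= hi:
            raise ValueError("TdP frequency range must satisfy 0 < low <= high")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be non-negative")
        window_end_h = self.dose_time_h + DEFAULT_WINDOW_S[1] / 3600.0
        if window_end_h > self.recording_duration_h:
            raise ValueError("challenge window extends past the recording")


@dataclass
class SessionRecord:
    """One animal-month Holter challenge session with its ground truth."""

    animal: int
    month: int
    rate_bpm: float
    dose_time_s: float
    duration_s: float
    beats: pd.DataFrame
    ground_truth: list[ArrhythmiaEvent]

    @property
    def windowed_truth(self) -> list[ArrhythmiaEvent]:
        lo = self.dose_time_s + DEFAULT_WINDOW_S[0]
        hi = self.dose_time_s + DEFAULT_WINDOW_S[1]
        return [e for e in self.ground_truth if lo <= e.onset_t < hi]


# ----------------------------------------------------------------- rhythm


def beat_train(
    rate_bpm: float,
    duration_s: float,
    rng: np.random.Generator,
    jitter_frac: float = 0.0,
) -> np.ndarray:
    """Times of a (possibly jittered) regular rhythm over ``duration_s``."""
    if rate_bpm <= 0:
        raise ValueError("rate must be positive")
    ibi = 60.0 / rate_bpm
    n = int(duration_s / ibi * 1.2) + 10
    intervals = np.full(n, ibi)
    if jitter_frac > 0:
        intervals = intervals * (1.0 + jitter_frac * rng.standard_normal(n))
        intervals = np.clip(intervals, 0.2 * ibi, 3.0 * ibi)
    t = 0.5 * ibi + np.cumsum(intervals) - intervals[0]
    return t[t < duration_s]


def _qt_effect(t: np.ndarray, dose_s: float, peak: float) -> np.ndarray:
    """Fractional QT prolongation vs time: ramps over the first post-dose
    hour, plateaus through hour 3, washes out by hour 6."""
    xp = [dose_s, dose_s + 3600.0, dose_s + 3 * 3600.0, dose_s + 6 * 3600.0]
    fp = [0.0, peak, peak, 0.0]
    return np.interp(t, xp, fp, left=0.0, right=0.0)


def _place_onsets(
    rng: np.random.Generator, n: int, lo: float, hi: float, min_gap: float
) -> np.ndarray:
    if n == 0:
        return np.empty(0)
    for _ in range(200):
        cand = np.sort(rng.uniform(lo, hi, size=n))
        if n < 2 or float(np.min(np.diff(cand))) >= min_gap:
            return cand
    # saturated window: fall back to evenly spaced slots
    return lo + (np.arange(n) + 0.5) * (hi - lo) / n


def generate_beat_stream(
    animal: int,
    month: int,
    config: CohortConfig,
    susceptible: bool,
) -> SessionRecord:
    """One 24-h (by default) beat-annotation stream plus its ground truth.

    Pre-block sessions carry sinus rhythm and exactly one single ectopic
    beat inside the counting window (the source of the universal 0.3
    pre-block score); post-block sessions carry escape rhythm,
    drug-triggered singles and runs inside the window, a sparse background
    of singles before the dose, and — in susceptible animals — TdP
    episodes of >= 6 polymorphic beats lasting at most the configured cap.
    """
    rng = _rng(config.seed, _TAG_BEATS, animal, month + 1)
    pre_block = month < 0
    rate = config.conscious_sinus_rate if pre_block else config.conscious_escape_rate
    base_label = "sinus" if pre_block else "escape"
    baseline_qt = config.sinus_qt_ms if pre_block else config.escape_qt_ms
    duration_s = config.recording_duration_h * 3600.0
    dose_s = config.dose_time_h * 3600.0
    win_lo, win_hi = dose_s + DEFAULT_WINDOW_S[0], dose_s + DEFAULT_WINDOW_S[1]

    base_t = beat_train(rate, duration_s, rng, 0.03 * config.noise_scale)

    # --- decide events ---------------------------------------------------
    specs: list[tuple[str, dict]] = []
    if pre_block:
        n_single, n_run, n_tdp = 1, 0, 0
    else:
        window_h = (win_hi - win_lo) / 3600.0
        n_ect = int(rng.poisson(config.ectopy_rate_per_h * window_h))
        n_single = int(np.sum(rng.random(n_ect) < 0.4)) if n_ect else 0
        n_run = n_ect - n_single
        n_tdp = int(rng.poisson(config.tdp_episode_rate)) if susceptible else 0
    margin = config.max_tdp_duration_s + 5.0
    onsets = _place_onsets(
        rng, n_single + n_run + n_tdp, win_lo + 1.0, win_hi - margin, margin + 10.0
    )
    kinds = ["single"] * n_single + ["run"] * n_run + ["tdp"] * n_tdp
    rng.shuffle(kinds)
    for kind, onset in zip(kinds, onsets):
        specs.append((kind, {"onset": float(onset)}))
    if not pre_block and config.background_ectopy_rate_per_h > 0 and dose_s > 1800.0:
        n_bg = int(
            rng.poisson(config.background_ectopy_rate_per_h * (dose_s - 1200.0) / 3600.0)
        )
        for onset in _place_onsets(rng, n_bg, 600.0, dose_s - 600.0, 30.0):
            specs.append(("single", {"onset": float(onset)}))
    specs.sort(key=lambda s: s[1]["onset"])

    # --- realise event beats ---------------------------------------------
    ev_times: list[np.ndarray] = []
    ev_morphs: list[np.ndarray] = []
    truth: list[ArrhythmiaEvent] = []
    f_lo, f_hi = config.tdp_beat_frequency_hz
    for kind, spec in specs:
        onset = spec["onset"]
        if kind == "single":
            times = np.array([onset])
            morph = np.array([-(0.5 + 0.4 * rng.random())])
        elif kind == "run":
            length = int(rng.integers(2, 5))
            times = onset + 0.3 * np.arange(length)
            morph = np.full(length, -(0.5 + 0.4 * rng.random()))
        else:  # tdp
            freq = float(rng.uniform(f_lo, f_hi))
            n_max = min(20, int(config.max_tdp_duration_s * freq) + 1)
            n_beats = int(rng.integers(6, n_max + 1))
            times = onset + np.arange(n_beats) / freq
            amp = 0.6 + 0.3 * rng.random(n_beats)
            morph = amp * (-1.0) ** np.arange(n_beats)
        ev_times.append(times)
        ev_morphs.append(morph)
        in_window = win_lo <= onset < win_hi
        truth.append(
            ArrhythmiaEvent(
                kind={"single": "single_pvb", "run": "run", "tdp": "tdp"}[kind],
                onset_t=float(times[0]),
                n_beats=len(times),
                duration_s=float(times[-1] - times[0]),
                polymorphic=(kind == "tdp"),
                qt_prolonged_before_onset=bool(in_window),
                spontaneously_terminated=True,
            )
        )

    # --- merge with the base rhythm --------------------------------------
    keep = np.ones(base_t.size, dtype=bool)
    for times in ev_times:
        keep &= ~((base_t >= times[0] - 0.3) & (base_t <= times[-1] + 0.3))
    base_t = base_t[keep]
    if config.noise_scale > 0:
        base_morph = 1.0 + 0.05 * config.noise_scale * rng.standard_normal(base_t.size)
        base_morph = np.clip(base_morph, 0.1, None)
    else:
        base_morph = np.ones(base_t.size)

    t = np.concatenate([base_t] + ev_times) if ev_times else base_t
    morph = np.concatenate([base_morph] + ev_morphs) if ev_morphs else base_morph
    label = np.concatenate(
        [np.full(base_t.size, base_label)]
        + [np.full(x.size, "ectopic") for x in ev_times]
    )
    order = np.argsort(t, kind="stable")
    t, morph, label = t[order], morph[order], label[order]

    qt = baseline_qt * (1.0 + _qt_effect(t, dose_s, config.drug_qt_peak_fraction))
    if config.noise_scale > 0:
        qt = qt * (1.0 + 0.01 * config.noise_scale * rng.standard_normal(t.size))

    beats = pd.DataFrame({"t": t, "label": label, "morphology": morph, "qt_ms": qt})
    return SessionRecord(
        animal=animal,
        month=month,
        rate_bpm=rate,
        dose_time_s=dose_s,
        duration_s=duration_s,
        beats=beats,
        ground_truth=truth,
    )


def assign_susceptibility(config: CohortConfig) -> dict[int, bool]:
    """Independent Bernoulli(tdp_prone_fraction) per animal, keyed by the
    animal's own child stream (stable under cohort-size changes)."""
    out = {}
    for animal in range(1, config.n_animals + 1):
        r = _rng(config.seed, _TAG_SUSCEPTIBILITY, animal)
        out[animal] = bool(r.random() < config.tdp_prone_fraction)
    return out


# ------------------------------------------------------------ trajectories


@dataclass(frozen=True)
class TrajectorySpec:
    """Per-month mean / s.e.m. / n calibration of one longitudinal variable."""

    variable: str
    months: tuple
    mean: tuple
    sem: tuple
    n: tuple
    state: str = "conscious"
    physiological_range: tuple | None = None

    def __post_init__(self) -> None:
        if not len(self.months) == len(self.mean) == len(self.sem) == len(self.n):
            raise ValueError("months/mean/sem/n must have equal length")
        if any(s < 0 for s in self.sem):
            raise ValueError("s.e.m. must be non-negative")
        if any(m <= 0 for m in self.mean):
            raise ValueError("trajectory means must be positive (lognormal model)")
        if self.physiological_range is not None:
            lo, hi = self.physiological_range
            if not lo < hi:
                raise ValueError("physiological range requires low < high")


def generate_trajectory(
    spec: TrajectorySpec,
    n_animals: int,
    seed: int,
    *,
    rho: float = 0.5,
    noise_scale: float = 1.0,
) -> pd.DataFrame:
    """Per-animal longitudinal values for one variable.

    Model: value = mean_m * exp(sigma_m*(rho*z_a + sqrt(1-rho^2)*z_am)
    - sigma_m^2/2) with sigma_m = sqrt(ln(1 + cv_m^2)) and
    cv_m = s.d._m / mean_m, s.d. = s.e.m. * sqrt(n).  The lognormal keeps
    positive physiology positive, reproduces the target mean exactly and
    the target s.d. exactly, and the shared z_a induces the within-animal
    correlation paired tests rely on.
    """
    months = np.asarray(spec.months)
    mean = np.asarray(spec.mean, dtype=float)
    sd = np.asarray(spec.sem, dtype=float) * np.sqrt(np.asarray(spec.n, dtype=float))
    sd = sd * noise_scale
    cv = np.divide(sd, mean)
    sigma = np.sqrt(np.log1p(cv**2))
    vkey = _var_key(spec.variable + ":" + spec.state)
    rows = []
    for animal in range(1, n_animals + 1):
        z_a = _rng(seed, _TAG_TRAJ_ANIMAL, animal, vkey).standard_normal()
        z_m = _rng(seed, _TAG_TRAJ_RESID, animal, vkey).standard_normal(months.size)
        z = rho * z_a + np.sqrt(1.0 - rho**2) * z_m
        values = mean * np.exp(sigma * z - 0.5 * sigma**2)
        for mth, v in zip(months, values):
            rows.append(
                {
                    "animal": animal,
                    "month": int(mth),
                    "state": spec.state,
                    "variable": spec.variable,
                    "value": float(v),
                }
            )
    return pd.DataFrame(rows)


def _ramp(pre: float, at1: float, at15: float, months: Sequence[int]) -> tuple:
    """Anchor a trajectory at the pre-block value, the 1-month value and a
    15-month value, interpolating linearly in between."""
    out = []
    for m in months:
        if m < 0:
            out.append(pre)
        elif m <= 1:
            out.append(at1)
        else:
            out.append(at1 + (at15 - at1) * (m - 1) / 14.0)
    return tuple(out)


_ECG_MONTHS = (-1, 1, 2, 3, 4, 5, 6, 7, 15)
_N_PER_MONTH = tuple(10 if m <= 7 else 8 for m in _ECG_MONTHS)
_ECHO_MONTHS = (-1, 0, 1, 2, 3, 4, 5, 6, 7, 15)
_N_ECHO = tuple(10 if m <= 7 else 8 for m in _ECHO_MONTHS)


def _spec(variable, state, pre, at1, at15, sem_pre, sem_post, months=_ECG_MONTHS, ns=None, rng_=None):
    ns = _N_PER_MONTH if ns is None else ns
    sems = tuple(sem_pre if m < 0 else sem_post for m in months)
    return TrajectorySpec(
        variable=variable,
        months=tuple(months),
        mean=_ramp(pre, at1, at15, months),
        sem=sems,
        n=ns,
        state=state,
        physiological_range=rng_,
    )


#: calibration of the longitudinal tables to the published cohort means
#: (pre-block and 1-month anchors; 15-month anchors follow the reported
#: qualitative trends)
DEFAULT_TRAJECTORIES: dict[str, TrajectorySpec] = {
    s.variable + ":" + s.state: s
    for s in [
        # conscious ECG / blood pressure
        _spec("ventricular_rate", "conscious", 231.0, 111.0, 106.0, 8.0, 19.0),
        _spec("sbp", "conscious", 120.0, 115.0, 112.0, 3.0, 4.0),
        _spec("dbp", "conscious", 65.0, 58.0, 57.0, 1.0, 3.0),
        _spec("qrs_ms", "conscious", 40.0, 46.0, 55.0, 1.0, 3.0),
        _spec("qt_ms", "conscious", 167.0, 235.0, 268.0, 5.0, 12.0),
        # anesthetised ECG / blood pressure
        _spec("ventricular_rate", "anesthetized", 91.0, 52.0, 51.0, 9.0, 3.0),
        _spec("sbp", "anesthetized", 84.0, 58.0, 57.0, 3.0, 6.0),
        _spec("dbp", "anesthetized", 44.0, 28.0, 28.0, 2.0, 3.0),
        _spec("qrs_ms", "anesthetized", 44.0, 45.0, 50.0, 1.0, 2.0),
        _spec("qt_ms", "anesthetized", 354.0, 383.0, 400.0, 23.0, 25.0),
        # echocardiography (mm; anesthetised), with the 0-month exam
        _spec("lvidd", "anesthetized", 17.4, 17.8, 19.5, 0.4, 0.5, _ECHO_MONTHS, _N_ECHO),
        _spec("lvids", "anesthetized", 12.7, 12.8, 13.3, 0.5, 0.5, _ECHO_MONTHS, _N_ECHO),
        _spec("lvpwd", "anesthetized", 2.4, 2.4, 2.8, 0.1, 0.1, _ECHO_MONTHS, _N_ECHO),
        _spec("ivsd", "anesthetized", 2.4, 2.4, 2.7, 0.1, 0.1, _ECHO_MONTHS, _N_ECHO),
        _spec("lad", "anesthetized", 9.7, 10.6, 10.4, 0.7, 0.7, _ECHO_MONTHS, _N_ECHO),
        _spec("echo_rate", "anesthetized", 128.0, 60.0, 62.0, 6.0, 4.0, _ECHO_MONTHS, _N_ECHO),
        _spec("ctr_pct", "anesthetized", 52.0, 56.5, 58.0, 1.2, 1.5, _ECHO_MONTHS, _N_ECHO),
        # neurohumoral factors (conscious morning samples)
        _spec("dopamine", "conscious", 0.013, 0.022, 0.028, 0.002, 0.004, rng_=(0.0001, 0.05)),
        _spec("noradrenaline", "conscious", 4.45, 4.6, 4.5, 1.30, 1.2, rng_=(2.6, 14.28)),
        _spec("adrenaline", "conscious", 7.20, 6.0, 5.5, 1.76, 1.5, rng_=(0.6, 5.36)),
        _spec("renin_activity", "conscious", 9.17, 10.0, 11.5, 1.53, 1.6, rng_=(6.0, 14.0)),
        _spec("angiotensin_ii", "conscious", 17.1, 21.0, 46.0, 1.8, 3.5, rng_=(12.0, 35.0)),
        _spec("aldosterone", "conscious", 25.3, 27.0, 41.0, 4.4, 4.5, rng_=(10.0, 20.0)),
        _spec("anp", "conscious", 7.23, 14.0, 21.0, 0.80, 2.5, rng_=(2.0, 44.0)),
        _spec("bnp", "conscious", 11.0, 10.0, 9.0, 1.3, 1.3, rng_=(2.0, 45.0)),
    ]
}

_INTERVAL_VARS = ("ventricular_rate", "sbp", "dbp", "qrs_ms", "qt_ms")
_ECHO_VARS = ("lvidd", "lvids", "lvpwd", "ivsd", "lad", "echo_rate", "ctr_pct")
_NEURO_VARS = (
    "dopamine",
    "noradrenaline",
    "adrenaline",
    "renin_activity",
    "angiotensin_ii",
    "aldosterone",
    "anp",
    "bnp",
)


def _pivot(long: pd.DataFrame) -> pd.DataFrame:
    wide = (
        long.pivot_table(
            index=["animal", "month", "state"], columns="variable", values="value"
        )
        .reset_index()
        .rename_axis(None, axis=1)
    )
    return wide.sort_values(["state", "animal", "month"]).reset_index(drop=True)


# ----------------------------------------------------------------- cohort


@dataclass
class SyntheticCohort:
    config: CohortConfig
    susceptibility: dict[int, bool]
    sessions: list[SessionRecord]
    intervals: pd.DataFrame
    echo: pd.DataFrame
    neurohumoral: pd.DataFrame
    pk_profiles: list[pkmod.PKProfile]

    def session(self, animal: int, month: int) -> SessionRecord:
        for s in self.sessions:
            if s.animal == animal and s.month == month:
                return s
        raise KeyError((animal, month))

    def ground_truth_records(self) -> list[dict]:
        out = []
        for s in self.sessions:
            out.append(
                {
                    "animal": s.animal,
                    "month": s.month,
                    "events": [
                        {
                            "kind": e.kind,
                            "onset_t": e.onset_t,
                            "n_beats": e.n_beats,
                            "duration_s": e.duration_s,
                            "polymorphic": e.polymorphic,
                        }
                        for e in s.ground_truth
                    ],
                }
            )
        return out

    def to_csv(self, outdir: str | Path) -> None:
        """One CSV per table kind plus a ground-truth JSON and the config."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        idx = pd.DataFrame(
            [
                {
                    "animal": s.animal,
                    "month": s.month,
                    "rate_bpm": s.rate_bpm,
                    "dose_time_s": s.dose_time_s,
                    "duration_s": s.duration_s,
                    "n_beats": len(s.beats),
                    "susceptible": self.susceptibility[s.animal],
                }
                for s in self.sessions
            ]
        )
        idx.to_csv(outdir / "sessions.csv", index=False)
        beats = pd.concat(
            [s.beats.assign(animal=s.animal, month=s.month) for s in self.sessions],
            ignore_index=True,
        )
        beats.to_csv(outdir / "beats.csv", index=False)
        self.intervals.to_csv(outdir / "intervals.csv", index=False)
        self.echo.to_csv(outdir / "echo.csv", index=False)
        self.neurohumoral.to_csv(outdir / "neurohumoral.csv", index=False)
        pd.DataFrame(
            [
                {"animal": p.animal, "month": p.month, "t_h": t, "conc_ug_ml": c}
                for p in self.pk_profiles
                for t, c in zip(p.times_h, p.conc_ug_ml)
            ]
        ).to_csv(outdir / "pk.csv", index=False)
        with open(outdir / "ground_truth.json", "w") as fh:
            json.dump(self.ground_truth_records(), fh, indent=1)
        with open(outdir / "config.json", "w") as fh:
            json.dump(asdict(self.config), fh, indent=1, default=list)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Full synthetic dataset: Holter sessions with ground truth, interval /
    echo / neurohumoral tables, and PK profiles."""
    susceptibility = assign_susceptibility(config)
    sessions = [
        generate_beat_stream(animal, month, config, susceptibility[animal])
        for animal in range(1, config.n_animals + 1)
        for month in config.months
    ]

    def table(variables: Sequence[str], states=("conscious", "anesthetized")) -> pd.DataFrame:
        frames = []
        for key, spec in DEFAULT_TRAJECTORIES.items():
            if spec.variable in variables and spec.state in states:
                frames.append(
                    generate_trajectory(
                        spec,
                        config.n_animals,
                        config.seed,
                        rho=config.animal_effect_rho,
                        noise_scale=config.noise_scale,
                    )
                )
        return _pivot(pd.concat(frames, ignore_index=True))

    intervals = table(_INTERVAL_VARS)
    intervals = derive_intervals(intervals)

    echo_raw = table(_ECHO_VARS, states=("anesthetized",))
    # physiology guard: end-systolic never exceeds end-diastolic diameter
    bad = echo_raw["lvids"] >= echo_raw["lvidd"]
    echo_raw.loc[bad, "lvids"] = 0.95 * echo_raw.loc[bad, "lvidd"]
    echo = derive_echo(
        echo_raw.rename(columns={"echo_rate": "ventricular_rate"}), units="mm"
    )

    neuro = table(_NEURO_VARS, states=("conscious",))

    pk_profiles = []
    for animal in range(1, config.n_animals + 1):
        months_pk = [1] + ([7] if susceptibility[animal] else [])
        for month in months_pk:
            rng = _rng(config.seed, _TAG_PK, animal, month)
            pk_profiles.append(
                pkmod.simulate_oral_pk(
                    animal,
                    month,
                    cv_noise=0.25 * config.noise_scale,
                    rng=rng,
                )
            )

    return SyntheticCohort(
        config=config,
        susceptibility=susceptibility,
        sessions=sessions,
        intervals=intervals,
        echo=echo,
        neurohumoral=neuro,
        pk_profiles=pk_profiles,
    )
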