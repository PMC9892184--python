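"""Generator properties: determinism, rhythm rates, episode shape, noise
calibration, and conservation of beats between stream and ground truth."""

import numpy as np
import pandas as pd
import pytest

from cavbmonkey.synthetic import (
    CohortConfig,
    TrajectorySpec,
    assign_susceptibility,
    beat_train,
    generate_beat_stream,
    generate_cohort,
    generate_trajectory,
)


def _tiny_cfg(**kw):
    base = dict(
        n_animals=2,
        months=(-1, 1),
        seed=3,
        recording_duration_h=6.0,
        tdp_prone_fraction=1.0,
    )
    base.update(kw)
    return CohortConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"n_animals": 0},
            {"months": ()},
            {"months": (1, 1, 2)},
            {"months": (2, 1)},
            {"tdp_prone_fraction": 1.5},
            {"conscious_escape_rate": -1.0},
            {"recording_duration_h": 3.0},  # window would overrun the record
            {"tdp_beat_frequency_hz": (0.0, 5.0)},
        ],
    )
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValueError):
            _tiny_cfg(**kw)


class TestDeterminism:
    def test_identical_seed_identical_bytes(self, tmp_path):
        cfg = _tiny_cfg()
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_cohort(cfg).to_csv(d1)
        generate_cohort(cfg).to_csv(d2)
        for name in ("sessions", "beats", "intervals", "echo", "neurohumoral", "pk"):
            assert (d1 / f"{name}.csv").read_bytes() == (d2 / f"{name}.csv").read_bytes()
        assert (d1 / "ground_truth.json").read_bytes() == (
            d2 / "ground_truth.json"
        ).read_bytes()

    def test_adding_an_animal_preserves_existing_streams(self):
        small = generate_cohort(_tiny_cfg(n_animals=2))
        large = generate_cohort(_tiny_cfg(n_animals=3))
        s1 = small.session(1, 1).beats
        s2 = large.session(1, 1).beats
        pd.testing.assert_frame_equal(s1, s2)


class TestBeatStream:
    def test_pure_escape_rhythm_beat_count(self):
        rng = np.random.default_rng(0)
        t = beat_train(52.0, 60.0, rng, jitter_frac=0.0)
        assert abs(len(t) - 52) <= 1
        assert np.all(np.diff(t) > 0)

    def test_stream_sorted_and_labels_valid(self, small_cohort):
        for s in small_cohort.sessions:
            t = s.beats["t"].to_numpy()
            assert np.all(np.diff(t) > 0)
            assert set(s.beats["label"]) <= {"sinus", "escape", "ectopic"}

    def test_beats_conserved_between_stream_and_truth(self, small_cohort):
        for s in small_cohort.sessions:
            n_ect = int((s.beats["label"] == "ectopic").sum())
            assert n_ect == sum(e.n_beats for e in s.ground_truth)

    def test_tdp_episodes_shape(self, small_cohort):
        cfg = small_cohort.config
        tdps = [e for s in small_cohort.sessions for e in s.ground_truth if e.kind == "tdp"]
        assert tdps, "susceptible cohort must produce TdP episodes"
        for e in tdps:
            assert e.n_beats >= 6
            assert e.duration_s <= cfg.max_tdp_duration_s
            assert e.polymorphic

    def test_tdp_interbeat_intervals_match_frequency_range(self, small_cohort):
        lo, hi = small_cohort.config.tdp_beat_frequency_hz
        for s in small_cohort.sessions:
            beats = s.beats
            for e in s.ground_truth:
                if e.kind != "tdp":
                    continue
                seg = beats[
                    (beats["t"] >= e.onset_t)
                    & (beats["t"] <= e.onset_t + e.duration_s)
                    & (beats["label"] == "ectopic")
                ]
                ibis = np.diff(seg["t"].to_numpy())
                assert np.all(ibis >= 1.0 / hi - 1e-9)
                assert np.all(ibis <= 1.0 / lo + 1e-9)

    def test_ectopy_confined_to_window_except_background(self, small_cohort):
        for s in small_cohort.sessions:
            lo = s.dose_time_s + 3600.0
            hi = s.dose_time_s + 3 * 3600.0
            for e in s.ground_truth:
                in_window = lo <= e.onset_t < hi
                if not in_window:
                    assert e.kind == "single_pvb" and e.onset_t < s.dose_time_s

    def test_no_overlapping_episodes(self, small_cohort):
        for s in small_cohort.sessions:
            spans = sorted(
                (e.onset_t, e.onset_t + e.duration_s) for e in s.ground_truth
            )
            for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
                assert a1 < b0

    def test_preblock_session_holds_one_single_in_window(self, small_cohort):
        for animal in (1, 2):
            s = small_cohort.session(animal, -1)
            assert [e.kind for e in s.windowed_truth] == ["single_pvb"]
            assert set(s.beats["label"]) == {"sinus", "ectopic"}


class TestSusceptibility:
    def test_zero_fraction_means_no_tdp(self):
        cohort = generate_cohort(_tiny_cfg(tdp_prone_fraction=0.0))
        kinds = [e.kind for s in cohort.sessions for e in s.ground_truth]
        assert "tdp" not in kinds

    def test_fraction_matches_binomial_law(self):
        # 200 replicate mini-cohorts: one post-block month, high episode
        # rate so a susceptible animal almost surely shows >=1 TdP; a slow
        # escape rate keeps the streams small without touching the law
        fractions = []
        for seed in range(200):
            cfg = CohortConfig(
                n_animals=10,
                months=(1,),
                seed=seed,
                recording_duration_h=6.0,
                noise_scale=0.0,
                tdp_prone_fraction=0.4,
                tdp_episode_rate=5.0,
                conscious_escape_rate=30.0,
                ectopy_rate_per_h=0.5,
            )
            cohort = generate_cohort(cfg)
            with_tdp = sum(
                any(e.kind == "tdp" for e in s.ground_truth) for s in cohort.sessions
            )
            fractions.append(with_tdp / 10.0)
        mean = np.mean(fractions)
        # binomial s.e. of the grand mean ~ sqrt(.4*.6/2000) ~ 0.011
        assert abs(mean - 0.4) < 0.05


class TestTrajectories:
    SPEC = TrajectorySpec(
        variable="qt_ms",
        months=(-1, 1),
        mean=(167.0, 235.0),
        sem=(5.0, 12.0),
        n=(10, 10),
        state="conscious",
    )

    def test_sample_mean_near_spec_mean(self):
        df = generate_trajectory(self.SPEC, 10, seed=1)
        pre = df[df["month"] == -1]["value"]
        # 3 s.d.-of-the-mean band around the calibrated 167 ms
        assert abs(pre.mean() - 167.0) < 3 * 5.0 * np.sqrt(10) / np.sqrt(10)

    def test_zero_sem_gives_exact_mean(self):
        spec = TrajectorySpec("x", (1,), (42.0,), (0.0,), (10,))
        df = generate_trajectory(spec, 5, seed=0)
        assert np.allclose(df["value"], 42.0)

    def test_empirical_sem_matches_spec(self):
        monthly_means = {m: [] for m in self.SPEC.months}
        for seed in range(1000):
            df = generate_trajectory(self.SPEC, 10, seed=seed)
            for m in self.SPEC.months:
                monthly_means[m].append(df[df["month"] == m]["value"].mean())
        for m, sem in zip(self.SPEC.months, self.SPEC.sem):
            emp = np.std(monthly_means[m], ddof=1)
            assert emp == pytest.approx(sem, rel=0.10)

    def test_animal_random_effect_induces_correlation(self):
        values = {m: [] for m in self.SPEC.months}
        for seed in range(300):
            df = generate_trajectory(self.SPEC, 1, seed=seed, rho=0.7)
            for m in self.SPEC.months:
                values[m].append(df[df["month"] == m]["value"].iloc[0])
        r = np.corrcoef(values[-1], values[1])[0, 1]
        assert r > 0.2

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            TrajectorySpec("x", (1, 2), (1.0,), (0.1,), (10,))
        with pytest.raises(ValueError):
            TrajectorySpec("x", (1,), (1.0,), (-0.1,), (10,))


class TestCohortTables:
    def test_cohort_shape_and_derived_columns(self, noisy_cohort):
        cfg = noisy_cohort.config
        assert len(noisy_cohort.sessions) == cfg.n_animals * len(cfg.months)
        for col in ("jt_ms", "qtcb_ms", "qtcf_ms"):
            assert col in noisy_cohort.intervals
        for col in ("edv_ml", "sv_ml", "ef_pct", "lv_mass_g", "co_l_min"):
            assert col in noisy_cohort.echo
        assert (noisy_cohort.echo["lvids"] < noisy_cohort.echo["lvidd"]).all()
        assert noisy_cohort.echo["ef_pct"].between(0, 100).all()

    def test_susceptible_animals_get_late_pk_profile(self, noisy_cohort):
        months = {(p.animal, p.month) for p in noisy_cohort.pk_profiles}
        for animal, susc in noisy_cohort.susceptibility.items():
            assert (animal, 1) in months
            assert ((animal, 7) in months) == susc
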