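"""Generator-level behavior: profiles, single trials, staircases, sessions."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from changeofmind import (
    GameConfig,
    PopulationParams,
    StaircaseState,
    default_population,
    known_effect_population,
    sample_player_profiles,
    session_to_frame,
    simulate_choice_trial,
    simulate_cohort,
    simulate_session,
    simulate_stop_trial,
    staircase_update,
)
from changeofmind.simkit import Dist


class TestConfigValidation:
    def test_lava_split_must_sum(self):
        with pytest.raises(ValueError, match="lava split"):
            GameConfig(lava_match_split=(40, 40))

    @pytest.mark.parametrize("kwargs", [
        {"n_regular": -1},
        {"ssd_step": 0},
        {"go_success_target": 1.0},
        {"stop_target": 0.0},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GameConfig(**kwargs)

    def test_correlations_bounded(self):
        with pytest.raises(ValueError, match="continuity_flanker"):
            PopulationParams(continuity_flanker=1.5)

    def test_config_json_roundtrip(self):
        cfg = GameConfig(n_regular=10, n_mismatch=10, n_lava=4,
                         lava_match_split=(2, 2), n_ice=4)
        assert GameConfig.from_json(cfg.to_json()) == cfg

    def test_population_json_roundtrip(self):
        pop = default_population().replace(stop_share=0.5)
        assert PopulationParams.from_json(pop.to_json()) == pop


class TestProfileSampling:
    def test_zero_players_gives_empty_list(self):
        assert sample_player_profiles(default_population(), 0, seed=1) == []

    def test_degenerate_population_equals_means(self):
        pop = default_population()
        zeroed = {f: Dist(getattr(pop, f).mean, 0.0)
                  for f in pop.__dataclass_fields__
                  if isinstance(getattr(pop, f), Dist)}
        pop0 = pop.replace(**zeroed)
        profiles = sample_player_profiles(pop0, 3, seed=2)
        for p in profiles:
            assert p.drift_base == pytest.approx(pop.drift_base.mean)
            assert p.stop_latency_mean == pytest.approx(
                pop.stop_latency_mean.mean)

    def test_sample_mean_matches_population(self):
        pop = default_population().replace(flanker_decrement_pre=(0.10, 0.02))
        profiles = sample_player_profiles(pop, 2000, seed=3)
        vals = np.array([p.flanker_decrement_pre for p in profiles])
        se = 0.02 / np.sqrt(2000)
        assert abs(vals.mean() - 0.10) < 3 * se

    def test_reproducible_for_fixed_seed(self):
        a = sample_player_profiles(default_population(), 5, seed=7)
        b = sample_player_profiles(default_population(), 5, seed=7)
        assert a == b

    def test_continuity_correlation_realized(self):
        pop = known_effect_population(flanker_effect=(50.0, 25.0),
                                      continuity_flanker=1.0)
        profiles = sample_player_profiles(pop, 400, seed=4)
        pre = np.array([p.flanker_shift_pre for p in profiles])
        post = np.array([p.flanker_shift_post for p in profiles])
        assert np.corrcoef(pre, post)[0, 1] > 0.99


class TestChoiceTrial:
    def test_zero_drift_accuracy_near_half(self, plain_profile):
        prof = plain_profile(drift_base=0.0, boundary=10.0, nondecision=0.0)
        rng = np.random.default_rng(11)
        acc = [simulate_choice_trial(prof, True, False, 4000.0, seed=rng,
                                     rotation_margin=0.0).first_response_correct
               for _ in range(10_000)]
        acc = np.array(acc)
        acc = acc[np.isfinite(acc)]
        # binomial 3*SE band around 0.5 at n=10,000
        assert abs(acc.mean() - 0.5) < 3 * np.sqrt(0.25 / len(acc))

    def test_strong_drift_always_correct_no_reversals(self, plain_profile):
        prof = plain_profile(drift_base=5.0, boundary=1.0, nondecision=0.0)
        rng = np.random.default_rng(12)
        recs = [simulate_choice_trial(prof, True, False, 2000.0, seed=rng)
                for _ in range(500)]
        assert np.mean([r.first_response_correct for r in recs]) > 0.99
        assert sum(np.isfinite(r.reversal_time) for r in recs) <= 2

    def test_mean_decision_time_matches_closed_form(self, plain_profile):
        # symmetric diffusion: E[T] = (a/v) tanh(a v / sigma^2); the 1 ms
        # Euler grid overshoots the boundary by ~0.58 evidence units, so
        # the empirical mean runs a few percent high of the closed form
        prof = plain_profile(drift_base=0.02, boundary=20.0, nondecision=0.0)
        rng = np.random.default_rng(1234)
        times = []
        for _ in range(4000):
            rec = simulate_choice_trial(prof, True, False, 8000.0, seed=rng,
                                        rotation_margin=0.0)
            if rec.responded:
                times.append(rec.first_response_time)
        closed = (20.0 / 0.02) * math.tanh(20.0 * 0.02)
        assert abs(np.mean(times) - closed) / closed < 0.07

    def test_nonfinite_profile_rejected(self, plain_profile):
        with pytest.raises(ValueError):
            plain_profile(drift_base=float("nan"))

    def test_reversal_strictly_after_first_response(self, plain_profile):
        prof = plain_profile(drift_base=0.02, boundary=15.0)
        rng = np.random.default_rng(13)
        seen = 0
        for _ in range(400):
            rec = simulate_choice_trial(prof, True, False, 2500.0, seed=rng)
            if np.isfinite(rec.reversal_time):
                seen += 1
                assert rec.reversal_time > rec.first_response_time
        assert seen > 10


class TestStopTrial:
    def test_stop_always_wins(self, plain_profile):
        prof = plain_profile(stop_latency_mean=1.0)
        rng = np.random.default_rng(21)
        recs = [simulate_stop_trial(prof, True, 0.0, seed=rng)
                for _ in range(200)]
        assert all(not r.responded and r.success for r in recs)

    def test_stop_never_finishes_in_time(self, plain_profile):
        prof = plain_profile(stop_latency_mean=1e9,
                             stop_latency_mean_late=1e9)
        rng = np.random.default_rng(22)
        recs = [simulate_stop_trial(prof, True, 300.0, seed=rng)
                for _ in range(100)]
        # go responses occur but no in-trial release, hence nothing
        # eligible for a time-to-stop measurement
        assert any(r.responded for r in recs)
        assert all(not np.isfinite(r.release_time) for r in recs)

    def test_deterministic_event_arithmetic(self, plain_profile):
        # go time 400 (instant crossing + 399 ms nondecision), ssd 300,
        # stop latency 250 -> movement at 400, release at 550
        prof = plain_profile(drift_base=50.0, boundary=1.0, nondecision=399.0,
                             stop_latency_mean=250.0, stop_latency_sd=0.0,
                             stop_latency_mean_late=250.0)
        rec = simulate_stop_trial(prof, True, 300.0, go_window=1317.0, seed=1)
        assert rec.responded
        assert rec.first_response_time == pytest.approx(400.0)
        assert rec.release_time == pytest.approx(550.0)
        assert rec.release_time - rec.ssd == pytest.approx(250.0)

    def test_negative_ssd_rejected(self, plain_profile):
        with pytest.raises(ValueError):
            simulate_stop_trial(plain_profile(), True, -1.0, seed=1)


class TestStaircase:
    def test_ssd_moves_down_after_response(self):
        st_ = StaircaseState("ssd_match", 300.0, 50.0, 50.0)
        assert staircase_update(st_, True).current_value == 250.0

    def test_ssd_moves_up_after_inhibition(self):
        st_ = StaircaseState("ssd_match", 300.0, 50.0, 50.0)
        assert staircase_update(st_, False).current_value == 350.0

    def test_go_window_asymmetric_steps(self):
        st_ = StaircaseState("go_window", 1000.0, step_up=80.0, step_down=20.0)
        assert staircase_update(st_, True).current_value == 980.0
        assert staircase_update(st_, False).current_value == 1080.0

    def test_floor_at_zero(self):
        st_ = StaircaseState("ssd_match", 20.0, 50.0, 50.0)
        assert staircase_update(st_, True).current_value == 0.0

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="unknown staircase mode"):
            StaircaseState("bogus", 100.0, 50.0, 50.0)

    @given(value=st.floats(0, 2000), responded=st.booleans())
    @settings(max_examples=50, deadline=None)
    def test_ssd_update_is_pure_and_bounded(self, value, responded):
        st_ = StaircaseState("ssd_match", value, 50.0, 50.0)
        out = staircase_update(st_, responded)
        assert out.current_value >= 0.0
        assert abs(out.current_value - value) <= 50.0 + 1e-9
        # purity: same input, same output
        assert staircase_update(st_, responded) == out

    def test_asymmetric_staircase_tracks_80pct(self):
        """A synthetic responder whose success probability rises smoothly
        with the window converges to ~80% long-run success."""
        rng = np.random.default_rng(33)
        st_ = StaircaseState("go_window", 500.0, step_up=80.0, step_down=20.0,
                             max_value=3000.0)
        hits = []
        for i in range(4000):
            p = 1.0 / (1.0 + np.exp(-(st_.current_value - 700.0) / 120.0))
            ok = rng.random() < p
            if i > 500:
                hits.append(ok)
            st_ = staircase_update(st_, ok)
        assert abs(np.mean(hits) - 0.80) < 0.05


class TestSession:
    def test_printed_composition(self, default_cohort):
        log, _ = default_cohort
        one = log[log.player_id == "p000"]
        test = one[one.phase == "test"]
        train = one[one.phase == "training"]
        assert len(train) == 40
        counts = {
            "regular": len(test[(test.flanker_match) & (~test.ice)
                                & (~test.lava)]),
            "mismatch": len(test[(~test.flanker_match) & (~test.ice)
                                 & (~test.lava)]),
            "lava": len(test[test.lava]),
            "ice": len(test[test.ice]),
        }
        assert counts == {"regular": 126, "mismatch": 126, "lava": 84,
                          "ice": 120}

    def test_lava_flanker_split(self, default_cohort):
        log, _ = default_cohort
        lava = log[(log.phase == "test") & log.lava]
        for _, d in lava.groupby("player_id"):
            assert int(d.flanker_match.sum()) == 42
            assert int((~d.flanker_match).sum()) == 42

    def test_lava_never_crossed_with_ice(self, default_cohort):
        log, _ = default_cohort
        assert not (log.lava & log.ice).any()

    def test_ssd_present_iff_lava(self, default_cohort):
        log, _ = default_cohort
        assert log.loc[log.lava, "ssd"].notna().all()
        assert log.loc[~log.lava, "ssd"].isna().all()

    def test_event_time_invariants(self, default_cohort):
        log, _ = default_cohort
        rev = log[log.reversal_time.notna()]
        assert (rev.reversal_time > rev.first_response_time).all()
        rel = log[log.release_time.notna()]
        assert (rel.release_time >= rel.first_response_time).all()
        assert rel.lava.all()
        assert rel.responded.all()
        for col in ("first_response_time", "reversal_time", "release_time"):
            assert (log[col].dropna() >= 0).all()

    def test_session_determinism(self, plain_profile):
        cfg = GameConfig()
        prof = plain_profile()
        a = session_to_frame(simulate_session(prof, cfg, seed=99))
        b = session_to_frame(simulate_session(prof, cfg, seed=99))
        pd.testing.assert_frame_equal(a, b)


class TestCohort:
    def test_single_player(self):
        log, truth = simulate_cohort(default_population(), 1, GameConfig(),
                                     seed=5)
        assert truth.shape[0] == 1
        assert log.player_id.nunique() == 1

    def test_cohort_csv_determinism(self, tmp_path):
        for name in ("a", "b"):
            log, truth = simulate_cohort(default_population(), 3,
                                         GameConfig(), seed=17)
            log.to_csv(tmp_path / f"log_{name}.csv", index=False)
            truth.to_csv(tmp_path / f"truth_{name}.csv", index=False)
        assert ((tmp_path / "log_a.csv").read_bytes()
                == (tmp_path / "log_b.csv").read_bytes())
        assert ((tmp_path / "truth_a.csv").read_bytes()
                == (tmp_path / "truth_b.csv").read_bytes())

    def test_invalid_cohort_size(self):
        with pytest.raises(ValueError):
            simulate_cohort(default_population(), 0, GameConfig(), seed=1)
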