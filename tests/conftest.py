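import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True,
                          deadline=None)
settings.load_profile("deterministic")

from changeofmind import GameConfig, default_population, simulate_cohort
from changeofmind.simkit import PlayerProfile


@pytest.fixture(scope="session")
def default_cohort():
    """Small default-condition cohort shared across read-only tests."""
    return simulate_cohort(default_population(), 20, GameConfig(),
                           seed=20240915)


@pytest.fixture()
def plain_profile():
    """A profile with no conflict parameters and no stochastic stop noise."""
    def make(**overrides) -> PlayerProfile:
        base = dict(
            drift_base=0.05, boundary=20.0, nondecision=180.0,
            flanker_decrement_pre=0.0, flanker_decrement_post=0.0,
            ice_decrement_pre=0.0, ice_modifier_post=0.0,
            stop_latency_mean=250.0, stop_latency_sd=0.0,
            stop_latency_mean_late=250.0, tts_flanker_shift=0.0,
            correction_latency_mean=191.0, correction_latency_sd=0.0,
            lava_correction_prob=1.0, post_drift_gain=6.0, fps=60.0,
            flanker_shift_pre=0.0, flanker_shift_post=0.0,
            ice_shift_pre=0.0, ice_shift_post=0.0,
        )
        base.update(overrides)
        return PlayerProfile(**base)
    return make


def make_session_frame(
    n_nonlava: int = 300,
    n_lava: int = 84,
    fps: float = 60.0,
    accuracy: float = 0.85,
    nonresponse_rate: float = 0.0,
    stop_rate: float = 0.5,
    correction_rate_nonlava: float = 0.9,
    correction_rate_lava: float = 0.9,
    player_id: str = "p000",
    seed: int = 0,
) -> pd.DataFrame:
    """Hand-built session log with exact marginal rates, for rule tests."""
    rng = np.random.default_rng(seed)
    rows = []

    def n_true(n, rate):
        k = int(round(n * rate))
        flags = np.zeros(n, dtype=bool)
        flags[:k] = True
        return flags

    responded = ~n_true(n_nonlava, nonresponse_rate)
    n_resp = int(responded.sum())
    correct = n_true(n_resp, accuracy)
    corrected = n_true(int((~correct).sum()), correction_rate_nonlava)
    ci = 0
    ri = 0
    for i in range(n_nonlava):
        rec = dict(player_id=player_id, trial_index=i, phase="test",
                   flanker_match=bool(i % 2), ice=False, lava=False,
                   ssd=np.nan, go_window=1000.0, responded=bool(responded[i]),
                   first_response_time=np.nan, first_response_correct=np.nan,
                   reversal_time=np.nan, release_time=np.nan,
                   correction_after_release_time=np.nan, success=False,
                   fps=fps)
        if responded[i]:
            rec["first_response_time"] = 400.0 + rng.normal(0, 30)
            ok = bool(correct[ri])
            rec["first_response_correct"] = float(ok)
            rec["success"] = ok
            if not ok:
                if corrected[ci]:
                    rec["reversal_time"] = rec["first_response_time"] + 200.0
                ci += 1
            ri += 1
        rows.append(rec)

    resp_lava = n_true(n_lava, 1.0 - stop_rate)
    corrected_lava = n_true(int(resp_lava.sum()), correction_rate_lava)
    cj = 0
    for i in range(n_lava):
        rec = dict(player_id=player_id, trial_index=n_nonlava + i,
                   phase="test", flanker_match=bool(i % 2), ice=False,
                   lava=True, ssd=300.0, go_window=1000.0,
                   responded=bool(resp_lava[i]),
                   first_response_time=np.nan, first_response_correct=np.nan,
                   reversal_time=np.nan, release_time=np.nan,
                   correction_after_release_time=np.nan,
                   success=not bool(resp_lava[i]), fps=fps)
        if resp_lava[i]:
            rec["first_response_time"] = 400.0
            rec["first_response_correct"] = 1.0
            rec["release_time"] = 550.0
            if corrected_lava[cj]:
                rec["correction_after_release_time"] = 191.0
            cj += 1
        rows.append(rec)
    return pd.DataFrame(rows)
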