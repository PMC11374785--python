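"""Synthetic session generator for a conflict-based runner game.

Players steer a central rat toward the tunnel section matching its color.
Each trial starts when the central rat is assigned a color; the player then
has a limited window (the time to obstacle collision) to end up in the
correct section.  Four trial types create response conflicts:

* regular trials           -- flanker rats match the central rat,
* mismatching flanker      -- flanker rats point at the wrong section,
* ice trials               -- the key mapping is reversed,
* lava trials              -- a delayed stop-signal penalises movement.

The generator implements the two cognitive models the analysis assumes:

* Non-lava choices come from a single evidence accumulator (symmetric
  drift-diffusion, Euler-Maruyama at 1 ms steps with unit diffusion
  coefficient).  After an incorrect first crossing the SAME accumulator
  keeps running -- with a separate post-decision drift -- toward the correct
  boundary; reaching it initiates an error-correcting response ("change of
  mind").
* Lava outcomes come from an independent race between that go process and a
  stop process with per-player latency.  When the stop process finishes
  after movement onset, the ongoing response is released late, which is what
  the time-to-stop (TTS) measure captures.

Two adaptive staircases mirror the game's difficulty adaptation: the
obstacle-collision window targets 80% success on regular/mismatching trials
(asymmetric 4:1 steps), and one +-50 ms stop-signal-delay staircase per
flanker condition targets 50% inhibition on lava trials.

Every operation that takes a ``seed`` is a pure function of its inputs.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Dist",
    "GameConfig",
    "PopulationParams",
    "PlayerProfile",
    "TrialRecord",
    "StaircaseState",
    "sample_player_profiles",
    "simulate_choice_trial",
    "simulate_stop_trial",
    "staircase_update",
    "simulate_session",
    "simulate_cohort",
    "session_to_frame",
    "default_population",
    "known_effect_population",
]

# Diffusion noise SD per 1-ms step (unit diffusion coefficient).
DIFFUSION_SIGMA = 1.0
STEP_MS = 1.0
_CHUNK = 512  # noise draws per block in the first-passage loop

# ---------------------------------------------------------------------------
# configuration and domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GameConfig:
    """Session composition, timing constants, and adaptation settings.

    Defaults reproduce the published game design: 40 training trials, then
    126 regular, 126 mismatching-flanker, 84 lava (42 per flanker condition)
    and 120 ice test trials; central/flanker colors assigned 433/350 ms
    after the obstacle appears; initial collision window 1317 ms; stop
    signals start at a 300 ms delay and move in 50 ms steps.
    """

    n_training: int = 40
    n_regular: int = 126
    n_mismatch: int = 126
    n_lava: int = 84
    n_ice: int = 120
    lava_match_split: tuple[int, int] = (42, 42)
    central_color_delay: float = 433.0
    flanker_color_delay: float = 350.0
    initial_go_window: float = 1317.0
    initial_ssd: float = 300.0
    ssd_step: float = 50.0
    go_success_target: float = 0.80
    stop_target: float = 0.50
    go_window_step: float = 20.0  # shrink on success; grows 4x this on failure
    rotation_margin: float = 200.0  # ms needed to rotate into the section
    adapt_go_window: bool = True
    max_go_window: float = 2600.0
    lapse_prob: float = 0.02
    seed: int | None = None

    def __post_init__(self) -> None:
        counts = (self.n_training, self.n_regular, self.n_mismatch,
                  self.n_lava, self.n_ice)
        if any(c < 0 for c in counts):
            raise ValueError("trial counts must be >= 0")
        if sum(self.lava_match_split) != self.n_lava:
            raise ValueError(
                f"lava split {self.lava_match_split} must sum to n_lava={self.n_lava}")
        if self.ssd_step <= 0 or self.go_window_step <= 0:
            raise ValueError("staircase steps must be > 0")
        for name in ("go_success_target", "stop_target"):
            p = getattr(self, name)
            if not 0.0 < p < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if not 0.0 <= self.lapse_prob < 1.0:
            raise ValueError("lapse_prob must be in [0, 1)")

    @property
    def n_test(self) -> int:
        return self.n_regular + self.n_mismatch + self.n_lava + self.n_ice

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["lava_match_split"] = list(self.lava_match_split)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GameConfig":
        d = json.loads(text)
        if "lava_match_split" in d:
            d["lava_match_split"] = tuple(d["lava_match_split"])
        return cls(**d)


@dataclass(frozen=True)
class Dist:
    """Population mean and between-player SD of one profile parameter."""

    mean: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


# Profile fields drawn from the population, in sampling order.
_PROFILE_FIELDS = (
    "drift_base",
    "boundary",
    "nondecision",
    "flanker_decrement_pre",
    "flanker_decrement_post",
    "ice_decrement_pre",
    "ice_modifier_post",
    "flanker_shift_pre",
    "flanker_shift_post",
    "ice_shift_pre",
    "ice_shift_post",
    "stop_latency_mean",
    "stop_latency_mean_late",
    "stop_latency_sd",
    "tts_flanker_shift",
    "correction_latency_mean",
    "correction_latency_sd",
    "lava_correction_prob",
    "post_drift_gain",
    "fps",
)

# Pairs whose between-player correlation is a named population knob.
_CORR_PAIRS = {
    ("flanker_decrement_pre", "flanker_decrement_post"): "continuity_flanker",
    ("flanker_shift_pre", "flanker_shift_post"): "continuity_flanker",
    ("ice_decrement_pre", "ice_modifier_post"): "continuity_ice",
    ("ice_shift_pre", "ice_shift_post"): "continuity_ice",
    ("stop_latency_mean", "stop_latency_mean_late"): "stop_share",
}


@dataclass(frozen=True)
class PopulationParams:
    """Population-level distribution of :class:`PlayerProfile` parameters.

    ``continuity_flanker`` / ``continuity_ice`` are the between-player
    correlations between the pre-decision conflict parameter and its
    post-decision (error-correcting) counterpart; they encode the cognitive
    continuity hypothesis as a generative dial.  ``stop_share`` correlates
    the stop-process latency as expressed in the inhibition race (SSRT) with
    its expression in the late-stop (TTS) timing.

    Two families of conflict parameters exist side by side: drift-space
    decrements (`*_decrement_*`, `ice_modifier_post`, evidence/ms) and
    additive millisecond shifts (`*_shift_*`).  The shifts inject exactly
    known per-player conflict effects on first-response and correction
    times, which is what parameter-recovery tests need; they default to 0.
    """

    drift_base: Dist = Dist(0.055, 0.008)
    boundary: Dist = Dist(16.0, 1.8)
    nondecision: Dist = Dist(270.0, 25.0)
    flanker_decrement_pre: Dist = Dist(0.012, 0.004)
    flanker_decrement_post: Dist = Dist(0.010, 0.005)
    ice_decrement_pre: Dist = Dist(0.004, 0.002)
    ice_modifier_post: Dist = Dist(-0.020, 0.010)
    flanker_shift_pre: Dist = Dist(25.0, 22.0)
    flanker_shift_post: Dist = Dist(15.0, 16.0)
    ice_shift_pre: Dist = Dist(25.0, 20.0)
    ice_shift_post: Dist = Dist(10.0, 18.0)
    stop_latency_mean: Dist = Dist(250.0, 70.0)
    stop_latency_mean_late: Dist = Dist(250.0, 70.0)
    stop_latency_sd: Dist = Dist(50.0, 10.0)
    tts_flanker_shift: Dist = Dist(15.0, 10.0)
    correction_latency_mean: Dist = Dist(191.0, 25.0)
    correction_latency_sd: Dist = Dist(40.0, 8.0)
    lava_correction_prob: Dist = Dist(0.85, 0.08)
    post_drift_gain: Dist = Dist(6.0, 1.0)
    fps: Dist = Dist(55.0, 5.0)
    continuity_flanker: float = 0.6
    continuity_ice: float = -0.3
    stop_share: float = 0.9

    def __post_init__(self) -> None:
        for name in ("continuity_flanker", "continuity_ice", "stop_share"):
            r = getattr(self, name)
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"{name} must be in [-1, 1]")

    def replace(self, **changes) -> "PopulationParams":
        """Return a copy with the given fields replaced.

        Scalar values for distribution fields are shorthand for a
        zero-variance :class:`Dist`; ``(mean, sd)`` tuples are accepted too.
        """
        coerced = {}
        for key, val in changes.items():
            if key in _PROFILE_FIELDS and not isinstance(val, Dist):
                if isinstance(val, (tuple, list)):
                    val = Dist(*val)
                else:
                    val = Dist(float(val), 0.0)
            coerced[key] = val
        return dataclasses.replace(self, **coerced)

    def correlation_matrix(self) -> np.ndarray:
        k = len(_PROFILE_FIELDS)
        idx = {f: i for i, f in enumerate(_PROFILE_FIELDS)}
        corr = np.eye(k)
        for (a, b), knob in _CORR_PAIRS.items():
            r = getattr(self, knob)
            corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = r
        return corr

    def to_json(self) -> str:
        d = {}
        for f in _PROFILE_FIELDS:
            dist: Dist = getattr(self, f)
            d[f] = {"mean": dist.mean, "sd": dist.sd}
        for f in ("continuity_flanker", "continuity_ice", "stop_share"):
            d[f] = getattr(self, f)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PopulationParams":
        raw = json.loads(text)
        kwargs = {}
        for key, val in raw.items():
            if isinstance(val, dict):
                kwargs[key] = Dist(**val)
            else:
                kwargs[key] = val
        return cls(**kwargs)


@dataclass(frozen=True)
class PlayerProfile:
    """Per-player generative parameters.

    Drifts are in evidence/ms, the boundary in evidence units (symmetric
    +-a around a neutral start), latencies in ms, fps in frames/s.
    ``post_drift_gain`` multiplies the base drift during the post-decision
    (error-correcting) accumulation stage, reflecting the rapid evidence
    build-up typically seen after an error.
    """

    drift_base: float
    boundary: float
    nondecision: float
    flanker_decrement_pre: float
    flanker_decrement_post: float
    ice_decrement_pre: float
    ice_modifier_post: float
    stop_latency_mean: float
    stop_latency_sd: float
    stop_latency_mean_late: float
    tts_flanker_shift: float = 0.0
    correction_latency_mean: float = 191.0
    correction_latency_sd: float = 40.0
    lava_correction_prob: float = 0.9
    post_drift_gain: float = 6.0
    fps: float = 55.0
    flanker_shift_pre: float = 0.0
    flanker_shift_post: float = 0.0
    ice_shift_pre: float = 0.0
    ice_shift_post: float = 0.0
    player_id: str = "p000"

    def __post_init__(self) -> None:
        if self.boundary <= 0:
            raise ValueError("boundary must be > 0")
        if self.nondecision < 0:
            raise ValueError("nondecision must be >= 0")
        if self.stop_latency_sd < 0:
            raise ValueError("stop_latency_sd must be >= 0")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        for name in ("drift_base", "boundary", "nondecision",
                     "stop_latency_mean", "post_drift_gain"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass
class TrialRecord:
    """One trial's condition flags, staircase state, and event times.

    All event times are in ms from the central rat's color assignment.
    ``reversal_time`` marks the initiation of an error-correcting response
    in non-lava trials; ``release_time`` marks the late stop of an ongoing
    response in lava trials, and ``correction_after_release_time`` the extra
    time from that release to the corrective response.
    """

    player_id: str
    trial_index: int
    phase: str  # "training" | "test"
    flanker_match: bool
    ice: bool
    lava: bool
    ssd: float  # NaN unless lava
    go_window: float
    responded: bool
    first_response_time: float  # NaN if no response
    first_response_correct: float  # 1.0/0.0, NaN if no response
    reversal_time: float  # NaN unless a change of mind occurred
    release_time: float  # NaN unless lava with a late stop
    correction_after_release_time: float  # NaN unless late stop corrected
    success: bool
    fps: float = float("nan")


_TRIAL_COLUMNS = [f.name for f in dataclasses.fields(TrialRecord)]


@dataclass(frozen=True)
class StaircaseState:
    """State of one difficulty staircase (floored at 0, capped optionally)."""

    mode: str  # "go_window" | "ssd_match" | "ssd_mismatch"
    current_value: float
    step_up: float
    step_down: float
    max_value: float = math.inf

    def __post_init__(self) -> None:
        if self.mode not in ("go_window", "ssd_match", "ssd_mismatch"):
            raise ValueError(f"unknown staircase mode {self.mode!r}")
        if self.current_value < 0:
            raise ValueError("current_value must be >= 0")
        if self.mode.startswith("ssd") and self.step_up != self.step_down:
            raise ValueError("ssd staircases use symmetric steps")


# ---------------------------------------------------------------------------
# population sampling
# ---------------------------------------------------------------------------


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_player_profiles(pop: PopulationParams, n: int,
                           seed=None) -> list[PlayerProfile]:
    """Draw ``n`` player profiles from the population.

    Fields are jointly Gaussian with the configured cross-correlations
    (continuity and stop-share knobs); parameters with hard ranges are
    clipped to their valid domain afterwards.  Reproducible for a fixed
    seed; with all SDs zero every profile equals the population means.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    corr = pop.correlation_matrix()
    eig = np.linalg.eigvalsh(corr)
    if eig.min() < -1e-10:
        raise ValueError("population correlation matrix is not positive semi-definite")
    rng = _as_rng(seed)
    means = np.array([getattr(pop, f).mean for f in _PROFILE_FIELDS])
    sds = np.array([getattr(pop, f).sd for f in _PROFILE_FIELDS])
    cov = corr * np.outer(sds, sds)
    if n == 0:
        return []
    draws = rng.multivariate_normal(means, cov, size=n, method="svd")
    profiles = []
    for i in range(n):
        vals = dict(zip(_PROFILE_FIELDS, draws[i]))
        vals["boundary"] = max(vals["boundary"], 1e-3)
        vals["nondecision"] = max(vals["nondecision"], 0.0)
        vals["stop_latency_sd"] = max(vals["stop_latency_sd"], 0.0)
        vals["correction_latency_sd"] = max(vals["correction_latency_sd"], 0.0)
        vals["lava_correction_prob"] = float(np.clip(vals["lava_correction_prob"], 0.0, 1.0))
        vals["fps"] = max(vals["fps"], 1e-3)
        vals["post_drift_gain"] = max(vals["post_drift_gain"], 0.1)
        profiles.append(PlayerProfile(player_id=f"p{i:03d}", **vals))
    return profiles


def default_population() -> PopulationParams:
    """The study-condition population: drift-space conflict parameters."""
    return PopulationParams()


def known_effect_population(
    flanker_effect: tuple[float, float] = (50.0, 25.0),
    flanker_effect_post: tuple[float, float] | None = None,
    ice_effect: tuple[float, float] = (0.0, 0.0),
    ice_effect_post: tuple[float, float] | None = None,
    continuity_flanker: float = 1.0,
    continuity_ice: float = 0.0,
) -> PopulationParams:
    """Population with conflict effects injected as known millisecond shifts.

    The drift-space conflict decrements are zeroed and replaced by additive
    per-player shifts: a mismatching-flanker (or ice) trial adds
    ``*_shift_pre`` ms to the first-response time and ``*_shift_post`` ms to
    the error-correction time, so the true fixed conflict effect and its
    between-player SD are exactly the supplied ``(mean, sd)``.  Post-stage
    shifts default to the pre-stage values (full sharing of magnitude).
    """
    if flanker_effect_post is None:
        flanker_effect_post = flanker_effect
    if ice_effect_post is None:
        ice_effect_post = ice_effect
    return PopulationParams().replace(
        flanker_decrement_pre=Dist(0.0, 0.0),
        flanker_decrement_post=Dist(0.0, 0.0),
        ice_decrement_pre=Dist(0.0, 0.0),
        ice_modifier_post=Dist(0.0, 0.0),
        flanker_shift_pre=Dist(*flanker_effect),
        flanker_shift_post=Dist(*flanker_effect_post),
        ice_shift_pre=Dist(*ice_effect),
        ice_shift_post=Dist(*ice_effect_post),
        continuity_flanker=continuity_flanker,
        continuity_ice=continuity_ice,
    )


# ---------------------------------------------------------------------------
# single-trial simulation
# ---------------------------------------------------------------------------


def _first_passage(rng: np.random.Generator, start: float, drift: float,
                   boundary: float, max_steps: int) -> tuple[float, int, float]:
    """First crossing of +-boundary from ``start`` under Euler-Maruyama.

    Returns ``(crossing_step, side, last_value)`` with side +1 (upper), -1
    (lower) or 0 if no boundary was crossed within ``max_steps`` 1-ms
    steps; ``last_value`` is the accumulator state at the end.
    """
    x = start
    t = 0
    while t < max_steps:
        n = min(_CHUNK, max_steps - t)
        path = x + np.cumsum(drift * STEP_MS
                             + DIFFUSION_SIGMA * rng.standard_normal(n))
        hit = np.abs(path) >= boundary
        if hit.any():
            i = int(np.argmax(hit))
            side = 1 if path[i] >= boundary else -1
            return float(t + i + 1), side, float(path[i])
        x = float(path[-1])
        t += n
    return float("nan"), 0, x


def _first_passage_upper(rng: np.random.Generator, start: float, drift: float,
                         boundary: float, max_steps: int) -> float:
    """First crossing of the upper boundary only (post-decision stage).

    After an incorrect response the accumulator keeps running toward the
    correct boundary; evidence drifting further past the incorrect boundary
    just means staying committed to the error, so only the correct (upper)
    boundary absorbs.  Returns the crossing step or NaN.
    """
    x = start
    t = 0
    while t < max_steps:
        n = min(_CHUNK, max_steps - t)
        path = x + np.cumsum(drift * STEP_MS
                             + DIFFUSION_SIGMA * rng.standard_normal(n))
        hit = path >= boundary
        if hit.any():
            return float(t + int(np.argmax(hit)) + 1)
        x = float(path[-1])
        t += n
    return float("nan")


def _blank_trial(profile: PlayerProfile, flanker_match: bool, ice: bool,
                 lava: bool, go_window: float) -> TrialRecord:
    return TrialRecord(
        player_id=profile.player_id, trial_index=-1, phase="test",
        flanker_match=flanker_match, ice=ice, lava=lava,
        ssd=float("nan"), go_window=go_window, responded=False,
        first_response_time=float("nan"), first_response_correct=float("nan"),
        reversal_time=float("nan"), release_time=float("nan"),
        correction_after_release_time=float("nan"), success=False,
        fps=profile.fps,
    )


def _pre_drift(profile: PlayerProfile, flanker_match: bool, ice: bool) -> float:
    v = profile.drift_base
    if not flanker_match:
        v -= profile.flanker_decrement_pre
    if ice:
        v -= profile.ice_decrement_pre
    return v


def _post_drift(profile: PlayerProfile, flanker_match: bool, ice: bool) -> float:
    v = profile.post_drift_gain * profile.drift_base
    if not flanker_match:
        v -= profile.flanker_decrement_post
    if ice:
        v -= profile.ice_modifier_post
    return v


def simulate_choice_trial(profile: PlayerProfile, flanker_match: bool,
                          ice: bool, go_window: float,
                          seed=None,
                          rotation_margin: float = 200.0) -> TrialRecord:
    """Simulate one non-lava trial.

    A diffusion with condition-dependent drift runs from 0 toward the
    symmetric boundaries; the first crossing plus non-decision time gives
    the first response.  On an incorrect crossing the same accumulator
    continues -- with the post-decision drift -- toward the correct boundary;
    reaching it before the collision window expires initiates the
    error-correcting reversal.  Additive per-player conflict shifts (if
    configured) are applied to the resulting event times.

    A trial succeeds only when the correct response (first or corrective)
    is initiated early enough to finish rotating into the correct section
    before collision (``rotation_margin`` before the window's end); a late
    reversal is still recorded as an error-correcting response even when
    the trial fails.  A player who has not reached a boundary by the last
    moment a rotation could still finish commits to the current evidence
    sign (a deadline guess), so genuine non-responses are rare.
    """
    if go_window <= 0:
        raise ValueError("go_window must be > 0")
    rng = _as_rng(seed)
    rec = _blank_trial(profile, flanker_match, ice, lava=False,
                       go_window=go_window)

    # step budget for a first response to land inside the window,
    # and the deadline at which an undecided player guesses
    max_resp = int(go_window - profile.nondecision)
    if max_resp <= 0:
        return rec
    guess_step = int(go_window - rotation_margin - profile.nondecision)

    run_steps = guess_step if guess_step > 0 else max_resp
    t1, side, x_last = _first_passage(
        rng, 0.0, _pre_drift(profile, flanker_match, ice),
        profile.boundary, run_steps)
    guessed = False
    if side == 0:
        if guess_step <= 0:
            return rec  # window too short for a deadline guess
        # deadline guess: commit to the current evidence sign
        guessed = True
        t1 = float(guess_step)
        if x_last == 0.0:
            side = 1 if rng.random() < 0.5 else -1
        else:
            side = 1 if x_last > 0 else -1
        start_post = x_last
    else:
        start_post = -profile.boundary

    shift_pre = ((0.0 if flanker_match else profile.flanker_shift_pre)
                 + (profile.ice_shift_pre if ice else 0.0))
    shift_post = ((0.0 if flanker_match else profile.flanker_shift_post)
                  + (profile.ice_shift_post if ice else 0.0))
    if guessed:
        shift_pre = 0.0  # the commit is clock-driven, not stimulus-driven

    first_rt = t1 + profile.nondecision + shift_pre
    if first_rt > go_window:
        return rec  # response would land after the collision
    correct = side > 0
    rec.responded = True
    rec.first_response_time = first_rt
    rec.first_response_correct = 1.0 if correct else 0.0
    if correct:
        rec.success = first_rt + rotation_margin <= go_window
        return rec

    # change of mind: keep accumulating toward the correct boundary
    remaining = max_resp - int(t1)
    if remaining > 0:
        t2 = _first_passage_upper(
            rng, start_post,
            _post_drift(profile, flanker_match, ice),
            profile.boundary, remaining)
        if math.isfinite(t2):
            reversal = t1 + t2 + profile.nondecision + shift_post
            reversal = max(reversal, first_rt + 1.0)
            if reversal <= go_window:
                rec.reversal_time = reversal
                rec.success = reversal + rotation_margin <= go_window
    return rec


def simulate_stop_trial(profile: PlayerProfile, flanker_match: bool,
                        ssd: float, go_window: float = 1317.0,
                        seed=None) -> TrialRecord:
    """Simulate one lava trial as an independent go/stop race.

    The go finishing time comes from the same first-crossing machinery as
    choice trials; the stop process finishes at ``ssd`` plus a latency draw.
    If the stop process wins there is no movement (successful inhibition);
    otherwise movement starts at the go time and is released when the stop
    process finishes, usually followed by a corrective response after a
    short per-player correction latency.
    """
    if ssd < 0:
        raise ValueError("ssd must be >= 0")
    rng = _as_rng(seed)
    rec = _blank_trial(profile, flanker_match, ice=False, lava=True,
                       go_window=go_window)
    rec.ssd = ssd

    max_steps = int(go_window)
    t1, side, _ = _first_passage(rng, 0.0,
                                 _pre_drift(profile, flanker_match, False),
                                 profile.boundary, max_steps)
    go_time = (t1 + profile.nondecision) if side != 0 else float("inf")
    if side != 0 and go_time > go_window:
        go_time = float("inf")

    mu = profile.stop_latency_mean + (0.0 if flanker_match
                                      else profile.tts_flanker_shift)
    latency = mu + profile.stop_latency_sd * rng.standard_normal()
    latency = max(latency, 1.0)
    stop_time = ssd + latency

    if stop_time <= go_time:
        rec.success = True  # inhibited before any movement
        return rec

    rec.responded = True
    rec.first_response_time = go_time
    rec.first_response_correct = 1.0 if side > 0 else 0.0
    # late stop: same latency draw, re-expressed on the player's late-stop scale
    late = stop_time + (profile.stop_latency_mean_late - profile.stop_latency_mean)
    late = max(late, go_time + 1.0)
    if late <= go_window:  # a release after the trial ends is never observed
        rec.release_time = late
        if rng.random() < profile.lava_correction_prob:
            corr = (profile.correction_latency_mean
                    + profile.correction_latency_sd * rng.standard_normal())
            rec.correction_after_release_time = max(corr, 1.0)
    return rec


# ---------------------------------------------------------------------------
# staircases
# ---------------------------------------------------------------------------


def staircase_update(state: StaircaseState, outcome: bool) -> StaircaseState:
    """Advance a staircase one trial.

    SSD staircases: a response moves the stop signal 50 ms earlier
    (``-step``), successful inhibition moves it 50 ms later (``+step``),
    driving the respond rate to 50%.  The go-window staircase shrinks the
    collision window by ``step_down`` on success and grows it by
    ``step_up = 4 * step_down`` on failure, so its stationary success rate
    is step_up / (step_up + step_down) = 0.80.  Values are floored at 0.
    """
    if state.mode.startswith("ssd"):
        delta = -state.step_down if outcome else state.step_up
    elif state.mode == "go_window":
        delta = -state.step_down if outcome else state.step_up
    else:  # pragma: no cover - constructor already rejects unknown modes
        raise ValueError(f"unknown staircase mode {state.mode!r}")
    value = min(max(state.current_value + delta, 0.0), state.max_value)
    return dataclasses.replace(state, current_value=value)


# ---------------------------------------------------------------------------
# sessions and cohorts
# ---------------------------------------------------------------------------

# condition codes: (flanker_match, ice, lava)
_CONDITIONS = {
    "regular": (True, False, False),
    "mismatch": (False, False, False),
    "ice_match": (True, True, False),
    "ice_mismatch": (False, True, False),
    "lava_match": (True, False, True),
    "lava_mismatch": (False, False, True),
}


def _test_condition_list(config: GameConfig, rng: np.random.Generator) -> list[str]:
    n_ice_match = config.n_ice // 2
    counts = {
        "regular": config.n_regular,
        "mismatch": config.n_mismatch,
        "ice_match": n_ice_match,
        "ice_mismatch": config.n_ice - n_ice_match,
        "lava_match": config.lava_match_split[0],
        "lava_mismatch": config.lava_match_split[1],
    }
    seq = [name for name, c in counts.items() for _ in range(c)]
    rng.shuffle(seq)
    return seq


def simulate_session(profile: PlayerProfile, config: GameConfig,
                     seed=None) -> list[TrialRecord]:
    """Simulate one full game session (training + test trials).

    Test trials follow the exact printed composition with uniformly random
    interleaving; training trials mirror the test-phase mix and warm up the
    staircases but are flagged ``phase="training"``.  The collision-window
    staircase is updated by regular/mismatching (non-ice, non-lava) trials
    only; each lava flanker condition drives its own SSD staircase.
    Deterministic given ``(profile, config, seed)``.
    """
    rng = _as_rng(seed if seed is not None else config.seed)
    test_seq = _test_condition_list(config, rng)
    names = list(_CONDITIONS)
    weights = np.array([test_seq.count(n) for n in names], dtype=float)
    weights = weights / weights.sum() if weights.sum() else np.ones(len(names)) / len(names)
    train_seq = list(rng.choice(names, size=config.n_training, p=weights))

    go_stair = StaircaseState("go_window", config.initial_go_window,
                              step_up=4.0 * config.go_window_step,
                              step_down=config.go_window_step,
                              max_value=config.max_go_window)
    ssd_stairs = {
        True: StaircaseState("ssd_match", config.initial_ssd,
                             config.ssd_step, config.ssd_step),
        False: StaircaseState("ssd_mismatch", config.initial_ssd,
                              config.ssd_step, config.ssd_step),
    }

    records: list[TrialRecord] = []
    for idx, cond in enumerate(train_seq + test_seq):
        flanker_match, ice, lava = _CONDITIONS[cond]
        window = max(go_stair.current_value, 300.0)
        lapse = rng.random() < config.lapse_prob
        if lava:
            ssd = ssd_stairs[flanker_match].current_value
            if lapse:
                rec = _blank_trial(profile, flanker_match, False, True, window)
                rec.ssd = ssd
                rec.success = True  # no movement at all counts as inhibited
            else:
                rec = simulate_stop_trial(profile, flanker_match, ssd,
                                          go_window=window, seed=rng)
            ssd_stairs[flanker_match] = staircase_update(
                ssd_stairs[flanker_match], rec.responded)
        else:
            if lapse:
                rec = _blank_trial(profile, flanker_match, ice, False, window)
            else:
                rec = simulate_choice_trial(
                    profile, flanker_match, ice, window, seed=rng,
                    rotation_margin=config.rotation_margin)
            if config.adapt_go_window and not ice:
                go_stair = staircase_update(go_stair, rec.success)
        rec.trial_index = idx
        rec.phase = "training" if idx < config.n_training else "test"
        records.append(rec)
    return records


def session_to_frame(records: Iterable[TrialRecord]) -> pd.DataFrame:
    """Long-format session log, one row per trial."""
    df = pd.DataFrame([dataclasses.asdict(r) for r in records],
                      columns=_TRIAL_COLUMNS)
    return df


def profiles_to_frame(profiles: Sequence[PlayerProfile]) -> pd.DataFrame:
    df = pd.DataFrame([dataclasses.asdict(p) for p in profiles])
    cols = ["player_id"] + [c for c in df.columns if c != "player_id"]
    return df[cols]


def simulate_cohort(pop: PopulationParams, n_players: int,
                    config: GameConfig | None = None,
                    seed=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort of sessions.

    Returns ``(log, truth)``: the concatenated session logs and the
    ground-truth profile table keyed by ``player_id`` (for parameter
    recovery).  All randomness derives from ``seed`` via spawned child
    streams, so output is reproducible byte for byte.
    """
    if n_players < 1:
        raise ValueError("n_players must be >= 1")
    config = config or GameConfig()
    if isinstance(seed, np.random.Generator):
        ss = np.random.SeedSequence(int(seed.integers(2 ** 63)))
    elif isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_players + 1)
    profiles = sample_player_profiles(pop, n_players,
                                      np.random.default_rng(children[0]))
    frames = []
    for profile, child in zip(profiles, children[1:]):
        recs = simulate_session(profile, config, np.random.default_rng(child))
        frames.append(session_to_frame(recs))
    log = pd.concat(frames, ignore_index=True)
    truth = profiles_to_frame(profiles)
    return log, truth
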