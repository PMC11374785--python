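"""Player exclusion scoring, trial-level filters, and measure eligibility.

Data quality rules operate at three levels:

* player exclusion via a point system (2 points excludes a player),
* trial filters on the extracted observation tables (absolute range rules
  followed by a per-player, per-condition 3-SD rule), and
* per-measure eligibility (enough error-correcting responses, and a lava
  stopping rate inside the range required by the integration method).

SSRT inputs are deliberately never trial-filtered; the integration method
uses the full go-RT and stop-trial record.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExclusionConfig",
    "ExclusionReport",
    "score_player_exclusions",
    "score_cohort_exclusions",
    "filter_trials",
    "measure_eligibility",
]


@dataclass(frozen=True)
class ExclusionConfig:
    """Thresholds of the point-based player exclusion rules.

    The accuracy rule targets near-chance responders: a player is flagged
    when first-response accuracy is within 3 binomial standard errors of
    0.5.  Above-chance play is the norm, so the rule is one-sided by
    default (``accuracy <= 0.5 + 3*SE``); set ``two_sided_accuracy`` for
    the symmetric version.  The fps and non-response rules are tiered: the
    severe threshold scores 2 points, the milder band 1 point.
    """

    fps_severe: float = 35.0
    fps_mild: float = 45.0
    accuracy_se_mult: float = 3.0
    two_sided_accuracy: bool = False
    nonresponse_severe: float = 0.10
    nonresponse_mild: float = 0.03
    stop_rate_low: float = 0.30
    stop_rate_high: float = 0.70
    correction_rate_min: float = 0.30
    exclusion_points: int = 2


@dataclass
class ExclusionReport:
    player_id: str
    points: int
    triggered_rules: list[str] = field(default_factory=list)
    excluded: bool = False

    def __post_init__(self) -> None:
        self.excluded = self.points >= 2


def score_player_exclusions(session: pd.DataFrame,
                            config: ExclusionConfig | None = None,
                            ) -> ExclusionReport:
    """Score one player's session against the exclusion rules.

    2 points each: mean fps below the severe threshold; first-response
    accuracy not above chance by more than 3 binomial SEs; non-response on
    more than 10% of non-lava trials.  1 point each: lava stopping rate
    outside [0.3, 0.7]; error-correction rate below 30% of opportunities
    (separately for non-lava and lava trials); non-response above 3% (but
    not above 10%); mean fps in the mild band.  Rules whose denominator is
    empty are skipped.
    """
    cfg = config or ExclusionConfig()
    test = session[session["phase"] == "test"]
    if len(test) == 0:
        raise ValueError("session has no test-phase trials")
    player_id = str(test["player_id"].iloc[0])
    nonlava = test[~test["lava"].astype(bool)]
    lava = test[test["lava"].astype(bool)]

    points = 0
    rules: list[str] = []

    def hit(name: str, pts: int) -> None:
        nonlocal points
        points += pts
        rules.append(name)

    mean_fps = test["fps"].mean()
    if np.isfinite(mean_fps):
        if mean_fps < cfg.fps_severe:
            hit("fps_below_severe", 2)
        elif mean_fps < cfg.fps_mild:
            hit("fps_below_mild", 1)

    scored = nonlava[nonlava["responded"].astype(bool)]
    n = len(scored)
    if n > 0:
        acc = scored["first_response_correct"].mean()
        se = np.sqrt(0.25 / n)
        near_chance = (abs(acc - 0.5) <= cfg.accuracy_se_mult * se
                       if cfg.two_sided_accuracy
                       else acc <= 0.5 + cfg.accuracy_se_mult * se)
        if near_chance:
            hit("accuracy_near_chance", 2)

    if len(nonlava) > 0:
        nr = 1.0 - nonlava["responded"].mean()
        if nr > cfg.nonresponse_severe:
            hit("nonresponse_above_severe", 2)
        elif nr > cfg.nonresponse_mild:
            hit("nonresponse_above_mild", 1)

    if len(lava) > 0:
        stop_rate = 1.0 - lava["responded"].mean()
        if not cfg.stop_rate_low <= stop_rate <= cfg.stop_rate_high:
            hit("stop_rate_extreme", 1)

    # error-correction opportunities: incorrect first responses (non-lava)
    opp_nl = scored[scored["first_response_correct"] == 0]
    if len(opp_nl) > 0:
        rate = opp_nl["reversal_time"].notna().mean()
        if rate < cfg.correction_rate_min:
            hit("low_correction_rate_nonlava", 1)

    # lava opportunities: trials with a post-signal (late-stopped) response
    opp_lv = lava[lava["responded"].astype(bool)]
    if len(opp_lv) > 0:
        rate = opp_lv["correction_after_release_time"].notna().mean()
        if rate < cfg.correction_rate_min:
            hit("low_correction_rate_lava", 1)

    return ExclusionReport(player_id=player_id, points=points,
                           triggered_rules=rules)


def score_cohort_exclusions(log: pd.DataFrame,
                            config: ExclusionConfig | None = None,
                            ) -> pd.DataFrame:
    """Exclusion report for every player in a cohort log."""
    reports = [score_player_exclusions(d, config)
               for _, d in log.groupby("player_id", sort=True)]
    return pd.DataFrame(
        {"player_id": [r.player_id for r in reports],
         "points": [r.points for r in reports],
         "triggered_rules": [";".join(r.triggered_rules) for r in reports],
         "excluded": [r.excluded for r in reports]})


_RANGE_RULES = {
    # rule_set -> (column filtered by the absolute rule, low, high)
    "rt1": ("time", 300.0, 1500.0),
    "correction": ("delay", -np.inf, 1000.0),
}


def filter_trials(observations: pd.DataFrame, rule_set: str,
                  sd_mult: float = 3.0,
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the trial-level filters for one observation family.

    ``rt1``: drop first-response times outside [300, 1500] ms, then drop
    trials more than 3 SD from the player's mean per condition cell.
    ``correction``: drop corrections more than 1000 ms after their
    reference event (the initial response for non-lava trials, the stop
    signal for lava trials; the table's ``delay`` column), then the same
    per-player-per-condition 3-SD rule on the correction time.  SD rules
    start from the range-filtered set and are iterated to a fixed point
    (convergent trimming), which makes the whole filter idempotent; in
    practice the first pass removes almost everything the rule ever will.

    Returns ``(retained, stats)`` with per-player filter accounting.
    """
    if rule_set not in _RANGE_RULES:
        raise ValueError(f"unknown rule_set {rule_set!r}")
    col, lo, hi = _RANGE_RULES[rule_set]
    obs = observations.copy()
    if len(obs) == 0:
        stats = pd.DataFrame(columns=["player_id", "rule_set", "n_input",
                                      "n_removed_range", "n_removed_sd",
                                      "n_retained"])
        return obs, stats

    in_range = obs[col].between(lo, hi)
    ranged = obs[in_range]

    # per-player, per-condition-cell 3-SD rule on the observation time,
    # iterated to a fixed point (SD 0 removes nothing)
    retained = ranged
    for _ in range(100):
        grp = retained.groupby(["player_id", "cond_cell"])["time"]
        mean = grp.transform("mean")
        sd = grp.transform("std").fillna(0.0)
        keep_sd = (retained["time"] - mean).abs() <= sd_mult * sd
        keep_sd |= sd == 0
        if keep_sd.all():
            break
        retained = retained[keep_sd]

    per_player_in = obs.groupby("player_id").size()
    per_player_ranged = ranged.groupby("player_id").size()
    per_player_kept = retained.groupby("player_id").size()
    stats = pd.DataFrame({"player_id": per_player_in.index})
    stats["rule_set"] = rule_set
    stats["n_input"] = per_player_in.values
    stats["n_removed_range"] = (per_player_in
                                - per_player_ranged.reindex(per_player_in.index,
                                                            fill_value=0)).values
    stats["n_retained"] = per_player_kept.reindex(per_player_in.index,
                                                  fill_value=0).values
    stats["n_removed_sd"] = (stats["n_input"] - stats["n_removed_range"]
                             - stats["n_retained"])
    stats = stats[["player_id", "rule_set", "n_input", "n_removed_range",
                   "n_removed_sd", "n_retained"]]
    return retained.copy(), stats


def measure_eligibility(corrections: pd.DataFrame,
                        tts: pd.DataFrame,
                        lava_trials: pd.DataFrame,
                        min_corrections: int = 3,
                        stop_rate_low: float = 0.30,
                        stop_rate_high: float = 0.70) -> pd.DataFrame:
    """Per-player eligibility flags for each measurement family.

    ``flanker``/``ice``: at least ``min_corrections`` retained
    error-correcting responses in each relevant trial type (both flanker
    conditions among non-ice trials; ice and non-ice trials respectively).
    ``ssrt_tts``: lava stopping rate within [0.30, 0.70], as the
    integration method requires.

    ``corrections`` is a filtered correction table (non-lava) with
    ``flanker_match`` and ``ice`` columns; ``tts`` a filtered TTS table;
    ``lava_trials`` the raw lava trial records.
    """
    players = sorted(lava_trials["player_id"].unique())
    out = pd.DataFrame(index=pd.Index(players, name="player_id"))

    def count_cell(df: pd.DataFrame, mask) -> pd.Series:
        sub = df[mask] if mask is not None else df
        return sub.groupby("player_id").size().reindex(out.index, fill_value=0)

    noice = ~corrections["ice"].astype(bool)
    fm = corrections["flanker_match"].astype(bool)
    out["flanker"] = ((count_cell(corrections, noice & fm) >= min_corrections)
                      & (count_cell(corrections, noice & ~fm) >= min_corrections))
    ice = corrections["ice"].astype(bool)
    out["ice"] = ((count_cell(corrections, ice) >= min_corrections)
                  & (count_cell(corrections, ~ice) >= min_corrections))

    stop_rate = (1.0 - lava_trials.groupby("player_id")["responded"].mean()
                 ).reindex(out.index)
    out["ssrt_tts"] = stop_rate.between(stop_rate_low, stop_rate_high)
    out["n_tts"] = tts.groupby("player_id").size().reindex(out.index,
                                                           fill_value=0)
    return out.reset_index()
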