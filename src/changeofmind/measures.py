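"""Reaction-time and stop-signal measures extracted from session logs.

Four quantities feed the downstream models:

* RT1 -- time from the central rat's color assignment to a correct first
  response.
* RT2 -- time from color assignment to the initiation of the reversal of
  an incorrect first response (the change of mind).
* TTS -- time from the stop signal to the release of an ongoing initial
  response in a lava trial, counted only when a corrective response
  follows (showing clear recognition of the error).
* SSRT -- integration-method stop-signal reaction time: the go-RT
  distribution's respond-rate percentile minus the mean stop-signal
  delay, computed separately per flanker condition with condition-matched
  go-RT sets.

The z-composite averages per-player standardized SSRT sub-measures, with
or without TTS as a third sub-measure.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = [
    "extract_response_table",
    "extract_tts_table",
    "ssrt_integration",
    "ssrt_results",
    "composite_z_average",
]


def _cond_cell(flanker_match: pd.Series, ice: pd.Series) -> pd.Series:
    f = np.where(flanker_match.astype(bool), "match", "mismatch")
    i = np.where(ice.astype(bool), "ice", "noice")
    return pd.Series([f"{a}_{b}" for a, b in zip(f, i)],
                     index=flanker_match.index)


def extract_response_table(log: pd.DataFrame) -> pd.DataFrame:
    """Long observation table for non-lava test trials.

    One row per correct first response (``response_type="first"``, time =
    first response time), per incorrect first response
    (``first_incorrect``; kept separately so the conflict effect on RT2
    can be decomposed), and per error-correcting response (``correction``,
    time = reversal time).  All times are clocked from the central rat's
    color assignment.  Non-response trials contribute no rows.
    """
    test = log[(log["phase"] == "test") & (~log["lava"].astype(bool))]
    resp = test[test["responded"].astype(bool)]

    def rows(sub: pd.DataFrame, rtype: str, timecol: str,
             delay: pd.Series | None) -> pd.DataFrame:
        out = pd.DataFrame({
            "player_id": sub["player_id"].to_numpy(),
            "trial_index": sub["trial_index"].to_numpy(),
            "flanker_match": sub["flanker_match"].astype(bool).to_numpy(),
            "ice": sub["ice"].astype(bool).to_numpy(),
            "response_type": rtype,
            "time": sub[timecol].to_numpy(dtype=float),
        })
        out["delay"] = (delay.to_numpy(dtype=float)
                        if delay is not None else np.nan)
        out["cond_cell"] = _cond_cell(out["flanker_match"], out["ice"]).to_numpy()
        return out

    correct = resp[resp["first_response_correct"] == 1]
    incorrect = resp[resp["first_response_correct"] == 0]
    corrections = incorrect[incorrect["reversal_time"].notna()]

    parts = [
        rows(correct, "first", "first_response_time", None),
        rows(incorrect, "first_incorrect", "first_response_time", None),
        rows(corrections, "correction", "reversal_time",
             corrections["reversal_time"] - corrections["first_response_time"]),
    ]
    table = pd.concat(parts, ignore_index=True)
    return table.sort_values(["player_id", "trial_index",
                              "response_type"]).reset_index(drop=True)


def extract_tts_table(log: pd.DataFrame) -> pd.DataFrame:
    """Per-trial TTS observations from lava test trials.

    TTS = release time - stop-signal delay, emitted only when the late
    stop was followed by a corrective response.  ``delay`` holds the time
    from the stop signal to that corrective response (used by the 1-second
    correction filter).
    """
    lava = log[(log["phase"] == "test") & (log["lava"].astype(bool))]
    ok = lava[lava["responded"].astype(bool)
              & lava["release_time"].notna()
              & lava["correction_after_release_time"].notna()]
    out = pd.DataFrame({
        "player_id": ok["player_id"].to_numpy(),
        "trial_index": ok["trial_index"].to_numpy(),
        "flanker_match": ok["flanker_match"].astype(bool).to_numpy(),
        "time": (ok["release_time"] - ok["ssd"]).to_numpy(dtype=float),
        "delay": (ok["release_time"] + ok["correction_after_release_time"]
                  - ok["ssd"]).to_numpy(dtype=float),
    })
    out["cond_cell"] = np.where(out["flanker_match"], "match", "mismatch")
    return out.reset_index(drop=True)


def ssrt_integration(go_rts, stop_trials) -> float:
    """Integration-method SSRT for one player and condition.

    ``go_rts`` are the condition-matched go reaction times with NaN for
    non-response trials; ``stop_trials`` is an iterable of
    ``(ssd, responded)`` pairs.  Non-responses are replaced by the maximum
    observed go RT, the go RTs sorted ascending, and SSRT is the RT at
    rank ``ceil(p * n)`` (1-based) minus the mean SSD, where ``p`` is the
    probability of responding given a stop signal.  Undefined when the
    respond rate is 0 or 1.
    """
    go = np.asarray(list(go_rts), dtype=float)
    if go.size == 0:
        raise ValueError("go_rts must be non-empty")
    stops = list(stop_trials)
    if not stops:
        raise ValueError("stop_trials must be non-empty")
    responded = np.array([bool(r) for _, r in stops])
    p = responded.mean()
    if p <= 0.0 or p >= 1.0:
        raise ValueError(f"respond rate {p} outside (0, 1); SSRT undefined")
    if np.all(np.isnan(go)):
        raise ValueError("all go RTs missing")
    go = go.copy()
    go[np.isnan(go)] = np.nanmax(go)
    go.sort(kind="stable")
    rank = math.ceil(p * go.size)  # 1-based
    rank = min(max(rank, 1), go.size)
    mean_ssd = float(np.mean([s for s, _ in stops]))
    return float(go[rank - 1] - mean_ssd)


def _go_set(nonlava_test: pd.DataFrame, flanker_match: bool) -> np.ndarray:
    """Condition-matched go RTs (non-ice), NaN for non-responses."""
    sub = nonlava_test[(nonlava_test["flanker_match"].astype(bool) == flanker_match)
                       & (~nonlava_test["ice"].astype(bool))]
    rts = sub["first_response_time"].to_numpy(dtype=float)
    rts[~sub["responded"].astype(bool).to_numpy()] = np.nan
    return rts


def ssrt_results(log: pd.DataFrame, tts_table: pd.DataFrame | None = None,
                 ) -> pd.DataFrame:
    """Per-player SSRT sub-measures and mean TTS.

    The matching-flanker SSRT uses regular trials as its go-RT reference,
    the mismatching SSRT uses mismatching-flanker (non-ice, non-lava)
    trials, mirroring the conditioning of the SSD staircases.  No trial
    filtering is applied to SSRT inputs.  Players whose respond rate makes
    the method undefined get NaN.
    """
    test = log[log["phase"] == "test"]
    nonlava = test[~test["lava"].astype(bool)]
    lava = test[test["lava"].astype(bool)]
    rows = []
    for pid, d in lava.groupby("player_id", sort=True):
        rec: dict = {"player_id": pid}
        for fm, name in ((True, "match"), (False, "mismatch")):
            dl = d[d["flanker_match"].astype(bool) == fm]
            go = _go_set(nonlava[nonlava["player_id"] == pid], fm)
            try:
                rec[f"ssrt_{name}"] = ssrt_integration(
                    go, zip(dl["ssd"], dl["responded"]))
            except ValueError:
                rec[f"ssrt_{name}"] = np.nan
            rec[f"n_stop_{name}"] = len(dl)
        rows.append(rec)
    out = pd.DataFrame(rows)
    if tts_table is not None and len(tts_table):
        tts_mean = tts_table.groupby("player_id")["time"].mean()
        out["tts_mean"] = out["player_id"].map(tts_mean)
    else:
        out["tts_mean"] = np.nan
    return out


def composite_z_average(submeasures: pd.DataFrame) -> pd.Series:
    """Per-player mean of column-wise z-scores.

    Standardization uses the (n-1) SD convention over the supplied cohort
    (rows with any missing column are dropped first).  Supports the
    2-column (first-responses-only) and 3-column (with TTS) variants.
    """
    if submeasures.shape[1] < 2:
        raise ValueError("need at least 2 sub-measure columns")
    data = submeasures.dropna()
    sds = data.std(ddof=1)
    if (sds == 0).any() or sds.isna().any():
        bad = list(sds.index[(sds == 0) | sds.isna()])
        raise ValueError(f"zero-variance sub-measure column(s): {bad}")
    z = (data - data.mean()) / sds
    return z.mean(axis=1)
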