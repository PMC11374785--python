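"""End-to-end pipeline: simulate -> preprocess -> measure -> model -> report.

A run simulates one cohort per study replicate (two replicates by
default, mirroring a two-study design), applies the exclusion and
filtering rules, extracts the measures, fits the hierarchical models, and
assembles a report with:

* a trials-per-measurement table (``table1``),
* conflict effects per response type with CR2 CIs and the RT2-RT1
  differences (``table2``),
* correlations between first-response and error-correction effects
  (``fig4``),
* reliability of first-only vs. combined measurements (``table3``), and
* measurement precision eta per measure (``table4``),

plus a provenance block (config hash, seed, package versions).  Stage
outputs are written as CSV/JSON files; the report references only numbers
computed from those files.  Identical configs produce byte-identical
reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import measures, models, preprocess, reliability
from .simkit import GameConfig, PopulationParams, simulate_cohort

__all__ = ["RunConfig", "run_pipeline", "simulate_stage", "analyze_stage",
           "make_report", "read_session_log"]

# canonical session-log schema (one row per trial)
SESSION_COLUMNS = [
    "player_id", "trial_index", "phase", "flanker_match", "ice", "lava",
    "ssd", "go_window", "responded", "first_response_time",
    "first_response_correct", "reversal_time", "release_time",
    "correction_after_release_time", "success", "fps",
]


def read_session_log(path, column_map: dict[str, str] | None = None,
                     ) -> pd.DataFrame:
    """Read a trial-level session log CSV into the canonical schema.

    ``column_map`` maps source column names to the canonical names in
    ``SESSION_COLUMNS``, so exports with different headers (e.g. a
    real-data deposit) can feed the same analysis chain.  Missing event
    times may be empty cells; boolean columns accept 0/1 or true/false.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in SESSION_COLUMNS if c not in df.columns and c != "fps"]
    if missing:
        raise ValueError(f"session log missing required columns: {missing}")
    if "fps" not in df.columns:
        df["fps"] = np.nan
    for col in ("flanker_match", "ice", "lava", "responded", "success"):
        df[col] = df[col].astype(bool)
    for col in ("ssd", "go_window", "first_response_time",
                "first_response_correct", "reversal_time", "release_time",
                "correction_after_release_time", "fps"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df[SESSION_COLUMNS]

log = logging.getLogger("changeofmind")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one full pipeline run."""

    n_players: int = 60
    n_studies: int = 2
    seed: int = 1234
    b_boot: int = 500
    variant: str = "both"  # first_only | combined | both
    reliability_ci: bool = False
    game: GameConfig = field(default_factory=GameConfig)
    population: PopulationParams = field(default_factory=PopulationParams)

    def __post_init__(self) -> None:
        if self.variant not in ("first_only", "combined", "both"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.n_players < 2 or self.n_studies < 1:
            raise ValueError("need at least 2 players and 1 study")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["game"]["lava_match_split"] = list(self.game.lava_match_split)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        game = d.pop("game", None)
        pop = d.pop("population", None)
        kwargs = dict(d)
        if game is not None:
            kwargs["game"] = GameConfig.from_json(json.dumps(game))
        if pop is not None:
            pop_kwargs = {}
            for key, val in pop.items():
                pop_kwargs[key] = val
            kwargs["population"] = PopulationParams.from_json(json.dumps(pop))
        return cls(**kwargs)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def _round(x, nd=4):
    if x is None:
        return None
    if isinstance(x, float) and not np.isfinite(x):
        return None
    return round(float(x), nd)


def simulate_stage(config: RunConfig, out_dir: Path) -> None:
    """Simulate each study's cohort and write session/truth CSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_studies)
    for s, child in enumerate(children, start=1):
        log.info("simulate: study %d (%d players)", s, config.n_players)
        cohort_log, truth = simulate_cohort(
            config.population, config.n_players, config.game,
            seed=np.random.default_rng(child))
        cohort_log.to_csv(out_dir / f"sessions_study{s}.csv", index=False)
        truth.to_csv(out_dir / f"truth_study{s}.csv", index=False)
    (out_dir / "config.json").write_text(config.to_json())


def _split_half_ci(even_odd_scores: pd.DataFrame, B: int, seed) -> tuple:
    """BCa CI for the Spearman-Brown split-half r by resampling players'
    half-score pairs (no model refit; an approximation to the full
    refit bootstrap)."""

    def stat(arr) -> float:
        r = np.corrcoef(arr[:, 0], arr[:, 1])[0, 1]
        return 2.0 * r / (1.0 + r)

    arr = even_odd_scores.to_numpy()
    lo, hi, _ = reliability.bca_ci(stat, arr, B=B, seed=seed)
    return lo, hi


def _omega_ci(indicators: pd.DataFrame, B: int, seed) -> tuple:
    def stat(arr) -> float:
        return reliability.mcdonalds_omega(
            pd.DataFrame(arr, columns=list("abc")[: arr.shape[1]]))

    lo, hi, _ = reliability.bca_ci(stat, indicators.dropna().to_numpy(),
                                   B=B, seed=seed)
    return lo, hi


def _cr_dict(cr: models.CRInference) -> dict:
    return {"estimate": _round(cr.estimate), "se": _round(cr.se),
            "df": _round(cr.df, 1), "t": _round(cr.t, 2),
            "p": _round(cr.p, 5),
            "ci": [_round(cr.ci_low), _round(cr.ci_high)]}


def _corr_dict(c: models.EffectCorrelation) -> dict:
    return {"r": _round(c.r, 3), "ci": [_round(c.ci_low, 3), _round(c.ci_high, 3)],
            "t": _round(c.t, 2), "df": int(c.df), "p": _round(c.p, 5)}


def _analyze_study(cohort_log: pd.DataFrame, config: RunConfig, study: int,
                   out_dir: Path, seed: int) -> dict:
    result: dict = {"study": study}

    # ---- preprocessing -------------------------------------------------
    excl = preprocess.score_cohort_exclusions(cohort_log)
    excl.to_csv(out_dir / f"exclusions_study{study}.csv", index=False)
    rule_counts = (pd.Series(
        [r for rules in excl["triggered_rules"] for r in rules.split(";") if r])
        .value_counts().to_dict())
    kept_players = set(excl.loc[~excl["excluded"], "player_id"])
    result["exclusions"] = {
        "n_players": int(len(excl)),
        "n_excluded": int(excl["excluded"].sum()),
        "rule_counts": {k: int(v) for k, v in sorted(rule_counts.items())},
    }
    kept_log = cohort_log[cohort_log["player_id"].isin(kept_players)]

    # ---- measures ------------------------------------------------------
    table = measures.extract_response_table(kept_log)
    firsts = table[table["response_type"].isin(["first", "first_incorrect"])]
    corrections = table[table["response_type"] == "correction"]
    firsts_f, stats_rt1 = preprocess.filter_trials(firsts, "rt1")
    corr_f, stats_corr = preprocess.filter_trials(corrections, "correction")
    tts_raw = measures.extract_tts_table(kept_log)
    tts_f, stats_tts = preprocess.filter_trials(tts_raw, "correction")
    pd.concat([stats_rt1, stats_corr, stats_tts], ignore_index=True).to_csv(
        out_dir / f"filter_stats_study{study}.csv", index=False)
    obs = pd.concat([firsts_f, corr_f], ignore_index=True)
    obs.to_csv(out_dir / f"observations_study{study}.csv", index=False)
    tts_f.to_csv(out_dir / f"tts_study{study}.csv", index=False)

    lava = kept_log[(kept_log["phase"] == "test") & kept_log["lava"].astype(bool)]
    elig = preprocess.measure_eligibility(corr_f, tts_f, lava)
    elig.to_csv(out_dir / f"eligibility_study{study}.csv", index=False)
    elig = elig.set_index("player_id")
    result["eligibility"] = {
        "flanker": int(elig["flanker"].sum()),
        "ice": int(elig["ice"].sum()),
        "ssrt_tts": int((elig["ssrt_tts"] & (elig["n_tts"] >= 3)).sum()),
    }

    ssrt = measures.ssrt_results(kept_log, tts_f)
    ssrt.to_csv(out_dir / f"ssrt_study{study}.csv", index=False)

    # ---- table 1: trials per measurement -------------------------------
    n_kept = max(len(kept_players), 1)

    def per_player(df) -> float:
        return _round(len(df) / n_kept, 1)

    result["table1"] = {
        "ice_first_responses": per_player(
            firsts_f[firsts_f["response_type"] == "first"]),
        "ice_error_corrections": per_player(corr_f),
        "flanker_first_responses": per_player(
            firsts_f[(firsts_f["response_type"] == "first")
                     & (~firsts_f["ice"])]),
        "flanker_error_corrections": per_player(corr_f[~corr_f["ice"]]),
        "ssrt_lava_trials": per_player(lava),
        "tts_observations": per_player(tts_f),
    }

    # ---- conflict-effect models (table 2 + fig 4) ----------------------
    table_f = pd.concat([firsts_f[firsts_f["response_type"] == "first"],
                         corr_f], ignore_index=True)
    result["table2"] = {}
    result["fig4"] = {}
    result["table4"] = {}
    effects_store: dict[str, pd.DataFrame] = {}
    for conflict in ("flanker", "ice"):
        ok_players = set(elig.index[elig[conflict]]) & kept_players
        frame = models.conflict_model_frame(
            table_f[table_f["player_id"].isin(ok_players)], conflict)
        if frame["player_id"].nunique() < 4:
            result["table2"][conflict] = "not run (too few eligible players)"
            continue
        fit = models.fit_mixed_model(frame, models.ModelSpec("maximal_joint"))
        if not fit.converged:
            result["table2"][conflict] = "not run (model did not converge)"
            continue
        c_rt2 = np.array([0.0, 1.0, 0.0, 1.0])
        X = frame[fit.spec.fixed].to_numpy(dtype=float)
        Z = frame[fit.spec.random].to_numpy(dtype=float)
        y = frame["time"].to_numpy(dtype=float)
        grp = frame["player_id"].to_numpy()
        rt2_cr = models.cr2_core(X, y, grp, Z, fit.cov_re.to_numpy(),
                                 fit.resid_sd ** 2, c_rt2)
        diff_cr = models.cr2_inference(fit, "inter")
        rt1_cr = models.cr2_inference(fit, "trial")
        result["table2"][conflict] = {
            "effect_rt1": _cr_dict(rt1_cr),
            "effect_rt2": _cr_dict(rt2_cr),
            "difference_rt2_minus_rt1": _cr_dict(diff_cr),
            "converged": bool(fit.converged),
        }
        eff = models.player_effects(fit)
        effects_store[conflict] = eff
        eff.to_csv(out_dir / f"effects_{conflict}_study{study}.csv",
                   index=False)
        result["fig4"][conflict] = _corr_dict(
            models.correlate_effects(eff["effect_rt1"], eff["effect_rt2"]))

        # table 4: single-response precision per response type
        for rtype, label in ((0.0, "rt1"), (1.0, "rt2")):
            sub = frame[frame["resp"] == rtype]
            if sub["player_id"].nunique() >= 4:
                sfit = models.fit_mixed_model(
                    sub, models.ModelSpec("single_response"))
                result["table4"][f"{conflict}_effect_{label}"] = _round(
                    models.precision_eta(sfit, "trial"), 2)

    # ---- TTS / SSRT ----------------------------------------------------
    ssrt_ok = set(elig.index[elig["ssrt_tts"] & (elig["n_tts"] >= 3)])
    tts_use = tts_f[tts_f["player_id"].isin(ssrt_ok)]
    ssrt_use = ssrt.set_index("player_id").loc[
        sorted(ssrt_ok & set(ssrt["player_id"]))]
    tts_score = None
    tfit = None
    if tts_use["player_id"].nunique() >= 4:
        tfit = models.fit_mixed_model(models.tts_model_frame(tts_use),
                                      models.ModelSpec("tts_model"))
        if not tfit.converged:
            tfit = None
    if tfit is not None:
        tts_cr = models.cr2_inference(tfit, "trial")
        result["table2"]["tts_flanker"] = _cr_dict(tts_cr)
        result["table4"]["tts"] = _round(
            models.precision_eta(tfit, "const"), 2)
        tts_score = tfit.params["const"] + tfit.modes["const"]

        # flanker effect on SSRT vs TTS: paired t across players
        per_cond = (tts_use.groupby(["player_id", "flanker_match"])["time"]
                    .mean().unstack())
        if per_cond.shape[1] == 2:
            tts_eff = per_cond[False] - per_cond[True]
            ssrt_eff = ssrt_use["ssrt_mismatch"] - ssrt_use["ssrt_match"]
            both = pd.concat({"tts": tts_eff, "ssrt": ssrt_eff},
                             axis=1).dropna()
            if len(both) >= 4:
                pt = models.paired_t(both["tts"], both["ssrt"])
                result["table2"]["difference_tts_minus_ssrt_flanker"] = {
                    "mean_diff": _round(pt.mean_diff),
                    "ci": [_round(pt.ci_low), _round(pt.ci_high)],
                    "t": _round(pt.t, 2), "df": int(pt.df),
                    "p": _round(pt.p, 5)}

        sub = ssrt_use[["ssrt_match", "ssrt_mismatch"]].dropna()
        comp = measures.composite_z_average(sub)
        common = comp.index.intersection(tts_score.index)
        if len(common) >= 4:
            result["fig4"]["ssrt_tts"] = _corr_dict(
                models.correlate_effects(comp.loc[common],
                                         tts_score.loc[common]))
    else:
        result["table2"]["tts_flanker"] = ("not run (too few eligible "
                                           "players or no convergence)")

    # ---- reliability (table 3) ----------------------------------------
    variants = (("first_only", "combined") if config.variant == "both"
                else (config.variant,))
    rel: dict = {}
    rng_seed = (seed * 1009 + study * 7919) % (2 ** 31)
    for conflict in ("flanker", "ice"):
        ok_players = set(elig.index[elig[conflict]]) & kept_players
        frame = models.conflict_model_frame(
            table_f[table_f["player_id"].isin(ok_players)], conflict)
        if frame["player_id"].nunique() < 4:
            rel[conflict] = "not run (too few eligible players)"
            continue
        rel[conflict] = {}
        for variant in variants:
            fn = reliability.conflict_measure_fn(variant)
            res = reliability.split_half_reliability(frame, fn)
            entry = {"r": _round(res.r_corrected, 3),
                     "r_raw": _round(res.r_raw, 3),
                     "n_players": res.n_players,
                     "n_dropped": res.n_dropped}
            if config.reliability_ci:
                even, odd = reliability.even_odd_halves(frame)
                pairs = pd.concat({"even": fn(even), "odd": fn(odd)},
                                  axis=1).dropna()
                lo, hi = _split_half_ci(pairs, config.b_boot, rng_seed)
                entry["ci"] = [_round(lo, 3), _round(hi, 3)]
            rel[conflict][variant] = entry

    sub = ssrt_use[["ssrt_match", "ssrt_mismatch"]].dropna() \
        if tfit is not None else pd.DataFrame()
    if len(sub) >= 4:
        rel["ssrt"] = {}
        z2 = (sub - sub.mean()) / sub.std(ddof=1)
        if "first_only" in variants:
            entry = {"omega": _round(reliability.mcdonalds_omega(z2), 3),
                     "n_players": len(z2)}
            if config.reliability_ci:
                lo, hi = _omega_ci(z2, config.b_boot, rng_seed + 1)
                entry["ci"] = [_round(lo, 3), _round(hi, 3)]
            rel["ssrt"]["first_only"] = entry
        if "combined" in variants and tts_score is not None:
            z3 = z2.copy()
            z3["tts"] = ((tts_score - tts_score.mean())
                         / tts_score.std(ddof=1))
            z3 = z3.dropna()
            entry = {"omega": _round(reliability.mcdonalds_omega(z3), 3),
                     "n_players": len(z3)}
            if config.reliability_ci:
                lo, hi = _omega_ci(z3, config.b_boot, rng_seed + 2)
                entry["ci"] = [_round(lo, 3), _round(hi, 3)]
            rel["ssrt"]["combined"] = entry
    else:
        rel["ssrt"] = "not run (too few eligible players)"
    result["table3"] = rel
    return result


def analyze_stage(config: RunConfig, out_dir: Path) -> dict:
    """Run preprocessing, measures, models and reliability per study."""
    out_dir = Path(out_dir)
    studies = []
    for s in range(1, config.n_studies + 1):
        path = out_dir / f"sessions_study{s}.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing stage output {path}")
        log.info("analyze: study %d", s)
        cohort_log = pd.read_csv(path)
        studies.append(_analyze_study(cohort_log, config, s, out_dir,
                                      config.seed))
    analysis = {"studies": studies}
    (out_dir / "analysis.json").write_text(
        json.dumps(analysis, indent=2, sort_keys=True))
    return analysis


def make_report(out_dir: Path) -> dict:
    """Assemble the final report from stage output files."""
    out_dir = Path(out_dir)
    cfg_path = out_dir / "config.json"
    ana_path = out_dir / "analysis.json"
    if not cfg_path.exists():
        raise FileNotFoundError(f"missing stage output {cfg_path}")
    config = RunConfig.from_json(cfg_path.read_text())
    if ana_path.exists():
        analysis = json.loads(ana_path.read_text())
    else:
        analysis = {"studies": "not run"}

    import scipy
    import statsmodels

    report = {
        "provenance": {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "n_players": config.n_players,
            "n_studies": config.n_studies,
            "versions": {"numpy": np.__version__,
                         "scipy": scipy.__version__,
                         "pandas": pd.__version__,
                         "statsmodels": statsmodels.__version__},
        },
        "studies": analysis["studies"],
    }
    (out_dir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True))
    return report


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute all stages in order and return the report."""
    out_dir = Path(out_dir)
    simulate_stage(config, out_dir)
    analyze_stage(config, out_dir)
    return make_report(out_dir)
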