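"""Reliability and its uncertainty for first-response and combined measures.

* Even-odd split-half reliability (trials split by within-condition parity
  of trial index, Spearman-Brown corrected), with the hierarchical model
  refitted per half for model-based measures.
* McDonald's omega for the z-composite SSRT (two or three standardized
  sub-measures, single-factor).
* BCa (bias-corrected and accelerated) bootstrap confidence intervals,
  resampling players -- reliability is a between-player statistic.
* Translation of a reliability increment into the equivalent gain at a
  baseline reliability of 0.50, via the effective trial multiplier.
* A simulation probing whether the player bootstrap correctly captures
  the association between the reliabilities of two *nested* measurements
  (one measure's trials contained in the other's).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .models import ModelSpec, fit_mixed_model

__all__ = [
    "SplitHalfResult",
    "split_half_reliability",
    "even_odd_halves",
    "conflict_measure_fn",
    "mcdonalds_omega",
    "BcaParams",
    "bca_ci",
    "trial_equivalent_gain",
    "NestedSimConfig",
    "nested_bootstrap_validity_sim",
]


# ---------------------------------------------------------------------------
# split-half reliability
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplitHalfResult:
    r_raw: float
    r_corrected: float  # Spearman-Brown full-length estimate
    n_players: int
    n_dropped: int


def even_odd_halves(observations: pd.DataFrame,
                    condition_cols: tuple[str, ...] = ("trial", "resp"),
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split observations into even/odd halves.

    Trials are ordered by ``trial_index`` within each player x condition
    cell and assigned to halves by rank parity, so both halves carry the
    same condition composition.
    """
    keys = ["player_id", *condition_cols]
    rank = (observations.sort_values("trial_index")
            .groupby(keys, sort=False).cumcount())
    rank = rank.reindex(observations.index)
    even = observations[rank % 2 == 0]
    odd = observations[rank % 2 == 1]
    return even, odd


def split_half_reliability(observations: pd.DataFrame,
                           measure_fn: Callable[[pd.DataFrame], pd.Series],
                           condition_cols: tuple[str, ...] = ("trial", "resp"),
                           ) -> SplitHalfResult:
    """Even-odd split-half reliability of a per-player measure.

    ``measure_fn`` maps an observation table to a per-player score Series
    (refitting any model involved); players with an undefined score in
    either half are dropped and counted.  The half-length correlation is
    Spearman-Brown corrected to full length: r_full = 2r / (1 + r).
    """
    even, odd = even_odd_halves(observations, condition_cols)
    s_even = measure_fn(even)
    s_odd = measure_fn(odd)
    joined = pd.concat({"even": s_even, "odd": s_odd}, axis=1)
    total = len(joined)
    joined = joined.replace([np.inf, -np.inf], np.nan).dropna()
    n = len(joined)
    if n < 3:
        raise ValueError("fewer than 3 players with defined half-measures")
    r = float(np.corrcoef(joined["even"], joined["odd"])[0, 1])
    r_full = 2.0 * r / (1.0 + r) if r > -1.0 else -1.0
    r_full = float(np.clip(r_full, -1.0, 1.0))
    return SplitHalfResult(r_raw=r, r_corrected=float(r_full),
                           n_players=n, n_dropped=total - n)


def conflict_measure_fn(variant: str) -> Callable[[pd.DataFrame], pd.Series]:
    """Per-player conflict-effect score from a joint model frame.

    ``first_only`` fits the single-response model to first responses;
    ``combined`` fits the shared-conflict model to first and
    error-correcting responses jointly (individual differences in the
    conflict effect shared between response types).  Either way the score
    is the fixed trial-type effect plus the player's conditional mode.
    """
    if variant not in ("first_only", "combined"):
        raise ValueError(f"unknown variant {variant!r}")

    def fn(frame: pd.DataFrame) -> pd.Series:
        if variant == "first_only":
            sub = frame[frame["resp"] == 0]
            spec = ModelSpec("single_response")
        else:
            sub = frame
            spec = ModelSpec("shared_conflict")
        fit = fit_mixed_model(sub, spec)
        score = fit.params["trial"] + fit.modes["trial"]
        score.name = variant
        return score

    return fn


# ---------------------------------------------------------------------------
# McDonald's omega
# ---------------------------------------------------------------------------


def mcdonalds_omega(indicators: pd.DataFrame) -> float:
    """Single-factor composite reliability of 2 or 3 standardized indicators.

    omega = (sum lambda)^2 / ((sum lambda)^2 + sum theta).  With three
    indicators the one-factor model is just identified and the loadings
    have the closed-form triad solution
    ``lambda_1 = sqrt(r12 * r13 / r23)`` (and rotations thereof), which is
    the unconstrained fit; with two indicators the model is identified
    under an equal-loadings constraint, ``lambda = sqrt(r12)``.  A
    non-positive correlation makes the composite incoherent and is
    signalled; a Heywood solution (loading above 1) is replaced by the
    boundary-constrained solution (loading 1, zero uniqueness).
    """
    data = indicators.dropna()
    k = data.shape[1]
    if k not in (2, 3):
        raise ValueError("omega implemented for 2 or 3 indicators")
    if len(data) < 3:
        raise ValueError("need at least 3 players")
    z = (data - data.mean()) / data.std(ddof=1)
    R = np.corrcoef(z.to_numpy(), rowvar=False)
    if k == 2:
        r12 = R[0, 1]
        if r12 <= 0:
            raise ValueError("negative inter-indicator correlation; "
                             "composite incoherent")
        lam = np.sqrt(r12) * np.ones(2)
    else:
        r12, r13, r23 = R[0, 1], R[0, 2], R[1, 2]
        prods = np.array([r12 * r13 / r23, r12 * r23 / r13, r13 * r23 / r12])
        if min(r12, r13, r23) <= 0 or np.any(prods <= 0):
            raise ValueError("non-positive correlation structure; "
                             "composite incoherent")
        lam = np.sqrt(prods)
    lam = np.clip(lam, 0.0, 1.0)  # Heywood case -> boundary solution
    theta = 1.0 - lam ** 2
    s = lam.sum()
    return float(s * s / (s * s + theta.sum()))


# ---------------------------------------------------------------------------
# BCa bootstrap
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BcaParams:
    z0: float
    a: float
    B: int
    seed: int | None


def _unit_resampler(data):
    """Return ``(n_units, fn)`` where fn maps unit indices to a resample."""
    if isinstance(data, pd.DataFrame) and "player_id" in data.columns:
        groups = [df for _, df in data.groupby("player_id", sort=False)]

        def take_df(take: np.ndarray):
            return pd.concat([groups[i] for i in take], ignore_index=True)

        return len(groups), take_df
    arr = np.asarray(data)
    return len(arr), lambda take: arr[take]


def bca_ci(stat_fn: Callable, data, B: int = 2000, seed=None,
           alpha: float = 0.05,
           force_z0: float | None = None,
           force_a: float | None = None,
           ) -> tuple[float, float, BcaParams]:
    """Bias-corrected and accelerated bootstrap CI, resampling players.

    If ``data`` is a DataFrame with a ``player_id`` column the resampling
    unit is the player (cluster bootstrap); otherwise rows of an array are
    resampled.  ``z0`` comes from the proportion of bootstrap statistics
    below the point estimate, ``a`` from the jackknife-over-units skewness.
    With ``force_z0=force_a=0`` the interval reduces to the plain
    percentile interval.  Fails if the statistic is undefined on more than
    5% of resamples.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    rng = np.random.default_rng(seed)
    n, resample = _unit_resampler(data)
    theta = float(stat_fn(data))

    boot = np.empty(B)
    failed = 0
    for b in range(B):
        take = rng.integers(0, n, n)
        try:
            val = float(stat_fn(resample(take)))
        except (ValueError, ZeroDivisionError, np.linalg.LinAlgError):
            val = np.nan
        if not np.isfinite(val):
            failed += 1
            val = np.nan
        boot[b] = val
    if failed > 0.05 * B:
        raise ValueError(f"statistic undefined on {failed}/{B} resamples")
    boot = boot[np.isfinite(boot)]

    if force_z0 is not None:
        z0 = float(force_z0)
    else:
        prop = np.mean(boot < theta)
        prop = min(max(prop, 1.0 / (len(boot) + 1)),
                   1.0 - 1.0 / (len(boot) + 1))
        z0 = float(stats.norm.ppf(prop))
    if force_a is not None:
        a = float(force_a)
    else:
        jack = np.empty(n)
        for i in range(n):
            keep = np.delete(np.arange(n), i)
            jack[i] = float(stat_fn(resample(keep)))
        jm = jack.mean()
        num = np.sum((jm - jack) ** 3)
        den = 6.0 * np.sum((jm - jack) ** 2) ** 1.5
        a = float(num / den) if den > 0 else 0.0

    z_lo = stats.norm.ppf(alpha / 2.0)
    z_hi = stats.norm.ppf(1.0 - alpha / 2.0)

    def adj(z_alpha: float) -> float:
        num = z0 + z_alpha
        return float(stats.norm.cdf(z0 + num / (1.0 - a * num)))

    lo, hi = np.quantile(boot, [adj(z_lo), adj(z_hi)])
    return float(lo), float(hi), BcaParams(z0=z0, a=a, B=B, seed=seed)


# ---------------------------------------------------------------------------
# reliability increment -> equivalent trials at a baseline
# ---------------------------------------------------------------------------


def trial_equivalent_gain(r1: float, r2: float, baseline: float = 0.50,
                          ) -> float:
    """Map a reliability increment r1 -> r2 onto a baseline reliability.

    Under the standard trial-number reliability relation
    ``R(n) = n*q / (n*q + 1)`` (q the per-trial signal-to-noise ratio),
    multiplying the trial count by ``m`` multiplies the reliability odds
    ``R/(1-R)`` by ``m``.  The increment r1 -> r2 therefore implies the
    multiplier ``m = [r2/(1-r2)] / [r1/(1-r1)]``, which applied to the
    baseline's odds gives the mapped reliability.  Equal reliabilities
    return the baseline unchanged; the mapping is monotone in r2.
    """
    if not (0.0 < r1 < 1.0 and 0.0 < r2 < 1.0 and 0.0 < baseline < 1.0):
        raise ValueError("reliabilities must lie strictly in (0, 1)")
    if r2 < r1:
        raise ValueError("r2 < r1: no reliability gain to translate")
    m = (r2 / (1.0 - r2)) / (r1 / (1.0 - r1))
    odds = baseline / (1.0 - baseline)
    return float(m * odds / (1.0 + m * odds))


# ---------------------------------------------------------------------------
# nested-bootstrap validity simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NestedSimConfig:
    """Design of the nested-measurement bootstrap check.

    Measure A scores ``n_trials_base`` trials per player; measure B scores
    either the same trials plus ``n_trials_extra`` more (``shared=True``,
    the nested case -- e.g. a first-response measure vs. the same measure
    supplemented with error-corrections) or an equally sized independent
    trial set (``shared=False``).
    """

    n_players: int = 80
    n_trials_base: int = 40
    n_trials_extra: int = 20
    true_sd: float = 1.0
    noise_sd: float = 2.0
    shared: bool = True
    n_cohorts: int = 200
    B: int = 500
    seed: int | None = None


def _split_half_of_trials(trials: np.ndarray) -> float:
    """Even-odd split-half (Spearman-Brown) of a players x trials matrix."""
    even = trials[:, 0::2].mean(axis=1)
    odd = trials[:, 1::2].mean(axis=1)
    r = float(np.corrcoef(even, odd)[0, 1])
    return 2.0 * r / (1.0 + r)


def nested_bootstrap_validity_sim(config: NestedSimConfig) -> dict:
    """Assess the player bootstrap for differences of nested reliabilities.

    Simulates many cohorts to obtain the true sampling correlation between
    the split-half reliabilities of measures A and B (and the true SD of
    their difference), then compares these with what the player bootstrap
    estimates from single cohorts.  With shared trials the bootstrap
    resamples players but keeps each player's (shared) trial noise, so it
    misses the trial-sampling component that couples the two
    reliabilities.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    nb, ne = cfg.n_trials_base, cfg.n_trials_extra

    def one_cohort():
        t = rng.normal(0.0, cfg.true_sd, cfg.n_players)
        base = t[:, None] + rng.normal(0.0, cfg.noise_sd,
                                       (cfg.n_players, nb))
        if cfg.shared:
            extra = t[:, None] + rng.normal(0.0, cfg.noise_sd,
                                            (cfg.n_players, ne))
            b_trials = np.concatenate([base, extra], axis=1)
        else:
            b_trials = t[:, None] + rng.normal(0.0, cfg.noise_sd,
                                               (cfg.n_players, nb + ne))
        return base, b_trials

    n_boot_cohorts = min(20, cfg.n_cohorts)
    rel_a = np.empty(cfg.n_cohorts)
    rel_b = np.empty(cfg.n_cohorts)
    cohorts = []
    for i in range(cfg.n_cohorts):
        base, b_trials = one_cohort()
        rel_a[i] = _split_half_of_trials(base)
        rel_b[i] = _split_half_of_trials(b_trials)
        if i < n_boot_cohorts:
            cohorts.append((base, b_trials))
    true_corr = float(np.corrcoef(rel_a, rel_b)[0, 1])
    true_sd_diff = float(np.std(rel_b - rel_a, ddof=1))

    # player bootstrap, one estimate per held cohort
    boot_corrs, boot_sds = [], []
    for base, b_trials in cohorts:
        ba = np.empty(cfg.B)
        bb = np.empty(cfg.B)
        for b in range(cfg.B):
            take = rng.integers(0, cfg.n_players, cfg.n_players)
            ba[b] = _split_half_of_trials(base[take])
            bb[b] = _split_half_of_trials(b_trials[take])
        boot_corrs.append(float(np.corrcoef(ba, bb)[0, 1]))
        boot_sds.append(float(np.std(bb - ba, ddof=1)))
    boot_corrs = np.asarray(boot_corrs)

    return {
        "true_reliability_corr": true_corr,
        "bootstrap_reliability_corr": float(np.mean(boot_corrs)),
        "bootstrap_corr_per_cohort": [float(c) for c in boot_corrs],
        "bootstrap_corr_rmse": float(
            np.sqrt(np.mean((boot_corrs - true_corr) ** 2))),
        "true_sd_diff": true_sd_diff,
        "bootstrap_sd_diff": float(np.mean(boot_sds)),
        "mean_rel_a": float(rel_a.mean()),
        "mean_rel_b": float(rel_b.mean()),
        "mean_diff": float((rel_b - rel_a).mean()),
        "shared": cfg.shared,
    }
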