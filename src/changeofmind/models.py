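"""Hierarchical conflict-effect models and cluster-robust inference.

Trial-level times are modeled with linear mixed models grouped by player,
using 0/1 treatment coding (reference: non-conflict trial, first
response).  Four specifications cover the analyses:

* ``maximal_joint`` -- fixed and random intercept, trial type, response
  type and their interaction; used to extract per-player conflict effects
  for each response type.
* ``shared_conflict`` -- random effects for intercept, trial type and
  response type but only a fixed interaction; this encodes the continuity
  assumption that individual differences in the conflict effect are
  shared between first and error-correcting responses, and is the
  "combined" measurement model.
* ``single_response`` -- fixed and random intercept and trial type, for
  one response type at a time.
* ``tts_model`` -- random intercept with a fixed trial-type effect, for
  the time-to-stop measure.

Fixed effects are tested with CR2 (bias-reduced linearization)
cluster-robust standard errors and Satterthwaite degrees of freedom,
clustering on players.  The CR2 adjustment uses the model-implied
covariance as the working model, so with singleton clusters and no random
effects it reduces to the HC2 heteroscedasticity-robust estimator.

Per-player conflict effects are empirical-Bayes conditional modes by
default; a no-pooling per-player OLS alternative is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "ModelSpec",
    "ModelFit",
    "conflict_model_frame",
    "tts_model_frame",
    "fit_mixed_model",
    "cr2_inference",
    "player_effects",
    "precision_eta",
    "correlate_effects",
    "paired_t",
    "CRInference",
    "EffectCorrelation",
    "PairedT",
]

_VARIANTS = {
    # variant -> (fixed columns, random columns)
    "maximal_joint": (["const", "trial", "resp", "inter"],
                      ["const", "trial", "resp", "inter"]),
    "shared_conflict": (["const", "trial", "resp", "inter"],
                        ["const", "trial", "resp"]),
    "single_response": (["const", "trial"], ["const", "trial"]),
    "tts_model": (["const", "trial"], ["const"]),
}


@dataclass(frozen=True)
class ModelSpec:
    """Named fixed/random structure for one analysis variant."""

    variant: str
    outcome: str = "time"

    def __post_init__(self) -> None:
        if self.variant not in _VARIANTS:
            raise ValueError(f"unknown model variant {self.variant!r}")

    @property
    def fixed(self) -> list[str]:
        return list(_VARIANTS[self.variant][0])

    @property
    def random(self) -> list[str]:
        return list(_VARIANTS[self.variant][1])


@dataclass
class ModelFit:
    """Results of one mixed-model fit plus what CR2 inference needs."""

    spec: ModelSpec
    params: pd.Series
    fe_se: pd.Series
    cov_re: pd.DataFrame
    resid_sd: float
    modes: pd.DataFrame  # per-player conditional modes of random effects
    converged: bool
    n_obs: int
    n_players: int
    data: pd.DataFrame = field(repr=False)

    @property
    def random_sds(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_re)),
                         index=self.cov_re.index)

    @property
    def random_corr(self) -> pd.DataFrame:
        sds = self.random_sds.to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = self.cov_re.to_numpy() / np.outer(sds, sds)
        return pd.DataFrame(corr, index=self.cov_re.index,
                            columns=self.cov_re.columns)

    def summary_dict(self) -> dict:
        return {
            "variant": self.spec.variant,
            "fixed_effects": self.params.round(6).to_dict(),
            "fixed_se": self.fe_se.round(6).to_dict(),
            "random_sds": self.random_sds.round(6).to_dict(),
            "residual_sd": round(self.resid_sd, 6),
            "converged": bool(self.converged),
            "n_obs": int(self.n_obs),
            "n_players": int(self.n_players),
        }


def conflict_model_frame(table: pd.DataFrame, conflict: str) -> pd.DataFrame:
    """Build the joint RT1/RT2 modeling frame from an observation table.

    ``conflict="flanker"`` uses non-ice rows with trial = mismatching
    flanker; ``conflict="ice"`` uses all non-lava rows with trial = ice.
    Response type: first (0) vs. error-correcting (1); incorrect first
    responses are not part of the joint frame.
    """
    if conflict == "flanker":
        sub = table[(~table["ice"].astype(bool))
                    & table["response_type"].isin(["first", "correction"])]
        trial = (~sub["flanker_match"].astype(bool)).astype(float)
    elif conflict == "ice":
        sub = table[table["response_type"].isin(["first", "correction"])]
        trial = sub["ice"].astype(bool).astype(float)
    else:
        raise ValueError(f"unknown conflict type {conflict!r}")
    out = pd.DataFrame({
        "player_id": sub["player_id"].to_numpy(),
        "trial_index": sub["trial_index"].to_numpy(),
        "time": sub["time"].to_numpy(dtype=float),
        "trial": trial.to_numpy(),
        "resp": (sub["response_type"] == "correction").astype(float).to_numpy(),
    })
    out["inter"] = out["trial"] * out["resp"]
    out["const"] = 1.0
    return out.reset_index(drop=True)


def tts_model_frame(tts_table: pd.DataFrame) -> pd.DataFrame:
    """Modeling frame for TTS: trial = mismatching flanker condition."""
    out = pd.DataFrame({
        "player_id": tts_table["player_id"].to_numpy(),
        "trial_index": tts_table["trial_index"].to_numpy(),
        "time": tts_table["time"].to_numpy(dtype=float),
        "trial": (~tts_table["flanker_match"].astype(bool)).astype(float).to_numpy(),
    })
    out["resp"] = 0.0
    out["inter"] = 0.0
    out["const"] = 1.0
    return out.reset_index(drop=True)


def fit_mixed_model(data: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """REML fit of the specified fixed/random structure, grouped by player.

    On a failed first optimization the fit is restarted once with a
    different optimizer; persistent failure is flagged (``converged=False``)
    rather than silently simplifying the random structure.
    """
    y = data[spec.outcome].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("outcome contains non-finite values")
    groups = data["player_id"].to_numpy()
    if len(pd.unique(groups)) < 2:
        raise ValueError("need at least 2 players")
    X = data[spec.fixed].to_numpy(dtype=float)
    Z = data[spec.random].to_numpy(dtype=float)

    model = sm.MixedLM(y, X, groups=groups, exog_re=Z)
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            res = model.fit(reml=True, method="lbfgs", maxiter=200)
        except (np.linalg.LinAlgError, ValueError):
            res = None
        if res is None or not res.converged:
            try:
                res2 = model.fit(reml=True, method="powell", maxiter=800)
                if res2 is not None and (res is None or res2.converged):
                    res = res2
            except (np.linalg.LinAlgError, ValueError):
                pass
        if res is None:
            raise RuntimeError("mixed model failed to produce a fit")
        converged = bool(res.converged)

    params = pd.Series(res.fe_params, index=spec.fixed)
    fe_se = pd.Series(res.bse_fe, index=spec.fixed)
    cov_re = pd.DataFrame(np.asarray(res.cov_re), index=spec.random,
                          columns=spec.random)
    try:
        modes = pd.DataFrame(
            {pid: np.asarray(b, dtype=float)[: len(spec.random)]
             for pid, b in res.random_effects.items()},
            index=spec.random).T
    except (ValueError, np.linalg.LinAlgError):
        # degenerate RE covariance (zero variance): all modes are zero
        labels = pd.unique(groups)
        modes = pd.DataFrame(0.0, index=labels, columns=spec.random)
    modes.index.name = "player_id"
    return ModelFit(spec=spec, params=params, fe_se=fe_se, cov_re=cov_re,
                    resid_sd=float(np.sqrt(res.scale)), modes=modes,
                    converged=converged, n_obs=len(y),
                    n_players=len(pd.unique(groups)), data=data)


# ---------------------------------------------------------------------------
# CR2 cluster-robust inference
# ---------------------------------------------------------------------------


class CRInference(NamedTuple):
    estimate: float
    se: float
    df: float
    t: float
    p: float
    ci_low: float
    ci_high: float


def _psd_sqrt_and_invsqrt(mat: np.ndarray, rtol: float = 1e-10):
    """Symmetric square root and pseudo-inverse square root."""
    vals, vecs = np.linalg.eigh(mat)
    tol = rtol * max(vals.max(), 1.0)
    pos = vals > tol
    sq = (vecs[:, pos] * np.sqrt(vals[pos])) @ vecs[:, pos].T
    inv = (vecs[:, pos] / np.sqrt(vals[pos])) @ vecs[:, pos].T
    return sq, inv


def cr2_core(X: np.ndarray, y: np.ndarray, groups: np.ndarray,
             Z: np.ndarray, cov_re: np.ndarray, scale: float,
             contrast: np.ndarray) -> CRInference:
    """CR2 variance and Satterthwaite df for a fixed-effect contrast.

    The working covariance is the model-implied block-diagonal
    ``V_j = scale * I + Z_j cov_re Z_j'``; the coefficient vector is the
    corresponding GLS estimate.  The CR2 (bias-reduced linearization)
    adjustment makes the meat unbiased under the working model, and the
    Satterthwaite df comes from the normal-theory moments of the variance
    estimator under that model.
    """
    labels = pd.unique(groups)
    if len(labels) < 4:
        raise ValueError("CR2 inference needs at least 4 clusters")
    p = X.shape[1]
    c = np.asarray(contrast, dtype=float)

    idx = {lab: np.flatnonzero(groups == lab) for lab in labels}
    Vs, Ws, Xs, ys = {}, {}, {}, {}
    XtWX = np.zeros((p, p))
    XtWy = np.zeros(p)
    for lab in labels:
        ii = idx[lab]
        Xj, yj, Zj = X[ii], y[ii], Z[ii]
        Vj = scale * np.eye(len(ii)) + Zj @ cov_re @ Zj.T
        Wj = np.linalg.inv(Vj)
        Vs[lab], Ws[lab], Xs[lab], ys[lab] = Vj, Wj, Xj, yj
        XtWX += Xj.T @ Wj @ Xj
        XtWy += Xj.T @ Wj @ yj
    M = np.linalg.inv(XtWX)
    beta = M @ XtWy

    meat = np.zeros((p, p))
    g_rows, a_rows, t_rows, d_diag = [], [], [], []
    for lab in labels:
        Xj, yj, Vj, Wj = Xs[lab], ys[lab], Vs[lab], Ws[lab]
        ej = yj - Xj @ beta
        Bj = Vj - Xj @ M @ Xj.T
        Vh, _ = _psd_sqrt_and_invsqrt(Vj)
        _, inner_inv = _psd_sqrt_and_invsqrt(Vh @ Bj @ Vh)
        Aj = Vh @ inner_inv @ Vh
        uj = Xj.T @ Wj @ Aj @ ej
        meat += np.outer(uj, uj)
        gj = c @ M @ Xj.T @ Wj @ Aj  # 1 x n_j
        g_rows.append(gj)
        a_rows.append(gj @ Xj)
        t_rows.append(M @ Xj.T @ gj)
        d_diag.append(float(gj @ Vj @ gj))

    var_c = float(c @ M @ meat @ M @ c)
    se = np.sqrt(var_c)

    A_mat = np.vstack(a_rows)            # J x p
    T_mat = np.vstack(t_rows)            # J x p
    S = -A_mat @ T_mat.T
    S = S + S.T + T_mat @ XtWX @ T_mat.T
    S[np.diag_indices_from(S)] += np.asarray(d_diag)
    df = float(np.trace(S) ** 2 / np.sum(S * S))

    est = float(c @ beta)
    tstat = est / se if se > 0 else np.inf
    pval = 2.0 * stats.t.sf(abs(tstat), df)
    crit = stats.t.ppf(0.975, df)
    return CRInference(est, float(se), df, float(tstat), float(pval),
                       est - crit * se, est + crit * se)


def cr2_inference(fit: ModelFit, coefficient: str) -> CRInference:
    """CR2 cluster-robust test of one fixed coefficient (clusters=players)."""
    if not fit.converged:
        raise ValueError("refusing CR2 inference on a non-converged fit")
    spec = fit.spec
    data = fit.data
    X = data[spec.fixed].to_numpy(dtype=float)
    Z = data[spec.random].to_numpy(dtype=float)
    y = data[spec.outcome].to_numpy(dtype=float)
    groups = data["player_id"].to_numpy()
    c = np.zeros(len(spec.fixed))
    c[spec.fixed.index(coefficient)] = 1.0
    return cr2_core(X, y, groups, Z, fit.cov_re.to_numpy(),
                    fit.resid_sd ** 2, c)


# ---------------------------------------------------------------------------
# per-player effects, precision, and simple comparisons
# ---------------------------------------------------------------------------


def player_effects(fit: ModelFit, method: str = "modes") -> pd.DataFrame:
    """Per-player conflict effects for each response type.

    ``modes`` (default): empirical-Bayes conditional effects from a
    ``maximal_joint`` fit -- effect_rt1 = fixed trial effect + that
    player's trial-slope mode; effect_rt2 adds the fixed interaction and
    the interaction mode.  ``ols``: no-pooling per-player least squares
    with the same design (players with a rank-deficient design get NaN).
    """
    if fit.spec.variant != "maximal_joint":
        raise ValueError("player_effects requires the maximal_joint variant "
                         "(random interaction present)")
    if method == "modes":
        eff1 = fit.params["trial"] + fit.modes["trial"]
        eff2 = eff1 + fit.params["inter"] + fit.modes["inter"]
        out = pd.DataFrame({"effect_rt1": eff1, "effect_rt2": eff2})
        out.index.name = "player_id"
        return out.reset_index()
    if method == "ols":
        cols = fit.spec.fixed
        rows = []
        for pid, d in fit.data.groupby("player_id", sort=True):
            Xp = d[cols].to_numpy(dtype=float)
            yp = d[fit.spec.outcome].to_numpy(dtype=float)
            if np.linalg.matrix_rank(Xp) < len(cols):
                rows.append((pid, np.nan, np.nan))
                continue
            b, *_ = np.linalg.lstsq(Xp, yp, rcond=None)
            bt = b[cols.index("trial")]
            bi = b[cols.index("inter")]
            rows.append((pid, bt, bt + bi))
        return pd.DataFrame(rows, columns=["player_id", "effect_rt1",
                                           "effect_rt2"])
    raise ValueError(f"unknown method {method!r}")


def precision_eta(fit: ModelFit, component: str = "trial") -> float:
    """Precision of a measurement: random-effect SD over residual SD."""
    if not fit.converged:
        raise ValueError("refusing precision from a non-converged fit")
    if component not in fit.cov_re.index:
        raise ValueError(f"no random component {component!r} in this fit")
    if fit.resid_sd <= 0:
        raise ValueError("residual SD is zero; precision undefined")
    return float(fit.random_sds[component] / fit.resid_sd)


class EffectCorrelation(NamedTuple):
    r: float
    ci_low: float
    ci_high: float
    t: float
    df: int
    p: float


def correlate_effects(x, y) -> EffectCorrelation:
    """Pearson correlation with t(n-2) test and Fisher-z 95% CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the inputs")
    r = float(np.corrcoef(x, y)[0, 1])
    df = n - 2
    denom = max(1.0 - r * r, np.finfo(float).tiny)
    t = r * np.sqrt(df / denom)
    p = 2.0 * stats.t.sf(abs(t), df)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    half = stats.norm.ppf(0.975) / np.sqrt(n - 3)
    return EffectCorrelation(r, float(np.tanh(z - half)),
                             float(np.tanh(z + half)), float(t), df, float(p))


class PairedT(NamedTuple):
    mean_diff: float
    ci_low: float
    ci_high: float
    t: float
    df: int
    p: float


def paired_t(x, y) -> PairedT:
    """Two-sided paired-samples t test with df = n - 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0:
        if md == 0:
            return PairedT(0.0, 0.0, 0.0, 0.0, df, 1.0)
        raise ValueError("zero variance of differences with nonzero mean; "
                         "paired t degenerate")
    se = sd / np.sqrt(n)
    t = md / se
    p = 2.0 * stats.t.sf(abs(t), df)
    crit = stats.t.ppf(0.975, df)
    return PairedT(md, md - crit * se, md + crit * se, float(t), df, float(p))
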