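"""Split-half reliability, omega, BCa bootstrap, and the nested-measures
bootstrap validity check."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from changeofmind.reliability import (
    NestedSimConfig,
    bca_ci,
    mcdonalds_omega,
    nested_bootstrap_validity_sim,
    split_half_reliability,
    trial_equivalent_gain,
)


def _trial_table(scores: np.ndarray, noise_sd: float, n_trials: int,
                 rng) -> pd.DataFrame:
    """Per-player trial table: time = true score + trial noise."""
    n = len(scores)
    rows = []
    for j in range(n):
        rows.append(pd.DataFrame({
            "player_id": f"p{j:03d}",
            "trial_index": np.arange(n_trials),
            "trial": 0.0, "resp": 0.0,
            "time": scores[j] + rng.normal(0, noise_sd, n_trials)}))
    return pd.concat(rows, ignore_index=True)


def _mean_fn(df: pd.DataFrame) -> pd.Series:
    return df.groupby("player_id")["time"].mean()


class TestSplitHalf:
    def test_identical_half_scores_give_unity(self):
        rng = np.random.default_rng(0)
        tab = _trial_table(rng.normal(0, 1, 30), noise_sd=0.0, n_trials=10,
                           rng=rng)
        out = split_half_reliability(tab, _mean_fn)
        assert out.r_raw == pytest.approx(1.0)
        assert out.r_corrected == pytest.approx(1.0)

    def test_pure_noise_gives_near_zero(self):
        rng = np.random.default_rng(1)
        tab = _trial_table(np.zeros(200), noise_sd=1.0, n_trials=20, rng=rng)
        out = split_half_reliability(tab, _mean_fn)
        assert abs(out.r_raw) < 3.0 / np.sqrt(200)

    def test_matches_spearman_brown_prediction(self):
        """With known true-score and noise variance the corrected
        coefficient estimates the analytic full-length reliability
        sigma_t^2 / (sigma_t^2 + sigma_e^2 / n)."""
        rng = np.random.default_rng(2)
        n_trials, noise = 40, 2.0
        tab = _trial_table(rng.normal(0, 1, 400), noise, n_trials, rng)
        out = split_half_reliability(tab, _mean_fn)
        predicted = 1.0 / (1.0 + noise ** 2 / n_trials)
        assert out.r_corrected == pytest.approx(predicted, abs=0.05)

    def test_undefined_half_measures_dropped_and_counted(self):
        rng = np.random.default_rng(3)
        tab = _trial_table(rng.normal(0, 1, 20), 0.5, 10, rng)

        def patchy(df):
            s = _mean_fn(df)
            s.iloc[0] = np.nan
            return s

        out = split_half_reliability(tab, patchy)
        assert out.n_dropped >= 1
        assert out.n_players + out.n_dropped == 20


def _exact_corr_indicators(R: np.ndarray, n: int = 60,
                           seed: int = 0) -> pd.DataFrame:
    """Indicators whose *sample* correlation matrix equals R exactly."""
    rng = np.random.default_rng(seed)
    raw = rng.normal(size=(n, R.shape[0]))
    raw -= raw.mean(axis=0)
    q, _ = np.linalg.qr(raw)
    L = np.linalg.cholesky(R)
    y = q @ L.T
    return pd.DataFrame(y, columns=[f"x{i}" for i in range(R.shape[0])])


class TestOmega:
    def test_equal_loadings_closed_form(self):
        # all pairwise correlations 0.5 -> lambda^2 = 0.5, omega = 0.75
        R = np.full((3, 3), 0.5)
        np.fill_diagonal(R, 1.0)
        assert mcdonalds_omega(_exact_corr_indicators(R)) == pytest.approx(0.75)

    def test_near_perfect_indicators(self):
        R = np.full((3, 3), 0.999)
        np.fill_diagonal(R, 1.0)
        assert mcdonalds_omega(_exact_corr_indicators(R)) > 0.99

    def test_nearly_uncorrelated_indicators(self):
        R = np.full((3, 3), 0.02)
        np.fill_diagonal(R, 1.0)
        assert mcdonalds_omega(_exact_corr_indicators(R)) < 0.10

    def test_two_indicator_equal_loading_identification(self):
        R = np.array([[1.0, 0.64], [0.64, 1.0]])
        # lambda = 0.8 each: omega = 1.6^2/(1.6^2 + 2*0.36)
        expected = 1.6 ** 2 / (1.6 ** 2 + 0.72)
        assert mcdonalds_omega(
            _exact_corr_indicators(R)) == pytest.approx(expected)

    def test_negative_correlation_signalled(self):
        R = np.array([[1.0, -0.4], [-0.4, 1.0]])
        with pytest.raises(ValueError, match="incoherent"):
            mcdonalds_omega(_exact_corr_indicators(R))

    def test_omega_monotone_in_stop_share(self):
        """The 3-indicator composite's coherence increases with the
        generator's shared stop-latency expression."""
        from changeofmind import (GameConfig, default_population,
                                  extract_tts_table, simulate_cohort,
                                  ssrt_results)
        omegas = {}
        for share in (0.2, 0.95):
            pop = default_population().replace(stop_share=share)
            log, _ = simulate_cohort(pop, 50, GameConfig(), seed=314)
            tts = extract_tts_table(log)
            res = ssrt_results(log, tts).dropna()
            z = res[["ssrt_match", "ssrt_mismatch", "tts_mean"]]
            z = (z - z.mean()) / z.std(ddof=1)
            omegas[share] = mcdonalds_omega(z)
        assert omegas[0.95] > omegas[0.2]


class TestBca:
    def test_reduces_to_percentile_when_unadjusted(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=80)
        lo, hi, _ = bca_ci(lambda d: float(np.mean(d)), x, B=1000, seed=9,
                           force_z0=0.0, force_a=0.0)
        boot = np.array([
            np.mean(x[np.random.default_rng(9).integers(0, 80, 80)])
            for _ in range(1)])  # placeholder; real check below
        # recompute the same bootstrap distribution for the oracle
        r = np.random.default_rng(9)
        boot = np.array([np.mean(x[r.integers(0, 80, 80)])
                         for _ in range(1000)])
        assert lo == pytest.approx(np.quantile(boot, 0.025))
        assert hi == pytest.approx(np.quantile(boot, 0.975))

    def test_symmetric_statistic_has_small_z0(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=200)
        _, _, params = bca_ci(lambda d: float(np.mean(d)), x, B=2000, seed=6)
        assert abs(params.z0) < 0.15

    def test_agrees_with_scipy_bca(self):
        """Independent-route check against scipy's BCa implementation."""
        rng = np.random.default_rng(5)
        x = rng.gamma(2, 1, 60)
        lo, hi, _ = bca_ci(lambda d: float(np.mean(d)), x, B=4000, seed=7)
        ref = stats.bootstrap((x,), np.mean, n_resamples=4000, method="BCa",
                              random_state=np.random.default_rng(8),
                              vectorized=False)
        width = ref.confidence_interval.high - ref.confidence_interval.low
        assert lo == pytest.approx(ref.confidence_interval.low,
                                   abs=0.1 * width)
        assert hi == pytest.approx(ref.confidence_interval.high,
                                   abs=0.1 * width)

    def test_cluster_resampling_on_dataframe(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame({
            "player_id": np.repeat([f"p{i}" for i in range(40)], 5),
            "time": rng.normal(500, 50, 200)})
        lo, hi, _ = bca_ci(lambda d: float(d["time"].mean()), df,
                           B=500, seed=11)
        assert lo < df["time"].mean() < hi
        assert hi - lo < 4 * 50 / np.sqrt(40)  # scales with cluster count

    def test_mostly_undefined_statistic_signalled(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=30)

        def bad(d):
            # defined on the original sample, undefined on (almost) any
            # with-replacement resample, which must contain duplicates
            if len(np.unique(d)) < len(d):
                raise ValueError("duplicate units")
            return float(np.mean(d))

        with pytest.raises(ValueError, match="resamples"):
            bca_ci(bad, x, B=200, seed=13)


class TestTrialEquivalentGain:
    def test_no_increment_returns_baseline(self):
        assert trial_equivalent_gain(0.7, 0.7) == pytest.approx(0.5)

    def test_monotone_in_r2(self):
        outs = [trial_equivalent_gain(0.7, r2) for r2 in (0.72, 0.75, 0.80)]
        assert outs == sorted(outs)
        assert all(o > 0.5 for o in outs)

    def test_decrement_signalled(self):
        with pytest.raises(ValueError, match="no reliability gain"):
            trial_equivalent_gain(0.8, 0.7)

    @pytest.mark.parametrize("bad", [(0.0, 0.5), (0.5, 1.0)])
    def test_bounds_enforced(self, bad):
        with pytest.raises(ValueError):
            trial_equivalent_gain(*bad)


class TestNestedBootstrapValidity:
    def test_identical_nested_measures_never_differ(self):
        cfg = NestedSimConfig(n_players=30, n_trials_base=10,
                              n_trials_extra=0, shared=True, n_cohorts=20,
                              B=200, seed=21)
        out = nested_bootstrap_validity_sim(cfg)
        assert out["mean_diff"] == pytest.approx(0.0)
        assert out["bootstrap_sd_diff"] == pytest.approx(0.0)

    def test_independent_measures_bootstrap_spread_calibrated(self):
        cfg = NestedSimConfig(n_players=50, n_trials_base=10,
                              n_trials_extra=30, noise_sd=3.0, shared=False,
                              n_cohorts=200, B=300, seed=22)
        out = nested_bootstrap_validity_sim(cfg)
        ratio = out["bootstrap_sd_diff"] / out["true_sd_diff"]
        assert 0.8 < ratio < 1.3

    def test_shared_trials_bootstrap_misestimates_reliability_corr(self):
        """With nested (shared-trial) measures the single-cohort player
        bootstrap is an unreliable estimator of the correlation between
        the two reliabilities, so no CI for their difference is trusted."""
        cfg = NestedSimConfig(n_players=50, n_trials_base=10,
                              n_trials_extra=30, noise_sd=3.0, shared=True,
                              n_cohorts=200, B=300, seed=23)
        out = nested_bootstrap_validity_sim(cfg)
        assert out["bootstrap_corr_rmse"] > 0.08
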