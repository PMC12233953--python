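"""RPE -> dopamine synthesis, regression arbitration, and lagged designs."""

import numpy as np
import pandas as pd
import pytest

from beliefbandit import (TaskConfig, TimingConfig, simulate_sessions,
                          generate_event_times, evaluate_latents)
from beliefbandit.linking import (SynthDaConfig, synthesize_da,
                                  build_rpe_design, fit_rpe_regression,
                                  cv_llk_compare, build_lagged_design,
                                  fit_lagged_model, history_binned_da)


@pytest.fixture(scope="module")
def linked_data():
    """BIfp-simulated sessions with event times and RPE columns for BIfp
    and RL4p (each evaluated at representative parameters)."""
    df = simulate_sessions("BIfp", dict(beta=3.0, phi=0.5, q=0.05),
                           TaskConfig(n_trials=400), 3, seed=31)
    df = generate_event_times(df, TimingConfig(), np.random.default_rng(31))
    df["rpe_BIfp"] = df["rpe"]
    lat = evaluate_latents("RL4p", [0.7, 0.6, 2.0, 0.3], df)
    df["rpe_RL4p"] = lat["rpe"]
    return df


def test_synthesize_da_noiseless_limit_linear_by_sign(linked_data):
    cfg = SynthDaConfig(gain_pos=2.0, gain_neg=1.0, dur_gain_pos=0.0,
                        dur_gain_neg=0.0, noise_sd=1e-12)
    df = synthesize_da(linked_data, cfg, np.random.default_rng(0),
                       rpe_col="rpe_BIfp")
    rpe = df["rpe_BIfp"]
    pos = rpe >= 0
    np.testing.assert_allclose(df.loc[pos, "da_pt"], 2.0 * rpe[pos], atol=1e-9)
    np.testing.assert_allclose(df.loc[~pos, "da_pt"], 1.0 * rpe[~pos],
                               atol=1e-9)


def test_synthesize_da_rewarded_exceeds_unrewarded(linked_data):
    df = synthesize_da(linked_data, SynthDaConfig(), np.random.default_rng(1),
                       rpe_col="rpe_BIfp")
    assert (df.loc[df["reward"] == 1, "da_pt"].mean()
            > df.loc[df["reward"] == 0, "da_pt"].mean())


def test_synthesize_da_requires_rpe(linked_data):
    with pytest.raises(ValueError, match="RPE"):
        synthesize_da(linked_data.drop(columns=["rpe_BIfp"]),
                      SynthDaConfig(), np.random.default_rng(0),
                      rpe_col="rpe_BIfp")


def test_rpe_regression_recovers_known_coefficients(linked_data):
    cfg = SynthDaConfig(gain_pos=1.5, gain_neg=1.5, dur_gain_pos=0.0,
                        dur_gain_neg=0.0, noise_sd=1e-10)
    df = synthesize_da(linked_data, cfg, np.random.default_rng(2),
                       rpe_col="rpe_BIfp")
    X, y = build_rpe_design(df, rpe_col="rpe_BIfp")
    res = fit_rpe_regression(X, y, rng=np.random.default_rng(3))
    assert res["coef"]["rpe_pos"] == pytest.approx(1.5, abs=1e-6)
    assert res["coef"]["rpe_neg"] == pytest.approx(1.5, abs=1e-6)
    assert abs(res["coef"]["port_dur_pos"]) < 1e-6


def test_rpe_regression_permuted_response_scores_worse(linked_data):
    df = synthesize_da(linked_data, SynthDaConfig(), np.random.default_rng(4),
                       rpe_col="rpe_BIfp")
    X, y = build_rpe_design(df, rpe_col="rpe_BIfp")
    res = fit_rpe_regression(X, y, rng=np.random.default_rng(5))
    y_perm = pd.Series(np.random.default_rng(6).permutation(y.to_numpy()),
                       index=y.index)
    res_perm = fit_rpe_regression(X, y_perm, rng=np.random.default_rng(5))
    assert res_perm["llk_out"] < res["llk_out"]


def test_rank_deficient_design_names_columns(linked_data):
    df = synthesize_da(linked_data, SynthDaConfig(), np.random.default_rng(7),
                       rpe_col="rpe_BIfp")
    X, y = build_rpe_design(df, rpe_col="rpe_BIfp")
    X["dup"] = X["rpe_pos"] * 2.0
    from beliefbandit.linking import _check_full_rank
    with pytest.raises(ValueError, match="collinear"):
        _check_full_rank(X)


def test_cv_llk_baseline_only_and_antisymmetry(linked_data):
    df = synthesize_da(linked_data, SynthDaConfig(), np.random.default_rng(8),
                       rpe_col="rpe_BIfp")
    only = cv_llk_compare(df, ["RL4p"], seed=9)
    assert only.loc["RL4p", "delta_llk_cv"] == 0.0
    ab = cv_llk_compare(df, ["BIfp", "RL4p"], seed=9, baseline="RL4p")
    ba = cv_llk_compare(df, ["BIfp", "RL4p"], seed=9, baseline="BIfp")
    assert ab.loc["BIfp", "delta_llk_cv"] == pytest.approx(
        -ba.loc["RL4p", "delta_llk_cv"], rel=1e-9)


def test_lagged_design_count_rules():
    df = pd.DataFrame({
        "subject_id": "m", "session_id": "s", "trial": range(5),
        "choice": [1.0, 1.0, 1.0, 1.0, 1.0],
        "reward": [1.0, 0.0, 1.0, 1.0, 0.0],
        "da_pt": np.zeros(5),
    })
    d = build_lagged_design(df, n_lags=4)
    assert len(d) == 1
    assert d.iloc[0]["R_chosen"] == 3 and d.iloc[0]["R_unchosen"] == 0
    df["choice"] = [1.0, 1.0, -1.0, -1.0, 1.0]
    df["reward"] = [1.0, 1.0, 1.0, 0.0, 0.0]
    d = build_lagged_design(df, n_lags=4)
    assert d.iloc[0]["R_chosen"] == 2 and d.iloc[0]["R_unchosen"] == 1
    assert d.iloc[0]["Switch"] == 1.0


def test_lagged_design_partition_identity(linked_data):
    d = build_lagged_design(linked_data, n_lags=4)
    win_rewards = d["R_chosen"] + d["R_unchosen"]
    assert (win_rewards <= 4).all()
    assert ((d["Switch"] + d["Stay"]) == 1.0).all()
    with pytest.raises(ValueError):
        build_lagged_design(linked_data, n_lags=0)


def test_lagged_model_sign_recovery_and_null_coverage(linked_data):
    d = build_lagged_design(linked_data, n_lags=4)
    rng = np.random.default_rng(10)
    d = d.copy()
    d["response"] = (0.5 * d["Reward"]
                     - 0.1 * d["R_chosen"] * d["Switch"]
                     + 0.1 * d["R_unchosen"] * d["Switch"]
                     + rng.normal(0, 0.05, len(d)))
    est, _ = fit_lagged_model(d)
    assert est.loc["Rch_Switch", "estimate"] < 0
    assert est.loc["Run_Switch", "estimate"] > 0
    assert est.loc["Reward_Switch", "estimate"] > 0
    # zero-noise response -> exact recovery
    d["response"] = 0.5 * d["Reward"] - 0.1 * d["R_chosen"] * d["Switch"]
    est, _ = fit_lagged_model(d)
    assert est.loc["Rch_Switch", "estimate"] == pytest.approx(-0.1, abs=1e-8)
    # independent response -> CIs cover zero for the reward-history slopes
    d["response"] = rng.normal(size=len(d))
    est, _ = fit_lagged_model(d)
    covers = ((est["ci_low"] <= 0) & (0 <= est["ci_high"]))
    assert covers[["Rch_Switch", "Run_Switch", "Rch_Stay", "Run_Stay"]].sum() >= 3


def test_lagged_model_single_subject_hierarchical_falls_back(linked_data):
    d = build_lagged_design(linked_data, n_lags=4)
    d["response"] = np.random.default_rng(11).normal(size=len(d))
    with pytest.warns(UserWarning, match="single subject"):
        fit_lagged_model(d, hierarchical=True)


def test_history_binned_da_uniform_value_flat(linked_data):
    df = linked_data.copy()
    df["da_pt"] = 1.0
    tab = history_binned_da(df)
    observed = tab.dropna()
    assert np.allclose(observed["mean"], 1.0)


def test_history_binned_da_declines_with_rewards_for_bifp(linked_data):
    cfg = SynthDaConfig(noise_sd=0.05, dur_gain_pos=0.0, dur_gain_neg=0.0)
    df = synthesize_da(linked_data, cfg, np.random.default_rng(12),
                       rpe_col="rpe_BIfp")
    tab = history_binned_da(df)
    # more rewards in recent same-port history -> smaller reward response,
    # but belief never saturates: AAA stays positive
    if tab.loc["aaa", "n"] > 0 and tab.loc["AAA", "n"] > 0:
        assert tab.loc["aaa", "mean"] > tab.loc["AAA", "mean"]
    assert tab.loc["AAA", "mean"] > 0
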