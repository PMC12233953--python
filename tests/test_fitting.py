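"""Maximum-likelihood machinery, AIC bookkeeping, and statistics utilities."""

import numpy as np
import pandas as pd
import pytest

from beliefbandit import (TaskConfig, simulate_sessions, fit_mle,
                          negative_log_likelihood, per_trial_loglik,
                          evaluate_latents, aic_compare, around_switch_loglik,
                          holm_bonferroni, min_sign_permutation_p)
from beliefbandit.agents import MAIN_MODELS, MODELS
from beliefbandit.identify import DEFAULT_RANGES, sample_generating_params


def test_uniform_policy_loglik_is_n_log2(small_bifp_data):
    n = len(small_bifp_data)
    nll = negative_log_likelihood("BIfp", [0.0, 0.0, 0.05], small_bifp_data)
    assert nll == pytest.approx(n * np.log(2), rel=1e-12)


def test_out_of_bounds_theta_rejected(small_bifp_data):
    with pytest.raises(ValueError, match="outside"):
        negative_log_likelihood("BIfp", [3.0, 0.5, 0.7], small_bifp_data)


def test_loglik_invariant_to_session_order(small_bifp_data):
    theta = [3.0, 0.5, 0.05]
    base = negative_log_likelihood("BIfp", theta, small_bifp_data)
    shuffled = small_bifp_data.sort_values(
        ["session_id", "trial"], ascending=[False, True], kind="stable")
    assert negative_log_likelihood("BIfp", theta, shuffled) == pytest.approx(
        base, rel=1e-12)


def test_nll_worse_at_perturbed_hazard_rate():
    """Evaluating BIfp far from the generating q costs likelihood."""
    worse = 0
    for seed in range(10):
        df = simulate_sessions("BIfp", dict(beta=3, phi=0.5, q=0.05),
                               TaskConfig(n_trials=1000), 1, seed=seed)
        at_truth = negative_log_likelihood("BIfp", [3, 0.5, 0.05], df)
        perturbed = negative_log_likelihood("BIfp", [3, 0.5, 0.4], df)
        worse += perturbed > at_truth
    assert worse >= 9


def test_missing_choice_trials_skipped_without_state_update(small_bifp_data):
    df = small_bifp_data.copy()
    drop = df.index[5:8]
    df.loc[drop, ["choice", "reward", "D", "belief_right", "rpe",
                  "Q_left", "Q_right", "p_right"]] = np.nan
    lp = per_trial_loglik("BIfp", [3, 0.5, 0.05], df)
    assert len(lp) == len(df) - 3
    # equivalent to evaluating on the table with those rows removed
    lp_removed = per_trial_loglik("BIfp", [3, 0.5, 0.05], df.drop(drop))
    np.testing.assert_allclose(lp.to_numpy(), lp_removed.to_numpy())


@pytest.mark.parametrize("model", MAIN_MODELS)
def test_kernel_matches_python_agent(model, small_bifp_data, rng):
    """Compiled likelihood kernels reproduce the readable agent path."""
    theta = sample_generating_params(DEFAULT_RANGES, model, rng)
    vec = [theta[p] for p in MODELS[model].param_names]
    lp_kernel = per_trial_loglik(model, vec, small_bifp_data)
    lat = evaluate_latents(model, vec, small_bifp_data)
    np.testing.assert_allclose(lp_kernel.to_numpy(),
                               lat["logp_choice"].to_numpy(),
                               rtol=0, atol=1e-10)


def test_fit_is_deterministic_and_aic_identity(small_bifp_data):
    f1 = fit_mle("BIfp", small_bifp_data, n_starts=3, seed=5)
    f2 = fit_mle("BIfp", small_bifp_data, n_starts=3, seed=5)
    np.testing.assert_array_equal(f1.theta, f2.theta)
    assert f1.aic == pytest.approx(2 * f1.k - 2 * f1.loglik, abs=1e-12)
    assert f1.loglik <= 0
    assert f1.k == 3


def test_bic_field_identity(small_bifp_data):
    f = fit_mle("BIfp", small_bifp_data, n_starts=2, seed=3)
    assert f.bic == pytest.approx(f.k * np.log(f.n_trials) - 2 * f.loglik,
                                  abs=1e-12)


def test_more_starts_never_worse(small_bifp_data):
    few = fit_mle("RL4p", small_bifp_data, n_starts=2, seed=9)
    many = fit_mle("RL4p", small_bifp_data, n_starts=6, seed=9)
    assert many.loglik >= few.loglik - 1e-9
    assert many.loglik >= max(-s["nll"] for s in many.starts) - 1e-12


def test_free_parameter_counts_match_models():
    expected = {"RL4p": 4, "RLCF": 4, "RFLR": 3, "RLFQ3p": 3, "RL_meta": 7,
                "BIfp": 3, "BRLfwr": 4}
    for model, k in expected.items():
        assert len(MODELS[model].param_names) == k


def test_fit_on_coin_flip_chooser_gives_beta_near_zero(rng):
    n = 1000
    df = pd.DataFrame({
        "subject_id": "m", "session_id": "s", "trial": np.arange(n),
        "choice": rng.choice([-1.0, 1.0], size=n),
        "reward": rng.integers(0, 2, size=n).astype(float),
    })
    fit = fit_mle("BIfp", df, n_starts=5, seed=2)
    assert fit.loglik == pytest.approx(-n * np.log(2), rel=0.01)


def test_aic_compare_baseline_and_penalty(small_bifp_data):
    fits = [fit_mle(m, small_bifp_data, n_starts=3, seed=4)
            for m in ("RL4p", "BIfp")]
    table = aic_compare(fits, baseline="RL4p").set_index("model")
    assert table.loc["RL4p", "delta_aic"] == 0.0
    diff = ((table.loc["BIfp", "aic"] - table.loc["RL4p", "aic"])
            - (-2 * (table.loc["BIfp", "loglik"] - table.loc["RL4p", "loglik"])))
    assert diff == pytest.approx(2 * (3 - 4), abs=1e-9)


def test_aic_compare_rejects_mismatched_data(small_bifp_data, bifp_data):
    f1 = fit_mle("BIfp", small_bifp_data, n_starts=2, seed=1)
    f2 = fit_mle("RL4p", bifp_data, n_starts=2, seed=1)
    with pytest.raises(ValueError, match="identical"):
        aic_compare([f1, f2])


def test_around_switch_window_covering_all_equals_full(small_bifp_data):
    theta = [3.0, 0.5, 0.05]
    full = -negative_log_likelihood("BIfp", theta, small_bifp_data)
    # the around-switch likelihood over an unbounded window covers every
    # post-switch trial but not the first block of each session
    res = around_switch_loglik("BIfp", theta, small_bifp_data, window=10**9)
    first_block_lp = 0.0
    lp = per_trial_loglik("BIfp", theta, small_bifp_data)
    df = small_bifp_data.reset_index(drop=True)
    for _, grp in df.groupby("session_id", sort=False):
        sel = grp.index[grp["block"] == grp["block"].iloc[0]]
        first_block_lp += lp.iloc[sel].sum()
    assert res["loglik"] == pytest.approx(full - first_block_lp, rel=1e-9)


def test_around_switch_summand_count():
    rows = []
    # one session, 4 blocks of 10 trials -> 3 switches x window 5 = 15 summands
    for t in range(40):
        rows.append({"subject_id": "m", "session_id": "s", "trial": t,
                     "choice": 1.0 if t % 2 else -1.0, "reward": float(t % 2),
                     "block": t // 10})
    df = pd.DataFrame(rows)
    res = around_switch_loglik("BIfp", [1.0, 0.0, 0.05], df, window=5)
    assert res["n_trials"] == 15


def test_around_switch_requires_switches():
    df = pd.DataFrame({"subject_id": "m", "session_id": "s",
                       "trial": range(10), "choice": [1.0] * 10,
                       "reward": [1.0] * 10, "block": [0] * 10})
    with pytest.raises(ValueError, match="switch"):
        around_switch_loglik("BIfp", [1.0, 0.0, 0.05], df)


# -- statistics utilities ---------------------------------------------------

def test_holm_bonferroni_step_down():
    np.testing.assert_allclose(holm_bonferroni([0.01, 0.04]), [0.02, 0.04])
    np.testing.assert_allclose(holm_bonferroni([0.2]), [0.2])
    np.testing.assert_allclose(holm_bonferroni([1.0, 1.0, 1.0]), [1, 1, 1])
    with pytest.raises(ValueError):
        holm_bonferroni([0.5, 1.5])


@pytest.mark.parametrize("n,expected", [
    (1, 0.5), (5, 0.03125), (10, 0.0009765625),
])
def test_min_sign_permutation_p_enumeration(n, expected):
    assert min_sign_permutation_p(n) == pytest.approx(expected, rel=1e-12)


def test_min_sign_permutation_p_refuses_large_n():
    with pytest.raises(ValueError):
        min_sign_permutation_p(21)
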