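"""Linking model reward-prediction errors to (synthetic) dopamine summaries.

``synthesize_da`` turns a generating model's per-trial RPEs into a
dLight-like trial summary (da_pt): sign-split gains on the RPE, a
port-duration modulation mirroring the observation that transient extent
scales with time spent at the port, and Gaussian noise.  The regression
machinery then asks the inverse question — which model's RPE sequence best
explains da_pt — via a featurized Gaussian regression scored by held-out
log-likelihood, plus a lagged reward design (R_chosen / R_unchosen counts
over the past trials, split by switch vs stay) fitted by OLS or a
mixed-effects model.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "SynthDaConfig",
    "synthesize_da",
    "build_rpe_design",
    "fit_rpe_regression",
    "cv_llk_compare",
    "build_lagged_design",
    "fit_lagged_model",
    "history_binned_da",
    "HISTORY3_STAY_ORDER",
]

LOG_FLOOR = 1e-3  # seconds; floor before log-transforming durations


@dataclasses.dataclass
class SynthDaConfig:
    """Generator for synthetic per-trial dopamine summaries from RPEs."""

    gain_pos: float = 1.5
    gain_neg: float = 1.5
    dur_gain_pos: float = 0.05
    dur_gain_neg: float = -0.05
    noise_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


def synthesize_da(records: pd.DataFrame, cfg: SynthDaConfig,
                  rng: np.random.Generator, rpe_col: str = "rpe") -> pd.DataFrame:
    """Attach a synthetic ``da_pt`` column driven by ``rpe_col``.

    da_pt = gain_pos*rpe [rpe>=0] + gain_neg*rpe [rpe<0]
            + dur_gain_pos*port_dur [rpe>=0] + dur_gain_neg*port_dur [rpe<0]
            + N(0, noise_sd).
    """
    if rpe_col not in records.columns or records[rpe_col].isna().all():
        raise ValueError(f"records lack an RPE column {rpe_col!r}")
    df = records.copy()
    rpe = df[rpe_col].to_numpy(dtype=float)
    pos = rpe >= 0
    dur = df["port_dur"].to_numpy(dtype=float) if "port_dur" in df.columns \
        else np.zeros(len(df))
    dur = np.nan_to_num(dur)
    da = np.where(pos, cfg.gain_pos * rpe + cfg.dur_gain_pos * dur,
                  cfg.gain_neg * rpe + cfg.dur_gain_neg * dur)
    da = da + rng.normal(0.0, cfg.noise_sd, size=len(df))
    da[np.isnan(rpe)] = np.nan
    df["da_pt"] = da
    return df


def build_rpe_design(records: pd.DataFrame, rpe_col: str = "rpe"):
    """Featurized covariate set for the RPE -> dopamine regression.

    Columns: the RPE split by sign, port duration split by the same sign
    indicators, egocentric action (the +-1 choice), session number, and log
    movement/center durations; plus an intercept.  Returns (X, y) with rows
    lacking any covariate dropped.
    """
    df = records.copy()
    rpe = df[rpe_col].astype(float)
    pos = (rpe >= 0).astype(float)
    sess_codes = pd.factorize(df["session_id"])[0].astype(float) \
        if "session_id" in df.columns else np.zeros(len(df))
    X = pd.DataFrame({
        "rpe_pos": rpe * pos,
        "rpe_neg": rpe * (1.0 - pos),
        "port_dur_pos": df.get("port_dur", np.nan) * pos,
        "port_dur_neg": df.get("port_dur", np.nan) * (1.0 - pos),
        "ego_action": df["choice"].astype(float),
        "session_num": sess_codes,
        "log_MVMT": np.log(np.clip(df.get("MVMT", np.nan), LOG_FLOOR, None)),
        "log_center_dur": np.log(np.clip(df.get("center_dur", np.nan),
                                         LOG_FLOOR, None)),
    })
    y = df["da_pt"].astype(float)
    ok = X.notna().all(axis=1) & y.notna()
    X, y = X[ok], y[ok]
    X.insert(0, "const", 1.0)
    _check_full_rank(X)
    return X, y


def _check_full_rank(X: pd.DataFrame) -> None:
    mat = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # name the trailing pivots from a pivoted QR as the collinear set
        from scipy.linalg import qr
        _, _, piv = qr(mat, pivoting=True, mode="economic")
        bad = [X.columns[i] for i in piv[rank:]]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")


def _gaussian_llk(resid: np.ndarray, sigma2: float) -> float:
    return float(-0.5 * len(resid) * np.log(2 * np.pi * sigma2)
                 - 0.5 * np.sum(resid ** 2) / sigma2)


def fit_rpe_regression(X: pd.DataFrame, y: pd.Series, split: float = 0.7,
                       rng: Optional[np.random.Generator] = None) -> dict:
    """Gaussian MLE fit on a random train split, scored on the held-out rest.

    Returns coefficients, the in-sample log-likelihood, and the summed and
    per-trial held-out log-likelihood (sigma estimated on the train split).
    """
    if len(X) < 50:
        raise ValueError("need at least 50 trials after filtering")
    rng = rng if rng is not None else np.random.default_rng(0)
    n = len(X)
    perm = rng.permutation(n)
    n_train = int(round(split * n))
    if n - n_train < 10:
        raise ValueError("fewer than 10 held-out trials")
    tr, te = perm[:n_train], perm[n_train:]
    Xtr, Xte = X.iloc[tr], X.iloc[te]
    ytr, yte = y.iloc[tr], y.iloc[te]
    fit = sm.OLS(ytr, Xtr).fit()
    resid_tr = ytr - fit.fittedvalues
    sigma2 = float(np.mean(resid_tr ** 2))  # MLE variance
    resid_te = yte - fit.predict(Xte)
    llk_out = _gaussian_llk(resid_te.to_numpy(), sigma2)
    return {
        "coef": fit.params.to_dict(),
        "llk_in": _gaussian_llk(resid_tr.to_numpy(), sigma2),
        "llk_out": llk_out,
        "llk_out_per_trial": llk_out / len(te),
        "n_train": int(n_train),
        "n_test": int(n - n_train),
        "ols": fit,
    }


def cv_llk_compare(records: pd.DataFrame, models: Sequence[str],
                   split: float = 0.7, seed: int = 0, n_repeats: int = 1,
                   baseline: str = "RL4p") -> pd.DataFrame:
    """Held-out log-likelihood of the RPE regression per candidate model,
    relative to the baseline model.

    ``records`` must carry one RPE column per model, named ``rpe_<model>``;
    the train/test split is identical across models (and re-drawn per
    repeat, with averaging).
    """
    if baseline not in models:
        models = list(models) + [baseline]
    cols = {m: f"rpe_{m}" for m in models}
    for m, col in cols.items():
        if col not in records.columns:
            raise ValueError(f"records lack column {col!r}")
    ok = records[list(cols.values())].notna().all(axis=1) \
        & records["da_pt"].notna()
    df = records[ok].reset_index(drop=True)
    llk = {m: [] for m in models}
    for rep in range(n_repeats):
        rng = np.random.default_rng([int(seed) % (2**31), rep])
        state = rng.bit_generator.state
        for m in models:
            rng_m = np.random.default_rng()
            rng_m.bit_generator.state = state  # same split for all models
            X, y = build_rpe_design(df, rpe_col=cols[m])
            res = fit_rpe_regression(X, y, split=split, rng=rng_m)
            llk[m].append(res["llk_out"])
    rows = [{"model": m, "llk_cv": float(np.mean(llk[m])),
             "delta_llk_cv": float(np.mean(llk[m]) - np.mean(llk[baseline]))}
            for m in models]
    return pd.DataFrame(rows).set_index("model")


def build_lagged_design(records: pd.DataFrame, n_lags: int = 4,
                        response: str = "da_pt") -> pd.DataFrame:
    """Lagged reward design: counts of past rewards at the currently chosen
    port (R_chosen) and the opposite port (R_unchosen), interacted with
    switch/stay indicators.

    For trial t, R_chosen counts rewarded trials among t-1..t-n_lags whose
    choice equals c_t; R_unchosen counts those at the other port; Switch is
    1 when c_t differs from c_{t-1}.  Rows lacking full history are
    dropped; windows never cross sessions.
    """
    if n_lags < 1:
        raise ValueError("n_lags must be >= 1")
    df = records.sort_values(["subject_id", "session_id", "trial"],
                             kind="stable").reset_index(drop=True)
    rows = []
    for (subj, _), grp in df.groupby(["subject_id", "session_id"], sort=False):
        c = grp["choice"].to_numpy(dtype=float)
        r = grp["reward"].to_numpy(dtype=float)
        resp = grp[response].to_numpy(dtype=float) if response in grp.columns \
            else np.full(len(grp), np.nan)
        for j in range(n_lags, len(grp)):
            win_c = c[j - n_lags:j]
            win_r = r[j - n_lags:j]
            if np.isnan(c[j]) or np.any(np.isnan(win_c)) or np.any(np.isnan(win_r)):
                continue
            r_ch = float(np.sum(win_r * (win_c == c[j])))
            r_un = float(np.sum(win_r * (win_c == -c[j])))
            switch = float(c[j] != c[j - 1])
            rows.append({"subject_id": subj, "response": resp[j],
                         "Reward": r[j], "R_chosen": r_ch,
                         "R_unchosen": r_un, "Switch": switch,
                         "Stay": 1.0 - switch})
    return pd.DataFrame(rows)


#: Fixed-effect columns of the lagged model (switch/stay split).
_LAGGED_TERMS = ["Reward_Switch", "Reward_Stay", "Rch_Switch", "Rch_Stay",
                 "Run_Switch", "Run_Stay", "Switch"]


def _lagged_matrix(design: pd.DataFrame) -> pd.DataFrame:
    X = pd.DataFrame({
        "Reward_Switch": design["Reward"] * design["Switch"],
        "Reward_Stay": design["Reward"] * design["Stay"],
        "Rch_Switch": design["R_chosen"] * design["Switch"],
        "Rch_Stay": design["R_chosen"] * design["Stay"],
        "Run_Switch": design["R_unchosen"] * design["Switch"],
        "Run_Stay": design["R_unchosen"] * design["Stay"],
        "Switch": design["Switch"],
    })
    X.insert(0, "const", 1.0)
    return X


def fit_lagged_model(design: pd.DataFrame, hierarchical: bool = False):
    """Fit the lagged reward model; OLS by default, or a mixed model with
    per-subject random slopes when ``hierarchical`` (falls back to OLS with
    a warning if only one subject is present).

    Returns ``(estimates, fit)`` where estimates is a DataFrame of slopes
    with 95% confidence bounds.
    """
    ok = design["response"].notna()
    d = design[ok].reset_index(drop=True)
    X = _lagged_matrix(d)
    y = d["response"]
    if hierarchical and d["subject_id"].nunique() < 2:
        import warnings
        warnings.warn("single subject; falling back to fixed effects")
        hierarchical = False
    if hierarchical:
        fit = sm.MixedLM(y, X, groups=d["subject_id"],
                         exog_re=X[["const"]]).fit(reml=True)
        params = fit.params[X.columns]
        ci = fit.conf_int().loc[X.columns]
    else:
        fit = sm.OLS(y, X).fit()
        params = fit.params
        ci = fit.conf_int()
    est = pd.DataFrame({"estimate": params,
                        "ci_low": ci[0], "ci_high": ci[1]})
    return est, fit


#: The eight three-back same-port codes ordered by increasing number, then
#: recency, of rewards (the last letter is trial t-1).
HISTORY3_STAY_ORDER = ["aaa", "Aaa", "aAa", "aaA", "AAa", "AaA", "aAA", "AAA"]


def history_binned_da(records: pd.DataFrame, value_col: str = "da_pt") -> pd.DataFrame:
    """Mean da_pt on rewarded stay trials binned by three-back same-port
    outcome history (aaa .. AAA)."""
    df = records.sort_values(["subject_id", "session_id", "trial"],
                             kind="stable").reset_index(drop=True)
    sums: Dict[str, List[float]] = {code: [] for code in HISTORY3_STAY_ORDER}
    for _, grp in df.groupby(["subject_id", "session_id"], sort=False):
        c = grp["choice"].to_numpy(dtype=float)
        r = grp["reward"].to_numpy(dtype=float)
        v = grp[value_col].to_numpy(dtype=float)
        for j in range(3, len(grp)):
            win = np.concatenate([c[j - 3:j + 1], r[j - 3:j + 1]])
            if np.any(np.isnan(win)) or np.isnan(v[j]):
                continue
            if r[j] != 1:
                continue
            if not (c[j - 3] == c[j - 2] == c[j - 1] == c[j]):
                continue
            code = "".join("A" if ri == 1 else "a" for ri in r[j - 3:j])
            sums[code].append(v[j])
    rows = [{"code": code, "n": len(vals),
             "mean": float(np.mean(vals)) if vals else np.nan}
            for code, vals in sums.items()]
    return pd.DataFrame(rows).set_index("code").loc[HISTORY3_STAY_ORDER]
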