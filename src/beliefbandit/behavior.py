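"""Trial-history encodings and behavioural summary statistics.

The three-back outcome-history code writes each of trials t-3..t-1 as one
letter: ``A/a`` when the chosen port equals the port chosen at t-3 (the
reference trial — so the first letter is always A or a), ``B/b`` when it is
the other port; uppercase means the trial was rewarded.  ``aBb`` therefore
reads "unrewarded at the reference port, then rewarded and unrewarded at the
other port".  Codes are invariant to a global left/right relabelling.
History windows never cross session boundaries.
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "encode_history3",
    "encode_histories",
    "switch_probability_by_history",
    "stay_probability_by_2history",
    "block_switch_aligned_accuracy",
    "trials_to_switch_metrics",
    "history_logit_design",
    "fit_history_logit",
]


def _session_groups(df: pd.DataFrame):
    df = df.sort_values(["subject_id", "session_id", "trial"],
                        kind="stable").reset_index(drop=True)
    return df, df.groupby(["subject_id", "session_id"], sort=False)


def encode_history3(records: pd.DataFrame, t: int) -> Optional[str]:
    """Outcome-history code of length 3 for positional trial ``t`` of a
    single-session table, or None when the window is invalid."""
    if t < 3 or t >= len(records):
        return None
    c = records["choice"].to_numpy()
    r = records["reward"].to_numpy()
    window_c, window_r = c[t - 3:t], r[t - 3:t]
    if np.any(pd.isna(window_c)) or np.any(pd.isna(window_r)):
        return None
    ref = window_c[0]
    letters = []
    for ci, ri in zip(window_c, window_r):
        same = ci == ref
        ch = ("A" if same else "B") if ri == 1 else ("a" if same else "b")
        letters.append(ch)
    return "".join(letters)


def encode_histories(records: pd.DataFrame) -> pd.Series:
    """Vectorised three-back history codes for every trial (None where the
    window is incomplete, has missing trials, or crosses a session)."""
    df, groups = _session_groups(records)
    codes = pd.Series([None] * len(df), index=df.index, dtype=object)
    for _, grp in groups:
        c = grp["choice"].to_numpy()
        r = grp["reward"].to_numpy()
        n = len(grp)
        for j in range(3, n):
            wc, wr = c[j - 3:j], r[j - 3:j]
            if np.any(pd.isna(wc)) or np.any(pd.isna(wr)):
                continue
            ref = wc[0]
            code = "".join(
                ("A" if ci == ref else "B") if ri == 1
                else ("a" if ci == ref else "b")
                for ci, ri in zip(wc, wr))
            codes.iloc[grp.index[j]] = code
    return codes


def switch_probability_by_history(records: pd.DataFrame) -> pd.DataFrame:
    """P(choose a different port at t than at t-1) per three-back code."""
    df, groups = _session_groups(records)
    codes = encode_histories(df)
    rows = {}
    for _, grp in groups:
        c = grp["choice"].to_numpy()
        for j in range(3, len(grp)):
            code = codes.iloc[grp.index[j]]
            if code is None or pd.isna(c[j]) or pd.isna(c[j - 1]):
                continue
            n, k = rows.get(code, (0, 0))
            rows[code] = (n + 1, k + int(c[j] != c[j - 1]))
    out = pd.DataFrame(
        [{"code": code, "n": n, "p_switch": k / n}
         for code, (n, k) in sorted(rows.items())])
    return out.set_index("code")


def stay_probability_by_2history(records: pd.DataFrame) -> pd.DataFrame:
    """P(repeat the previous choice) after two same-port outcomes.

    Qualifying trials are those where t-2 and t-1 were at the same port;
    the two outcomes are coded R/U oldest-first, e.g. 'RU' = rewarded at
    t-2, unrewarded at t-1.
    """
    df, groups = _session_groups(records)
    counts: Dict[str, Tuple[int, int]] = {}
    for _, grp in groups:
        c = grp["choice"].to_numpy()
        r = grp["reward"].to_numpy()
        for j in range(2, len(grp)):
            win = (c[j - 2], c[j - 1], c[j], r[j - 2], r[j - 1])
            if any(pd.isna(v) for v in win):
                continue
            if c[j - 2] != c[j - 1]:
                continue
            code = ("R" if r[j - 2] == 1 else "U") + ("R" if r[j - 1] == 1 else "U")
            n, k = counts.get(code, (0, 0))
            counts[code] = (n + 1, k + int(c[j] == c[j - 1]))
    out = pd.DataFrame(
        [{"history": h, "n": n, "p_stay": k / n}
         for h, (n, k) in counts.items()])
    order = ["RR", "RU", "UR", "UU"]
    out["history"] = pd.Categorical(out["history"], categories=order)
    return out.sort_values("history").set_index("history")


def block_switch_aligned_accuracy(records: pd.DataFrame,
                                  window: int = 10) -> pd.Series:
    """P(correct choice) at trial offsets around block switches.

    Offset 0 is the first trial under the new contingency; negative offsets
    index back into the previous block.  Alignment never crosses sessions.
    """
    df, groups = _session_groups(records)
    offsets = np.arange(-window, window + 1)
    num = np.zeros(len(offsets))
    den = np.zeros(len(offsets))
    for _, grp in groups:
        blk = grp["block"].to_numpy()
        correct = (grp["choice"] == grp["state"]).to_numpy()
        valid = grp["choice"].notna().to_numpy() & grp["state"].notna().to_numpy()
        switch_pos = np.where(np.diff(blk) > 0)[0] + 1
        for sp in switch_pos:
            for oi, off in enumerate(offsets):
                j = sp + off
                if 0 <= j < len(grp) and valid[j]:
                    den[oi] += 1
                    num[oi] += correct[j]
    with np.errstate(invalid="ignore"):
        acc = np.where(den > 0, num / den, np.nan)
    return pd.Series(acc, index=pd.Index(offsets, name="offset"),
                     name="p_correct")


def trials_to_switch_metrics(records: pd.DataFrame) -> pd.DataFrame:
    """Per-block (trial2sw, trial2asymp) adaptation metrics.

    trial2sw: 1-based index within the block of the first correct choice;
    trial2asymp: first index whose choice and the two following are all
    correct.  Missing when never achieved within the block.
    """
    df, groups = _session_groups(records)
    rows = []
    for (subj, sess), grp in groups:
        for blk, bgrp in grp.groupby("block", sort=True):
            correct = (bgrp["choice"] == bgrp["state"]).to_numpy()
            valid = bgrp["choice"].notna().to_numpy()
            correct = correct & valid
            t2sw = np.nan
            hits = np.where(correct)[0]
            if len(hits):
                t2sw = float(hits[0] + 1)
            t2asymp = np.nan
            for i in range(len(correct) - 2):
                if correct[i] and correct[i + 1] and correct[i + 2]:
                    t2asymp = float(i + 1)
                    break
            rows.append({"subject_id": subj, "session_id": sess, "block": blk,
                         "trial2sw": t2sw, "trial2asymp": t2asymp})
    return pd.DataFrame(rows)


def history_logit_design(records: pd.DataFrame, n_lags: int,
                         variant: str = "decay"):
    """Design matrix and response for the lagged choice-history logistic
    regressions.

    ``decay``: per lag i, a choice-x-reward interaction ``C~_{t-i} R_{t-i}``,
    a reward main effect, and a signed-choice main effect (C~ = the +-1
    choice code), 3 columns per lag.  ``blocking``: the interaction columns
    start at lag 2 and are split by whether trial t-1 was rewarded, probing
    whether a recent reward blocks credit assignment to older outcomes.
    Response is the current choice as 0/1.  Rows with incomplete history are
    dropped; windows never cross sessions.
    """
    if n_lags < 1:
        raise ValueError("n_lags must be >= 1")
    if variant not in ("decay", "blocking"):
        raise ValueError(f"unknown variant {variant!r}")
    df, groups = _session_groups(records)
    X_rows, y_rows = [], []
    for _, grp in groups:
        c = grp["choice"].to_numpy(dtype=float)
        r = grp["reward"].to_numpy(dtype=float)
        if len(grp) <= n_lags:
            raise ValueError(
                f"n_lags={n_lags} exceeds available history in a session "
                f"of {len(grp)} trials")
        for j in range(n_lags, len(grp)):
            win = np.concatenate([c[j - n_lags:j + 1], r[j - n_lags:j]])
            if np.any(np.isnan(win)):
                continue
            row = {}
            if variant == "decay":
                for i in range(1, n_lags + 1):
                    row[f"CxR_lag{i}"] = c[j - i] * r[j - i]
                    row[f"R_lag{i}"] = r[j - i]
                    row[f"C_lag{i}"] = c[j - i]
            else:
                blocked = 1.0 if r[j - 1] == 0 else 0.0
                for i in range(2, n_lags + 1):
                    row[f"CxR_lag{i}_r1absent"] = c[j - i] * r[j - i] * blocked
                    row[f"CxR_lag{i}_r1present"] = (c[j - i] * r[j - i]
                                                    * (1.0 - blocked))
                for i in range(1, n_lags + 1):
                    row[f"R_lag{i}"] = r[j - i]
                    row[f"C_lag{i}"] = c[j - i]
            X_rows.append(row)
            y_rows.append((c[j] + 1.0) / 2.0)
    X = pd.DataFrame(X_rows)
    y = pd.Series(y_rows, name="choice01")
    return X, y


def fit_history_logit(X: pd.DataFrame, y: pd.Series, **fit_kwargs):
    """Fit the history logistic regression (no intercept) via statsmodels."""
    model = sm.Logit(y, X)
    return model.fit(disp=0, **fit_kwargs)
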