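"""Maximum-likelihood fitting, AIC model comparison, and small statistics.

Fitting maximises the summed log choice likelihood of an agent run forward
through a subject's sessions (latent state resets at session boundaries;
trials with a missing choice are skipped without a state update).  The
optimiser is a bounded quasi-Newton search (L-BFGS-B) restarted from
multiple random initial points drawn from per-model distributions; model
comparison uses AIC = 2k - 2 log L reported relative to the RL4p baseline.
"""

from __future__ import annotations

import dataclasses
import hashlib
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from statsmodels.stats.multitest import multipletests

from . import _kernels
from .agents import MODELS, RHO1_DEFAULT, RHO2_DEFAULT

__all__ = [
    "FitResult",
    "evaluate_latents",
    "negative_log_likelihood",
    "per_trial_loglik",
    "fit_mle",
    "aic_compare",
    "around_switch_loglik",
    "holm_bonferroni",
    "min_sign_permutation_p",
    "DEFAULT_INITS",
]


def _prepare_arrays(records: pd.DataFrame):
    """Extract (choice, reward, session-start flag) arrays for the kernels.

    Rows with a missing choice are dropped, which is equivalent to skipping
    them without a state update.  Returns the positional index of kept rows
    so per-trial log-likelihoods can be re-aligned with the table.
    """
    df = records.sort_values(["subject_id", "session_id", "trial"],
                             kind="stable").reset_index()
    ok = df["choice"].notna() & df["reward"].notna()
    df = df[ok]
    c = df["choice"].to_numpy(dtype=np.int64)
    r = df["reward"].to_numpy(dtype=np.float64)
    sess = (df["subject_id"].astype(str) + "\x00" + df["session_id"].astype(str))
    new_sess = np.ones(len(df), dtype=np.bool_)
    new_sess[1:] = sess.to_numpy()[1:] != sess.to_numpy()[:-1]
    return c, r, new_sess, df


def _data_hash(c: np.ndarray, r: np.ndarray) -> str:
    h = hashlib.sha1()
    h.update(c.tobytes())
    h.update(r.tobytes())
    return h.hexdigest()[:16]


def _check_theta(model: str, theta: np.ndarray) -> np.ndarray:
    cls = MODELS[model]
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (len(cls.param_names),):
        raise ValueError(
            f"{model} expects {len(cls.param_names)} parameters "
            f"{cls.param_names}, got shape {theta.shape}")
    for v, name, (lo, hi) in zip(theta, cls.param_names, cls.param_bounds):
        if not lo <= v <= hi:
            raise ValueError(f"{model} parameter {name}={v} outside [{lo}, {hi}]")
    return theta


def _kernel_loglik(model: str, theta: np.ndarray, c, r, new_sess) -> np.ndarray:
    t = theta
    if model == "RL4p":
        return _kernels.nll_rl4p(c, r, new_sess, t[0], t[1], t[2], t[3], False)
    if model == "RLCF":
        return _kernels.nll_rl4p(c, r, new_sess, t[0], t[1], t[2], t[3], True)
    if model == "RLFQ3p":
        zeta = 1.0 - 0.5 * (t[0] + t[1])
        return _kernels.nll_rlfq(c, r, new_sess, t[0], t[1], t[2], zeta)
    if model == "RFLR":
        return _kernels.nll_rflr(c, r, new_sess, t[0], t[1], t[2])
    if model == "RL_meta":
        return _kernels.nll_rlmeta(c, r, new_sess, t[0], t[1], t[2], t[3],
                                   t[4], t[5], t[6])
    if model == "PearceHall":
        return _kernels.nll_pearcehall(c, r, new_sess, t[0], t[1], t[2], t[3],
                                       t[4], t[5], t[6])
    if model == "BIfp":
        return _kernels.nll_belief(c, r, new_sess, t[0], t[1], t[2], 0.0,
                                   RHO1_DEFAULT, RHO2_DEFAULT, 0)
    if model == "BRLfwr":
        return _kernels.nll_belief(c, r, new_sess, t[0], t[1], t[2], t[3],
                                   RHO1_DEFAULT, RHO2_DEFAULT, 1)
    if model == "BRLfw":
        return _kernels.nll_belief(c, r, new_sess, t[0], t[1], t[2], t[3],
                                   RHO1_DEFAULT, RHO2_DEFAULT, 2)
    if model == "BRLwrp":
        return _kernels.nll_belief(c, r, new_sess, t[0], t[1], t[2], t[3],
                                   t[4], t[5], 2)
    raise KeyError(f"unknown model {model!r}")


def per_trial_loglik(model: str, theta: Sequence[float],
                     records: pd.DataFrame) -> pd.Series:
    """Log-likelihood of each observed choice, indexed like ``records``."""
    theta = _check_theta(model, np.asarray(theta, dtype=float))
    c, r, new_sess, df = _prepare_arrays(records)
    lp = _kernel_loglik(model, theta, c, r, new_sess)
    return pd.Series(lp, index=df["index"].to_numpy())


def evaluate_latents(model: str, theta, records: pd.DataFrame) -> pd.DataFrame:
    """Run the (pure-Python) agent through observed choices and rewards.

    Returns a frame aligned with the usable rows of ``records`` holding the
    pre-update latents on every trial: predicted P(c=+1), the decision
    variable D, the (pseudo-)RPE where the model defines one, and the belief
    state for Bayesian agents.  State resets at session boundaries.  This is
    the readable reference path for the compiled likelihood kernels and the
    source of per-trial RPE columns for the neural-linking analyses.
    """
    from .agents import make_agent, pseudo_rpe, PseudoRpeUnavailable
    cls = MODELS[model]
    if isinstance(theta, dict):
        params = dict(theta)
    else:
        theta = _check_theta(model, np.asarray(theta, dtype=float))
        params = dict(zip(cls.param_names, map(float, theta)))
    agent = make_agent(model, **params)
    c, r, new_sess, df = _prepare_arrays(records)
    rows = []
    for i in range(len(c)):
        if new_sess[i]:
            agent.reset()
        p_right = agent.predict()
        lat = agent.latents()
        try:
            delta = pseudo_rpe(agent, c[i], r[i])
        except PseudoRpeUnavailable:
            delta = np.nan
        rows.append({"p_right": p_right,
                     "logp_choice": float(np.log(max(
                         p_right if c[i] == 1 else 1.0 - p_right, 1e-12))),
                     "D": lat.get("D", np.nan),
                     "belief_right": lat.get("belief_right", np.nan),
                     "Q_left": lat.get("Q_left", np.nan),
                     "Q_right": lat.get("Q_right", np.nan),
                     "rpe": delta})
        agent.update(c[i], r[i])
    return pd.DataFrame(rows, index=df["index"].to_numpy())


def negative_log_likelihood(model: str, theta: Sequence[float],
                            records: pd.DataFrame) -> float:
    """Summed negative log choice likelihood of ``model`` on a trial table."""
    return float(-per_trial_loglik(model, theta, records).sum())


# -- multi-start initialisation --------------------------------------------

def _u(a, b):
    return ("uniform", a, b)


#: Per-model initialisation distributions for the multi-start optimiser,
#: mirroring the sampling families used when fitting behaving animals:
#: learning rates and unit-interval rates Unif(0,1), stickiness Gamma(2, .2),
#: inverse temperature Exp(1), hazard rate Unif(0, .05), RFLR's weight Exp(1)
#: and its stickiness N(0,1).
DEFAULT_INITS: Dict[str, list] = {
    "RL4p": [_u(0, 1), _u(0, 1), ("exp", 1.0), ("gamma", 2.0, 0.2)],
    "RLCF": [_u(0, 1), _u(0, 1), ("exp", 1.0), ("gamma", 2.0, 0.2)],
    "RLFQ3p": [_u(0, 1), _u(0, 1), ("exp", 1.0)],
    "RFLR": [("exp", 1.0), ("normal", 0.0, 1.0), ("exp", 1.0)],
    "RL_meta": [_u(0, 1), _u(0, 1), ("exp", 1.0), ("gamma", 2.0, 0.2),
                _u(0, 1), _u(0, 1), _u(0, 1)],
    "PearceHall": [_u(0, 1), _u(0, 1), ("exp", 1.0), ("gamma", 2.0, 0.2),
                   _u(0, 1), _u(0, 1), _u(0, 1)],
    "BIfp": [("exp", 1.0), ("gamma", 2.0, 0.2), _u(0, 0.05)],
    "BRLfwr": [("exp", 1.0), ("gamma", 2.0, 0.2), _u(0, 0.05), _u(0, 1)],
    "BRLfw": [("exp", 1.0), ("gamma", 2.0, 0.2), _u(0, 0.05), _u(0, 1)],
    "BRLwrp": [("exp", 1.0), ("gamma", 2.0, 0.2), _u(0, 0.05), _u(0, 1),
               _u(0.5, 1.0), _u(0.0, 0.3)],
}


def sample_init(model: str, rng: np.random.Generator,
                init: Optional[list] = None) -> np.ndarray:
    """Draw one initial parameter vector, clipped into the fitting bounds."""
    spec = init if init is not None else DEFAULT_INITS[model]
    bounds = MODELS[model].param_bounds
    theta = np.empty(len(spec))
    for i, fam in enumerate(spec):
        kind = fam[0]
        if kind == "uniform":
            v = rng.uniform(fam[1], fam[2])
        elif kind == "exp":
            v = rng.exponential(fam[1])
        elif kind == "gamma":
            v = rng.gamma(fam[1], fam[2])
        elif kind == "normal":
            v = rng.normal(fam[1], fam[2])
        else:
            raise ValueError(f"unknown init family {kind!r}")
        lo, hi = bounds[i]
        theta[i] = min(max(v, lo), hi)
    return theta


@dataclasses.dataclass
class FitResult:
    model: str
    param_names: List[str]
    theta: np.ndarray
    k: int
    loglik: float
    aic: float
    n_trials: int
    n_starts: int
    best_start: int
    converged: bool
    data_hash: str
    starts: List[dict] = dataclasses.field(default_factory=list, repr=False)

    def params_dict(self) -> Dict[str, float]:
        return dict(zip(self.param_names, map(float, self.theta)))

    @property
    def bic(self) -> float:
        """Bayesian information criterion, k ln(n) - 2 log L."""
        return self.k * float(np.log(self.n_trials)) - 2.0 * self.loglik


def fit_mle(model: str, records: pd.DataFrame, n_starts: int = 10,
            seed: int = 0, init: Optional[list] = None) -> FitResult:
    """Fit a model by multi-start bounded maximum likelihood.

    Each start draws an initial point from the model's initialisation
    distributions (nested rng streams derived from ``(seed, start)``, so
    enlarging ``n_starts`` can only improve the returned optimum) and runs
    L-BFGS-B inside the parameter box; the best final value wins.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    cls = MODELS[model]
    c, r, new_sess, _ = _prepare_arrays(records)
    if len(c) == 0:
        raise ValueError("no usable trials (all choices missing)")
    bounds = list(cls.param_bounds)

    def objective(theta: np.ndarray) -> float:
        return -float(_kernel_loglik(model, theta, c, r, new_sess).sum())

    starts = []
    best = None
    for s in range(n_starts):
        rng = np.random.default_rng([int(seed) % (2**31), s])
        x0 = sample_init(model, rng, init)
        res = optimize.minimize(objective, x0, method="L-BFGS-B", bounds=bounds)
        rec = {"start": s, "x0": x0, "theta": res.x, "nll": float(res.fun),
               "converged": bool(res.success), "message": str(res.message)}
        starts.append(rec)
        if np.isfinite(res.fun) and (best is None or res.fun < best["nll"]):
            best = rec
    if best is None:
        raise RuntimeError(f"all {n_starts} starts failed for {model}: "
                           f"{[s['message'] for s in starts]}")
    loglik = -best["nll"]
    k = len(cls.param_names)
    return FitResult(
        model=model, param_names=list(cls.param_names),
        theta=np.asarray(best["theta"], dtype=float), k=k, loglik=loglik,
        aic=2.0 * k - 2.0 * loglik, n_trials=int(len(c)),
        n_starts=n_starts, best_start=int(best["start"]),
        converged=bool(best["converged"]), data_hash=_data_hash(c, r),
        starts=starts)


def aic_compare(fits: Iterable[FitResult], baseline: str = "RL4p") -> pd.DataFrame:
    """Tabulate delta AIC = AIC(model) - AIC(baseline), sorted best first."""
    fits = list(fits)
    hashes = {f.data_hash for f in fits}
    if len(hashes) > 1:
        raise ValueError("fits were not computed on identical records")
    by_name = {f.model: f for f in fits}
    if baseline not in by_name:
        raise ValueError(f"baseline {baseline!r} not among fits")
    base_aic = by_name[baseline].aic
    rows = [{"model": f.model, "k": f.k, "loglik": f.loglik, "aic": f.aic,
             "delta_aic": f.aic - base_aic} for f in fits]
    return (pd.DataFrame(rows).sort_values("delta_aic", kind="stable")
            .reset_index(drop=True))


def around_switch_loglik(model: str, theta: Sequence[float],
                         records: pd.DataFrame, window: int = 5):
    """Log-likelihood restricted to the first ``window`` trials of each
    post-switch block.

    The agent still runs over the full sequence (its latents evolve on every
    trial); only the summation is restricted.  AIC uses the model's full
    parameter count.  Pass ``window=None`` to sum over all trials.
    """
    if "block" not in records.columns:
        raise ValueError("records lack block labels")
    lp = per_trial_loglik(model, theta, records)
    df = records.sort_values(["subject_id", "session_id", "trial"],
                             kind="stable").reset_index()
    df = df[df["choice"].notna() & df["reward"].notna()].reset_index(drop=True)
    mask = np.zeros(len(df), dtype=bool)
    n_switches = 0
    for _, grp in df.groupby(["subject_id", "session_id"], sort=False):
        blk = grp["block"].to_numpy()
        pos_in_block = np.zeros(len(blk), dtype=int)
        for i in range(len(blk)):
            pos_in_block[i] = 1 if (i == 0 or blk[i] != blk[i - 1]) \
                else pos_in_block[i - 1] + 1
        after_switch = blk > blk[0]
        n_switches += len(np.unique(blk[after_switch]))
        sel = after_switch if window is None \
            else after_switch & (pos_in_block <= window)
        mask[grp.index.to_numpy()] = sel if window is not None else after_switch
    if n_switches == 0:
        raise ValueError("no block switches in records")
    if window is None:
        subset = float(lp.sum())
        n_used = len(df)
    else:
        subset = float(lp.to_numpy()[mask].sum())
        n_used = int(mask.sum())
    k = len(MODELS[model].param_names)
    return {"loglik": subset, "aic": 2.0 * k - 2.0 * subset, "n_trials": n_used}


def holm_bonferroni(pvalues: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("pvalues must be a non-empty 1-d sequence")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def min_sign_permutation_p(n: int) -> float:
    """Smallest one-sided p attainable by an exact paired sign-flip test.

    Enumerates all 2^n sign assignments for a configuration in which every
    paired difference shares a sign and has a distinct magnitude; the
    returned value is the probability mass of permutations at least as
    extreme as the observed all-same-sign configuration.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > 20:
        raise ValueError("n > 20 refused (2^n enumeration bound)")
    mags = np.arange(1.0, n + 1.0)
    observed = mags.sum()
    count = 0
    for bits in range(2 ** n):
        signs = 1.0 - 2.0 * ((bits >> np.arange(n)) & 1)
        if float(signs @ mags) >= observed:
            count += 1
    return count / 2.0 ** n
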