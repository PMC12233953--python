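"""Simulate -> cross-fit -> confusion-matrix model identification, and
parameter recovery.

The protocol has three stages: (1) draw generating parameters uniformly
from per-model empirical ranges and simulate sessions, (2) fit every
candidate model to each simulated data set, (3) tabulate how often each
candidate wins on AIC, giving a row-stochastic confusion matrix
P(best-fit model j | generating model i).  Parameter recovery refits the
generating model to its own simulations and correlates truth with
estimates, with an outlier mask at 6 SD of the true-parameter
distribution.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .agents import MAIN_MODELS, MODELS
from .fitting import fit_mle
from .task import TaskConfig, simulate_sessions

__all__ = [
    "DEFAULT_RANGES",
    "sample_generating_params",
    "identification_study",
    "parameter_recovery",
    "six_sd_outlier_mask",
]

#: Plausible per-model uniform simulation ranges standing in for the
#: empirical min/max of animal fits (which are free settings here).  Rates
#: are high — behaving mice in this task are fast learners — hazard rates
#: sit near the true block-switch frequency (~1/15 trials), and inverse
#: temperatures give clearly value-driven but stochastic choice.
DEFAULT_RANGES: Dict[str, Dict[str, Tuple[float, float]]] = {
    "RL4p": {"alpha_plus": (0.4, 0.95), "alpha_minus": (0.4, 0.9),
             "beta": (1.0, 4.0), "phi": (0.1, 1.5)},
    "RLCF": {"alpha_plus": (0.4, 0.95), "alpha_minus": (0.4, 0.9),
             "beta": (1.0, 4.0), "phi": (0.1, 1.5)},
    "RLFQ3p": {"alpha_plus": (0.4, 0.95), "alpha_minus": (0.4, 0.9),
               "beta": (1.0, 4.0)},
    "RFLR": {"alpha": (0.5, 2.5), "phi": (0.0, 1.5), "tau": (0.8, 2.5)},
    "RL_meta": {"alpha_plus": (0.4, 0.95), "alpha_minus": (0.2, 0.8),
                "beta": (1.0, 4.0), "phi": (0.1, 1.5), "zeta": (0.3, 0.9),
                "alpha_nu": (0.1, 0.6), "psi": (0.1, 0.6)},
    "PearceHall": {"alpha_plus": (0.4, 0.95), "alpha_minus": (0.4, 0.9),
                   "beta": (2.0, 8.0), "phi": (0.1, 1.5),
                   "alpha_nu_init": (0.3, 0.9), "psi": (0.1, 0.6),
                   "zeta": (0.3, 0.9)},
    "BIfp": {"beta": (2.0, 6.0), "phi": (0.1, 1.5), "q": (0.01, 0.15)},
    "BRLfwr": {"beta": (2.0, 6.0), "phi": (0.1, 1.5), "q": (0.01, 0.15),
               "alpha_w": (0.0, 0.3)},
}


def sample_generating_params(ranges: Dict[str, Dict[str, Tuple[float, float]]],
                             model: str, rng: np.random.Generator) -> Dict[str, float]:
    """Draw one parameter set uniformly and independently within ranges."""
    if model not in ranges:
        raise KeyError(f"no parameter ranges for model {model!r}")
    spec = ranges[model]
    missing = set(MODELS[model].param_names) - set(spec)
    if missing:
        raise KeyError(f"ranges for {model} missing parameters {missing}")
    out = {}
    for name in MODELS[model].param_names:
        lo, hi = spec[name]
        if lo > hi:
            raise ValueError(f"range for {model}.{name} has min > max")
        out[name] = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
    return out


def _tie_break_key(model: str) -> Tuple[int, str]:
    return (len(MODELS[model].param_names), model)


def identification_study(models: Optional[Sequence[str]] = None,
                         ranges: Optional[dict] = None,
                         n_iter: int = 100,
                         trials_per_session: int = 500,
                         sessions: int = 5,
                         seed: int = 0,
                         n_starts: int = 3,
                         cfg: Optional[TaskConfig] = None):
    """Run the full confusion-matrix protocol.

    Returns ``(confusion, provenance)``: a row-stochastic DataFrame of
    P(best-fit j | generated by i) and a per-iteration provenance table
    (seeds, generating parameters, per-candidate AICs, winner).  AIC ties
    break deterministically toward fewer parameters, then model name.
    """
    models = list(models) if models is not None else list(MAIN_MODELS)
    ranges = ranges if ranges is not None else DEFAULT_RANGES
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    base_cfg = cfg or TaskConfig()
    counts = pd.DataFrame(0.0, index=models, columns=models)
    provenance = []
    n_failed = 0
    for gi, gen in enumerate(models):
        for it in range(n_iter):
            rng = np.random.default_rng([int(seed) % (2**31), gi, it])
            theta_gen = sample_generating_params(ranges, gen, rng)
            sim_seed = int(rng.integers(2**31))
            cfg_i = TaskConfig(**{**base_cfg.__dict__,
                                  "n_trials": trials_per_session})
            data = simulate_sessions(gen, theta_gen, cfg_i, sessions, sim_seed,
                                     subject_id=f"{gen}_{it}")
            aics = {}
            try:
                for cand in models:
                    fit = fit_mle(cand, data, n_starts=n_starts,
                                  seed=int(rng.integers(2**31)))
                    aics[cand] = fit.aic
            except RuntimeError as exc:  # a candidate failed on every start
                n_failed += 1
                provenance.append({"generator": gen, "iteration": it,
                                   "sim_seed": sim_seed, "error": str(exc)})
                continue
            best_aic = min(aics.values())
            tied = [m for m, a in aics.items() if a <= best_aic + 1e-9]
            winner = min(tied, key=_tie_break_key)
            counts.loc[gen, winner] += 1
            provenance.append({"generator": gen, "iteration": it,
                               "sim_seed": sim_seed, "winner": winner,
                               "theta_gen": theta_gen, "aics": aics})
    row_sums = counts.sum(axis=1)
    confusion = counts.div(row_sums.replace(0, np.nan), axis=0)
    confusion.attrs["n_iterations"] = n_iter
    confusion.attrs["n_failed"] = n_failed
    return confusion, pd.DataFrame(provenance)


def six_sd_outlier_mask(truth: np.ndarray, estimate: np.ndarray) -> np.ndarray:
    """True where an estimate lies > 6 SD (of the truth values) from the
    truth mean; such points are excluded from recovery correlations."""
    truth = np.asarray(truth, dtype=float)
    estimate = np.asarray(estimate, dtype=float)
    sd = truth.std()
    if sd <= 1e-12 * (1.0 + np.abs(truth).max(initial=0.0)):
        return np.zeros(len(estimate), dtype=bool)
    return np.abs(estimate - truth.mean()) > 6.0 * sd


def parameter_recovery(model: str,
                       ranges: Optional[dict] = None,
                       n_iter: int = 100,
                       trials_per_session: int = 500,
                       sessions: int = 5,
                       seed: int = 0,
                       n_starts: int = 5,
                       cfg: Optional[TaskConfig] = None):
    """Truth-vs-estimate study for one model.

    Returns ``(pairs, correlations)``: a long table of (parameter, truth,
    estimate, outlier flag) and the per-parameter Pearson r computed on
    non-outlier pairs (NaN when the truth is constant).
    """
    if n_iter < 10:
        raise ValueError("n_iter must be >= 10 for a meaningful correlation")
    ranges = ranges if ranges is not None else DEFAULT_RANGES
    base_cfg = cfg or TaskConfig()
    names = MODELS[model].param_names
    rows = []
    for it in range(n_iter):
        rng = np.random.default_rng([int(seed) % (2**31), 997, it])
        theta_gen = sample_generating_params(ranges, model, rng)
        cfg_i = TaskConfig(**{**base_cfg.__dict__,
                              "n_trials": trials_per_session})
        data = simulate_sessions(model, theta_gen, cfg_i, sessions,
                                 int(rng.integers(2**31)),
                                 subject_id=f"{model}_{it}")
        fit = fit_mle(model, data, n_starts=n_starts,
                      seed=int(rng.integers(2**31)))
        est = fit.params_dict()
        for name in names:
            rows.append({"iteration": it, "parameter": name,
                         "truth": theta_gen[name], "estimate": est[name]})
    pairs = pd.DataFrame(rows)
    pairs["outlier"] = False
    corr = {}
    for name in names:
        sub = pairs[pairs["parameter"] == name]
        mask = six_sd_outlier_mask(sub["truth"].to_numpy(),
                                   sub["estimate"].to_numpy())
        pairs.loc[sub.index, "outlier"] = mask
        kept = sub[~mask]
        if kept["truth"].nunique() < 2 or len(kept) < 3:
            corr[name] = np.nan
        else:
            corr[name] = float(stats.pearsonr(kept["truth"],
                                              kept["estimate"])[0])
    return pairs, corr
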