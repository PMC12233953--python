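"""Generative two-armed-bandit environment and agent-in-the-loop simulator.

The environment has a hidden state ``z in {-1, +1}`` naming the currently
correct port.  A correct choice (``c == z``) is rewarded with probability
``rho1`` (0.75 in the full task) and an incorrect one with ``rho2``
(0 in the real task).  Two switching regimes are provided:

* ``cumulative_rewards`` (the task animals experience): the hidden state
  flips once the animal has earned a per-block target number of rewards,
  drawn uniformly from {block_reward_min .. block_reward_max} (7-23 by
  default), after which a new target is drawn;
* ``per_trial``: the hidden state flips independently each trial with
  probability ``q_env`` — the process the belief-state models assume.

The deliberate mismatch between the two (models assume per-trial switching
while the environment switches on cumulative rewards) is part of the study
design and can itself be studied by toggling ``switch_mode``.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .agents import Agent, make_agent, pseudo_rpe, PseudoRpeUnavailable
from .trials import validate_trials

__all__ = [
    "TaskConfig",
    "TimingConfig",
    "BlockState",
    "step_environment",
    "simulate_session",
    "simulate_sessions",
    "generate_event_times",
]


@dataclasses.dataclass
class TaskConfig:
    rho1: float = 0.75
    rho2: float = 0.0
    switch_mode: str = "cumulative_rewards"
    block_reward_min: int = 7
    block_reward_max: int = 23
    q_env: float = 0.05
    n_trials: int = 500

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho2 < self.rho1 <= 1.0:
            raise ValueError("require 0 <= rho2 < rho1 <= 1")
        if not 1 <= self.block_reward_min <= self.block_reward_max:
            raise ValueError("require 1 <= block_reward_min <= block_reward_max")
        if not 0.0 <= self.q_env <= 0.5:
            raise ValueError("require 0 <= q_env <= 0.5")
        if self.switch_mode not in ("cumulative_rewards", "per_trial"):
            raise ValueError(f"unknown switch_mode {self.switch_mode!r}")


@dataclasses.dataclass
class BlockState:
    """Mutable bookkeeping of the current reward block."""

    block: int = 0
    rewards_in_block: int = 0
    target: int = 0

    @classmethod
    def fresh(cls, cfg: TaskConfig, rng: np.random.Generator) -> "BlockState":
        return cls(block=0, rewards_in_block=0,
                   target=int(rng.integers(cfg.block_reward_min,
                                           cfg.block_reward_max + 1)))


def step_environment(z: int, c: int, cfg: TaskConfig, block: BlockState,
                     rng: np.random.Generator):
    """Emit a reward for choice ``c`` under hidden state ``z`` and advance.

    Returns ``(r, z_next, block)``; ``block`` is mutated in place.  In
    cumulative mode the state flips exactly when the earned-reward count
    reaches the per-block target, and a new target is drawn.
    """
    if c not in (-1, 1):
        raise ValueError(f"choice must be -1 or +1, got {c!r}")
    if z not in (-1, 1):
        raise ValueError(f"hidden state must be -1 or +1, got {z!r}")
    p = cfg.rho1 if c == z else cfg.rho2
    r = int(rng.random() < p)
    z_next = z
    if cfg.switch_mode == "cumulative_rewards":
        block.rewards_in_block += r
        if block.rewards_in_block >= block.target:
            z_next = -z
            block.block += 1
            block.rewards_in_block = 0
            block.target = int(rng.integers(cfg.block_reward_min,
                                            cfg.block_reward_max + 1))
    else:
        if rng.random() < cfg.q_env:
            z_next = -z
            block.block += 1
            block.rewards_in_block = 0
        else:
            block.rewards_in_block += r
    return r, z_next, block


def simulate_session(agent: Agent, cfg: TaskConfig, rng: np.random.Generator,
                     subject_id: str = "sim", session_id: str = "s0") -> pd.DataFrame:
    """Run one agent-in-the-loop session and return a validated trial table.

    Per trial the agent emits P(c=+1) from its current latents, a choice is
    sampled, the environment returns a reward, the agent updates, and the
    pre-update latents (D, belief, Q, pseudo-RPE) are recorded on the row.
    """
    agent.reset()
    z = 1 if rng.random() < 0.5 else -1
    block = BlockState.fresh(cfg, rng)
    rows = []
    for t in range(cfg.n_trials):
        p_right = agent.predict()
        c = 1 if rng.random() < p_right else -1
        blk, rib = block.block, block.rewards_in_block
        r, z_next, block = step_environment(z, c, cfg, block, rng)
        lat = agent.latents()
        try:
            delta = pseudo_rpe(agent, c, r)
        except PseudoRpeUnavailable:
            delta = np.nan
        rows.append({
            "subject_id": subject_id, "session_id": session_id, "trial": t,
            "choice": float(c), "reward": float(r), "state": float(z),
            "block": blk, "rewards_in_block": rib,
            "D": lat.get("D", np.nan),
            "belief_right": lat.get("belief_right", np.nan),
            "Q_left": lat.get("Q_left", np.nan),
            "Q_right": lat.get("Q_right", np.nan),
            "rpe": delta,
            "p_right": p_right,
        })
        agent.update(c, r)
        z = z_next
    return validate_trials(pd.DataFrame(rows))


def simulate_sessions(model: str, params: dict, cfg: TaskConfig, n_sessions: int,
                      seed: int, subject_id: str = "sim") -> pd.DataFrame:
    """Simulate several independent sessions of one agent.

    Each session draws its own rng stream from ``(seed, session index)`` so
    sessions are independently reproducible.
    """
    frames = []
    for s in range(n_sessions):
        rng = np.random.default_rng([int(seed) % (2**31), s])
        agent = make_agent(model, **params)
        frames.append(simulate_session(agent, cfg, rng, subject_id=subject_id,
                                       session_id=f"s{s}"))
    return pd.concat(frames, ignore_index=True)


@dataclasses.dataclass
class TimingConfig:
    """Log-normal/exponential event-timing model for synthetic sessions.

    Shapes are chosen so that typical draws sit comfortably inside the
    trial-quality filters (center_dur <= 0.8 s, port_dur <= 6 s,
    MVMT <= 3 s, SO_lat <= 1 s) and rewarded trials linger longer at the
    port than unrewarded ones.  ``outlier_frac`` deliberately pushes that
    fraction of trials outside at least one filter to exercise them.
    """

    center_dur_mu: float = -1.2
    center_dur_sigma: float = 0.35
    mvmt_mu: float = -0.2
    mvmt_sigma: float = 0.4
    move_latency_mu: float = -1.0
    move_latency_sigma: float = 0.3
    port_dur_rewarded_mu: float = 0.7
    port_dur_rewarded_sigma: float = 0.3
    port_dur_unrewarded_mu: float = -0.3
    port_dur_unrewarded_sigma: float = 0.4
    so_lat_scale: float = 0.05
    outcome_latency: float = 0.005
    outlier_frac: float = 0.0


def generate_event_times(df: pd.DataFrame, tcfg: Optional[TimingConfig] = None,
                         rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Populate CI..SOf event times and the derived durations.

    Events are laid out sequentially within each session so the event-order
    invariant holds by construction.  MVMT/ITI are undefined on the first
    trial of a session.
    """
    tcfg = tcfg or TimingConfig()
    rng = rng if rng is not None else np.random.default_rng(0)
    df = df.copy()
    for col in ["CI", "CO", "SI", "O", "SO0", "SO1", "SOf",
                "MVMT", "ITI", "center_dur", "port_dur", "SO_lat"]:
        df[col] = np.nan

    for _, idx in df.groupby(["subject_id", "session_id"], sort=False).groups.items():
        t_clock = 0.0
        first = True
        for i in idx:
            mvmt = float(rng.lognormal(tcfg.mvmt_mu, tcfg.mvmt_sigma))
            center = float(rng.lognormal(tcfg.center_dur_mu, tcfg.center_dur_sigma))
            move = float(rng.lognormal(tcfg.move_latency_mu, tcfg.move_latency_sigma))
            rewarded = df.at[i, "reward"] == 1.0
            if rewarded:
                port = float(rng.lognormal(tcfg.port_dur_rewarded_mu,
                                           tcfg.port_dur_rewarded_sigma))
            else:
                port = float(rng.lognormal(tcfg.port_dur_unrewarded_mu,
                                           tcfg.port_dur_unrewarded_sigma))
            so_lat = float(rng.exponential(tcfg.so_lat_scale))
            tail = float(rng.exponential(0.02))

            if tcfg.outlier_frac > 0 and rng.random() < tcfg.outlier_frac:
                which = rng.integers(4)
                if which == 0:
                    center = float(rng.uniform(0.9, 1.5))
                elif which == 1:
                    port = float(rng.uniform(6.5, 10.0))
                elif which == 2:
                    mvmt = float(rng.uniform(3.5, 8.0))
                else:
                    so_lat = float(rng.uniform(1.2, 3.0))
                    port = max(port, so_lat + 0.05)
            so_lat = min(so_lat, port)  # SO0 may not precede the outcome

            ci = t_clock + mvmt
            co = ci + center
            si = co + move
            o = si + tcfg.outcome_latency
            so1 = o + port
            so0 = so1 - so_lat
            sof = so1 + tail
            df.loc[i, ["CI", "CO", "SI", "O", "SO0", "SO1", "SOf"]] = (
                ci, co, si, o, so0, so1, sof)
            df.at[i, "center_dur"] = center
            df.at[i, "port_dur"] = port
            df.at[i, "SO_lat"] = so_lat
            if not first:
                df.at[i, "MVMT"] = mvmt
                df.at[i, "ITI"] = ci - prev_so1
            first = False
            prev_so1 = so1
            t_clock = sof
    return validate_trials(df)
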