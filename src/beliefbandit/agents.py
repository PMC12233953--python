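"""Cognitive agents for the two-armed-bandit reversal task.

Every agent maps a scalar decision variable ``D`` (a value difference) to a
choice probability through a common logistic policy,

    P(c_t = +1) = sigma(beta * D_t + phi * c_{t-1}),

where ``beta`` is an inverse temperature, ``phi`` a stickiness (perseveration)
bias toward the previous choice, and ``c_t in {-1, +1}`` codes left/right.
The stickiness term is dropped on the first trial of a session.  Agents differ
only in how experience updates ``D``:

* ``RL4p`` — Q-learning with asymmetric learning rates for positive and
  negative reward prediction errors (RPEs).
* ``RLCF`` — RL4p plus a counterfactual update that pushes the unchosen
  option's value in the opposite direction.
* ``RLFQ3p`` — Q-learning with forgetting: the unchosen value decays by a
  factor ``zeta`` tied to the learning rates; no stickiness (3 parameters).
* ``RFLR`` — recursively formulated logistic regression: the decision
  variable itself decays exponentially and is bumped by rewarded choices.
* ``RL_meta`` — forgetting Q-learning whose negative learning rate adapts to
  unexpected uncertainty (running surprise about |RPE|).
* ``PearceHall`` — dynamic learning rate proportional to an associability
  term tracking recent |RPE|, with forgetting toward a neutral value.
* ``BIfp`` — Bayesian inference with fixed parameters: a two-state hidden
  Markov model over which side is rewarded; ``D = 2 b - 1`` where ``b`` is
  the posterior belief that the right side is correct.
* ``BRLfwr`` / ``BRLfw`` / ``BRLwrp`` — hybrid belief-state RL: values are a
  learned linear readout of the belief state, updated by gradient descent on
  the RPE.  ``fwr`` fixes the low reward weight, ``fw`` learns both weights,
  ``wrp`` additionally fits the assumed reward probabilities.

Agents expose ``reset()``, ``predict() -> P(c=+1)``, ``update(c, r)`` and
``latents()``; a registry :data:`MODELS` keys them by name.
"""

from __future__ import annotations

import math
from typing import Dict, List, Tuple, Type

import numpy as np

__all__ = [
    "Agent",
    "MODELS",
    "MAIN_MODELS",
    "make_agent",
    "choice_prob",
    "belief_update",
    "bifp_value_diff",
    "rflr_update",
    "pseudo_rpe",
    "PseudoRpeUnavailable",
]

#: Default assumed reward probabilities for the belief-state models.  The
#: environment's true incorrect-side reward probability is 0, but the model
#: side uses a small positive value so the belief filter never degenerates.
RHO1_DEFAULT = 0.75
RHO2_DEFAULT = 1e-4

#: Q-value initialisation for all RL-family agents (midpoint of reward range).
Q_INIT = 0.5


def _sigmoid(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def choice_prob(D: float, prev_choice: float, beta: float, phi: float) -> float:
    """Common logistic policy P(c=+1) = sigma(beta*D + phi*prev_choice).

    ``prev_choice`` is 0 on the first trial of a session, which drops the
    stickiness term.
    """
    return _sigmoid(beta * D + phi * prev_choice)


def belief_update(b: float, c: float, r: float, q: float,
                  rho1: float = RHO1_DEFAULT, rho2: float = RHO2_DEFAULT) -> float:
    """One forward-filter step of the two-state hidden Markov model.

    ``b`` is the prior P(z=+1).  The observed (choice, reward) pair is scored
    under each hidden state with the reward rule P(r=1|c,z) = rho1 if c==z
    else rho2; the posterior is then pushed through the symmetric transition
    with per-trial switch probability ``q``.
    """
    lik_pos = (rho1 if c == 1 else rho2)
    lik_neg = (rho1 if c == -1 else rho2)
    if r == 0:
        lik_pos, lik_neg = 1.0 - lik_pos, 1.0 - lik_neg
    num = b * lik_pos
    den = num + (1.0 - b) * lik_neg
    if den <= 0.0:
        raise FloatingPointError(
            "belief normaliser vanished; rho2_model must be > 0")
    post = num / den
    return (1.0 - q) * post + q * (1.0 - post)


def bifp_value_diff(b: float) -> float:
    """Decision variable of the fixed-parameter Bayesian agent: D = 2b - 1."""
    return 2.0 * b - 1.0


def rflr_update(D: float, c: float, r: float, alpha: float, tau: float) -> float:
    """Recursive logistic-regression update D <- exp(-1/tau) D + alpha*r*c."""
    return math.exp(-1.0 / tau) * D + alpha * r * c


class PseudoRpeUnavailable(ValueError):
    """Raised when a model has no defined (pseudo-)RPE."""


class Agent:
    """Common agent contract: predict / update / latents with session resets."""

    name: str = ""
    #: Names of free parameters, in the canonical vector order used by the
    #: fitting kernels.
    param_names: List[str] = []
    #: Box bounds matching ``param_names``.
    param_bounds: List[Tuple[float, float]] = []

    def __init__(self, **params: float) -> None:
        unknown = set(params) - set(self.param_names)
        if unknown:
            raise ValueError(f"unknown parameters for {self.name}: {unknown}")
        missing = set(self.param_names) - set(params)
        if missing:
            raise ValueError(f"missing parameters for {self.name}: {missing}")
        self.params = {k: float(params[k]) for k in self.param_names}
        self.reset()

    @property
    def k(self) -> int:
        return len(self.param_names)

    def theta(self) -> np.ndarray:
        return np.array([self.params[p] for p in self.param_names])

    # -- state -----------------------------------------------------------
    def reset(self) -> None:
        """Reset latents at a session boundary."""
        self.prev_choice = 0.0

    # -- policy ----------------------------------------------------------
    def value_diff(self) -> float:
        raise NotImplementedError

    def _policy_params(self) -> Tuple[float, float]:
        return self.params.get("beta", 1.0), self.params.get("phi", 0.0)

    def predict(self) -> float:
        """Probability of choosing the right port (+1) on the next trial."""
        beta, phi = self._policy_params()
        p = choice_prob(self.value_diff(), self.prev_choice, beta, phi)
        if not 0.0 <= p <= 1.0:
            raise RuntimeError("agent emitted probability outside [0, 1]")
        return p

    # -- learning --------------------------------------------------------
    def expected_reward(self, c: float) -> float:
        """Predicted reward for choosing ``c`` given the current latents."""
        raise PseudoRpeUnavailable(
            f"model {self.name} has no defined (pseudo-)RPE")

    def update(self, c: float, r: float) -> None:
        raise NotImplementedError

    def latents(self) -> Dict[str, float]:
        """Named latent variables for logging onto trial rows."""
        return {"D": self.value_diff()}


def pseudo_rpe(agent: Agent, c: float, r: float) -> float:
    """Observed minus expected reward under the agent's pre-update latents.

    Defined for all value-based agents; raises
    :class:`PseudoRpeUnavailable` for RFLR, which carries no reward
    expectation.
    """
    return r - agent.expected_reward(c)


# ---------------------------------------------------------------------------
# RL family
# ---------------------------------------------------------------------------

class _QAgent(Agent):
    """Shared plumbing for agents holding a two-entry Q table."""

    def reset(self) -> None:
        super().reset()
        self.Q = {-1.0: Q_INIT, 1.0: Q_INIT}

    def value_diff(self) -> float:
        return self.Q[1.0] - self.Q[-1.0]

    def expected_reward(self, c: float) -> float:
        return self.Q[float(c)]

    def latents(self) -> Dict[str, float]:
        return {"D": self.value_diff(), "Q_left": self.Q[-1.0],
                "Q_right": self.Q[1.0]}


class RL4p(_QAgent):
    """Q-learning with asymmetric learning rates, softmax + stickiness."""

    name = "RL4p"
    param_names = ["alpha_plus", "alpha_minus", "beta", "phi"]
    param_bounds = [(0.0, 1.0), (0.0, 1.0), (0.0, 50.0), (0.0, 10.0)]

    def update(self, c: float, r: float) -> None:
        c = float(c)
        delta = r - self.Q[c]
        alpha = self.params["alpha_plus"] if delta >= 0 else self.params["alpha_minus"]
        self.Q[c] += alpha * delta
        self.prev_choice = c


class RLCF(_QAgent):
    """RL4p plus a counterfactual update of the unchosen option.

    The unchosen value moves toward ``1 - r`` with the same learning rate
    that the factual RPE selected.
    """

    name = "RLCF"
    param_names = ["alpha_plus", "alpha_minus", "beta", "phi"]
    param_bounds = [(0.0, 1.0), (0.0, 1.0), (0.0, 50.0), (0.0, 10.0)]

    def update(self, c: float, r: float) -> None:
        c = float(c)
        delta = r - self.Q[c]
        alpha = self.params["alpha_plus"] if delta >= 0 else self.params["alpha_minus"]
        delta_cf = (1.0 - r) - self.Q[-c]
        self.Q[c] += alpha * delta
        self.Q[-c] += alpha * delta_cf
        self.prev_choice = c


class RLFQ3p(_QAgent):
    """Forgetting Q-learning, 3 parameters and no stickiness.

    The unchosen value decays multiplicatively by ``zeta``.  Two renderings
    of the zeta formula circulate; the default ties it to the learning rates
    as ``zeta = 1 - (alpha_plus + alpha_minus)/2``, which makes the model
    exactly equivalent to RFLR in the symmetric-rate case.  Pass
    ``zeta_convention="mean"`` for the alternative ``(alpha+ + alpha-)/2``.
    """

    name = "RLFQ3p"
    param_names = ["alpha_plus", "alpha_minus", "beta"]
    param_bounds = [(0.0, 1.0), (0.0, 1.0), (0.0, 50.0)]

    def __init__(self, zeta_convention: str = "one_minus_mean", **params: float) -> None:
        if zeta_convention not in ("one_minus_mean", "mean"):
            raise ValueError(f"unknown zeta convention {zeta_convention!r}")
        self.zeta_convention = zeta_convention
        super().__init__(**params)

    @property
    def zeta(self) -> float:
        m = 0.5 * (self.params["alpha_plus"] + self.params["alpha_minus"])
        return 1.0 - m if self.zeta_convention == "one_minus_mean" else m

    def update(self, c: float, r: float) -> None:
        c = float(c)
        delta = r - self.Q[c]
        alpha = self.params["alpha_plus"] if delta >= 0 else self.params["alpha_minus"]
        self.Q[c] += alpha * delta
        self.Q[-c] *= self.zeta
        self.prev_choice = c


class RFLR(Agent):
    """Recursively formulated logistic regression.

    The decision variable decays with timescale ``tau`` and is incremented by
    ``alpha * r * c``.  Beta is fixed at 1 and the stickiness is
    unconstrained in sign.  No reward expectation is defined, so the model
    has no (pseudo-)RPE.
    """

    name = "RFLR"
    param_names = ["alpha", "phi", "tau"]
    param_bounds = [(0.0, 20.0), (-10.0, 10.0), (1e-2, 100.0)]

    def reset(self) -> None:
        super().reset()
        self.D = 0.0

    def value_diff(self) -> float:
        return self.D

    def _policy_params(self) -> Tuple[float, float]:
        return 1.0, self.params["phi"]

    def update(self, c: float, r: float) -> None:
        self.D = rflr_update(self.D, c, r, self.params["alpha"], self.params["tau"])
        self.prev_choice = float(c)


class RLMeta(_QAgent):
    """Forgetting Q-learning with uncertainty-adapted negative learning rate.

    A running estimate ``omega`` of the expected |RPE| defines the unexpected
    uncertainty ``nu = |delta| - omega``; on negative RPEs the negative
    learning rate is pulled toward ``nu + alpha0_minus`` at rate ``psi``
    (clamped at 0 from below).  ``alpha0_minus`` doubles as the initial
    negative rate.
    """

    name = "RL_meta"
    param_names = ["alpha_plus", "alpha_minus", "beta", "phi",
                   "zeta", "alpha_nu", "psi"]
    param_bounds = [(0.0, 1.0), (0.0, 1.0), (0.0, 50.0), (0.0, 10.0),
                    (0.0, 1.0), (0.0, 1.0), (0.0, 1.0)]

    def reset(self) -> None:
        super().reset()
        self.omega = 0.0
        self.alpha_minus_t = self.params["alpha_minus"] if hasattr(self, "params") else 0.0

    def update(self, c: float, r: float) -> None:
        c = float(c)
        delta = r - self.Q[c]
        nu = abs(delta) - self.omega
        if delta < 0:
            psi = self.params["psi"]
            self.alpha_minus_t = max(
                0.0,
                psi * (nu + self.params["alpha_minus"])
                + (1.0 - psi) * self.alpha_minus_t,
            )
        self.omega += self.params["alpha_nu"] * nu
        alpha = self.params["alpha_plus"] if delta >= 0 else self.alpha_minus_t
        self.Q[c] += alpha * delta
        self.Q[-c] *= self.params["zeta"]
        self.prev_choice = c

    def latents(self) -> Dict[str, float]:
        out = super().latents()
        out.update(alpha_minus_t=self.alpha_minus_t, omega=self.omega)
        return out


class PearceHall(_QAgent):
    """Pearce-Hall associability model with forgetting.

    The associability ``alpha_nu`` tracks recent |RPE| at rate ``psi`` and
    multiplies the asymmetric learning rates; the unchosen value relaxes
    toward ``Q0`` (the Q initialisation, 0.5) by factor ``zeta``.  The
    associability is updated before the value step, following the model's
    stated equation order.
    """

    name = "PearceHall"
    param_names = ["alpha_plus", "alpha_minus", "beta", "phi",
                   "alpha_nu_init", "psi", "zeta"]
    param_bounds = [(0.0, 1.0), (0.0, 1.0), (0.0, 50.0), (0.0, 10.0),
                    (0.0, 1.0), (0.0, 1.0), (0.0, 1.0)]

    Q0 = Q_INIT

    def reset(self) -> None:
        super().reset()
        self.alpha_nu = self.params["alpha_nu_init"] if hasattr(self, "params") else 0.0

    def update(self, c: float, r: float) -> None:
        c = float(c)
        delta = r - self.Q[c]
        self.alpha_nu += self.params["psi"] * (abs(delta) - self.alpha_nu)
        alpha = self.params["alpha_plus"] if delta >= 0 else self.params["alpha_minus"]
        self.Q[c] += self.alpha_nu * alpha * delta
        self.Q[-c] = self.Q0 + self.params["zeta"] * (self.Q[-c] - self.Q0)
        self.prev_choice = c

    def latents(self) -> Dict[str, float]:
        out = super().latents()
        out["alpha_nu_t"] = self.alpha_nu
        return out


# ---------------------------------------------------------------------------
# Belief-state family
# ---------------------------------------------------------------------------

class _BeliefAgent(Agent):
    """Shared belief-state plumbing: b = P(z = +1), initialised to 0.5."""

    rho1 = RHO1_DEFAULT
    rho2 = RHO2_DEFAULT

    def reset(self) -> None:
        super().reset()
        self.b = 0.5

    def b_of(self, c: float) -> float:
        return self.b if c == 1 else 1.0 - self.b

    def latents(self) -> Dict[str, float]:
        return {"D": self.value_diff(), "belief_right": self.b}


class BIfp(_BeliefAgent):
    """Bayesian inference with fixed parameters.

    Pure hidden-Markov-model filtering with assumed reward probabilities
    (rho1, rho2) and switch rate ``q``; the decision variable is
    ``D = 2 b - 1``.  The pseudo-RPE uses the belief-weighted expected reward
    ``rho1 * b(c) + rho2 * b(-c)``.
    """

    name = "BIfp"
    param_names = ["beta", "phi", "q"]
    param_bounds = [(0.0, 50.0), (0.0, 10.0), (0.0, 0.5)]

    def value_diff(self) -> float:
        return bifp_value_diff(self.b)

    def expected_reward(self, c: float) -> float:
        return self.rho1 * self.b_of(c) + self.rho2 * self.b_of(-c)

    def update(self, c: float, r: float) -> None:
        self.b = belief_update(self.b, c, r, self.params["q"], self.rho1, self.rho2)
        self.prev_choice = float(c)


class BRL(_BeliefAgent):
    """Hybrid belief-state RL with learned reward weights.

    Values are ``Q(c) = w1 b(c) + w2 b(-c)``; the weights follow a gradient
    step on the RPE, ``dw1 = alpha_w * delta * b(c)`` (and symmetrically for
    w2 when learned).  Weights are initialised at the assumed reward
    probabilities.  ``variant`` selects which quantities are learned/fitted:

    - ``"fwr"`` — w2 pinned at rho2 (the default, 4 free parameters);
    - ``"fw"``  — both weights learned;
    - ``"wrp"`` — both weights learned and (rho1, rho2) fitted.
    """

    name = "BRLfwr"
    param_names = ["beta", "phi", "q", "alpha_w"]
    param_bounds = [(0.0, 50.0), (0.0, 10.0), (0.0, 0.5), (0.0, 1.0)]
    variant = "fwr"

    def reset(self) -> None:
        super().reset()
        self.w1 = self.rho1
        self.w2 = self.rho2

    def q_value(self, c: float) -> float:
        return self.w1 * self.b_of(c) + self.w2 * self.b_of(-c)

    def value_diff(self) -> float:
        return self.q_value(1.0) - self.q_value(-1.0)

    def expected_reward(self, c: float) -> float:
        return self.q_value(c)

    def update(self, c: float, r: float) -> None:
        c = float(c)
        delta = r - self.q_value(c)
        aw = self.params["alpha_w"]
        w1_new = self.w1 + aw * delta * self.b_of(c)
        if self.variant in ("fw", "wrp"):
            self.w2 = self.w2 + aw * delta * self.b_of(-c)
        self.w1 = w1_new
        self.b = belief_update(self.b, c, r, self.params["q"], self.rho1, self.rho2)
        self.prev_choice = c

    def latents(self) -> Dict[str, float]:
        out = super().latents()
        out.update(w1=self.w1, w2=self.w2)
        return out


class BRLfw(BRL):
    name = "BRLfw"
    variant = "fw"


class BRLwrp(BRL):
    name = "BRLwrp"
    variant = "wrp"
    param_names = ["beta", "phi", "q", "alpha_w", "rho1", "rho2"]
    param_bounds = [(0.0, 50.0), (0.0, 10.0), (0.0, 0.5), (0.0, 1.0),
                    (1e-4, 1.0), (1e-6, 0.5)]

    def __init__(self, **params: float) -> None:
        # rho1/rho2 are free parameters; bind the class attributes per instance.
        super().__init__(**params)

    def reset(self) -> None:
        if hasattr(self, "params"):
            self.rho1 = self.params["rho1"]
            self.rho2 = self.params["rho2"]
        super().reset()


MODELS: Dict[str, Type[Agent]] = {
    cls.name: cls
    for cls in (RL4p, RLCF, RFLR, RLFQ3p, RLMeta, PearceHall, BIfp, BRL,
                BRLfw, BRLwrp)
}

#: The eight model variants entering model comparison and identification.
MAIN_MODELS = ["RL4p", "RLCF", "RFLR", "RLFQ3p", "RL_meta", "PearceHall",
               "BIfp", "BRLfwr"]


def make_agent(name: str, **params: float) -> Agent:
    """Instantiate a registered agent by name."""
    if name not in MODELS:
        raise KeyError(f"unknown model {name!r}; known: {sorted(MODELS)}")
    return MODELS[name](**params)
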