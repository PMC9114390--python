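"""Structural utility models and the logistic stochastic-choice rule.

Player B's utility after Player A has trusted (chosen W) combines the
monetary payoff with social-preference penalties:

* absolute-difference inequity: ``u = pay_B - alpha * |pay_A - pay_B|``;
* Fehr-Schmidt inequity: separate penalties ``phi`` for disadvantageous
  (``pay_A > pay_B``) and ``omega`` for advantageous inequality;
* combined model: absolute inequity plus, on Defect only, a guilt cost
  ``gamma * tau * (x_A - y_A)`` — the belief-weighted harm done to A.

Choice is stochastic: P(Cooperate) is the logistic of the utility
difference (cooperate minus defect), optionally scaled by a temperature and
shifted by an intercept.  With temperature 1 and intercept 0 the combined
model's log-odds equal ``1*Reward + gamma*Guilt + alpha*Inequity`` in the
task-design regressors, which is the identity the per-subject logistic
regression exploits.

Only Player B carries preference parameters: guilt is role-dependent and
affects only the second mover.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from guiltgame.task_design import Trial

__all__ = [
    "AgentParams",
    "Profile",
    "utility_abs",
    "utility_fs",
    "utility_combined",
    "cooperate_deterministic",
    "choice_probability",
]


class Profile(enum.Enum):
    """Terminal profiles of the game tree reachable by the players."""

    W_COOPERATE = "W_Cooperate"
    W_DEFECT = "W_Defect"
    Z = "Z"


@dataclass(frozen=True)
class AgentParams:
    """A simulated Player B's structural preferences and choice noise.

    gamma: guilt sensitivity, utility cost per point of belief-weighted harm.
    alpha: absolute-inequity sensitivity.
    phi / omega: Fehr-Schmidt disadvantageous / advantageous sensitivities.
    intercept: choice bias on the log-odds scale.
    temperature: positive scale on the utility difference (1 = raw points).
    """

    gamma: float = 0.0
    alpha: float = 0.0
    phi: float = 0.0
    omega: float = 0.0
    intercept: float = 0.0
    temperature: float = 1.0

    def __post_init__(self) -> None:
        for name in ("gamma", "alpha", "phi", "omega"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


def _require_b_move(p: Profile) -> None:
    if p is Profile.Z:
        raise ValueError("Player B has no move on the Z profile")


def utility_abs(t: Trial, a: AgentParams, p: Profile) -> float:
    """Absolute-difference inequity utility for Player B."""
    _require_b_move(p)
    pay = t.payoffs
    if p is Profile.W_COOPERATE:
        return pay.x_B - a.alpha * abs(pay.x_A - pay.x_B)
    return pay.y_B - a.alpha * abs(pay.y_A - pay.y_B)


def utility_fs(t: Trial, a: AgentParams, p: Profile) -> float:
    """Fehr-Schmidt inequity utility for Player B."""
    _require_b_move(p)
    pay = t.payoffs
    if p is Profile.W_COOPERATE:
        own, other = pay.x_B, pay.x_A
    else:
        own, other = pay.y_B, pay.y_A
    return own - a.phi * max(other - own, 0) - a.omega * max(own - other, 0)


def utility_combined(t: Trial, a: AgentParams, p: Profile) -> float:
    """Guilt aversion plus absolute inequity; guilt binds only on Defect."""
    _require_b_move(p)
    pay = t.payoffs
    if p is Profile.W_COOPERATE:
        return pay.x_B - a.alpha * abs(pay.x_A - pay.x_B)
    guilt_cost = a.gamma * t.tau * (pay.x_A - pay.y_A)
    return pay.y_B - guilt_cost - a.alpha * abs(pay.y_A - pay.y_B)


def cooperate_deterministic(t: Trial, gamma: float) -> str:
    """Noise-free guilt-averse choice: Cooperate iff the guilt-discounted
    defect payoff falls strictly below the cooperate payoff.

    Exact indifference resolves to Defect (the cooperation condition is a
    strict inequality).
    """
    pay = t.payoffs
    defect_value = pay.y_B - gamma * t.tau * (pay.x_A - pay.y_A)
    return "Cooperate" if defect_value < pay.x_B else "Defect"


_UTILITY_FNS = {
    "abs": utility_abs,
    "fs": utility_fs,
    "combined": utility_combined,
}


def choice_probability(t: Trial, a: AgentParams, model: str = "combined") -> float:
    """P(Cooperate) = logistic(temperature * (u_C - u_D) + intercept).

    Strictly inside (0, 1) for finite inputs.
    """
    try:
        u = _UTILITY_FNS[model]
    except KeyError:
        raise ValueError(f"unknown utility model {model!r}; use abs, fs or combined")
    diff = u(t, a, Profile.W_COOPERATE) - u(t, a, Profile.W_DEFECT)
    eta = a.temperature * diff + a.intercept
    # numerically safe logistic, clamped to the open interval
    if eta >= 0:
        p = 1.0 / (1.0 + np.exp(-eta))
    else:
        ex = np.exp(eta)
        p = ex / (1.0 + ex)
    tiny = np.finfo(float).tiny
    return float(np.clip(p, tiny, np.nextafter(1.0, 0.0)))
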