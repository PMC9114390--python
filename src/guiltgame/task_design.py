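"""Trust-game trial designs with near-orthogonal psychological regressors.

A trial of the binary trust game is defined by six monetary payoffs and the
first mover's stated belief ``tau`` that the second mover will cooperate.
Player A chooses between an outside option Z (payoffs ``z_A``, ``z_B``) and
trusting (W); after W, Player B chooses Cooperate (payoffs ``x_A``, ``x_B``)
or Defect (``y_A``, ``y_B``).  Two strict orderings make the game a trust
game: ``y_A < z_A < x_A`` (trusting is a genuine risk for A) and
``z_B < x_B < y_B`` (B is tempted to defect, so cooperating is costly and
defecting can induce guilt).

Each trial maps to three psychological regressors for Player B's choice:

* ``reward = x_B - y_B`` — the monetary gain from cooperating (negative by
  construction);
* ``guilt = tau * (x_A - y_A)`` — the belief-weighted harm to Player A from
  defecting, i.e. how far defection lets A down relative to what A expects;
* ``inequity = -(|x_A - x_B| - |y_A - y_B|)`` — how much cooperation reduces
  payoff inequality relative to defection (absolute-difference form).

The design generator rejection-samples integer payoff tables until the
pairwise correlations among the three regressors fall under configurable
bounds, so that guilt aversion can be estimated without contamination from
inequity aversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Payoffs",
    "Trial",
    "RegressorRow",
    "TrialDesign",
    "DesignDiagnostics",
    "DesignConfig",
    "DEFAULT_TAU_SCHEDULE",
    "build_tau_schedule",
    "validate_payoffs",
    "compute_regressors",
    "generate_design",
    "design_diagnostics",
]

#: Belief schedule used in the study design: tau level -> number of trials.
#: 60% x 7, 70% x 5, 80% x 13, 90% x 11, 100% x 9 (45 trials in total).
DEFAULT_TAU_SCHEDULE: dict[float, int] = {0.6: 7, 0.7: 5, 0.8: 13, 0.9: 11, 1.0: 9}

_REGRESSOR_TRIPLE = ("reward", "guilt", "inequity_abs")


@dataclass(frozen=True)
class Payoffs:
    """Monetary payoffs of one trial (non-negative integer points).

    ``x``: (W, Cooperate); ``y``: (W, Defect); ``z``: outside option.
    """

    x_A: int
    x_B: int
    y_A: int
    y_B: int
    z_A: int
    z_B: int

    def __post_init__(self) -> None:
        for name in ("x_A", "x_B", "y_A", "y_B", "z_A", "z_B"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"payoff {name} must be non-negative, got {v}")


@dataclass(frozen=True)
class Trial:
    """One game: payoffs plus Player A's stated belief ``tau`` in [0, 1]."""

    trial_id: int
    payoffs: Payoffs
    tau: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.tau <= 1.0:
            raise ValueError(f"tau must be a fraction in [0, 1], got {self.tau}")


@dataclass(frozen=True)
class RegressorRow:
    """Per-trial psychological regressors for Player B's cooperate choice."""

    reward: float
    guilt: float
    inequity_abs: float
    inequity_disadv: float
    inequity_adv: float


@dataclass
class DesignDiagnostics:
    """Pairwise Pearson correlations among the three regressors plus flags."""

    correlations: dict[tuple[str, str], float]
    flags: list[str] = field(default_factory=list)
    bounds_ok: bool = True

    @property
    def max_abs_correlation(self) -> float:
        finite = [abs(v) for v in self.correlations.values() if math.isfinite(v)]
        return max(finite) if finite else float("nan")


@dataclass
class TrialDesign:
    """An ordered collection of trials with regressors and diagnostics."""

    trials: list[Trial]
    diagnostics: DesignDiagnostics

    def __len__(self) -> int:
        return len(self.trials)

    def to_frame(self) -> pd.DataFrame:
        """Long table: payoffs, tau (4 decimals) and regressors per trial."""
        rows = []
        for t in self.trials:
            p = t.payoffs
            r = compute_regressors(t)
            rows.append(
                {
                    "trial_id": t.trial_id,
                    "x_A": p.x_A,
                    "x_B": p.x_B,
                    "y_A": p.y_A,
                    "y_B": p.y_B,
                    "z_A": p.z_A,
                    "z_B": p.z_B,
                    "tau": round(t.tau, 4),
                    "reward": r.reward,
                    "guilt": r.guilt,
                    "inequity_abs": r.inequity_abs,
                    "inequity_disadv": r.inequity_disadv,
                    "inequity_adv": r.inequity_adv,
                }
            )
        return pd.DataFrame(rows)

    def regressor_matrix(self) -> np.ndarray:
        """(n_trials, 3) array of (reward, guilt, inequity_abs)."""
        return self.to_frame()[list(_REGRESSOR_TRIPLE)].to_numpy(dtype=float)


@dataclass
class DesignConfig:
    """Knobs for the rejection-sampling design generator.

    ``payoff_low``/``payoff_high`` bound the integer payoffs (inclusive).
    ``max_abs_corr`` bounds every pairwise |r| among the three regressors;
    ``max_guilt_inequity_corr`` additionally tightens the guilt-inequity
    pair, the contrast the design exists to dissociate.
    """

    payoff_low: int = 1
    payoff_high: int = 20
    tau_schedule: dict[float, int] = field(
        default_factory=lambda: dict(DEFAULT_TAU_SCHEDULE)
    )
    max_abs_corr: float = 0.30
    max_guilt_inequity_corr: float = 0.05
    max_attempts: int = 100_000


def build_tau_schedule(
    counts_by_level: dict[float, int], seed: int | None = None
) -> list[float]:
    """Expand a {tau level: count} map into a shuffled trial sequence.

    Levels given as percentages (values > 1) are converted to fractions.
    With ``seed=None`` the sequence is returned in sorted-level order;
    otherwise the order is a seeded permutation, mirroring randomized trial
    order across participants.
    """
    levels: list[float] = []
    for level, count in counts_by_level.items():
        if not isinstance(count, (int, np.integer)) or isinstance(count, bool):
            raise ValueError(f"count for level {level!r} must be an integer, got {count!r}")
        if count <= 0:
            raise ValueError(f"count for level {level!r} must be positive, got {count}")
        lv = float(level)
        if lv > 1.0:  # percent input
            lv = lv / 100.0
        if not 0.0 <= lv <= 1.0:
            raise ValueError(f"tau level {level!r} outside [0, 1] after conversion")
        levels.extend([lv] * int(count))
    levels.sort()
    if seed is not None:
        rng = np.random.default_rng(seed)
        levels = [levels[i] for i in rng.permutation(len(levels))]
    return levels


def validate_payoffs(p: Payoffs) -> tuple[bool, list[str]]:
    """Check the two strict ordering chains; return (valid, violations).

    Total function: never raises on complete payoff sets.
    """
    violations: list[str] = []
    if not p.y_A < p.z_A:
        violations.append("y_A < z_A violated")
    if not p.z_A < p.x_A:
        violations.append("z_A < x_A violated")
    if not p.z_B < p.x_B:
        violations.append("z_B < x_B violated")
    if not p.x_B < p.y_B:
        violations.append("x_B < y_B violated")
    return (not violations, violations)


def compute_regressors(t: Trial) -> RegressorRow:
    """Compute Reward, Guilt and the inequity contrasts for one trial.

    ``inequity_abs`` is the absolute-difference contrast; ``inequity_disadv``
    and ``inequity_adv`` split it into the Fehr-Schmidt disadvantageous and
    advantageous components (cooperate-minus-defect differences, negated so
    that positive values mean cooperation reduces that inequity type).
    """
    p = t.payoffs
    reward = float(p.x_B - p.y_B)
    guilt = t.tau * (p.x_A - p.y_A)
    inequity_abs = -(abs(p.x_A - p.x_B) - abs(p.y_A - p.y_B))
    inequity_disadv = -(max(p.x_A - p.x_B, 0) - max(p.y_A - p.y_B, 0))
    inequity_adv = -(max(p.x_B - p.x_A, 0) - max(p.y_B - p.y_A, 0))
    return RegressorRow(
        reward=reward,
        guilt=guilt,
        inequity_abs=float(inequity_abs),
        inequity_disadv=float(inequity_disadv),
        inequity_adv=float(inequity_adv),
    )


def _pairwise_correlations(mat: np.ndarray) -> dict[tuple[str, str], float]:
    corr: dict[tuple[str, str], float] = {}
    for i in range(3):
        for j in range(i + 1, 3):
            xi, xj = mat[:, i], mat[:, j]
            if np.std(xi) == 0.0 or np.std(xj) == 0.0:
                r = float("nan")
            else:
                r = float(np.corrcoef(xi, xj)[0, 1])
            corr[(_REGRESSOR_TRIPLE[i], _REGRESSOR_TRIPLE[j])] = r
    return corr


def design_diagnostics(
    trials: list[Trial],
    max_abs_corr: float = 0.30,
    max_guilt_inequity_corr: float = 0.05,
) -> DesignDiagnostics:
    """Pairwise Pearson correlations of (reward, guilt, inequity_abs).

    Fewer than 3 trials or a zero-variance column yields flagged NaN entries
    rather than an exception.
    """
    if len(trials) < 3:
        corr = {
            (_REGRESSOR_TRIPLE[i], _REGRESSOR_TRIPLE[j]): float("nan")
            for i in range(3)
            for j in range(i + 1, 3)
        }
        return DesignDiagnostics(
            correlations=corr, flags=["insufficient trials"], bounds_ok=False
        )
    mat = np.array(
        [
            [r.reward, r.guilt, r.inequity_abs]
            for r in (compute_regressors(t) for t in trials)
        ]
    )
    corr = _pairwise_correlations(mat)
    flags: list[str] = []
    bounds_ok = True
    for (a, b), r in corr.items():
        if not math.isfinite(r):
            flags.append(f"correlation ({a}, {b}) undefined (zero variance)")
            bounds_ok = False
            continue
        bound = max_abs_corr
        if {a, b} == {"guilt", "inequity_abs"}:
            bound = min(bound, max_guilt_inequity_corr)
        if abs(r) >= bound:
            flags.append(f"|r({a}, {b})| = {abs(r):.3f} >= {bound}")
            bounds_ok = False
    return DesignDiagnostics(correlations=corr, flags=flags, bounds_ok=bounds_ok)


def _sample_payoffs(rng: np.random.Generator, low: int, high: int) -> Payoffs:
    """Draw one integer payoff table satisfying both ordering chains."""
    # y_A < z_A < x_A and z_B < x_B < y_B: sample three distinct values per
    # player and assign by rank.
    a = np.sort(rng.choice(np.arange(low, high + 1), size=3, replace=False))
    b = np.sort(rng.choice(np.arange(low, high + 1), size=3, replace=False))
    return Payoffs(
        x_A=int(a[2]), y_A=int(a[0]), z_A=int(a[1]),
        x_B=int(b[1]), y_B=int(b[2]), z_B=int(b[0]),
    )


def generate_design(config: DesignConfig | None = None, seed: int = 0) -> TrialDesign:
    """Rejection-sample a trial design meeting the correlation bounds.

    Candidate designs pair a seeded permutation of the tau schedule with
    independently drawn valid payoff tables; a candidate is accepted when
    every pairwise regressor |r| is under ``max_abs_corr`` and the
    guilt-inequity pair under ``max_guilt_inequity_corr``.  Deterministic
    for a fixed (config, seed).  Designs too small for correlations are
    returned with flagged diagnostics.
    """
    cfg = config or DesignConfig()
    rng = np.random.default_rng(seed)
    taus = build_tau_schedule(cfg.tau_schedule, seed=None)
    n = len(taus)
    if cfg.payoff_high - cfg.payoff_low < 2:
        raise ValueError(
            "payoff range must span at least 3 integers to satisfy the orderings"
        )

    for _ in range(cfg.max_attempts):
        order = rng.permutation(n)
        trials = [
            Trial(
                trial_id=i,
                payoffs=_sample_payoffs(rng, cfg.payoff_low, cfg.payoff_high),
                tau=taus[order[i]],
            )
            for i in range(n)
        ]
        diag = design_diagnostics(trials, cfg.max_abs_corr, cfg.max_guilt_inequity_corr)
        if n < 3:
            # degenerate request: correlations undefined, return flagged
            return TrialDesign(trials=trials, diagnostics=diag)
        if diag.bounds_ok:
            return TrialDesign(trials=trials, diagnostics=diag)
    raise RuntimeError(
        f"no design met the correlation bounds (max |r| < {cfg.max_abs_corr}, "
        f"|r(guilt, inequity)| < {cfg.max_guilt_inequity_corr}) "
        f"within {cfg.max_attempts} attempts"
    )


def design_to_csv(design: TrialDesign, path) -> None:
    """Write trials.csv (trial_id, payoffs, tau to 4 decimals)."""
    df = design.to_frame()[
        ["trial_id", "x_A", "x_B", "y_A", "y_B", "z_A", "z_B", "tau"]
    ]
    df.to_csv(path, index=False)


def design_from_frame(df: pd.DataFrame) -> TrialDesign:
    """Rebuild a TrialDesign from a trials table (as written by design_to_csv)."""
    trials = [
        Trial(
            trial_id=int(row.trial_id),
            payoffs=Payoffs(
                x_A=int(row.x_A), x_B=int(row.x_B),
                y_A=int(row.y_A), y_B=int(row.y_B),
                z_A=int(row.z_A), z_B=int(row.z_B),
            ),
            tau=float(row.tau),
        )
        for row in df.itertuples()
    ]
    return TrialDesign(trials=trials, diagnostics=design_diagnostics(trials))
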