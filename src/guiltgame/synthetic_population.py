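"""Synthetic cohorts shaped like the two-country guilt-aversion study.

Generates participants with observable covariates (gender, age, education,
income, Big Five scores) and latent structural preferences (guilt
sensitivity ``gamma``, inequity sensitivity ``alpha``), then simulates
their 45-trial cooperate/defect records from the combined
guilt-plus-inequity choice model.  The generating equations build in the
study's qualitative structure:

* men carry a higher mean guilt sensitivity than women;
* women score higher on neuroticism and agreeableness;
* one country-specific Big Five trait modulates guilt sensitivity among
  men only — conscientiousness in the "UK-like" profile, neuroticism in
  the "KR-like" profile;
* gender, income and education are mutually correlated through a Gaussian
  copula.

The "observed" participant table and the latent truth table are kept
separate so estimation code can never touch the generating parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from guiltgame.task_design import TrialDesign, generate_design, design_to_csv

__all__ = [
    "CountryConfig",
    "PopulationConfig",
    "StudyBundle",
    "sample_participants",
    "simulate_choices",
    "generate_study",
]

BIG5 = ("neuroticism", "extraversion", "openness", "agreeableness", "conscientiousness")


@dataclass
class CountryConfig:
    """One cohort's size, gender mix and trait-guilt link.

    ``guilt_trait`` names the Big Five trait whose (mean-centered) score
    raises guilt sensitivity among men in this country;
    ``trait_gamma_slope`` is that effect per trait point.
    """

    name: str = "KR-like"
    n: int = 294
    frac_women: float = 0.595
    guilt_trait: str = "neuroticism"
    trait_gamma_slope: float = 0.15


@dataclass
class PopulationConfig:
    """Generating distributions for covariates and latent preferences.

    Guilt sensitivity: ``gamma ~ Normal(mean_by_gender, sd)`` left-censored
    at 0, plus the country's men-only trait slope.  Big Five scores are
    normals truncated to the 1-5 scale with gender shifts for neuroticism
    and agreeableness.  Gender, income and education share a Gaussian
    copula with the configured latent correlations.
    """

    countries: list[CountryConfig] = field(
        default_factory=lambda: [
            CountryConfig("KR-like", 294, 0.595, "neuroticism", 0.15),
            CountryConfig("UK-like", 347, 0.548, "conscientiousness", 0.15),
        ]
    )
    gamma_mean_women: float = 0.3
    gamma_mean_men: float = 0.5
    gamma_sd: float = 0.3
    alpha_mean: float = 0.15
    alpha_sd: float = 0.1
    big5_mean: float = 3.0
    big5_sd: float = 0.8
    neuroticism_shift_women: float = 0.4
    agreeableness_shift_women: float = 0.3
    gender_income_corr: float = 0.25
    income_education_corr: float = 0.30
    temperature_mean: float = 1.0
    temperature_sd: float = 0.0
    intercept_mean: float = 0.0
    intercept_sd: float = 0.0
    age_mean: float = 40.0
    age_sd: float = 12.0
    n_education_levels: int = 6
    n_income_bands: int = 10


def _truncated_normal(
    rng: np.random.Generator, mean, sd: float, low: float, high: float, size: int
) -> np.ndarray:
    """Draw from Normal(mean, sd) truncated to [low, high] by resampling."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), (size,)).copy()
    if sd == 0:
        return np.clip(mean, low, high)
    out = rng.normal(mean, sd)
    bad = (out < low) | (out > high)
    # bounded retries, then clip the stragglers
    for _ in range(100):
        if not bad.any():
            break
        out[bad] = rng.normal(mean[bad], sd)
        bad = (out < low) | (out > high)
    return np.clip(out, low, high)


def _sample_country(
    cfg: PopulationConfig, country: CountryConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    n = country.n
    if n <= 0:
        raise ValueError(f"cohort size must be positive, got {n}")
    if country.guilt_trait not in BIG5:
        raise ValueError(f"unknown guilt_trait {country.guilt_trait!r}")

    # Gaussian copula over (gender latent, income latent, education latent).
    r_gi, r_ie = cfg.gender_income_corr, cfg.income_education_corr
    cov = np.array([[1.0, r_gi, 0.0], [r_gi, 1.0, r_ie], [0.0, r_ie, 1.0]])
    z = rng.multivariate_normal(np.zeros(3), cov, size=n, method="cholesky")
    # men = 1 for the top (1 - frac_women) quantile of the gender latent
    cut = np.quantile(z[:, 0], country.frac_women)
    gender = (z[:, 0] > cut).astype(int)
    from scipy.stats import norm

    income = np.ceil(norm.cdf(z[:, 1]) * cfg.n_income_bands).astype(int)
    income = np.clip(income, 1, cfg.n_income_bands)
    education = np.ceil(norm.cdf(z[:, 2]) * cfg.n_education_levels).astype(int)
    education = np.clip(education, 1, cfg.n_education_levels)

    age = np.clip(np.round(rng.normal(cfg.age_mean, cfg.age_sd, size=n)), 18, 79)

    big5 = {}
    for trait in BIG5:
        mean = np.full(n, cfg.big5_mean)
        if trait == "neuroticism":
            mean = mean + cfg.neuroticism_shift_women * (gender == 0)
        elif trait == "agreeableness":
            mean = mean + cfg.agreeableness_shift_women * (gender == 0)
        big5[trait] = _truncated_normal(rng, mean, cfg.big5_sd, 1.0, 5.0, n)

    gamma_mean = np.where(gender == 1, cfg.gamma_mean_men, cfg.gamma_mean_women)
    trait_c = big5[country.guilt_trait] - cfg.big5_mean
    gamma_mean = gamma_mean + country.trait_gamma_slope * gender * trait_c
    gamma = np.maximum(rng.normal(gamma_mean, cfg.gamma_sd), 0.0)
    alpha = np.maximum(rng.normal(cfg.alpha_mean, cfg.alpha_sd, size=n), 0.0)
    temperature = np.maximum(
        rng.normal(cfg.temperature_mean, cfg.temperature_sd, size=n), 1e-6
    )
    intercept = rng.normal(cfg.intercept_mean, cfg.intercept_sd, size=n)

    pids = [f"{country.name}-{i:04d}" for i in range(n)]
    participants = pd.DataFrame(
        {
            "pid": pids,
            "country": country.name,
            "gender": gender,
            "age": age.astype(int),
            "education": education,
            "income": income,
            **{t: np.round(big5[t], 3) for t in BIG5},
        }
    )
    truth = pd.DataFrame(
        {
            "pid": pids,
            "country": country.name,
            "gamma": gamma,
            "alpha": alpha,
            "temperature": temperature,
            "intercept": intercept,
        }
    )
    return participants, truth


def sample_participants(
    cfg: PopulationConfig | None = None, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw all cohorts; returns (participants, truth) tables.

    Deterministic given the seed.  The participants table holds only
    observables; the truth table holds the latent AgentParams fields used
    for simulation and parameter-recovery checks.
    """
    cfg = cfg or PopulationConfig()
    rng = np.random.default_rng(seed)
    parts, truths = [], []
    for country in cfg.countries:
        p, t = _sample_country(cfg, country, rng)
        parts.append(p)
        truths.append(t)
    return (
        pd.concat(parts, ignore_index=True),
        pd.concat(truths, ignore_index=True),
    )


def simulate_choices(
    truth: pd.DataFrame, design: TrialDesign, seed: int = 0
) -> pd.DataFrame:
    """Simulate every participant's cooperate/defect record on the design.

    Each choice is an independent Bernoulli draw with success probability
    given by the combined-model stochastic choice rule, vectorized through
    the log-odds identity ``temperature * (Reward + gamma*Guilt +
    alpha*Inequity) + intercept``.

    Returns a long table (pid, trial_id, choice) with choice 1 = Cooperate.
    """
    required = {"pid", "gamma", "alpha", "temperature", "intercept"}
    missing_cols = required - set(truth.columns)
    if missing_cols:
        raise ValueError(f"truth table missing columns: {sorted(missing_cols)}")
    if truth["pid"].isna().any():
        bad = truth.index[truth["pid"].isna()].tolist()
        raise ValueError(f"truth table has missing pid at rows {bad}")

    rng = np.random.default_rng(seed)
    frame = design.to_frame()
    reward = frame["reward"].to_numpy()
    guilt = frame["guilt"].to_numpy()
    inequity = frame["inequity_abs"].to_numpy()
    trial_ids = frame["trial_id"].to_numpy()

    gamma = truth["gamma"].to_numpy()[:, None]
    alpha = truth["alpha"].to_numpy()[:, None]
    temp = truth["temperature"].to_numpy()[:, None]
    icpt = truth["intercept"].to_numpy()[:, None]

    eta = temp * (reward[None, :] + gamma * guilt[None, :] + alpha * inequity[None, :])
    eta = eta + icpt
    prob = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
    choice = (rng.random(prob.shape) < prob).astype(int)

    n_subj, n_trials = prob.shape
    return pd.DataFrame(
        {
            "pid": np.repeat(truth["pid"].to_numpy(), n_trials),
            "trial_id": np.tile(trial_ids, n_subj),
            "choice": choice.ravel(),
        }
    )


@dataclass
class StudyBundle:
    """In-memory handle to a generated study plus its on-disk files."""

    design: TrialDesign
    participants: pd.DataFrame
    truth: pd.DataFrame
    choices: pd.DataFrame
    manifest: dict
    paths: dict[str, Path] = field(default_factory=dict)


def generate_study(
    cfg: PopulationConfig | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
    design: TrialDesign | None = None,
) -> StudyBundle:
    """Design + cohorts + simulated choices, optionally written to disk.

    Stage seeds are derived from the master seed as ``seed * 1000 + k``
    (k = 0 design, 1 participants, 2 choices) so stages can be reproduced
    in isolation.  Files: trials.csv, participants.csv, truth.csv,
    choices.csv, manifest.json.
    """
    cfg = cfg or PopulationConfig()
    if design is None:
        design = generate_design(seed=seed * 1000)
    participants, truth = sample_participants(cfg, seed=seed * 1000 + 1)
    choices = simulate_choices(truth, design, seed=seed * 1000 + 2)

    manifest = {
        "seed": seed,
        "package": "guiltgame",
        "n_trials": len(design),
        "config": {
            **{
                k: v
                for k, v in asdict(cfg).items()
                if k != "countries"
            },
            "countries": [asdict(c) for c in cfg.countries],
        },
    }
    bundle = StudyBundle(
        design=design,
        participants=participants,
        truth=truth,
        choices=choices,
        manifest=manifest,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "trials": out / "trials.csv",
            "participants": out / "participants.csv",
            "truth": out / "truth.csv",
            "choices": out / "choices.csv",
            "manifest": out / "manifest.json",
        }
        try:
            design_to_csv(design, paths["trials"])
            participants.to_csv(paths["participants"], index=False)
            truth.to_csv(paths["truth"], index=False)
            choices.to_csv(paths["choices"], index=False)
            paths["manifest"].write_text(json.dumps(manifest, indent=2))
        except OSError as exc:
            raise OSError(f"failed writing study bundle under {out}: {exc}") from exc
        bundle.paths = paths
    return bundle
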