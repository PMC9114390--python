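"""End-to-end orchestration: design -> simulate -> subject fits -> model
selection -> group inference -> report.

Runs the whole desk-scale study in the analysis order of the original
design: per-participant BIC model selection first, then the cooperation-
level mixed logit, then the two Lasso specifications on beta(Guilt) with
the OLS cross-check, always stratified by country.  Every reported number
is recomputable from the CSV/JSON artifacts the run writes.

Seed policy: the master seed ``s`` derives stage seeds as ``s*1000 + k``
(k = 0 design, 1 participants, 2 choices, 3 cross-validation folds), so a
stage can be replayed in isolation and two runs with the same config and
seed produce byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from guiltgame.task_design import DesignConfig, TrialDesign, generate_design
from guiltgame.synthetic_population import PopulationConfig, StudyBundle, generate_study
from guiltgame.subject_estimation import BatchFitResult, batch_fit
from guiltgame.group_inference import (
    build_group_table,
    cv_lasso,
    fit_mixed_logit,
    fit_ols,
)

__all__ = ["StudyConfig", "StudyReport", "run_full_study", "sample_size_floor"]

DISPLAY_SCALE = 1e3  # coefficient tables are displayed multiplied by 10^3


def sample_size_floor(n_explanatory: int, events_per_variable: int = 10) -> int:
    """Minimum sample size under the events-per-variable rule.

    With the conventional 10 events per explanatory variable, a 17-variable
    regression needs at least 170 observations.
    """
    for name, v in (("n_explanatory", n_explanatory), ("events_per_variable", events_per_variable)):
        if not isinstance(v, (int, np.integer)) or isinstance(v, bool) or v <= 0:
            raise ValueError(f"{name} must be a positive integer, got {v!r}")
    return int(n_explanatory) * int(events_per_variable)


@dataclass
class StudyConfig:
    """Everything a full study run needs."""

    population: PopulationConfig = field(default_factory=PopulationConfig)
    design: DesignConfig = field(default_factory=DesignConfig)
    quadrature_nodes: int = 8
    cv_folds: int = 10
    lambda_rule: str = "min"
    seed: int = 0


@dataclass
class StudyReport:
    """Report tables plus handles to the artifact bundle."""

    report: dict
    bundle: StudyBundle
    batch: BatchFitResult

    def to_json(self) -> str:
        return json.dumps(self.report, indent=2, sort_keys=True, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _scaled(coefs: dict[str, float]) -> dict[str, float]:
    return {k: round(v * DISPLAY_SCALE, 3) for k, v in coefs.items()}


def _country_analysis(
    country: str,
    cfg: StudyConfig,
    bundle: StudyBundle,
    batch: BatchFitResult,
) -> dict:
    participants = bundle.participants[bundle.participants["country"] == country]
    pids = set(participants["pid"])
    n = len(participants)
    out: dict = {"country": country, "n_participants": n}
    out["prop_abs_selected"] = batch.prop_abs_by_country.get(country, float("nan"))

    min_n = max(cfg.cv_folds + 1, 20)
    if n < min_n:
        out["flag"] = f"insufficient n ({n} < {min_n}); group models skipped"
        return out

    # mixed logit on the long data joined to regressors and gender
    frame = bundle.design.to_frame()[["trial_id", "reward", "guilt", "inequity_abs"]]
    long = bundle.choices[bundle.choices["pid"].isin(pids)].merge(frame, on="trial_id")
    long = long.merge(participants[["pid", "gender"]], on="pid")
    mixed = fit_mixed_logit(long, nodes=cfg.quadrature_nodes)
    out["mixed_logit"] = {
        "coefficients_x1e3": _scaled(mixed.coefficients),
        "standard_errors_x1e3": _scaled(mixed.standard_errors),
        "pvalues": {k: float(v) for k, v in mixed.pvalues.items()},
        "sigma": mixed.sigma,
        "loglik": mixed.loglik,
        "mcfadden_r2": mixed.mcfadden_r2,
        "nodes": mixed.nodes,
        "scale": "x1e3",
    }

    fits = batch.fits[batch.fits["pid"].isin(pids)]
    lasso_tables = {}
    for spec, with_inter in (("1", False), ("2", True)):
        table = build_group_table(fits, participants, with_interactions=with_inter)
        lasso = cv_lasso(
            table,
            folds=cfg.cv_folds,
            seed=cfg.seed * 1000 + 3,
            lambda_rule=cfg.lambda_rule,
        )
        entry = {
            "coefficients_x1e3": _scaled(lasso.coefficients),
            "chosen_lambda": lasso.chosen_lambda,
            "rule": lasso.rule,
            "dropped": lasso.dropped,
            "scale": "x1e3",
            "fig2_bar_data_x1e3": _scaled(
                {k: v for k, v in lasso.coefficients.items() if k != "intercept"}
            ),
        }
        try:
            ols = fit_ols(table)
            entry["ols_cross_check"] = {
                "coefficients_x1e3": _scaled(ols.coefficients),
                "pvalues": {k: float(v) for k, v in ols.pvalues.items()},
                "scale": "x1e3",
            }
        except ValueError as exc:
            entry["ols_cross_check"] = {"error": str(exc)}
        lasso_tables[spec] = entry
    out["lasso"] = lasso_tables
    return out


def run_full_study(
    cfg: StudyConfig | None = None,
    out_dir: str | Path | None = None,
    design: TrialDesign | None = None,
) -> StudyReport:
    """Run every stage of the study and assemble the report.

    Stages halt loudly: any failure raises with the stage name prepended.
    Countries too small for group models are flagged, not fatal.
    """
    cfg = cfg or StudyConfig()
    try:
        bundle = generate_study(
            cfg.population, seed=cfg.seed, out_dir=out_dir, design=design
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc

    try:
        batch = batch_fit(bundle.choices, bundle.design, bundle.participants)
    except Exception as exc:
        raise RuntimeError(f"stage 'fit-subjects' failed: {exc}") from exc

    report: dict = {
        "manifest": bundle.manifest,
        "design_diagnostics": {
            "correlations": {
                f"{a}~{b}": v for (a, b), v in bundle.design.diagnostics.correlations.items()
            },
            "max_abs_correlation": bundle.design.diagnostics.max_abs_correlation,
            "flags": bundle.design.diagnostics.flags,
        },
        "countries": {},
    }
    for country_cfg in cfg.population.countries:
        try:
            report["countries"][country_cfg.name] = _country_analysis(
                country_cfg.name, cfg, bundle, batch
            )
        except Exception as exc:
            raise RuntimeError(
                f"stage 'group-fit' failed for {country_cfg.name}: {exc}"
            ) from exc

    result = StudyReport(report=report, bundle=bundle, batch=batch)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        batch.fits.to_csv(out / "subject_fits.csv", index=False)
        batch.selection.to_csv(out / "model_selection.csv", index=False)
        (out / "report.json").write_text(result.to_json())
        (out / "report.md").write_text(_report_markdown(report))
    return result


def _report_markdown(report: dict) -> str:
    lines = ["# Study report", ""]
    diag = report["design_diagnostics"]
    lines.append(
        f"Design: max |r| among regressors = {diag['max_abs_correlation']:.3f}"
    )
    for country, c in report["countries"].items():
        lines += ["", f"## {country} (n = {c['n_participants']})", ""]
        if "flag" in c:
            lines.append(f"**{c['flag']}**")
            continue
        lines.append(
            f"Absolute-difference inequity model selected for "
            f"{100 * c['prop_abs_selected']:.1f}% of participants."
        )
        m = c["mixed_logit"]
        lines += [
            "",
            "### Mixed-effects logistic regression (coefficients x 10^3)",
            "",
            "| term | coef | SE | p |",
            "|---|---|---|---|",
        ]
        for term, v in m["coefficients_x1e3"].items():
            lines.append(
                f"| {term} | {v} | {m['standard_errors_x1e3'][term]} | "
                f"{m['pvalues'][term]:.2g} |"
            )
        lines.append(f"\nMcFadden's R^2 = {m['mcfadden_r2']:.3f}")
        for spec in ("1", "2"):
            lasso = c["lasso"][spec]
            lines += [
                "",
                f"### Lasso specification ({spec}) (coefficients x 10^3)",
                "",
                "| term | coef |",
                "|---|---|",
            ]
            for term, v in lasso["coefficients_x1e3"].items():
                lines.append(f"| {term} | {v} |")
    return "\n".join(lines) + "\n"


def load_config(path: str | Path) -> StudyConfig:
    """Build a StudyConfig from a YAML or JSON mapping.

    Top-level keys mirror the dataclass fields; ``population`` and
    ``design`` are nested mappings, ``population.countries`` a list of
    mappings.
    """
    import yaml
    from guiltgame.synthetic_population import CountryConfig

    raw = yaml.safe_load(Path(path).read_text()) or {}
    pop_raw = dict(raw.pop("population", {}))
    countries = pop_raw.pop("countries", None)
    pop = PopulationConfig(**pop_raw)
    if countries is not None:
        pop.countries = [CountryConfig(**c) for c in countries]
    design = DesignConfig(**raw.pop("design", {}))
    return StudyConfig(population=pop, design=design, **raw)


def _replace_seed(cfg: StudyConfig, seed: int | None) -> StudyConfig:
    if seed is None:
        return cfg
    return dataclasses.replace(cfg, seed=seed)
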