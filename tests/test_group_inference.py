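"""Group-level models: random-intercept logit (with an independent
integration oracle), the Lasso machinery (closed forms and KKT), and OLS."""

import numpy as np
import pandas as pd
import pytest

from guiltgame.group_inference import (
    GroupTable,
    build_group_table,
    cv_lasso,
    fit_mixed_logit,
    fit_ols,
    mcfadden_r2,
    mixed_logit_loglik,
)
from guiltgame.subject_estimation import batch_fit

from conftest import simulate_subject


def toy_mixed_data(seed=0, n_subj=3, n_trials=4, sigma=0.8):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subj):
        u = rng.normal(0, sigma)
        for t in range(n_trials):
            x = rng.normal()
            eta = -0.3 + 0.9 * x + u
            y = int(rng.random() < 1 / (1 + np.exp(-eta)))
            rows.append({"pid": f"s{i}", "x": x, "choice": y})
    return pd.DataFrame(rows)


def bruteforce_marginal_loglik(beta, sigma, X, y, groups, n_grid=8001, span=10.0):
    """Trapezoid integration over the random intercept, subject by subject."""
    u = np.linspace(-span * sigma, span * sigma, n_grid)
    phi = np.exp(-0.5 * (u / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))
    total = 0.0
    for g in np.unique(groups):
        m = groups == g
        eta = X[m] @ beta
        ll_u = np.zeros_like(u)
        for e, yi in zip(eta, y[m]):
            p = 1 / (1 + np.exp(-(e + u)))
            ll_u += yi * np.log(p) + (1 - yi) * np.log1p(-p)
        total += np.log(np.trapezoid(np.exp(ll_u) * phi, u))
    return total


class TestMixedLogit:
    def test_marginal_loglik_matches_bruteforce_integration(self):
        df = toy_mixed_data()
        X = np.column_stack([np.ones(len(df)), df["x"]])
        y = df["choice"].to_numpy(float)
        groups = pd.factorize(df["pid"])[0]
        beta = np.array([-0.3, 0.9])
        for sigma in (0.3, 0.8, 1.5):
            oracle = bruteforce_marginal_loglik(beta, sigma, X, y, groups)
            ours = mixed_logit_loglik(beta, sigma, X, y, groups, nodes=24)
            assert ours == pytest.approx(oracle, abs=1e-4)

    def test_estimates_stable_beyond_16_nodes(self, design45):
        bundle_data = _long_data(design45, n=30, sigma=0.6, seed=2)
        fits = [fit_mixed_logit(bundle_data, nodes=k) for k in (16, 32)]
        for term in fits[0].coefficients:
            assert fits[0].coefficients[term] == pytest.approx(
                fits[1].coefficients[term], abs=1e-3
            )

    def test_zero_between_subject_variance_limit(self, design45):
        import statsmodels.api as sm

        data = _long_data(design45, n=25, sigma=0.0, seed=3)
        fit = fit_mixed_logit(data)
        assert fit.sigma < 0.05
        X = np.column_stack(
            [np.ones(len(data))]
            + [
                data[c].to_numpy()
                for c in ("reward", "guilt", "inequity_abs", "gender", "gender_x_guilt")
            ]
        )
        plain = sm.Logit(data["choice"], X).fit(disp=0)
        for est, ref in zip(fit.coefficients.values(), plain.params):
            assert est == pytest.approx(ref, abs=1e-3)

    def test_input_validation(self, design45):
        data = _long_data(design45, n=4, sigma=0.2, seed=1)
        with pytest.raises(ValueError, match="nodes"):
            fit_mixed_logit(data, nodes=2)
        one = data[data["pid"] == data["pid"].iloc[0]]
        with pytest.raises(ValueError, match="participants"):
            fit_mixed_logit(one)


def _long_data(design, n, sigma, seed):
    rng = np.random.default_rng(seed)
    frame = design.to_frame()[["trial_id", "reward", "guilt", "inequity_abs"]]
    parts = []
    for i in range(n):
        gender = i % 2
        icpt = rng.normal(0, sigma) if sigma > 0 else 0.0
        ch = simulate_subject(
            design, gamma=0.4, alpha=0.15, seed=int(rng.integers(2**31)),
            intercept=icpt, pid=f"s{i:03d}",
        )
        ch["gender"] = gender
        parts.append(ch)
    long = pd.concat(parts).merge(frame, on="trial_id")
    long["gender_x_guilt"] = long["gender"] * long["guilt"]
    return long


class TestMcFadden:
    def test_identities_and_hand_value(self):
        assert mcfadden_r2(-120.0, -120.0) == 0.0
        assert mcfadden_r2(-100.0, -120.0) == pytest.approx(0.16667, abs=1e-4)
        assert mcfadden_r2(-1e-9, -120.0) == pytest.approx(1.0, abs=1e-9)

    def test_sign_errors_rejected(self):
        with pytest.raises(ValueError):
            mcfadden_r2(1.0, -10.0)
        with pytest.raises(ValueError):
            mcfadden_r2(-1.0, 0.0)


class TestGroupTable:
    def test_predictor_counts(self, small_bundle):
        batch = batch_fit(
            small_bundle.choices, small_bundle.design, small_bundle.participants
        )
        t1 = build_group_table(batch.fits, small_bundle.participants)
        t2 = build_group_table(
            batch.fits, small_bundle.participants, with_interactions=True
        )
        assert len(t1.predictors) == 9
        assert len(t2.predictors) == 17
        assert t1.target == "beta_guilt"

    def test_all_women_cohort_flags_constant_columns(self, small_bundle):
        women = small_bundle.participants[small_bundle.participants.gender == 0]
        batch = batch_fit(
            small_bundle.choices[small_bundle.choices.pid.isin(women.pid)],
            small_bundle.design,
            women,
        )
        table = build_group_table(batch.fits, women, with_interactions=True)
        assert "gender" in table.constant_columns
        assert all(
            c in table.constant_columns
            for c in table.predictors
            if c.startswith("gender_x_")
        )

    def test_unmatched_pid_rejected(self, small_bundle, design45):
        ch = simulate_subject(design45, 0.5, 0.1, 0, pid="ghost")
        batch = batch_fit(ch, design45)
        with pytest.raises(ValueError, match="ghost"):
            build_group_table(batch.fits, small_bundle.participants)


def _toy_table(seed=0, n=60, n_pred=4):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, n_pred))
    beta = np.r_[[1.5, -1.0], np.zeros(n_pred - 2)]
    y = X @ beta + rng.normal(0, 0.5, n)
    cols = [f"p{i}" for i in range(n_pred)]
    frame = pd.DataFrame(X, columns=cols)
    frame["target"] = y
    return GroupTable(frame=frame, target="target", predictors=cols)


class TestLasso:
    def test_soft_threshold_closed_form(self):
        """Single unit-variance predictor: beta = S(ols, lambda)."""
        n = 50
        rng = np.random.default_rng(1)
        x = rng.normal(size=n)
        x = (x - x.mean()) / x.std()  # population-sd standardized
        y = 2.0 * x  # OLS coefficient exactly 2.0, centered target
        frame = pd.DataFrame({"p0": x, "target": y})
        table = GroupTable(frame=frame, target="target", predictors=["p0"])
        res = cv_lasso(table, folds=5, seed=0, lambdas=np.array([0.5]))
        assert res.coefficients_std["p0"] == pytest.approx(1.5, abs=1e-6)

    def test_zero_penalty_recovers_ols(self):
        table = _toy_table()
        res = cv_lasso(table, folds=5, seed=0, lambdas=np.array([1e-10]))
        ols = fit_ols(table)
        for p in table.predictors:
            assert res.coefficients[p] == pytest.approx(ols.coefficients[p], abs=1e-6)

    def test_kkt_conditions_at_solution(self):
        table = _toy_table(seed=2, n=80, n_pred=6)
        res = cv_lasso(table, folds=10, seed=3)
        df = table.frame
        X = df[table.predictors].to_numpy(float)
        Xs = (X - X.mean(0)) / X.std(0)
        y = df["target"].to_numpy(float)
        yc = y - y.mean()
        b = np.array([res.coefficients_std[p] for p in table.predictors])
        resid = yc - Xs @ b
        resid = resid - resid.mean()  # unpenalized intercept absorbs the mean
        g = Xs.T @ resid / len(yc)
        lam = res.chosen_lambda
        for gj, bj in zip(g, b):
            if bj == 0.0:
                assert abs(gj) <= lam + 1e-6
            else:
                assert gj == pytest.approx(lam * np.sign(bj), abs=1e-6)

    def test_large_penalty_zeroes_everything(self):
        table = _toy_table()
        res = cv_lasso(table, folds=5, seed=0, lambdas=np.array([1e6]))
        assert all(v == 0.0 for k, v in res.coefficients_std.items())

    def test_cv_determinism(self):
        table = _toy_table(seed=5)
        r1 = cv_lasso(table, folds=10, seed=42)
        r2 = cv_lasso(table, folds=10, seed=42)
        assert r1.chosen_lambda == r2.chosen_lambda
        assert r1.coefficients == r2.coefficients

    def test_one_se_rule_picks_larger_lambda(self):
        table = _toy_table(seed=6, n=100)
        rmin = cv_lasso(table, folds=10, seed=1, lambda_rule="min")
        r1se = cv_lasso(table, folds=10, seed=1, lambda_rule="1se")
        assert r1se.chosen_lambda >= rmin.chosen_lambda

    def test_degenerate_inputs_rejected(self):
        table = _toy_table(n=8)
        with pytest.raises(ValueError, match="fold"):
            cv_lasso(table, folds=10, seed=0)
        const = _toy_table()
        const.frame["target"] = 1.0
        with pytest.raises(ValueError, match="variance"):
            cv_lasso(const, folds=5, seed=0)


class TestOLS:
    def test_noiseless_target_recovered_exactly(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 3))
        y = 2.0 + X @ np.array([1.0, -2.0, 0.5])
        frame = pd.DataFrame(X, columns=["a", "b", "c"])
        frame["target"] = y
        table = GroupTable(frame=frame, target="target", predictors=["a", "b", "c"])
        res = fit_ols(table)
        assert res.coefficients["intercept"] == pytest.approx(2.0, abs=1e-10)
        assert res.coefficients["a"] == pytest.approx(1.0, abs=1e-10)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_orthonormal_design_inner_products(self):
        n = 64
        # two exactly orthonormal columns (scaled so X'X = I)
        x1 = np.tile([1.0, -1.0], n // 2) / np.sqrt(n)
        x2 = np.tile([1.0, 1.0, -1.0, -1.0], n // 4) / np.sqrt(n)
        y = 3.0 * x1 - 1.0 * x2
        frame = pd.DataFrame({"a": x1, "b": x2, "target": y})
        table = GroupTable(frame=frame, target="target", predictors=["a", "b"])
        res = fit_ols(table)
        assert res.coefficients["a"] == pytest.approx(float(x1 @ y), abs=1e-10)
        assert res.coefficients["b"] == pytest.approx(float(x2 @ y), abs=1e-10)

    def test_duplicate_column_names_both(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        frame = pd.DataFrame({"a": x, "a_copy": x, "target": rng.normal(size=30)})
        table = GroupTable(frame=frame, target="target", predictors=["a", "a_copy"])
        with pytest.raises(ValueError) as exc:
            fit_ols(table)
        assert "a" in str(exc.value) and "a_copy" in str(exc.value)
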