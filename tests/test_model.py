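import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from metanue.errors import (
    CollinearityError,
    ContractError,
    UnderdeterminedError,
    ValidationError,
)
from metanue.model import (
    MetaRegression,
    ModelSpec,
    build_design,
    design_matrix,
    fit,
    information_criteria,
    predict,
    pseudo_r2,
    qe_test,
    wald_moderator_test,
)
from metanue.simulate import SyntheticConfig, generate_observations

from conftest import make_obs_frame, ml_loglik_dense, reml_loglik_dense


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------


class TestDesignMatrix:
    def test_treatment_coding_one_indicator(self):
        spec = ModelSpec(moderators=["RFR"])
        df = make_obs_frame([{"practice": "RFR"}, {"practice": "ZT"}])
        X = design_matrix(df, spec)
        np.testing.assert_array_equal(X.to_numpy(), [[1.0, 1.0], [1.0, 0.0]])

    def test_interaction_is_elementwise_product(self):
        spec = ModelSpec(moderators=["RFR", "soc"], interactions=[("RFR", "soc")])
        df = make_obs_frame([{"practice": "RFR", "soc": 2.0}, {"practice": "ZT", "soc": 5.0}])
        X = design_matrix(df, spec)
        np.testing.assert_allclose(
            X["RFR:soc"].to_numpy(), X["RFR"].to_numpy() * X["soc"].to_numpy()
        )

    def test_crop_expands_to_non_reference_dummies(self):
        spec = ModelSpec(moderators=["crop"], reference_crop="wheat")
        df = make_obs_frame([{"crop": c} for c in ("wheat", "maize", "rice")])
        X = design_matrix(df, spec)
        assert list(X.columns) == ["intercept", "crop_maize", "crop_rice"]
        np.testing.assert_array_equal(X["crop_maize"], [0.0, 1.0, 0.0])

    def test_crop_interaction_expansion(self):
        spec = ModelSpec(moderators=["RFP", "crop"], interactions=[("RFP", "crop")])
        df = make_obs_frame([{"practice": "RFP", "crop": "maize"}])
        X = design_matrix(df, spec)
        assert "RFP:crop_maize" in X.columns
        assert X.loc[0, "RFP:crop_maize"] == 1.0

    def test_duplicate_moderator_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ModelSpec(moderators=["soc", "soc"])

    def test_exact_collinearity_raises_with_names(self):
        spec = ModelSpec(moderators=["soc", "mat"])
        df = make_obs_frame([{"soc": s, "mat": s} for s in (1.0, 2.0, 3.0)])
        df["yi"], df["vi"] = [1.0, 2.0, 3.0], 1.0
        with pytest.raises(CollinearityError):
            build_design(df, spec)

    def test_metric_mismatch_rejected(self):
        spec = ModelSpec(moderators=["RFR"], response_metric="MD")
        df = make_obs_frame([{}, {}])
        df["yi"], df["vi"], df["method"] = [1.0, 2.0], 1.0, "ROM"
        with pytest.raises(ValidationError, match="ROM"):
            build_design(df, spec)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


class TestFit:
    def test_fixed_effect_gls_closed_form(self):
        model = fit(
            y=np.array([10.0, 20.0]),
            v=np.array([1.0, 4.0]),
            X=np.ones((2, 1)),
            study_ids=np.array(["a", "b"]),
            constraints={"tau2": 0.0},
        )
        assert model.beta_[0] == pytest.approx(12.0, abs=1e-10)
        assert math.sqrt(model.cov_beta_[0, 0]) == pytest.approx(0.894427, abs=1e-6)

    def test_one_effect_per_study_reduces_to_mean_and_flags_rho(self):
        y = np.array([3.0, 9.0, 6.0, 12.0])
        model = fit(
            y=y, v=np.full(4, 2.0), X=np.ones((4, 1)), study_ids=np.arange(4)
        )
        assert model.beta_[0] == pytest.approx(y.mean(), abs=1e-8)
        assert not model.rho_identifiable_
        assert model.rho_ == 0.0

    def test_fixed_effect_limit_matches_wls_exactly(self):
        rng = np.random.default_rng(3)
        k = 12
        X = np.column_stack([np.ones(k), rng.normal(size=k)])
        y = rng.normal(size=k)
        v = rng.uniform(0.5, 2.0, size=k)
        model = fit(y, v, X, study_ids=np.repeat(np.arange(4), 3), constraints={"tau2": 0.0})
        w = 1 / v
        beta_wls = np.linalg.solve((X * w[:, None]).T @ X, (X * w[:, None]).T @ y)
        np.testing.assert_allclose(model.beta_, beta_wls, atol=1e-12)

    def test_underdetermined_raises(self):
        with pytest.raises(UnderdeterminedError):
            fit(np.array([1.0]), np.array([1.0]), np.ones((1, 1)), np.array(["a"]))

    def test_row_permutation_leaves_estimates_unchanged(self, fitted_synthetic):
        f = fitted_synthetic
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(f["y"]))
        model_p = MetaRegression().fit(
            f["X"].iloc[perm], f["y"][perm], v=f["v"][perm], study_ids=f["ids"][perm]
        )
        m = f["model"]
        np.testing.assert_allclose(model_p.beta_, m.beta_, atol=1e-10)
        assert model_p.tau2_ == pytest.approx(m.tau2_, abs=1e-8)
        assert model_p.rho_ == pytest.approx(m.rho_, abs=1e-8)
        assert model_p.loglik_reml_ == pytest.approx(m.loglik_reml_, abs=1e-10)

    def test_six_effects_grid_oracle(self):
        """k = 6 in 3 studies: optimizer matches the dense-likelihood grid."""
        rng = np.random.default_rng(42)
        ids = np.repeat(["s1", "s2", "s3"], 2)
        X = np.ones((6, 1))
        v = rng.uniform(0.5, 1.5, 6)
        y = 5.0 + rng.normal(scale=1.5, size=6)
        model = fit(y, v, X, ids)
        tau2_grid = np.linspace(0.0, 10.0, 201)
        rho_grid = np.linspace(0.0, 0.98, 99)
        best = (-np.inf, None, None)
        for t in tau2_grid:
            for r in rho_grid:
                ll = reml_loglik_dense(t, r, y, v, X, ids)
                if ll > best[0]:
                    best = (ll, t, r)
        assert model.loglik_reml_ >= best[0] - 1e-6
        assert model.tau2_ == pytest.approx(best[1], abs=0.06)

    def test_collinearity_screen_warns(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=20)
        X = pd.DataFrame(
            {"intercept": 1.0, "a": a, "b": a + rng.normal(scale=0.05, size=20)}
        )
        y = rng.normal(size=20)
        with pytest.warns(UserWarning, match="highly correlated"):
            MetaRegression(tau2=0.0).fit(X, y, v=np.ones(20), study_ids=np.arange(20))

    def test_serialization_round_trip(self, fitted_synthetic, tmp_path):
        m = fitted_synthetic["model"]
        path = tmp_path / "model.json"
        m.save(path)
        m2 = MetaRegression.load(path)
        np.testing.assert_allclose(m2.beta_, m.beta_)
        np.testing.assert_allclose(m2.cov_beta_, m.cov_beta_)
        assert m2.tau2_ == m.tau2_ and m2.rho_ == m.rho_
        assert m2.column_names_ == m.column_names_


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
def test_reml_fit_cross_checked_against_metafor(tmp_path):
    """Independent oracle: metafor's rma.mv with ~1|study/obs random effects.

    That nested structure is the compound-symmetry model with
    tau2 = sigma2_study + sigma2_obs and rho = sigma2_study / tau2; metafor's
    REML log-likelihood additionally carries its REMLf constant +0.5 ln|X'X|.
    """
    config = SyntheticConfig(n_studies=12, obs_per_study=4, missing_sd_fraction=0.0)
    table, truth = generate_observations(config, seed=7)
    from metanue.effects import compute_effect_sizes
    from metanue.ingest import scale_covariates

    eff = compute_effect_sizes(table, "MD")
    merged = table.join(eff[["yi", "vi"]])
    merged, _ = scale_covariates(
        merged, variables=list(truth.scaling.center), params=truth.scaling
    )
    y, v, X, ids = build_design(merged, config.spec)
    model = MetaRegression().fit(X, y, v=v, study_ids=ids)

    df = X.copy()
    df.columns = [c.replace(":", "_x_") for c in df.columns]
    df["yi"], df["vi"], df["study"], df["obs"] = y, v, ids, range(len(y))
    csv = tmp_path / "mf.csv"
    df.to_csv(csv, index=False)
    mods = [c for c in df.columns if c not in ("intercept", "yi", "vi", "study", "obs")]
    script = f"""
    suppressMessages(library(metafor))
    d <- read.csv("{csv}")
    X <- as.matrix(d[, c({', '.join(repr(c) for c in mods)})])
    f <- rma.mv(yi, vi, mods = X, random = ~1 | study/obs, data = d, method = "REML",
                control = list(optimizer = "optim", optmethod = "Nelder-Mead"))
    cat(coef(f), f$sigma2, logLik(f), sep = "\\n")
    """
    out = subprocess.run(
        ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
    )
    assert out.returncode == 0, out.stderr
    vals = [float(x) for x in out.stdout.split()]
    beta_r, s1, s2, ll_r = vals[:-3], vals[-3], vals[-2], vals[-1]
    np.testing.assert_allclose(model.beta_, beta_r, atol=2e-3)
    assert model.tau2_ == pytest.approx(s1 + s2, abs=0.02)
    assert model.rho_ == pytest.approx(s1 / (s1 + s2), abs=0.01)
    remlf = 0.5 * np.linalg.slogdet(X.to_numpy().T @ X.to_numpy())[1]
    assert model.loglik_reml_ + remlf == pytest.approx(ll_r, abs=1e-3)


# ---------------------------------------------------------------------------
# tests on fitted models: Wald, QE, AIC, pseudo-R2, prediction
# ---------------------------------------------------------------------------


def _stub_model(beta, cov, ll_ml=-100.0, ll_reml=-100.0, k=10, rho_ident=True):
    m = MetaRegression()
    m.beta_ = np.asarray(beta, float)
    m.cov_beta_ = np.asarray(cov, float)
    m.tau2_, m.rho_ = 1.0, 0.5
    m.rho_identifiable_ = rho_ident
    m.loglik_ml_, m.loglik_reml_ = ll_ml, ll_reml
    m.k_, m.p_ = k, len(m.beta_)
    m.qe_, m.qe_df_, m.qe_p_ = 0.0, k - m.p_, 1.0
    m.column_names_ = [f"b{i}" for i in range(m.p_)]
    return m


class TestWald:
    def test_single_term_hand_value(self):
        m = _stub_model([2.0], [[1.0]])
        chi2, df, p = wald_moderator_test(m, [0])
        assert chi2 == pytest.approx(4.0)
        assert df == 1
        assert p == pytest.approx(0.04550, abs=1e-5)

    def test_zero_coefficients_give_p_one(self):
        m = _stub_model([0.0, 0.0], np.eye(2))
        chi2, df, p = wald_moderator_test(m, [0, 1])
        assert chi2 == 0.0 and p == 1.0

    def test_two_independent_unit_terms_add(self):
        m = _stub_model([1.0, 1.0], np.eye(2))
        chi2, df, _ = wald_moderator_test(m, ["b0", "b1"])
        assert chi2 == pytest.approx(2.0)
        assert df == 2

    def test_unknown_term_rejected(self):
        m = _stub_model([1.0], [[1.0]])
        with pytest.raises(ContractError):
            wald_moderator_test(m, ["nope"])


class TestQE:
    def test_exact_fit_gives_zero(self):
        X = np.column_stack([np.ones(4), np.arange(4.0)])
        y = X @ np.array([2.0, 3.0])
        qe, df, p = qe_test(y, np.ones(4), X)
        assert qe == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_hand_computed_intercept_case(self):
        qe, df, p = qe_test(np.array([10.0, 20.0]), np.ones(2), np.ones((2, 1)))
        assert qe == pytest.approx(50.0)
        assert df == 1

    def test_matches_explicit_residual_loop(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            k = int(rng.integers(5, 15))
            X = np.column_stack([np.ones(k), rng.normal(size=k)])
            y = rng.normal(size=k)
            v = rng.uniform(0.2, 3.0, size=k)
            qe, df, _ = qe_test(y, v, X)
            w = 1 / v
            beta = np.linalg.solve((X * w[:, None]).T @ X, (X * w[:, None]).T @ y)
            qe_loop = sum(w[i] * (y[i] - X[i] @ beta) ** 2 for i in range(k))
            assert qe == pytest.approx(qe_loop, rel=1e-10)
            assert df == k - 2


class TestInformationCriteria:
    def test_formula_with_both_components(self):
        m = _stub_model([0.0] * 3, np.eye(3), ll_ml=-100.0, ll_reml=-100.0)
        aic_ml, aic_reml = information_criteria(m)
        assert aic_ml == pytest.approx(210.0)  # q = 3 + 2

    def test_rho_unidentifiable_drops_a_parameter(self):
        m = _stub_model([0.0] * 3, np.eye(3), ll_ml=-100.0, rho_ident=False)
        aic_ml, _ = information_criteria(m)
        assert aic_ml == pytest.approx(208.0)

    def test_extra_column_never_lowers_ml_deviance(self, fitted_synthetic):
        f = fitted_synthetic
        m_full = MetaRegression(method="ML").fit(
            f["X"], f["y"], v=f["v"], study_ids=f["ids"]
        )
        X_red = f["X"].drop(columns=["soc"])
        m_red = MetaRegression(method="ML").fit(
            X_red, f["y"], v=f["v"], study_ids=f["ids"]
        )
        assert -2 * m_full.loglik_ml_ <= -2 * m_red.loglik_ml_ + 1e-6

    def test_aic_ml_matches_independent_likelihood(self, fitted_synthetic):
        f = fitted_synthetic
        m = f["model"]
        ll = ml_loglik_dense(
            m.tau2_, m.rho_, f["y"], f["v"], f["X"].to_numpy(), f["ids"], m.beta_
        )
        # ML value reported by the REML fit is the full likelihood at the
        # REML variance components and GLS beta
        assert m.loglik_ml_ == pytest.approx(ll, abs=1e-8)
        q = m.p_ + 2
        assert m.aic_ml_ == pytest.approx(-2 * ll + 2 * q, abs=1e-6)


class TestPseudoR2:
    def test_half_for_hand_likelihoods(self):
        m = _stub_model([0.0], [[1.0]], ll_ml=-50.0)
        null = _stub_model([0.0], [[1.0]], ll_ml=-100.0)
        assert pseudo_r2(m, null) == pytest.approx(0.5)

    def test_null_against_itself_is_zero(self):
        null = _stub_model([0.0], [[1.0]], ll_ml=-80.0)
        assert pseudo_r2(null, null) == 0.0

    def test_strong_moderators_beat_reduced_model(self, fitted_synthetic):
        f = fitted_synthetic
        full = MetaRegression(method="ML").fit(f["X"], f["y"], v=f["v"], study_ids=f["ids"])
        reduced = MetaRegression(method="ML").fit(
            f["X"][["intercept", "soc"]], f["y"], v=f["v"], study_ids=f["ids"]
        )
        null = MetaRegression(method="ML").fit(
            f["X"][["intercept"]], f["y"], v=f["v"], study_ids=f["ids"]
        )
        assert pseudo_r2(full, null) > pseudo_r2(reduced, null)


class TestPredict:
    def test_intercept_only_prediction(self):
        model = fit(
            np.array([10.0, 20.0]), np.array([1.0, 4.0]), np.ones((2, 1)),
            np.array(["a", "b"]), constraints={"tau2": 0.0},
        )
        res = predict(model, [1.0])
        assert res.mean == pytest.approx(12.0, abs=1e-9)
        assert res.se == pytest.approx(0.894427, abs=1e-6)
        assert res.ci_low == pytest.approx(10.247, abs=1e-3)
        assert res.ci_high == pytest.approx(13.753, abs=1e-3)

    def test_ci_width_is_2x196_se(self, fitted_synthetic):
        m = fitted_synthetic["model"]
        X = fitted_synthetic["X"]
        mean, se, lo, hi = m.predict_interval(X.iloc[:5])
        np.testing.assert_allclose(hi - lo, 2 * 1.96 * se, atol=1e-12)
        assert np.all(lo <= mean) and np.all(mean <= hi)

    def test_dimension_mismatch_rejected(self, fitted_synthetic):
        with pytest.raises(ContractError):
            predict(fitted_synthetic["model"], [1.0, 2.0])


def test_reml_and_ml_agree_with_grid_oracle_on_small_instances():
    """Optimizer vs dense restricted-likelihood grid over 8 random instances."""
    rng = np.random.default_rng(2024)
    for trial in range(8):
        n_studies = int(rng.integers(3, 6))
        per = int(rng.integers(2, 4))
        k = n_studies * per
        ids = np.repeat(np.arange(n_studies), per)
        X = np.column_stack([np.ones(k), rng.normal(size=k)])
        v = rng.uniform(0.3, 2.0, size=k)
        tau2_t, rho_t = 1.5, 0.4
        shared = rng.normal(size=n_studies)[ids] * math.sqrt(rho_t * tau2_t)
        u = shared + rng.normal(size=k) * math.sqrt((1 - rho_t) * tau2_t)
        y = X @ np.array([2.0, 1.0]) + u + rng.normal(size=k) * np.sqrt(v)
        model = fit(y, v, X, ids)
        # coarse-to-fine pure grid search (independent oracle)
        t_hi = max(4 * np.var(y), 1.0)
        best = (-np.inf, 0.0, 0.0)
        for t in np.linspace(0, t_hi, 60):
            for r in np.linspace(0, 0.98, 50):
                ll = reml_loglik_dense(t, r, y, v, X, ids)
                if ll > best[0]:
                    best = (ll, t, r)
        t_step, r_step = t_hi / 59, 0.02
        t0, r0 = best[1], best[2]
        for t in np.linspace(max(t0 - t_step, 0), t0 + t_step, 40):
            for r in np.linspace(max(r0 - r_step, 0), min(r0 + r_step, 0.98), 20):
                ll = reml_loglik_dense(t, r, y, v, X, ids)
                if ll > best[0]:
                    best = (ll, t, r)
        assert model.loglik_reml_ >= best[0] - 1e-6, f"trial {trial}"
        assert model.tau2_ == pytest.approx(best[1], abs=2 * t_step)
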