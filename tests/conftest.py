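import numpy as np
import pandas as pd
import pytest

from metanue.effects import compute_effect_sizes
from metanue.ingest import scale_covariates
from metanue.model import MetaRegression, ModelSpec, build_design
from metanue.simulate import SyntheticConfig, generate_observations

#: The worked toy observation used across the effect-size checks.
TOY_OBS = {
    "obs_id": "toy",
    "mean_t": 40.0,
    "mean_c": 32.0,
    "sd_t": 4.0,
    "sd_c": 3.0,
    "n_t": 3,
    "n_c": 3,
}


@pytest.fixture
def toy_obs():
    return dict(TOY_OBS)


def make_obs_frame(rows):
    """Observation table with complete site covariates for given overrides."""
    base = {
        "study_id": "S1",
        "practice": "RFR",
        "crop": "wheat",
        "mean_t": 40.0,
        "mean_c": 32.0,
        "sd_t": 4.0,
        "sd_c": 3.0,
        "n_t": 3,
        "n_c": 3,
        "n_rate": 150.0,
        "mat": 12.0,
        "map": 800.0,
        "soc": 15.0,
        "clay": 25.0,
        "ph": 6.5,
    }
    records = []
    for i, overrides in enumerate(rows):
        rec = dict(base)
        rec["obs_id"] = f"o{i}"
        rec.update(overrides)
        records.append(rec)
    return pd.DataFrame(records)


@pytest.fixture
def obs_csv(tmp_path):
    """A 3-row well-formed observation CSV on disk."""
    df = make_obs_frame(
        [
            {"study_id": "S1", "practice": "RFR"},
            {"study_id": "S1", "practice": "EE", "sd_t": np.nan},
            {"study_id": "S2", "practice": "RES", "mean_t": 30.0},
        ]
    )
    path = tmp_path / "obs.csv"
    df.to_csv(path, index=False)
    return path


@pytest.fixture(scope="session")
def fitted_synthetic():
    """One seeded synthetic corpus fitted end to end (shared, read-only)."""
    config = SyntheticConfig(missing_sd_fraction=0.0)
    table, truth = generate_observations(config, seed=11)
    eff = compute_effect_sizes(table, "MD")
    merged = table.join(eff[["yi", "vi"]])
    merged, _ = scale_covariates(
        merged, variables=list(truth.scaling.center), params=truth.scaling
    )
    y, v, X, ids = build_design(merged, config.spec)
    model = MetaRegression().fit(X, y, v=v, study_ids=ids)
    return {
        "config": config,
        "table": table,
        "truth": truth,
        "merged": merged,
        "y": y,
        "v": v,
        "X": X,
        "ids": ids,
        "model": model,
    }


def reml_loglik_dense(tau2, rho, y, v, X, study_ids):
    """Independent restricted log-likelihood via an explicit dense marginal
    covariance (the brute-force oracle; shares no code with the estimator)."""
    y = np.asarray(y, float)
    v = np.asarray(v, float)
    X = np.asarray(X, float)
    ids = np.asarray(study_ids)
    k, p = X.shape
    M = np.diag(v + tau2).astype(float)
    for i in range(k):
        for j in range(k):
            if i != j and ids[i] == ids[j]:
                M[i, j] = rho * tau2
    sign, logdet_m = np.linalg.slogdet(M)
    if sign <= 0:
        return -np.inf
    Minv = np.linalg.inv(M)
    A = X.T @ Minv @ X
    beta = np.linalg.solve(A, X.T @ Minv @ y)
    r = y - X @ beta
    sign_a, logdet_a = np.linalg.slogdet(A)
    return -0.5 * (
        (k - p) * np.log(2 * np.pi) + logdet_m + logdet_a + float(r @ Minv @ r)
    )


def ml_loglik_dense(tau2, rho, y, v, X, study_ids, beta):
    """Independent full log-likelihood at given parameters."""
    y = np.asarray(y, float)
    v = np.asarray(v, float)
    X = np.asarray(X, float)
    ids = np.asarray(study_ids)
    k = len(y)
    M = np.diag(v + tau2).astype(float)
    for i in range(k):
        for j in range(k):
            if i != j and ids[i] == ids[j]:
                M[i, j] = rho * tau2
    _, logdet_m = np.linalg.slogdet(M)
    r = y - X @ np.asarray(beta, float)
    return -0.5 * (k * np.log(2 * np.pi) + logdet_m + float(r @ np.linalg.inv(M) @ r))
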