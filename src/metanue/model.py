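"""Multivariate mixed-effects meta-regression with compound-symmetric
within-study random effects.

The observed effect of observation *i* in study *s* is modelled as

    y_i = x_i' beta + u_i + e_i,      e_i ~ N(0, v_i),

where v_i is the known sampling variance from the effect-size stage and the
true-effect deviations u_i are correlated within a study: Var(u_i) = tau2
and Corr(u_i, u_j) = rho for i, j in the same study (compound symmetry).
The marginal covariance is therefore M = D + diag(v) with D block-diagonal
by study, tau2 on the diagonal and rho*tau2 off it.

Variance components (tau2, rho) are estimated by restricted maximum
likelihood (optionally full ML); beta is the generalized least-squares
solution at the optimum with cov(beta) = (X' M^-1 X)^-1.  Moderator blocks
are tested with Wald chi-square contrasts, residual heterogeneity with the
Q_E statistic (weighted residual sum of squares at the fixed-effects fit),
and models are compared via AIC and McFadden's pseudo-R^2 on full-likelihood
values.  Fitting is fully deterministic: the optimizer starts from a fixed
5x5 grid over (tau2, rho) and polishes the best points with bounded
quasi-Newton steps.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._base import BaseEstimator
from .errors import (
    CollinearityError,
    ContractError,
    ConvergenceError,
    NoDataError,
    UnderdeterminedError,
    ValidationError,
)
from .ingest import CROPS, PRACTICES, ScalingParams

logger = logging.getLogger(__name__)

_LOG2PI = math.log(2.0 * math.pi)

#: Continuous moderator vocabulary (scaled site covariates + quadratic N rate).
CONTINUOUS_TERMS = ("n_rate", "mat", "map", "soc", "clay", "ph", "n_sq")


# ---------------------------------------------------------------------------
# Model specification and design construction
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class ModelSpec:
    """Declarative description of the meta-regression design.

    moderators are listed in the order their columns appear in the design
    matrix: practice indicators (treatment-coded against the conventional
    control, which carries all zeros), the ``"crop"`` factor (treatment-coded
    against ``reference_crop``), and scaled continuous covariates.
    Interactions are pairs of term names; ``"crop"`` in a pair expands to
    one product column per non-reference crop.
    """

    response_metric: str = "MD"
    moderators: Sequence[str] = dataclasses.field(
        default_factory=lambda: list(PRACTICES) + ["crop"] + list(CONTINUOUS_TERMS)
    )
    interactions: Sequence[tuple[str, str]] = dataclasses.field(default_factory=list)
    reference_crop: str = "wheat"
    scaling: ScalingParams | None = None

    def __post_init__(self) -> None:
        if self.response_metric not in ("ROM", "MD", "SMD"):
            raise ValueError("response_metric must be ROM, MD or SMD")
        if self.reference_crop not in CROPS:
            raise ValueError(f"reference_crop must be one of {CROPS}")
        seen = set()
        for term in self.moderators:
            if term in seen:
                raise ValueError(f"duplicate moderator term {term!r}")
            seen.add(term)
        base = set(self.moderators)
        for a, b in self.interactions:
            for t in (a, b):
                root = t.split("_")[0] if t.startswith("crop_") else t
                if t not in base and not (t.startswith("crop_") and "crop" in base):
                    raise ValueError(
                        f"interaction parent {t!r} is not among the moderators"
                    )

    @property
    def crop_dummies(self) -> list[str]:
        return [f"crop_{c}" for c in CROPS if c != self.reference_crop]

    def column_names(self) -> list[str]:
        cols = ["intercept"]
        for term in self.moderators:
            if term == "crop":
                cols.extend(self.crop_dummies)
            else:
                cols.append(term)
        for a, b in self.interactions:
            cols.extend(_interaction_names(a, b, self))
        return cols

    def to_dict(self) -> dict:
        return {
            "response_metric": self.response_metric,
            "moderators": list(self.moderators),
            "interactions": [list(p) for p in self.interactions],
            "reference_crop": self.reference_crop,
            "scaling": self.scaling.to_dict() if self.scaling else None,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelSpec":
        return cls(
            response_metric=d.get("response_metric", "MD"),
            moderators=list(d.get("moderators", [])),
            interactions=[tuple(p) for p in d.get("interactions", [])],
            reference_crop=d.get("reference_crop", "wheat"),
            scaling=ScalingParams.from_dict(d["scaling"]) if d.get("scaling") else None,
        )


def _interaction_names(a: str, b: str, spec: ModelSpec) -> list[str]:
    lefts = spec.crop_dummies if a == "crop" else [a]
    rights = spec.crop_dummies if b == "crop" else [b]
    return [f"{l}:{r}" for l in lefts for r in rights]


def _base_columns(df: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Expand a moderator table into named 0/1 indicators and covariates."""
    out = pd.DataFrame(index=df.index)
    out["intercept"] = 1.0
    for p in PRACTICES:
        if p in df.columns:
            out[p] = df[p].astype(float)
        elif "practice" in df.columns:
            out[p] = (df["practice"] == p).astype(float)
        else:
            out[p] = 0.0
    for name in spec.crop_dummies:
        crop = name.removeprefix("crop_")
        if name in df.columns:
            out[name] = df[name].astype(float)
        elif "crop" in df.columns:
            out[name] = (df["crop"] == crop).astype(float)
        else:
            out[name] = 0.0
    for term in CONTINUOUS_TERMS:
        if term in df.columns:
            out[term] = df[term].astype(float)
    return out


def design_matrix(df: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Build the fixed-effects design matrix for a moderator table.

    `df` may carry a categorical ``practice``/``crop`` column (observation
    tables) or explicit 0/1 indicator columns (scenario rows).  Continuous
    covariates must already be on the fitted (scaled) scale.  Column order is
    deterministic and given by ``spec.column_names()``.
    """
    base = _base_columns(df, spec)
    cols = {}
    for name in spec.column_names():
        if ":" in name:
            a, b = name.split(":", 1)
            for t in (a, b):
                if t not in base.columns:
                    raise ValidationError(f"interaction parent column {t!r} not found")
            cols[name] = base[a].to_numpy() * base[b].to_numpy()
        else:
            if name not in base.columns:
                raise ValidationError(f"moderator column {name!r} not found in table")
            cols[name] = base[name].to_numpy(dtype=float)
    return pd.DataFrame(cols, index=df.index)


def _check_rank(X: pd.DataFrame) -> None:
    A = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        # identify dependent columns via rank-revealing QR pivots
        _, r, piv = _qr_pivot(A)
        keep = piv[:rank]
        dropped = [X.columns[i] for i in sorted(set(range(A.shape[1])) - set(keep))]
        raise CollinearityError(
            f"design matrix is rank deficient (rank {rank} < {A.shape[1]}); "
            f"linearly dependent column(s): {dropped}"
        )


def _qr_pivot(A: np.ndarray):
    from scipy.linalg import qr

    q, r, piv = qr(A, mode="economic", pivoting=True)
    return q, r, piv


def collinearity_screen(X: pd.DataFrame, threshold: float = 0.8) -> list[tuple[str, str, float]]:
    """Pairwise correlation screen over non-constant design columns.

    Returns the offending pairs with |r| above the threshold; the caller
    decides whether to warn or refuse.
    """
    cols = [c for c in X.columns if X[c].std(ddof=0) > 0]
    flagged = []
    if len(cols) < 2:
        return flagged
    corr = X[cols].corr().to_numpy()
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            r = corr[i, j]
            if np.isfinite(r) and abs(r) > threshold:
                flagged.append((cols[i], cols[j], float(r)))
    return flagged


def build_design(
    table: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame, np.ndarray]:
    """Assemble (y, v, X, study_ids) from an effects+moderators table.

    The table must hold ``yi`` and ``vi`` for ``spec.response_metric`` (merge
    the effect-size frame onto the observation table first), a ``study_id``
    column, and the moderator columns on the fitted scale.
    """
    for col in ("yi", "vi", "study_id"):
        if col not in table.columns:
            raise ValidationError(f"column {col!r} required to build the design")
    if "method" in table.columns:
        methods = set(table["method"].unique())
        if methods != {spec.response_metric}:
            raise ValidationError(
                f"effect sizes are {sorted(methods)} but spec expects "
                f"{spec.response_metric}"
            )
    y = table["yi"].to_numpy(dtype=float)
    v = table["vi"].to_numpy(dtype=float)
    if not (v > 0).all():
        raise ValidationError("all sampling variances must be strictly positive")
    X = design_matrix(table, spec)
    _check_rank(X)
    study_ids = table["study_id"].to_numpy()
    return y, v, X, study_ids


# ---------------------------------------------------------------------------
# Likelihood machinery
# ---------------------------------------------------------------------------


class _Blocks:
    """Rows grouped by study, in canonical order, batched by block size.

    The canonical sort (study, then the data values) makes every fit
    bit-identical under row permutation of the inputs.
    """

    def __init__(self, v: np.ndarray, study_ids: np.ndarray, y: np.ndarray, X: np.ndarray):
        codes0 = pd.factorize(np.asarray(study_ids), sort=True)[0]
        keys = [X[:, j] for j in range(X.shape[1] - 1, -1, -1)] + [v, y, codes0]
        order = np.lexsort(keys)
        self.order = order
        codes = codes0[order]
        self.sizes = np.bincount(codes)
        self.max_size = int(self.sizes.max())
        self.v = v[order]
        self.y = y[order]
        self.X = X[order]
        # row indices of each study's block in sorted space, batched by size
        self.by_size: dict[int, np.ndarray] = {}
        start = 0
        blocks: dict[int, list[np.ndarray]] = {}
        for m in self.sizes:
            blocks.setdefault(int(m), []).append(np.arange(start, start + m))
            start += m
        for m, idx_list in sorted(blocks.items()):
            self.by_size[m] = np.stack(idx_list)  # (g, m)
        self.k = len(self.v)


def _gls_at(tau2, rho, blocks: _Blocks, want_grad: bool = False):
    """GLS and (restricted) likelihood at fixed variance components.

    Returns (beta, cov_beta, ll_ml, ll_reml) and, when requested, the
    analytic gradients of both likelihoods with respect to (tau2, rho).
    The marginal covariance factors into per-study compound-symmetry blocks,
    so traces and quadratic forms reduce to per-block sums and row sums.
    """
    X, y, v = blocks.X, blocks.y, blocks.v
    k, p = X.shape
    Z = np.column_stack([X, y])
    MinvZ = np.empty_like(Z)
    logdet = 0.0
    tr_minv = 0.0
    sum_minv = 0.0
    for m, idx in blocks.by_size.items():
        g = idx.shape[0]
        vb = v[idx]  # (g, m)
        if m == 1:
            d = tau2 + vb[:, 0]
            MinvZ[idx[:, 0]] = Z[idx[:, 0]] / d[:, None]
            logdet += float(np.sum(np.log(d)))
            if want_grad:
                tr_minv += float(np.sum(1.0 / d))
                sum_minv += float(np.sum(1.0 / d))
            continue
        V = np.full((g, m, m), rho * tau2)
        diag = np.arange(m)
        V[:, diag, diag] = tau2 + vb
        L = np.linalg.cholesky(V)
        logdet += 2.0 * float(np.sum(np.log(L[:, diag, diag])))
        MinvZ[idx.reshape(-1)] = np.linalg.solve(V, Z[idx]).reshape(g * m, -1)
        if want_grad:
            Vinv = np.linalg.inv(V)
            tr_minv += float(Vinv[:, diag, diag].sum())
            sum_minv += float(Vinv.sum())
    MinvX, Minvy = MinvZ[:, :p], MinvZ[:, p]
    A = X.T @ MinvX
    b = X.T @ Minvy
    try:
        cov_beta = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by rank check
        raise CollinearityError("X' M^-1 X is singular") from exc
    beta = cov_beta @ b
    quad = float(y @ Minvy - b @ beta)
    sign, logdetA = np.linalg.slogdet(A)
    if sign <= 0:  # pragma: no cover
        raise CollinearityError("X' M^-1 X is not positive definite")
    ll_ml = -0.5 * (k * _LOG2PI + logdet + quad)
    ll_reml = -0.5 * ((k - p) * _LOG2PI + logdet + logdetA + quad)
    if not want_grad:
        return beta, cov_beta, ll_ml, ll_reml

    # residual weights w = M^-1 (y - X beta); per-block sums feed the
    # quadratic forms w' (dM/dtheta) w for the two CS directions
    w = Minvy - MinvX @ beta
    w_sq = float(w @ w)
    G_sq = MinvX.T @ MinvX  # sum_b G_b' G_b
    w_ones = 0.0
    G_ones = np.zeros((p, p))
    for m, idx in blocks.by_size.items():
        if m == 1:
            wb = w[idx[:, 0]]
            w_ones += float(wb @ wb)
            s = MinvX[idx[:, 0]]  # (g, p)
            G_ones += s.T @ s
        else:
            wb = w[idx].sum(axis=1)  # (g,)
            w_ones += float(wb @ wb)
            s = MinvX[idx].sum(axis=1)  # (g, p)
            G_ones += s.T @ s

    # dM/dtau2 = (1-rho) I + rho J per block; dM/drho = tau2 (J - I)
    grads = {}
    for name, c_eye, c_ones in (
        ("tau2", 1.0 - rho, rho),
        ("rho", -tau2, tau2),
    ):
        tr_term = c_eye * tr_minv + c_ones * sum_minv
        quad_term = c_eye * w_sq + c_ones * w_ones
        gmat = c_eye * G_sq + c_ones * G_ones
        reml_corr = float(np.trace(cov_beta @ gmat))
        grads[name] = {
            "ml": -0.5 * (tr_term - quad_term),
            "reml": -0.5 * (tr_term - reml_corr - quad_term),
        }
    return beta, cov_beta, ll_ml, ll_reml, grads


@dataclasses.dataclass(frozen=True)
class PredictionResult:
    """Fixed-effects prediction with a 1.96-based 95% confidence interval."""

    mean: float
    ci_low: float
    ci_high: float
    se: float


# ---------------------------------------------------------------------------
# The estimator
# ---------------------------------------------------------------------------


class MetaRegression(BaseEstimator):
    """Mixed-effects meta-regression estimator (REML, compound symmetry).

    Parameters
    ----------
    method : {"REML", "ML"}
        Likelihood used to estimate the variance components.
    tau2, rho : float or None
        Constrain a variance component to a fixed value instead of
        estimating it (``tau2=0`` gives the fixed-effect / weighted
        least-squares limit exactly).
    tol : float
        Convergence tolerance on the (restricted) log-likelihood.
    max_iter : int
        Iteration cap per quasi-Newton start.
    corr_threshold : float
        Pairwise |r| above which a collinearity warning is emitted before
        fitting.

    Fitted attributes (after :meth:`fit`): ``beta_``, ``cov_beta_``,
    ``tau2_``, ``rho_``, ``rho_identifiable_``, ``loglik_reml_``,
    ``loglik_ml_``, ``aic_ml_``, ``aic_reml_``, ``qe_``, ``qe_df_``,
    ``qe_p_``, ``k_``, ``p_``, ``column_names_``.
    """

    def __init__(
        self,
        method: str = "REML",
        tau2: float | None = None,
        rho: float | None = None,
        tol: float = 1e-8,
        max_iter: int = 500,
        corr_threshold: float = 0.8,
    ):
        self.method = method
        self.tau2 = tau2
        self.rho = rho
        self.tol = tol
        self.max_iter = max_iter
        self.corr_threshold = corr_threshold

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        X,
        y,
        v=None,
        study_ids=None,
    ) -> "MetaRegression":
        if self.method not in ("REML", "ML"):
            raise ValueError("method must be 'REML' or 'ML'")
        if v is None:
            raise ContractError("sampling variances v are required")
        y = np.asarray(y, dtype=float)
        v = np.asarray(v, dtype=float)
        if isinstance(X, pd.DataFrame):
            self.column_names_ = list(X.columns)
            Xa = X.to_numpy(dtype=float)
        else:
            Xa = np.asarray(X, dtype=float)
            if Xa.ndim == 1:
                Xa = Xa[:, None]
            self.column_names_ = [f"x{i}" for i in range(Xa.shape[1])]
        k, p = Xa.shape
        if not (len(y) == len(v) == k):
            raise ContractError("y, v and X must have matching lengths")
        if study_ids is None:
            study_ids = np.arange(k)
        study_ids = np.asarray(study_ids)
        if len(study_ids) != k:
            raise ContractError("study_ids length must match y")
        if not (v > 0).all():
            raise ValidationError("all sampling variances must be strictly positive")
        if k <= p:
            raise UnderdeterminedError(f"k = {k} effects cannot identify p = {p} coefficients")

        if isinstance(X, pd.DataFrame):
            flagged = collinearity_screen(X, self.corr_threshold)
            for a, b, r in flagged:
                warnings.warn(
                    f"moderators {a!r} and {b!r} are highly correlated (r = {r:.2f})",
                    stacklevel=2,
                )

        blocks = _Blocks(v, study_ids, y, Xa)
        multi_obs = blocks.max_size > 1
        self.rho_identifiable_ = bool(multi_obs and self.tau2 != 0)

        tau2_hat, rho_hat = self._estimate_components(y, v, blocks, multi_obs)

        # snap a vanishing tau2 to the exact fixed-effect limit
        if self.tau2 is None and tau2_hat < 1e-10 * float(np.mean(v)):
            tau2_hat = 0.0
        if tau2_hat == 0.0:
            self.rho_identifiable_ = False

        beta, cov_beta, ll_ml, ll_reml = _gls_at(tau2_hat, rho_hat, blocks)
        self.beta_ = beta
        self.cov_beta_ = cov_beta
        self.tau2_ = float(tau2_hat)
        self.rho_ = float(rho_hat) if self.rho_identifiable_ or self.rho is not None else 0.0
        self.loglik_ml_ = float(ll_ml)
        self.loglik_reml_ = float(ll_reml)
        self.k_ = k
        self.p_ = p
        self.qe_, self.qe_df_, self.qe_p_ = qe_test(y, v, Xa)
        self.aic_ml_, self.aic_reml_ = information_criteria(self)
        self._y, self._v, self._X, self._study_ids = y, v, Xa, study_ids
        return self

    def _objective(self, blocks):
        which = "reml" if self.method == "REML" else "ml"

        def nll(tau2: float, rho: float) -> float:
            try:
                _, _, ll_ml, ll_reml = _gls_at(tau2, rho, blocks)
            except np.linalg.LinAlgError:
                return np.inf
            return -(ll_reml if which == "reml" else ll_ml)

        def nll_grad(tau2: float, rho: float):
            try:
                _, _, ll_ml, ll_reml, grads = _gls_at(tau2, rho, blocks, want_grad=True)
            except np.linalg.LinAlgError:
                return np.inf, (0.0, 0.0)
            value = -(ll_reml if which == "reml" else ll_ml)
            return value, (-grads["tau2"][which], -grads["rho"][which])

        return nll, nll_grad

    def _estimate_components(self, y, v, blocks, multi_obs):
        fixed_tau2, fixed_rho = self.tau2, self.rho
        if fixed_tau2 is not None and fixed_tau2 == 0.0:
            return 0.0, float(fixed_rho) if fixed_rho is not None else 0.0
        if not multi_obs:
            fixed_rho = 0.0 if fixed_rho is None else fixed_rho

        nll, nll_grad = self._objective(blocks)
        scale = max(float(np.var(y)), float(np.mean(v)), 1e-8)
        lo_t, hi_t = math.log(1e-12 * scale), math.log(1e6 * scale)
        lo_r, hi_r = math.log(1e-6 / (1 - 1e-6)), math.log(0.999 / 0.001)

        def unpack(z, free_tau2, free_rho):
            i = 0
            if free_tau2:
                tau2 = math.exp(z[i]); i += 1
            else:
                tau2 = float(fixed_tau2)
            if free_rho:
                rho = 1.0 / (1.0 + math.exp(-z[i]))
            else:
                rho = float(fixed_rho) if fixed_rho is not None else 0.0
            return tau2, rho

        free_tau2 = fixed_tau2 is None
        free_rho = fixed_rho is None and multi_obs
        if not free_tau2 and not free_rho:
            return float(fixed_tau2), float(fixed_rho) if fixed_rho is not None else 0.0

        tau2_grid = np.array([1e-3, 0.1, 0.5, 1.0, 2.0]) * scale
        rho_grid = np.array([0.05, 0.25, 0.5, 0.75, 0.95])
        starts = []
        for t in tau2_grid if free_tau2 else [fixed_tau2]:
            for r in rho_grid if free_rho else [fixed_rho if fixed_rho is not None else 0.0]:
                z = []
                if free_tau2:
                    z.append(math.log(t))
                if free_rho:
                    z.append(math.log(r / (1 - r)))
                starts.append((nll(t, r), z))
        starts.sort(key=lambda s: s[0])
        finite = [s for s in starts if np.isfinite(s[0])]
        if not finite:
            raise ConvergenceError("likelihood not finite at any grid start")

        bounds = []
        if free_tau2:
            bounds.append((lo_t, hi_t))
        if free_rho:
            bounds.append((lo_r, hi_r))

        def fz(z):
            t, r = unpack(z, free_tau2, free_rho)
            value, (g_t, g_r) = nll_grad(t, r)
            # chain rule onto (log tau2, logit rho)
            grad = []
            if free_tau2:
                grad.append(g_t * t)
            if free_rho:
                grad.append(g_r * r * (1.0 - r))
            return value, np.asarray(grad)

        best = None
        for _, z0 in finite[:3]:
            res = optimize.minimize(
                fz,
                np.asarray(z0, dtype=float),
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": self.max_iter, "ftol": self.tol * 1e-4, "gtol": 1e-12},
            )
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise ConvergenceError(
                "variance-component optimization failed from every start; "
                f"grid minimum was {finite[0][0]:.4g}"
            )
        tau2_hat, rho_hat = unpack(best.x, free_tau2, free_rho)

        # the logit parametrization cannot reach rho = 0 exactly; when the
        # optimum sits on that boundary, fix rho = 0 and re-profile tau2
        if free_rho and rho_hat < 1e-5:
            if free_tau2:
                res0 = optimize.minimize(
                    lambda z: (
                        nll_grad(math.exp(z[0]), 0.0)[0],
                        np.array([nll_grad(math.exp(z[0]), 0.0)[1][0] * math.exp(z[0])]),
                    ),
                    np.array([math.log(max(tau2_hat, 1e-12 * scale))]),
                    jac=True,
                    method="L-BFGS-B",
                    bounds=[(lo_t, hi_t)],
                    options={"maxiter": self.max_iter, "ftol": self.tol * 1e-4, "gtol": 1e-12},
                )
                if res0.fun <= best.fun:
                    tau2_hat, rho_hat = math.exp(res0.x[0]), 0.0
            elif nll(tau2_hat, 0.0) <= best.fun:
                rho_hat = 0.0
        return tau2_hat, rho_hat

    # -- inference ---------------------------------------------------------

    def predict(self, X) -> np.ndarray:
        """Fixed-effects linear predictor for design rows X."""
        self._check_is_fitted("beta_")
        Xa = self._conform(X)
        return Xa @ self.beta_

    def predict_interval(self, X):
        """Predictions with standard errors and 1.96-based 95% CIs.

        Returns (mean, se, ci_low, ci_high) arrays; intervals reflect only
        the fixed-effects covariance, matching prediction of the mean effect.
        """
        self._check_is_fitted("beta_")
        Xa = self._conform(X)
        mean = Xa @ self.beta_
        se = np.sqrt(np.einsum("ij,jk,ik->i", Xa, self.cov_beta_, Xa))
        return mean, se, mean - 1.96 * se, mean + 1.96 * se

    def _conform(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.column_names_ if c not in X.columns]
            if missing:
                raise ContractError(f"design row(s) lack fitted column(s) {missing}")
            Xa = X[self.column_names_].to_numpy(dtype=float)
        else:
            Xa = np.atleast_2d(np.asarray(X, dtype=float))
        if Xa.shape[1] != len(self.beta_):
            raise ContractError(
                f"design has {Xa.shape[1]} columns, model has {len(self.beta_)}"
            )
        return Xa

    def wald_test(self, terms: Sequence[int] | Sequence[str]):
        """Wald chi-square test that a coefficient subset is jointly zero."""
        self._check_is_fitted("beta_")
        idx = self._term_indices(terms)
        b = self.beta_[idx]
        C = self.cov_beta_[np.ix_(idx, idx)]
        try:
            chi2 = float(b @ np.linalg.solve(C, b))
        except np.linalg.LinAlgError as exc:
            raise ValidationError("singular covariance for the selected terms") from exc
        df = len(idx)
        p = float(stats.chi2.sf(chi2, df))
        return chi2, df, p

    def _term_indices(self, terms) -> list[int]:
        idx = []
        for t in terms:
            if isinstance(t, str):
                if t not in self.column_names_:
                    raise ContractError(f"unknown coefficient {t!r}")
                idx.append(self.column_names_.index(t))
            else:
                i = int(t)
                if not 0 <= i < len(self.beta_):
                    raise ContractError(f"coefficient index {i} out of range")
                idx.append(i)
        return idx

    def coefficient_table(self) -> pd.DataFrame:
        """Estimates, SEs, z, p and significance stars per coefficient."""
        self._check_is_fitted("beta_")
        se = np.sqrt(np.diag(self.cov_beta_))
        z = self.beta_ / se
        p = 2.0 * stats.norm.sf(np.abs(z))
        stars = np.select(
            [p < 0.001, p < 0.01, p < 0.05], ["***", "**", "*"], default=""
        )
        return pd.DataFrame(
            {
                "term": self.column_names_,
                "estimate": self.beta_,
                "se": se,
                "z": z,
                "p": p,
                "signif": stars,
            }
        )

    # -- persistence -------------------------------------------------------

    def to_dict(self) -> dict:
        self._check_is_fitted("beta_")
        return {
            "method": self.method,
            "beta": self.beta_.tolist(),
            "cov_beta": self.cov_beta_.tolist(),
            "tau2": self.tau2_,
            "rho": self.rho_,
            "rho_identifiable": self.rho_identifiable_,
            "loglik_reml": self.loglik_reml_,
            "loglik_ml": self.loglik_ml_,
            "aic_ml": self.aic_ml_,
            "aic_reml": self.aic_reml_,
            "qe": self.qe_,
            "qe_df": self.qe_df_,
            "qe_p": self.qe_p_,
            "k": self.k_,
            "p": self.p_,
            "column_names": self.column_names_,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "MetaRegression":
        model = cls(method=d.get("method", "REML"))
        model.beta_ = np.asarray(d["beta"], dtype=float)
        model.cov_beta_ = np.asarray(d["cov_beta"], dtype=float)
        model.tau2_ = float(d["tau2"])
        model.rho_ = float(d["rho"])
        model.rho_identifiable_ = bool(d.get("rho_identifiable", True))
        model.loglik_reml_ = float(d["loglik_reml"])
        model.loglik_ml_ = float(d["loglik_ml"])
        model.aic_ml_ = float(d["aic_ml"])
        model.aic_reml_ = float(d["aic_reml"])
        model.qe_ = float(d["qe"])
        model.qe_df_ = int(d["qe_df"])
        model.qe_p_ = float(d["qe_p"])
        model.k_ = int(d["k"])
        model.p_ = int(d["p"])
        model.column_names_ = list(d["column_names"])
        return model

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "MetaRegression":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Module-level operations (thin wrappers over the estimator)
# ---------------------------------------------------------------------------


def fit(
    y,
    v,
    X,
    study_ids,
    method: str = "REML",
    constraints: Mapping[str, float] | None = None,
) -> MetaRegression:
    """Fit the compound-symmetry meta-regression; see :class:`MetaRegression`."""
    constraints = constraints or {}
    model = MetaRegression(
        method=method,
        tau2=constraints.get("tau2"),
        rho=constraints.get("rho"),
    )
    return model.fit(X, y, v=v, study_ids=study_ids)


def wald_moderator_test(model: MetaRegression, terms) -> tuple[float, int, float]:
    """Wald chi-square contrast on a moderator block (ANOVA-style test)."""
    return model.wald_test(terms)


def qe_test(y, v, X) -> tuple[float, int, float]:
    """Residual heterogeneity Q_E at the fixed-effects (tau2 = 0) fit.

    Q_E is the 1/v-weighted residual sum of squares about the weighted
    least-squares fit, chi-square with k - p degrees of freedom when the
    moderators capture all systematic variation.
    """
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    Xa = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    if Xa.ndim == 1:
        Xa = Xa[:, None]
    k, p = Xa.shape
    if k <= p:
        raise UnderdeterminedError(f"k = {k} effects cannot identify p = {p} coefficients")
    w = 1.0 / v
    A = (Xa * w[:, None]).T @ Xa
    b = (Xa * w[:, None]).T @ y
    beta_fe = np.linalg.solve(A, b)
    resid = y - Xa @ beta_fe
    qe = float(np.sum(w * resid**2))
    df = k - p
    pval = float(stats.chi2.sf(qe, df))
    return qe, df, pval


def information_criteria(model: MetaRegression) -> tuple[float, float]:
    """AIC = -2 lnL + 2q on both the ML and REML likelihood values.

    q counts the fixed effects plus the variance components (tau2 and rho;
    rho is dropped when unidentifiable).  ML-based AIC is the one comparable
    across different fixed-effects structures; the REML-based value is
    reported alongside for traceability to REML-default software output.
    """
    model._check_is_fitted("beta_")
    q = model.p_ + (2 if model.rho_identifiable_ else 1)
    aic_ml = -2.0 * model.loglik_ml_ + 2.0 * q
    aic_reml = -2.0 * model.loglik_reml_ + 2.0 * q
    return float(aic_ml), float(aic_reml)


def pseudo_r2(model: MetaRegression, null_model: MetaRegression) -> float:
    """McFadden pseudo-R^2, 1 - lnL_model / lnL_null, on ML likelihoods."""
    model._check_is_fitted("beta_")
    null_model._check_is_fitted("beta_")
    if null_model.p_ != 1:
        raise ContractError("null model must be intercept-only")
    if null_model.loglik_ml_ == 0:
        raise ZeroDivisionError("null log-likelihood is zero; ratio undefined")
    return 1.0 - model.loglik_ml_ / null_model.loglik_ml_


def predict(model: MetaRegression, x_new) -> PredictionResult:
    """Fixed-effects prediction for one moderator vector with a 95% CI."""
    x = np.asarray(x_new, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[0] != 1:
        raise ContractError("predict takes a single moderator vector; use predict_interval")
    mean, se, lo, hi = model.predict_interval(x)
    return PredictionResult(
        mean=float(mean[0]), ci_low=float(lo[0]), ci_high=float(hi[0]), se=float(se[0])
    )
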