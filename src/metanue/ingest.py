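"""Ingestion and completion of paired NUEr observation tables.

One row is one control-treatment pair: group means of nitrogen recovery
efficiency (NUEr, %), their dispersions and replicate counts, the management
practice applied, the crop, and the site covariates used as moderators
downstream (N application rate, MAT, MAP, SOC, clay, pH).

Field syntheses rarely find every study reporting dispersions and replicate
counts, so the module completes them the way meta-analysts do: a missing
group SD is rebuilt from the database-wide mean coefficient of variation,

    SD_i = CV_mean * mean_i * inflation        (inflation 1.25 by default)

and a missing replicate count defaults to 3, the modal design of small
agronomic trials. Continuous covariates are centered and scaled to unit
sample variance before model fitting; the quadratic N-rate term is formed
from the raw rate first and then scaled as a variable of its own.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._base import BaseEstimator
from .errors import (
    DegenerateScaleError,
    ImputationError,
    SchemaError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Management practice classes: nutrient (4R stewardship plus fertilizer
#: types), crop and soil management. Controls carry none of them.
PRACTICES = ("EE", "CF", "OF", "RFP", "RFR", "RFT", "RES", "CC", "ROT", "ZT", "RT")
CROPS = ("wheat", "maize", "rice")

#: Continuous site covariates eligible for unit-variance scaling.
COVARIATES = ("n_rate", "mat", "map", "soc", "clay", "ph")

REQUIRED_COLUMNS = (
    "study_id",
    "practice",
    "crop",
    "mean_t",
    "mean_c",
    "n_rate",
    "mat",
    "map",
    "soc",
    "clay",
    "ph",
)
OPTIONAL_COLUMNS = ("obs_id", "sd_t", "sd_c", "n_t", "n_c", "lat", "lon", "duration_yr")
NUMERIC_COLUMNS = (
    "mean_t",
    "mean_c",
    "sd_t",
    "sd_c",
    "n_t",
    "n_c",
    "n_rate",
    "mat",
    "map",
    "soc",
    "clay",
    "ph",
    "lat",
    "lon",
    "duration_yr",
)


@dataclasses.dataclass(frozen=True)
class ImputationParams:
    """Parameters behind SD and replicate imputation.

    cv_mean is the mean coefficient of variation of NUEr over all reported
    (sd, mean) pairs; cv_by_arm holds the per-arm means when per-arm pooling
    is requested.
    """

    cv_mean: float
    inflation: float = 1.25
    default_replicates: int = 3
    cv_by_arm: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if not self.cv_mean > 0:
            raise ImputationError("cv_mean must be strictly positive")
        if not self.inflation > 0:
            raise ValueError("inflation must be strictly positive")
        if self.default_replicates < 2:
            raise ValueError("default_replicates must be >= 2")


@dataclasses.dataclass(frozen=True)
class ScalingParams:
    """Per-variable centers and scales for unit-variance covariate scaling.

    Also records the observed range of each variable so grid predictions can
    flag extrapolation beyond the calibration domain.
    """

    center: Mapping[str, float]
    scale: Mapping[str, float]
    low: Mapping[str, float] = dataclasses.field(default_factory=dict)
    high: Mapping[str, float] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, s in self.scale.items():
            if not s > 0:
                raise DegenerateScaleError(f"scale for {name!r} must be > 0")

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(self.center)

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        """Return a copy of `df` with the scaled variables replaced in place.

        The quadratic N-rate term (`n_sq`) is always rebuilt from the raw
        `n_rate` column when present, so callers can pass raw tables.
        """
        out = df.copy()
        if "n_sq" in self.center:
            if "n_sq" not in out.columns:
                out["n_sq"] = out["n_rate"].astype(float) ** 2
        for name in self.center:
            if name not in out.columns:
                raise SchemaError(f"column {name!r} required for scaling is missing")
            out[name] = (out[name].astype(float) - self.center[name]) / self.scale[name]
        return out

    def inverse_transform(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        for name in self.center:
            if name in out.columns:
                out[name] = out[name].astype(float) * self.scale[name] + self.center[name]
        return out

    def to_dict(self) -> dict:
        return {
            "center": dict(self.center),
            "scale": dict(self.scale),
            "low": dict(self.low),
            "high": dict(self.high),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScalingParams":
        return cls(
            center=dict(d["center"]),
            scale=dict(d["scale"]),
            low=dict(d.get("low", {})),
            high=dict(d.get("high", {})),
        )


def _read_schema(schema) -> Mapping[str, str]:
    """Accept a dict, a YAML file path, or None as a column map."""
    if schema is None:
        return {}
    if isinstance(schema, (str, Path)):
        import yaml

        with open(schema, "r", encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, Mapping):
            raise SchemaError("schema file must contain a mapping of column names")
        return loaded
    return dict(schema)


def load_observations(
    path,
    schema: Mapping[str, str] | str | None = None,
    *,
    strict: bool = False,
) -> pd.DataFrame:
    """Read and validate a paired-observation CSV.

    Parameters
    ----------
    path
        CSV file, UTF-8 with a header row; missing values as empty fields or
        "NA".
    schema
        Optional map from canonical column names (``study_id``, ``mean_t``,
        ...) to the names used in the file, or a YAML file containing one.
    strict
        If True, any invalid row raises :class:`ValidationError` instead of
        being dropped with a logged diagnostic.

    Returns
    -------
    pandas.DataFrame
        Validated table in the input row order.  Rows violating hard
        invariants (nonpositive dispersion, replicate count < 2, pH outside
        [0, 14], clay outside [0, 100], missing site covariates) are rejected
        with row-indexed diagnostics.  Rows with a nonpositive control or
        treatment mean are retained but flagged ``rom_valid = False``: the
        log ratio of means is undefined for them while MD/SMD are not.
    """
    colmap = _read_schema(schema)
    df = pd.read_csv(path, na_values=["NA", "na", ""], encoding="utf-8")
    rename = {v: k for k, v in colmap.items() if v in df.columns}
    df = df.rename(columns=rename)

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    for col in NUMERIC_COLUMNS:
        if col in df.columns:
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError) as exc:
                bad = df.index[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
                raise SchemaError(
                    f"non-numeric value in column {col!r} at row(s) {list(bad)}"
                ) from exc
    if "obs_id" not in df.columns:
        df["obs_id"] = [f"obs{i}" for i in range(len(df))]

    diagnostics: list[tuple[int, str]] = []

    def _flag(mask: pd.Series, message: str) -> None:
        for idx in df.index[mask.fillna(False)]:
            diagnostics.append((int(idx), message))

    _flag(~df["practice"].isin(PRACTICES), f"practice not one of {PRACTICES}")
    _flag(~df["crop"].isin(CROPS), f"crop not one of {CROPS}")
    _flag(df["mean_t"].isna() | df["mean_c"].isna(), "missing group mean")
    for col in ("sd_t", "sd_c"):
        if col in df.columns:
            _flag(df[col] < 0, f"{col} negative")
    for col in ("n_t", "n_c"):
        if col in df.columns:
            _flag(df[col] < 2, f"{col} < 2 (variance formulas degenerate)")
    _flag(df["n_rate"] < 0, "negative N application rate")
    _flag((df["ph"] < 0) | (df["ph"] > 14), "pH outside [0, 14]")
    _flag((df["clay"] < 0) | (df["clay"] > 100), "clay outside [0, 100] %")
    # Site covariates are not re-derived from coordinates here; incomplete
    # rows are rejected so the model matrix is always complete.
    for col in ("n_rate", "mat", "map", "soc", "clay", "ph"):
        _flag(df[col].isna(), f"missing site covariate {col}")

    bad_rows = sorted({idx for idx, _ in diagnostics})
    if diagnostics:
        for idx, msg in diagnostics:
            logger.warning("row %d rejected: %s", idx, msg)
        if strict:
            detail = "; ".join(f"row {i}: {m}" for i, m in diagnostics[:20])
            raise ValidationError(f"{len(bad_rows)} invalid row(s): {detail}")
    out = df.drop(index=bad_rows)

    # ROM needs strictly positive means; MD/SMD do not.
    out = out.copy()
    out["rom_valid"] = (out["mean_t"] > 0) & (out["mean_c"] > 0)
    n_nonpos = int((~out["rom_valid"]).sum())
    if n_nonpos:
        logger.warning(
            "%d row(s) have nonpositive means: retained, flagged invalid for ROM",
            n_nonpos,
        )
    out.attrs["rejected_rows"] = diagnostics
    return out


def impute_missing_sd(
    table: pd.DataFrame,
    inflation: float = 1.25,
    *,
    pooling: str = "pooled",
) -> tuple[pd.DataFrame, ImputationParams]:
    """Fill missing group SDs from the mean coefficient of variation.

    CV_mean is averaged over all reported (sd, mean) pairs; with
    ``pooling="per_arm"`` the treatment and control arms keep separate means.
    Each missing SD becomes ``cv * own group mean * inflation``; reported SDs
    are untouched and imputed cells are flagged in ``sd_t_imputed`` /
    ``sd_c_imputed``.
    """
    if pooling not in ("pooled", "per_arm"):
        raise ValueError("pooling must be 'pooled' or 'per_arm'")
    out = table.copy()
    for col in ("sd_t", "sd_c"):
        if col not in out.columns:
            out[col] = np.nan

    cvs = {}
    for arm in ("t", "c"):
        sd = out[f"sd_{arm}"]
        mean = out[f"mean_{arm}"]
        ok = sd.notna() & mean.notna() & (mean > 0)
        cvs[arm] = (sd[ok] / mean[ok]).to_numpy(dtype=float)
    all_cvs = np.concatenate([cvs["t"], cvs["c"]])
    if all_cvs.size == 0:
        raise ImputationError(
            "no reported SDs anywhere in the table; CV-based imputation impossible"
        )
    cv_mean = float(np.mean(all_cvs))
    if not cv_mean > 0:
        raise ImputationError("all reported SDs are zero; cannot form a positive CV")
    cv_by_arm = {
        arm: float(np.mean(v)) if v.size else cv_mean for arm, v in cvs.items()
    }

    params = ImputationParams(
        cv_mean=cv_mean, inflation=inflation, cv_by_arm=cv_by_arm
    )
    for arm in ("t", "c"):
        col = f"sd_{arm}"
        flag = f"{col}_imputed"
        cv = cv_by_arm[arm] if pooling == "per_arm" else cv_mean
        missing = out[col].isna()
        newly = missing & ~out.get(flag, pd.Series(False, index=out.index)).astype(bool)
        out.loc[missing, col] = cv * out.loc[missing, f"mean_{arm}"] * inflation
        if flag in out.columns:
            out[flag] = out[flag].astype(bool) | missing
        else:
            out[flag] = missing
        if newly.any():
            logger.info("imputed %d missing %s values (cv=%.4f)", int(newly.sum()), col, cv)
    return out, params


def impute_missing_replicates(table: pd.DataFrame, default: int = 3) -> pd.DataFrame:
    """Set missing replicate counts to `default` (3: the modal trial design)."""
    if default < 2:
        raise ValueError("default replicate count must be >= 2")
    out = table.copy()
    for col in ("n_t", "n_c"):
        if col not in out.columns:
            out[col] = np.nan
        present = out[col].notna()
        if (out.loc[present, col] < 2).any():
            bad = out.index[present & (out[col] < 2)]
            raise ValidationError(
                f"{col} < 2 at row(s) {list(bad)}: sampling-variance formulas degenerate"
            )
        out.loc[~present, col] = default
        out[col] = out[col].astype(int)
    return out


def scale_covariates(
    table: pd.DataFrame,
    variables: Sequence[str] = COVARIATES + ("n_sq",),
    params: ScalingParams | None = None,
) -> tuple[pd.DataFrame, ScalingParams]:
    """Center and scale the named covariates to unit sample variance.

    The quadratic N-rate term ``n_sq`` is computed from the *raw* ``n_rate``
    before any scaling, then scaled as its own variable.  Passing ``params``
    applies a previously fitted scaling instead of estimating a new one
    (required when encoding grid cells for a fitted model).
    """
    out = table.copy()
    variables = list(variables)
    if "n_sq" in variables and "n_sq" not in out.columns:
        out["n_sq"] = out["n_rate"].astype(float) ** 2

    if params is not None:
        extra = [v for v in variables if v not in params.center]
        if extra:
            raise SchemaError(f"scaling params missing variables: {extra}")
        return params.transform(out), params

    center, scale, low, high = {}, {}, {}, {}
    for name in variables:
        if name not in out.columns:
            raise SchemaError(f"covariate column {name!r} not found")
        x = out[name].astype(float)
        s = float(x.std(ddof=1))
        if not np.isfinite(s) or s <= 0:
            raise DegenerateScaleError(
                f"covariate {name!r} has zero sample variance; cannot scale"
            )
        center[name] = float(x.mean())
        scale[name] = s
        low[name] = float(x.min())
        high[name] = float(x.max())
        out[name] = (x - center[name]) / s
    fitted = ScalingParams(center=center, scale=scale, low=low, high=high)
    return out, fitted


class SDImputer(BaseEstimator):
    """Transformer wrapper around :func:`impute_missing_sd`."""

    def __init__(self, inflation: float = 1.25, pooling: str = "pooled"):
        self.inflation = inflation
        self.pooling = pooling

    def fit(self, X: pd.DataFrame, y=None) -> "SDImputer":
        _, self.params_ = impute_missing_sd(X, self.inflation, pooling=self.pooling)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        self._check_is_fitted("params_")
        out = X.copy()
        for arm in ("t", "c"):
            col = f"sd_{arm}"
            if col not in out.columns:
                out[col] = np.nan
            cv = (
                self.params_.cv_by_arm[arm]
                if self.pooling == "per_arm"
                else self.params_.cv_mean
            )
            missing = out[col].isna()
            out.loc[missing, col] = (
                cv * out.loc[missing, f"mean_{arm}"] * self.params_.inflation
            )
            out[f"{col}_imputed"] = out.get(f"{col}_imputed", False) | missing
        return out

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X).transform(X)


class ReplicateImputer(BaseEstimator):
    """Transformer wrapper around :func:`impute_missing_replicates`."""

    def __init__(self, default: int = 3):
        self.default = default

    def fit(self, X: pd.DataFrame, y=None) -> "ReplicateImputer":
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return impute_missing_replicates(X, self.default)

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.transform(X)


class CovariateScaler(BaseEstimator):
    """Transformer wrapper around :func:`scale_covariates`."""

    def __init__(self, variables: Sequence[str] = COVARIATES + ("n_sq",)):
        self.variables = variables

    def fit(self, X: pd.DataFrame, y=None) -> "CovariateScaler":
        _, self.params_ = scale_covariates(X, self.variables)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        self._check_is_fitted("params_")
        out, _ = scale_covariates(X, self.variables, params=self.params_)
        return out

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X).transform(X)

    def inverse_transform(self, X: pd.DataFrame) -> pd.DataFrame:
        self._check_is_fitted("params_")
        return self.params_.inverse_transform(X)
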