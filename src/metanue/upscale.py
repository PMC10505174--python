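"""Scenario encoding and gridded upscaling of predicted NUEr changes.

A management scenario is a bundle of 0/1 practice indicators applied on top
of a grid cell's baseline covariates.  For every cell and crop the change in
NUEr is the fixed-effects contrast between the scenario row and the baseline
row of the fitted meta-regression; its standard error comes from the
coefficient covariance on the difference vector, and 95% bounds use the
1.96 normal critical value.  Per-cell values are crop-share-weighted means
over the crops grown there, and regional/global summaries are
cropland-area-weighted means of the per-cell results.

A practice bundle is one design row with several indicators set (its
interactions then contribute jointly); it is not a sum of separately
predicted single-practice effects.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, NoDataError, ValidationError
from .ingest import CROPS, PRACTICES, ScalingParams
from .model import MetaRegression, ModelSpec, design_matrix

logger = logging.getLogger(__name__)

#: Mutually exclusive fertilizer-type indicators (vs the mineral reference).
FERTILIZER_TYPES = ("EE", "CF", "OF")

GRID_COLUMNS = ("cell_id", "n_rate", "mat", "map", "soc", "clay", "ph")


@dataclasses.dataclass(frozen=True)
class ScenarioVector:
    """A named bundle of management-practice indicators.

    Setting several fertilizer-type indicators at once requires
    ``bundle=True``: that encodes a joint adoption row, the semantics used
    for "optimal combination" scenarios.
    """

    name: str
    practice_settings: Mapping[str, int] = dataclasses.field(default_factory=dict)
    description: str = ""
    bundle: bool = False

    def __post_init__(self) -> None:
        for practice, value in self.practice_settings.items():
            if practice not in PRACTICES:
                raise ValidationError(f"unknown practice {practice!r}")
            if value not in (0, 1):
                raise ValidationError("practice indicators must be 0 or 1")
        n_fert = sum(
            self.practice_settings.get(p, 0) for p in FERTILIZER_TYPES
        )
        if n_fert > 1 and not self.bundle:
            raise ValidationError(
                "several fertilizer-type indicators are set; pass bundle=True "
                "to encode a joint-adoption scenario explicitly"
            )

    def indicator(self, practice: str) -> int:
        return int(self.practice_settings.get(practice, 0))

    @classmethod
    def from_yaml(cls, path) -> "ScenarioVector":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        return cls(
            name=d.get("name", "scenario"),
            practice_settings={k: int(v) for k, v in (d.get("practices") or {}).items()},
            description=d.get("description", ""),
            bundle=bool(d.get("bundle", False)),
        )


BASELINE = ScenarioVector(name="conventional", practice_settings={}, description="all-conventional baseline")


def _check_grid(grid: pd.DataFrame) -> None:
    missing = [c for c in GRID_COLUMNS if c not in grid.columns]
    if missing:
        raise ValidationError(f"grid lacks column(s) {missing}")
    shares = [f"share_{c}" for c in CROPS if f"share_{c}" in grid.columns]
    if not shares:
        raise ValidationError("grid lacks crop share columns (share_wheat, ...)")
    total = grid[shares].sum(axis=1)
    if (total > 1.0 + 1e-9).any():
        raise ValidationError("crop shares exceed 1 in some cells")
    if "area_weight" in grid.columns and (grid["area_weight"] < 0).any():
        raise ValidationError("area weights must be nonnegative")


def _flag_extrapolation(grid: pd.DataFrame, scaling: ScalingParams, *, clip: bool) -> pd.DataFrame:
    """Warn (and optionally clip) covariates outside the calibration range."""
    out = grid.copy()
    for name in scaling.center:
        if name == "n_sq" or name not in out.columns:
            continue
        lo = scaling.low.get(name)
        hi = scaling.high.get(name)
        if lo is None or hi is None:
            continue
        vals = out[name].astype(float)
        outside = (vals < lo) | (vals > hi)
        if outside.any():
            cells = out.loc[outside, "cell_id"].tolist()
            logger.warning(
                "covariate %s outside calibration range [%.3g, %.3g] in %d cell(s): %s",
                name, lo, hi, int(outside.sum()), cells[:10],
            )
            warnings.warn(
                f"covariate {name!r} outside the calibration range in "
                f"{int(outside.sum())} grid cell(s); predictions extrapolate",
                stacklevel=3,
            )
            if clip:
                out[name] = vals.clip(lo, hi)
    return out


def _scenario_frame(
    scenario: ScenarioVector, grid: pd.DataFrame, crop: str, scaling: ScalingParams
) -> pd.DataFrame:
    """Raw moderator frame for one scenario x crop over all cells."""
    df = pd.DataFrame(index=grid.index)
    for p in PRACTICES:
        df[p] = float(scenario.indicator(p))
    df["crop"] = crop
    for cov in ("n_rate", "mat", "map", "soc", "clay", "ph"):
        df[cov] = grid[cov].astype(float)
    return scaling.transform(df)


def encode_scenario(
    scenario: ScenarioVector,
    cell: Mapping,
    crop: str,
    spec: ModelSpec,
    scaling: ScalingParams,
) -> pd.Series:
    """Design row for one scenario applied to one grid cell and crop.

    Covariates come raw from the cell and are scaled with the fitted
    ScalingParams (the quadratic N term is rebuilt from the raw N rate);
    values outside the calibration range trigger an extrapolation warning.
    """
    if crop not in CROPS:
        raise ValidationError(f"crop must be one of {CROPS}")
    cell_df = pd.DataFrame([dict(cell)])
    if "cell_id" not in cell_df.columns:
        cell_df["cell_id"] = "cell"
    cell_df = _flag_extrapolation(cell_df, scaling, clip=False)
    raw = _scenario_frame(scenario, cell_df, crop, scaling)
    X = design_matrix(raw, spec)
    return X.iloc[0]


def predict_grid(
    model: MetaRegression,
    grid: pd.DataFrame,
    scenario: ScenarioVector,
    baseline: ScenarioVector = BASELINE,
    *,
    spec: ModelSpec,
    scaling: ScalingParams | None = None,
    clip: bool = False,
) -> pd.DataFrame:
    """Per-cell ΔNUEr (scenario minus baseline) with 95% confidence bounds.

    Predictions are per crop with nonzero share, then crop-share weighted
    within the cell; the contrast SE uses only the fixed-effects covariance.
    Cells growing none of the modelled crops are skipped.
    """
    model._check_is_fitted("beta_")
    if len(grid) == 0:
        raise NoDataError("empty grid")
    scaling = scaling or spec.scaling
    if scaling is None:
        raise ContractError("ScalingParams are required to encode grid covariates")
    if spec.response_metric != "MD":
        warnings.warn(
            "upscaling a non-MD model: ΔNUEr is then on the "
            f"{spec.response_metric} scale, not NUEr percentage points",
            stacklevel=2,
        )
    _check_grid(grid)
    grid = _flag_extrapolation(grid, scaling, clip=clip)

    share_cols = {c: f"share_{c}" for c in CROPS if f"share_{c}" in grid.columns}
    shares = np.column_stack(
        [grid[col].to_numpy(dtype=float) for col in share_cols.values()]
    )
    total = shares.sum(axis=1)
    grown = total > 0
    if not grown.any():
        raise NoDataError("no cell grows any modelled crop")
    weights = np.zeros_like(shares)
    weights[grown] = shares[grown] / total[grown, None]

    p = len(model.beta_)
    d_cell = np.zeros((len(grid), p))
    for j, crop in enumerate(share_cols):
        if not (weights[:, j] > 0).any():
            continue
        Xs = design_matrix(_scenario_frame(scenario, grid, crop, scaling), spec)
        Xb = design_matrix(_scenario_frame(baseline, grid, crop, scaling), spec)
        D = Xs.to_numpy(dtype=float) - Xb.to_numpy(dtype=float)
        d_cell += weights[:, j][:, None] * D

    mean = d_cell @ model.beta_
    se = np.sqrt(np.einsum("ij,jk,ik->i", d_cell, model.cov_beta_, d_cell))
    out = pd.DataFrame(
        {
            "cell_id": grid["cell_id"].to_numpy(),
            "delta_nuer_mean": mean,
            "se": se,
            "ci_low": mean - 1.96 * se,
            "ci_high": mean + 1.96 * se,
        },
        index=grid.index,
    )
    for col in ("lat", "lon"):
        if col in grid.columns:
            out[col] = grid[col].to_numpy()
    skipped = int((~grown).sum())
    if skipped:
        logger.info("skipped %d cell(s) with zero share for all modelled crops", skipped)
    return out[grown].reset_index(drop=True)


def summarize(
    predictions: pd.DataFrame,
    grid: pd.DataFrame,
    regions: Mapping | None = None,
) -> pd.DataFrame:
    """Area-weighted mean ΔNUEr and CI bounds, globally and per region.

    Weights are the grid's ``area_weight`` (all-ones when absent),
    renormalized over the cells present in `predictions`.
    """
    if "cell_id" not in predictions.columns:
        raise ValidationError("predictions lack cell_id")
    gw = grid.set_index("cell_id")
    merged = predictions.set_index("cell_id")
    missing = merged.index.difference(gw.index)
    if len(missing):
        raise ValidationError(f"predictions reference unknown cell(s): {list(missing)[:5]}")
    w = (
        gw.loc[merged.index, "area_weight"].to_numpy(dtype=float)
        if "area_weight" in gw.columns
        else np.ones(len(merged))
    )
    if regions is not None:
        region = np.array([regions.get(c, "unassigned") for c in merged.index])
    elif "region" in gw.columns:
        region = gw.loc[merged.index, "region"].to_numpy()
    else:
        region = None

    def _row(label, mask):
        ww = w[mask]
        if ww.sum() <= 0:
            raise NoDataError(f"total area weight is zero for {label!r}")
        ww = ww / ww.sum()
        sub = merged[mask]
        return {
            "region": label,
            "delta_nuer_mean": float(ww @ sub["delta_nuer_mean"].to_numpy()),
            "ci_low": float(ww @ sub["ci_low"].to_numpy()),
            "ci_high": float(ww @ sub["ci_high"].to_numpy()),
            "n_cells": int(mask.sum()),
            "total_weight": float(w[mask].sum()),
        }

    rows = [_row("global", np.ones(len(merged), dtype=bool))]
    if region is not None:
        for r in sorted(pd.unique(region)):
            rows.append(_row(str(r), region == r))
    return pd.DataFrame(rows)
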