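"""Per-observation effect sizes for paired NUEr observations.

Three effect metrics are supported, each with its large-sample sampling
variance:

* ROM — log ratio of means, ``ln(X_t/X_c)``, variance
  ``s_t^2/(n_t X_t^2) + s_c^2/(n_c X_c^2)``; back-transformed to a relative
  percent change ``(e^lnRR - 1) * 100``.
* MD — raw mean difference ``X_t - X_c`` in NUEr percentage points, variance
  ``s_t^2/n_t + s_c^2/n_c``.
* SMD — standardized mean difference ``(X_t - X_c)/SD_p`` with the pooled
  within-group SD, variance ``(n_t+n_c)/(n_t n_c) + SMD^2/(2(n_t+n_c))``.
  The uncorrected standardized difference is the default; the Hedges
  small-sample factor ``1 - 3/(4(n_t+n_c-2)-1)`` is available behind a flag.

Relative (ROM) and standardized (SMD) results are converted to absolute
NUEr changes with the practice-group average control mean and average pooled
SD respectively, so the three metrics can be compared on one scale.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DomainError, ValidationError

METHODS = ("ROM", "MD", "SMD")


@dataclasses.dataclass(frozen=True)
class EffectSize:
    """One observation's effect estimate and its sampling variance."""

    obs_id: str
    method: str
    yi: float
    vi: float
    pooled_sd: float | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if not self.vi > 0:
            raise ValidationError("sampling variance must be strictly positive")


@dataclasses.dataclass(frozen=True)
class ConversionContext:
    """Practice-group averages used to express effects as absolute NUEr change.

    group_control_mean is the average control NUEr (X̄_c) of the practice
    class; group_pooled_sd_mean the average pooled within-group SD (SD̄_p).
    """

    group_control_mean: float
    group_pooled_sd_mean: float

    def __post_init__(self) -> None:
        if not self.group_control_mean > 0:
            raise ValidationError("group control mean must be strictly positive")
        if not self.group_pooled_sd_mean > 0:
            raise ValidationError("group pooled SD must be strictly positive")


def _get(obs: Mapping, key: str) -> float:
    try:
        value = obs[key]
    except (KeyError, IndexError) as exc:
        raise ValidationError(f"observation lacks required field {key!r}") from exc
    if value is None or (isinstance(value, float) and math.isnan(value)):
        raise ValidationError(f"observation field {key!r} is missing")
    return float(value)


def compute_rom(obs: Mapping) -> EffectSize:
    """Log ratio of means and its sampling variance for one observation."""
    xt, xc = _get(obs, "mean_t"), _get(obs, "mean_c")
    if xt <= 0 or xc <= 0:
        raise DomainError("ROM requires strictly positive group means")
    st, sc = _get(obs, "sd_t"), _get(obs, "sd_c")
    nt, nc = _get(obs, "n_t"), _get(obs, "n_c")
    yi = math.log(xt / xc)
    vi = st**2 / (nt * xt**2) + sc**2 / (nc * xc**2)
    return EffectSize(obs_id=str(obs.get("obs_id", "")), method="ROM", yi=yi, vi=vi)


def relative_change(yi_rom: float) -> float:
    """Back-transform a log ratio of means to a relative change in percent."""
    return (math.exp(yi_rom) - 1.0) * 100.0


def compute_md(obs: Mapping) -> EffectSize:
    """Raw mean difference (NUEr percentage points) and its variance."""
    xt, xc = _get(obs, "mean_t"), _get(obs, "mean_c")
    st, sc = _get(obs, "sd_t"), _get(obs, "sd_c")
    nt, nc = _get(obs, "n_t"), _get(obs, "n_c")
    yi = xt - xc
    vi = st**2 / nt + sc**2 / nc
    return EffectSize(obs_id=str(obs.get("obs_id", "")), method="MD", yi=yi, vi=vi)


def compute_smd(obs: Mapping, *, hedges_correction: bool = False) -> EffectSize:
    """Standardized mean difference with the pooled within-group SD.

    No small-sample correction is applied unless ``hedges_correction=True``.
    """
    xt, xc = _get(obs, "mean_t"), _get(obs, "mean_c")
    st, sc = _get(obs, "sd_t"), _get(obs, "sd_c")
    nt, nc = _get(obs, "n_t"), _get(obs, "n_c")
    if nt + nc <= 2:
        raise ValidationError("SMD requires n_t + n_c > 2")
    sd_p = math.sqrt(((nt - 1) * st**2 + (nc - 1) * sc**2) / (nt + nc - 2))
    if sd_p == 0:
        raise DomainError("pooled SD is zero; SMD undefined for degenerate dispersion")
    yi = (xt - xc) / sd_p
    if hedges_correction:
        yi *= 1.0 - 3.0 / (4.0 * (nt + nc - 2.0) - 1.0)
    vi = (nt + nc) / (nt * nc) + yi**2 / (2.0 * (nt + nc))
    return EffectSize(
        obs_id=str(obs.get("obs_id", "")), method="SMD", yi=yi, vi=vi, pooled_sd=sd_p
    )


def absolute_from_rom(relative_pct: float, ctx: ConversionContext) -> float:
    """Absolute NUEr change (percentage points) from a relative percent change.

    The relative change is treated as a fraction of the practice-group
    average control NUEr: 25% relative at X̄_c = 32% is 8 percentage points.
    """
    return (relative_pct / 100.0) * ctx.group_control_mean


def absolute_from_smd(smd: float, ctx: ConversionContext) -> float:
    """Absolute NUEr change from a standardized difference via SD̄_p."""
    return smd * ctx.group_pooled_sd_mean


_DISPATCH = {"ROM": compute_rom, "MD": compute_md, "SMD": compute_smd}


def compute_effect_sizes(
    table: pd.DataFrame, method: str, *, hedges_correction: bool = False
) -> pd.DataFrame:
    """Vectorized effect sizes for a whole observation table.

    Returns a frame aligned with the input (obs_id, study_id, method, yi, vi
    and, for SMD, pooled_sd).  Rows flagged ``rom_valid = False`` are dropped
    when ``method="ROM"``; the log ratio is undefined there.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    df = table
    if method == "ROM" and "rom_valid" in df.columns:
        df = df[df["rom_valid"].astype(bool)]

    xt = df["mean_t"].to_numpy(dtype=float)
    xc = df["mean_c"].to_numpy(dtype=float)
    st = df["sd_t"].to_numpy(dtype=float)
    sc = df["sd_c"].to_numpy(dtype=float)
    nt = df["n_t"].to_numpy(dtype=float)
    nc = df["n_c"].to_numpy(dtype=float)
    if np.isnan(st).any() or np.isnan(sc).any():
        raise ValidationError("missing SDs; run impute_missing_sd first")
    if np.isnan(nt).any() or np.isnan(nc).any():
        raise ValidationError("missing replicate counts; run impute_missing_replicates first")

    out = pd.DataFrame(
        {
            "obs_id": df["obs_id"].to_numpy(),
            "study_id": df["study_id"].to_numpy(),
            "method": method,
        },
        index=df.index,
    )
    if method == "ROM":
        if (xt <= 0).any() or (xc <= 0).any():
            raise DomainError("ROM requires strictly positive group means")
        out["yi"] = np.log(xt / xc)
        out["vi"] = st**2 / (nt * xt**2) + sc**2 / (nc * xc**2)
    elif method == "MD":
        out["yi"] = xt - xc
        out["vi"] = st**2 / nt + sc**2 / nc
    else:
        sd_p = np.sqrt(((nt - 1) * st**2 + (nc - 1) * sc**2) / (nt + nc - 2))
        if (sd_p == 0).any():
            raise DomainError("pooled SD is zero for some rows; SMD undefined")
        yi = (xt - xc) / sd_p
        if hedges_correction:
            yi = yi * (1.0 - 3.0 / (4.0 * (nt + nc - 2.0) - 1.0))
        out["yi"] = yi
        out["vi"] = (nt + nc) / (nt * nc) + yi**2 / (2.0 * (nt + nc))
        out["pooled_sd"] = sd_p
    if not (out["vi"] > 0).all():
        raise ValidationError("nonpositive sampling variance produced; check SDs")
    return out


def conversion_context(table: pd.DataFrame, practice: str) -> ConversionContext:
    """Practice-group averages (X̄_c, SD̄_p) from an observation table."""
    grp = table[table["practice"] == practice]
    if grp.empty:
        raise ValidationError(f"no observations for practice {practice!r}")
    xbar_c = float(grp["mean_c"].mean())
    nt = grp["n_t"].to_numpy(dtype=float)
    nc = grp["n_c"].to_numpy(dtype=float)
    st = grp["sd_t"].to_numpy(dtype=float)
    sc = grp["sd_c"].to_numpy(dtype=float)
    sd_p = np.sqrt(((nt - 1) * st**2 + (nc - 1) * sc**2) / (nt + nc - 2))
    return ConversionContext(
        group_control_mean=xbar_c, group_pooled_sd_mean=float(np.mean(sd_p))
    )
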