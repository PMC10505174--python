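"""Inverse-variance pooling of published per-practice estimates.

When several published meta-analyses report an effect of the same practice,
their estimates are combined into one fixed-effect (common-effect) summary:

    x̄  = Σ(x_i/σ_i²) / Σ(1/σ_i²)          σ_x̄ = 1 / sqrt(Σ(1/σ_i²))

No between-source heterogeneity term is added; a warning is emitted when the
Cochran Q statistic across sources exceeds its degrees of freedom, the usual
sign that a common-effect pool understates uncertainty.  Sources reporting
the same practice under different effect-size metrics are pooled only within
metric.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import NoDataError, ValidationError

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class MetaEstimate:
    """One published estimate: effect x_i with standard error se_i."""

    practice: str
    x_i: float
    se_i: float
    source_id: str = ""
    metric: str = ""

    def __post_init__(self) -> None:
        if not self.se_i > 0:
            raise ValidationError(
                f"standard error must be strictly positive (got {self.se_i})"
            )


@dataclasses.dataclass(frozen=True)
class AggregateSummary:
    practice: str
    x_bar: float
    se_bar: float
    k: int
    q: float = 0.0
    heterogeneous: bool = False


def combine_estimates(estimates: Sequence[MetaEstimate]) -> AggregateSummary:
    """Inverse-variance weighted mean and its standard error over sources."""
    estimates = list(estimates)
    if not estimates:
        raise NoDataError("cannot combine an empty list of estimates")
    metrics = {e.metric for e in estimates}
    if len(metrics) > 1:
        raise ValidationError(
            f"refusing to pool across effect-size metrics {sorted(metrics)}; "
            "pool within one metric at a time"
        )
    practices = {e.practice for e in estimates}
    if len(practices) > 1:
        raise ValidationError(
            f"estimates span several practices {sorted(practices)}; pool per practice"
        )
    x = np.array([e.x_i for e in estimates], dtype=float)
    w = np.array([1.0 / e.se_i**2 for e in estimates], dtype=float)
    x_bar = float(np.sum(w * x) / np.sum(w))
    se_bar = float(1.0 / math.sqrt(np.sum(w)))
    q = float(np.sum(w * (x - x_bar) ** 2))
    df = len(estimates) - 1
    heterogeneous = df > 0 and q > df
    if heterogeneous:
        logger.warning(
            "practice %s: Q = %.2f exceeds df = %d; common-effect pool may "
            "understate uncertainty",
            estimates[0].practice,
            q,
            df,
        )
    return AggregateSummary(
        practice=estimates[0].practice,
        x_bar=x_bar,
        se_bar=se_bar,
        k=len(estimates),
        q=q,
        heterogeneous=heterogeneous,
    )


def combine_table(df: pd.DataFrame) -> pd.DataFrame:
    """Pool a (source_id, practice, metric, x_i, se_i) table per practice+metric."""
    required = {"practice", "x_i", "se_i"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"missing column(s) {sorted(missing)}")
    rows = []
    keys = ["practice"] + (["metric"] if "metric" in df.columns else [])
    for key, grp in df.groupby(keys, sort=True):
        ests = [
            MetaEstimate(
                practice=str(r["practice"]),
                x_i=float(r["x_i"]),
                se_i=float(r["se_i"]),
                source_id=str(r.get("source_id", "")),
                metric=str(r.get("metric", "")),
            )
            for _, r in grp.iterrows()
        ]
        s = combine_estimates(ests)
        rows.append(
            {
                "practice": s.practice,
                "metric": ests[0].metric,
                "x_bar": s.x_bar,
                "se_bar": s.se_bar,
                "k": s.k,
                "q": s.q,
                "heterogeneous": s.heterogeneous,
            }
        )
    return pd.DataFrame(rows)
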