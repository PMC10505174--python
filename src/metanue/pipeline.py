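"""End-to-end orchestration: imputation -> effect sizes -> fit -> upscaling.

One YAML (or :class:`RunConfig`) drives the whole chain and every artifact
is written deterministically; the emitted manifest lists each output with a
content hash so identical inputs provably reproduce identical results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd

from . import __version__
from .aggregate import combine_table
from .effects import compute_effect_sizes
from .errors import MetanueError, SchemaError
from .ingest import (
    impute_missing_replicates,
    impute_missing_sd,
    load_observations,
    scale_covariates,
)
from .model import CONTINUOUS_TERMS, MetaRegression, ModelSpec, build_design
from .simulate import SyntheticConfig, generate_grid, generate_observations
from .upscale import BASELINE, ScenarioVector, predict_grid, summarize

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Either ``observations`` (a CSV path) or ``simulate`` (a mapping of
    :class:`SyntheticConfig` fields) must be provided; ``grid`` may likewise
    be a CSV path or ``{"n_cells": ...}`` for a synthetic grid.
    """

    out_dir: str
    observations: str | None = None
    schema: str | None = None
    meta_estimates: str | None = None
    grid: str | Mapping | None = None
    simulate: Mapping | None = None
    model: Mapping = dataclasses.field(default_factory=dict)
    scenarios: Sequence[Mapping] = dataclasses.field(default_factory=list)
    baseline: Mapping | None = None
    inflation: float = 1.25
    default_replicates: int = 3
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            d = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise SchemaError(f"unknown run-config field(s): {sorted(unknown)}")
        if "out_dir" not in d:
            raise SchemaError("run config must name out_dir")
        return cls(**d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _scenario(d: Mapping | None, fallback: ScenarioVector) -> ScenarioVector:
    if d is None:
        return fallback
    return ScenarioVector(
        name=d.get("name", "scenario"),
        practice_settings={k: int(v) for k, v in (d.get("practices") or {}).items()},
        description=d.get("description", ""),
        bundle=bool(d.get("bundle", False)),
    )


class _Stage:
    """Context manager that renames any error with its pipeline stage."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None:
            raise MetanueError(f"stage {self.name!r} failed: {exc}") from exc
        logger.info("stage %s: done", self.name)
        return False


def run_pipeline(config: RunConfig | str | Path) -> dict[str, Any]:
    """Execute all configured stages and return the run manifest."""
    if not isinstance(config, RunConfig):
        config = RunConfig.from_yaml(config)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    counts: dict[str, int] = {}

    def _write(df: pd.DataFrame, name: str) -> None:
        path = out_dir / name
        df.to_csv(path, index=False)
        artifacts[name] = _sha256(path)
        counts[name] = len(df)

    spec = ModelSpec.from_dict(config.model) if config.model else ModelSpec()
    sim_config = None

    with _Stage("ingest"):
        if config.observations:
            table = load_observations(config.observations, schema=config.schema)
        elif config.simulate is not None:
            sim = dict(config.simulate)
            sim.setdefault("seed", config.seed)
            if "spec" in sim:
                sim["spec"] = ModelSpec.from_dict(sim["spec"])
            else:
                sim["spec"] = spec
            sim_config = SyntheticConfig(**sim)
            table, truth = generate_observations(sim_config)
            with open(out_dir / "truth.json", "w", encoding="utf-8") as fh:
                json.dump(
                    {
                        "true_beta": truth.true_beta,
                        "tau2_true": truth.tau2_true,
                        "rho_true": truth.rho_true,
                        "seed": truth.seed,
                    },
                    fh,
                    indent=2,
                )
            artifacts["truth.json"] = _sha256(out_dir / "truth.json")
        else:
            raise SchemaError("config must provide observations or simulate")

    with _Stage("impute"):
        table, imp = impute_missing_sd(table, inflation=config.inflation)
        table = impute_missing_replicates(table, default=config.default_replicates)

    with _Stage("effects"):
        eff = compute_effect_sizes(table, spec.response_metric)
        merged = table.join(eff[["yi", "vi", "method"]], how="inner")
        _write(eff, "effects.csv")

    with _Stage("scale"):
        variables = [t for t in spec.moderators if t in CONTINUOUS_TERMS]
        for a, b in spec.interactions:
            for t in (a, b):
                if t in CONTINUOUS_TERMS and t not in variables:
                    variables.append(t)
        if variables:
            merged, scaling = scale_covariates(merged, variables=variables)
            spec.scaling = scaling
        _write(merged, "clean.csv")

    if config.meta_estimates:
        with _Stage("aggregate"):
            pooled = combine_table(pd.read_csv(config.meta_estimates))
            _write(pooled, "pooled.csv")

    with _Stage("fit"):
        y, v, X, ids = build_design(merged, spec)
        model = MetaRegression().fit(X, y, v=v, study_ids=ids)
        payload = model.to_dict()
        payload["spec"] = spec.to_dict()
        with open(out_dir / "model.json", "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)
        artifacts["model.json"] = _sha256(out_dir / "model.json")
        _write(model.coefficient_table(), "coefficients.csv")

    grid = None
    if isinstance(config.grid, str):
        grid = pd.read_csv(config.grid)
    elif isinstance(config.grid, Mapping):
        gc = sim_config or SyntheticConfig(spec=spec, seed=config.seed)
        grid = generate_grid(gc, int(config.grid["n_cells"]), seed=config.seed)

    if grid is not None and config.scenarios:
        baseline = _scenario(config.baseline, BASELINE)
        for sdict in config.scenarios:
            scenario = _scenario(sdict, BASELINE)
            with _Stage(f"predict[{scenario.name}]"):
                preds = predict_grid(
                    model, grid, scenario, baseline, spec=spec, scaling=spec.scaling
                )
                _write(preds, f"pred_{scenario.name}.csv")
                _write(summarize(preds, grid), f"summary_{scenario.name}.csv")

    manifest = {
        "package": "metanue",
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "inputs": {
            "observations": config.observations,
            "meta_estimates": config.meta_estimates,
            "grid": config.grid if isinstance(config.grid, str) else None,
            "simulate": dict(config.simulate) if config.simulate else None,
        },
        "artifacts": artifacts,
        "row_counts": counts,
    }
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
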