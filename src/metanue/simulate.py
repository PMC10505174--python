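"""Synthetic paired-observation tables and covariate grids with known truth.

The generator emulates the statistical structure the meta-regression
assumes: study-clustered true effects with compound-symmetric heterogeneity
(shared study component of variance rho*tau2 plus an idiosyncratic
(1-rho)*tau2 part), moderator effects through a known coefficient vector,
site covariates drawn within the ranges observed in global cereal field
trials (MAT -0.6..29 degC, MAP 45..2330 mm, SOC 2.7..80 g/kg, pH 4.5..8.5,
clay 8.8..53 %), and control NUEr between 20 and 60 %.  Group means are
drawn so that the chosen effect metric equals the true effect plus sampling
noise whose variance matches the analytic effect-size formulas exactly,
which makes full parameter-recovery experiments possible.

True coefficients are defined on a fixed population scaling of the
covariates (the analytic mean and SD of each uniform range), recorded in the
emitted :class:`GroundTruth` so fits can reuse the identical scaling.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .effects import compute_effect_sizes
from .errors import ValidationError
from .ingest import CROPS, PRACTICES, ScalingParams, scale_covariates
from .model import (
    CONTINUOUS_TERMS,
    MetaRegression,
    ModelSpec,
    build_design,
    design_matrix,
)

#: Covariate ranges of the compiled field-trial database (original units).
DEFAULT_COVARIATE_RANGES: dict[str, tuple[float, float]] = {
    "n_rate": (30.0, 350.0),
    "mat": (-0.6, 29.0),
    "map": (45.0, 2330.0),
    "soc": (2.7, 80.0),
    "clay": (8.8, 53.0),
    "ph": (4.5, 8.5),
}


def _default_spec() -> ModelSpec:
    return ModelSpec(
        response_metric="MD",
        moderators=["RFR", "EE", "crop", "n_rate", "soc"],
        interactions=[("RFR", "soc")],
    )


def _default_beta() -> dict[str, float]:
    # NUEr percentage points per unit (scaled) moderator
    return {
        "intercept": 2.0,
        "RFR": 8.0,
        "EE": 6.0,
        "crop_maize": 1.5,
        "crop_rice": -1.0,
        "n_rate": -2.0,
        "soc": 2.0,
        "RFR:soc": 2.0,
    }


@dataclasses.dataclass
class SyntheticConfig:
    """Study conditions of the synthetic corpus.

    Defaults describe a mid-sized synthesis: 30 studies of 5 paired
    observations, a raw-mean-difference response with between-effect
    variance tau2 = 4 (NUEr %)^2 shared within studies at rho = 0.5, group
    sampling SDs of 3-8 NUEr % (CVs of roughly 0.1-0.25 at 20-60 % control
    NUEr), 3-5 replicates per arm, and 20 % of rows not reporting SDs, the
    incompleteness real compilations show.
    """

    n_studies: int = 30
    obs_per_study: int | tuple[int, int] = 5
    spec: ModelSpec = dataclasses.field(default_factory=_default_spec)
    true_beta: Mapping[str, float] = dataclasses.field(default_factory=_default_beta)
    tau2_true: float = 4.0
    rho_true: float = 0.5
    sampling_sd_range: tuple[float, float] = (3.0, 8.0)
    replicate_range: tuple[int, int] = (3, 5)
    covariate_ranges: Mapping[str, tuple[float, float]] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_RANGES)
    )
    control_mean_range: tuple[float, float] = (20.0, 60.0)
    practice_mix: Mapping[str, float] | None = dataclasses.field(
        default_factory=lambda: {"RFR": 1 / 3, "EE": 1 / 3, "RES": 1 / 3}
    )
    missing_sd_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_studies < 1:
            raise ValidationError("n_studies must be >= 1")
        if self.tau2_true < 0:
            raise ValidationError("tau2_true must be >= 0")
        if not 0.0 <= self.rho_true < 1.0:
            raise ValidationError("rho_true must be in [0, 1)")
        for name, (lo, hi) in {
            "sampling_sd_range": self.sampling_sd_range,
            "control_mean_range": self.control_mean_range,
            **dict(self.covariate_ranges),
        }.items():
            if not lo < hi:
                raise ValidationError(f"range {name} must have low < high")
        if not 0.0 <= self.missing_sd_fraction < 1.0:
            raise ValidationError("missing_sd_fraction must be in [0, 1)")
        if self.practice_mix is not None:
            total = sum(self.practice_mix.values())
            if not math.isclose(total, 1.0, rel_tol=1e-9):
                raise ValidationError("practice_mix probabilities must sum to 1")
            unknown = set(self.practice_mix) - set(PRACTICES)
            if unknown:
                raise ValidationError(f"unknown practice(s) in mix: {sorted(unknown)}")

    def practices(self) -> tuple[list[str], list[float]]:
        """Practice labels and draw probabilities.

        With no explicit mix, rows are spread uniformly over the modelled
        practices; note that a model including *every* practice occurring in
        the data plus an intercept is rank deficient (each row carries
        exactly one indicator), so the default mix keeps one class outside
        the default model spec to act as the conventional reference.
        """
        if self.practice_mix is not None:
            names = sorted(self.practice_mix)
            return names, [self.practice_mix[n] for n in names]
        names = [m for m in self.spec.moderators if m in PRACTICES]
        if not names:
            names = list(PRACTICES)
        return names, [1.0 / len(names)] * len(names)


@dataclasses.dataclass
class GroundTruth:
    """What the generator knew: reproducible bit-for-bit from (config, seed)."""

    true_beta: dict[str, float]
    tau2_true: float
    rho_true: float
    scaling: ScalingParams
    spec: ModelSpec
    true_effects: np.ndarray
    study_effects: np.ndarray
    seed: int


def population_scaling(config: SyntheticConfig) -> ScalingParams:
    """Analytic center/scale of each continuous moderator under the config.

    Covariates are uniform on their ranges; the quadratic N term uses the
    exact moments of the square of a uniform variate.
    """
    center, scale, low, high = {}, {}, {}, {}
    needed = [t for t in config.spec.moderators if t in CONTINUOUS_TERMS]
    for a, b in config.spec.interactions:
        for t in (a, b):
            if t in CONTINUOUS_TERMS and t not in needed:
                needed.append(t)
    for name in needed:
        if name == "n_sq":
            lo, hi = config.covariate_ranges["n_rate"]
            m2 = (hi**3 - lo**3) / (3.0 * (hi - lo))
            m4 = (hi**5 - lo**5) / (5.0 * (hi - lo))
            center[name] = m2
            scale[name] = math.sqrt(m4 - m2**2)
            low[name], high[name] = lo**2, hi**2
        else:
            lo, hi = config.covariate_ranges[name]
            center[name] = (lo + hi) / 2.0
            scale[name] = (hi - lo) / math.sqrt(12.0)
            low[name], high[name] = lo, hi
    return ScalingParams(center=center, scale=scale, low=low, high=high)


def generate_observations(
    config: SyntheticConfig, seed: int | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a paired-observation table with known moderator truth.

    For the MD response the observed difference of group means equals the
    true effect plus noise with variance s_t^2/n_t + s_c^2/n_c, exactly the
    analytic MD sampling variance of the emitted SDs and replicate counts.
    ROM and SMD responses derive the treatment mean from a target ratio or
    standardized difference instead.
    """
    seed = config.seed if seed is None else int(seed)
    rng = np.random.default_rng(seed)
    metric = config.spec.response_metric
    scaling = population_scaling(config)
    practice_names, practice_probs = config.practices()

    if isinstance(config.obs_per_study, int):
        sizes = np.full(config.n_studies, config.obs_per_study, dtype=int)
    else:
        lo, hi = config.obs_per_study
        sizes = rng.integers(lo, hi + 1, size=config.n_studies)
    n_obs = int(sizes.sum())

    rows = []
    shared = rng.standard_normal(config.n_studies)
    tau2, rho = config.tau2_true, config.rho_true
    study_effects = math.sqrt(rho * tau2) * shared
    u_all = np.empty(n_obs)
    i = 0
    for s in range(config.n_studies):
        for _ in range(sizes[s]):
            u_all[i] = study_effects[s] + math.sqrt((1.0 - rho) * tau2) * rng.standard_normal()
            covs = {
                name: rng.uniform(*config.covariate_ranges[name])
                for name in DEFAULT_COVARIATE_RANGES
            }
            rows.append(
                {
                    "study_id": f"S{s:04d}",
                    "obs_id": f"S{s:04d}_o{i}",
                    "practice": practice_names[
                        rng.choice(len(practice_names), p=practice_probs)
                    ],
                    "crop": CROPS[rng.integers(len(CROPS))],
                    "lat": rng.uniform(-50.0, 60.0),
                    "lon": rng.uniform(-180.0, 180.0),
                    **covs,
                }
            )
            i += 1
    table = pd.DataFrame(rows)

    scaled, _ = scale_covariates(
        table, variables=list(scaling.center), params=scaling
    )
    X = design_matrix(scaled, config.spec)
    beta = np.array([config.true_beta.get(c, 0.0) for c in X.columns])
    theta = X.to_numpy() @ beta + u_all

    sd_c = rng.uniform(*config.sampling_sd_range, size=n_obs)
    sd_t = rng.uniform(*config.sampling_sd_range, size=n_obs)
    n_lo, n_hi = config.replicate_range
    n_c = rng.integers(n_lo, n_hi + 1, size=n_obs)
    n_t = rng.integers(n_lo, n_hi + 1, size=n_obs)
    xc_true = rng.uniform(*config.control_mean_range, size=n_obs)

    eps_c = rng.standard_normal(n_obs) * sd_c / np.sqrt(n_c)
    eps_t = rng.standard_normal(n_obs) * sd_t / np.sqrt(n_t)
    mean_c = xc_true + eps_c
    if metric == "MD":
        mean_t = xc_true + theta + eps_t
    elif metric == "ROM":
        mean_t = xc_true * np.exp(theta) + eps_t
    else:  # SMD target: difference in pooled-SD units
        sd_p = np.sqrt(((n_t - 1) * sd_t**2 + (n_c - 1) * sd_c**2) / (n_t + n_c - 2))
        mean_t = xc_true + theta * sd_p + eps_t
    table["mean_c"] = mean_c
    table["mean_t"] = mean_t
    table["sd_c"] = sd_c
    table["sd_t"] = sd_t
    table["n_c"] = n_c
    table["n_t"] = n_t
    if config.missing_sd_fraction > 0:
        drop = rng.random(n_obs) < config.missing_sd_fraction
        # keep at least one reported pair so CV imputation stays possible
        if drop.all():
            drop[0] = False
        table.loc[drop, ["sd_c", "sd_t"]] = np.nan
    table["rom_valid"] = (table["mean_t"] > 0) & (table["mean_c"] > 0)

    truth = GroundTruth(
        true_beta={c: float(b) for c, b in zip(X.columns, beta)},
        tau2_true=tau2,
        rho_true=rho,
        scaling=scaling,
        spec=config.spec,
        true_effects=theta,
        study_effects=study_effects,
        seed=seed,
    )
    return table, truth


def generate_grid(
    config: SyntheticConfig, n_cells: int, seed: int | None = None
) -> pd.DataFrame:
    """Covariate grid cells with crop shares (summing <= 1) and area weights."""
    if n_cells < 1:
        raise ValidationError("n_cells must be >= 1")
    seed = config.seed if seed is None else int(seed)
    rng = np.random.default_rng(seed)
    cells = {
        "cell_id": [f"C{i:05d}" for i in range(n_cells)],
        "lat": np.round(rng.uniform(-55.75, 69.75, n_cells) * 2) / 2 + 0.25,
        "lon": np.round(rng.uniform(-179.75, 179.75, n_cells) * 2) / 2 + 0.25,
    }
    for name, (lo, hi) in config.covariate_ranges.items():
        cells[name] = rng.uniform(lo, hi, n_cells)
    raw = rng.dirichlet(np.ones(len(CROPS)), size=n_cells)
    total = rng.uniform(0.3, 1.0, n_cells)
    for j, crop in enumerate(CROPS):
        cells[f"share_{crop}"] = raw[:, j] * total
    cells["area_weight"] = rng.uniform(0.1, 1.0, n_cells)
    cells["region"] = np.array(["north", "south", "east", "west"])[
        rng.integers(0, 4, n_cells)
    ]
    return pd.DataFrame(cells)


def recovery_experiment(
    config: SyntheticConfig,
    n_replicates: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Monte Carlo fit-and-check: CI coverage per coefficient, tau2/rho bias.

    Each replicate draws a fresh corpus, computes effect sizes for the
    config's response metric, scales covariates with the ground-truth
    population scaling, fits the REML meta-regression, and scores whether
    each 95% Wald interval covers the true coefficient.  Recovery runs with
    fully reported sampling SDs (the generator's known-SD condition), so the
    effect-size variances entering the fit are exact and coverage checks the
    estimator rather than the imputation heuristic.
    """
    config = dataclasses.replace(config, missing_sd_fraction=0.0)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_replicates)
    cover: dict[str, int] = {}
    tau2_hats, rho_hats = [], []
    truth0 = None
    for rep_seed in seeds:
        table, truth = generate_observations(config, seed=int(rep_seed))
        truth0 = truth
        eff = compute_effect_sizes(table, config.spec.response_metric)
        merged = table.join(eff[["yi", "vi"]], how="inner")
        merged, _ = scale_covariates(
            merged, variables=list(truth.scaling.center), params=truth.scaling
        )
        y, v, X, ids = build_design(merged, config.spec)
        model = MetaRegression().fit(X, y, v=v, study_ids=ids)
        se = np.sqrt(np.diag(model.cov_beta_))
        lo = model.beta_ - 1.96 * se
        hi = model.beta_ + 1.96 * se
        for j, name in enumerate(model.column_names_):
            b = truth.true_beta[name]
            cover[name] = cover.get(name, 0) + int(lo[j] <= b <= hi[j])
        tau2_hats.append(model.tau2_)
        rho_hats.append(model.rho_)
    rows = [
        {
            "term": name,
            "true_beta": truth0.true_beta[name],
            "coverage": cover[name] / n_replicates,
        }
        for name in cover
    ]
    out = pd.DataFrame(rows)
    out.attrs["tau2_mean"] = float(np.mean(tau2_hats))
    out.attrs["tau2_true"] = config.tau2_true
    out.attrs["rho_mean"] = float(np.mean(rho_hats))
    out.attrs["rho_true"] = config.rho_true
    out.attrs["n_replicates"] = n_replicates
    return out
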