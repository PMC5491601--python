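"""Design-faithful synthetic data for both experimental blocks.

The generator emulates the study layout (12 SSA x ST conditions, 3 replicates,
t1 grid {6,12,24,36,48,72} h, t2 grid {6,12,24,48} h) with phenomenological
trends and known ground truth:

* zeta rises (becomes less negative) to a 24 h peak and falls after — a
  quadratic-in-log-time kernel peaking at 24 h — plus small linear SSA/ST
  condition effects and additive Gaussian replicate noise; defaults keep all
  values inside the observed -40..-20 mV window.
* mobility is zeta divided by a fixed Henry-type conversion constant.
* gamma relaxes from the condition's initial surface tension toward a common
  asymptote (surfactant-dosed media drift toward the untreated level as
  fermentation products accumulate).
* VFAs rise to a ~24 h maximum and decline slightly (a log-Gaussian kernel),
  with small ST effects on propionate and isovalerate.
* optional covariates: pH drifts slightly down, NDF digestibility saturates,
  ammonia-N accumulates.

There is no mechanistic fermentation kinetics here; trends are shape-matched
placeholders whose parameters are recorded in :class:`GroundTruth` so recovery
tests can check the pipeline against what generated the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigError
from .features import (
    FeatureConfig,
    IntegratedDataset,
    assemble_integrated_dataset,
)
from .io import (
    ExperimentDesign,
    TimeScale1Record,
    TimeScale2Record,
    VFA_NAMES,
)

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate_blocks",
    "generate_linear_ptml",
    "zeta_trend",
]

#: per-VFA (base, amplitude) of the time kernel, mM — calibrated so condition
#: means land in the printed concentration ranges
_VFA_BASE_AMP = {
    "c2": (4.0, 15.0),
    "c3": (3.3, 7.0),
    "c4": (2.7, 6.5),
    "ic4": (0.5, 0.8),
    "c5": (0.5, 0.8),
    "ic5": (0.8, 1.2),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design defaults plus trend/noise parameters (units in comments)."""

    design: ExperimentDesign = field(default_factory=ExperimentDesign)
    seed: int = 0

    # zeta trend: baseline + amp * (1 - ((ln t - ln peak)/width)^2)
    zeta_baseline: float = -34.5     # mV
    zeta_amp: float = 6.0            # mV
    zeta_peak_h: float = 24.0
    zeta_logwidth: float = 1.6
    zeta_ssa_coef: float = 1.2       # mV per m^2/g above the SSA mean
    zeta_st_coef: float = 0.05       # mV per mN/m above the ST mean
    zeta_noise_sd: float = 0.8       # mV

    conversion_k: float = 10.2308    # mV per 1e-8 m^2/V/s (mobility = zeta/k)

    # gamma relaxation toward a common asymptote
    gamma_asymptote: float = 46.0    # mN/m
    gamma_tau_h: float = 10.0
    gamma_mix: float = 0.8
    gamma_noise_sd: float = 0.8      # mN/m

    # optional covariates
    ph_baseline: float = 6.9
    ph_slope: float = -0.002         # per hour
    ph_noise_sd: float = 0.08
    d_max: float = 0.65              # NDF digestibility asymptote (fraction)
    d_half_h: float = 6.0
    d_noise_sd: float = 0.04
    nh3n_baseline: float = 12.0      # mg/dL
    nh3n_amp: float = 8.0
    nh3n_half_h: float = 8.0
    nh3n_noise_sd: float = 1.5

    # VFA kernel: base + amp * exp(-((ln t - ln peak)/width)^2)
    vfa_peak_h: float = 26.0
    vfa_logwidth: float = 1.0
    vfa_noise_frac: float = 0.05     # noise sd as a fraction of base + amp
    vfa_st_coef_c3: float = 0.02     # mM propionate per mN/m above ST mean
    vfa_st_coef_ic5: float = -0.01   # mM isovalerate per mN/m above ST mean

    def __post_init__(self):
        d = self.design
        if not (d.ssa_levels and d.st_levels and d.t1_grid and d.t2_grid
                and d.replicates >= 1):
            raise ConfigError("design must have non-empty levels and grids")
        if min(d.t1_grid) <= 0 or min(d.t2_grid) <= 0:
            raise ConfigError("time grids must be positive (log-time kernels)")
        for name in ("zeta_noise_sd", "gamma_noise_sd", "ph_noise_sd",
                     "d_noise_sd", "nh3n_noise_sd", "vfa_noise_frac"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """What generated a dataset: trend parameters and, when applicable, the
    additive-model coefficients used to write the target."""

    trend_params: Mapping[str, float]
    linear_coefficients: Mapping[str, float] | None = None


def zeta_trend(t: float, config: GeneratorConfig) -> float:
    """Noise-free, condition-free zeta trajectory (mV); peak at zeta_peak_h."""
    u = (math.log(t) - math.log(config.zeta_peak_h)) / config.zeta_logwidth
    return config.zeta_baseline + config.zeta_amp * (1.0 - u * u)


def _vfa_kernel(t: float, config: GeneratorConfig) -> float:
    u = (math.log(t) - math.log(config.vfa_peak_h)) / config.vfa_logwidth
    return math.exp(-u * u)


def _trend_params(config: GeneratorConfig) -> dict:
    skip = {"design", "seed"}
    return {k: v for k, v in asdict(config).items() if k not in skip}


def generate_blocks(
    config: GeneratorConfig = GeneratorConfig(),
) -> tuple[list[TimeScale1Record], list[TimeScale2Record], GroundTruth]:
    """Generate both blocks; bit-identical for a fixed config (seed included)."""
    rng = np.random.default_rng(config.seed)
    design = config.design
    ssa_mean = float(np.mean(design.ssa_levels))
    st_mean = float(np.mean(design.st_levels))

    t1_records: list[TimeScale1Record] = []
    for cond in design.conditions():
        cond_effect = (config.zeta_ssa_coef * (cond.ssa - ssa_mean)
                       + config.zeta_st_coef * (cond.st - st_mean))
        for rep in range(1, design.replicates + 1):
            for t in design.t1_grid:
                zeta = (zeta_trend(t, config) + cond_effect
                        + rng.normal(0.0, config.zeta_noise_sd))
                gamma = (cond.st
                         + (config.gamma_asymptote - cond.st) * config.gamma_mix
                         * (1.0 - math.exp(-t / config.gamma_tau_h))
                         + rng.normal(0.0, config.gamma_noise_sd))
                ph = (config.ph_baseline + config.ph_slope * t
                      + rng.normal(0.0, config.ph_noise_sd))
                dig = (config.d_max * t / (t + config.d_half_h)
                       + rng.normal(0.0, config.d_noise_sd))
                nh3n = (config.nh3n_baseline
                        + config.nh3n_amp * t / (t + config.nh3n_half_h)
                        + rng.normal(0.0, config.nh3n_noise_sd))
                t1_records.append(TimeScale1Record(
                    condition=cond, replicate=rep, t1=float(t),
                    mobility=zeta / config.conversion_k, zeta=zeta,
                    gamma=gamma, ph=ph,
                    digestibility=min(max(dig, 0.0), 1.0),
                    nh3n=max(nh3n, 0.0),
                ))

    t2_records: list[TimeScale2Record] = []
    for cond in design.conditions():
        st_dev = cond.st - st_mean
        for rep in range(1, design.replicates + 1):
            for t in design.t2_grid:
                kern = _vfa_kernel(t, config)
                vfa = []
                for name in VFA_NAMES:
                    base, amp = _VFA_BASE_AMP[name]
                    level = base + amp * kern
                    if name == "c3":
                        level += config.vfa_st_coef_c3 * st_dev
                    elif name == "ic5":
                        level += config.vfa_st_coef_ic5 * st_dev
                    level += rng.normal(
                        0.0, config.vfa_noise_frac * (base + amp))
                    vfa.append(max(level, 0.0))
                t2_records.append(TimeScale2Record(
                    condition=cond, replicate=rep, t2=float(t), vfa=tuple(vfa),
                ))

    return t1_records, t2_records, GroundTruth(trend_params=_trend_params(config))


def generate_linear_ptml(
    config: GeneratorConfig = GeneratorConfig(),
    coefficients: Mapping[str, float] | Sequence[float] | None = None,
    noise_sd: float = 0.0,
    interaction: tuple[str, str, float] | None = None,
    feature_config: FeatureConfig | None = None,
) -> tuple[IntegratedDataset, GroundTruth]:
    """An integrated dataset whose target follows the additive model exactly.

    Features are built by the real featurization pipeline on generated blocks;
    the target is then overwritten with

        intercept + sum_j beta_j * x_j [+ c * x_a * x_b] + N(0, noise_sd)

    so the linear fit is correctly specified by construction (and misspecified
    exactly by the optional interaction term).  ``coefficients`` maps
    'intercept' and manifest feature names to values (missing names mean 0);
    a bare sequence must have length p+1, intercept first.  Default: intercept
    0, weight 1 on zeta_em, small weights on the time and delta inputs.
    """
    if noise_sd < 0:
        raise ConfigError("noise_sd must be >= 0")
    t1_records, t2_records, _ = generate_blocks(config)
    dataset = assemble_integrated_dataset(t1_records, t2_records, feature_config)
    manifest = dataset.manifest
    p = len(manifest)

    if coefficients is None:
        coef_map = {"intercept": 0.0, "zeta_em": 1.0}
        coef_map.update({name: 0.2 for name in manifest if name.startswith("delta_")})
        coef_map.update({"t1_h": 0.01, "t2_h": 0.01})
    elif isinstance(coefficients, Mapping):
        unknown = set(coefficients) - set(manifest) - {"intercept"}
        if unknown:
            raise ConfigError(f"coefficients for unknown features: {sorted(unknown)}")
        coef_map = dict(coefficients)
    else:
        if len(coefficients) != p + 1:
            raise ConfigError(
                f"coefficient vector length {len(coefficients)} != 1 + {p} "
                f"(intercept + manifest)"
            )
        coef_map = {"intercept": float(coefficients[0])}
        coef_map.update(
            {name: float(c) for name, c in zip(manifest, coefficients[1:])}
        )

    beta = np.array([coef_map.get(name, 0.0) for name in manifest])
    X = dataset.X
    target = coef_map.get("intercept", 0.0) + X @ beta
    if interaction is not None:
        name_a, name_b, c = interaction
        for nm in (name_a, name_b):
            if nm not in manifest:
                raise ConfigError(f"interaction feature '{nm}' not in manifest")
        target = target + c * X[:, manifest.index(name_a)] * X[:, manifest.index(name_b)]
        coef_map[f"{name_a}*{name_b}"] = c
    rng = np.random.default_rng(config.seed + 1)
    target = target + rng.normal(0.0, noise_sd, size=len(target))

    truth = GroundTruth(
        trend_params=_trend_params(config),
        linear_coefficients=coef_map,
    )
    return dataset.with_target(target), truth
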