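"""Perturbation-theory featurization over two time scales.

The model treats every measured case as "an expected value plus a
perturbation".  For each variable V measured under combinatorial condition c
(an SSA x ST level pair), the moving-average (Box-Jenkins) operator is

    dV(t_k) = V(t_k) - <V(t_k)>

where <V(t_k)> is the mean of V over all replicates and time points of the
same condition.  Condition-constant treatment factors (SSA, ST) would have
identically zero within-condition deltas, so they are centred on the grand
mean instead, which keeps them informative.

The response enters twice, both times standardized by the mean and (sample)
standard deviation of zeta over the whole t1 block:

* the expected-measurement input ``zeta_em`` — the z-score of the case's
  condition-mean zeta (the "known solution" the perturbations correct), and
* the regression target — the z-score of the observed zeta.

Because the two blocks are sampled on different grids (t1: electrokinetics,
gamma, optional covariates; t2: the six VFAs), a modelling case is an ordered
pair (t1 case, t2 case): the full Cartesian product of the blocks, t1-major.
The default 15-input manifest is

    zeta_em, t1_h, delta_ssa, delta_st, delta_d, delta_nh3n, delta_ph,
    delta_gamma, t2_h, delta_c2, delta_c3, delta_c4, delta_ic4, delta_c5,
    delta_ic5

shrinking to 12 when the optional covariates (digestibility, ammonia-N, pH)
are absent from the t1 block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateInputError,
    FeatureError,
    SplitError,
)
from .io import (
    Condition,
    TimeScale1Record,
    TimeScale2Record,
    VFA_NAMES,
)

__all__ = [
    "ConditionExpectation",
    "StandardizationParams",
    "FeatureConfig",
    "IntegratedDataset",
    "condition_means",
    "box_jenkins_delta",
    "standardize_zeta",
    "expected_measurement",
    "assemble_integrated_dataset",
    "split_train_validation",
    "WITHIN_CONDITION",
    "GRAND_MEAN",
]

WITHIN_CONDITION = "within-condition"
GRAND_MEAN = "grand-mean"

#: t1-block variables addressable by name
_T1_VARIABLES = {
    "ssa": lambda r: r.condition.ssa,
    "st": lambda r: r.condition.st,
    "zeta": lambda r: r.zeta,
    "mobility": lambda r: r.mobility,
    "gamma": lambda r: r.gamma,
    "ph": lambda r: r.ph,
    "digestibility": lambda r: r.digestibility,
    "nh3n": lambda r: r.nh3n,
}

_OPTIONAL_T1 = ("digestibility", "nh3n", "ph")

#: (feature name, variable name) for the t1 delta block, manifest order
_T1_DELTA_FEATURES = (
    ("delta_ssa", "ssa"),
    ("delta_st", "st"),
    ("delta_d", "digestibility"),
    ("delta_nh3n", "nh3n"),
    ("delta_ph", "ph"),
    ("delta_gamma", "gamma"),
)

_T2_DELTA_FEATURES = tuple((f"delta_{v}", v) for v in VFA_NAMES)


def _values(records: Sequence, variable: str) -> np.ndarray:
    if records and isinstance(records[0], TimeScale2Record):
        if variable not in VFA_NAMES:
            raise FeatureError(f"variable '{variable}' not in the t2 block")
        idx = VFA_NAMES.index(variable)
        vals = [r.vfa[idx] for r in records]
    else:
        try:
            getter = _T1_VARIABLES[variable]
        except KeyError:
            raise FeatureError(f"unknown variable '{variable}'") from None
        vals = [getter(r) for r in records]
    if any(v is None for v in vals):
        raise FeatureError(f"variable '{variable}' is missing from some records")
    return np.asarray(vals, dtype=float)


@dataclass(frozen=True)
class ConditionExpectation:
    """Expected values <V> of one variable, per condition or globally."""

    variable: str
    grouping: str
    means: Mapping[Condition, float] | None = None   # within-condition mode
    grand: float | None = None                       # grand-mean mode

    def expected(self, condition: Condition) -> float:
        if self.grouping == GRAND_MEAN:
            return self.grand
        try:
            return self.means[condition]
        except KeyError:
            raise FeatureError(
                f"condition {condition} not covered by the expectation "
                f"for '{self.variable}'"
            ) from None


def condition_means(
    records: Sequence,
    variable: str,
    grouping: str = WITHIN_CONDITION,
) -> ConditionExpectation:
    """Moving-average expectations <V>: per-condition (or grand) arithmetic
    means over all replicates and time points."""
    vals = _values(records, variable)
    if grouping == GRAND_MEAN:
        return ConditionExpectation(variable, grouping, grand=float(vals.mean()))
    if grouping != WITHIN_CONDITION:
        raise FeatureError(f"unknown grouping '{grouping}'")
    sums: dict[Condition, list] = {}
    for rec, v in zip(records, vals):
        sums.setdefault(rec.condition, []).append(v)
    means = {cond: float(np.mean(v)) for cond, v in sums.items()}
    return ConditionExpectation(variable, grouping, means=means)


def box_jenkins_delta(
    value: float, condition: Condition, expectation: ConditionExpectation
) -> float:
    """The perturbation dV = V - <V> of one measurement."""
    return float(value) - expectation.expected(condition)


@dataclass(frozen=True)
class StandardizationParams:
    """Mean/sd of zeta over a block (sample sd, n-1 denominator)."""

    mean: float
    sd: float

    def __post_init__(self):
        if not self.sd > 0:
            raise DegenerateInputError("standardization requires sd > 0")

    def zscore(self, x):
        return (np.asarray(x, dtype=float) - self.mean) / self.sd


def standardize_zeta(
    records: Sequence[TimeScale1Record],
) -> tuple[StandardizationParams, np.ndarray]:
    """Z-score all zeta values of a block against the block mean and sd."""
    vals = _values(records, "zeta")
    if len(vals) < 2 or np.ptp(vals) == 0.0:
        raise DegenerateInputError(
            "standardization needs at least two distinct zeta values"
        )
    params = StandardizationParams(mean=float(vals.mean()),
                                   sd=float(vals.std(ddof=1)))
    return params, params.zscore(vals)


def expected_measurement(
    t1_records: Sequence[TimeScale1Record],
    std: StandardizationParams,
) -> dict[Condition, float]:
    """The EM input zeta_em: z-score of each condition's mean zeta."""
    exp = condition_means(t1_records, "zeta", WITHIN_CONDITION)
    return {cond: float(std.zscore(m)) for cond, m in exp.means.items()}


@dataclass(frozen=True)
class FeatureConfig:
    """Controls which inputs enter the integrated dataset.

    include_optional: force the digestibility/ammonia-N/pH deltas in (True),
        out (False) or include them iff present on every t1 record (None).
    grouping_overrides: per-variable override of the centring mode.
    condition_matched: restrict the cross-scale pairing to pairs from the same
        condition instead of the full Cartesian product (off by default; only
        the unrestricted product reproduces the published case arithmetic).
    """

    include_optional: bool | None = None
    grouping_overrides: Mapping[str, str] = field(default_factory=dict)
    condition_matched: bool = False

    def grouping(self, variable: str) -> str:
        default = GRAND_MEAN if variable in ("ssa", "st") else WITHIN_CONDITION
        return self.grouping_overrides.get(variable, default)


@dataclass(frozen=True)
class IntegratedDataset:
    """The cross-scale modelling dataset.

    ``frame`` holds one row per (t1 case, t2 case) pair with manifest-ordered
    feature columns, the standardized target, and integer provenance columns
    ``t1_case`` / ``t2_case`` (0-based row indices into the source blocks).
    """

    frame: pd.DataFrame
    manifest: tuple[str, ...]
    standardization: StandardizationParams

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def X(self) -> np.ndarray:
        return self.frame[list(self.manifest)].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.frame["target"].to_numpy(dtype=float)

    def subset(self, indices) -> "IntegratedDataset":
        return IntegratedDataset(
            frame=self.frame.iloc[np.asarray(indices)].reset_index(drop=True),
            manifest=self.manifest,
            standardization=self.standardization,
        )

    def with_target(self, target: np.ndarray) -> "IntegratedDataset":
        frame = self.frame.copy()
        frame["target"] = np.asarray(target, dtype=float)
        return IntegratedDataset(frame, self.manifest, self.standardization)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def save(self, path) -> None:
        """CSV export plus a JSON sidecar (manifest + standardization)."""
        import json
        from pathlib import Path

        path = Path(path)
        self.to_csv(path)
        meta = {
            "manifest": list(self.manifest),
            "standardization": {
                "mean": self.standardization.mean,
                "sd": self.standardization.sd,
            },
        }
        path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path) -> "IntegratedDataset":
        import json
        from pathlib import Path

        path = Path(path)
        frame = pd.read_csv(path)
        meta_path = path.with_suffix(".meta.json")
        if meta_path.exists():
            meta = json.loads(meta_path.read_text())
            manifest = tuple(meta["manifest"])
            std = StandardizationParams(**meta["standardization"])
        else:
            manifest = tuple(
                c for c in frame.columns
                if c not in ("target", "t1_case", "t2_case")
            )
            t = frame["target"]
            std = StandardizationParams(mean=float(t.mean()), sd=float(t.std(ddof=1)))
        return cls(frame=frame, manifest=manifest, standardization=std)


def _optional_available(t1_records, config: FeatureConfig) -> bool:
    present = all(
        all(_T1_VARIABLES[v](r) is not None for v in _OPTIONAL_T1)
        for r in t1_records
    )
    if config.include_optional is None:
        return present
    if config.include_optional and not present:
        raise FeatureError(
            "optional covariates (digestibility, nh3n, ph) requested but "
            "missing from the t1 block"
        )
    return config.include_optional


def assemble_integrated_dataset(
    t1_records: Sequence[TimeScale1Record],
    t2_records: Sequence[TimeScale2Record],
    config: FeatureConfig | None = None,
) -> IntegratedDataset:
    """Build the Cartesian dual-time-scale dataset (t1-major ordering)."""
    config = config or FeatureConfig()
    if not t1_records or not t2_records:
        raise FeatureError("cannot assemble dataset from an empty block")

    with_optional = _optional_available(t1_records, config)
    t1_features = [
        (f, v) for f, v in _T1_DELTA_FEATURES
        if with_optional or v not in _OPTIONAL_T1
    ]
    manifest = (
        ("zeta_em", "t1_h")
        + tuple(f for f, _ in t1_features)
        + ("t2_h",)
        + tuple(f for f, _ in _T2_DELTA_FEATURES)
    )

    std, z_target = standardize_zeta(t1_records)
    em = expected_measurement(t1_records, std)

    n1, n2 = len(t1_records), len(t2_records)
    t1_part = np.empty((n1, 2 + len(t1_features)))
    t1_part[:, 0] = [em[r.condition] for r in t1_records]
    t1_part[:, 1] = [r.t1 for r in t1_records]
    for j, (_, var) in enumerate(t1_features):
        exp = condition_means(t1_records, var, config.grouping(var))
        vals = _values(t1_records, var)
        t1_part[:, 2 + j] = [
            box_jenkins_delta(v, r.condition, exp)
            for v, r in zip(vals, t1_records)
        ]

    t2_part = np.empty((n2, 1 + len(_T2_DELTA_FEATURES)))
    t2_part[:, 0] = [r.t2 for r in t2_records]
    for j, (_, var) in enumerate(_T2_DELTA_FEATURES):
        exp = condition_means(t2_records, var, config.grouping(var))
        vals = _values(t2_records, var)
        t2_part[:, 1 + j] = [
            box_jenkins_delta(v, r.condition, exp)
            for v, r in zip(vals, t2_records)
        ]

    X = np.hstack([np.repeat(t1_part, n2, axis=0), np.tile(t2_part, (n1, 1))])
    idx1 = np.repeat(np.arange(n1), n2)
    idx2 = np.tile(np.arange(n2), n1)
    target = np.repeat(z_target, n2)

    if config.condition_matched:
        match = np.array([
            t1_records[i].condition == t2_records[j].condition
            for i, j in zip(idx1, idx2)
        ])
        X, idx1, idx2, target = X[match], idx1[match], idx2[match], target[match]

    if not np.all(np.isfinite(X)):
        raise FeatureError("non-finite feature values in assembled dataset")

    frame = pd.DataFrame(X, columns=list(manifest))
    frame["target"] = target
    frame["t1_case"] = idx1
    frame["t2_case"] = idx2
    return IntegratedDataset(frame=frame, manifest=manifest, standardization=std)


def split_train_validation(
    dataset: IntegratedDataset,
    ratio: float = 0.75,
    seed: int = 0,
) -> tuple[IntegratedDataset, IntegratedDataset]:
    """Disjoint, exhaustive random split; |train| = round(ratio * n)."""
    n = dataset.n
    if n < 4:
        raise SplitError(f"need at least 4 cases to split, got {n}")
    n_train = int(round(ratio * n))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train_idx = np.sort(perm[:n_train])
    val_idx = np.sort(perm[n_train:])
    return dataset.subset(train_idx), dataset.subset(val_idx)
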