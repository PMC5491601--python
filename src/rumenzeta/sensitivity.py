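"""Per-input sensitivity (Var Ratio) analysis.

The Var Ratio of an input is the ratio of the model's root-mean-squared error
when that input is neutralized — replaced, for every case of the evaluation
subset, by its subset mean — to the unperturbed RMSE.  A ratio near 1 marks an
input the model does not use; the larger the ratio, the more the model's
accuracy depends on the input.  Ranks order inputs by descending ratio, ties
broken by manifest order.

Mean-substitution is one of several conventions for this statistic; it is the
one this package implements and documents, evaluated on the training subset by
default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, PredictionError
from .features import IntegratedDataset

__all__ = ["SensitivityReport", "variable_ratio", "rank_variables"]


def _eval_arrays(model, subset: IntegratedDataset):
    missing = [c for c in model.manifest if c not in subset.frame.columns]
    if missing:
        raise PredictionError(f"dataset lacks model features: {missing}")
    X = subset.frame[list(model.manifest)].to_numpy(dtype=float)
    return X, subset.y


def _rmse(model, X, y) -> float:
    pred = model.predict(X)
    return float(np.sqrt(np.mean((y - pred) ** 2)))


def variable_ratio(model, subset: IntegratedDataset, input_name: str) -> float:
    """RMSE(input replaced by its subset mean) / RMSE(baseline)."""
    if input_name not in model.manifest:
        raise PredictionError(
            f"'{input_name}' is not a model input {model.manifest}"
        )
    X, y = _eval_arrays(model, subset)
    baseline = _rmse(model, X, y)
    if baseline == 0.0:
        raise DegenerateInputError(
            "baseline error is zero (perfect model); Var Ratio undefined"
        )
    j = model.manifest.index(input_name)
    Xp = X.copy()
    Xp[:, j] = X[:, j].mean()
    return _rmse(model, Xp, y) / baseline


@dataclass(frozen=True)
class SensitivityReport:
    """Var Ratios for every model input, with ranks (1 = most important)."""

    table: pd.DataFrame          # index: input name; columns: var_ratio, rank
    baseline_rmse: float

    def ratios(self) -> dict[str, float]:
        return self.table["var_ratio"].to_dict()

    def to_csv(self, path) -> None:
        # one row per model, inputs as columns — the published table shape
        row = self.table["var_ratio"]
        pd.DataFrame([row.to_dict()], index=["var_ratio"]).to_csv(path)


def rank_variables(model, subset: IntegratedDataset) -> SensitivityReport:
    """Var Ratios of all inputs on one subset, ranked descending."""
    X, y = _eval_arrays(model, subset)
    baseline = _rmse(model, X, y)
    if baseline == 0.0:
        raise DegenerateInputError(
            "baseline error is zero (perfect model); Var Ratio undefined"
        )
    means = X.mean(axis=0)
    ratios = []
    for j, name in enumerate(model.manifest):
        Xp = X.copy()
        Xp[:, j] = means[j]
        ratios.append(_rmse(model, Xp, y) / baseline)
    ratios = np.asarray(ratios)
    # stable sort on -ratio => ties keep manifest order
    order = np.argsort(-ratios, kind="stable")
    rank = np.empty(len(ratios), dtype=int)
    rank[order] = np.arange(1, len(ratios) + 1)
    table = pd.DataFrame(
        {"var_ratio": ratios, "rank": rank},
        index=list(model.manifest),
    )
    return SensitivityReport(table=table, baseline_rmse=baseline)
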