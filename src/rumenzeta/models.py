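"""The three regression families compared on the integrated dataset.

* LNN — an affine model in the 15 perturbation inputs, fitted by pseudo-inverse
  (minimum-norm linear least squares).  This is the additive
  perturbation-theory model proper: target = a0 + a1*zeta_em + sum_q b_q*dV_q(t1)
  + sum_f c_f*dV_f(t2).
* MLP — one logistic-sigmoid hidden layer with a linear output, trained in two
  phases: plain gradient-descent backpropagation, then Polak-Ribiere conjugate
  gradient refinement.
* RBF — Gaussian hidden units whose centers come from k-means on the inputs,
  widths from the mean distance to each center's k nearest neighbour centers,
  and a linear output layer solved by pseudo-inverse.

All fits are deterministic given a seed.  Inputs are optionally z-scaled using
constants stored on the model (default: on for MLP/RBF, off for the linear
model); predictions always apply the stored constants, so a serialized model
is self-contained.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

from .errors import DegenerateInputError, FitError, PredictionError
from .features import IntegratedDataset

__all__ = [
    "Preprocessing",
    "LinearModel",
    "MLPModel",
    "RBFModel",
    "SubsetStats",
    "FitReport",
    "fit_linear",
    "fit_mlp",
    "fit_rbf",
    "predict",
    "fit_report",
    "select_best_model",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# shared plumbing


@dataclass(frozen=True)
class Preprocessing:
    """Per-feature z-scaling constants applied before the model proper."""

    means: tuple[float, ...] | None = None
    sds: tuple[float, ...] | None = None

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.means is None:
            return X
        return (X - np.asarray(self.means)) / np.asarray(self.sds)

    @staticmethod
    def fit(X: np.ndarray) -> "Preprocessing":
        sds = X.std(axis=0, ddof=0)
        sds = np.where(sds > 0, sds, 1.0)  # constant columns pass through
        return Preprocessing(means=tuple(X.mean(axis=0)), sds=tuple(sds))


def _design(data, manifest: Sequence[str] | None):
    """Extract (X, y, manifest) from an IntegratedDataset, restricted to
    ``manifest`` columns when given."""
    if isinstance(data, IntegratedDataset):
        names = tuple(manifest) if manifest is not None else data.manifest
        missing = [c for c in names if c not in data.frame.columns]
        if missing:
            raise PredictionError(f"features missing from dataset: {missing}")
        X = data.frame[list(names)].to_numpy(dtype=float)
        return X, data.y, names
    X, y = data
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    names = tuple(manifest) if manifest is not None else tuple(
        f"x{i}" for i in range(X.shape[1])
    )
    return X, np.asarray(y, dtype=float), names


def _model_inputs(model, data) -> np.ndarray:
    if isinstance(data, IntegratedDataset):
        missing = [c for c in model.manifest if c not in data.frame.columns]
        if missing:
            raise PredictionError(
                f"dataset lacks features required by the model: {missing}"
            )
        X = data.frame[list(model.manifest)].to_numpy(dtype=float)
    else:
        X = np.asarray(data, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[1] != len(model.manifest):
            raise PredictionError(
                f"expected {len(model.manifest)} features "
                f"({model.manifest}), got {X.shape[1]}"
            )
    return model.preprocessing.transform(X)


# ---------------------------------------------------------------------------
# linear (pseudo-inverse)


@dataclass(frozen=True)
class LinearModel:
    """Affine perturbation model; coefficients align with ``manifest``."""

    intercept: float
    coef: tuple[float, ...]
    manifest: tuple[str, ...]
    preprocessing: Preprocessing = Preprocessing()
    rank: int | None = None

    def predict(self, data) -> np.ndarray:
        X = _model_inputs(self, data)
        return self.intercept + X @ np.asarray(self.coef)


def fit_linear(
    data,
    manifest: Sequence[str] | None = None,
    standardize_inputs: bool = False,
) -> LinearModel:
    """Minimum-norm least squares via pseudo-inverse.

    Requires more cases than features; a rank-deficient design is solved (and
    logged) rather than rejected, matching pseudo-inverse behaviour.
    """
    X, y, names = _design(data, manifest)
    n, p = X.shape
    if n <= p:
        raise FitError(f"need n > p to fit the linear model (n={n}, p={p})")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise FitError("non-finite values in the training data")
    prep = Preprocessing.fit(X) if standardize_inputs else Preprocessing()
    Xp = prep.transform(X)
    A = np.column_stack([np.ones(n), Xp])
    beta, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < p + 1:
        logger.warning(
            "rank-deficient design (rank %d < %d); minimum-norm solution used",
            rank, p + 1,
        )
    return LinearModel(
        intercept=float(beta[0]),
        coef=tuple(float(b) for b in beta[1:]),
        manifest=names,
        preprocessing=prep,
        rank=int(rank),
    )


# ---------------------------------------------------------------------------
# multilayer perceptron


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class MLPModel:
    """One-hidden-layer perceptron with logistic hidden units, linear output."""

    w1: np.ndarray          # (hidden, p)
    b1: np.ndarray          # (hidden,)
    w2: np.ndarray          # (hidden,)
    b2: float
    manifest: tuple[str, ...]
    preprocessing: Preprocessing
    loss_trace: tuple[tuple[str, int, float], ...] = ()

    def predict(self, data) -> np.ndarray:
        X = _model_inputs(self, data)
        return _sigmoid(X @ self.w1.T + self.b1) @ self.w2 + self.b2


def _mlp_pack(w1, b1, w2, b2):
    return np.concatenate([w1.ravel(), b1, w2, [b2]])


def _mlp_unpack(theta, hidden, p):
    w1 = theta[: hidden * p].reshape(hidden, p)
    b1 = theta[hidden * p: hidden * p + hidden]
    w2 = theta[hidden * p + hidden: hidden * p + 2 * hidden]
    b2 = theta[-1]
    return w1, b1, w2, b2


def _mlp_loss_grad(theta, X, y, hidden):
    # overflow here just signals divergence, which the caller reports
    with np.errstate(over="ignore", invalid="ignore"):
        n, p = X.shape
        w1, b1, w2, b2 = _mlp_unpack(theta, hidden, p)
        h = _sigmoid(X @ w1.T + b1)           # (n, hidden)
        pred = h @ w2 + b2
        err = pred - y
        loss = float(err @ err) / n
        # d loss / d pred = 2 err / n
        gpred = 2.0 * err / n
        gw2 = h.T @ gpred
        gb2 = float(gpred.sum())
        gh = np.outer(gpred, w2) * h * (1.0 - h)   # (n, hidden)
        gw1 = gh.T @ X
        gb1 = gh.sum(axis=0)
        return loss, _mlp_pack(gw1, gb1, gw2, gb2)


def fit_mlp(
    data,
    hidden: int = 5,
    epochs_bp: int = 100,
    epochs_cg: int = 500,
    learning_rate: float = 0.01,
    momentum: float = 0.9,
    seed: int = 0,
    manifest: Sequence[str] | None = None,
    standardize_inputs: bool = True,
) -> MLPModel:
    """Backpropagation (fixed-rate gradient descent with momentum) followed by
    Polak-Ribiere conjugate-gradient refinement of the same MSE loss."""
    if hidden < 1:
        raise FitError("need at least one hidden unit")
    X, y, names = _design(data, manifest)
    prep = Preprocessing.fit(X) if standardize_inputs else Preprocessing()
    Xp = prep.transform(X)
    n, p = Xp.shape

    rng = np.random.default_rng(seed)
    scale = 1.0 / np.sqrt(p)
    theta = _mlp_pack(
        rng.normal(0.0, scale, size=(hidden, p)),
        np.zeros(hidden),
        rng.normal(0.0, 1.0 / np.sqrt(hidden), size=hidden),
        0.0,
    )

    trace: list[tuple[str, int, float]] = []
    velocity = np.zeros_like(theta)
    for epoch in range(epochs_bp):
        loss, grad = _mlp_loss_grad(theta, Xp, y, hidden)
        if not np.isfinite(loss):
            raise FitError(
                "MLP training diverged (non-finite loss); try a smaller "
                "learning rate"
            )
        trace.append(("bp", epoch, loss))
        velocity = momentum * velocity - learning_rate * grad
        theta = theta + velocity

    if epochs_cg > 0:
        start_loss, _ = _mlp_loss_grad(theta, Xp, y, hidden)
        trace.append(("cg", 0, start_loss))

        def record(tk):
            loss_k, _ = _mlp_loss_grad(tk, Xp, y, hidden)
            trace.append(("cg", len([t for t in trace if t[0] == "cg"]), loss_k))

        res = minimize(
            _mlp_loss_grad, theta, args=(Xp, y, hidden), jac=True,
            method="CG", callback=record,
            options={"maxiter": epochs_cg, "gtol": 1e-12},
        )
        if not np.all(np.isfinite(res.x)):
            raise FitError("MLP conjugate-gradient phase produced non-finite weights")
        if res.fun <= start_loss:
            theta = res.x

    w1, b1, w2, b2 = _mlp_unpack(theta, hidden, p)
    return MLPModel(
        w1=w1, b1=b1, w2=w2, b2=float(b2),
        manifest=names, preprocessing=prep, loss_trace=tuple(trace),
    )


# ---------------------------------------------------------------------------
# radial basis functions


@dataclass(frozen=True)
class RBFModel:
    """Gaussian RBF network: k-means centers, kNN widths, linear output."""

    centers: np.ndarray      # (k, p) in preprocessed space
    widths: np.ndarray       # (k,)
    weights: np.ndarray      # (k,)
    bias: float
    manifest: tuple[str, ...]
    preprocessing: Preprocessing

    @property
    def hidden_units(self) -> int:
        return len(self.centers)

    def _activations(self, Xp: np.ndarray) -> np.ndarray:
        d2 = cdist(Xp, self.centers, "sqeuclidean")
        return np.exp(-d2 / (2.0 * self.widths**2))

    def predict(self, data) -> np.ndarray:
        Xp = _model_inputs(self, data)
        return self._activations(Xp) @ self.weights + self.bias


def _kmeans(X: np.ndarray, k: int, rng: np.random.Generator,
            max_iter: int = 100, tol: float = 1e-6) -> np.ndarray:
    """Lloyd's algorithm with seeded k-means++ initialization.

    Empty clusters are reseeded to the point farthest from its center.
    """
    n = len(X)
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = ((X - centers[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total > 0:
            centers[j] = X[rng.choice(n, p=d2 / total)]
        else:
            centers[j] = X[rng.integers(n)]
        d2 = np.minimum(d2, ((X - centers[j]) ** 2).sum(axis=1))

    for _ in range(max_iter):
        dist = cdist(X, centers, "sqeuclidean")
        labels = dist.argmin(axis=1)
        new_centers = centers.copy()
        for j in range(k):
            members = labels == j
            if members.any():
                new_centers[j] = X[members].mean(axis=0)
            else:
                new_centers[j] = X[dist.min(axis=1).argmax()]
        shift = float(np.abs(new_centers - centers).max())
        centers = new_centers
        if shift < tol:
            break
    return centers


def _rbf_widths(centers: np.ndarray, knn_k: int, floor: float = 1e-6) -> np.ndarray:
    k = len(centers)
    if k == 1:
        return np.array([1.0])
    D = cdist(centers, centers)
    np.fill_diagonal(D, np.inf)
    kk = min(knn_k, k - 1)
    nearest = np.sort(D, axis=1)[:, :kk]
    widths = nearest.mean(axis=1)
    if np.any(widths < floor):
        logger.warning("near-duplicate k-means centers; widths floored at %g", floor)
    return np.maximum(widths, floor)


def fit_rbf(
    data,
    hidden: int,
    knn_k: int = 2,
    seed: int = 0,
    manifest: Sequence[str] | None = None,
    standardize_inputs: bool = True,
    kmeans_max_iter: int = 100,
) -> RBFModel:
    """K-means centers, k-nearest-neighbour widths, pseudo-inverse output."""
    if knn_k < 1:
        raise FitError("knn_k must be >= 1")
    X, y, names = _design(data, manifest)
    n = len(X)
    if hidden > n:
        raise FitError(f"hidden units ({hidden}) exceed training cases ({n})")
    if hidden < 1:
        raise FitError("need at least one hidden unit")
    prep = Preprocessing.fit(X) if standardize_inputs else Preprocessing()
    Xp = prep.transform(X)

    rng = np.random.default_rng(seed)
    centers = _kmeans(Xp, hidden, rng, max_iter=kmeans_max_iter)
    widths = _rbf_widths(centers, knn_k)

    d2 = cdist(Xp, centers, "sqeuclidean")
    phi = np.exp(-d2 / (2.0 * widths**2))
    A = np.column_stack([phi, np.ones(n)])
    beta, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    return RBFModel(
        centers=centers, widths=widths,
        weights=beta[:-1], bias=float(beta[-1]),
        manifest=names, preprocessing=prep,
    )


# ---------------------------------------------------------------------------
# prediction & reporting


def predict(model, data) -> np.ndarray:
    """Apply any fitted model (with its stored preprocessing) to cases."""
    return model.predict(data)


@dataclass(frozen=True)
class SubsetStats:
    """Table-3-style statistics for one subset."""

    correlation: float
    sd_observed: float
    error_mean: float
    error_sd: float
    n: int
    degenerate: bool = False


@dataclass(frozen=True)
class FitReport:
    training: SubsetStats
    validation: SubsetStats | None = None

    def to_frame(self):
        import pandas as pd

        rows = [("T", self.training)]
        if self.validation is not None:
            rows.append(("V", self.validation))
        return pd.DataFrame([
            {
                "subset": tag,
                "correlation": s.correlation,
                "sd_observed": s.sd_observed,
                "error_mean": s.error_mean,
                "error_sd": s.error_sd,
                "n": s.n,
            }
            for tag, s in rows
        ])


def _subset_stats(model, data) -> SubsetStats:
    if isinstance(data, IntegratedDataset):
        pred = model.predict(data)
        y = data.y
    else:
        X, y = data
        pred = model.predict(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float)
    err = y - pred  # error = observed - predicted
    degenerate = bool(np.ptp(pred) == 0.0 or np.ptp(y) == 0.0)
    if degenerate:
        corr = 0.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            corr = float(np.corrcoef(pred, y)[0, 1])
    return SubsetStats(
        correlation=corr,
        sd_observed=float(np.std(y, ddof=1)) if len(y) > 1 else 0.0,
        error_mean=float(err.mean()),
        error_sd=float(np.std(err, ddof=1)) if len(err) > 1 else 0.0,
        n=len(y),
        degenerate=degenerate,
    )


def fit_report(model, training, validation=None) -> FitReport:
    """Pearson correlation (predicted vs observed), observed sd, and the mean
    and sd of error = observed - predicted, per subset."""
    if (isinstance(training, IntegratedDataset) and training.n == 0) or (
        validation is not None
        and isinstance(validation, IntegratedDataset)
        and validation.n == 0
    ):
        raise DegenerateInputError("fit_report requires non-empty subsets")
    return FitReport(
        training=_subset_stats(model, training),
        validation=None if validation is None else _subset_stats(model, validation),
    )


def select_best_model(reports: dict) -> str:
    """Table-3-style family comparison: highest validation correlation wins."""
    if not reports:
        raise DegenerateInputError("no fit reports to compare")
    return max(
        reports,
        key=lambda k: (
            reports[k].validation.correlation
            if reports[k].validation is not None
            else reports[k].training.correlation
        ),
    )


# ---------------------------------------------------------------------------
# serialization


def _prep_dict(prep: Preprocessing):
    return {"means": prep.means and list(prep.means),
            "sds": prep.sds and list(prep.sds)}


def _prep_from(d) -> Preprocessing:
    return Preprocessing(
        means=None if d["means"] is None else tuple(d["means"]),
        sds=None if d["sds"] is None else tuple(d["sds"]),
    )


def model_to_dict(model) -> dict:
    if isinstance(model, LinearModel):
        return {
            "family": "linear",
            "manifest": list(model.manifest),
            "preprocessing": _prep_dict(model.preprocessing),
            "intercept": model.intercept,
            "coef": list(model.coef),
        }
    if isinstance(model, MLPModel):
        return {
            "family": "mlp",
            "manifest": list(model.manifest),
            "preprocessing": _prep_dict(model.preprocessing),
            "w1": model.w1.tolist(), "b1": model.b1.tolist(),
            "w2": model.w2.tolist(), "b2": model.b2,
        }
    if isinstance(model, RBFModel):
        return {
            "family": "rbf",
            "manifest": list(model.manifest),
            "preprocessing": _prep_dict(model.preprocessing),
            "centers": model.centers.tolist(), "widths": model.widths.tolist(),
            "weights": model.weights.tolist(), "bias": model.bias,
        }
    raise TypeError(f"unknown model type {type(model)!r}")


def model_from_dict(d: dict):
    family = d["family"]
    manifest = tuple(d["manifest"])
    prep = _prep_from(d["preprocessing"])
    if family == "linear":
        return LinearModel(intercept=d["intercept"], coef=tuple(d["coef"]),
                           manifest=manifest, preprocessing=prep)
    if family == "mlp":
        return MLPModel(
            w1=np.asarray(d["w1"]), b1=np.asarray(d["b1"]),
            w2=np.asarray(d["w2"]), b2=d["b2"],
            manifest=manifest, preprocessing=prep,
        )
    if family == "rbf":
        return RBFModel(
            centers=np.asarray(d["centers"]), widths=np.asarray(d["widths"]),
            weights=np.asarray(d["weights"]), bias=d["bias"],
            manifest=manifest, preprocessing=prep,
        )
    raise ValueError(f"unknown model family '{family}'")


def save_model(model, path) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=1)


def load_model(path):
    with open(path) as fh:
        return model_from_dict(json.load(fh))
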