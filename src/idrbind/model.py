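"""Per-function ridge-penalized logistic regression.

The objective is the negative log-likelihood plus 0.5 * lambda * ||w||^2
with an unpenalized intercept, minimized by L-BFGS from a zero start on
features standardized to zero mean / unit variance over the training
corpus. The standardization parameters are stored in the model so
prediction is self-contained. The problem is convex and the initialization
deterministic, so training is reproducible without seeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.metrics import roc_auc_score

from idrbind.features import FeatureVectorSet, WindowSpec

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1


@dataclass
class BindingModel:
    function: str
    feature_ids: list[str]
    coefficients: np.ndarray
    intercept: float
    ridge_lambda: float
    window_spec: WindowSpec
    feature_means: np.ndarray
    feature_stds: np.ndarray
    training_library_ref: str = ""
    objective_trace: list[float] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if len(self.coefficients) != len(self.feature_ids):
            raise ValueError("coefficient / feature id length mismatch")
        if self.ridge_lambda <= 0:
            raise ValueError("ridge_lambda must be positive")


@dataclass
class PropensityProfile:
    """Per-residue propensities in [0, 1] per function, with transfer flags."""

    protein_id: str
    propensities: dict[str, np.ndarray] = field(default_factory=dict)
    transferred: dict[str, np.ndarray] = field(default_factory=dict)

    def set(self, function: str, p: np.ndarray,
            transferred: np.ndarray | None = None) -> None:
        p = np.asarray(p, dtype=float)
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("propensities must lie in [0, 1]")
        self.propensities[function] = p
        self.transferred[function] = (
            np.zeros(p.size, dtype=bool) if transferred is None
            else np.asarray(transferred, dtype=bool)
        )


def _penalized_nll(theta: np.ndarray, X: np.ndarray, y: np.ndarray,
                   lam: float) -> tuple[float, np.ndarray]:
    b, w = theta[0], theta[1:]
    z = b + X @ w
    # log(1 + exp(z)) - y*z, numerically stable
    nll = float(np.sum(np.logaddexp(0.0, z) - y * z))
    p = expit(z)
    grad_b = float(np.sum(p - y))
    grad_w = X.T @ (p - y) + lam * w
    obj = nll + 0.5 * lam * float(w @ w)
    return obj, np.concatenate(([grad_b], grad_w))


def train(
    features: FeatureVectorSet,
    function: str,
    window_spec: WindowSpec,
    ridge_lambda: float = 1.0,
    training_library_ref: str = "",
    grad_tol: float = 1e-8,
) -> BindingModel:
    """Fit the ridge logistic model on a corpus-wide feature set."""
    y = features.labels.astype(float)
    if y.min() == y.max():
        raise ValueError(f"training labels for {function!r} contain a single class")
    X = features.matrix
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    means = X.mean(axis=0)
    stds = X.std(axis=0)
    stds = np.where(stds > 0, stds, 1.0)
    Xs = (X - means) / stds

    def fun(theta):
        return _penalized_nll(theta, Xs, y, ridge_lambda)

    theta0 = np.zeros(X.shape[1] + 1)
    # trace holds the objective at each accepted iterate (line-search probes
    # excluded), so it is non-increasing for this convex problem
    trace: list[float] = [fun(theta0)[0]]
    res = minimize(fun, theta0, jac=True, method="L-BFGS-B",
                   callback=lambda t: trace.append(fun(t)[0]),
                   options={"gtol": grad_tol, "ftol": 0.0, "maxiter": 2000})
    logger.info("trained %s model: %d features, %d residues, objective %.4f",
                function, X.shape[1], X.shape[0], res.fun)
    return BindingModel(
        function=function,
        feature_ids=list(features.feature_ids),
        coefficients=res.x[1:].copy(),
        intercept=float(res.x[0]),
        ridge_lambda=ridge_lambda,
        window_spec=window_spec,
        feature_means=means,
        feature_stds=stds,
        training_library_ref=training_library_ref,
        objective_trace=trace,
    )


def select_ridge_lambda(
    features: FeatureVectorSet,
    function: str,
    window_spec: WindowSpec,
    candidates: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0),
    n_folds: int = 4,
    seed: int = 0,
) -> float:
    """Pick ridge_lambda by protein-grouped k-fold CV maximizing AUC."""
    rng = np.random.default_rng(seed)
    proteins = np.unique(features.protein_ids)
    perm = rng.permutation(len(proteins))
    folds = np.array_split(perm, n_folds)
    best_lam, best_auc = candidates[0], -1.0
    for lam in candidates:
        aucs = []
        for fold in folds:
            held = set(proteins[fold])
            test_mask = np.isin(features.protein_ids, list(held))
            train_mask = ~test_mask
            ytr, yte = features.labels[train_mask], features.labels[test_mask]
            if ytr.min() == ytr.max() or yte.min() == yte.max():
                continue
            sub = FeatureVectorSet(
                features.feature_ids, features.matrix[train_mask], ytr,
                features.protein_ids[train_mask], features.positions[train_mask],
            )
            m = train(sub, function, window_spec, ridge_lambda=lam)
            scores = _linear_scores(m, features.matrix[test_mask])
            aucs.append(roc_auc_score(yte, scores))
        mean_auc = float(np.mean(aucs)) if aucs else -1.0
        if mean_auc > best_auc:
            best_auc, best_lam = mean_auc, lam
    return best_lam


def _linear_scores(model: BindingModel, X: np.ndarray) -> np.ndarray:
    Xs = (X - model.feature_means) / model.feature_stds
    return model.intercept + Xs @ model.coefficients


def predict(model: BindingModel, features: FeatureVectorSet) -> np.ndarray:
    """Regression-part propensities for the rows of one protein's features."""
    if features.feature_ids != model.feature_ids:
        missing = [f for f in model.feature_ids if f not in features.feature_ids]
        if missing:
            raise ValueError(f"missing feature column(s): {missing}")
        features = features.select(model.feature_ids)
    return expit(_linear_scores(model, features.matrix))


def save_model(model: BindingModel, path: str | Path) -> None:
    """Write the versioned plain-text model file."""
    with open(path, "w") as fh:
        fh.write(f"format_version\t{MODEL_FORMAT_VERSION}\n")
        fh.write(f"function\t{model.function}\n")
        fh.write(f"ws\t{model.window_spec.ws}\n")
        fh.write(f"ridge_lambda\t{float(model.ridge_lambda)!r}\n")
        fh.write(f"intercept\t{float(model.intercept)!r}\n")
        fh.write(f"training_library\t{model.training_library_ref}\n")
        fh.write(f"n_features\t{len(model.feature_ids)}\n")
        for fid, c, m, s in zip(model.feature_ids, model.coefficients,
                                model.feature_means, model.feature_stds):
            fh.write(f"feature\t{fid}\t{float(c)!r}\t{float(m)!r}\t{float(s)!r}\n")


def load_model(path: str | Path) -> BindingModel:
    kv: dict[str, str] = {}
    rows: list[tuple[str, float, float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if parts[0] == "feature":
                if len(parts) != 5:
                    raise ValueError(f"{path}:{lineno}: malformed feature row")
                rows.append((parts[1], float(parts[2]), float(parts[3]), float(parts[4])))
            elif len(parts) == 2:
                kv[parts[0]] = parts[1]
            else:
                raise ValueError(f"{path}:{lineno}: malformed line")
    if kv.get("format_version") != str(MODEL_FORMAT_VERSION):
        raise ValueError(
            f"unsupported model format version {kv.get('format_version')!r} "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    required = {"function", "ws", "ridge_lambda", "intercept", "n_features"}
    missing = required - kv.keys()
    if missing:
        raise ValueError(f"model file {path} missing keys: {sorted(missing)}")
    if len(rows) != int(kv["n_features"]):
        raise ValueError(
            f"model file {path}: expected {kv['n_features']} feature rows, "
            f"found {len(rows)}"
        )
    return BindingModel(
        function=kv["function"],
        feature_ids=[r[0] for r in rows],
        coefficients=np.array([r[1] for r in rows]),
        intercept=float(kv["intercept"]),
        ridge_lambda=float(kv["ridge_lambda"]),
        window_spec=WindowSpec(kv["function"], int(kv["ws"])),
        feature_means=np.array([r[2] for r in rows]),
        feature_stds=np.array([r[3] for r in rows]),
        training_library_ref=kv.get("training_library", ""),
    )
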