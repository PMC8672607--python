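"""Sparse nearest-centroid classifier with a confidence score and rejection.

Training learns a sparse projection W (d x k) and centroids mu (k x k)
by the primal-dual solver; a new sample x is projected to xW and
assigned to the class whose centroid is nearest in l1 distance.  Each
prediction carries a confidence score (CSP): in the binary case

    csp = (d1 - d2) / (d1 + d2)  in [-1, 1]

(negative = closer to centroid 1), and for k > 2 classes

    csp = 1 - k * min(d) / sum(d)  in [0, 1].

Predictions whose confidence falls strictly inside the rejection band
are reported as "rejected" instead of a class label, which trades a
rejection rate for a lower misclassification load.  Feature importance
is read directly off W: the rows with nonzero weight are the selected
features.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import cdist

from .optim import SolverConfig, SolverResult, pd_solve
from .preprocess import (
    FeatureTable,
    LabelData,
    ScalingParams,
    apply_scaling,
    fit_scaling,
    log_transform,
    prevalence_filter,
)

__all__ = [
    "ModelState",
    "PredictionResult",
    "fit",
    "distances_to_centroids",
    "predict",
    "csp_binary",
    "csp_multiclass",
    "predict_with_rejection",
    "feature_ranking",
    "save_model",
    "load_model",
    "model_to_dict",
    "model_from_dict",
    "write_predictions",
]

REJECTED = "rejected"
_FORMAT_VERSION = 1


@dataclass
class ModelState:
    """Everything needed to score unseen raw samples identically.

    ``input_feature_ids`` is the full training feature list (used to
    align test tables), ``kept_indices`` the prevalence-filter survivors
    within it, and ``feature_ids`` the kept features that W is indexed by.
    """

    W: np.ndarray
    mu: np.ndarray
    class_names: list[str]
    scaling: ScalingParams
    config_used: SolverConfig
    feature_ids: list[str]
    input_feature_ids: list[str]
    kept_indices: np.ndarray
    min_fraction: float = 0.1
    solver_info: dict | None = None

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        self.kept_indices = np.asarray(self.kept_indices, dtype=int)
        k = len(self.class_names)
        if self.W.shape[1] != k or self.mu.shape != (k, k):
            raise ValueError("W / mu / class_names dimensions disagree")
        if self.W.shape[0] != len(self.feature_ids):
            raise ValueError("W row count != number of kept features")
        if np.abs(self.W).sum() > self.config_used.eta + 1e-9:
            raise ValueError("W violates the l1-ball constraint")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)


@dataclass
class PredictionResult:
    """One sample's distances, predicted class, confidence and rejection state."""

    sample_id: str
    distances: np.ndarray
    predicted_class: int  # 0-based index into class_names
    predicted_label: str
    csp: float
    rejected: bool = False
    final_label: str = ""

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        if not self.final_label:
            self.final_label = self.predicted_label


def fit(
    table: FeatureTable,
    labels: LabelData,
    config: SolverConfig | None = None,
    min_fraction: float = 0.1,
    pseudocount: float = 1.0,
    log_base: float = 10.0,
) -> ModelState:
    """Fit the full pipeline on a raw table: filter, log, autoscale, solve.

    The preprocessing parameters are fitted on this (training) table
    only and stored in the model so held-out samples are transformed
    identically at prediction time.
    """
    if config is None:
        config = SolverConfig()
    if table.n_samples != len(labels.assignment):
        raise ValueError("table and labels are not aligned on samples")
    if config.eta == 0:
        warnings.warn("eta = 0 forces W = 0: no features selected", RuntimeWarning, stacklevel=2)

    filtered, kept = prevalence_filter(table, min_fraction)
    logged = log_transform(filtered, pseudocount, log_base)
    scaling = fit_scaling(logged, pseudocount, log_base)
    scaled = apply_scaling(logged, scaling)

    result: SolverResult = pd_solve(scaled.values, labels.onehot, config)
    return ModelState(
        W=result.W,
        mu=result.mu,
        class_names=list(labels.class_names),
        scaling=scaling,
        config_used=config,
        feature_ids=list(filtered.feature_ids),
        input_feature_ids=list(table.feature_ids),
        kept_indices=kept,
        min_fraction=min_fraction,
        solver_info={
            "iterations_run": result.iterations_run,
            "converged": result.converged,
            "final_objective": result.objective_trace[-1] if result.objective_trace else None,
        },
    )


def distances_to_centroids(model: ModelState, x_scaled: np.ndarray) -> np.ndarray:
    """l1 distances d_j = || mu_j - x W ||_1 for one scaled sample."""
    x_scaled = np.asarray(x_scaled, dtype=float).ravel()
    if x_scaled.shape[0] != model.W.shape[0]:
        raise ValueError(
            f"sample has {x_scaled.shape[0]} features, model expects {model.W.shape[0]}"
        )
    proj = x_scaled @ model.W
    return np.abs(model.mu - proj[None, :]).sum(axis=1)


def csp_binary(d1: float, d2: float) -> float:
    """Binary confidence score (d1 - d2) / (d1 + d2) in [-1, 1].

    Negative means closer to centroid 1 (first class in sorted order),
    positive closer to centroid 2. Returns 0 with a warning in the
    degenerate case d1 = d2 = 0.
    """
    if d1 < 0 or d2 < 0:
        raise ValueError("distances must be nonnegative")
    if d1 + d2 == 0:
        warnings.warn("both centroid distances are zero (degenerate geometry)",
                      RuntimeWarning, stacklevel=2)
        return 0.0
    return (d1 - d2) / (d1 + d2)


def csp_multiclass(d) -> float:
    """Multi-class confidence 1 - k * min(d) / sum(d) in [0, 1]."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    total = d.sum()
    if total == 0:
        warnings.warn("all centroid distances are zero (degenerate geometry)",
                      RuntimeWarning, stacklevel=2)
        return 1.0
    return float(1.0 - d.size * d.min() / total)


def _transform_like_training(model: ModelState, table: FeatureTable) -> np.ndarray:
    """Reorder, filter, log and scale a raw test table with stored parameters."""
    if set(table.feature_ids) != set(model.input_feature_ids):
        missing = sorted(set(model.input_feature_ids) - set(table.feature_ids))[:5]
        extra = sorted(set(table.feature_ids) - set(model.input_feature_ids))[:5]
        raise ValueError(
            "test features do not match the training features; "
            f"missing {missing}, unexpected {extra}"
        )
    col = {fid: j for j, fid in enumerate(table.feature_ids)}
    order = [col[f] for f in model.input_feature_ids]
    vals = table.values[:, order][:, model.kept_indices]
    sub = FeatureTable(
        sample_ids=list(table.sample_ids),
        feature_ids=list(model.feature_ids),
        values=vals,
        stage="raw",
    )
    logged = log_transform(sub, model.scaling.pseudocount, model.scaling.log_base)
    return apply_scaling(logged, model.scaling).values


def predict(model: ModelState, table: FeatureTable) -> list[PredictionResult]:
    """Classify every sample of a raw table by l1 nearest centroid.

    Ties in the argmin go to the lowest class index. The confidence
    score is the signed binary CSP when k = 2 and the multi-class CSP
    otherwise.
    """
    Xs = _transform_like_training(model, table)
    P = Xs @ model.W
    D = cdist(P, model.mu, metric="cityblock")
    k = model.n_classes
    results = []
    for i, sid in enumerate(table.sample_ids):
        d = D[i]
        j_star = int(np.argmin(d))  # argmin takes the lowest index on ties
        if k == 2:
            score = csp_binary(d[0], d[1])
        else:
            score = csp_multiclass(d)
        results.append(
            PredictionResult(
                sample_id=sid,
                distances=d,
                predicted_class=j_star,
                predicted_label=model.class_names[j_star],
                csp=score,
            )
        )
    return results


def predict_with_rejection(
    results: list[PredictionResult], epsilon: float
) -> list[PredictionResult]:
    """Apply the rejection rule at threshold ``epsilon``.

    Binary: label class 1 if csp < -epsilon, class 2 if csp > epsilon,
    reject strictly inside the band (|csp| = epsilon is classified, per
    the strict inequalities of the rule; epsilon = 0 rejects nothing).
    Multi-class: reject when csp < epsilon.
    """
    if not 0 <= epsilon <= 1:
        raise ValueError("epsilon must lie in [0, 1]")
    out = []
    for r in results:
        if len(r.distances) == 2:
            rejected = abs(r.csp) < epsilon
        else:
            rejected = r.csp < epsilon
        out.append(
            replace(
                r,
                rejected=rejected,
                final_label=REJECTED if rejected else r.predicted_label,
            )
        )
    return out


def feature_ranking(model: ModelState) -> list[tuple[str, float]]:
    """Rank features by total absolute weight in W, descending.

    score_f = sum_j |W[f, j]|; ties are broken by feature index, so the
    order is deterministic. Zero-score features (not selected by the
    l1 constraint) trail the list.
    """
    scores = np.abs(model.W).sum(axis=1)
    if np.all(scores == 0):
        warnings.warn("no features selected (W = 0)", RuntimeWarning, stacklevel=2)
    order = np.lexsort((np.arange(scores.size), -scores))
    return [(model.feature_ids[f], float(scores[f])) for f in order]


# ---------------------------------------------------------------------------
# serialization


def model_to_dict(model: ModelState) -> dict:
    cfg = model.config_used
    return {
        "format_version": _FORMAT_VERSION,
        "class_names": model.class_names,
        "feature_ids": model.feature_ids,
        "input_feature_ids": model.input_feature_ids,
        "kept_indices": model.kept_indices.tolist(),
        "W": model.W.tolist(),
        "mu": model.mu.tolist(),
        "scaling": {
            "means": model.scaling.means.tolist(),
            "scales": model.scaling.scales.tolist(),
            "pseudocount": model.scaling.pseudocount,
            "log_base": model.scaling.log_base,
        },
        "min_fraction": model.min_fraction,
        "config_used": {
            "sigma": cfg.sigma,
            "tau": cfg.tau,
            "delta": cfg.delta,
            "rho_penalty": cfg.rho_penalty,
            "eta": cfg.eta,
            "loss": cfg.loss,
            "max_iter": cfg.max_iter,
            "tol": cfg.tol,
            "auto_steps": cfg.auto_steps,
        },
    }


def model_from_dict(doc: dict) -> ModelState:
    if doc.get("format_version") != _FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {doc.get('format_version')!r}")
    scaling = ScalingParams(
        means=np.array(doc["scaling"]["means"], dtype=float),
        scales=np.array(doc["scaling"]["scales"], dtype=float),
        pseudocount=doc["scaling"]["pseudocount"],
        log_base=doc["scaling"]["log_base"],
    )
    return ModelState(
        W=np.array(doc["W"], dtype=float),
        mu=np.array(doc["mu"], dtype=float),
        class_names=list(doc["class_names"]),
        scaling=scaling,
        config_used=SolverConfig(**doc["config_used"]),
        feature_ids=list(doc["feature_ids"]),
        input_feature_ids=list(doc["input_feature_ids"]),
        kept_indices=np.array(doc["kept_indices"], dtype=int),
        min_fraction=doc["min_fraction"],
    )


def save_model(model: ModelState, path) -> None:
    """Write the model as human-inspectable JSON (bit-exact round trip)."""
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh)


def load_model(path) -> ModelState:
    with open(path) as fh:
        return model_from_dict(json.load(fh))


def write_predictions(results: list[PredictionResult], path) -> None:
    """Predictions CSV: sample_id, d_1..d_k, predicted_class, csp, final_label."""
    import pandas as pd

    k = len(results[0].distances) if results else 0
    rows = [
        {
            "sample_id": r.sample_id,
            **{f"d_{j + 1}": r.distances[j] for j in range(k)},
            "predicted_class": r.predicted_label,
            "csp": r.csp,
            "final_label": r.final_label,
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
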