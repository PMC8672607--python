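"""Evaluation protocol: stratified k-fold CV, accuracy/AUC, rejection curves.

Cross-validation refits the entire pipeline — prevalence filter, log
transform, autoscaling and the primal-dual solver — on each training
fold, so no information from held-out samples leaks into the model.
The rejection curve reports, on a grid of confidence thresholds
epsilon, the misclassification load FDR(eps) = (# misclassified among
non-rejected) / (total samples) together with the rejection rate
RRS(eps) = (# rejected) / (total samples).  Note the FDR denominator is
ALL samples, a misclassification load rather than the conventional
rate conditional on acceptance; the conditional rate is emitted as a
clearly named secondary column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from . import classifier as clf
from .classifier import PredictionResult
from .optim import SolverConfig
from .preprocess import FeatureTable, LabelData

__all__ = [
    "CVReport",
    "RejectionCurve",
    "stratified_kfold_cv",
    "accuracy",
    "auc_from_scores",
    "rejection_curve",
    "csp_histogram_data",
]


@dataclass
class CVReport:
    """Aggregated cross-validation results over several shuffle seeds."""

    per_fold_accuracy: np.ndarray  # (seeds, folds)
    per_fold_auc: np.ndarray  # (seeds, folds); NaN when k > 2
    mean_accuracy: float
    mean_auc: float
    per_fold_top_features: list[list[list[str]]]  # [seed][fold] -> top ids
    folds: int
    seeds: list[int]
    config: SolverConfig

    def to_dict(self) -> dict:
        return {
            "folds": self.folds,
            "seeds": list(self.seeds),
            "mean_accuracy": self.mean_accuracy,
            "mean_auc": self.mean_auc,
            "per_fold_accuracy": self.per_fold_accuracy.tolist(),
            "per_fold_auc": self.per_fold_auc.tolist(),
            "per_fold_top_features": self.per_fold_top_features,
            "eta": self.config.eta,
            "delta": self.config.delta,
            "rho_penalty": self.config.rho_penalty,
            "loss": self.config.loss,
        }


@dataclass
class RejectionCurve:
    """FDR and RRS as functions of the confidence threshold epsilon."""

    epsilons: np.ndarray
    fdr: np.ndarray
    fdr_conditional: np.ndarray
    rrs: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "epsilon": self.epsilons,
                "fdr": self.fdr,
                "fdr_conditional": self.fdr_conditional,
                "rrs": self.rrs,
            }
        )


def accuracy(predicted: list[str], truth: list[str]) -> float:
    """Fraction of exact label matches."""
    if len(predicted) != len(truth):
        raise ValueError("predicted and truth differ in length")
    if len(truth) == 0:
        raise ValueError("empty input")
    return float(np.mean([p == t for p, t in zip(predicted, truth)]))


def auc_from_scores(scores, truth) -> float:
    """Mann-Whitney AUC of ``scores`` for the positive class, ties counted 1/2.

    ``truth`` is binary (0/1 or bool); higher scores should indicate the
    positive class. Computed from midranks, equivalent to the fraction
    of positive-negative pairs ordered correctly with ties worth 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(bool)
    if scores.shape != truth.shape:
        raise ValueError("scores and truth differ in length")
    n_pos = int(truth.sum())
    n_neg = int((~truth).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute an AUC")
    ranks = rankdata(scores)  # midranks handle ties at 1/2
    u = ranks[truth].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def stratified_kfold_cv(
    table: FeatureTable,
    labels: LabelData,
    folds: int = 4,
    seeds: list[int] | None = None,
    config: SolverConfig | None = None,
    min_fraction: float = 0.1,
    pseudocount: float = 1.0,
    log_base: float = 10.0,
    top_n: int = 10,
) -> CVReport:
    """Stratified k-fold cross-validation repeated over shuffle seeds.

    For every seed the samples are shuffled and split into ``folds``
    stratified folds; the model (including preprocessing) is refit on
    each training partition and evaluated on the held-out fold. AUC is
    computed per fold from the signed binary confidence score (the
    model's only continuous output) and is NaN for k > 2.
    """
    if seeds is None:
        seeds = [0, 1, 2]
    if folds < 2:
        raise ValueError("folds must be >= 2")
    counts = np.bincount(labels.assignment, minlength=labels.n_classes)
    if counts.min() < folds:
        small = labels.class_names[int(np.argmin(counts))]
        raise ValueError(
            f"class {small!r} has {counts.min()} samples, fewer than {folds} folds"
        )
    if config is None:
        config = SolverConfig()

    k = labels.n_classes
    truth_names = labels.labels
    acc = np.zeros((len(seeds), folds))
    auc = np.full((len(seeds), folds), np.nan)
    top_features: list[list[list[str]]] = []

    for si, seed in enumerate(seeds):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        seed_tops: list[list[str]] = []
        for fi, (tr, te) in enumerate(skf.split(table.values, labels.assignment)):
            sub_table = FeatureTable(
                sample_ids=[table.sample_ids[i] for i in tr],
                feature_ids=list(table.feature_ids),
                values=table.values[tr],
                stage="raw",
            )
            sub_labels = LabelData(
                class_names=list(labels.class_names),
                assignment=labels.assignment[tr],
            )
            model = clf.fit(
                sub_table, sub_labels, config,
                min_fraction=min_fraction, pseudocount=pseudocount, log_base=log_base,
            )
            test_table = FeatureTable(
                sample_ids=[table.sample_ids[i] for i in te],
                feature_ids=list(table.feature_ids),
                values=table.values[te],
                stage="raw",
            )
            results = clf.predict(model, test_table)
            pred_names = [r.predicted_label for r in results]
            true_names = [truth_names[i] for i in te]
            acc[si, fi] = accuracy(pred_names, true_names)
            if k == 2:
                scores = [r.csp for r in results]
                is_pos = [t == labels.class_names[1] for t in true_names]
                auc[si, fi] = auc_from_scores(scores, is_pos)
            seed_tops.append([fid for fid, _ in clf.feature_ranking(model)[:top_n]])
        top_features.append(seed_tops)

    return CVReport(
        per_fold_accuracy=acc,
        per_fold_auc=auc,
        mean_accuracy=float(acc.mean()),
        mean_auc=float(np.nanmean(auc)) if k == 2 else float("nan"),
        per_fold_top_features=top_features,
        folds=folds,
        seeds=list(seeds),
        config=config,
    )


def rejection_curve(
    results: list[PredictionResult],
    truth: list[str],
    epsilons=None,
) -> RejectionCurve:
    """FDR(eps) and RRS(eps) over a grid of confidence thresholds.

    FDR uses all samples in the denominator (a misclassification load);
    ``fdr_conditional`` divides by the accepted count instead.
    """
    if len(results) == 0:
        raise ValueError("empty prediction list")
    if len(results) != len(truth):
        raise ValueError("results and truth differ in length")
    if epsilons is None:
        epsilons = np.linspace(0.0, 1.0, 101)
    epsilons = np.asarray(epsilons, dtype=float)
    total = len(results)
    fdr = np.zeros_like(epsilons)
    fdr_cond = np.zeros_like(epsilons)
    rrs = np.zeros_like(epsilons)
    for i, eps in enumerate(epsilons):
        withrej = clf.predict_with_rejection(results, float(eps))
        rejected = sum(r.rejected for r in withrej)
        errors = sum(
            (not r.rejected) and r.final_label != t for r, t in zip(withrej, truth)
        )
        accepted = total - rejected
        fdr[i] = errors / total
        fdr_cond[i] = errors / accepted if accepted else 0.0
        rrs[i] = rejected / total
    return RejectionCurve(epsilons=epsilons, fdr=fdr, fdr_conditional=fdr_cond, rrs=rrs)


def csp_histogram_data(
    results: list[PredictionResult],
    truth: list[str],
    bins: int = 20,
) -> dict:
    """Binned CSP counts per true class over [-1, 1] (plot-ready)."""
    edges = np.linspace(-1.0, 1.0, bins + 1)
    out: dict[str, np.ndarray] = {}
    truth = list(truth)
    for name in sorted(set(truth)):
        scores = [r.csp for r, t in zip(results, truth) if t == name]
        counts, _ = np.histogram(scores, bins=edges)
        out[name] = counts
    return {"bin_edges": edges, "counts": out}
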