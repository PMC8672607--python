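"""Preprocessing of LC-MS feature tables.

Raw intensity tables go through three stages before classification:
prevalence filtering (drop features detected in too few samples), log
transformation (multiplicative noise becomes additive) and autoscaling
(per-feature mean centering and division by the standard deviation).
Class labels are encoded as a one-hot indicator matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FeatureTable",
    "LabelData",
    "ScalingParams",
    "prevalence_filter",
    "log_transform",
    "fit_scaling",
    "apply_scaling",
    "encode_labels",
    "decode_labels",
    "suggest_pseudocount",
]

_STAGES = ("raw", "logged", "scaled")


@dataclass
class FeatureTable:
    """An m-samples x d-features intensity matrix with identifiers.

    ``stage`` tracks how far the table has progressed through the
    preprocessing pipeline: ``raw`` (nonnegative intensities), ``logged``
    (log-transformed) or ``scaled`` (autoscaled, analysis-ready).
    """

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        m, d = self.values.shape
        if len(self.sample_ids) != m:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {m} rows")
        if len(self.feature_ids) != d:
            raise ValueError(f"{len(self.feature_ids)} feature ids for {d} columns")
        if len(set(self.sample_ids)) != m:
            raise ValueError("duplicate sample ids")
        if len(set(self.feature_ids)) != d:
            raise ValueError("duplicate feature ids")
        if self.stage not in _STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.stage == "scaled" and not np.all(np.isfinite(self.values)):
            raise ValueError("scaled table contains non-finite entries")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class LabelData:
    """Per-sample class assignment with its one-hot matrix.

    ``assignment`` holds 0-based class indices into ``class_names``;
    ``onehot`` is the m x k binary indicator matrix with exactly one
    nonzero entry per row.
    """

    class_names: list[str]
    assignment: np.ndarray
    onehot: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=int)
        k = len(self.class_names)
        if k < 2:
            raise ValueError("need at least 2 classes")
        if len(set(self.class_names)) != k:
            raise ValueError("duplicate class names")
        if self.assignment.min() < 0 or self.assignment.max() >= k:
            raise ValueError("assignment index out of range")
        if len(np.unique(self.assignment)) != k:
            raise ValueError("every class must occur at least once")
        if self.onehot is None:
            self.onehot = np.eye(k)[self.assignment]
        self.onehot = np.asarray(self.onehot, dtype=float)
        if self.onehot.shape != (len(self.assignment), k):
            raise ValueError("onehot shape mismatch")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def labels(self) -> list[str]:
        return [self.class_names[j] for j in self.assignment]


@dataclass
class ScalingParams:
    """Fitted autoscaling parameters (per-feature mean and scale).

    Fit on training data only and re-applied unchanged to held-out
    samples, so no test-fold information leaks into the transform.
    """

    means: np.ndarray
    scales: np.ndarray
    pseudocount: float = 1.0
    log_base: float = 10.0

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.scales = np.asarray(self.scales, dtype=float)
        if self.means.shape != self.scales.shape:
            raise ValueError("means/scales length mismatch")
        if np.any(self.scales <= 0):
            raise ValueError("scales must be strictly positive")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be nonnegative")
        if self.log_base <= 0 or self.log_base == 1:
            raise ValueError("log_base must be positive and != 1")


def prevalence_filter(
    table: FeatureTable, min_fraction: float = 0.1
) -> tuple[FeatureTable, np.ndarray]:
    """Drop features detected (intensity > 0) in fewer than
    ``min_fraction`` of the samples.

    Returns the filtered table and the integer indices of the kept
    features in the original column order.
    """
    if not 0 <= min_fraction <= 1:
        raise ValueError("min_fraction must lie in [0, 1]")
    if table.stage != "raw":
        raise ValueError("prevalence filtering applies to raw tables only")
    detected = (table.values > 0).mean(axis=0)
    kept = np.nonzero(detected >= min_fraction)[0]
    if kept.size == 0:
        raise ValueError("prevalence filter removed all features (empty table)")
    filtered = FeatureTable(
        sample_ids=list(table.sample_ids),
        feature_ids=[table.feature_ids[i] for i in kept],
        values=table.values[:, kept].copy(),
        stage="raw",
    )
    return filtered, kept


def log_transform(
    table: FeatureTable, pseudocount: float = 1.0, log_base: float = 10.0
) -> FeatureTable:
    """Entrywise x -> log_base(x + pseudocount)."""
    if table.stage != "raw":
        raise ValueError("log transform applies to raw tables only")
    if log_base <= 0 or log_base == 1:
        raise ValueError("log_base must be positive and != 1")
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    if np.any(table.values < 0):
        raise ValueError("raw intensities must be nonnegative")
    shifted = table.values + pseudocount
    if np.any(shifted <= 0):
        i, f = np.argwhere(shifted <= 0)[0]
        raise ValueError(
            f"zero intensity at sample {table.sample_ids[i]!r}, feature "
            f"{table.feature_ids[f]!r} with pseudocount 0; use a positive pseudocount"
        )
    return FeatureTable(
        sample_ids=list(table.sample_ids),
        feature_ids=list(table.feature_ids),
        values=np.log(shifted) / np.log(log_base),
        stage="logged",
    )


def fit_scaling(
    table: FeatureTable, pseudocount: float = 1.0, log_base: float = 10.0
) -> ScalingParams:
    """Fit per-feature means and sample (n-1) standard deviations.

    Zero-variance features get scale 1 (with a warning) so constant
    columns pass through centered at 0 instead of raising.
    """
    if table.stage != "logged":
        raise ValueError("fit scaling on a logged table")
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples to estimate a standard deviation")
    means = table.values.mean(axis=0)
    scales = table.values.std(axis=0, ddof=1)
    zero_var = scales == 0
    if np.any(zero_var):
        warnings.warn(
            f"{int(zero_var.sum())} zero-variance feature(s); scale set to 1",
            RuntimeWarning,
            stacklevel=2,
        )
        scales = np.where(zero_var, 1.0, scales)
    return ScalingParams(means=means, scales=scales, pseudocount=pseudocount, log_base=log_base)


def apply_scaling(table: FeatureTable, params: ScalingParams) -> FeatureTable:
    """Entrywise (x - mean_f) / scale_f; yields the analysis-ready matrix."""
    if table.stage != "logged":
        raise ValueError("apply scaling to a logged table")
    if table.n_features != params.means.shape[0]:
        raise ValueError(
            f"table has {table.n_features} features, params fitted on {params.means.shape[0]}"
        )
    return FeatureTable(
        sample_ids=list(table.sample_ids),
        feature_ids=list(table.feature_ids),
        values=(table.values - params.means) / params.scales,
        stage="scaled",
    )


def suggest_pseudocount(table: FeatureTable) -> float:
    """Median positive intensity of a raw table.

    For tables with true zeros (detection dropout) a pseudocount on the
    scale of the intensity distribution keeps non-detects from becoming
    extreme low outliers after the log transform — the same role as the
    half-minimum imputation common in metabolomics pipelines.  With no
    zeros present any pseudocount is harmless; the default of 1 in
    :func:`log_transform` is then the conventional choice.
    """
    if table.stage != "raw":
        raise ValueError("pseudocount suggestion applies to raw tables")
    positive = table.values[table.values > 0]
    if positive.size == 0:
        raise ValueError("table has no positive intensities")
    return float(np.median(positive))


def encode_labels(raw_labels: list[str]) -> LabelData:
    """Encode string labels; class order is lexicographic on the names."""
    names = sorted(set(str(l) for l in raw_labels))
    if len(names) < 2:
        raise ValueError("need at least 2 distinct class labels")
    index = {name: j for j, name in enumerate(names)}
    assignment = np.array([index[str(l)] for l in raw_labels], dtype=int)
    return LabelData(class_names=names, assignment=assignment)


def decode_labels(labels: LabelData) -> list[str]:
    """Inverse of :func:`encode_labels`: recover the original label strings."""
    return labels.labels
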