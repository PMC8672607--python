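"""Synthetic two-class LC-MS-like feature tables with known ground truth.

The generator emulates the structure of untargeted metabolomics feature
tables: lognormal intensities, a small set of discriminative base
metabolites whose fold change is planted on the log scale, blocks of
highly correlated adduct/isotopologue features per base metabolite,
detection dropout (exact zeros) and optional outlier samples with
inflated noise. Everything downstream — filtering, log transform,
autoscaling, the sparse primal-dual classifier and the rejection-curve
protocol — can therefore be exercised against a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import FeatureTable, LabelData, encode_labels

__all__ = ["SyntheticSpec", "SyntheticTruth", "generate", "empirical_block_correlation"]

_LOG10_2 = np.log10(2.0)


@dataclass
class SyntheticSpec:
    """Generator parameters.

    m balanced samples over two classes, d features of which
    s * adducts_per_base are informative: each of the s base metabolites
    carries a class-2 fold change of 2**log2_fold_change and is observed
    through adducts_per_base correlated feature columns (the base
    per-sample log-signal plus a fixed per-adduct offset and small
    jitter). Background features share one log10 mean across classes.
    Dropout zeroes entries independently; a fraction of samples can be
    made outliers by inflating their additive log-scale noise.
    """

    m: int = 100
    d: int = 1000
    s: int = 10
    adducts_per_base: int = 3
    log2_fold_change: float = 1.6
    base_log10_mean_range: tuple[float, float] = (3.0, 6.0)
    feature_sd_log10: float = 0.3
    adduct_jitter_sd: float = 0.05
    dropout_prob: float = 0.1
    outlier_sample_frac: float = 0.0
    outlier_scale: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 4 or self.d < 1:
            raise ValueError("need m >= 4 samples and d >= 1 features")
        if self.s < 0 or self.adducts_per_base < 1:
            raise ValueError("s >= 0 and adducts_per_base >= 1 required")
        if self.s * self.adducts_per_base > self.d:
            raise ValueError("s * adducts_per_base must not exceed d")
        if not 0 <= self.dropout_prob < 1:
            raise ValueError("dropout_prob in [0, 1) required")
        if not 0 <= self.outlier_sample_frac < 1:
            raise ValueError("outlier_sample_frac in [0, 1) required")
        if self.feature_sd_log10 <= 0 or self.adduct_jitter_sd < 0:
            raise ValueError("noise scales must be positive")
        if self.outlier_scale <= 0:
            raise ValueError("outlier_scale must be positive")
        lo, hi = self.base_log10_mean_range
        if hi < lo:
            raise ValueError("base_log10_mean_range must be increasing")


@dataclass
class SyntheticTruth:
    """Ground truth attached to a generated table."""

    labels: LabelData
    informative_feature_ids: list[str]
    block_map: dict[str, list[str]]
    outlier_sample_ids: list[str] = field(default_factory=list)


def generate(spec: SyntheticSpec) -> tuple[FeatureTable, SyntheticTruth]:
    """Draw one synthetic raw feature table. Deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    m, d = spec.m, spec.d
    n_info = spec.s * spec.adducts_per_base

    sample_ids = [f"S{i:04d}" for i in range(m)]
    # pseudo m/z feature names in the style of untargeted LC-MS tables
    mz = rng.uniform(70.0, 900.0, size=d)
    feature_ids = [f"MZ{mz[f]:.4f}_{f:04d}" for f in range(d)]

    # balanced classes, order shuffled
    raw = ["class1"] * (m // 2) + ["class2"] * (m - m // 2)
    order = rng.permutation(m)
    raw_labels = [raw[i] for i in order]
    labels = encode_labels(raw_labels)
    is_class2 = np.array([l == "class2" for l in raw_labels], dtype=float)

    lo, hi = spec.base_log10_mean_range
    feature_means = rng.uniform(lo, hi, size=d)

    n_out = int(round(spec.outlier_sample_frac * m))
    outlier_idx = rng.choice(m, size=n_out, replace=False) if n_out else np.array([], int)
    noise_scale = np.ones(m)
    noise_scale[outlier_idx] = spec.outlier_scale

    # background: independent per-feature lognormal intensities
    log10_vals = feature_means[None, :] + (
        rng.standard_normal((m, d)) * spec.feature_sd_log10 * noise_scale[:, None]
    )

    # informative blocks overwrite their columns with correlated copies
    # of a shared per-sample base signal carrying the class fold change
    info_pos = rng.choice(d, size=n_info, replace=False) if n_info else np.array([], int)
    shift = spec.log2_fold_change * _LOG10_2
    block_map: dict[str, list[str]] = {}
    informative_ids: list[str] = []
    for b in range(spec.s):
        cols = info_pos[b * spec.adducts_per_base : (b + 1) * spec.adducts_per_base]
        base_mean = feature_means[cols[0]]
        base_signal = (
            base_mean
            + shift * is_class2
            + rng.standard_normal(m) * spec.feature_sd_log10 * noise_scale
        )
        offsets = rng.uniform(-0.3, 0.3, size=len(cols))
        for a, f in enumerate(cols):
            jitter = rng.standard_normal(m) * spec.adduct_jitter_sd * noise_scale
            log10_vals[:, f] = base_signal + offsets[a] + jitter
        member_ids = [feature_ids[f] for f in cols]
        block_map[f"base{b:02d}"] = member_ids
        informative_ids.extend(member_ids)

    values = 10.0**log10_vals
    if spec.dropout_prob > 0:
        values[rng.random((m, d)) < spec.dropout_prob] = 0.0

    table = FeatureTable(sample_ids=sample_ids, feature_ids=feature_ids, values=values)
    truth = SyntheticTruth(
        labels=labels,
        informative_feature_ids=informative_ids,
        block_map=block_map,
        outlier_sample_ids=[sample_ids[i] for i in sorted(outlier_idx)],
    )
    return table, truth


def empirical_block_correlation(
    table: FeatureTable, truth: SyntheticTruth
) -> dict[str, float]:
    """Mean pairwise Pearson correlation of log10 intensities per adduct block.

    Requires a table generated without dropout (all intensities > 0);
    blocks of size 1 are skipped.
    """
    if np.any(table.values <= 0):
        raise ValueError("block correlation needs a dropout-free table")
    col = {fid: j for j, fid in enumerate(table.feature_ids)}
    logv = np.log10(table.values)
    out: dict[str, float] = {}
    for base, members in truth.block_map.items():
        if len(members) < 2:
            continue
        sub = logv[:, [col[f] for f in members]]
        C = np.corrcoef(sub, rowvar=False)
        iu = np.triu_indices_from(C, k=1)
        out[base] = float(C[iu].mean())
    return out
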