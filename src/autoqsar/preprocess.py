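"""Dataset-level filters and scaling.

Three steps, applied in a fixed order ahead of any train/test splitting:

1. near-zero-variance removal — drops constant columns and columns whose
   value distribution is dominated by a single level;
2. scaling — feature-wise standardization (z-score) or min-max
   normalization; the response is never scaled;
3. correlated-feature removal — greedy elimination until no retained pair
   of features has |Pearson r| at or above the cutoff.

Each filter returns the reduced dataset plus a machine-readable report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .dataset import Dataset


class PreprocessError(ValueError):
    """Fatal problem during preprocessing."""


@dataclass
class FilterReport:
    filter_name: str
    #: (feature name, reason, diagnostic value)
    removed_features: list[tuple[str, str, float]]
    parameters: dict

    @property
    def removed_names(self) -> list[str]:
        return [name for name, _, _ in self.removed_features]


@dataclass
class ScalingParams:
    """Per-feature affine transform x -> (x - location) / scale."""

    mode: str  # none | standardize | normalize
    feature_names: list[str]
    location: np.ndarray
    scale: np.ndarray

    def transform(self, X: np.ndarray, feature_names) -> np.ndarray:
        pos = {n: j for j, n in enumerate(self.feature_names)}
        idx = [pos[n] for n in feature_names]
        return (X - self.location[idx]) / self.scale[idx]


def near_zero_variance_filter(
    ds: Dataset, freq_cut: float = 95.0 / 5.0, unique_cut: float = 10.0
) -> tuple[Dataset, FilterReport]:
    """Remove constant and near-constant features.

    A feature is removed iff it has a single unique value ("zero variance"),
    or the ratio of the most frequent to the second most frequent value is
    >= ``freq_cut`` AND the percentage of unique values (100·distinct/n) is
    <= ``unique_cut`` ("near zero variance").
    """
    if freq_cut <= 1:
        raise PreprocessError("freq_cut must be > 1")
    if not 0 < unique_cut <= 100:
        raise PreprocessError("unique_cut must be in (0, 100]")
    n = ds.n_cases
    removed: list[tuple[str, str, float]] = []
    keep: list[str] = []
    for j, name in enumerate(ds.feature_names):
        col = ds.X[:, j]
        values, counts = np.unique(col, return_counts=True)
        if len(values) == 1:
            removed.append((name, "zero variance", float("inf")))
            continue
        counts = np.sort(counts)[::-1]
        freq_ratio = counts[0] / counts[1]
        pct_unique = 100.0 * len(values) / n
        if freq_ratio >= freq_cut and pct_unique <= unique_cut:
            removed.append((name, "near zero variance", float(freq_ratio)))
        else:
            keep.append(name)
    if not keep:
        raise PreprocessError("near-zero-variance filter removed all features")
    report = FilterReport(
        filter_name="near_zero_variance",
        removed_features=removed,
        parameters={"freq_cut": freq_cut, "unique_cut": unique_cut},
    )
    return ds.subset_features(keep), report


def scale_features(ds: Dataset, mode: str = "standardize") -> tuple[Dataset, ScalingParams]:
    """Scale features; fitted parameters are stored for reuse on new rows.

    standardize: (x - mean) / sd (sample sd, n-1 denominator).
    normalize:   (x - min) / (max - min).
    The response y is never scaled.
    """
    if mode not in ("none", "standardize", "normalize"):
        raise PreprocessError(f"unknown scaling mode {mode!r}")
    p = ds.n_features
    if mode == "none":
        params = ScalingParams(
            mode="none",
            feature_names=list(ds.feature_names),
            location=np.zeros(p),
            scale=np.ones(p),
        )
        return ds, params
    if mode == "standardize":
        location = ds.X.mean(axis=0)
        scale = ds.X.std(axis=0, ddof=1)
    else:  # normalize
        location = ds.X.min(axis=0)
        scale = ds.X.max(axis=0) - location
    for j, s in enumerate(scale):
        if s <= 0:
            raise PreprocessError(
                f"feature {ds.feature_names[j]!r} has zero scale under mode {mode!r}"
            )
    params = ScalingParams(
        mode=mode, feature_names=list(ds.feature_names), location=location, scale=scale
    )
    scaled = replace(ds, X=(ds.X - location) / scale)
    return scaled, params


def correlation_filter(ds: Dataset, cutoff: float = 0.9) -> tuple[Dataset, FilterReport]:
    """Greedy pairwise elimination of highly correlated features.

    While any feature pair has |Pearson r| >= cutoff, take the pair with the
    largest |r| (ties: earliest pair by column index) and remove the member
    with the larger mean absolute correlation to all remaining features
    (ties: the later column is removed).  Deterministic given column order.
    """
    if not 0 < cutoff <= 1:
        raise PreprocessError("cutoff must be in (0, 1]")
    if ds.n_features < 2:
        raise PreprocessError("correlation filter needs at least two features")
    names = list(ds.feature_names)
    with np.errstate(invalid="ignore"):
        corr = np.abs(np.corrcoef(ds.X, rowvar=False))
    np.fill_diagonal(corr, 0.0)
    corr = np.nan_to_num(corr, nan=0.0)  # constant columns: treat as uncorrelated
    alive = list(range(len(names)))
    removed: list[tuple[str, str, float]] = []
    while len(alive) > 1:
        sub = corr[np.ix_(alive, alive)]
        k = len(alive)
        iu = np.triu_indices(k, 1)
        if not len(iu[0]):
            break
        vals = sub[iu]
        best = np.argmax(vals)
        if vals[best] < cutoff:
            break
        # argmax on the flattened upper triangle ties toward earlier pairs
        a, b = alive[iu[0][best]], alive[iu[1][best]]
        r_ab = float(corr[a, b])
        mean_a = corr[a, alive].sum() / (k - 1)
        mean_b = corr[b, alive].sum() / (k - 1)
        drop = b if mean_b >= mean_a else a  # tie -> later column removed
        other = a if drop == b else b
        removed.append(
            (names[drop], f"|r|={r_ab:.6g} with {names[other]}", r_ab)
        )
        alive.remove(drop)
    if len(alive) == 1:
        warnings.warn("correlation filter reduced the dataset to a single feature")
    report = FilterReport(
        filter_name="correlation",
        removed_features=removed,
        parameters={"cutoff": cutoff},
    )
    keep = [names[i] for i in sorted(alive)]
    return ds.subset_features(keep), report


def preprocess(
    ds: Dataset,
    nzv: bool = True,
    freq_cut: float = 95.0 / 5.0,
    unique_cut: float = 10.0,
    scaling: str = "standardize",
    corr_filter: bool = True,
    corr_cutoff: float = 0.9,
) -> tuple[Dataset, list[FilterReport], ScalingParams]:
    """Apply the full pipeline: near-zero variance -> scaling -> correlation."""
    reports: list[FilterReport] = []
    if nzv:
        ds, rep = near_zero_variance_filter(ds, freq_cut=freq_cut, unique_cut=unique_cut)
        reports.append(rep)
    ds, params = scale_features(ds, mode=scaling)
    if corr_filter and ds.n_features >= 2:
        ds, rep = correlation_filter(ds, cutoff=corr_cutoff)
        reports.append(rep)
    return ds, reports, params
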