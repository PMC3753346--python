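"""Dimensionality reduction for spectral data: binning and MI ranking.

Two families of feature selection are provided.  *Binning* splits the
spectrum into sequential, non-overlapping regions and replaces each region
by its per-subject average intensity — the classical approach for metabolic
spectra.  *Mutual-information ranking* scores each measurement by the
average information (in bits) it shares with every other measurement,

    S_i = (1 / (N - 1)) * sum_{j != i} I(X_i; X_j),

and keeps either the k highest-S features (noise shares little information,
so high-S features form groups of correlated, meaningful measurements) or
the k lowest-S features (the minimal-redundancy principle: each selected
feature adds new information).

MI is estimated by discretizing each variable into ``n_levels`` equal-width
levels over its own observed range and summing the discrete MI of the
empirical joint distribution with base-2 logarithms.  The estimator is
deterministic; absolute score values depend on the discretization, so only
orderings should be interpreted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra_io import SpectraDataset

DEFAULT_N_LEVELS = 8


@dataclass
class BinningScheme:
    """Partition of the column range into contiguous half-open intervals."""

    n_bins: int
    boundaries: list  # list of (start, end) with end exclusive

    def __post_init__(self) -> None:
        if self.n_bins != len(self.boundaries):
            raise ValueError("n_bins does not match number of intervals")
        prev_end = 0
        for start, end in self.boundaries:
            if start != prev_end or end <= start:
                raise ValueError("intervals must be contiguous and non-empty")
            prev_end = end


@dataclass
class FeatureRanking:
    """Per-feature shared-information scores S (bits) and the high-S order.

    ``order`` sorts features by decreasing S; ties are broken by the smaller
    original index so rankings are reproducible across runs and platforms.
    """

    scores: np.ndarray
    n_levels: int
    order: np.ndarray = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if not np.all(np.isfinite(self.scores)) or np.any(self.scores < 0):
            raise ValueError("scores must be finite and >= 0")
        if self.order is None:
            self.order = self.order_for("high_S")
        self.order = np.asarray(self.order, dtype=int)

    @property
    def n_features(self) -> int:
        return len(self.scores)

    def order_for(self, strategy: str) -> np.ndarray:
        """Feature indices sorted by the given strategy, ties by index."""
        idx = np.arange(len(self.scores))
        if strategy == "high_S":
            return idx[np.lexsort((idx, -self.scores))]
        if strategy == "low_S":
            return idx[np.lexsort((idx, self.scores))]
        raise ValueError(f"unknown strategy {strategy!r}")


def make_binning_scheme(n_features: int, n_bins: int) -> BinningScheme:
    """Sequential non-overlapping intervals covering all columns.

    With N features and B bins, the first ``N mod B`` bins have width
    ``ceil(N/B)`` and the rest ``floor(N/B)``: widths differ by at most one
    and the union is exactly the column range.
    """
    if n_bins <= 0:
        raise ValueError("n_bins must be positive")
    if n_bins > n_features:
        raise ValueError(
            f"n_bins={n_bins} exceeds feature count {n_features}"
        )
    base, rem = divmod(n_features, n_bins)
    boundaries = []
    start = 0
    for b in range(n_bins):
        width = base + (1 if b < rem else 0)
        boundaries.append((start, start + width))
        start += width
    return BinningScheme(n_bins=n_bins, boundaries=boundaries)


def bin_average(dataset: SpectraDataset, n_bins: int) -> SpectraDataset:
    """Average sequential spectrum regions into ``n_bins`` new features."""
    scheme = make_binning_scheme(dataset.n_features, n_bins)
    cols = [
        dataset.intensities[:, s:e].mean(axis=1)
        for s, e in scheme.boundaries
    ]
    return SpectraDataset(
        intensities=np.column_stack(cols),
        labels=dataset.labels.copy(),
        feature_ids=[f"bin{b}" for b in range(n_bins)],
        subject_ids=list(dataset.subject_ids),
        allow_negative=dataset.allow_negative,
    )


def discretize(x, n_levels: int) -> np.ndarray:
    """Equal-width level codes in [0, n_levels) over the observed range.

    A zero-range (constant) variable occupies a single level, which makes
    its MI with anything exactly zero.
    """
    if n_levels < 1:
        raise ValueError("n_levels must be positive")
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros(x.shape, dtype=np.intp)
    codes = np.floor((x - lo) / (hi - lo) * n_levels).astype(np.intp)
    return np.clip(codes, 0, n_levels - 1)


def _mi_from_codes(cx: np.ndarray, cy: np.ndarray, n_levels: int) -> float:
    n = len(cx)
    joint = np.bincount(
        cx * n_levels + cy, minlength=n_levels * n_levels
    ).reshape(n_levels, n_levels)
    pxy = joint / n
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    nz = pxy > 0
    ratio = pxy[nz] / np.outer(px, py)[nz]
    return float(np.sum(pxy[nz] * np.log2(ratio)))


def mutual_information(x, y, n_levels: int = DEFAULT_N_LEVELS) -> float:
    """Mutual information I(X;Y) in bits under equal-width discretization.

    Terms with zero joint probability contribute 0; the result is >= 0 up
    to floating-point rounding and bounded by log2(n_levels).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D sequences of equal length")
    if len(x) < 2:
        raise ValueError("need at least 2 observations")
    mi = _mi_from_codes(discretize(x, n_levels), discretize(y, n_levels), n_levels)
    return max(mi, 0.0)


def pairwise_mi_matrix(
    dataset: SpectraDataset, n_levels: int = DEFAULT_N_LEVELS
) -> np.ndarray:
    """Symmetric matrix of pairwise feature MIs (diagonal zeroed)."""
    k = dataset.n_features
    codes = [
        discretize(dataset.intensities[:, i], n_levels) for i in range(k)
    ]
    mi = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            v = max(_mi_from_codes(codes[i], codes[j], n_levels), 0.0)
            mi[i, j] = mi[j, i] = v
    return mi


def shared_information_score(
    dataset: SpectraDataset, n_levels: int = DEFAULT_N_LEVELS
) -> FeatureRanking:
    """Average MI of each feature with all others (the S score, in bits)."""
    if dataset.n_features < 2:
        raise ValueError("shared information needs at least 2 features")
    mi = pairwise_mi_matrix(dataset, n_levels)
    scores = mi.sum(axis=1) / (dataset.n_features - 1)
    return FeatureRanking(scores=scores, n_levels=n_levels)


def select_features(
    ranking: FeatureRanking, k: int, strategy: str = "high_S"
) -> np.ndarray:
    """The k top features under ``high_S`` or ``low_S``, sorted by index.

    Ties are broken toward the smaller original index; the returned indices
    are sorted ascending so downstream pair enumeration is stable.
    """
    if not 1 <= k <= ranking.n_features:
        raise ValueError(
            f"k={k} out of range [1, {ranking.n_features}]"
        )
    chosen = ranking.order_for(strategy)[:k]
    return np.sort(chosen)
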