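"""End-to-end convenience: feature selection -> networks -> metrics -> scores."""

from __future__ import annotations

import numpy as np

from .evaluation import EvaluationCurve, evaluate_pnn, evaluate_svm
from .feature_selection import (
    DEFAULT_N_LEVELS,
    bin_average,
    select_features,
    shared_information_score,
)
from .spectra_io import SpectraDataset
from .topology_metrics import ThresholdGrid

METHODS = ("bin_average", "high_S", "low_S")


def prepare_features(
    dataset: SpectraDataset,
    method: str,
    k: int,
    n_levels: int = DEFAULT_N_LEVELS,
):
    """Apply one feature-selection method; returns (dataset, selected indices).

    For binning the returned dataset is the binned one and all k bins are
    selected; for the MI strategies the dataset is unchanged and the k
    chosen column indices are returned.  None of the methods look at class
    labels.
    """
    if method == "bin_average":
        binned = bin_average(dataset, k)
        return binned, np.arange(k)
    if method in ("high_S", "low_S"):
        ranking = shared_information_score(dataset, n_levels=n_levels)
        return dataset, select_features(ranking, k, strategy=method)
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")


def run_curve(
    dataset: SpectraDataset,
    method: str = "high_S",
    k: int = 25,
    classifier: str = "svm",
    grid: ThresholdGrid | None = None,
    protocol="loo",
    n_levels: int = DEFAULT_N_LEVELS,
    seed: int = 0,
    **classifier_kwargs,
) -> EvaluationCurve:
    """Full pipeline for one (method, k, classifier) combination."""
    working, selected = prepare_features(dataset, method, k, n_levels=n_levels)
    if classifier == "svm":
        return evaluate_svm(
            working, selected, grid=grid, protocol=protocol, seed=seed,
            method=method, **classifier_kwargs,
        )
    if classifier == "pnn":
        return evaluate_pnn(
            working, selected, grid=grid, protocol=protocol, seed=seed,
            method=method, **classifier_kwargs,
        )
    raise ValueError(f"unknown classifier {classifier!r}")
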