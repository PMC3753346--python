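"""Group-conditional pairwise linear models and per-subject weighted cliques.

For every unordered pair of selected measurements (i, j) with i < j, two
ordinary-least-squares lines are fitted for m_j as a function of m_i: one on
the control subjects and one on the patients,

    m_j = a^h m_i + b^h + e^h      (controls)
    m_j = a^c m_i + b^c + e^c      (patients)

with residual standard deviations sigma_h and sigma_c (denominator n - 2,
floored at a small epsilon so perfectly collinear training pairs stay
usable).  Given a subject's measured values (x_i, x_j), the vertical
residual from each line is scored under a zero-mean normal distribution
with the corresponding sigma, and the edge weight is the normalized
probability of following the patient model:

    w = p_c / (p_c + p_h),

evaluated stably in log-density space.  Applying this to every pair yields
a weighted clique (fully connected weighted graph) representing the
subject: edges with w near 1 mark measurement pairs behaving like the
patient population, w near 0 like controls, and w near 0.5 pairs that do
not discriminate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .spectra_io import CONTROL, PATIENT, SpectraDataset

logger = logging.getLogger(__name__)

MIN_SUBJECTS_PER_CLASS = 3
EPSILON_SCALE = 1e-9


@dataclass(frozen=True)
class PairModel:
    """Control and patient OLS fits of feature j on feature i (i < j)."""

    feature_i: int
    feature_j: int
    slope_control: float
    intercept_control: float
    sigma_control: float
    slope_patient: float
    intercept_patient: float
    sigma_patient: float

    def __post_init__(self) -> None:
        if self.sigma_control <= 0 or self.sigma_patient <= 0:
            raise ValueError("residual standard deviations must be positive")


@dataclass
class PairModelSet:
    """One :class:`PairModel` per unordered pair of selected features.

    Internally stored as flat arrays aligned with the upper-triangle pair
    order (lexicographic in (i, j), i < j); ``models`` materializes the
    individual dataclasses on demand.
    """

    selected_features: np.ndarray
    pair_i: np.ndarray  # positions into selected_features, lower index
    pair_j: np.ndarray
    slope_control: np.ndarray
    intercept_control: np.ndarray
    sigma_control: np.ndarray
    slope_patient: np.ndarray
    intercept_patient: np.ndarray
    sigma_patient: np.ndarray
    epsilon: np.ndarray  # per-pair sigma floor actually applied

    @property
    def n_pairs(self) -> int:
        return len(self.pair_i)

    @property
    def n_features(self) -> int:
        return len(self.selected_features)

    @property
    def models(self) -> list[PairModel]:
        sel = self.selected_features
        return [
            PairModel(
                feature_i=int(sel[self.pair_i[p]]),
                feature_j=int(sel[self.pair_j[p]]),
                slope_control=float(self.slope_control[p]),
                intercept_control=float(self.intercept_control[p]),
                sigma_control=float(self.sigma_control[p]),
                slope_patient=float(self.slope_patient[p]),
                intercept_patient=float(self.intercept_patient[p]),
                sigma_patient=float(self.sigma_patient[p]),
            )
            for p in range(self.n_pairs)
        ]


@dataclass
class SubjectNetwork:
    """Weighted clique over the selected features for one subject.

    ``weights`` is condensed upper-triangle order matching
    ``np.triu_indices(k, 1)`` over ``nodes``.
    """

    subject_id: object
    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes)
        self.weights = np.asarray(self.weights, dtype=float)
        k = len(self.nodes)
        if len(self.weights) != k * (k - 1) // 2:
            raise ValueError("need k(k-1)/2 weights for a k-node clique")
        if len(self.weights) and (
            not np.all(np.isfinite(self.weights))
            or self.weights.min() < 0
            or self.weights.max() > 1
        ):
            raise ValueError("weights must be finite and within [0, 1]")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def weight_matrix(self) -> np.ndarray:
        k = self.n_nodes
        w = np.zeros((k, k))
        ii, jj = np.triu_indices(k, 1)
        w[ii, jj] = self.weights
        w[jj, ii] = self.weights
        return w

    def iter_edges(self):
        """Yield ((node_i, node_j), weight) with i < j in node order."""
        ii, jj = np.triu_indices(self.n_nodes, 1)
        for a, b, w in zip(ii, jj, self.weights):
            yield (self.nodes[a], self.nodes[b]), float(w)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(int(n) for n in self.nodes)
        for (i, j), w in self.iter_edges():
            g.add_edge(int(i), int(j), weight=w)
        return g


def _class_fit(x: np.ndarray, ii, jj, eps_col):
    """Vectorized per-pair OLS of column jj on column ii over rows of x."""
    n = x.shape[0]
    mu = x.mean(axis=0)
    c = x - mu
    s = c.T @ c  # centered cross-products
    var = np.diag(s)
    sxx = var[ii]
    sxy = s[ii, jj]
    syy = var[jj]
    degenerate = sxx <= 0
    if np.any(degenerate):
        logger.warning(
            "%d pair(s) have a zero-variance predictor in one class; "
            "using slope 0 and the class mean as intercept",
            int(degenerate.sum()),
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(degenerate, 0.0, sxy / np.where(degenerate, 1.0, sxx))
    intercept = mu[jj] - slope * mu[ii]
    rss = syy - np.where(degenerate, 0.0, sxy**2 / np.where(degenerate, 1.0, sxx))
    rss = np.clip(rss, 0.0, None)
    sigma = np.sqrt(rss / (n - 2))
    sigma = np.maximum(sigma, eps_col[jj])
    return slope, intercept, sigma


def fit_pair_models(
    train: SpectraDataset,
    selected,
    epsilon_scale: float = EPSILON_SCALE,
) -> PairModelSet:
    """Fit control and patient lines for every unordered selected pair.

    The higher-index feature is always regressed on the lower-index one, so
    each unordered pair carries exactly one model and results are
    deterministic.  The residual-SD floor for a pair is
    ``epsilon_scale * IQR(m_j)`` measured over the whole training set
    (``epsilon_scale`` absolute when that IQR is zero).
    """
    selected = np.asarray(sorted(int(s) for s in selected), dtype=int)
    if len(selected) != len(set(selected.tolist())):
        raise ValueError("selected feature indices must be unique")
    if len(selected) < 2:
        raise ValueError("need at least 2 selected features")
    if selected.min() < 0 or selected.max() >= train.n_features:
        raise ValueError("selected indices out of range")
    rows_h = train.class_rows(CONTROL)
    rows_c = train.class_rows(PATIENT)
    for name, rows in ((CONTROL, rows_h), (PATIENT, rows_c)):
        if len(rows) < MIN_SUBJECTS_PER_CLASS:
            raise ValueError(
                f"need at least {MIN_SUBJECTS_PER_CLASS} {name} subjects, "
                f"got {len(rows)}"
            )

    cols = train.intensities[:, selected]
    q75, q25 = np.percentile(cols, [75, 25], axis=0)
    iqr = q75 - q25
    eps_col = np.where(iqr > 0, epsilon_scale * iqr, epsilon_scale)

    k = len(selected)
    ii, jj = np.triu_indices(k, 1)
    sh, bh, eh = _class_fit(cols[rows_h], ii, jj, eps_col)
    sc, bc, ec = _class_fit(cols[rows_c], ii, jj, eps_col)
    return PairModelSet(
        selected_features=selected,
        pair_i=ii,
        pair_j=jj,
        slope_control=sh,
        intercept_control=bh,
        sigma_control=eh,
        slope_patient=sc,
        intercept_patient=bc,
        sigma_patient=ec,
        epsilon=eps_col[jj],
    )


def _log_normal_density(d: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    # sqrt(2*pi) prefactor omitted: it cancels in the normalized ratio
    return -np.log(sigma) - 0.5 * (d / sigma) ** 2


def link_weight(model: PairModel, x_i: float, x_j: float) -> float:
    """Probability that the pair (x_i, x_j) follows the patient model.

    Computed as the ratio of the two normal densities (including the
    1/sigma prefactor) in log space; equal models or equal scaled
    residuals give exactly 0.5.
    """
    if not (np.isfinite(x_i) and np.isfinite(x_j)):
        raise ValueError("measurement values must be finite")
    d_h = x_j - (model.slope_control * x_i + model.intercept_control)
    d_c = x_j - (model.slope_patient * x_i + model.intercept_patient)
    lp_h = _log_normal_density(np.asarray(d_h), np.asarray(model.sigma_control))
    lp_c = _log_normal_density(np.asarray(d_c), np.asarray(model.sigma_patient))
    diff = lp_c - lp_h
    if not np.isfinite(diff):
        return 0.5
    return float(expit(diff))


def build_subject_network(
    models: PairModelSet, subject_row, subject_id=None
) -> SubjectNetwork:
    """Evaluate every pair model on one subject's measurement vector.

    ``subject_row`` is the full-length intensity vector; the selected
    features are picked out by the model set.  The result is deterministic
    given the models and the row.
    """
    row = np.asarray(subject_row, dtype=float)
    if row.ndim != 1 or row.shape[0] <= models.selected_features.max():
        raise ValueError(
            "subject row does not cover all selected features"
        )
    vals = row[models.selected_features]
    if not np.all(np.isfinite(vals)):
        raise ValueError("subject has non-finite values on selected features")
    x_i = vals[models.pair_i]
    x_j = vals[models.pair_j]
    d_h = x_j - (models.slope_control * x_i + models.intercept_control)
    d_c = x_j - (models.slope_patient * x_i + models.intercept_patient)
    diff = _log_normal_density(d_c, models.sigma_patient) - _log_normal_density(
        d_h, models.sigma_control
    )
    w = np.where(np.isfinite(diff), expit(np.nan_to_num(diff)), 0.5)
    return SubjectNetwork(subject_id=subject_id, nodes=models.selected_features, weights=w)


def build_all_networks(models: PairModelSet, dataset: SpectraDataset):
    """One weighted clique per subject of ``dataset``, in row order."""
    return [
        build_subject_network(models, dataset.intensities[r], dataset.subject_ids[r])
        for r in range(dataset.n_subjects)
    ]
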