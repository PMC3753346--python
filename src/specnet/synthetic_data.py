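"""Synthetic labeled spectra with planted class-dependent pair structure.

The generator emulates, at desk scale, the statistical structure the
network method assumes in SELDI-style benchmark data: many mutually
independent noisy measurements plus a small minority of measurements whose
pairwise linear relationship differs between patients and controls.

The informative measurements form a chain: the first one is drawn around
the baseline, and each subsequent one follows

    m_{i+1} = a_class * m_i + b_class + eps,   eps ~ N(0, residual_sd),

with class-specific slope/intercept.  A chain (rather than independent
coupled pairs) makes every informative feature share high mutual
information with the others — the regime where high-S selection is
expected to recover them — while keeping the per-class OLS slopes of
adjacent pairs analytically known.  Uninformative features are independent
Gaussians around the baseline.

Defaults describe the "strong effect" regime: control slope +1, patient
slope -1, equal intercepts, residual sd 0.1, noise sd 1.0.  The baseline
defaults to 0, so intensities are mean-centered arbitrary units and may be
negative; generated datasets therefore set ``allow_negative``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .feature_selection import FeatureRanking
from .spectra_io import CONTROL, PATIENT, SpectraDataset

GENERATOR = "numpy PCG64 (np.random.default_rng)"


@dataclass(frozen=True)
class Coupling:
    """Class-conditional linear chain parameters for informative features."""

    control_slope: float = 1.0
    control_intercept: float = 0.0
    patient_slope: float = -1.0
    patient_intercept: float = 0.0
    residual_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be positive")


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of one synthetic cohort; the seed is part of it."""

    n_control: int = 30
    n_patient: int = 30
    n_features: int = 200
    informative_features: tuple = tuple(range(20))
    coupling: Coupling = field(default_factory=Coupling)
    noise_sd: float = 1.0
    baseline: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 3 or self.n_patient < 3:
            raise ValueError("need at least 3 subjects per class")
        if self.n_features < 1:
            raise ValueError("n_features must be positive")
        inf = tuple(int(i) for i in self.informative_features)
        if len(set(inf)) != len(inf):
            raise ValueError("informative_features must be unique")
        if inf and (min(inf) < 0 or max(inf) >= self.n_features):
            raise ValueError("informative_features out of range")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        object.__setattr__(self, "informative_features", inf)

    @property
    def q(self) -> int:
        return len(self.informative_features)


def strong_effect_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """The strong-effect regime: opposite class slopes, low residual noise."""
    return replace(SyntheticSpec(seed=seed), **overrides)


def null_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """No class difference: both classes share the control chain parameters.

    The informative chain is still present (features are correlated), but
    carries no class signal, so any downstream classification above the
    class prior indicates leakage.
    """
    coupling = Coupling(
        control_slope=1.0,
        control_intercept=0.0,
        patient_slope=1.0,
        patient_intercept=0.0,
        residual_sd=0.1,
    )
    return replace(SyntheticSpec(seed=seed, coupling=coupling), **overrides)


def _class_block(rng, n, spec: SyntheticSpec, slope, intercept) -> np.ndarray:
    x = rng.normal(spec.baseline, spec.noise_sd, size=(n, spec.n_features))
    chain = spec.informative_features
    for prev, nxt in zip(chain[:-1], chain[1:]):
        eps = rng.normal(0.0, spec.coupling.residual_sd, size=n)
        x[:, nxt] = slope * x[:, prev] + intercept + eps
    return x


def generate(spec: SyntheticSpec) -> SpectraDataset:
    """Generate a labeled cohort; identical spec (incl. seed) -> identical data.

    Controls occupy the first ``n_control`` rows.  Ground truth lives in
    the spec itself (``informative_features`` and the coupling).
    """
    rng = np.random.default_rng(spec.seed)
    ctrl = _class_block(
        rng, spec.n_control, spec,
        spec.coupling.control_slope, spec.coupling.control_intercept,
    )
    pat = _class_block(
        rng, spec.n_patient, spec,
        spec.coupling.patient_slope, spec.coupling.patient_intercept,
    )
    labels = np.array(
        [CONTROL] * spec.n_control + [PATIENT] * spec.n_patient, dtype=object
    )
    subject_ids = [f"C{i:03d}" for i in range(spec.n_control)] + [
        f"P{i:03d}" for i in range(spec.n_patient)
    ]
    return SpectraDataset(
        intensities=np.vstack([ctrl, pat]),
        labels=labels,
        feature_ids=list(range(spec.n_features)),
        subject_ids=subject_ids,
        allow_negative=True,
    )


def ground_truth_recovery(
    dataset: SpectraDataset,
    ranking: FeatureRanking,
    spec: SyntheticSpec,
    strategy: str = "high_S",
) -> float:
    """Fraction of planted features among the top-q of the given ordering."""
    if ranking.n_features != spec.n_features or dataset.n_features != spec.n_features:
        raise ValueError("ranking/dataset do not match the synthetic spec")
    if spec.q == 0:
        raise ValueError("spec has no informative features")
    top = set(ranking.order_for(strategy)[: spec.q].tolist())
    return len(top & set(spec.informative_features)) / spec.q
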