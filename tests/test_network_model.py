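"""Pairwise OLS model fitting and normalized-likelihood link weights."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from specnet import (
    PairModel,
    SpectraDataset,
    build_subject_network,
    fit_pair_models,
    generate,
    link_weight,
    strong_effect_spec,
)


def ols_oracle(x, y):
    """Closed-form OLS by the normal equations, independent of the library
    path, with residual SD on n - 2 degrees of freedom."""
    A = np.column_stack([x, np.ones_like(x)])
    slope, intercept = np.linalg.solve(A.T @ A, A.T @ y)
    resid = y - (slope * x + intercept)
    sigma = np.sqrt(resid @ resid / (len(x) - 2))
    return slope, intercept, sigma


def _dataset(ctrl, pat):
    mat = np.vstack([ctrl, pat])
    labels = ["control"] * len(ctrl) + ["patient"] * len(pat)
    return SpectraDataset(
        mat, np.array(labels, dtype=object), allow_negative=True
    )


def _model(sh=1.0, bh=0.0, eh=1.0, sc=1.0, bc=0.0, ec=1.0):
    return PairModel(
        feature_i=0, feature_j=1,
        slope_control=sh, intercept_control=bh, sigma_control=eh,
        slope_patient=sc, intercept_patient=bc, sigma_patient=ec,
    )


class TestFitPairModels:
    def test_perfect_fit_recovers_line_and_floors_sigma(self, rng):
        x = np.linspace(0, 1, 5)
        ctrl = np.column_stack([x, 2 * x + 1])
        pat = np.column_stack([x, rng.normal(size=5)])
        models = fit_pair_models(_dataset(ctrl, pat), [0, 1])
        m = models.models[0]
        assert m.slope_control == pytest.approx(2.0, abs=1e-12)
        assert m.intercept_control == pytest.approx(1.0, abs=1e-12)
        assert m.sigma_control == models.epsilon[0]  # collinear -> floor

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(20):
            ctrl = rng.normal(size=(5, 2)) * rng.uniform(0.5, 20)
            pat = rng.normal(size=(6, 2))
            models = fit_pair_models(_dataset(ctrl, pat), [0, 1])
            m = models.models[0]
            s, b, e = ols_oracle(ctrl[:, 0], ctrl[:, 1])
            assert m.slope_control == pytest.approx(s, abs=1e-10)
            assert m.intercept_control == pytest.approx(b, abs=1e-10)
            assert m.sigma_control == pytest.approx(e, abs=1e-10)
            s, b, e = ols_oracle(pat[:, 0], pat[:, 1])
            assert m.slope_patient == pytest.approx(s, abs=1e-10)

    def test_pair_count_for_25_features(self, rng):
        ds = _dataset(rng.normal(size=(4, 30)), rng.normal(size=(4, 30)))
        models = fit_pair_models(ds, np.arange(25))
        assert models.n_pairs == 300

    def test_requires_three_subjects_per_class(self, rng):
        ds = _dataset(rng.normal(size=(2, 3)), rng.normal(size=(5, 3)))
        with pytest.raises(ValueError, match="control"):
            fit_pair_models(ds, [0, 1])

    def test_zero_variance_predictor_falls_back_to_class_mean(self, rng):
        ctrl = np.column_stack([np.full(4, 7.0), [1.0, 2.0, 3.0, 4.0]])
        pat = rng.normal(size=(4, 2))
        models = fit_pair_models(_dataset(ctrl, pat), [0, 1])
        m = models.models[0]
        assert m.slope_control == 0.0
        assert m.intercept_control == pytest.approx(2.5)

    def test_row_order_invariance(self, rng):
        ctrl = rng.normal(size=(6, 3))
        pat = rng.normal(size=(5, 3))
        ds = _dataset(ctrl, pat)
        perm = rng.permutation(ds.n_subjects)
        a = fit_pair_models(ds, [0, 1, 2])
        b = fit_pair_models(ds.subset(perm), [0, 1, 2])
        np.testing.assert_allclose(a.slope_control, b.slope_control, atol=1e-12)
        np.testing.assert_allclose(a.sigma_patient, b.sigma_patient, atol=1e-12)


class TestLinkWeight:
    def test_identical_models_give_half(self):
        m = _model(sh=1.5, bh=0.3, eh=0.7, sc=1.5, bc=0.3, ec=0.7)
        assert link_weight(m, 2.0, 5.0) == 0.5

    def test_closed_form_density_ratio(self):
        # residual 0 from the patient line, 2 from the control line, unit
        # sigmas: w = 1 / (1 + exp(-2))
        m = _model(sh=1.0, bh=2.0, eh=1.0, sc=1.0, bc=0.0, ec=1.0)
        w = link_weight(m, 1.0, 1.0)
        assert w == pytest.approx(1.0 / (1.0 + np.exp(-2.0)), abs=1e-12)
        assert w == pytest.approx(0.880797, abs=1e-6)

    def test_equal_absolute_residuals_equal_sigmas_give_half(self):
        m = _model(bh=1.0, bc=-1.0)  # residuals -1 and +1 at x_j = x_i
        assert link_weight(m, 0.5, 0.5) == 0.5

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError):
            link_weight(_model(), np.nan, 1.0)

    @given(
        d_h=st.floats(0.1, 5), d_c=st.floats(0.1, 5),
        bump=st.floats(0.1, 3), sigma=st.floats(0.2, 3),
    )
    def test_monotone_in_residual_distances(self, d_h, d_c, bump, sigma):
        """w grows with the control-line residual and shrinks with the
        patient-line residual, at fixed sigmas."""
        def w(dh, dc):
            m = _model(sh=0.0, bh=-dh, eh=sigma, sc=0.0, bc=-dc, ec=sigma)
            return link_weight(m, 0.0, 0.0)  # residuals are dh, dc

        assert w(d_h + bump, d_c) >= w(d_h, d_c)
        assert w(d_h, d_c + bump) <= w(d_h, d_c)


class TestBuildSubjectNetwork:
    def _separated_models(self):
        x = np.linspace(0, 1, 8)
        ctrl = np.column_stack([x, x, x])  # m_j = m_i
        pat = np.column_stack([x, x + 5, x + 10])  # far offset lines
        ctrl += np.random.default_rng(0).normal(0, 1e-3, ctrl.shape)
        pat += np.random.default_rng(1).normal(0, 1e-3, pat.shape)
        return fit_pair_models(_dataset(ctrl, pat), [0, 1, 2])

    def test_patient_like_subject_gets_heavy_edges(self):
        models = self._separated_models()
        net = build_subject_network(models, np.array([0.5, 5.5, 10.5]), "p")
        assert np.all(net.weights > 0.5)

    def test_control_like_subject_gets_light_edges(self):
        models = self._separated_models()
        net = build_subject_network(models, np.array([0.5, 0.5, 0.5]), "c")
        assert np.all(net.weights < 0.5)

    def test_determinism(self):
        models = self._separated_models()
        row = np.array([0.2, 3.0, 7.0])
        a = build_subject_network(models, row, "s")
        b = build_subject_network(models, row, "s")
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_missing_feature_value_rejected(self):
        models = self._separated_models()
        with pytest.raises(ValueError):
            build_subject_network(models, np.array([0.1, 0.2]), "s")
        with pytest.raises(ValueError):
            build_subject_network(models, np.array([0.1, np.nan, 0.3]), "s")

    def test_weights_lie_in_unit_interval(self, rng):
        ds = generate(strong_effect_spec(seed=3, n_features=12,
                                         informative_features=tuple(range(6))))
        models = fit_pair_models(ds, np.arange(12))
        for r in range(0, ds.n_subjects, 7):
            net = build_subject_network(models, ds.intensities[r], r)
            assert np.all((net.weights >= 0) & (net.weights <= 1))
            assert np.all(np.isfinite(net.weights))


class TestClassSwapSymmetry:
    def test_relabeling_classes_flips_weights(self):
        spec = strong_effect_spec(seed=11, n_control=12, n_patient=10,
                                  n_features=15,
                                  informative_features=tuple(range(6)))
        ds = generate(spec)
        swapped = SpectraDataset(
            ds.intensities,
            np.array(
                ["patient" if l == "control" else "control" for l in ds.labels],
                dtype=object,
            ),
            feature_ids=list(ds.feature_ids),
            subject_ids=list(ds.subject_ids),
            allow_negative=True,
        )
        sel = np.arange(10)
        m1 = fit_pair_models(ds, sel)
        m2 = fit_pair_models(swapped, sel)
        row = ds.intensities[0]
        w1 = build_subject_network(m1, row, "s").weights
        w2 = build_subject_network(m2, row, "s").weights
        np.testing.assert_allclose(w2, 1.0 - w1, atol=1e-9)
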