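"""Tests for the integral-coefficient identifiability metric."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from practident import (
    IGT,
    NGT,
    build_case,
    case_delta_norm,
    coefficient_curves,
    delta_norm,
    disst_protocol,
    fit_mu,
    iterative_fit,
    predicted_cv_ratio,
)
from practident.metric import CoefficientCurves


def curves_from(c1, c2):
    c1, c2 = np.asarray(c1, float), np.asarray(c2, float)
    t = np.arange(1.0, len(c1) + 1.0)
    return CoefficientCurves(t, ("a", "b"), c1, c2, c1 / c1.mean(), c2 / c2.mean())


class TestNormalisation:
    def test_normalised_curves_have_unit_mean(self, ngt_cases):
        cc = coefficient_curves(ngt_cases["nT_VP"])
        assert cc.n1.mean() == pytest.approx(1.0, abs=1e-12)
        assert cc.n2.mean() == pytest.approx(1.0, abs=1e-12)

    def test_proportional_coefficients_are_indistinct(self):
        c1 = np.array([1.0, 2.0, 5.0, 7.0])
        d = delta_norm(curves_from(c1, 3.7 * c1))
        assert d.delta_norm == pytest.approx(0.0, abs=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(
        c=arrays(np.float64, 6, elements=st.floats(0.1, 100.0)),
        d=arrays(np.float64, 6, elements=st.floats(0.1, 100.0)),
        k=st.floats(0.01, 1000.0),
    )
    def test_delta_invariant_to_positive_rescaling(self, c, d, k):
        a = delta_norm(curves_from(c, d)).delta_norm
        b = delta_norm(curves_from(k * c, d)).delta_norm
        assert a == pytest.approx(b, rel=1e-9, abs=1e-12)

    def test_more_than_two_free_parameters_out_of_scope(self, ngt_cases):
        with pytest.raises(ValueError, match="two-free-parameter"):
            coefficient_curves(ngt_cases["five_param"])


class TestDeltaNorm:
    def test_identical_curves_give_zero(self):
        c = np.array([1.0, 4.0, 9.0])
        assert delta_norm(curves_from(c, c)).delta_norm == 0.0

    def test_unit_offset_gives_one(self):
        cc = curves_from([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        cc.n1 = cc.n2 + np.array([1.0, 0.0, 0.0])
        assert delta_norm(cc).delta_norm == 1.0

    def test_saturation_free_case_exactly_zero(self, prot5):
        case = build_case("nK_nL", NGT.with_overrides(alphaI=0.0), prot5)
        assert case_delta_norm(case).delta_norm == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_metric_implies_singular_fit(self, prot5):
        # metric <-> matrix singularity: a vanishing distinction must trip
        # the condition-number flag of the fit on the same case
        case = build_case("nK_nL", NGT.with_overrides(alphaI=0.0), prot5)
        assert case_delta_norm(case).delta_norm < 1e-10
        fit = iterative_fit(case, case.noiseless_samples())
        assert fit.ill_conditioned


class TestQualitativeShapes:
    def test_pG_coefficient_convex_for_ngt(self, prot10):
        # glucose crosses basal during the test, so the pG coefficient
        # integral rises then falls (convex shape) for the NGT participant
        cc = coefficient_curves(build_case("SI_pG", NGT, prot10))
        pg_raw = cc.c2
        peak = np.argmax(np.abs(pg_raw))
        assert 0 < peak < len(pg_raw) - 1
        assert np.abs(pg_raw[-1]) < np.abs(pg_raw[peak])

    def test_ir_participant_less_identifiable(self, prot10):
        d_ngt = case_delta_norm(build_case("SI_pG", NGT, prot10)).delta_norm
        d_ir = case_delta_norm(build_case("SI_pG", IGT, prot10)).delta_norm
        assert d_ngt > d_ir


class TestPredictedRatio:
    def test_equal_norms_ratio_one(self):
        c = np.array([1.0, 2.0, 3.0])
        d = delta_norm(curves_from(c, c**2))
        assert predicted_cv_ratio(d, d) == 1.0

    def test_zero_denominator_is_infinite(self):
        c = np.array([1.0, 2.0, 3.0])
        zero = delta_norm(curves_from(c, c))
        other = delta_norm(curves_from(c, c**2))
        assert predicted_cv_ratio(zero, other) == np.inf


class TestFitMu:
    def test_single_point_slope(self):
        mu = fit_mu({"a": [(0.02, 0.5, 0.12)]})
        assert mu.mu["a"] == pytest.approx(0.12 / (0.02 / 0.5))

    def test_exact_line_through_origin(self):
        pts = [(e, 0.5, 3.0 * e / 0.5) for e in (0.01, 0.02, 0.035)]
        mu = fit_mu({"a": pts})
        assert mu.mu["a"] == pytest.approx(3.0)
        assert mu.max_rel_residual["a"] == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_points_rejected(self):
        with pytest.raises(ValueError):
            fit_mu({"a": [(0.0, 1.0, 0.1)]})
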