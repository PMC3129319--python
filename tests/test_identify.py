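"""Tests for the iterative integral identification method."""

import numpy as np
import pytest

from practident import (
    IGT,
    NGT,
    add_noise,
    build_case,
    disst_protocol,
    integral_coefficients,
    iterative_fit,
    nls_fit,
)

ALL_KINDS = ("nK_nL", "nT_VP", "SI_VG", "SI_pG", "five_param")


class TestBuildCase:
    def test_unknown_kind_rejected(self, prot5):
        with pytest.raises(ValueError):
            build_case("bogus", NGT, prot5)

    def test_nT_VP_matrix_has_twelve_rows(self, ngt_cases, prot5):
        case = ngt_cases["nT_VP"]
        A, b = integral_coefficients(case, case.noiseless_samples(), case.assumed_profiles())
        assert A.shape == (12, 2)
        assert b.shape == (12,)

    def test_VG_column_is_bolus_step(self, ngt_cases):
        # 1/VG column: zero before the glucose bolus at t = 7.5, equal to
        # the bolus dose in mmol afterwards
        case = ngt_cases["SI_VG"]
        A = case.columns_fn(case.assumed_profiles(), np.asarray(case.protocol.sample_times))
        col = A[:, 1]
        times = np.asarray(case.protocol.sample_times)[1:]
        dose_mmol = 10.0 * 1000.0 / 180.16
        assert np.all(col[times < 7.5] == 0.0)
        assert np.allclose(col[times > 7.5], dose_mmol)

    def test_saturation_free_clearances_are_collinear(self, prot5):
        # with alphaI = 0 the nK and nL columns coincide and A is rank 1
        case = build_case("nK_nL", NGT.with_overrides(alphaI=0.0), prot5)
        A, _ = integral_coefficients(case, case.noiseless_samples(), case.assumed_profiles())
        assert np.allclose(A[:, 0], A[:, 1])
        assert np.linalg.matrix_rank(A) == 1

    def test_underdetermined_sampling_rejected(self, prot5):
        case = build_case("nK_nL", NGT, disst_protocol(sample_times=(0.0, 30.0)))
        with pytest.raises(ValueError, match="underdetermined"):
            integral_coefficients(case, case.noiseless_samples(), case.assumed_profiles())


class TestIntegralIdentity:
    @pytest.mark.parametrize("kind", ALL_KINDS)
    def test_truth_satisfies_integral_equation(self, ngt_cases, kind):
        case = ngt_cases[kind]
        A, b = integral_coefficients(case, case.noiseless_samples(), case.assumed_profiles())
        theta = case.to_linear(case.true_values)
        resid = A @ theta - b
        assert np.max(np.abs(resid)) / np.max(np.abs(b)) < 1e-10


class TestIterativeFit:
    @pytest.mark.parametrize("kind", ALL_KINDS)
    def test_noiseless_recovery_from_half_truth(self, ngt_cases, kind):
        case = ngt_cases[kind]
        fit = iterative_fit(case, case.noiseless_samples())
        assert fit.converged
        for s in case.free_params:
            assert fit.estimates[s] == pytest.approx(case.true_values[s], rel=1e-3)

    def test_init_at_truth_converges_immediately(self, ngt_cases):
        case = ngt_cases["SI_VG"]
        fit = iterative_fit(case, case.noiseless_samples(), init=case.true_values,
                            method="picard")
        assert fit.converged and fit.iterations <= 2

    def test_sparse_protocol_still_exact_without_noise(self):
        case = build_case("nT_VP", NGT, disst_protocol(sample_times=(0, 5, 45, 60)))
        fit = iterative_fit(case, case.noiseless_samples())
        assert fit.converged
        for s in case.free_params:
            assert fit.estimates[s] == pytest.approx(case.true_values[s], rel=1e-3)

    def test_free_parameter_order_is_immaterial(self, ngt_cases):
        # swap the two columns/symbols of the SI_pG case and check the
        # per-symbol estimates are unchanged
        import copy

        case = ngt_cases["SI_pG"]
        swapped = copy.copy(case)
        swapped.free_params = case.free_params[::-1]
        swapped.columns_fn = lambda prof, t: case.columns_fn(prof, t)[:, ::-1]
        orig_corr = case.correction_fn
        swapped.correction_fn = lambda prof, m, t: (
            orig_corr(prof, m, t)[0][:, ::-1],
            orig_corr(prof, m, t)[1],
        )
        swapped.to_linear = lambda nat: case.to_linear(nat)[::-1]
        swapped.from_linear = lambda v: case.from_linear(np.asarray(v)[::-1])
        data = add_noise(case.noiseless_samples(), 0.01, 42)
        fit_a = iterative_fit(case, data)
        fit_b = iterative_fit(swapped, data)
        for s in case.free_params:
            assert fit_a.estimates[s] == pytest.approx(fit_b.estimates[s], rel=1e-6)

    def test_degenerate_case_flagged_not_raised(self, prot5):
        case = build_case("nK_nL", NGT.with_overrides(alphaI=0.0), prot5)
        fit = iterative_fit(case, case.noiseless_samples())
        assert fit.ill_conditioned

    def test_history_records_every_update(self, ngt_cases):
        case = ngt_cases["SI_VG"]
        fit = iterative_fit(case, case.noiseless_samples())
        assert len(fit.history) >= fit.iterations
        assert set(fit.history[0]) == set(case.free_params)

    def test_json_export(self, ngt_cases):
        case = ngt_cases["SI_VG"]
        fit = iterative_fit(case, case.noiseless_samples())
        import json

        d = json.loads(json.dumps(fit.to_json_dict()))
        assert set(d["estimates"]) == {"SI", "VG"}
        assert d["converged"] is True


class TestOracleEquivalence:
    @pytest.mark.parametrize("kind", ("nK_nL", "SI_pG"))
    def test_matches_nonlinear_least_squares_on_noiseless_data(self, ngt_cases, kind):
        case = ngt_cases[kind]
        data = case.noiseless_samples()
        it = iterative_fit(case, data)
        nls = nls_fit(case, data)
        for s in case.free_params:
            assert it.estimates[s] == pytest.approx(nls[s], rel=5e-3)

    def test_igt_case_matches_oracle(self, prot10):
        case = build_case("SI_pG", IGT, prot10)
        data = case.noiseless_samples()
        it = iterative_fit(case, data)
        nls = nls_fit(case, data)
        for s in case.free_params:
            assert it.estimates[s] == pytest.approx(nls[s], rel=5e-3)
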