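"""Tests of the mixed-effects objective, fitting and selection machinery."""

import numpy as np
import pytest

from cefapk import (
    FINAL_MODEL,
    ModelStructure,
    StudyDesign,
    compare_structures,
    covariate_search,
    default_init,
    fit,
    ofv,
    simulate_dataset,
)
from cefapk.estimate import _build
from oracles import agq_neg2ll

NO_IIV = {"cl": False, "vc": False, "q": False, "vp": False, "fpa": False}


@pytest.fixture(scope="module")
def tiny_cohort(reference_params):
    """Two-subject toy with IIV on CL only (quadrature oracle target)."""
    truth = reference_params.with_(
        omega_cl=0.1, omega_vc=0.0, omega_vp=0.0, omega_fpa=0.0, sigma_prop=0.15
    )
    return simulate_dataset(truth, StudyDesign(n_subjects=2), seed=5), truth


class TestOFV:
    def test_single_gaussian_closed_form(self, reference_params):
        """With no random effects the OFV is the plain Gaussian deviance."""
        truth = reference_params.with_(sigma_prop=0.2)
        ds = simulate_dataset(truth, StudyDesign(n_subjects=3), seed=9)
        structure = ModelStructure(iiv=NO_IIV, covariate_terms=(("cl", "clcr", "power"),),
                                  covariate_refs={"clcr": 69.0})
        est = default_init(structure)
        est.update(truth.as_estimates())
        data, par, eng = _build(ds, structure)
        typ = eng.typical_params(est)
        f = eng.predict(typ, np.zeros((data.n_subjects, 0)))
        v = truth.sigma_prop**2 * f**2
        expected = np.where(
            eng.mask, np.log(2 * np.pi) + np.log(v) + (data.y - f) ** 2 / v, 0.0
        ).sum()
        assert ofv(ds, structure, est) == pytest.approx(expected, rel=1e-9)
        # foce and laplace coincide in the no-random-effects limit
        assert ofv(ds, structure, est, method="laplace") == pytest.approx(expected, rel=1e-9)

    def test_zero_residual_case(self, reference_params):
        """y == f exactly: only the ln(2 pi v) terms remain."""
        truth = reference_params.with_(
            omega_cl=0, omega_vc=0, omega_vp=0, omega_fpa=0, sigma_prop=1e-12
        )
        ds = simulate_dataset(truth, StudyDesign(n_subjects=2), seed=4)
        structure = ModelStructure(iiv=NO_IIV, covariate_terms=(("cl", "clcr", "power"),),
                                  covariate_refs={"clcr": 69.0})
        est = default_init(structure)
        est.update(truth.as_estimates())
        est["sigma_prop"] = 0.1
        data, par, eng = _build(ds, structure)
        typ = eng.typical_params(est)
        f = eng.predict(typ, np.zeros((data.n_subjects, 0)))
        expected = np.where(
            eng.mask, np.log(2 * np.pi) + np.log(0.1**2 * f**2), 0.0
        ).sum()
        assert ofv(ds, structure, est) == pytest.approx(expected, rel=1e-6)

    @pytest.mark.parametrize("method", ["foce", "laplace"])
    def test_matches_quadrature_oracle_one_random_effect(self, tiny_cohort, method):
        """FOCE/Laplace agree with adaptive Gauss–Hermite within 1%."""
        ds, truth = tiny_cohort
        structure = ModelStructure(
            iiv={"cl": True, "vc": False, "q": False, "vp": False, "fpa": False},
            covariate_terms=(("cl", "clcr", "power"),),
            covariate_refs={"clcr": 69.0},
        )
        est = default_init(structure)
        est.update(truth.as_estimates())
        data, par, eng = _build(ds, structure)
        oracle = agq_neg2ll(eng, est, n_nodes=41)
        approx = eng.ofv(est, method=method)
        assert approx == pytest.approx(oracle, rel=0.01)

    def test_matches_quadrature_oracle_two_random_effects(self, reference_params):
        truth = reference_params.with_(
            omega_cl=0.4, omega_vc=0.5, omega_vp=0.0, omega_fpa=0.0, sigma_prop=0.15
        )
        ds = simulate_dataset(truth, StudyDesign(n_subjects=4), seed=13)
        structure = ModelStructure(
            iiv={"cl": True, "vc": True, "q": False, "vp": False, "fpa": False},
            covariate_terms=(("cl", "clcr", "power"),),
            covariate_refs={"clcr": 69.0},
        )
        est = default_init(structure)
        est.update(truth.as_estimates())
        _, _, eng = _build(ds, structure)
        oracle = agq_neg2ll(eng, est, n_nodes=31)
        for method in ("foce", "laplace"):
            assert eng.ofv(est, method=method) == pytest.approx(oracle, rel=0.01)


class TestFit:
    def test_noise_free_recovery(self, reference_params):
        """Degenerate generator (omega = sigma = 0) is recovered to <=0.1%."""
        truth = reference_params.with_(
            omega_cl=0, omega_vc=0, omega_vp=0, omega_fpa=0, sigma_prop=1e-8
        )
        ds = simulate_dataset(truth, seed=3)
        structure = ModelStructure(iiv=NO_IIV, covariate_terms=(("cl", "clcr", "power"),),
                                  covariate_refs={"clcr": 69.0})
        fr = fit(ds, structure, compute_se=False)
        for name, expected in [
            ("cl", 25.8), ("vc", 44.3), ("q", 44.0), ("vp", 52.2),
            ("fpa", 0.638), ("beta_cl_clcr", 0.735),
        ]:
            assert fr.estimates[name] == pytest.approx(expected, rel=1e-3), name

    def test_aic_identity_and_metadata(self, small_cohort, final_structure, fast_fit_options):
        fr = fit(small_cohort, final_structure, options=fast_fit_options, compute_se=False)
        assert fr.aic == pytest.approx(fr.ofv + 2 * fr.n_params)
        assert fr.n_params == 11
        assert fr.n_subjects == 16
        assert fr.eta_modes.shape == (16, 4)

    def test_deterministic_given_init_and_options(self, small_cohort, final_structure, fast_fit_options):
        a = fit(small_cohort, final_structure, options=fast_fit_options, compute_se=False)
        b = fit(small_cohort, final_structure, options=fast_fit_options, compute_se=False)
        assert a.ofv == b.ofv
        assert a.estimates == b.estimates

    def test_multistart_agreement(self, small_cohort, final_structure):
        """Two sane starting points reach the same optimum."""
        init_b = default_init(final_structure)
        init_b.update({"cl": 30.0, "vc": 60.0, "q": 20.0, "vp": 35.0, "beta_cl_clcr": 0.5})
        a = fit(small_cohort, final_structure, compute_se=False)
        b = fit(small_cohort, final_structure, init=init_b, compute_se=False)
        assert a.ofv == pytest.approx(b.ofv, abs=1.0)

    def test_standard_errors_reported(self, small_cohort, final_structure, fast_fit_options):
        fr = fit(small_cohort, final_structure, options=fast_fit_options)
        assert set(fr.rse) == set(fr.estimates)
        finite = [v for v in fr.rse.values() if np.isfinite(v)]
        assert finite and all(v > 0 for v in finite)


class TestCompareStructures:
    def test_identical_candidates_tie(self, small_cohort, final_structure, fast_fit_options):
        ranked = compare_structures(
            small_cohort, [final_structure, final_structure], options=fast_fit_options
        )
        assert ranked[0]["aic"] == pytest.approx(ranked[1]["aic"], abs=1e-6)
        assert ranked[0]["delta_aic"] == 0.0


class TestCovariateSearch:
    def test_empty_candidate_list_returns_base(self, small_cohort, fast_fit_options):
        base = ModelStructure.base_2cpt()
        final, fr, log = covariate_search(
            small_cohort, base, candidates=(), options=fast_fit_options
        )
        assert final == base
        assert log == []

    def test_nesting_property(self, small_cohort, fast_fit_options):
        """Adding a covariate term can only decrease the optimal OFV."""
        base = ModelStructure.base_2cpt()
        with_term = base.with_term(("cl", "clcr", "power"))
        fr_base = fit(small_cohort, base, options=fast_fit_options, compute_se=False)
        init = dict(fr_base.estimates)
        init["beta_cl_clcr"] = 0.0
        fr_full = fit(small_cohort, with_term, init=init, options=fast_fit_options,
                      compute_se=False)
        assert fr_full.ofv <= fr_base.ofv + 1e-6
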