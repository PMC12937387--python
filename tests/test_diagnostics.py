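"""Tests of CWRES, pc-VPC and bootstrap mechanics on small problems."""

import numpy as np
import pytest

from cefapk import ModelStructure, StudyDesign, bootstrap, cwres, fit, pcvpc, simulate_dataset
from cefapk.estimate import default_init
from cefapk.pkmodel import SERUM, TISSUE

NO_IIV = {"cl": False, "vc": False, "q": False, "vp": False, "fpa": False}


@pytest.fixture(scope="module")
def pooled_fit(reference_params):
    """A no-IIV fit whose CWRES reduce to plain weighted residuals."""
    truth = reference_params.with_(
        omega_cl=0, omega_vc=0, omega_vp=0, omega_fpa=0, sigma_prop=0.2
    )
    ds = simulate_dataset(truth, StudyDesign(n_subjects=12), seed=31)
    structure = ModelStructure(iiv=NO_IIV, covariate_terms=(("cl", "clcr", "power"),),
                              covariate_refs={"clcr": 69.0})
    fr = fit(ds, structure, compute_se=False)
    return ds, fr


@pytest.fixture(scope="module")
def small_fit(small_cohort, final_structure, fast_fit_options):
    fr = fit(small_cohort, final_structure, options=fast_fit_options, compute_se=False)
    return small_cohort, fr


class TestCWRES:
    def test_reduces_to_weighted_residuals_without_random_effects(self, pooled_fit):
        ds, fr = pooled_fit
        table = cwres(ds, fr)
        sigma = fr.estimates["sigma_prop"]
        expected = (table.dv - table.ipred) / (sigma * table.ipred)
        np.testing.assert_allclose(table.cwres, expected, rtol=1e-6)

    def test_invariant_to_observation_order_within_subject(self, small_fit):
        ds, fr = small_fit
        table = cwres(ds, fr)
        shuffled = []
        for s in ds.subjects:
            import copy

            s2 = copy.copy(s)
            s2.observations = list(reversed(s.observations))
            shuffled.append(s2)
        table2 = cwres(shuffled, fr)
        a = table.sort_values(["id", "time", "channel"]).cwres.to_numpy()
        b = table2.sort_values(["id", "time", "channel"]).cwres.to_numpy()
        np.testing.assert_allclose(np.sort(a), np.sort(b), rtol=1e-8)

    def test_rows_cover_both_channels(self, small_fit):
        ds, fr = small_fit
        table = cwres(ds, fr)
        assert set(table.channel) == {SERUM, TISSUE}
        assert len(table) == sum(len(s.observations) for s in ds.subjects)


class TestPcVPC:
    def test_identity_correction_when_pred_constant(self, small_fit):
        """All PRED equal within a bin -> prediction correction is a no-op."""
        ds, fr = small_fit
        res = pcvpc(ds, fr, n_rep=30, bins=1, seed=2, channel=TISSUE)
        # single bin: correction = median(PRED)/PRED; check the observed
        # median is within the simulated envelope rather than distorted
        assert res.observed.shape[0] == 1
        assert res.n_replicates == 30

    def test_single_replicate_degenerate_bands(self, small_fit):
        ds, fr = small_fit
        res = pcvpc(ds, fr, n_rep=1, bins=3, seed=9)
        np.testing.assert_allclose(res.ci_lower, res.ci_upper)

    def test_deterministic_given_seed(self, small_fit):
        ds, fr = small_fit
        a = pcvpc(ds, fr, n_rep=25, seed=4)
        b = pcvpc(ds, fr, n_rep=25, seed=4)
        np.testing.assert_array_equal(a.ci_lower, b.ci_lower)
        np.testing.assert_array_equal(a.observed, b.observed)

    def test_percentile_bands_ordered(self, small_fit):
        ds, fr = small_fit
        res = pcvpc(ds, fr, n_rep=50, seed=6)
        assert np.all(res.ci_lower <= res.ci_upper)
        assert np.all(np.diff(res.observed, axis=1) >= 0)  # 2.5 <= 50 <= 97.5


class TestBootstrap:
    def test_identical_subjects_give_degenerate_percentiles(self, reference_params):
        """Resampling a cohort of clones returns the point estimate everywhere."""
        from cefapk import DoseEvent, Observation, SubjectCovariates, SubjectRecord, apply_iiv
        from cefapk.pkmodel import conc_unbound

        truth = reference_params
        cov = SubjectCovariates(age=69, weight=67.2, serum_creatinine=0.92)
        doses = [DoseEvent(0.0, 1000.0, 1 / 6), DoseEvent(3.0, 1000.0, 1 / 6)]
        ind = apply_iiv(truth, cov.clcr, np.zeros(4))
        rng = np.random.default_rng(8)
        obs = []
        for t in (0.3, 0.8, 1.5, 2.2, 3.0, 3.6, 4.2, 4.8, 6.5, 9.0, 12.0):
            f = float(conc_unbound(ind, doses, t))
            obs.append(Observation(t, f * (1 + 0.15 * rng.standard_normal()), SERUM))
        f_tis = truth.theta6 * float(conc_unbound(ind, doses, 2.2))
        obs.append(Observation(2.2, f_tis * (1 + 0.15 * rng.standard_normal()), TISSUE))
        obs.sort(key=lambda o: (o.time, o.channel))
        clones = [SubjectRecord(i + 1, cov, doses, list(obs)) for i in range(6)]
        # no covariate term: a single shared CLcr value cannot identify one
        structure = ModelStructure(iiv=NO_IIV)
        br = bootstrap(clones, structure, n_rep=4, seed=3)
        assert br.n_success == br.n_total == 4
        assert {"median", "q2.5", "q97.5"} == set(br.table.columns)
        for name in ("cl", "vc", "vp"):
            assert br.table.loc[name, "q2.5"] == pytest.approx(
                br.table.loc[name, "q97.5"], rel=1e-6
            )

    def test_resample_indices_reproducible(self):
        a = np.random.default_rng(11).integers(0, 67, 67)
        b = np.random.default_rng(11).integers(0, 67, 67)
        np.testing.assert_array_equal(a, b)

    def test_rejects_unconverged_original_fit(self, small_fit):
        ds, fr = small_fit
        broken = type(fr)(**{**fr.__dict__, "converged": False})
        with pytest.raises(RuntimeError, match="did not converge"):
            bootstrap(ds, fr.structure, n_rep=4, seed=17, original_fit=broken)
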