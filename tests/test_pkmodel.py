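"""Unit and property tests of the closed-form kinetics and covariate model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cefapk import (
    DoseEvent,
    IndividualParameters,
    apply_iiv,
    cockcroft_gault,
    conc_tissue,
    conc_unbound,
    typical_cl,
)
from oracles import ode_profile_2cpt


class TestCockcroftGault:
    @pytest.mark.parametrize(
        "age, weight, scr, expected",
        [
            (69, 67.2, 0.92, 72.03),  # cohort median covariates
            (72, 72, 1.0, 68.0),  # exact cancellation case: (140-72)*72/(72*1)
            (63, 60.4, 0.83, 77.83),  # cohort IQR endpoints
        ],
    )
    def test_known_values(self, age, weight, scr, expected):
        assert cockcroft_gault(age, weight, scr) == pytest.approx(expected, abs=0.01)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            cockcroft_gault(140, 70, 1.0)
        with pytest.raises(ValueError):
            cockcroft_gault(60, 70, 0.0)


class TestTypicalCL:
    def test_reference_point_is_exact(self):
        assert typical_cl(25.8, 0.735, 69, 69) == pytest.approx(25.8, rel=1e-12)

    def test_zero_exponent_removes_covariate_effect(self):
        for clcr in (10, 69, 300):
            assert typical_cl(25.8, 0.0, clcr, 69) == 25.8

    def test_high_renal_function_value(self):
        # independent evaluation: 25.8 * exp(0.735 * ln(120/69))
        assert typical_cl(25.8, 0.735, 120, 69) == pytest.approx(38.75, abs=0.01)

    def test_monotone_in_clcr(self):
        grid = np.linspace(5, 120, 40)
        vals = [typical_cl(25.8, 0.735, c, 69) for c in grid]
        assert np.all(np.diff(vals) > 0)

    def test_rejects_nonpositive_clcr(self):
        with pytest.raises(ValueError):
            typical_cl(25.8, 0.735, 0.0, 69)


class TestApplyIIV:
    def test_zero_eta_reproduces_typical_values(self, reference_params):
        ind = apply_iiv(reference_params, 69.0, np.zeros(4))
        assert (ind.cl, ind.vc, ind.q, ind.vp, ind.fpa) == pytest.approx(
            (25.8, 44.3, 44.0, 52.2, 0.638), rel=1e-9
        )

    def test_log_scale_shift_multiplies_cl_only(self, reference_params):
        base = apply_iiv(reference_params, 69.0, np.zeros(4))
        shifted = apply_iiv(reference_params, 69.0, np.array([np.log(2), 0, 0, 0]))
        assert shifted.cl == pytest.approx(2 * base.cl, rel=1e-12)
        assert (shifted.vc, shifted.q, shifted.vp, shifted.fpa) == pytest.approx(
            (base.vc, base.q, base.vp, base.fpa), rel=1e-12
        )

    def test_one_sd_cl_perturbation(self, reference_params):
        ind = apply_iiv(reference_params, 69.0, np.array([0.283, 0, 0, 0]))
        assert ind.cl == pytest.approx(25.8 * np.exp(0.283), rel=1e-9)
        assert ind.cl == pytest.approx(34.24, abs=0.01)


@pytest.fixture(scope="module")
def typical_individual(reference_params):
    return apply_iiv(reference_params, 69.0, np.zeros(4))


class TestConcUnbound:
    def test_zero_before_and_at_dose_start(self, typical_individual):
        doses = [DoseEvent(0.0, 1000.0, 0.25)]
        assert conc_unbound(typical_individual, doses, 0.0) == 0.0

    def test_zero_amount_gives_zero_profile(self, typical_individual):
        doses = [DoseEvent(0.0, 0.0, 0.25)]
        t = np.linspace(0, 12, 25)
        assert np.all(conc_unbound(typical_individual, doses, t) == 0.0)

    def test_matches_ode_oracle_at_reference_parameters(self, typical_individual):
        doses = [DoseEvent(0.0, 1000.0, 0.25)]
        ours = conc_unbound(typical_individual, doses, 3.0)
        oracle, _ = ode_profile_2cpt(
            typical_individual.cl, typical_individual.vc,
            typical_individual.q, typical_individual.vp,
            [(0.0, 1000.0, 0.25)], [3.0],
        )
        assert ours == pytest.approx(oracle[0], rel=1e-3)

    def test_superposition_linearity(self, typical_individual):
        t = np.linspace(0.05, 10, 37)
        c1 = conc_unbound(typical_individual, [DoseEvent(0.0, 500.0, 0.25)], t)
        c3 = conc_unbound(typical_individual, [DoseEvent(0.0, 1500.0, 0.25)], t)
        np.testing.assert_allclose(c3, 3 * c1, rtol=1e-12)

    def test_multiple_doses_superpose(self, typical_individual):
        d1 = [DoseEvent(0.0, 1000.0, 1 / 6)]
        d2 = [DoseEvent(3.0, 1000.0, 1 / 6)]
        both = d1 + d2
        t = np.linspace(0, 8, 33)
        c = conc_unbound(typical_individual, both, t)
        expected = conc_unbound(typical_individual, d1, t) + conc_unbound(
            typical_individual, d2, t
        )
        np.testing.assert_allclose(c, expected, rtol=1e-12)

    def test_monotone_decline_after_infusion(self, typical_individual):
        t = np.linspace(0.25, 24, 200)
        c = conc_unbound(typical_individual, [DoseEvent(0.0, 1000.0, 0.25)], t)
        assert np.all(np.diff(c) < 0)


positive = st.floats(min_value=0.5, max_value=300.0, allow_nan=False)


class TestOracleEquivalence:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(cl=positive, vc=positive, q=positive, vp=positive,
           amount=st.floats(min_value=100, max_value=3000),
           data=st.data())
    def test_closed_form_matches_stiff_ode(self, cl, vc, q, vp, amount, data):
        """Random parameter sets and schedules agree with ODE integration <0.1%."""
        ind = IndividualParameters(cl=cl, vc=vc, q=q, vp=vp, fpa=1.0)
        n_doses = data.draw(st.integers(1, 3))
        doses = [DoseEvent(3.0 * k, amount, 0.25) for k in range(n_doses)]
        rng = np.random.default_rng(data.draw(st.integers(0, 2**16)))
        t = np.sort(rng.uniform(0.01, 12.0, 50))
        ours = conc_unbound(ind, doses, t)
        oracle, _ = ode_profile_2cpt(
            cl, vc, q, vp, [(d.start_time, d.amount, d.infusion_duration) for d in doses], t
        )
        scale = np.maximum(oracle, 1e-9 * amount)
        assert np.max(np.abs(ours - oracle) / scale) < 1e-3

    def test_mass_balance(self, typical_individual):
        """Central + peripheral + eliminated amounts equal the total infused."""
        doses = [(0.0, 1000.0, 0.25), (3.0, 1000.0, 0.25)]
        _, amounts = ode_profile_2cpt(
            typical_individual.cl, typical_individual.vc,
            typical_individual.q, typical_individual.vp, doses, [8.0],
        )
        assert amounts.sum() == pytest.approx(2000.0, rel=1e-7)


class TestConcTissue:
    def test_reference_partition(self):
        assert conc_tissue(10.0, 0.638) == pytest.approx(6.38)

    def test_identity_partition(self):
        c = np.linspace(0, 20, 7)
        np.testing.assert_allclose(conc_tissue(c, 1.0), c)

    def test_zero_input(self):
        assert conc_tissue(0.0, 0.638) == 0.0

    def test_rejects_negative_concentration(self):
        with pytest.raises(ValueError):
            conc_tissue(-1.0, 0.5)
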