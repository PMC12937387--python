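"""Tests of the Monte Carlo probability-of-target-attainment engine."""

import numpy as np
import pytest

from cefapk import DoseEvent, PTAConfig, apply_iiv, conc_unbound, simulate_pta, target_attained
from cefapk.pkmodel import SERUM, TISSUE
from oracles import trough_switch_clcr


@pytest.fixture(scope="module")
def small_config():
    return PTAConfig(n_virtual=400, eval_times=(3.0, 5.0, 6.0), seed=12)


class TestSimulatePTA:
    def test_zero_mic_gives_certain_attainment(self, reference_params):
        cfg = PTAConfig(mic=0.0, n_virtual=50, eval_times=(3.0, 6.0), seed=1)
        grid = simulate_pta(reference_params, cfg)
        for ch in cfg.channels:
            assert np.all(grid.probability[ch] == 1.0)

    def test_probabilities_bounded_and_deterministic(self, reference_params, small_config):
        a = simulate_pta(reference_params, small_config)
        b = simulate_pta(reference_params, small_config)
        for ch in small_config.channels:
            assert np.all((0 <= a.probability[ch]) & (a.probability[ch] <= 1))
            np.testing.assert_array_equal(a.probability[ch], b.probability[ch])

    def test_no_iiv_collapses_to_step_function_at_oracle_switch_point(
        self, reference_params
    ):
        """With omega = 0 the PTA is 0/1 with the switch at the root-found CLcr."""
        pop = reference_params.with_(omega_cl=0, omega_vc=0, omega_vp=0, omega_fpa=0)
        cfg = PTAConfig(n_virtual=20, eval_times=(12.0,), seed=5, channels=(SERUM,))
        grid = simulate_pta(pop, cfg)
        pta = grid.probability[SERUM][:, 0]
        assert set(np.unique(pta)) <= {0.0, 1.0}
        switch = trough_switch_clcr(pop, t=12.0, mic=cfg.mic)
        assert switch is not None
        # grid points strictly below the switch attain, strictly above fail
        assert np.all(pta[grid.clcr <= switch - cfg.clcr_step] == 1.0)
        assert np.all(pta[grid.clcr >= switch + cfg.clcr_step] == 0.0)

    def test_monotone_in_mic(self, reference_params):
        cfg_lo = PTAConfig(mic=0.25, n_virtual=300, eval_times=(5.0,), seed=8)
        cfg_hi = PTAConfig(mic=1.0, n_virtual=300, eval_times=(5.0,), seed=8)
        lo = simulate_pta(reference_params, cfg_lo).probability[SERUM]
        hi = simulate_pta(reference_params, cfg_hi).probability[SERUM]
        assert np.all(lo >= hi)

    def test_dose_doubling_maps_to_halved_mic(self, reference_params):
        """Linear kinetics: PTA(2 g, MIC m) == PTA(1 g, MIC m/2) with shared seeds."""
        base = PTAConfig(dose=1000.0, mic=0.25, n_virtual=300, eval_times=(3.0, 6.0), seed=21)
        double = PTAConfig(dose=2000.0, mic=0.5, n_virtual=300, eval_times=(3.0, 6.0), seed=21)
        a = simulate_pta(reference_params, base)
        b = simulate_pta(reference_params, double)
        for ch in base.channels:
            np.testing.assert_array_equal(a.probability[ch], b.probability[ch])

    def test_typical_value_grid_monotone_in_time_and_clcr(self, reference_params):
        pop = reference_params.with_(omega_cl=0, omega_vc=0, omega_vp=0, omega_fpa=0)
        cfg = PTAConfig(n_virtual=10, eval_times=(3.0, 5.0, 6.0, 9.0, 12.0), seed=2)
        grid = simulate_pta(pop, cfg)
        for ch in cfg.channels:
            p = grid.probability[ch]
            assert np.all(np.diff(p, axis=1) <= 0)  # later times never better
            assert np.all(np.diff(p, axis=0) <= 0)  # higher clearance never better

    def test_long_frame_layout(self, reference_params, small_config):
        df = simulate_pta(reference_params, small_config).to_frame()
        assert set(df.columns) == {"channel", "clcr", "time", "pta"}
        n_grid = len(small_config.clcr_grid)
        assert len(df) == 2 * n_grid * len(small_config.eval_times)
        assert df.pta.between(0, 1).all()


class TestTargetAttained:
    def test_constant_profile_above_mic(self):
        assert target_attained(lambda t: 1.0, mic=0.5, interval=6.0)

    def test_interval_shorter_than_infusion_rejected(self):
        with pytest.raises(ValueError):
            target_attained(lambda t: 1.0, mic=0.5, interval=0.2, infusion_duration=0.25)

    def test_matches_dense_grid_oracle_for_typical_profile(self, reference_params):
        """Trough rule agrees with a dense fT>MIC evaluation (CLcr 80, 6 h)."""
        from cefapk.pkmodel import typical_cl

        pop = reference_params
        ind = apply_iiv(
            pop.with_(theta1=typical_cl(pop.theta1, pop.theta2, 80.0, pop.clcr_ref), theta2=0.0),
            80.0,
            np.zeros(4),
        )
        doses = [DoseEvent(0.0, 1000.0, 0.25)]

        def profile(t):
            return float(conc_unbound(ind, doses, float(t)))

        flag = target_attained(profile, mic=0.5, interval=6.0, infusion_duration=0.25)
        tgrid = np.linspace(0, 6.0, 4001)
        frac_above = np.mean([profile(t) > 0.5 for t in tgrid])
        assert flag == (frac_above >= 0.9)

    def test_trough_above_mic_implies_attainment(self, reference_params):
        ind = apply_iiv(reference_params, 60.0, np.zeros(4))
        doses = [DoseEvent(0.0, 1000.0, 0.25)]
        trough = float(conc_unbound(ind, doses, 3.0))
        assert trough > 0.5
        assert target_attained(
            lambda t: float(conc_unbound(ind, doses, float(t))), mic=0.5, interval=3.0
        )
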