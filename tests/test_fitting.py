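"""Signal models and the nonlinear least-squares estimation engine."""

import math

import numpy as np
import pytest

from t1sim.fitting import (
    INF_DELAY,
    SampleSeries,
    fit_series,
    fit_volume_stack,
    model_ir3,
    model_sateff,
    model_sr2,
)
from t1sim.io import WeightedVolumeSet


def grid_search_sr2(delays, signals, step=1.0):
    """Brute-force oracle: T1 grid at `step` ms, closed-form optimal A per T1."""
    t1_grid = np.arange(1.0, 10000.0 + step, step)
    f = np.where(
        np.isinf(delays)[None, :], 1.0,
        -np.expm1(-np.where(np.isinf(delays), 1.0, delays)[None, :] / t1_grid[:, None]),
    )
    a_opt = (f * signals).sum(axis=1) / (f * f).sum(axis=1)
    rss = ((a_opt[:, None] * f - signals) ** 2).sum(axis=1)
    return t1_grid[np.argmin(rss)]


class TestModels:
    def test_sr2_equilibrium_marker_returns_a_exactly(self):
        assert model_sr2(1.0, 1550.0, INF_DELAY) == 1.0

    def test_sr2_phantom_delay_value(self):
        assert model_sr2(1.0, 1550.0, 788.0) == pytest.approx(
            1 - math.exp(-788 / 1550), rel=1e-12
        )

    def test_sr2_linear_in_a(self):
        t = np.array([100.0, 500.0, INF_DELAY])
        assert np.allclose(model_sr2(2.0, 900.0, t), 2 * model_sr2(1.0, 900.0, t))

    def test_sr2_zero_delay_gives_zero(self):
        assert model_sr2(1.0, 1550.0, 0.0) == 0.0

    def test_ir3_null_point_at_t1_ln2(self):
        assert model_ir3(1.0, -2.0, 1000.0, 1000.0 * math.log(2)) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_ir3_limits(self):
        assert model_ir3(1.0, -2.0, 1000.0, 0.0) == -1.0
        assert model_ir3(1.0, -2.0, 1000.0, INF_DELAY) == 1.0
        assert model_ir3(1.0, 0.0, 1000.0, 123.0) == 1.0

    def test_sateff_reduces_to_sr2_at_unit_efficiency(self):
        t = np.array([50.0, 300.0, 1200.0, INF_DELAY])
        assert np.allclose(model_sateff(1.3, 1.0, 777.0, t), model_sr2(1.3, 777.0, t))

    def test_sateff_example_and_zero_efficiency(self):
        assert model_sateff(1.0, 0.999, 1000.0, 300.0) == pytest.approx(
            1 - 0.999 * math.exp(-0.3), rel=1e-12
        )
        assert model_sateff(1.0, 0.0, 1000.0, 300.0) == 1.0


class TestFitSeries:
    T1_SWEEP = np.linspace(300, 2500, 25)

    @pytest.mark.parametrize("t1_true", T1_SWEEP)
    def test_sr2_exact_recovery_noiseless(self, t1_true):
        delays = np.array([300.0, 600.0, 1200.0, INF_DELAY])
        fit = fit_series(SampleSeries(delays, model_sr2(1.0, t1_true, delays)))
        assert fit.converged
        assert fit.t1 == pytest.approx(t1_true, rel=1e-6)
        assert fit.a == pytest.approx(1.0, rel=1e-6)

    @pytest.mark.parametrize("t1_true", T1_SWEEP)
    def test_ir3_exact_recovery_noiseless(self, t1_true):
        delays = np.linspace(100, 3000, 14)
        sig = model_ir3(1.0, -2.0, t1_true, delays)
        fit = fit_series(SampleSeries(delays, sig, delay_kind="inversion"),
                         model="ir3")
        assert fit.t1 == pytest.approx(t1_true, rel=1e-6)
        assert fit.b == pytest.approx(-2.0, rel=1e-6)

    @pytest.mark.parametrize("t1_true", T1_SWEEP)
    def test_sateff_exact_recovery_noiseless(self, t1_true):
        delays = np.array([300.0, 480.0, 660.0, 840.0, 1020.0, 1200.0, INF_DELAY])
        sig = model_sateff(1.0, 0.97, t1_true, delays)
        fit = fit_series(SampleSeries(delays, sig), model="sateff")
        assert fit.t1 == pytest.approx(t1_true, rel=1e-6)
        assert fit.eta == pytest.approx(0.97, rel=1e-5)

    def test_exact_three_point_recovery(self):
        delays = np.array([300.0, 600.0, INF_DELAY])
        fit = fit_series(SampleSeries(delays, model_sr2(1.0, 1234.0, delays)))
        assert fit.t1 == pytest.approx(1234.0, abs=1e-3)

    def test_finite_recovery_anchor_biases_t1_below_4_pct(self):
        # equilibrium sample deflated to the 6-s recovery fraction of T1=1550
        delays = np.array([400.0, 800.0, INF_DELAY])
        signals = np.array([0.2275, 0.4033, 0.9790])
        fit = fit_series(SampleSeries(delays, signals))
        assert abs(100 * (fit.t1 - 1550) / 1550) < 4.0

    def test_scale_invariance_of_t1(self):
        delays = np.array([250.0, 700.0, 1500.0, INF_DELAY])
        sig = model_sr2(1.0, 1100.0, delays)
        f1 = fit_series(SampleSeries(delays, sig))
        f2 = fit_series(SampleSeries(delays, 37.5 * sig))
        assert f2.t1 == pytest.approx(f1.t1, rel=1e-8)
        assert f2.a == pytest.approx(37.5 * f1.a, rel=1e-8)

    def test_agrees_with_grid_search_oracle_on_noisy_series(self, rng):
        delays = np.array([400.0, 800.0, 1600.0, INF_DELAY])
        for _ in range(100):
            t1_true = rng.uniform(500, 2000)
            sig = model_sr2(1.0, t1_true, delays) + rng.normal(0, 0.01, delays.size)
            fit = fit_series(SampleSeries(delays, sig))
            t1_grid = grid_search_sr2(delays, sig)
            assert abs(fit.t1 - t1_grid) <= 2.0

    def test_ir3_and_sr2_agree_on_perfectly_saturated_data(self):
        delays = np.array([300.0, 700.0, 1400.0, 2800.0, INF_DELAY])
        sig = model_sr2(1.0, 1300.0, delays)
        f_sr = fit_series(SampleSeries(delays, sig))
        f_ir = fit_series(SampleSeries(delays, sig), model="ir3")
        assert f_ir.t1 == pytest.approx(f_sr.t1, rel=1e-5)

    def test_ir3_polarity_restoration_on_magnitude_data(self):
        delays = np.linspace(100, 3000, 14)
        sig = np.abs(model_ir3(1.0, -2.0, 900.0, delays))
        fit = fit_series(SampleSeries(delays, sig, delay_kind="inversion"),
                         model="ir3", polarity_restore=True)
        assert fit.t1 == pytest.approx(900.0, rel=1e-4)

    def test_constant_signal_flags_non_convergence(self):
        delays = np.array([300.0, 600.0, INF_DELAY])
        fit = fit_series(SampleSeries(delays, np.zeros(3)))
        assert not fit.converged and np.isnan(fit.t1)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_series(SampleSeries(np.array([300.0, 600.0]),
                                    np.array([0.1, 0.2])), model="ir3")

    def test_unknown_model_rejected(self):
        delays = np.array([300.0, 600.0, INF_DELAY])
        with pytest.raises(ValueError):
            fit_series(SampleSeries(delays, np.ones(3)), model="molli")


class TestFitVolumeStack:
    def _stack(self, t1_map_true, delays):
        data = np.stack(
            [np.where(np.isinf(d), 1.0, -np.expm1(-d / t1_map_true)) for d in delays],
            axis=-1,
        )
        return WeightedVolumeSet(data=data, delays_ms=tuple(delays))

    def test_noiseless_voxelwise_recovery(self):
        true = np.full((4, 4, 2), 1000.0)
        true[:2] = 1500.0
        wvs = self._stack(true, (400.0, 800.0, INF_DELAY))
        t1map = fit_volume_stack(wvs)
        assert np.allclose(t1map.t1, true, rtol=1e-6)
        assert t1map.converged.all()

    def test_empty_mask_yields_empty_map(self):
        true = np.full((3, 3, 1), 900.0)
        wvs = self._stack(true, (400.0, 800.0, INF_DELAY))
        t1map = fit_volume_stack(wvs, mask=np.zeros((3, 3, 1), bool))
        assert np.isnan(t1map.t1).all()
        assert not t1map.converged.any()

    def test_mask_restricts_fitting(self):
        true = np.full((3, 3, 1), 900.0)
        wvs = self._stack(true, (400.0, 800.0, INF_DELAY))
        mask = np.zeros((3, 3, 1), bool)
        mask[0, 0, 0] = True
        t1map = fit_volume_stack(wvs, mask=mask)
        assert np.isfinite(t1map.t1[mask]).all()
        assert np.isnan(t1map.t1[~mask]).all()

    def test_missing_delay_metadata_raises(self):
        class Bare:
            data = np.ones((2, 2, 1, 3))
            delays_ms = None

        with pytest.raises(ValueError, match="delay"):
            fit_volume_stack(Bare())
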