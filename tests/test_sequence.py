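"""Acquisition scheduling, gating, and signal-evolution behavior."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from t1sim.bloch import RFReadoutParams, TissueSpecies
from t1sim.sequence import (
    ConfigurationError,
    HeartRateProcess,
    NavigatorModel,
    ScanAbortedError,
    SequenceParams,
    available_magnetization_surface,
    compute_idle_beats,
    compute_tmax,
    simulate_acquisition,
)


def ideal_seq(**kw) -> SequenceParams:
    kw.setdefault("rf", RFReadoutParams(n_readouts=0))
    return SequenceParams(**kw)


FIXED_60 = HeartRateProcess(mean_bpm=60, sd_bpm=0, model="fixed")
NAV_OPEN = NavigatorModel(acceptance_prob=1.0)


class TestTmax:
    def test_eighty_percent_rule(self):
        assert compute_tmax(1000, 0.8) == 800

    def test_linearity(self):
        assert compute_tmax(500, 0.8) == 400

    def test_identity_fraction(self):
        assert compute_tmax(1000, 1.0) == 1000


class TestIdleBeats:
    @pytest.mark.parametrize("rr,target,n", [
        (1000, 6000, 6),
        (950, 6000, 7),
        (600, 6000, 10),
    ])
    def test_ceiling_examples(self, rr, target, n):
        assert compute_idle_beats(rr, target) == n

    @given(rr=st.floats(300, 2000), target=st.floats(1000, 10000))
    def test_ceiling_contract(self, rr, target):
        n = compute_idle_beats(rr, target)
        assert n * rr >= target - 1e-6
        assert n * rr - target < rr


class TestSimulateAcquisition:
    def test_fixed_hr_ideal_readout_realizes_exact_recovery(self):
        sim = simulate_acquisition(ideal_seq(), FIXED_60, NAV_OPEN,
                                   TissueSpecies(t1=1550))
        img3 = [s for s in sim.shots if s.volume_id == "IMG3"][0]
        assert img3.recovery_ms == pytest.approx(6000, abs=1e-6)
        assert sim.mean_signal("IMG3") == pytest.approx(
            1 - math.exp(-6000 / 1550), rel=1e-9
        )

    def test_short_t1_first_volume_signal(self):
        sim = simulate_acquisition(ideal_seq(), FIXED_60, NAV_OPEN,
                                   TissueSpecies(t1=500))
        assert sim.mean_signal("IMG1") == pytest.approx(
            1 - math.exp(-400 / 500), rel=1e-9
        )

    def test_saturation_delays_follow_tmax_rule(self):
        sim = simulate_acquisition(ideal_seq(), FIXED_60, NAV_OPEN,
                                   TissueSpecies(t1=1550))
        df = sim.to_dataframe()
        assert df[df.volume_id == "IMG1"].t_sat_ms.iloc[0] == pytest.approx(400)
        assert df[df.volume_id == "IMG2"].t_sat_ms.iloc[0] == pytest.approx(800)

    def test_explicit_t_sat_override(self):
        seq = ideal_seq(t_sat_override=(395.0, 788.0))
        sim = simulate_acquisition(seq, FIXED_60, NAV_OPEN, TissueSpecies(t1=1000))
        df = sim.to_dataframe()
        assert df[df.volume_id == "IMG1"].t_sat_ms.iloc[0] == 395.0
        assert df[df.volume_id == "IMG2"].t_sat_ms.iloc[0] == 788.0

    def test_closed_navigator_aborts_with_guard(self):
        with pytest.raises(ScanAbortedError):
            simulate_acquisition(
                ideal_seq(), FIXED_60, NavigatorModel(acceptance_prob=0.0),
                TissueSpecies(t1=1550), max_beats=500,
            )

    def test_unreachable_t_sat_raises_configuration_error(self):
        # T_SAT2 longer than the whole available window cannot be realized
        seq = ideal_seq(t_sat_override=(400.0, 2000.0))
        with pytest.raises(ConfigurationError, match="IMG2"):
            simulate_acquisition(seq, FIXED_60, NAV_OPEN, TissueSpecies(t1=1000))

    def test_rejections_only_lengthen_recovery(self):
        seq = ideal_seq(n_shots=20)
        gated = simulate_acquisition(
            seq, HeartRateProcess(mean_bpm=60, sd_bpm=0, model="fixed"),
            NavigatorModel(acceptance_prob=0.4, seed=7),
            TissueSpecies(t1=1550),
        )
        recov = [s.recovery_ms for s in gated.shots
                 if s.volume_id == "IMG3" and s.accepted]
        assert len(recov) == 20
        assert all(r >= 6000 - 1e-6 for r in recov)
        assert np.mean(recov) >= 6000

    def test_spgr_readout_perturbs_but_preserves_signal_ordering(self):
        sim = simulate_acquisition(SequenceParams(), FIXED_60, NAV_OPEN,
                                   TissueSpecies(t1=1550))
        s1, s2, s3 = sim.mean_signals
        assert s1 < s2 < s3

    def test_reproducible_given_seeds(self):
        def run():
            return simulate_acquisition(
                ideal_seq(n_shots=5),
                HeartRateProcess(mean_bpm=70, sd_bpm=5, seed=3),
                NavigatorModel(acceptance_prob=0.6, seed=4),
                TissueSpecies(t1=1200),
            ).to_dataframe()

        assert run().equals(run())


class TestSchedulingGuarantee:
    @pytest.mark.parametrize("hr_bpm,accept", [(40, 1.0), (80, 0.5), (120, 0.2)])
    def test_recovery_target_met_under_hr_noise_and_gating(self, hr_bpm, accept):
        sim = simulate_acquisition(
            ideal_seq(n_shots=25),
            HeartRateProcess(mean_bpm=hr_bpm, sd_bpm=5, seed=hr_bpm),
            NavigatorModel(acceptance_prob=accept, seed=1),
            TissueSpecies(t1=1550),
        )
        recov = [s.recovery_ms for s in sim.shots
                 if s.volume_id == "IMG3" and s.accepted]
        assert len(recov) == 25
        assert min(recov) >= 6000 - 1e-6


class TestMagnetizationSurface:
    def test_highest_heart_rate_longest_t1_example(self):
        df = available_magnetization_surface([1750.0], [120.0])
        row = df.iloc[0]
        assert row.t_sat1_ms == pytest.approx(200.0)
        assert row.s1 == pytest.approx(1 - math.exp(-200 / 1750), rel=1e-9)

    def test_s2_always_exceeds_s1(self):
        df = available_magnetization_surface(
            np.linspace(500, 1750, 6), np.arange(40, 121, 10)
        )
        assert (df.s2 > df.s1).all()

    def test_s1_monotone_non_increasing_in_heart_rate(self):
        df = available_magnetization_surface([1550.0], np.arange(40, 121, 10))
        s1 = df.sort_values("hr_bpm").s1.to_numpy()
        assert (np.diff(s1) <= 1e-12).all()

    def test_minimum_recovery_fraction_exceeds_96_pct(self):
        df = available_magnetization_surface(
            np.linspace(500, 1750, 26), np.arange(40, 121, 10)
        )
        assert df.s3.min() > 0.96

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            available_magnetization_surface([], [60.0])
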