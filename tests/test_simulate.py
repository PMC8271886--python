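import numpy as np
import pytest
from dataclasses import replace

from somnoring.acc import mad_epochs
from somnoring.core import EpochGrid, FOUR_STAGES, Hypnogram
from somnoring.hrv import clean_ibi
from somnoring.simulate import (
    SimConfig,
    SubjectProfile,
    expected_occupancy,
    simulate_acc,
    simulate_cohort,
    simulate_hypnogram,
    simulate_ibi,
    simulate_night,
    simulate_temp,
)
from somnoring.temp import mask_artifacts

from conftest import make_hypnogram


class TestHypnogramSimulation:
    def test_deterministic_under_seed(self):
        cfg = SimConfig(seed=3, night_duration_h=2.0)
        a = simulate_hypnogram(cfg)
        b = simulate_hypnogram(cfg)
        assert np.array_equal(a.stages, b.stages)

    def test_starts_in_wake(self):
        h = simulate_hypnogram(SimConfig(seed=0, night_duration_h=2.0))
        assert h.stages[0] == "wake"

    def test_absorbing_wake_rejected(self):
        P = ((1.0, 0, 0, 0), (0.1, 0.8, 0.05, 0.05),
             (0.1, 0.1, 0.8, 0.0), (0.1, 0.1, 0.0, 0.8))
        with pytest.raises(ValueError, match="absorbing"):
            simulate_hypnogram(SimConfig(base_transitions=P))

    def test_invalid_rows_rejected(self):
        P = ((0.5, 0.1, 0, 0), (0.1, 0.8, 0.05, 0.05),
             (0.1, 0.1, 0.8, 0.0), (0.1, 0.1, 0.0, 0.8))
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_hypnogram(SimConfig(base_transitions=P))

    def test_occupancy_matches_chain_analysis(self):
        cfg = SimConfig(seed=0)
        rng = np.random.default_rng(99)
        counts = np.zeros(4)
        n_nights = 200
        for _ in range(n_nights):
            s = simulate_hypnogram(cfg, rng).stages
            for j, st in enumerate(FOUR_STAGES):
                counts[j] += np.sum(s == st)
        emp = counts / counts.sum()
        exp = expected_occupancy(cfg)
        assert np.max(np.abs(emp - exp)) < 0.03


class TestIbiSimulation:
    def test_rem_more_variable_than_light(self):
        # night-level arcs zeroed so the comparison isolates the
        # stage-conditioned RSA amplitudes
        cfg = SimConfig(seed=0, ibi_ectopic_rate=0.0, hr_slow_sd_bpm=0.0,
                        amp_slow_log_sd=0.0, hr_circ_dip_bpm=0.0,
                        amp_circ_rise=0.0, nrem_drift_bpm=0.0)
        stages = ["light"] * 120 + ["REM"] * 120
        hyp = make_hypnogram(stages)
        ibi, _ = simulate_ibi(hyp, cfg, np.random.default_rng(0))
        light_iv = ibi.interval_ms[ibi.t < 110 * 30]
        rem_iv = ibi.interval_ms[ibi.t > 130 * 30]
        assert np.std(rem_iv) > np.std(light_iv)

    def test_injected_ectopics_flagged(self):
        cfg = SimConfig(seed=0, ibi_ectopic_rate=0.02)
        hyp = make_hypnogram(["light"] * 240)
        ibi, truth = simulate_ibi(hyp, cfg, np.random.default_rng(1))
        labeled = clean_ibi(ibi)
        flagged = ~labeled.normal
        inj = truth["ectopic_idx"]
        assert len(inj) > 5
        assert np.mean(flagged[inj]) >= 0.99

    def test_zero_noise_zero_modulation_constant(self):
        cfg = SimConfig(seed=0, ibi_noise_ms=0.0, rsa_amp_ms=(0, 0, 0, 0),
                        hr_slow_sd_bpm=0.0, amp_slow_log_sd=0.0,
                        hr_circ_dip_bpm=0.0, amp_circ_rise=0.0, nrem_drift_bpm=0.0,
                        ibi_ectopic_rate=0.0)
        hyp = make_hypnogram(["light"] * 120)
        ibi, _ = simulate_ibi(hyp, cfg, np.random.default_rng(0))
        # amp floor of 2 ms still modulates; intervals stay within that band
        assert np.all(np.abs(ibi.interval_ms - 1000.0) <= 2.5)

    def test_impossible_config_rejected(self):
        cfg = SimConfig(ibi_noise_ms=400.0)
        with pytest.raises(ValueError, match="non-positive"):
            simulate_ibi(make_hypnogram(["light"] * 60), cfg, np.random.default_rng(0))

    def test_beat_time_interval_consistency(self):
        cfg = SimConfig(seed=0)
        ibi, _ = simulate_ibi(make_hypnogram(["light"] * 120), cfg,
                              np.random.default_rng(2))
        assert np.allclose(np.diff(ibi.t) * 1000.0, ibi.interval_ms[1:], atol=1.0)


class TestAccSimulation:
    def test_wake_mad_exceeds_sleep_mad(self):
        cfg = SimConfig(seed=0)
        stages = ["wake"] * 60 + ["light"] * 60
        hyp = make_hypnogram(stages)
        acc, _ = simulate_acc(hyp, cfg, np.random.default_rng(0))
        mads = mad_epochs(acc[["x", "y", "z"]].to_numpy(), hyp.grid)["tmean"]
        assert np.nanmean(mads[:60]) > 3 * np.nanmean(mads[60:])

    def test_no_movement_config_noise_floor(self):
        cfg = SimConfig(seed=0, burst_prob_wake=0.0, burst_prob_sleep=0.0,
                        posture_shift_prob_wake=0.0, posture_shift_prob_sleep=0.0)
        hyp = make_hypnogram(["wake"] * 40)
        acc, _ = simulate_acc(hyp, cfg, np.random.default_rng(0))
        mads = mad_epochs(acc[["x", "y", "z"]].to_numpy(), hyp.grid)["tmean"]
        assert np.nanmax(mads) < 4 * cfg.acc_noise_g

    def test_bursts_tracked_in_truth(self):
        cfg = SimConfig(seed=0)
        hyp = make_hypnogram(["wake"] * 120)
        acc, truth = simulate_acc(hyp, cfg, np.random.default_rng(3))
        mads = mad_epochs(acc[["x", "y", "z"]].to_numpy(), hyp.grid)["tmean"].to_numpy()
        burst = truth["burst_epochs"]
        assert burst.sum() > 10
        assert np.nanmean(mads[burst]) > np.nanmean(mads[~burst])

    def test_values_within_sensor_range(self, short_night):
        acc = short_night.streams.acc
        assert acc[["x", "y", "z"]].abs().to_numpy().max() <= 2.0


class TestTempSimulation:
    def test_no_artifacts_nothing_masked(self):
        cfg = SimConfig(seed=0, temp_artifact_rate=0.0)
        hyp = make_hypnogram(["light"] * 240)
        temp, truth = simulate_temp(hyp, cfg, np.random.default_rng(0))
        assert len(truth["artifact_idx"]) == 0
        assert not np.isnan(mask_artifacts(temp["celsius"].to_numpy())).any()

    def test_temperature_rises_across_night(self):
        cfg = SimConfig(seed=0)
        hyp = make_hypnogram(["light"] * 840)
        temp, _ = simulate_temp(hyp, cfg, np.random.default_rng(1))
        v = temp["celsius"].to_numpy()
        assert v[-360:].mean() > v[:360].mean()

    def test_injected_artifacts_equal_masked(self):
        cfg = SimConfig(seed=0, temp_artifact_rate=0.01)
        hyp = make_hypnogram(["light"] * 840)
        temp, truth = simulate_temp(hyp, cfg, np.random.default_rng(2))
        masked = np.isnan(mask_artifacts(temp["celsius"].to_numpy()))
        assert masked.sum() == len(truth["artifact_idx"])
        assert np.array_equal(np.flatnonzero(masked), np.sort(truth["artifact_idx"]))


class TestCohort:
    def test_manifest_structure_and_determinism(self):
        cfg = SimConfig(seed=12, night_duration_h=0.5)
        a = simulate_cohort(5, 2, cfg)
        b = simulate_cohort(5, 2, cfg)
        assert len(a) == 10
        assert sorted({n.subject_id for n in a}) == [f"s{i:03d}" for i in range(5)]
        for x, y in zip(a, b):
            assert np.array_equal(x.hypnogram.stages, y.hypnogram.stages)
            assert np.allclose(x.streams.ibi.interval_ms, y.streams.ibi.interval_ms)

    def test_subject_profiles_vary(self):
        cfg = SimConfig(seed=12, night_duration_h=0.5)
        nights = simulate_cohort(6, 1, cfg)
        offsets = [n.truth["profile"].hr_offset_bpm for n in nights]
        assert np.std(offsets) > 0.5

    def test_streams_span_grid(self, short_night):
        grid = short_night.hypnogram.grid
        assert short_night.streams.acc["t"].iloc[-1] >= grid.duration - 1.0
        assert short_night.streams.temp["t"].iloc[-1] >= grid.duration - 15.0
        assert short_night.streams.ibi.t[-1] >= grid.duration

    def test_invalid_cohort_size(self):
        with pytest.raises(ValueError):
            simulate_cohort(0, 1, SimConfig())
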