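import numpy as np
import pandas as pd
import pytest

from somnoring.core import EpochGrid, Hypnogram
from somnoring.hrv import (
    IbiSeries,
    apply_run_rule,
    clean_ibi,
    detect_beats,
    extract_hrv_features,
    label_ibi_artifacts,
    time_domain_features,
)
from somnoring.simulate import SimConfig, simulate_ibi


def brute_force_labels(iv):
    """Independent oracle for the 16-bpm / 7-point-median artifact rule."""
    n = len(iv)
    if n < 7:
        return np.zeros(n, dtype=bool)
    normal = np.empty(n, dtype=bool)
    for i in range(n):
        win = iv[max(0, i - 3): i + 4]
        m = np.median(win)
        normal[i] = abs(60000.0 / iv[i] - 60000.0 / m) <= 16.0
    return normal


def ibi_from_intervals(iv):
    iv = np.asarray(iv, dtype=float)
    return IbiSeries(t=np.cumsum(iv) / 1000.0, interval_ms=iv)


def modulated_ibi(f_mod, amp=50.0, base=1000.0, dur=720.0, seed=0, noise=1.0):
    rng = np.random.default_rng(seed)
    t, iv = 0.0, []
    while t < dur:
        d = base + amp * np.sin(2 * np.pi * f_mod * t) + rng.normal(0, noise)
        t += d / 1000.0
        iv.append(d)
    return ibi_from_intervals(iv)


class TestArtifactLabeling:
    def test_constant_series_all_normal(self):
        ibi = label_ibi_artifacts(ibi_from_intervals([1000.0] * 20))
        assert ibi.normal.all()

    def test_single_deviant_flagged(self):
        iv = [1000.0] * 10
        iv[5] = 750.0  # 80 vs 60 bpm: 20 bpm deviation
        ibi = label_ibi_artifacts(ibi_from_intervals(iv))
        assert not ibi.normal[5]
        assert ibi.normal.sum() == 9
        assert np.array_equal(ibi.normal, brute_force_labels(np.array(iv)))

    def test_boundary_deviation_retained(self):
        iv = [1000.0] * 10
        iv[5] = 790.0  # 75.9 vs 60 bpm: 15.9 bpm, inside the 16 bpm rule
        ibi = label_ibi_artifacts(ibi_from_intervals(iv))
        assert ibi.normal.all()

    def test_matches_bruteforce_on_noisy_series(self, rng):
        iv = rng.normal(900, 60, size=300).clip(500, 1500)
        ibi = label_ibi_artifacts(ibi_from_intervals(iv))
        assert np.array_equal(ibi.normal, brute_force_labels(iv))

    def test_short_series_all_abnormal(self):
        ibi = label_ibi_artifacts(ibi_from_intervals([1000.0] * 6))
        assert not ibi.normal.any()


class TestRunRule:
    def test_all_normal_interior_usable(self):
        ibi = clean_ibi(ibi_from_intervals([1000.0] * 10))
        assert np.array_equal(np.flatnonzero(ibi.usable), np.arange(2, 8))

    def test_single_artifact_blocks_neighborhood(self):
        labels = np.array([1, 1, 0, 1, 1, 1, 1, 1], dtype=bool)
        ibi = ibi_from_intervals([1000.0] * 8)
        ibi = IbiSeries(ibi.t, ibi.interval_ms, normal=labels)
        out = apply_run_rule(ibi)
        assert np.array_equal(np.flatnonzero(out.usable), [5])

    def test_all_abnormal_none_usable(self):
        ibi = ibi_from_intervals([1000.0] * 10)
        ibi = IbiSeries(ibi.t, ibi.interval_ms, normal=np.zeros(10, dtype=bool))
        assert not apply_run_rule(ibi).usable.any()

    def test_more_artifacts_never_increase_usable(self, rng):
        iv = rng.normal(1000, 20, size=400)
        base = clean_ibi(ibi_from_intervals(iv))
        for n_art in (5, 20, 60):
            iv2 = iv.copy()
            idx = rng.choice(400, size=n_art, replace=False)
            iv2[idx] *= 0.6
            more = clean_ibi(ibi_from_intervals(iv2))
            assert more.usable.sum() <= base.usable.sum()


class TestTimeDomain:
    def test_constant_intervals(self):
        f = time_domain_features(np.full(60, 1000.0))
        assert f["hr"] == pytest.approx(60.0)
        assert f["rmssd"] == pytest.approx(0.0)
        assert f["sdnn"] == pytest.approx(0.0)
        assert f["pnn50"] == pytest.approx(0.0)

    def test_rmssd_formula(self):
        f = time_domain_features(np.array([1000.0, 900.0, 1100.0]))
        assert f["rmssd"] == pytest.approx(np.sqrt((100**2 + 200**2) / 2), rel=1e-12)

    def test_alternating_pnn50(self):
        iv = np.tile([950.0, 1050.0], 30)
        f = time_domain_features(iv)
        assert f["pnn50"] == pytest.approx(100.0)
        assert f["rmssd"] == pytest.approx(100.0)

    def test_shift_invariance_of_variability(self, rng):
        iv = rng.normal(1000, 40, size=100)
        a = time_domain_features(iv)
        b = time_domain_features(iv + 200.0)
        assert b["rmssd"] == pytest.approx(a["rmssd"], rel=1e-12)
        assert b["sdnn"] == pytest.approx(a["sdnn"], rel=1e-12)
        assert b["hr"] != pytest.approx(a["hr"])


class TestSpectral:
    def grid_for(self, ibi):
        return EpochGrid.from_duration(ibi.t[-1])

    def test_hf_modulation_recovered(self):
        ibi = modulated_ibi(0.25)
        feats = extract_hrv_features(clean_ibi(ibi), self.grid_for(ibi))
        mid = feats.iloc[8:-8]
        assert np.nanmedian(mid["hf_peak_5min"]) == pytest.approx(0.25, abs=0.02)
        assert np.nanmedian(mid["breathing_rate_5min"]) == pytest.approx(15.0, abs=1.2)
        assert np.nanmedian(mid["hf_nu_5min"]) > 0.9

    def test_lf_modulation_recovered(self):
        ibi = modulated_ibi(0.1)
        feats = extract_hrv_features(clean_ibi(ibi), self.grid_for(ibi))
        assert np.nanmedian(feats.iloc[8:-8]["lf_nu_5min"]) > 0.9

    def test_constant_intervals_negligible_power(self):
        ibi = ibi_from_intervals([1000.0] * 700)
        feats = extract_hrv_features(clean_ibi(ibi), self.grid_for(ibi))
        assert np.nanmax(feats["total_power_5min"]) < 1.0

    def test_parseval_total_power(self):
        ibi = modulated_ibi(0.25, amp=40.0, noise=5.0, dur=900.0)
        grid = self.grid_for(ibi)
        feats = extract_hrv_features(clean_ibi(ibi), grid)
        # compare mid-night total power against tachogram variance
        from scipy.interpolate import CubicSpline
        from scipy.signal import detrend
        u = clean_ibi(ibi)
        ut, uiv = u.t[u.usable], u.interval_ms[u.usable]
        mid_t = grid.midpoints()[len(grid.midpoints()) // 2]
        gt = np.arange(mid_t - 150, mid_t + 150, 0.25)
        var = np.var(detrend(CubicSpline(ut, uiv)(gt)))
        tp = feats["total_power_5min"].iloc[len(feats) // 2]
        assert tp == pytest.approx(var, rel=0.15)


class TestZeroCrossings:
    def test_constant_missing(self):
        ibi = ibi_from_intervals([1000.0] * 700)
        feats = extract_hrv_features(clean_ibi(ibi), EpochGrid.from_duration(ibi.t[-1]))
        assert feats["zc_mean_5min"].isna().all()

    def test_pure_modulation_period(self):
        ibi = modulated_ibi(0.25, noise=0.0)
        feats = extract_hrv_features(clean_ibi(ibi), EpochGrid.from_duration(ibi.t[-1]))
        mid = feats.iloc[8:-8]
        assert np.nanmedian(mid["zc_mean_5min"]) == pytest.approx(2.0, abs=0.1)
        assert np.nanmedian(mid["zc_cv_5min"]) == pytest.approx(0.0, abs=0.05)

    def test_mixed_frequencies_have_cv(self):
        rng = np.random.default_rng(3)
        t, iv = 0.0, []
        while t < 720.0:
            d = 1000.0 + 40 * np.sin(2 * np.pi * 0.25 * t) + 35 * np.sin(2 * np.pi * 0.07 * t)
            t += d / 1000.0
            iv.append(d)
        ibi = ibi_from_intervals(iv)
        feats = extract_hrv_features(clean_ibi(ibi), EpochGrid.from_duration(ibi.t[-1]))
        assert np.nanmedian(feats.iloc[8:-8]["zc_cv_5min"]) > 0.05


class TestEpochAlignment:
    def test_step_change_transitions_quickly(self):
        iv = [1000.0] * 300 + [800.0] * 300
        ibi = clean_ibi(ibi_from_intervals(iv))
        grid = EpochGrid.from_duration(ibi.t[-1])
        feats = extract_hrv_features(ibi, grid)
        hr = feats["hr_1min"]
        k = int(300.0 / 30)  # step at 300 s -> epoch 10
        assert np.nanmax(np.abs(hr.iloc[:k - 2] - 60.0)) < 1.0
        assert np.nanmax(np.abs(hr.iloc[k + 2:] - 75.0)) < 1.0

    def test_edge_windows_missing_when_undercovered(self):
        ibi = clean_ibi(ibi_from_intervals([1000.0] * 700))
        grid = EpochGrid.from_duration(ibi.t[-1])
        feats = extract_hrv_features(ibi, grid)
        # first epoch's 5-min window extends 135 s before the night: coverage < 0.7
        assert np.isnan(feats["hr_5min"].iloc[0])
        assert feats["coverage_5min"].iloc[0] < 0.7
        assert not np.isnan(feats["hr_5min"].iloc[len(feats) // 2])

    def test_stationary_1min_5min_agree(self):
        ibi = modulated_ibi(0.25, amp=30.0, noise=3.0, dur=900.0)
        feats = extract_hrv_features(clean_ibi(ibi), EpochGrid.from_duration(ibi.t[-1]))
        mid = feats.iloc[10:-10]
        assert np.nanmedian(np.abs(mid["hr_1min"] - mid["hr_5min"])) < 1.0


class TestBeatDetection:
    def make_ppg(self, rate_bpm, dur=60.0, fs=125.0, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(int(dur * fs)) / fs
        beat_times = np.arange(0.5, dur - 0.5, 60.0 / rate_bpm)
        sig = np.zeros_like(t)
        for bt in beat_times:
            sig += np.exp(-((t - bt) ** 2) / (2 * 0.05 ** 2))
        sig += rng.normal(0, noise, size=len(t))
        return pd.DataFrame({"t": t, "value": sig}), beat_times

    def test_clean_pulse_train_60bpm(self):
        ppg, _ = self.make_ppg(60.0)
        ibi = detect_beats(ppg)
        assert len(ibi) > 50
        assert np.all(np.abs(ibi.interval_ms - 1000.0) <= 8.0 + 1e-9)

    def test_flat_signal_no_beats(self):
        t = np.arange(0, 60, 1 / 125.0)
        ppg = pd.DataFrame({"t": t, "value": np.full(len(t), 3.0)})
        assert len(detect_beats(ppg)) == 0

    def test_noisy_train_50bpm(self):
        ppg, truth = self.make_ppg(50.0, noise=0.1, seed=2)  # ~20 dB SNR
        ibi = detect_beats(ppg)
        detected = np.concatenate([[ibi.t[0] - ibi.interval_ms[0] / 1000.0], ibi.t])
        hits = 0
        for bt in truth:
            if np.min(np.abs(detected - bt)) <= 2.0 / 125.0 + 1e-9:
                hits += 1
        assert hits / len(truth) >= 0.95


def test_ibi_series_invariants():
    with pytest.raises(ValueError):
        IbiSeries(t=np.array([1.0, 0.5]), interval_ms=np.array([1000.0, 1000.0]))
    with pytest.raises(ValueError):
        IbiSeries(t=np.array([1.0]), interval_ms=np.array([-5.0]))
    s = IbiSeries.from_beats(np.array([0.0, 1.0, 2.1]))
    assert np.allclose(s.interval_ms, [1000.0, 1100.0])
    assert np.allclose(s.t, [1.0, 2.1])
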