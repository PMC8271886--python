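"""Inter-beat-interval quality control and HRV features.

Beat-to-beat intervals from the optical pulse signal are first screened for
artifacts with a median-filter rule: an interval whose instantaneous heart
rate deviates by more than 16 bpm from the heart rate of the 7-point median
interval in its neighborhood is abnormal. An interval then enters analysis
only if it sits inside a run of five consecutive normal intervals (two
before, itself, two after).

Features are computed on sliding windows of 1 and 5 min centered on each
30-s epoch midpoint: time-domain statistics (heart rate, rMSSD, SDNN,
pNN50), spectral band powers and peak frequencies in the LF (0.04–0.15 Hz)
and HF (0.15–0.4 Hz) bands of the 4 Hz cubic-interpolated tachogram,
normalized band powers, breathing rate (HF peak x 60), and the mean and
coefficient of variation of the tachogram's zero-crossing interval. LF and
total power need the frequency resolution of the 5-min window; the 1-min
window carries the HF-band and time-domain quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.interpolate import CubicSpline

from .core import EpochGrid

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.4)
DEVIATION_BPM = 16.0
MEDIAN_POINTS = 7
RUN_CONTEXT = 2  # intervals required normal on each side
WINDOWS_S = (60.0, 300.0)
WINDOW_SUFFIX = {60.0: "1min", 300.0: "5min"}
COVERAGE_MIN = 0.7
MAX_GAP_S = 5.0
FS_INTERP = 4.0


@dataclass
class IbiSeries:
    """Beat times (s), interval durations (ms), and quality flags.

    ``t[i]`` is the time of the beat *ending* interval ``i``; the invariant
    interval[i] == (t[i] - t[i-1]) * 1000 holds within 1 ms for
    series built from a contiguous beat train.
    """

    t: np.ndarray
    interval_ms: np.ndarray
    normal: np.ndarray | None = None
    usable: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.interval_ms = np.asarray(self.interval_ms, dtype=float)
        if len(self.t) != len(self.interval_ms):
            raise ValueError("t and interval_ms must have equal length")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("beat times must be strictly increasing")
        if np.any(self.interval_ms <= 0):
            raise ValueError("intervals must be positive")

    def __len__(self) -> int:
        return len(self.t)

    @classmethod
    def from_beats(cls, beat_times: np.ndarray) -> "IbiSeries":
        beat_times = np.asarray(beat_times, dtype=float)
        if len(beat_times) < 2:
            return cls(t=np.empty(0), interval_ms=np.empty(0))
        return cls(t=beat_times[1:], interval_ms=np.diff(beat_times) * 1000.0)


def _centered_median7(x: np.ndarray) -> np.ndarray:
    """Median of the 7 values centered on each index, truncated at the edges."""
    n = len(x)
    half = MEDIAN_POINTS // 2
    med = np.empty(n)
    if n >= MEDIAN_POINTS:
        sw = np.lib.stride_tricks.sliding_window_view(x, MEDIAN_POINTS)
        med[half: n - half] = np.median(sw, axis=1)
    for i in list(range(min(half, n))) + list(range(max(n - half, 0), n)):
        med[i] = np.median(x[max(0, i - half): i + half + 1])
    return med


def label_ibi_artifacts(ibi: IbiSeries) -> IbiSeries:
    """Flag intervals deviating > 16 bpm from their 7-point median neighborhood.

    With fewer than 7 intervals there is not enough context and everything
    is labeled abnormal.
    """
    n = len(ibi)
    if n < MEDIAN_POINTS:
        normal = np.zeros(n, dtype=bool)
    else:
        med = _centered_median7(ibi.interval_ms)
        dev_bpm = np.abs(60000.0 / ibi.interval_ms - 60000.0 / med)
        normal = dev_bpm <= DEVIATION_BPM
    return IbiSeries(ibi.t, ibi.interval_ms, normal=normal)


def apply_run_rule(ibi: IbiSeries) -> IbiSeries:
    """Usable iff the interval and its two neighbors on each side are all normal.

    The first and last two intervals of a record never have full context and
    are unusable.
    """
    if ibi.normal is None:
        raise ValueError("label artifacts before applying the run rule")
    n = len(ibi)
    usable = np.zeros(n, dtype=bool)
    run = 2 * RUN_CONTEXT + 1
    if n >= run:
        sw = np.lib.stride_tricks.sliding_window_view(ibi.normal, run)
        usable[RUN_CONTEXT: n - RUN_CONTEXT] = np.all(sw, axis=1)
    return IbiSeries(ibi.t, ibi.interval_ms, normal=ibi.normal, usable=usable)


def clean_ibi(ibi: IbiSeries) -> IbiSeries:
    """Artifact labeling followed by the run rule."""
    return apply_run_rule(label_ibi_artifacts(ibi))


def detect_beats(ppg: pd.DataFrame, fs: float = 125.0) -> IbiSeries:
    """Locate heartbeats as local maxima of the moving-average-smoothed PPG.

    A short moving average suppresses high-frequency noise and a 1-s moving
    average estimates the baseline; peaks of the difference, at least 0.33 s
    apart and above half the signal's spread, are taken as beats. A flat or
    saturated signal yields an empty series.
    """
    v = ppg["value"].to_numpy(dtype=float)
    t = ppg["t"].to_numpy(dtype=float)
    if len(v) < int(fs) or np.std(v) < 1e-12:
        return IbiSeries(np.empty(0), np.empty(0))
    short = int(round(0.12 * fs)) | 1
    long = int(round(1.0 * fs)) | 1
    kernel_s = np.ones(short) / short
    kernel_l = np.ones(long) / long
    smooth = np.convolve(v, kernel_s, mode="same")
    baseline = np.convolve(v, kernel_l, mode="same")
    d = smooth - baseline
    height = 0.5 * np.std(d)
    peaks, _ = signal.find_peaks(d, distance=max(1, int(0.33 * fs)), height=height)
    return IbiSeries.from_beats(t[peaks])


# ---------------------------------------------------------------------------
# Window feature extraction
# ---------------------------------------------------------------------------

def time_domain_features(intervals_ms: np.ndarray,
                         successive_diff_ms: np.ndarray | None = None) -> dict[str, float]:
    """Time-domain HRV statistics of one window's usable intervals.

    hr = 60000 / mean interval; SDNN is the sample SD; rMSSD and pNN50 are
    computed over the successive differences of adjacent usable pairs (pass
    them explicitly when gaps break adjacency).
    """
    iv = np.asarray(intervals_ms, dtype=float)
    if len(iv) < 2:
        raise ValueError("need at least two intervals")
    d = np.diff(iv) if successive_diff_ms is None else np.asarray(successive_diff_ms, dtype=float)
    out = {"hr": 60000.0 / float(np.mean(iv)), "sdnn": float(np.std(iv, ddof=1))}
    if len(d) > 0:
        out["rmssd"] = float(np.sqrt(np.mean(d ** 2)))
        out["pnn50"] = 100.0 * float(np.mean(np.abs(d) > 50.0))
    return out

def _band_slice(freqs: np.ndarray, band: tuple[float, float], closed_right: bool) -> np.ndarray:
    lo, hi = band
    return (freqs >= lo) & ((freqs <= hi) if closed_right else (freqs < hi))


def _spectral(x: np.ndarray, full: bool) -> dict[str, float]:
    """Welch band powers/peaks of one detrended uniform tachogram slice."""
    nper = min(len(x), 256)
    freqs, psd = signal.welch(x, fs=FS_INTERP, nperseg=nper,
                              noverlap=nper // 2, detrend="linear")
    out: dict[str, float] = {}
    hf = _band_slice(freqs, HF_BAND, closed_right=True)
    if hf.any() and np.any(psd[hf] > 0):
        out["hf_power"] = float(np.trapezoid(psd[hf], freqs[hf]))
        out["hf_peak"] = float(freqs[hf][np.argmax(psd[hf])])
        out["breathing_rate"] = out["hf_peak"] * 60.0
    if full:
        lf = _band_slice(freqs, LF_BAND, closed_right=False)
        if lf.any():
            out["lf_power"] = float(np.trapezoid(psd[lf], freqs[lf]))
            out["lf_peak"] = float(freqs[lf][np.argmax(psd[lf])])
        out["total_power"] = float(np.trapezoid(psd, freqs))
        lfp, hfp = out.get("lf_power", np.nan), out.get("hf_power", np.nan)
        if lfp + hfp > 0:
            out["lf_nu"] = lfp / (lfp + hfp)
            out["hf_nu"] = hfp / (lfp + hfp)
        if hfp > 0:
            out["lf_hf_ratio"] = lfp / hfp
    return out


def _zero_crossings(x: np.ndarray, dt: float) -> dict[str, float]:
    """Mean and CV of the gap between sign changes of the mean-centered slice."""
    c = x - np.mean(x)
    s = np.sign(c)
    nz = s != 0
    idx = np.flatnonzero(nz)
    if len(idx) < 2:
        return {}
    sv = s[idx]
    flips = np.flatnonzero(sv[:-1] * sv[1:] < 0)
    if len(flips) < 2:
        return {}
    i0, i1 = idx[flips], idx[flips + 1]
    # linear interpolation of the crossing time between samples i0 and i1
    ct = (i0 + c[i0] / (c[i0] - c[i1]) * (i1 - i0)) * dt
    gaps = np.diff(ct)
    mean = float(np.mean(gaps))
    if mean <= 0:
        return {}
    return {"zc_mean": mean, "zc_cv": float(np.std(gaps) / mean)}


_TIME_COLS = ("hr", "rmssd", "sdnn", "pnn50")
_SPEC_COLS_1 = ("hf_power", "hf_peak", "breathing_rate")
_SPEC_COLS_5 = ("lf_power", "hf_power", "lf_peak", "hf_peak", "total_power",
                "lf_nu", "hf_nu", "lf_hf_ratio", "breathing_rate")
_ZC_COLS = ("zc_mean", "zc_cv")


def hrv_feature_columns(windows: tuple[float, ...] = WINDOWS_S) -> list[str]:
    """Names of all HRV columns emitted by :func:`extract_hrv_features`."""
    cols = []
    for w in windows:
        suf = WINDOW_SUFFIX[w]
        spec = _SPEC_COLS_5 if w >= 300.0 else _SPEC_COLS_1
        cols += [f"{c}_{suf}" for c in _TIME_COLS + spec + _ZC_COLS + ("coverage",)]
    return cols


def extract_hrv_features(ibi: IbiSeries, grid: EpochGrid,
                         windows: tuple[float, ...] = WINDOWS_S,
                         coverage_min: float = COVERAGE_MIN,
                         max_gap_s: float = MAX_GAP_S) -> pd.DataFrame:
    """HRV features per 30-s epoch from the usable intervals.

    Each epoch takes its values from the 1-min and 5-min windows centered on
    the epoch midpoint. A window needs at least ``coverage_min`` of its
    duration covered by usable intervals; spectral and zero-crossing
    features additionally require no unusable gap longer than ``max_gap_s``
    inside the window.
    """
    if ibi.usable is None:
        ibi = clean_ibi(ibi)
    n = grid.n_epochs
    cols = hrv_feature_columns(windows)
    out = {c: np.full(n, np.nan) for c in cols}
    u = ibi.usable
    ut = ibi.t[u]
    uiv = ibi.interval_ms[u]
    if len(ut) >= 4:
        # cumulative usable duration for O(1) coverage queries
        cum = np.concatenate([[0.0], np.cumsum(uiv) / 1000.0])
        # successive pairs: adjacent in the original record, both usable
        oi = np.flatnonzero(u)
        adj = np.flatnonzero(np.diff(oi) == 1)
        pair_t = ibi.t[oi[adj + 1]]
        pair_d = ibi.interval_ms[oi[adj + 1]] - ibi.interval_ms[oi[adj]]
        # global 4 Hz tachogram over the usable span
        cs = CubicSpline(ut, uiv)
        gt = np.arange(ut[0], ut[-1], 1.0 / FS_INTERP)
        gx = cs(gt)
        # unusable gaps: stretches between usable coverage intervals
        starts = ut[:-1]
        ends = ut[1:] - uiv[1:] / 1000.0
        big = (ends - starts) > max_gap_s
        gap_lo, gap_hi = starts[big], ends[big]
        mids = grid.midpoints()
        for w in windows:
            suf = WINDOW_SUFFIX[w]
            full = w >= 300.0
            lo_t, hi_t = mids - w / 2.0, mids + w / 2.0
            lo = np.searchsorted(ut, lo_t)
            hi = np.searchsorted(ut, hi_t, side="right")
            cov = (cum[hi] - cum[lo]) / w
            g0 = np.searchsorted(gt, lo_t)
            g1 = np.searchsorted(gt, hi_t)
            for e in range(n):
                out[f"coverage_{suf}"][e] = cov[e]
                if cov[e] < coverage_min or hi[e] - lo[e] < 2:
                    continue
                p0 = np.searchsorted(pair_t, lo_t[e])
                p1 = np.searchsorted(pair_t, hi_t[e], side="right")
                td = time_domain_features(uiv[lo[e]: hi[e]], pair_d[p0:p1])
                for k, v in td.items():
                    out[f"{k}_{suf}"][e] = v
                # spectral path: reject windows with long unusable gaps
                if np.any((gap_lo < hi_t[e]) & (gap_hi > lo_t[e])):
                    continue
                x = gx[g0[e]: g1[e]]
                if len(x) < 2 * FS_INTERP:
                    continue
                spec = _spectral(x, full=full)
                for k, v in spec.items():
                    key = f"{k}_{suf}"
                    if key in out:
                        out[key][e] = v
                for k, v in _zero_crossings(x, 1.0 / FS_INTERP).items():
                    out[f"{k}_{suf}"][e] = v
    return pd.DataFrame(out, index=pd.RangeIndex(n, name="epoch"))[cols]
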