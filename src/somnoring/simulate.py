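"""Seeded simulation of complete synthetic nights.

A night is drawn in layers. The hypnogram comes from a first-order Markov
chain over {wake, light, deep, REM} on the 30-s epoch grid, whose
transition probabilities into deep sleep are damped across the night and
into REM amplified, reproducing the early-deep / late-REM asymmetry of
human sleep architecture. Sensor streams are then generated conditionally
on the stage sequence:

- **IBI**: interval = 60000/HR(stage) + respiratory sinus-arrhythmia
  modulation A(stage)·sin(2π f(stage) t) + noise, with a smooth ramp across
  stage boundaries, a slow within-night heart-rate fluctuation, a downward
  NREM drift, and ectopic-like short/long intervals injected at a
  configured rate (positions bookkept as ground truth).
- **Accelerometer**: a gravity-dominated orientation with occasional
  posture shifts, white sensor noise, and 3–11 Hz movement bursts
  concentrated in wake epochs.
- **Temperature**: a saturating rise from a start to an end value (distal
  skin temperature climbs as the night progresses) plus noise, with
  out-of-range artifact samples injected at a configured rate.

Everything is a pure function of (config, seed), and every injected event
(ectopics, bursts, posture shifts, temperature artifacts) is returned as
ground truth so downstream filters and features can be scored against
truth rather than heuristics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .core import EPOCH_LEN_S, FOUR_STAGES, EpochGrid, Hypnogram, SensorStreams
from .hrv import IbiSeries

_STAGE_IDX = {s: i for i, s in enumerate(FOUR_STAGES)}  # wake, light, deep, REM


def _default_transitions() -> np.ndarray:
    # rows/cols ordered wake, light, deep, REM; per-30-s-epoch probabilities
    return np.array([
        [0.880, 0.120, 0.000, 0.000],
        [0.012, 0.943, 0.025, 0.020],
        [0.004, 0.031, 0.965, 0.000],
        [0.012, 0.033, 0.000, 0.955],
    ])


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the simulator; all rates and levels configurable."""

    seed: int = 0
    night_duration_h: float = 7.0
    base_transitions: tuple = field(default_factory=lambda: tuple(map(tuple, _default_transitions())))
    sleep_latency_epochs: int = 4          # epochs pinned to wake at lights-off
    deep_mod_scale: float = 3.0            # early-night boost of deep transitions
    deep_mod_tau_h: float = 1.2            # decay constant of that boost
    rem_mod_lo: float = 0.1                # REM transition weight at night start
    rem_mod_hi: float = 2.8                # ... and at night end
    # cardiovascular parameters per stage (wake, light, deep, REM)
    hr_bpm: tuple = (70.0, 60.0, 56.0, 66.0)
    rsa_amp_ms: tuple = (25.0, 30.0, 15.0, 40.0)   # modulation amplitude, REM > light > deep
    breathing_hz: tuple = (0.28, 0.25, 0.22, 0.30)
    ibi_noise_ms: float = 8.0
    hr_slow_sd_bpm: float = 5.0            # slow within-night autonomic HR fluctuation
    amp_slow_log_sd: float = 0.4           # slow multiplicative wander of RSA amplitude
    breathing_slow_sd_hz: float = 0.02     # slow wander of breathing frequency
    nrem_drift_bpm: float = 3.0            # NREM HR decline across the night
    hr_circ_dip_bpm: float = 16.0          # stage-independent circadian HR arc (mid-night dip)
    amp_circ_rise: float = 1.4             # fractional RSA-amplitude rise toward night end
    breathing_circ_rise_hz: float = 0.09   # stage-independent breathing-rate rise across night
    ibi_ectopic_rate: float = 0.01         # per-interval injection probability
    ectopic_delta_bpm: tuple = (25.0, 45.0)  # HR deviation range of injected ectopics
    # accelerometer
    acc_noise_g: float = 0.005
    burst_amp_g: float = 0.35
    burst_prob_wake: float = 0.65          # per wake epoch
    burst_prob_sleep: float = 0.015
    posture_shift_prob_wake: float = 0.10  # per epoch
    posture_shift_prob_sleep: float = 0.01
    # temperature
    temp_start_c: float = 33.8
    temp_end_c: float = 35.2
    temp_tau_h: float = 2.0
    temp_noise_c: float = 0.06
    temp_vasomotor_sd_c: float = 0.45      # slow vasomotor waves (tens of minutes)
    temp_artifact_rate: float = 0.0
    # per-subject variability (used by simulate_cohort)
    subject_hr_sd_bpm: float = 4.0
    subject_temp_sd_c: float = 0.6
    subject_amp_log_sd: float = 0.2
    # stage-dependent autonomic modulation is a per-subject trait: one shared
    # coupling factor scales the HR, RSA-amplitude and breathing-rate stage
    # contrasts together, and a subpopulation shows nearly flat coupling
    subject_coupling_log_sd: float = 0.5
    subject_flat_prob: float = 0.4
    subject_flat_range: tuple = (0.0, 0.2)
    subject_contrast_jitter_log_sd: float = 0.15

    def grid(self) -> EpochGrid:
        return EpochGrid.from_duration(self.night_duration_h * 3600.0)

    def transitions(self) -> np.ndarray:
        P = np.array(self.base_transitions, dtype=float)
        if P.shape != (4, 4) or np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0):
            raise ValueError("transition rows must be non-negative and sum to 1")
        return P


@dataclass(frozen=True)
class SubjectProfile:
    """Between-subject physiology: baseline offsets (which per-night
    normalization must remove) and stage-contrast scalings (how strongly this
    person's heart rate and RSA amplitude differ between stages; real cohorts
    span subjects with pronounced to nearly flat autonomic stage responses)."""

    hr_offset_bpm: float = 0.0
    temp_offset_c: float = 0.0
    amp_scale: float = 1.0
    hr_contrast: float = 1.0
    amp_contrast: float = 1.0
    breathing_contrast: float = 1.0


@dataclass
class SyntheticNight:
    """One simulated night: streams, ground-truth hypnogram, and bookkeeping."""

    streams: SensorStreams
    hypnogram: Hypnogram
    truth: dict
    config: SimConfig
    subject_id: str = "s0"
    night_id: str = "s0_n0"


def _modulation_weights(cfg: SimConfig, grid: EpochGrid) -> tuple[np.ndarray, np.ndarray]:
    t = grid.midpoints()
    u = t / grid.duration
    w_deep = cfg.deep_mod_scale * np.exp(-t / (cfg.deep_mod_tau_h * 3600.0))
    w_rem = cfg.rem_mod_lo + (cfg.rem_mod_hi - cfg.rem_mod_lo) * u
    return w_deep, w_rem


def modulated_transitions(cfg: SimConfig) -> np.ndarray:
    """Per-epoch modulated transition matrices, shape (n_epochs, 4, 4)."""
    grid = cfg.grid()
    P = cfg.transitions()
    w_deep, w_rem = _modulation_weights(cfg, grid)
    mats = np.repeat(P[None, :, :], grid.n_epochs, axis=0)
    mats[:, :, _STAGE_IDX["deep"]] *= w_deep[:, None]
    mats[:, :, _STAGE_IDX["REM"]] *= w_rem[:, None]
    mats /= mats.sum(axis=2, keepdims=True)
    return mats


def time_averaged_transitions(cfg: SimConfig) -> np.ndarray:
    """The epoch-averaged modulated transition matrix (for occupancy analysis)."""
    return modulated_transitions(cfg).mean(axis=0)


def expected_occupancy(cfg: SimConfig) -> np.ndarray:
    """Mean stage occupancy of the configured chain, by exact forward propagation.

    Because the chain is time-inhomogeneous, the mean occupancy is the
    average of the forward-propagated marginal distributions, not the
    stationary vector of any single matrix.
    """
    mats = modulated_transitions(cfg)
    p = np.zeros(4)
    p[_STAGE_IDX["wake"]] = 1.0
    marg = np.empty_like(mats[:, 0, :])
    for e in range(mats.shape[0]):
        marg[e] = p
        if e + 1 >= cfg.sleep_latency_epochs:
            p = p @ mats[e]
    return marg.mean(axis=0)


def stationary_occupancy(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of a transition matrix via eigen-analysis."""
    vals, vecs = np.linalg.eig(P.T)
    v = np.real(vecs[:, np.argmin(np.abs(vals - 1.0))])
    return v / v.sum()


def simulate_hypnogram(cfg: SimConfig, rng: np.random.Generator | None = None) -> Hypnogram:
    """Draw one night's stage sequence from the time-modulated Markov chain."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    grid = cfg.grid()
    P = cfg.transitions()
    if P[0, 0] >= 1.0:
        raise ValueError("wake is absorbing: the night would never enter sleep")
    w_deep, w_rem = _modulation_weights(cfg, grid)
    stages = np.empty(grid.n_epochs, dtype=object)
    state = _STAGE_IDX["wake"]
    u = rng.random(grid.n_epochs)
    for e in range(grid.n_epochs):
        stages[e] = FOUR_STAGES[state]
        if e + 1 < cfg.sleep_latency_epochs:
            continue
        row = P[state].copy()
        row[_STAGE_IDX["deep"]] *= w_deep[e]
        row[_STAGE_IDX["REM"]] *= w_rem[e]
        row /= row.sum()
        state = int(np.searchsorted(np.cumsum(row), u[e]))
    return Hypnogram(grid, stages, vocab="four")


def _stage_seconds(hyp: Hypnogram, per_stage: tuple) -> np.ndarray:
    values = np.array([per_stage[_STAGE_IDX[s]] for s in hyp.stages])
    return np.repeat(values, int(EPOCH_LEN_S))


def simulate_ibi(hyp: Hypnogram, cfg: SimConfig,
                 rng: np.random.Generator | None = None,
                 profile: SubjectProfile = SubjectProfile()) -> tuple[IbiSeries, dict]:
    """Stage-conditioned inter-beat intervals with bookkept ectopic injections."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    dur = hyp.grid.duration
    n_sec = int(dur)
    hr_mean = float(np.mean(cfg.hr_bpm))
    hr_stage = tuple(hr_mean + (h - hr_mean) * profile.hr_contrast for h in cfg.hr_bpm)
    hr = _stage_seconds(hyp, hr_stage) + profile.hr_offset_bpm
    # NREM heart rate declines across the night
    is_nrem = np.isin(np.asarray(hyp.stages), ["light", "deep"])
    nrem_sec = np.repeat(is_nrem, int(EPOCH_LEN_S)).astype(float)
    tt = np.arange(n_sec) / n_sec
    hr = hr - cfg.nrem_drift_bpm * rng.uniform(0.3, 1.5) * tt * nrem_sec
    # circadian arc of heart rate, independent of stage: the nocturnal HR
    # minimum falls mid-night, confounding absolute HR with time of night.
    # Depth and timing vary night to night, so the arc is a confound but not
    # a reliable clock.
    dip = cfg.hr_circ_dip_bpm * rng.uniform(0.3, 1.4)
    center = rng.uniform(0.25, 0.75)
    hr = hr - dip * np.exp(-((tt - center) ** 2) / (2 * 0.25 ** 2))
    hr = gaussian_filter1d(hr, sigma=15.0)

    def slow_walk(sigma_s: float = 120.0) -> np.ndarray:
        w = gaussian_filter1d(np.cumsum(rng.standard_normal(n_sec)), sigma=sigma_s)
        sd = np.std(w)
        # clip so degenerate short records cannot blow up the exponent
        return np.clip(w / sd, -4.0, 4.0) if sd > 0 else np.zeros(n_sec)

    # slow autonomic wander: within-night fluctuations of heart rate, RSA
    # amplitude and breathing rate comparable to the between-stage contrasts,
    # so that instantaneous HRV alone does not fully determine the stage
    if cfg.hr_slow_sd_bpm > 0:
        hr = hr + slow_walk() * cfg.hr_slow_sd_bpm
    hr = np.clip(hr, 40.0, 100.0)  # physiological night-time range
    amps = np.maximum(np.asarray(cfg.rsa_amp_ms, dtype=float), 1e-9)
    amp_gm = float(np.exp(np.mean(np.log(amps))))
    amp_stage = tuple(amp_gm * (a / amp_gm) ** profile.amp_contrast for a in amps)
    amp = gaussian_filter1d(_stage_seconds(hyp, amp_stage), sigma=10.0) * profile.amp_scale
    if cfg.amp_slow_log_sd > 0:
        amp = amp * np.exp(slow_walk(300.0) * cfg.amp_slow_log_sd)
    # parasympathetic surges with night-varying magnitude and timing,
    # weighted toward the morning hours; a bump rather than a monotone ramp,
    # so per-night normalization cannot turn it into a clock
    a_mag = cfg.amp_circ_rise * rng.uniform(0.2, 1.5)
    a_center = rng.uniform(0.3, 0.9)
    amp = amp * (1.0 + a_mag * np.exp(-((tt - a_center) ** 2) / (2 * 0.3 ** 2)))
    # RSA amplitude is physiologically bounded as a fraction of the beat
    # interval; this also keeps breathing modulation clear of the 16-bpm
    # artifact rule at any heart rate
    base_iv = 60000.0 / hr
    amp = np.clip(amp, 2.0, np.maximum(2.0, 0.13 * base_iv - 5.0 * cfg.ibi_noise_ms))
    f_mean = float(np.mean(cfg.breathing_hz))
    f_stage = tuple(f_mean + (f - f_mean) * profile.breathing_contrast
                    for f in cfg.breathing_hz)
    freq = gaussian_filter1d(_stage_seconds(hyp, f_stage), sigma=10.0)
    f_mag = cfg.breathing_circ_rise_hz * rng.uniform(0.2, 1.5)
    f_center = rng.uniform(0.3, 0.9)
    freq = freq + f_mag * np.exp(-((tt - f_center) ** 2) / (2 * 0.3 ** 2))
    if cfg.breathing_slow_sd_hz > 0:
        freq = freq + slow_walk(300.0) * cfg.breathing_slow_sd_hz
    freq = np.clip(freq, 0.16, 0.38)
    floor_ms = 60000.0 / np.max(hr) - np.max(amp) - 5 * cfg.ibi_noise_ms
    if floor_ms <= 0:
        raise ValueError("configured HR/amplitude/noise can produce non-positive intervals")

    est = int(dur / (60.0 / np.max(hr))) + 200
    noise = rng.standard_normal(est) * cfg.ibi_noise_ms
    intervals, t, phase, k = [], 0.0, 0.0, 0
    tail = 45.0  # generate past lights-on so edge windows stay covered
    while t < dur + tail and k < est:
        i = min(int(t), n_sec - 1)
        iv = 60000.0 / hr[i] + amp[i] * np.sin(phase) + noise[k]
        iv = max(iv, 250.0)
        phase += 2.0 * np.pi * freq[i] * iv / 1000.0
        t += iv / 1000.0
        intervals.append(iv)
        k += 1
    iv = np.array(intervals)

    ectopic_idx = np.array([], dtype=int)
    if cfg.ibi_ectopic_rate > 0 and len(iv) > 10:
        cand = np.flatnonzero(rng.random(len(iv)) < cfg.ibi_ectopic_rate)
        cand = cand[(cand >= 3) & (cand < len(iv) - 3)]
        keep, last = [], -10
        for c in cand:
            if c - last >= 8:  # isolate ectopics so each sits in a clean neighborhood
                keep.append(c)
                last = c
        ectopic_idx = np.array(keep, dtype=int)
        # target each ectopic's instantaneous-HR deviation directly, so every
        # injection exceeds the 16-bpm rule by construction at any local HR
        hr_local = 60000.0 / iv[ectopic_idx]
        delta = rng.uniform(*cfg.ectopic_delta_bpm, size=len(ectopic_idx))
        go_long = (rng.random(len(ectopic_idx)) < 0.5) & (hr_local - delta >= 25.0)
        hr_new = np.where(go_long, hr_local - delta, hr_local + delta)
        iv[ectopic_idx] = 60000.0 / hr_new

    beat_t = iv.cumsum() / 1000.0
    return IbiSeries(t=beat_t, interval_ms=iv), {"ectopic_idx": ectopic_idx}


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def simulate_acc(hyp: Hypnogram, cfg: SimConfig,
                 rng: np.random.Generator | None = None,
                 fs: float = 50.0) -> tuple[pd.DataFrame, dict]:
    """Gravity + posture shifts + wake-concentrated 3–11 Hz movement bursts."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n_ep = hyp.grid.n_epochs
    spe = int(round(EPOCH_LEN_S * fs))
    n = n_ep * spe
    is_wake = np.asarray(hyp.stages) == "wake"

    shift_p = np.where(is_wake, cfg.posture_shift_prob_wake, cfg.posture_shift_prob_sleep)
    shifts = rng.random(n_ep) < shift_p
    shifts[0] = False
    orient = np.empty((n_ep, 3))
    cur = _random_unit(rng)
    for e in range(n_ep):
        if shifts[e]:
            cur = _random_unit(rng)
        orient[e] = cur
    sig = np.repeat(orient, spe, axis=0)
    # smooth orientation transitions over ~1 s so shifts are not step artifacts
    sig = gaussian_filter1d(sig, sigma=0.5 * fs, axis=0)
    sig += rng.standard_normal((n, 3)) * cfg.acc_noise_g

    burst_p = np.where(is_wake, cfg.burst_prob_wake, cfg.burst_prob_sleep)
    bursts = rng.random(n_ep) < burst_p
    t = np.arange(n) / fs
    for e in np.flatnonzero(bursts):
        dur_s = rng.uniform(1.0, 8.0)
        start = e * spe + int(rng.uniform(0, max(1.0, EPOCH_LEN_S - dur_s)) * fs)
        length = min(int(dur_s * fs), n - start)
        if length < int(fs):
            continue
        env = np.hanning(length)
        tt = t[start: start + length]
        for ax in range(3):
            f1, f2 = rng.uniform(4.0, 10.0, size=2)
            a = cfg.burst_amp_g * rng.uniform(0.4, 1.2)
            wave = np.sin(2 * np.pi * f1 * tt + rng.uniform(0, 2 * np.pi)) \
                + 0.6 * np.sin(2 * np.pi * f2 * tt + rng.uniform(0, 2 * np.pi))
            sig[start: start + length, ax] += a * env * wave
    sig = np.clip(sig, -2.0, 2.0)  # sensor range is +/- 2 g
    df = pd.DataFrame({"t": t, "x": sig[:, 0], "y": sig[:, 1], "z": sig[:, 2]})
    return df, {"burst_epochs": bursts, "shift_epochs": shifts}


def simulate_temp(hyp: Hypnogram, cfg: SimConfig,
                  rng: np.random.Generator | None = None,
                  profile: SubjectProfile = SubjectProfile(),
                  sample_interval_s: float = 10.0) -> tuple[pd.DataFrame, dict]:
    """Rising distal skin temperature with injected out-of-range artifacts."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    dur = hyp.grid.duration
    t = np.arange(0.0, dur, sample_interval_s)
    # the speed and span of the nocturnal rise vary night to night
    tau = cfg.temp_tau_h * 3600.0 * rng.uniform(0.5, 1.5)
    rise = (1.0 - np.exp(-t / tau)) / (1.0 - np.exp(-dur / tau))
    span = (cfg.temp_end_c - cfg.temp_start_c) * rng.uniform(0.4, 1.6)
    v = cfg.temp_start_c + span * rise
    if cfg.temp_vasomotor_sd_c > 0:
        # distal skin temperature rides on slow vasomotor waves, so the rise
        # is a trend, not a clean clock
        walk = gaussian_filter1d(np.cumsum(rng.standard_normal(len(t))), sigma=120.0)
        sd = np.std(walk)
        if sd > 0:
            v = v + walk / sd * cfg.temp_vasomotor_sd_c
    v = v + profile.temp_offset_c + rng.standard_normal(len(t)) * cfg.temp_noise_c
    artifact_idx = np.flatnonzero(rng.random(len(t)) < cfg.temp_artifact_rate)
    for i in artifact_idx:
        v[i] = rng.uniform(24.0, 30.5) if rng.random() < 0.5 else rng.uniform(40.5, 45.0)
    return pd.DataFrame({"t": t, "celsius": v}), {"artifact_idx": artifact_idx}


def simulate_night(cfg: SimConfig, subject_id: str = "s0", night_id: str = "s0_n0",
                   profile: SubjectProfile = SubjectProfile(),
                   seed_seq: np.random.SeedSequence | None = None) -> SyntheticNight:
    """One complete night; deterministic under (config, seed)."""
    if seed_seq is None:
        seed_seq = np.random.SeedSequence(cfg.seed)
    r_hyp, r_ibi, r_acc, r_temp = [np.random.default_rng(s) for s in seed_seq.spawn(4)]
    hyp = simulate_hypnogram(cfg, r_hyp)
    ibi, ibi_truth = simulate_ibi(hyp, cfg, r_ibi, profile=profile)
    acc, acc_truth = simulate_acc(hyp, cfg, r_acc)
    temp, temp_truth = simulate_temp(hyp, cfg, r_temp, profile=profile)
    streams = SensorStreams(acc=acc, temp=temp, ibi=ibi,
                            subject_id=subject_id, night_id=night_id)
    truth = {**{f"ibi_{k}": v for k, v in ibi_truth.items()},
             **{f"acc_{k}": v for k, v in acc_truth.items()},
             **{f"temp_{k}": v for k, v in temp_truth.items()},
             "profile": profile}
    return SyntheticNight(streams=streams, hypnogram=hyp, truth=truth,
                          config=cfg, subject_id=subject_id, night_id=night_id)


def simulate_cohort(n_subjects: int, nights_per_subject: int,
                    cfg: SimConfig) -> list[SyntheticNight]:
    """A multi-subject, multi-night cohort with between-subject baseline offsets."""
    if n_subjects < 1 or nights_per_subject < 1:
        raise ValueError("need at least one subject and one night")
    root = np.random.SeedSequence(cfg.seed)
    subj_seqs = root.spawn(n_subjects)
    nights = []
    for si, sseq in enumerate(subj_seqs):
        prof_rng = np.random.default_rng(sseq)
        if prof_rng.random() < cfg.subject_flat_prob:
            coupling = float(prof_rng.uniform(*cfg.subject_flat_range))
        else:
            coupling = float(np.exp(prof_rng.normal(0.0, cfg.subject_coupling_log_sd)))
        jit = cfg.subject_contrast_jitter_log_sd
        profile = SubjectProfile(
            hr_offset_bpm=float(prof_rng.normal(0.0, cfg.subject_hr_sd_bpm)),
            temp_offset_c=float(prof_rng.normal(0.0, cfg.subject_temp_sd_c)),
            amp_scale=float(np.exp(prof_rng.normal(0.0, cfg.subject_amp_log_sd))),
            hr_contrast=coupling * float(np.exp(prof_rng.normal(0.0, jit))),
            amp_contrast=coupling * float(np.exp(prof_rng.normal(0.0, jit))),
            breathing_contrast=coupling * float(np.exp(prof_rng.normal(0.0, jit))),
        )
        for ni, nseq in enumerate(sseq.spawn(nights_per_subject)):
            sid, nid = f"s{si:03d}", f"s{si:03d}_n{ni}"
            nights.append(simulate_night(cfg, subject_id=sid, night_id=nid,
                                         profile=profile, seed_seq=nseq))
    return nights
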