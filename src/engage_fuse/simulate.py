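"""Seeded synthetic multimodal recording sessions with a known engagement state.

The generator emulates the recording protocol the rest of the pipeline
expects: a 90-s neutral baseline followed by a train of 10-s encoding
windows (separated by short answer gaps that are never analysed), with a
latent binary engagement state that persists across adjacent windows and
jointly modulates

* EEG (Fz, Pz @ 500 Hz): the theta/alpha/beta/gamma band-power mix,
* ECG (1 lead @ 500 Hz): mean heart rate and the amplitude of a 0.3 Hz
  (high-frequency band) respiratory modulation of the RR intervals,
* vertical EOG (@ 500 Hz): blink transients at a Poisson rate — fewer
  blinks when engaged,
* pupil diameter (@ 30 or 60 Hz): a smoothed random walk around a
  state-dependent mean — larger when engaged — with short missing-sample
  gaps at every blink,
* NIRS (Fp1, Fp2 @ 10.2 Hz): slow (< 0.1 Hz) hemodynamic oscillations
  plus drift; the total-hemoglobin trace is exactly oxy + deoxy.

Effect sizes are NOT taken from any human dataset — none are published
for this protocol — so the default profiles below are explicitly
fictional, chosen to encode the qualitative physiology (engagement =
beta/gamma shift, higher HR, lower vagal HF power, fewer blinks, larger
pupils) at magnitudes a desk-scale classifier study would call realistic.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal
from scipy.ndimage import gaussian_filter1d

from .session import SessionRecording, Stream, Window

__all__ = [
    "StateProfile",
    "SimulationConfig",
    "DEFAULT_HIGH",
    "DEFAULT_LOW",
    "generate_session",
    "generate_sessions",
    "neutral_profile",
]

BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 65.0),
}


@dataclass(frozen=True)
class StateProfile:
    """Physiological operating point of one latent engagement state."""

    band_power_fracs: dict[str, float]  # theta/alpha/beta/gamma, sums to 1
    mean_hr: float  # beats/min
    hf_power: float  # ms^2, variance of HF RR modulation
    blink_rate: float  # blinks/min
    pupil_mean: float  # arbitrary diameter units (~mm)
    nirs_oxy_drift: float  # concentration units per second
    noise_sd: dict[str, float] = field(
        default_factory=lambda: dict(eeg=20.0, ecg=0.02, eog=10.0, pupil=0.12, nirs=1.0)
    )

    def __post_init__(self):
        fr = self.band_power_fracs
        if set(fr) != set(BANDS):
            raise ValueError(f"band_power_fracs must have keys {sorted(BANDS)}")
        if any(v < 0 for v in fr.values()):
            raise ValueError("band fractions must be nonnegative")
        if abs(sum(fr.values()) - 1.0) > 1e-9:
            raise ValueError("band fractions must sum to 1 within 1e-9")
        if self.blink_rate < 0:
            raise ValueError("blink_rate must be >= 0")
        if not (30.0 < self.mean_hr < 200.0):
            raise ValueError("mean_hr must lie in (30, 200) bpm")
        if self.hf_power < 0:
            raise ValueError("hf_power must be >= 0")


#: disengaged: alpha-dominant EEG, slower heart with strong vagal HF
#: modulation, frequent blinking, constricted pupil, flat NIRS.
DEFAULT_LOW = StateProfile(
    band_power_fracs=dict(theta=0.25, alpha=0.45, beta=0.20, gamma=0.10),
    mean_hr=65.0,
    hf_power=900.0,
    blink_rate=20.0,
    pupil_mean=3.6,
    nirs_oxy_drift=0.0005,
    noise_sd=dict(eeg=20.0, ecg=0.02, eog=10.0, pupil=0.12, nirs=0.5),
)

#: engaged: beta/gamma shift, faster heart with vagal withdrawal, sparse
#: blinking, dilated pupil, larger hemodynamic slow waves and drift.
DEFAULT_HIGH = StateProfile(
    band_power_fracs=dict(theta=0.20, alpha=0.20, beta=0.40, gamma=0.20),
    mean_hr=78.0,
    hf_power=300.0,
    blink_rate=5.0,
    pupil_mean=4.4,
    nirs_oxy_drift=0.002,
    noise_sd=dict(eeg=20.0, ecg=0.02, eog=10.0, pupil=0.12, nirs=1.5),
)


def neutral_profile(high: StateProfile, low: StateProfile) -> StateProfile:
    """Midpoint profile used for the baseline and inter-trial gaps."""
    fr = {b: 0.5 * (high.band_power_fracs[b] + low.band_power_fracs[b]) for b in BANDS}
    s = sum(fr.values())
    fr = {b: v / s for b, v in fr.items()}
    return StateProfile(
        band_power_fracs=fr,
        mean_hr=0.5 * (high.mean_hr + low.mean_hr),
        hf_power=0.5 * (high.hf_power + low.hf_power),
        blink_rate=0.5 * (high.blink_rate + low.blink_rate),
        pupil_mean=0.5 * (high.pupil_mean + low.pupil_mean),
        nirs_oxy_drift=0.5 * (high.nirs_oxy_drift + low.nirs_oxy_drift),
        noise_sd={k: 0.5 * (high.noise_sd[k] + low.noise_sd[k]) for k in high.noise_sd},
    )


@dataclass(frozen=True)
class SimulationConfig:
    n_participants: int = 1
    n_trials: int = 30
    window_s: float = 10.0
    baseline_s: float = 90.0
    gap_s: float = 4.0  # un-analysed answer period between encoding windows
    fs_eeg_ecg_eog: float = 500.0
    fs_nirs: float = 10.2
    fs_pupil: float = 60.0
    state_params_high: StateProfile = DEFAULT_HIGH
    state_params_low: StateProfile = DEFAULT_LOW
    prior_high: float = 0.62  # marginal probability of the engaged state
    mean_block_len: float = 5.0  # mean run length of a latent state, in windows
    duration_s: float | None = None  # optional hard cap on recording length
    seed: int = 0

    def __post_init__(self):
        if min(self.fs_eeg_ecg_eog, self.fs_nirs, self.fs_pupil) <= 0:
            raise ValueError("all sampling rates must be > 0")
        if self.fs_pupil not in (30.0, 60.0, 30, 60):
            raise ValueError("fs_pupil must be 30 or 60 Hz")
        if self.window_s <= 0 or self.baseline_s < 0 or self.gap_s < 0:
            raise ValueError("durations must be nonnegative, window_s > 0")
        if self.n_trials < 1 or self.n_participants < 1:
            raise ValueError("need at least one trial and one participant")
        if not (0.0 < self.prior_high < 1.0):
            raise ValueError("prior_high must lie in (0, 1)")
        need = self.baseline_s + self.n_trials * (self.window_s + self.gap_s)
        if self.duration_s is not None and need > self.duration_s + 1e-9:
            raise ValueError(
                f"window grid needs {need:.1f}s but duration_s caps the recording "
                f"at {self.duration_s:.1f}s"
            )

    @property
    def total_duration_s(self) -> float:
        return self.baseline_s + self.n_trials * (self.window_s + self.gap_s)


# --------------------------------------------------------------------------
# internals


def _rng_for(config: SimulationConfig, participant_id: str) -> np.random.Generator:
    # one named generator per (seed, participant); crc32 keeps it text-stable
    tag = zlib.crc32(str(participant_id).encode())
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), tag]))


def _latent_states(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Blocks of geometric length (mean ``mean_block_len`` windows)."""
    p_switch = 1.0 / config.mean_block_len
    states = np.empty(config.n_trials, dtype=object)
    cur = "high" if rng.random() < config.prior_high else "low"
    for i in range(config.n_trials):
        if i > 0 and rng.random() < p_switch:
            cur = "high" if rng.random() < config.prior_high else "low"
        states[i] = cur
    return states


def _segments(config: SimulationConfig, states: np.ndarray):
    """Full timeline partition: (start_s, end_s, profile-key) with no holes."""
    segs = [(0.0, config.baseline_s, "neutral")]
    t = config.baseline_s
    windows = [Window(0.0, config.baseline_s, "baseline")]
    for i in range(config.n_trials):
        segs.append((t, t + config.window_s, states[i]))
        windows.append(Window(t, t + config.window_s, "encoding"))
        t += config.window_s
        if config.gap_s > 0:
            segs.append((t, t + config.gap_s, "neutral"))
            t += config.gap_s
    return segs, windows


def _bandpass_sos(lo, hi, fs, order=4):
    return signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")


def _gen_eeg(config, segs, profiles, rng, n):
    """Sum of four band-limited noise carriers, band mix switched per segment."""
    fs = config.fs_eeg_ecg_eog
    carriers = {}
    for band, (lo, hi) in BANDS.items():
        w = rng.standard_normal(n)
        x = signal.sosfiltfilt(_bandpass_sos(lo, min(hi, 0.49 * fs), fs), w)
        carriers[band] = x / x.std()
    out = np.zeros(n)
    for start, end, key in segs:
        i0, i1 = int(round(start * fs)), int(round(end * fs))
        prof = profiles[key]
        sd = prof.noise_sd["eeg"]
        for band in BANDS:
            out[i0:i1] += sd * np.sqrt(prof.band_power_fracs[band]) * carriers[band][i0:i1]
    return out


def _pqrst_template(fs: float) -> tuple[np.ndarray, int]:
    """One PQRST complex in mV; returns (waveform, index of the R sample)."""
    t = np.arange(-0.30, 0.45, 1.0 / fs)
    wave = (
        0.15 * np.exp(-((t + 0.20) ** 2) / (2 * 0.025**2))  # P
        - 0.15 * np.exp(-((t + 0.025) ** 2) / (2 * 0.010**2))  # Q
        + 1.00 * np.exp(-(t**2) / (2 * 0.008**2))  # R
        - 0.25 * np.exp(-((t - 0.030) ** 2) / (2 * 0.010**2))  # S
        + 0.30 * np.exp(-((t - 0.30) ** 2) / (2 * 0.040**2))  # T
    )
    return wave, int(np.argmin(np.abs(t)))


def _gen_ecg(config, segs, profiles, rng, n):
    """PQRST train; RR = 60/HR plus a 0.3 Hz HF oscillation of variance hf_power."""
    fs = config.fs_eeg_ecg_eog
    starts = np.array([s[0] for s in segs])
    keys = [s[2] for s in segs]
    template, r_off = _pqrst_template(fs)
    out = np.zeros(n + len(template))
    dur = n / fs
    t = 0.2
    while t < dur:
        prof = profiles[keys[min(np.searchsorted(starts, t, "right") - 1, len(keys) - 1)]]
        hf_amp_s = np.sqrt(2.0 * prof.hf_power) / 1000.0
        rr = 60.0 / prof.mean_hr + hf_amp_s * np.sin(2 * np.pi * 0.3 * t)
        rr += rng.normal(0.0, 0.004)
        i = int(round(t * fs))
        out[i : i + len(template)] += template
        t += max(rr, 0.3)
    out = out[r_off : r_off + n]
    out += rng.normal(0.0, profiles["neutral"].noise_sd["ecg"], n)
    return out


def _place_events(rng, n_events, t0, t1, min_sep=0.4):
    """Uniform event times in (t0, t1) with a minimum separation."""
    placed: list[float] = []
    if t1 <= t0:
        return placed
    for _ in range(n_events):
        for _ in range(20):
            t = rng.uniform(t0, t1)
            if all(abs(t - p) >= min_sep for p in placed):
                placed.append(t)
                break
    return sorted(placed)


def _gen_blink_times(config, segs, profiles, rng):
    # the EOG trace is continuous across segments, so only the recording
    # edges need a margin for the blink waveform's support
    times = []
    end_of_rec = segs[-1][1]
    for start, end, key in segs:
        rate = profiles[key].blink_rate  # per minute
        n_ev = rng.poisson(rate * (end - start) / 60.0)
        lo = max(start, 0.3)
        hi = min(end, end_of_rec - 0.3)
        times.extend(_place_events(rng, n_ev, lo, hi))
    return np.array(times)


def _gen_eog(config, blink_times, profiles, rng, n):
    """Blink transients (~300 uV, 200-400 ms) on low-amplitude background noise."""
    fs = config.fs_eeg_ecg_eog
    t = np.arange(n) / fs
    out = rng.normal(0.0, profiles["neutral"].noise_sd["eog"], n)
    for bt in blink_times:
        amp = rng.uniform(250.0, 350.0)
        i0 = max(0, int((bt - 0.3) * fs))
        i1 = min(n, int((bt + 0.3) * fs))
        out[i0:i1] += amp * np.exp(-((t[i0:i1] - bt) ** 2) / (2 * 0.07**2))
    return out


def _gen_pupil(config, segs, profiles, blink_times, rng, n):
    fs = config.fs_pupil
    mean = np.zeros(n)
    for start, end, key in segs:
        i0, i1 = int(round(start * fs)), int(round(end * fs))
        mean[i0:i1] = profiles[key].pupil_mean
    mean[int(round(segs[-1][1] * fs)) :] = profiles["neutral"].pupil_mean
    mean = gaussian_filter1d(mean, sigma=0.2 * fs, mode="nearest")
    noise = gaussian_filter1d(
        rng.normal(0.0, 1.0, n), sigma=0.3 * fs, mode="nearest"
    )
    if noise.std() > 0:
        noise = noise / noise.std() * profiles["neutral"].noise_sd["pupil"]
    out = mean + noise
    # each blink blanks the tracker for ~150 ms
    for bt in blink_times:
        i0 = max(0, int((bt - 0.075) * fs))
        i1 = min(n, int((bt + 0.075) * fs) + 1)
        out[i0:i1] = np.nan
    return out


def _gen_nirs_site(config, segs, profiles, rng, n, phase):
    """Returns (oxy, deoxy, total) for one optode site; total = oxy + deoxy exactly."""
    fs = config.fs_nirs
    t = np.arange(n) / fs
    osc = np.sin(2 * np.pi * 0.06 * t + phase)
    amp = np.zeros(n)
    drift = np.zeros(n)
    for start, end, key in segs:
        i0, i1 = int(round(start * fs)), int(round(end * fs))
        prof = profiles[key]
        amp[i0:i1] = 2.0 * prof.noise_sd["nirs"]
        drift[i0:i1] = prof.nirs_oxy_drift * (t[i0:i1] - start)
    nz = profiles["neutral"].noise_sd["nirs"]

    def slow_noise():
        x = gaussian_filter1d(rng.standard_normal(n), sigma=2.0 * fs, mode="nearest")
        return x / x.std() if x.std() > 0 else x

    oxy = drift + amp * osc + 0.3 * nz * slow_noise()
    deoxy = -0.4 * amp * osc - 0.3 * drift + 0.15 * nz * slow_noise()
    return oxy, deoxy, oxy + deoxy


# --------------------------------------------------------------------------
# public API


def generate_session(config: SimulationConfig, participant_id: str) -> SessionRecording:
    """Generate one participant's full multimodal session.

    Deterministic: the same (config.seed, participant_id) pair always yields
    bit-identical streams.
    """
    rng = _rng_for(config, participant_id)
    states = _latent_states(config, rng)
    segs, window_map = _segments(config, states)
    profiles = {
        "high": config.state_params_high,
        "low": config.state_params_low,
        "neutral": neutral_profile(config.state_params_high, config.state_params_low),
    }
    dur = config.total_duration_s
    n_fast = int(round(dur * config.fs_eeg_ecg_eog))
    n_pupil = int(round(dur * config.fs_pupil))
    n_nirs = int(round(dur * config.fs_nirs))

    streams: dict[str, Stream] = {}
    fs_fast = config.fs_eeg_ecg_eog
    for ch in ("fz", "pz"):
        streams[f"eeg_{ch}"] = Stream(_gen_eeg(config, segs, profiles, rng, n_fast), fs_fast)
    streams["ecg"] = Stream(_gen_ecg(config, segs, profiles, rng, n_fast), fs_fast)
    blink_times = _gen_blink_times(config, segs, profiles, rng)
    streams["eog"] = Stream(_gen_eog(config, blink_times, profiles, rng, n_fast), fs_fast)
    streams["pupil"] = Stream(
        _gen_pupil(config, segs, profiles, blink_times, rng, n_pupil), config.fs_pupil
    )
    for site in ("fp1", "fp2"):
        phase = rng.uniform(0, 2 * np.pi)
        oxy, deoxy, tot = _gen_nirs_site(config, segs, profiles, rng, n_nirs, phase)
        streams[f"nirs_oxy_{site}"] = Stream(oxy, config.fs_nirs)
        streams[f"nirs_deoxy_{site}"] = Stream(deoxy, config.fs_nirs)
        streams[f"nirs_tot_{site}"] = Stream(tot, config.fs_nirs)

    session = SessionRecording(
        participant_id=str(participant_id),
        streams=streams,
        latent_states=states,
        window_map=window_map,
    )
    session.validate()
    return session


def generate_sessions(config: SimulationConfig) -> list[SessionRecording]:
    """One session per participant (ids ``P01``, ``P02``, ...)."""
    return [
        generate_session(config, f"P{i + 1:02d}") for i in range(config.n_participants)
    ]


def null_config(**kwargs) -> SimulationConfig:
    """A configuration whose two states are physiologically identical.

    Under this null every downstream classifier should sit at chance; it is
    the type-I calibration of the whole pipeline.
    """
    prof = neutral_profile(DEFAULT_HIGH, DEFAULT_LOW)
    return SimulationConfig(state_params_high=prof, state_params_low=prof, **kwargs)
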