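"""Per-window multimodal feature extraction (59 features).

Every retained 10-s encoding window yields:

* EEG, per electrode (Fz, Pz), 17 features: Hjorth activity/mobility/
  complexity, an LZ76 Kolmogorov-complexity proxy, per-band (theta, alpha,
  beta, gamma) maximum PSD and PSD integral, per-band relative wavelet
  power, and normalized spectral entropy — 34 in total;
* ECG, 7 features: Hjorth triple, LZ76 complexity and spectral entropy of
  the filtered waveform, heart rate from the median RR interval, and
  high-frequency (0.15-0.4 Hz) HRV power;
* NIRS, 18 features: the Hjorth triple of each of oxy-, deoxy- and
  total-hemoglobin at each optode site (Fp1, Fp2).

Band powers come from a 6-level Daubechies-8 wavelet decomposition whose
detail levels at 500 Hz align with the conventional QEEG bands (D6
3.9-7.8 Hz -> theta, D5 7.8-15.6 -> alpha, D4 15.6-31.25 -> beta, D3
31.25-62.5 -> gamma); the relative powers therefore share one denominator
and sum to exactly 1. Max-PSD and PSD-integral features use a Welch
estimate over the nominal band edges instead, since they are densities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
from scipy import signal as sps
from scipy.integrate import trapezoid

from .session import SessionRecording

__all__ = [
    "DegenerateSignalError",
    "MissingStreamError",
    "HjorthTriple",
    "BandPowerSet",
    "hjorth",
    "eeg_preprocess",
    "wavelet_band_powers",
    "kolmogorov_complexity",
    "lz76_phrase_count",
    "spectral_entropy",
    "detect_r_peaks",
    "heart_rate",
    "hrv_hf",
    "extract_features",
    "feature_columns",
    "MODALITIES",
]

BAND_EDGES = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 65.0),
}
#: discrete-wavelet detail level holding each band at fs = 500 Hz
WAVELET_LEVEL = {"gamma": 3, "beta": 4, "alpha": 5, "theta": 6}
EEG_FS = 500.0


class DegenerateSignalError(ValueError):
    """A constant (zero-variance) window where a ratio feature is undefined."""


class MissingStreamError(KeyError):
    """The requested modality needs a stream the session does not carry."""


# --------------------------------------------------------------------------
# time-domain descriptors


@dataclass(frozen=True)
class HjorthTriple:
    activity: float  # variance of the window
    mobility: float  # sqrt(var(dy)/var(y)): per-sample RMS frequency proxy
    complexity: float  # mobility(dy)/mobility(y); 1 for a pure sinusoid


def hjorth(window: np.ndarray) -> HjorthTriple:
    """Hjorth activity, mobility and complexity of one window.

    Mobility is reported per sample (dimensionless); multiply by fs/(2*pi)
    for a Hz-equivalent reading.
    """
    y = np.asarray(window, dtype=float)
    if y.size < 3:
        raise ValueError("Hjorth parameters need at least 3 samples")
    var_y = y.var()
    if var_y == 0:
        raise DegenerateSignalError(
            "constant window: activity is 0 and mobility/complexity are undefined"
        )
    dy = np.diff(y)
    ddy = np.diff(dy)
    var_dy = dy.var()
    mobility = np.sqrt(var_dy / var_y)
    if var_dy == 0:
        raise DegenerateSignalError("linear window: complexity is undefined")
    mobility_dy = np.sqrt(ddy.var() / var_dy)
    return HjorthTriple(float(var_y), float(mobility), float(mobility_dy / mobility))


def lz76_phrase_count(bits: str) -> int:
    """Lempel-Ziv 1976 production-history length of a binary string.

    Each step extends the current phrase until it is no longer a substring
    of everything seen so far (excluding its own final character).
    """
    i, c, n = 0, 0, len(bits)
    while i < n:
        length = 1
        while i + length <= n and bits.find(bits[i : i + length], 0, i + length - 1) != -1:
            length += 1
        c += 1
        i += length
    return c


def kolmogorov_complexity(window: np.ndarray) -> float:
    """Normalized LZ76 complexity of the median-binarized window.

    Returns c(n) / (n / log2 n): ~1 for algorithmically random sequences,
    near 0 for periodic ones. A constant window binarizes to all zeros and
    returns the minimum (not an error).
    """
    y = np.asarray(window, dtype=float)
    n = y.size
    if n < 64:
        raise ValueError("LZ76 complexity needs at least 64 samples")
    med = np.median(y)
    above = y > med
    if not above.any() and (y != med).any():
        # two-valued signals can have median == max; fall back to >= so the
        # binarization still separates the levels
        above = y >= med
    bits = "".join("1" if v else "0" for v in above)
    return lz76_phrase_count(bits) * np.log2(n) / n


# --------------------------------------------------------------------------
# spectral descriptors


def eeg_preprocess(window: np.ndarray, fs: float = EEG_FS) -> np.ndarray:
    """Zero-phase 3rd-order Butterworth band-pass, 0.5-65 Hz, at 500 Hz."""
    if fs != EEG_FS:
        raise ValueError(f"EEG pipeline is defined at {EEG_FS:g} Hz, got {fs:g}")
    x = np.asarray(window, dtype=float)
    x = x - x.mean()
    sos = sps.butter(3, [0.5, 65.0], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def _welch(x: np.ndarray, fs: float):
    nper = min(len(x), int(2 * fs))
    return sps.welch(x, fs=fs, nperseg=nper)


@dataclass(frozen=True)
class BandPowerSet:
    band_power: dict[str, float]  # mean squared wavelet detail coefficients
    relative: dict[str, float]  # shares one denominator, sums to 1
    max_psd: dict[str, float]  # max Welch PSD within the band (power/Hz)
    density_integral: dict[str, float]  # trapezoidal PSD integral over the band


def wavelet_band_powers(filtered: np.ndarray, fs: float = EEG_FS) -> BandPowerSet:
    """Per-band power of a filtered EEG window.

    Band power is the mean squared coefficient of the Daubechies-8 detail
    level mapped to the band; relative powers divide each by the sum over
    the four bands. Max PSD and the PSD integral are read off a Welch
    estimate over the nominal band edges.
    """
    x = np.asarray(filtered, dtype=float)
    w = pywt.Wavelet("db8")
    max_lvl = pywt.dwt_max_level(len(x), w.dec_len)
    if max_lvl < max(WAVELET_LEVEL.values()):
        raise ValueError("window too short for a 6-level db8 decomposition")
    coeffs = pywt.wavedec(x, w, level=6)  # [A6, D6, D5, ..., D1]
    details = {6 - i: c for i, c in enumerate(coeffs[1:])}  # level -> detail array
    # band power = band energy = sum of squared coefficients (the DWT is
    # energy-preserving); a per-level mean would weight narrow low bands by
    # their coarser coefficient grid
    power = {
        band: float(np.sum(details[lvl] ** 2)) for band, lvl in WAVELET_LEVEL.items()
    }
    total = sum(power.values())
    if total == 0:
        raise DegenerateSignalError("window has no in-band power")
    relative = {band: p / total for band, p in power.items()}
    f, psd = _welch(x, fs)
    max_psd, integral = {}, {}
    for band, (lo, hi) in BAND_EDGES.items():
        sel = (f >= lo) & (f <= hi)
        max_psd[band] = float(psd[sel].max())
        integral[band] = float(trapezoid(psd[sel], f[sel]))
    return BandPowerSet(power, relative, max_psd, integral)


def spectral_entropy(window: np.ndarray, fs: float = EEG_FS) -> float:
    """Shannon entropy of the normalized Welch spectrum, scaled to [0, 1].

    Uses 2-s segments with 50% overlap; near 0 for a pure tone, near 1 for
    white noise.
    """
    x = np.asarray(window, dtype=float)
    if x.var() == 0:
        raise DegenerateSignalError("constant window has no spectrum")
    _, psd = _welch(x - x.mean(), fs)
    psd = psd[psd > 0]
    p = psd / psd.sum()
    return float(-(p * np.log(p)).sum() / np.log(len(p)))


# --------------------------------------------------------------------------
# cardiac descriptors


def detect_r_peaks(ecg: np.ndarray, fs: float = EEG_FS) -> np.ndarray:
    """RR intervals (in samples) from a derivative-square-integrate detector.

    The classic energy chain: band-pass 5-20 Hz, differentiate, square,
    150-ms moving-window integrate, then peak-pick with an adaptive
    threshold and a 250-ms refractory period; each candidate is refined to
    the nearest maximum of the band-passed waveform. Returns an empty array
    when fewer than two R peaks are found (the caller marks the window's
    cardiac features missing).
    """
    x = np.asarray(ecg, dtype=float)
    if x.size < fs:  # need at least a second of signal
        return np.array([], dtype=int)
    x = x - x.mean()
    sos = sps.butter(3, [5.0, 20.0], btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, x)
    energy = np.convolve(np.diff(bp) ** 2, np.ones(int(0.15 * fs)) / (0.15 * fs), "same")
    if energy.max() <= 0:
        return np.array([], dtype=int)
    thresh = 0.25 * np.percentile(energy, 99)
    peaks, _ = sps.find_peaks(energy, height=thresh, distance=int(0.25 * fs))
    half = int(0.06 * fs)
    r_locs = []
    for p in peaks:
        lo, hi = max(0, p - half), min(len(bp), p + half + 1)
        r_locs.append(lo + int(np.argmax(bp[lo:hi])))
    r_locs = np.unique(r_locs)
    if len(r_locs) < 2:
        return np.array([], dtype=int)
    return np.diff(r_locs)


def heart_rate(rr_intervals: np.ndarray, fs: float = EEG_FS) -> float:
    """Heart rate in beats/min: 60 / (median RR interval in seconds)."""
    rr = np.asarray(rr_intervals, dtype=float)
    if rr.size == 0:
        raise ValueError("heart rate needs at least one RR interval")
    return 60.0 / (np.median(rr) / fs)


def hrv_hf(rr_intervals: np.ndarray, fs: float = EEG_FS) -> float:
    """High-frequency (0.15-0.4 Hz) HRV power in ms^2.

    The RR series is placed at its beat times, linearly resampled to a
    uniform 4 Hz tachogram, detrended, and its periodogram integrated over
    the HF band.
    """
    rr = np.asarray(rr_intervals, dtype=float)
    if rr.size < 4:
        raise ValueError("HF power needs at least 4 RR intervals")
    rr_ms = rr / fs * 1000.0
    beat_t = np.cumsum(rr_ms) / 1000.0  # seconds
    grid = np.arange(beat_t[0], beat_t[-1], 0.25)
    if grid.size < 8:
        raise ValueError("RR series spans too little time for the HF band")
    tach = np.interp(grid, beat_t, rr_ms)
    tach = sps.detrend(tach, type="linear")
    f, psd = sps.periodogram(tach, fs=4.0)
    sel = (f >= 0.15) & (f <= 0.4)
    return float(trapezoid(psd[sel], f[sel]))


# --------------------------------------------------------------------------
# table assembly

MODALITIES = ("hybrid", "eeg", "ecg", "nirs")
_BANDS_ORDER = ("theta", "alpha", "beta", "gamma")


def feature_columns(modality: str = "hybrid") -> list[str]:
    """Ordered feature-column names for a modality (59/34/7/18 columns)."""
    eeg = []
    for ch in ("fz", "pz"):
        eeg += [f"eeg_{p}_{ch}" for p in ("activity", "mobility", "complexity")]
        eeg.append(f"eeg_kolmogorov_{ch}")
        eeg += [f"eeg_maxpsd_{b}_{ch}" for b in _BANDS_ORDER]
        eeg += [f"eeg_density_{b}_{ch}" for b in _BANDS_ORDER]
        eeg += [f"eeg_relative_{b}_{ch}" for b in _BANDS_ORDER]
        eeg.append(f"eeg_entropy_{ch}")
    ecg = [
        "ecg_activity",
        "ecg_mobility",
        "ecg_complexity",
        "ecg_kolmogorov",
        "ecg_hr",
        "ecg_hf",
        "ecg_entropy",
    ]
    nirs = [
        f"nirs_{p}_{c}_{site}"
        for site in ("fp1", "fp2")
        for c in ("oxy", "deoxy", "tot")
        for p in ("activity", "mobility", "complexity")
    ]
    table = dict(hybrid=eeg + ecg + nirs, eeg=eeg, ecg=ecg, nirs=nirs)
    if modality not in table:
        raise ValueError(f"unknown modality {modality!r}; pick one of {MODALITIES}")
    return table[modality]


def _nirs_preprocess(window: np.ndarray, fs: float) -> np.ndarray:
    """0.01-0.5 Hz band-pass detrend: isolates hemodynamics from drift/offset."""
    x = np.asarray(window, dtype=float)
    x = x - x.mean()
    sos = sps.butter(2, [0.01, 0.5], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def _ecg_waveform_preprocess(window: np.ndarray, fs: float) -> np.ndarray:
    x = np.asarray(window, dtype=float)
    x = x - x.mean()
    sos = sps.butter(3, [0.5, 40.0], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def _eeg_features(x: np.ndarray, ch: str) -> dict[str, float]:
    filt = eeg_preprocess(x)
    hj = hjorth(filt)
    bp = wavelet_band_powers(filt)
    out = {
        f"eeg_activity_{ch}": hj.activity,
        f"eeg_mobility_{ch}": hj.mobility,
        f"eeg_complexity_{ch}": hj.complexity,
        f"eeg_kolmogorov_{ch}": kolmogorov_complexity(filt),
        f"eeg_entropy_{ch}": spectral_entropy(filt),
    }
    for b in _BANDS_ORDER:
        out[f"eeg_maxpsd_{b}_{ch}"] = bp.max_psd[b]
        out[f"eeg_density_{b}_{ch}"] = bp.density_integral[b]
        out[f"eeg_relative_{b}_{ch}"] = bp.relative[b]
    return out


def _ecg_features(x: np.ndarray, fs: float) -> dict[str, float] | None:
    rr = detect_r_peaks(x, fs)
    if rr.size == 0:
        return None
    wav = _ecg_waveform_preprocess(x, fs)
    hj = hjorth(wav)
    out = {
        "ecg_activity": hj.activity,
        "ecg_mobility": hj.mobility,
        "ecg_complexity": hj.complexity,
        "ecg_kolmogorov": kolmogorov_complexity(wav),
        "ecg_hr": heart_rate(rr, fs),
        "ecg_entropy": spectral_entropy(wav, fs),
    }
    try:
        out["ecg_hf"] = hrv_hf(rr, fs)
    except ValueError:
        return None
    return out


def _nirs_features(session: SessionRecording, w) -> dict[str, float]:
    out = {}
    fs = session.streams["nirs_oxy_fp1"].fs
    for site in ("fp1", "fp2"):
        for c in ("oxy", "deoxy", "tot"):
            x = session.slice(f"nirs_{c}_{site}", w.start_s, w.end_s)
            hj = hjorth(_nirs_preprocess(x, fs))
            out[f"nirs_activity_{c}_{site}"] = hj.activity
            out[f"nirs_mobility_{c}_{site}"] = hj.mobility
            out[f"nirs_complexity_{c}_{site}"] = hj.complexity
    return out


_REQUIRED_STREAMS = dict(
    eeg=("eeg_fz", "eeg_pz"),
    ecg=("ecg",),
    nirs=tuple(
        f"nirs_{c}_{s}" for s in ("fp1", "fp2") for c in ("oxy", "deoxy", "tot")
    ),
)


def extract_features(
    session: SessionRecording,
    labels: pd.DataFrame,
    modality: str = "hybrid",
) -> pd.DataFrame:
    """Feature table for every labeled (non-unlabeled) encoding window.

    Columns: the modality's feature set (see :func:`feature_columns`), then
    ``label``, ``participant_id`` and a unit ``instance_weight``. Windows
    whose ECG yields fewer than two R peaks are dropped with a warning.
    """
    cols = feature_columns(modality)
    wanted = ("eeg", "ecg", "nirs") if modality == "hybrid" else (modality,)
    for m in wanted:
        for st in _REQUIRED_STREAMS[m]:
            if st not in session.streams:
                raise MissingStreamError(
                    f"modality {modality!r} needs stream {st!r}, absent from session"
                )
    windows = session.encoding_windows
    fs = session.streams["ecg"].fs if "ecg" in session.streams else EEG_FS
    rows = []
    dropped = 0
    for _, lab in labels.iterrows():
        if lab["label"] not in ("high", "low"):
            continue
        w = windows[int(lab["window_id"])]
        feats: dict[str, float] = {}
        if "eeg" in wanted:
            for ch in ("fz", "pz"):
                feats.update(_eeg_features(session.slice(f"eeg_{ch}", w.start_s, w.end_s), ch))
        if "ecg" in wanted:
            cardiac = _ecg_features(session.slice("ecg", w.start_s, w.end_s), fs)
            if cardiac is None:
                dropped += 1
                continue
            feats.update(cardiac)
        if "nirs" in wanted:
            feats.update(_nirs_features(session, w))
        feats["label"] = lab["label"]
        feats["participant_id"] = session.participant_id
        feats["instance_weight"] = 1.0
        feats["window_id"] = int(lab["window_id"])
        rows.append(feats)
    if dropped:
        warnings.warn(
            f"{session.participant_id}: dropped {dropped} windows with <2 R peaks",
            stacklevel=2,
        )
    frame = pd.DataFrame(rows)
    if len(frame) == 0:
        return pd.DataFrame(columns=cols + ["label", "participant_id", "instance_weight", "window_id"])
    return frame[cols + ["label", "participant_id", "instance_weight", "window_id"]]
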