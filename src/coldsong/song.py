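"""Courtship pulse-song processing.

Turns a mono recording plus its metadata into per-song metrics: band-pass
filtering (100-1000 Hz, zero phase), envelope-threshold pulse detection,
burst segmentation, interpulse intervals (IPIs, ms) from bursts of at least
three pulses, a linear temperature correction of mean IPI to 25 degC, and the
song and courtship indices. Songs with fewer than 15 IPIs are flagged as not
retained for mean-IPI analyses.

Pulse detection replaces the study's manual oscillogram scoring with an
automatic detector (Hilbert envelope, robust MAD threshold, refractory
window); it is validated against synthetic ground truth only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from coldsong.synthetic import AudioRecording, PulseTrain

#: Printed default slope (ms/degC) of mean IPI on recording temperature; users
#: can re-derive it from their own songs with estimate_ipi_temperature_slope.
DEFAULT_IPI_TEMP_SLOPE = -1.0437
REFERENCE_TEMP_C = 25.0
MIN_IPI_RETENTION = 15
DEFAULT_BURST_GAP_MS = 100.0
DEFAULT_REFRACTORY_MS = 15.0


@dataclass(frozen=True)
class IPISeries:
    """Ordered interpulse intervals (ms) for one song."""

    ipis_ms: np.ndarray
    recording_temp_c: float
    song_id: str = ""

    def __post_init__(self) -> None:
        ipis = np.asarray(self.ipis_ms, dtype=float)
        object.__setattr__(self, "ipis_ms", ipis)
        if (ipis <= 0).any():
            raise ValueError("all IPIs must be positive")
        if not np.isfinite(self.recording_temp_c):
            raise ValueError("recording temperature must be finite")

    @property
    def n_ipi(self) -> int:
        return int(self.ipis_ms.size)

    @property
    def mean_ipi(self) -> float:
        return float(self.ipis_ms.mean()) if self.n_ipi else float("nan")


@dataclass(frozen=True)
class SongMetrics:
    song_id: str
    n_ipi: int
    mean_ipi_raw: float
    mean_ipi_corrected: float
    song_index: float
    courtship_index: float
    courtship_duration_s: float
    mated: bool
    recording_temp_c: float = float("nan")
    line: str = ""
    male_trt: str = ""
    extra: dict = field(default_factory=dict, compare=False)

    @property
    def retained(self) -> bool:
        return self.n_ipi >= MIN_IPI_RETENTION


def bandpass(audio: AudioRecording, low: float = 100.0,
             high: float = 1000.0, order: int = 4) -> AudioRecording:
    """Zero-phase Butterworth band-pass (forward-backward, so no group delay)."""
    nyquist = audio.sample_rate / 2
    if not 0 < low < high < nyquist:
        raise ValueError(f"invalid band [{low}, {high}] Hz for "
                         f"sample rate {audio.sample_rate} Hz")
    sos = signal.butter(order, [low, high], btype="bandpass",
                        fs=audio.sample_rate, output="sos")
    return AudioRecording(signal.sosfiltfilt(sos, audio.samples),
                          audio.sample_rate)


def detect_pulses(audio: AudioRecording, threshold_k: float = 8.0,
                  refractory_ms: float = DEFAULT_REFRACTORY_MS,
                  smooth_ms: float = 0.5) -> PulseTrain:
    """Envelope-threshold pulse detection with a refractory window.

    The Hilbert envelope is lightly smoothed; local maxima exceeding
    ``median + threshold_k x (1.4826 MAD)`` of the envelope (a robust noise
    scale) and separated by at least ``refractory_ms`` are pulse peaks. Two
    true pulses closer than the refractory window merge into one detection —
    a documented limitation.
    """
    x = np.asarray(audio.samples, dtype=float)
    if x.size == 0:
        return PulseTrain(np.empty(0))
    envelope = np.abs(signal.hilbert(x))
    sigma = smooth_ms / 1000.0 * audio.sample_rate
    if sigma > 0:
        from scipy.ndimage import gaussian_filter1d
        envelope = gaussian_filter1d(envelope, sigma)
    med = np.median(envelope)
    mad = np.median(np.abs(envelope - med)) * 1.4826
    threshold = med + threshold_k * mad
    distance = max(1, int(round(refractory_ms / 1000.0 * audio.sample_rate)))
    peaks, _ = signal.find_peaks(envelope, height=threshold, distance=distance)
    return PulseTrain(peaks / audio.sample_rate)


def segment_bursts(train: PulseTrain,
                   max_gap_ms: float = DEFAULT_BURST_GAP_MS) -> list[np.ndarray]:
    """Maximal runs of pulses whose consecutive gaps are <= ``max_gap_ms``."""
    times = train.pulse_times
    if times.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(times) > max_gap_ms / 1000.0) + 1
    return [np.asarray(b) for b in np.split(times, breaks)]


def extract_ipis(bursts: list[np.ndarray], recording_temp: float,
                 song_id: str = "") -> IPISeries:
    """IPIs (ms) from bursts of >= 3 pulses; 1-2 pulse bursts contribute none."""
    chunks = [np.diff(b) * 1000.0 for b in bursts if len(b) >= 3]
    ipis = np.concatenate(chunks) if chunks else np.empty(0)
    return IPISeries(ipis, recording_temp, song_id)


def recording_temperature(start_c: float, end_c: float) -> float:
    """Recording temperature = mean of start and end ambient temperature."""
    if not (np.isfinite(start_c) and np.isfinite(end_c)):
        raise ValueError("temperatures must be finite")
    return (start_c + end_c) / 2.0


@dataclass(frozen=True)
class TemperatureSlopeFit:
    slope: float
    intercept: float
    stderr: float
    ci_low: float
    ci_high: float
    n_songs: int


def estimate_ipi_temperature_slope(songs: list[IPISeries],
                                   ci_level: float = 0.95) -> TemperatureSlopeFit:
    """OLS slope of per-song mean raw IPI on recording temperature (ms/degC)."""
    songs = [s for s in songs if s.n_ipi > 0]
    if len(songs) < 3:
        raise ValueError("need >= 3 songs with IPIs")
    temps = np.array([s.recording_temp_c for s in songs])
    means = np.array([s.mean_ipi for s in songs])
    if np.ptp(temps) == 0:
        raise ValueError("recording temperatures are constant")
    fit = stats.linregress(temps, means)
    tcrit = stats.t.ppf(0.5 + ci_level / 2, len(songs) - 2)
    return TemperatureSlopeFit(
        slope=float(fit.slope), intercept=float(fit.intercept),
        stderr=float(fit.stderr),
        ci_low=float(fit.slope - tcrit * fit.stderr),
        ci_high=float(fit.slope + tcrit * fit.stderr),
        n_songs=len(songs))


def correct_ipi(measured_ipi_ms: float, recording_temp_c: float,
                slope: float = DEFAULT_IPI_TEMP_SLOPE,
                reference_c: float = REFERENCE_TEMP_C) -> float:
    """Linear temperature correction of an IPI to the reference temperature.

    ``corrected = slope * (reference - recording_temp) + measured``; the
    identity at the reference temperature.
    """
    return slope * (reference_c - recording_temp_c) + measured_ipi_ms


def song_index(ipis: IPISeries, courtship_duration_s: float) -> float:
    """Total singing time (sum of IPIs, s) / courtship duration."""
    if courtship_duration_s <= 0:
        raise ValueError("courtship duration must be positive")
    total_s = float(ipis.ipis_ms.sum()) / 1000.0
    index = total_s / courtship_duration_s
    if index > 1:
        raise ValueError(
            f"singing time {total_s:.3f} s exceeds courtship duration "
            f"{courtship_duration_s:.3f} s — inconsistent annotation")
    return index


def merge_intervals(intervals: list[tuple[float, float]]
                    ) -> list[tuple[float, float]]:
    """Union of possibly overlapping [start, end] intervals."""
    merged: list[list[float]] = []
    for a, b in sorted((float(a), float(b)) for a, b in intervals):
        if b < a:
            raise ValueError(f"interval end {b} precedes start {a}")
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def courtship_index(courting_intervals: list[tuple[float, float]],
                    courtship_duration_s: float) -> float:
    """Fraction of courtship duration spent actively courting.

    Overlapping intervals are merged before summing.
    """
    if courtship_duration_s <= 0:
        raise ValueError("courtship duration must be positive")
    total = sum(b - a for a, b in merge_intervals(courting_intervals))
    index = total / courtship_duration_s
    if index > 1 + 1e-9:
        raise ValueError("courting time exceeds courtship duration")
    return min(index, 1.0)


def retain_songs(metrics: list[SongMetrics],
                 min_ipi: int = MIN_IPI_RETENTION) -> list[SongMetrics]:
    """Songs eligible for mean-IPI analyses: at least ``min_ipi`` IPIs."""
    return [m for m in metrics if m.n_ipi >= min_ipi]


def compute_song_metrics(audio: AudioRecording, *, song_id: str,
                         start_temp_c: float, end_temp_c: float,
                         courtship_start_s: float, courtship_end_s: float,
                         courting_intervals: list[tuple[float, float]],
                         mated: bool, line: str = "", male_trt: str = "",
                         slope: float = DEFAULT_IPI_TEMP_SLOPE,
                         burst_gap_ms: float = DEFAULT_BURST_GAP_MS,
                         threshold_k: float = 8.0,
                         refractory_ms: float = DEFAULT_REFRACTORY_MS,
                         ) -> SongMetrics:
    """Full per-song pipeline: filter, detect, segment, measure, correct."""
    filtered = bandpass(audio)
    train = detect_pulses(filtered, threshold_k=threshold_k,
                          refractory_ms=refractory_ms)
    bursts = segment_bursts(train, max_gap_ms=burst_gap_ms)
    temp = recording_temperature(start_temp_c, end_temp_c)
    ipis = extract_ipis(bursts, temp, song_id)
    duration = courtship_end_s - courtship_start_s
    mean_raw = ipis.mean_ipi
    mean_corr = correct_ipi(mean_raw, temp, slope=slope) if ipis.n_ipi \
        else float("nan")
    return SongMetrics(
        song_id=song_id, n_ipi=ipis.n_ipi, mean_ipi_raw=mean_raw,
        mean_ipi_corrected=mean_corr,
        song_index=song_index(ipis, duration),
        courtship_index=courtship_index(courting_intervals, duration),
        courtship_duration_s=duration, mated=bool(mated),
        recording_temp_c=temp, line=line, male_trt=male_trt,
        extra={"ipis": ipis})
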