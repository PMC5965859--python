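"""Synthetic data emulating the DGRP cold-hardening study design.

Three generators with known ground truth exercise every downstream stage:

* :func:`gen_survival_table` — vial-level cold-shock survival counts for
  19 lines x 2 sexes x {basal, acclimated} x replicate vials of 10 flies;
* :func:`gen_courtship_table` — per-pair courtship latency/duration/mating
  outcomes for the 4 male x female acclimation pairings;
* :func:`gen_pulse_train` / :func:`synthesize_audio` — pulse-song audio whose
  interpulse intervals (IPIs) follow a linear temperature dependence around a
  35 ms baseline, rendered as Gaussian-enveloped sinusoid pulses in noise.

All randomness flows through one ``numpy.random.Generator`` seeded per call;
fixed seed gives bit-identical output. Latency and duration are log-normal
(right-skewed, positive), matching the reported non-normality of the
behavioral data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.io import wavfile

SEXES = ("female", "male")
TREATMENTS = ("basal", "acclimated")
MALE_TRTS = ("control", "acclimated")
FEMALE_TRTS = ("control", "acclimated")

DEFAULT_LINES = tuple(f"DGRP_{i:03d}" for i in range(1, 20))


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value}")


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

@dataclass
class SurvivalSimParams:
    """Parameters of the vial-level survival simulation.

    ``basal_survival_by_line`` gives each line's survival probability after
    the severe cold shock alone; ``rch_effect_by_line`` is the additive shift
    under prior acclimation (the line's true RCH capacity, may be negative);
    ``sex_effect`` is an additive shift applied to females. Realized
    probabilities are clipped to [0, 1].
    """

    lines: tuple[str, ...] = DEFAULT_LINES
    basal_survival_by_line: dict[str, float] | float = 0.5
    rch_effect_by_line: dict[str, float] | float = 0.25
    sex_effect: float = 0.0
    n_replicates: int = 4
    flies_per_vial: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.flies_per_vial < 1:
            raise ValueError("flies_per_vial must be >= 1")
        for line in self.lines:
            _check_prob(f"basal_survival_by_line[{line}]", self.basal(line))

    def basal(self, line: str) -> float:
        if isinstance(self.basal_survival_by_line, dict):
            return self.basal_survival_by_line[line]
        return float(self.basal_survival_by_line)

    def rch(self, line: str) -> float:
        if isinstance(self.rch_effect_by_line, dict):
            return self.rch_effect_by_line[line]
        return float(self.rch_effect_by_line)

    def realized_probability(self, line: str, sex: str, treatment: str) -> float:
        p = self.basal(line)
        if treatment == "acclimated":
            p += self.rch(line)
        if sex == "female":
            p += self.sex_effect
        return float(np.clip(p, 0.0, 1.0))


def gen_survival_table(params: SurvivalSimParams) -> pd.DataFrame:
    """One row per line x sex x treatment x replicate vial.

    ``n_survived ~ Binomial(flies_per_vial, realized probability)``.
    """
    rng = np.random.default_rng(params.seed)
    rows = []
    for line in params.lines:
        for sex in SEXES:
            for treatment in TREATMENTS:
                p = params.realized_probability(line, sex, treatment)
                survived = rng.binomial(params.flies_per_vial, p,
                                        size=params.n_replicates)
                for rep, n_surv in enumerate(survived, start=1):
                    rows.append((line, sex, treatment, rep,
                                 params.flies_per_vial, int(n_surv)))
    return pd.DataFrame(rows, columns=["line", "sex", "treatment", "replicate",
                                       "n_tested", "n_survived"])


# ---------------------------------------------------------------------------
# courtship / mating
# ---------------------------------------------------------------------------

@dataclass
class CourtshipSimParams:
    """Parameters of the courtship-observation simulation.

    Latency and duration are log-normal: ``*_location`` is the median in
    seconds, ``*_scale`` the standard deviation on the log scale. Durations
    of pairs with an acclimated male are multiplied by
    ``male_acclimation_duration_effect``. Non-courting males (probability
    ``1 - courtship_prob``) receive latency = ``screen_length`` and a missing
    duration; duration is recorded only for pairs that mated (the four-hour
    screen convention). The mated flag is Bernoulli with a probability set by
    the male's treatment, independent of the sampled duration (an optional
    ``mating_prob_fn`` hook allows dependence).
    """

    lines: tuple[str, ...] = DEFAULT_LINES
    latency_location: float = 600.0
    latency_scale: float = 0.9
    duration_location: float = 900.0
    duration_scale: float = 0.6
    male_acclimation_duration_effect: float = 1.3
    mating_prob_control: float = 0.725
    mating_prob_acclimated_male: float = 0.513
    courtship_prob: float = 0.97
    screen_length: float = 14_400.0
    n_reps_per_cell: int = 6
    seed: int = 0
    mating_prob_fn: object | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        _check_prob("mating_prob_control", self.mating_prob_control)
        _check_prob("mating_prob_acclimated_male", self.mating_prob_acclimated_male)
        _check_prob("courtship_prob", self.courtship_prob)
        if self.screen_length <= 0:
            raise ValueError("screen_length must be > 0")
        if self.male_acclimation_duration_effect < 0:
            raise ValueError("male_acclimation_duration_effect must be >= 0")


def gen_courtship_table(params: CourtshipSimParams) -> pd.DataFrame:
    """One row per line x (male trt x female trt) x replicate pairing."""
    rng = np.random.default_rng(params.seed)
    lat_mu = math.log(params.latency_location)
    dur_mu = math.log(params.duration_location)
    rows = []
    for line in params.lines:
        for male_trt in MALE_TRTS:
            for female_trt in FEMALE_TRTS:
                for rep in range(1, params.n_reps_per_cell + 1):
                    courted = rng.random() < params.courtship_prob
                    latency = float(rng.lognormal(lat_mu, params.latency_scale))
                    duration = float(rng.lognormal(dur_mu, params.duration_scale))
                    if male_trt == "acclimated":
                        duration *= params.male_acclimation_duration_effect
                    if params.mating_prob_fn is not None:
                        p_mate = params.mating_prob_fn(male_trt, female_trt, duration)
                    elif male_trt == "acclimated":
                        p_mate = params.mating_prob_acclimated_male
                    else:
                        p_mate = params.mating_prob_control
                    mated = bool(rng.random() < p_mate)
                    if not courted or latency >= params.screen_length:
                        courted = False
                        latency = params.screen_length
                        duration = np.nan
                        mated = False
                    elif not mated:
                        duration = np.nan
                    rows.append((line, male_trt, female_trt, rep, courted,
                                 latency, duration, mated,
                                 params.screen_length))
    return pd.DataFrame(rows, columns=[
        "line", "male_trt", "female_trt", "replicate", "courted",
        "latency_s", "duration_s", "mated", "screen_length_s"])


# ---------------------------------------------------------------------------
# pulse song
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PulseTrain:
    """Strictly increasing pulse times in seconds."""

    pulse_times: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.pulse_times, dtype=float)
        object.__setattr__(self, "pulse_times", times)
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("pulse times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.pulse_times.size)


@dataclass(frozen=True)
class AudioRecording:
    """Mono audio samples with their sampling rate."""

    samples: np.ndarray
    sample_rate: float

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate


@dataclass
class SongSimParams:
    """Ground-truth parameters of the pulse-song generator.

    Within-burst IPIs are drawn around
    ``baseline_mean_ipi + ipi_temp_slope * (recording_temp - 25)`` with
    standard deviation ``ipi_within_song_sd``, truncated positive. Pulses are
    Gaussian-enveloped sinusoids at ``pulse_carrier_freq`` (band-limited well
    inside the 100-1000 Hz passband) with peak amplitude 1, so the default
    ``noise_sd`` keeps pulse peaks >= 5x the noise scale.
    """

    lines: tuple[str, ...] = DEFAULT_LINES[:5]
    baseline_mean_ipi: float = 35.0         # ms at 25 degC
    ipi_temp_slope: float = -1.04           # ms per degC
    ipi_within_song_sd: float = 3.0         # ms
    pulses_per_burst_range: tuple[int, int] = (3, 10)
    n_bursts_range: tuple[int, int] = (1, 10)
    inter_burst_gap: float = 300.0          # ms, minimum gap between bursts
    recording_temp_range: tuple[float, float] = (23.5, 26.5)
    pulse_carrier_freq: float = 250.0       # Hz
    pulse_envelope_width: float = 2.0       # ms (Gaussian sigma)
    noise_sd: float = 0.05                  # amplitude units (pulse peak = 1)
    sample_rate: float = 10_000.0           # Hz
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate < 2 * self.pulse_carrier_freq:
            raise ValueError("sample_rate must be >= 2x pulse_carrier_freq")
        lo, hi = self.recording_temp_range
        if not (0 < lo <= hi < 40):
            raise ValueError("recording_temp_range must lie within (0, 40) degC")

    def mean_ipi_at(self, temp_c: float) -> float:
        return self.baseline_mean_ipi + self.ipi_temp_slope * (temp_c - 25.0)


def gen_pulse_train(params: SongSimParams, recording_temp: float,
                    rng: np.random.Generator | None = None) -> PulseTrain:
    """Pulse times (s) arranged in bursts with known IPI distribution.

    Burst-to-burst gaps are ``inter_burst_gap`` plus an exponential excess,
    hence always >= ``inter_burst_gap``.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    mu = params.mean_ipi_at(recording_temp)
    n_bursts = int(rng.integers(params.n_bursts_range[0],
                                params.n_bursts_range[1] + 1))
    times_ms: list[float] = []
    t = 100.0  # lead-in before the first pulse, ms
    for _ in range(n_bursts):
        n_pulses = int(rng.integers(params.pulses_per_burst_range[0],
                                    params.pulses_per_burst_range[1] + 1))
        times_ms.append(t)
        for _ in range(n_pulses - 1):
            ipi = rng.normal(mu, params.ipi_within_song_sd)
            ipi = max(ipi, 0.1)  # truncate positive
            t += ipi
            times_ms.append(t)
        t += params.inter_burst_gap + rng.exponential(params.inter_burst_gap / 2)
    return PulseTrain(np.asarray(times_ms) / 1000.0)


def synthesize_audio(train: PulseTrain, params: SongSimParams,
                     rng: np.random.Generator | None = None,
                     duration: float | None = None) -> AudioRecording:
    """Render a pulse train as audio: enveloped oscillations plus noise."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    fs = params.sample_rate
    if duration is None:
        last = train.pulse_times[-1] if len(train) else 0.0
        duration = last + 0.2
    elif len(train) and train.pulse_times[-1] > duration:
        raise ValueError("pulse times extend beyond the requested duration")
    n = int(round(duration * fs))
    samples = rng.normal(0.0, params.noise_sd, size=n) if params.noise_sd > 0 \
        else np.zeros(n)
    sigma_s = params.pulse_envelope_width / 1000.0
    half_width = int(round(5 * sigma_s * fs))
    tt = np.arange(-half_width, half_width + 1) / fs
    for tc in train.pulse_times:
        center = int(round(tc * fs))
        kernel = np.exp(-((tt - (tc - center / fs)) ** 2) / (2 * sigma_s ** 2)) \
            * np.cos(2 * np.pi * params.pulse_carrier_freq * (tt - (tc - center / fs)))
        lo = center - half_width
        hi = center + half_width + 1
        klo = max(0, -lo)
        khi = len(kernel) - max(0, hi - n)
        samples[max(0, lo):min(n, hi)] += kernel[klo:khi]
    return AudioRecording(samples, fs)


# ---------------------------------------------------------------------------
# full song dataset
# ---------------------------------------------------------------------------

def gen_song_dataset(params: SongSimParams, n_songs: int = 148,
                     mating_prob_control: float = 0.725,
                     mating_prob_acclimated: float = 0.513,
                     ) -> tuple[pd.DataFrame, list[PulseTrain]]:
    """Metadata table plus ground-truth pulse trains for ``n_songs`` songs.

    Songs are spread evenly over ``params.lines`` x {control, acclimated}
    male treatments with per-recording temperatures drawn uniformly from
    ``recording_temp_range`` and a small start/end temperature difference.
    Courtship runs from 0.5 s to the end of the recording; courting intervals
    cover roughly 70% of it in two blocks.
    """
    rng = np.random.default_rng(params.seed)
    rows = []
    trains = []
    for i in range(n_songs):
        line = params.lines[i % len(params.lines)]
        male_trt = MALE_TRTS[(i // len(params.lines)) % 2]
        temp = rng.uniform(*params.recording_temp_range)
        delta = rng.normal(0.0, 0.065)  # start/end difference ~0.09 degC mean abs
        start_t, end_t = temp - delta / 2, temp + delta / 2
        train = gen_pulse_train(params, temp, rng)
        trains.append(train)
        rec_end = train.pulse_times[-1] + 0.5 if len(train) else 2.0
        c_start = 0.5
        c_dur = rec_end - c_start
        gap_mid = c_start + 0.55 * c_dur
        intervals = [(c_start, c_start + 0.40 * c_dur),
                     (gap_mid, gap_mid + 0.30 * c_dur)]
        p = mating_prob_acclimated if male_trt == "acclimated" else mating_prob_control
        rows.append({
            "song_id": f"song_{i:03d}",
            "line": line,
            "male_trt": male_trt,
            "start_temp": start_t,
            "end_temp": end_t,
            "courtship_start_s": c_start,
            "courtship_end_s": rec_end,
            "courting_intervals": ";".join(f"{a:.4f}-{b:.4f}" for a, b in intervals),
            "mated": bool(rng.random() < p),
        })
    return pd.DataFrame(rows), trains


def write_wav(path, audio: AudioRecording) -> None:
    """Write mono 16-bit PCM WAV, scaling to 90% full scale."""
    peak = np.max(np.abs(audio.samples)) or 1.0
    scaled = np.clip(audio.samples / peak * 0.9, -1, 1)
    wavfile.write(path, int(audio.sample_rate),
                  (scaled * 32767).astype(np.int16))


def read_wav(path) -> AudioRecording:
    """Read a mono PCM WAV as float samples in [-1, 1]."""
    fs, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono audio")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / np.iinfo(data.dtype).max
    return AudioRecording(np.asarray(data, dtype=float), float(fs))
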