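"""Seeded synthetic cohorts of 4-channel headband-style EEG.

The generator emulates the signal families the prediction pipeline
feeds on, with planted, recoverable age effects:

* a 1/f^beta background mixed across channels so spatial covariance is
  informative;
* an alpha oscillator (wake/meditation) whose peak frequency decreases
  and whose power drifts with age;
* sigma-band (12-15 Hz) activity in N2 epochs and delta (1-4 Hz) waves
  in N3 epochs, each with an age-dependent power trend (delta declines
  with age, as slow-wave power does);
* all-channel sample dropouts (lost wireless packets, NaN-encoded) and
  occasional high-amplitude artifact bursts exceeding the 250 uV
  rejection threshold.

Session-level and subject-level log-normal power fluctuations make the
age effects noisy at realistic levels, so cross-validated prediction
accuracy lands well below 1.  Everything is driven by one integer seed:
identical (config, seed) pairs give bit-identical cohorts.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .containers import (
    DEFAULT_CHANNELS,
    EPOCH_LENGTH,
    Hypnogram,
    Recording,
    SLEEP_STAGES,
)

# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort-level knobs of the synthetic generator.

    Age-trend slopes are relative changes per year of age (reference
    age 20); the alpha peak slope is in Hz per year and must be
    negative, as must the N3 delta power slope.
    """

    n_subjects: int = 300
    age_range: tuple[float, float] = (18.0, 81.0)
    sampling_rate: float = 256.0
    n_channels: int = 4
    modality: str = "meditation"
    duration: float | None = None  # seconds; None -> modality default
    alpha_peak_intercept: float = 10.5  # Hz at age 20
    alpha_peak_slope: float = -0.03  # Hz per year (< 0)
    alpha_power_slope: float = 0.008  # relative power per year
    delta_n3_slope: float = -0.012  # relative power per year (< 0)
    sigma_n2_slope: float = -0.010  # relative power per year
    noise_exponent: float = 1.0  # 1/f slope of the background
    dropout_rate: float = 0.002  # fraction of samples missing
    artifact_rate: float = 1.0  # expected artifact bursts per recording
    alpha_peak_sd: float = 0.7  # Hz; inter-individual peak spread (age-independent)
    session_noise_sd: float = 0.30  # log-normal sd of per-session power
    subject_noise_sd: float = 0.15  # log-normal sd of stable per-subject power
    n_sessions: int = 1  # > 1 -> longitudinal cohort
    session_span_days: int = 1
    seed: int = 0

    def __post_init__(self):
        low, high = self.age_range
        if low >= high:
            raise ValueError(f"invalid age_range {self.age_range}: low >= high")
        if low < 18.0 or high > 81.0:
            raise ValueError("age_range must lie within [18, 81]")
        if self.alpha_peak_slope >= 0:
            raise ValueError("alpha_peak_slope must be negative (peak slows with age)")
        if self.delta_n3_slope >= 0:
            raise ValueError("delta_n3_slope must be negative (slow waves fade with age)")
        if self.modality not in ("meditation", "sleep"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")

    @property
    def effective_duration(self) -> float:
        if self.duration is not None:
            return float(self.duration)
        # meditation: 9 min raw -> 8 min after the 60 s crop;
        # sleep: desk-scale 40 min "night" with the full stage repertoire
        return 540.0 if self.modality == "meditation" else 2400.0

    def replace(self, **kwargs) -> "GeneratorConfig":
        return replace(self, **kwargs)


#: default first-order Markov transition matrix over (W, N1, N2, N3, R)
#: at 30 s epoch resolution.  Started at W; N3 is typically reached
#: before R (deep sleep concentrates early, REM later).
DEFAULT_TRANSITIONS = np.array(
    [
        # W     N1    N2    N3    R
        [0.82, 0.15, 0.03, 0.00, 0.00],  # W
        [0.08, 0.48, 0.40, 0.00, 0.04],  # N1
        [0.02, 0.05, 0.76, 0.11, 0.06],  # N2
        [0.01, 0.00, 0.14, 0.85, 0.00],  # N3
        [0.02, 0.06, 0.07, 0.00, 0.85],  # R
    ]
)

#: fixed channel mixing of the four background sources (TP9, Fp1, Fp2, TP10)
_BACKGROUND_MIX = np.array(
    [
        [1.00, 0.35, 0.20, 0.30],
        [0.35, 1.00, 0.45, 0.20],
        [0.20, 0.45, 1.00, 0.35],
        [0.30, 0.20, 0.35, 1.00],
    ]
)

#: per-oscillator channel gains (temporal electrodes see more alpha/delta)
_ALPHA_GAINS = np.array([1.0, 0.45, 0.45, 0.95])
_SIGMA_GAINS = np.array([0.65, 1.0, 0.95, 0.6])
_DELTA_GAINS = np.array([0.85, 1.0, 1.0, 0.8])

#: baseline RMS amplitudes in microvolts (strongest channel)
_BACKGROUND_RMS = 14.0
_ALPHA_RMS = 6.0
_SIGMA_RMS = 3.5
_DELTA_RMS = 11.0
_REFERENCE_AGE = 20.0


def stationary_distribution(transitions: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector)."""
    vals, vecs = np.linalg.eig(transitions.T)
    idx = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# cohort metadata


def sample_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Sample subject metadata: id, age, sex, and dated sessions.

    Ages are uniform over ``config.age_range``.  With
    ``config.n_sessions > 1`` each subject receives that many distinct
    session dates spread over ``config.session_span_days`` days
    (longitudinal mode).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    low, high = config.age_range
    ages = rng.uniform(low, high, size=config.n_subjects)
    sexes = rng.choice(["F", "M"], size=config.n_subjects)
    base = _dt.date(2023, 1, 1)
    rows = []
    for i in range(config.n_subjects):
        if config.n_sessions == 1:
            offsets = [int(rng.integers(0, max(config.session_span_days, 1)))]
        else:
            # distinct day offsets spanning the configured period
            span = max(config.session_span_days, config.n_sessions)
            offsets = sorted(
                rng.choice(span, size=config.n_sessions, replace=False).tolist()
            )
        dates = [(base + _dt.timedelta(days=int(o))).isoformat() for o in offsets]
        rows.append(
            {
                "subject_id": f"sub-{i:04d}",
                "age": float(ages[i]),
                "sex": str(sexes[i]),
                "n_sessions": config.n_sessions,
                "session_dates": dates,
            }
        )
    return pd.DataFrame(rows)


def generate_hypnogram(
    duration: float,
    age: float = 40.0,
    seed: int | np.random.SeedSequence = 0,
    transitions: np.ndarray | None = None,
    start_stage: str = "W",
) -> Hypnogram:
    """Sample a hypnogram from a first-order Markov chain over the stages.

    One label per 30 s epoch; the default chain starts awake, reaches
    deep sleep (N3) before REM on average, and visits every stage with
    probability approaching one as the duration grows.  ``age`` is
    accepted for interface symmetry but does not alter the chain: stage
    architecture trends with age are outside the generator's scope.
    """
    del age  # spectral content, not stage architecture, carries the age signal
    if duration < EPOCH_LENGTH:
        raise ValueError(f"duration {duration} s is shorter than one {EPOCH_LENGTH} s epoch")
    p = DEFAULT_TRANSITIONS if transitions is None else np.asarray(transitions, float)
    if p.shape != (5, 5) or not np.allclose(p.sum(axis=1), 1.0):
        raise ValueError("transitions must be a 5x5 row-stochastic matrix")
    rng = np.random.default_rng(seed)
    n_epochs = int(duration // EPOCH_LENGTH)
    cum = np.cumsum(p, axis=1)
    draws = rng.random(n_epochs)
    state = SLEEP_STAGES.index(start_stage)
    labels = []
    for k in range(n_epochs):
        labels.append(SLEEP_STAGES[state])
        state = int(np.searchsorted(cum[state], draws[k]))
    return Hypnogram(labels=tuple(labels))


# ---------------------------------------------------------------------------
# signal synthesis


def _colored_noise(rng, n: int, sfreq: float, exponent: float, size: int) -> np.ndarray:
    """``size`` independent 1/f^exponent noise traces of unit variance."""
    freqs = np.fft.rfftfreq(n, 1.0 / sfreq)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = amp * (rng.standard_normal((size, freqs.size)) + 1j * rng.standard_normal((size, freqs.size)))
    x = np.fft.irfft(spec, n=n, axis=-1)
    x /= x.std(axis=-1, keepdims=True)
    return x


def _narrowband_noise(rng, n: int, sfreq: float, center: float, sigma: float) -> np.ndarray:
    """Unit-variance noise with a Gaussian spectral bump at ``center`` Hz."""
    freqs = np.fft.rfftfreq(n, 1.0 / sfreq)
    amp = np.exp(-0.5 * ((freqs - center) / sigma) ** 2)
    spec = amp * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    x = np.fft.irfft(spec, n=n)
    std = x.std()
    if std > 0:
        x /= std
    return x


def _power_factor(slope: float, age: float) -> float:
    return max(0.05, 1.0 + slope * (age - _REFERENCE_AGE))


def _stage_mask(hypnogram: Hypnogram, stage: str, n: int, sfreq: float) -> np.ndarray:
    per_epoch = int(EPOCH_LENGTH * sfreq)
    mask = np.zeros(n)
    for k, lab in enumerate(hypnogram.labels):
        if lab == stage:
            mask[k * per_epoch : (k + 1) * per_epoch] = 1.0
    return mask


def _artifact_burst(rng, sfreq: float) -> np.ndarray:
    """A ~0.5 s high-amplitude oscillatory burst (survives the band-pass)."""
    n = int(0.5 * sfreq)
    t = np.arange(n) / sfreq
    freq = rng.uniform(3.0, 8.0)
    envelope = np.hanning(n)
    amp = rng.uniform(500.0, 1200.0)
    return amp * envelope * np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))


def synthesize_recording(
    subject: dict | pd.Series,
    hypnogram: Hypnogram | None,
    config: GeneratorConfig,
    seed: int | np.random.SeedSequence = 0,
    session_id: str = "ses-000",
    date: str | None = None,
) -> Recording:
    """Generate one recording for a subject under the configured effects.

    Meditation recordings must come without a hypnogram (alpha runs
    throughout); sleep recordings require one (stage-gated oscillators).
    """
    if config.modality == "sleep" and hypnogram is None:
        raise ValueError("sleep synthesis requires a hypnogram")
    if config.modality == "meditation" and hypnogram is not None:
        raise ValueError("meditation synthesis takes no hypnogram")

    age = float(subject["age"])
    subject_id = str(subject.get("subject_id", "sub-000"))
    subject_index = int(subject_id.split("-")[-1]) if "-" in subject_id else 0

    sfreq = config.sampling_rate
    n = int(round(config.effective_duration * sfreq))
    rng = np.random.default_rng(seed)
    # stable per-subject power fluctuation (trait), independent of session
    subj_rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 77_000 + subject_index])
    )
    trait = np.exp(subj_rng.normal(0.0, config.subject_noise_sd, size=4))
    state = np.exp(rng.normal(0.0, config.session_noise_sd, size=4))
    # stable per-subject alpha-peak offset: individual peak frequency varies
    # widely at any age, which is what limits age decoding in practice
    peak_offset = subj_rng.normal(0.0, config.alpha_peak_sd)

    # --- background: mixed 1/f sources
    sources = _colored_noise(rng, n, sfreq, config.noise_exponent, config.n_channels)
    mix = _BACKGROUND_MIX[: config.n_channels, : config.n_channels]
    signal = _BACKGROUND_RMS * trait[3] * state[3] * (mix @ sources)
    signal /= np.linalg.norm(mix, axis=1, keepdims=True)  # keep channel RMS ~ baseline

    # --- alpha oscillator (wake / meditation)
    peak = (
        config.alpha_peak_intercept
        + config.alpha_peak_slope * (age - _REFERENCE_AGE)
        + peak_offset
        + rng.normal(0.0, 0.15)  # small session-to-session drift
    )
    peak = float(np.clip(peak, 7.0, 14.0))
    alpha_amp = (
        _ALPHA_RMS
        * np.sqrt(_power_factor(config.alpha_power_slope, age))
        * trait[0]
        * state[0]
    )
    alpha = _narrowband_noise(rng, n, sfreq, peak, 0.5)
    if config.modality == "meditation":
        alpha_gate = 1.0
    else:
        alpha_gate = _stage_mask(hypnogram, "W", n, sfreq)
    signal += alpha_amp * _ALPHA_GAINS[: config.n_channels, None] * (alpha * alpha_gate)

    if config.modality == "sleep":
        sigma_amp = (
            _SIGMA_RMS
            * np.sqrt(_power_factor(config.sigma_n2_slope, age))
            * trait[1]
            * state[1]
        )
        sigma = _narrowband_noise(rng, n, sfreq, 13.5, 0.8)
        signal += (
            sigma_amp
            * _SIGMA_GAINS[: config.n_channels, None]
            * (sigma * _stage_mask(hypnogram, "N2", n, sfreq))
        )
        delta_amp = (
            _DELTA_RMS
            * np.sqrt(_power_factor(config.delta_n3_slope, age))
            * trait[2]
            * state[2]
        )
        delta = _narrowband_noise(rng, n, sfreq, 2.0, 0.9)
        signal += (
            delta_amp
            * _DELTA_GAINS[: config.n_channels, None]
            * (delta * _stage_mask(hypnogram, "N3", n, sfreq))
        )

    # --- artifact bursts (> 250 uV peak-to-peak, rejected downstream)
    n_artifacts = rng.poisson(config.artifact_rate)
    for _ in range(n_artifacts):
        burst = _artifact_burst(rng, sfreq)
        start = int(rng.integers(0, max(n - burst.size, 1)))
        channel = int(rng.integers(0, config.n_channels))
        signal[channel, start : start + burst.size] += burst[: n - start]

    # --- dropouts: all-channel NaN runs (lost packets)
    if config.dropout_rate > 0:
        target = config.dropout_rate * n
        dropped = 0
        while dropped < target:
            run = int(rng.geometric(1.0 / 26.0))  # mean ~0.1 s at 256 Hz
            start = int(rng.integers(0, n))
            signal[:, start : start + run] = np.nan
            dropped += run

    return Recording(
        signal=signal,
        sfreq=sfreq,
        channel_names=list(DEFAULT_CHANNELS[: config.n_channels]),
        modality=config.modality,
        subject_id=subject_id,
        session_id=session_id,
        age=age,
        date=date,
        hypnogram=hypnogram,
    )


def generate_cohort(config: GeneratorConfig):
    """Yield (metadata row, Recording) for every session of a cohort.

    Per-session seeds are spawned deterministically from
    ``config.seed``, the subject index, and the session index.
    """
    cohort = sample_cohort(config)
    for i, row in cohort.iterrows():
        for s, date in enumerate(row["session_dates"]):
            seed = np.random.SeedSequence([config.seed, int(i), int(s)])
            hyp = None
            if config.modality == "sleep":
                hyp_seed = np.random.SeedSequence([config.seed, int(i), int(s), 5])
                hyp = generate_hypnogram(config.effective_duration, row["age"], hyp_seed)
            rec = synthesize_recording(
                row, hyp, config, seed=seed, session_id=f"ses-{s:03d}", date=date
            )
            yield row, rec
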