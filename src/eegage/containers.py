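"""Core data containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

#: canonical sleep-stage alphabet, in the fixed order used everywhere
SLEEP_STAGES: tuple[str, ...] = ("W", "N1", "N2", "N3", "R")

#: default channel montage of the 4-channel headband (referenced to Fpz)
DEFAULT_CHANNELS: tuple[str, ...] = ("TP9", "Fp1", "Fp2", "TP10")

#: hypnogram epoch length in seconds (sleep-staging convention)
EPOCH_LENGTH: float = 30.0


@dataclass(frozen=True)
class Hypnogram:
    """Sleep-stage labels, one per 30 s epoch."""

    labels: tuple[str, ...]
    epoch_length: float = EPOCH_LENGTH

    def __post_init__(self):
        bad = set(self.labels) - set(SLEEP_STAGES)
        if bad:
            raise ValueError(f"unknown sleep stages {sorted(bad)}; allowed: {SLEEP_STAGES}")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def duration(self) -> float:
        return len(self.labels) * self.epoch_length

    def stage_fractions(self) -> dict[str, float]:
        n = len(self.labels)
        return {s: self.labels.count(s) / n for s in SLEEP_STAGES}


@dataclass
class Recording:
    """One subject-session of multichannel EEG with metadata.

    ``signal`` is channels x time in microvolts; missing samples are
    encoded as NaN until :func:`eegage.preprocess.interpolate_missing`
    runs.
    """

    signal: np.ndarray
    sfreq: float
    channel_names: Sequence[str]
    modality: str  # "meditation" | "sleep"
    subject_id: str = "sub-000"
    session_id: str = "ses-000"
    age: float = float("nan")
    date: Optional[str] = None  # ISO-8601
    hypnogram: Optional[Hypnogram] = None

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be channels x time")
        if self.signal.shape[1] == 0:
            raise ValueError("signal has zero time points")
        if self.modality not in ("meditation", "sleep"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if len(self.channel_names) != self.signal.shape[0]:
            raise ValueError("channel_names length does not match signal rows")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sfreq

    def copy_with(self, **kwargs) -> "Recording":
        return replace(self, **kwargs)


@dataclass
class WindowSet:
    """Non-overlapping fixed-length windows cut from one recording.

    ``windows`` is n_windows x channels x samples.  ``retained`` flags
    windows that survived artifact rejection; ``stages`` holds one sleep
    stage per window for sleep data (None for meditation).
    """

    windows: np.ndarray
    sfreq: float
    window_length: float
    retained: np.ndarray = field(default=None)  # type: ignore[assignment]
    stages: Optional[np.ndarray] = None
    channel_names: Sequence[str] = DEFAULT_CHANNELS
    modality: str = "meditation"

    def __post_init__(self):
        self.windows = np.asarray(self.windows, dtype=float)
        if self.windows.ndim != 3:
            raise ValueError("windows must be n_windows x channels x samples")
        if self.retained is None:
            self.retained = np.ones(self.windows.shape[0], dtype=bool)
        else:
            self.retained = np.asarray(self.retained, dtype=bool)
        if self.stages is not None:
            self.stages = np.asarray(self.stages, dtype=object)

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())

    def copy_with(self, **kwargs) -> "WindowSet":
        out = WindowSet(
            windows=kwargs.get("windows", self.windows),
            sfreq=kwargs.get("sfreq", self.sfreq),
            window_length=kwargs.get("window_length", self.window_length),
            retained=kwargs.get("retained", self.retained.copy()),
            stages=kwargs.get("stages", None if self.stages is None else self.stages.copy()),
            channel_names=kwargs.get("channel_names", list(self.channel_names)),
            modality=kwargs.get("modality", self.modality),
        )
        return out
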