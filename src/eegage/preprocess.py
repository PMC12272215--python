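"""Preprocessing chain from raw recording to retained, downsampled windows.

The stage order is fixed:

    crop -> interpolate -> band-pass -> notch bank -> window -> reject -> resample

Meditation recordings lose their first minute (signal quality settles)
and keep at most the next eight minutes; sleep recordings are kept in
their entirety.  Missing samples (lost wireless packets, encoded as
NaN) are linearly interpolated from surrounding valid samples.  A
zero-phase FIR band-pass (0.1-49 Hz) and a bank of FIR notches at
hardware-specific peaks (16, 21.3, 32, 42.7 Hz) plus line frequencies
(50, 60 Hz) precede windowing.  Windows whose peak-to-peak amplitude
exceeds 250 uV on any channel are flagged as rejected, and the retained
windows are downsampled to 128 Hz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sp_signal

from .containers import Recording, WindowSet
from .filters import apply_fir, design_bandpass, design_notch_bank

#: hardware-specific spectral peaks and power-line frequencies (Hz)
NOTCH_FREQS: tuple[float, ...] = (16.0, 21.3, 32.0, 42.7, 50.0, 60.0)

CROP_SECONDS = 60.0
KEEP_SECONDS = 480.0
BANDPASS = (0.1, 49.0)
PTP_THRESHOLD_UV = 250.0
RESAMPLE_HZ = 128.0
WINDOW_SECONDS = {"meditation": 10.0, "sleep": 30.0}


class TooShortError(ValueError):
    """Recording too short for the requested operation."""


def crop_meditation(rec: Recording) -> Recording:
    """Drop the first minute and keep at most the next eight minutes."""
    if rec.modality != "meditation":
        raise ValueError("crop_meditation applies to meditation recordings only")
    if rec.duration <= CROP_SECONDS:
        raise TooShortError(
            f"recording {rec.session_id} lasts {rec.duration:.1f} s; "
            f"need > {CROP_SECONDS:.0f} s"
        )
    start = int(round(CROP_SECONDS * rec.sfreq))
    stop = start + int(round(KEEP_SECONDS * rec.sfreq))
    return rec.copy_with(signal=rec.signal[:, start:stop].copy())


def interpolate_missing(rec: Recording) -> Recording:
    """Replace NaN samples by linear interpolation from valid neighbours.

    Interior gaps are linearly interpolated; leading/trailing gaps are
    filled with the nearest valid sample (no extrapolation).
    """
    sig = rec.signal
    if not np.isnan(sig).any():
        return rec.copy_with(signal=sig.copy())
    out = np.empty_like(sig)
    t = np.arange(sig.shape[1])
    for c in range(sig.shape[0]):
        valid = ~np.isnan(sig[c])
        if not valid.any():
            raise ValueError(
                f"channel {rec.channel_names[c]} of {rec.session_id} is fully missing"
            )
        out[c] = np.interp(t, t[valid], sig[c, valid])
    return rec.copy_with(signal=out)


def bandpass_filter(
    rec: Recording, low: float = BANDPASS[0], high: float = BANDPASS[1]
) -> Recording:
    """Zero-phase FIR band-pass between ``low`` and ``high`` Hz."""
    kernel = design_bandpass(low, high, rec.sfreq)
    return rec.copy_with(signal=apply_fir(rec.signal, kernel))


def notch_filter(rec: Recording, freqs: tuple[float, ...] = NOTCH_FREQS) -> Recording:
    """Zero-phase FIR notch bank (1 Hz stop bands centred on ``freqs``)."""
    kernel = design_notch_bank(list(freqs), rec.sfreq)
    return rec.copy_with(signal=apply_fir(rec.signal, kernel))


def make_windows(rec: Recording, length: float | None = None) -> WindowSet:
    """Cut non-overlapping windows; label sleep windows from the hypnogram.

    Sleep uses 30 s windows that align one-to-one with hypnogram epochs;
    meditation uses 10 s windows.  The trailing remainder is dropped.
    """
    if length is None:
        length = WINDOW_SECONDS[rec.modality]
    n_per = int(round(length * rec.sfreq))
    n_win = rec.n_samples // n_per
    if n_win == 0:
        raise TooShortError(
            f"recording lasts {rec.duration:.1f} s; need >= {length:.0f} s"
        )
    stages = None
    if rec.modality == "sleep":
        if rec.hypnogram is None:
            raise ValueError("sleep recording requires a hypnogram to label windows")
        # 30 s windows align 1:1 with 30 s epochs; never cross an epoch boundary
        labels = rec.hypnogram.labels
        n_win = min(n_win, len(labels))
        stages = np.array(labels[:n_win], dtype=object)
    windows = rec.signal[:, : n_win * n_per].reshape(rec.n_channels, n_win, n_per)
    windows = np.ascontiguousarray(windows.transpose(1, 0, 2))
    return WindowSet(
        windows=windows,
        sfreq=rec.sfreq,
        window_length=length,
        stages=stages,
        channel_names=list(rec.channel_names),
        modality=rec.modality,
    )


def reject_ptp(ws: WindowSet, threshold: float = PTP_THRESHOLD_UV) -> WindowSet:
    """Flag windows whose peak-to-peak amplitude exceeds ``threshold`` uV.

    A window is retained iff max-minus-min on *every* channel is at or
    below the threshold.  Windows are preserved; only flags change, so
    the operation is idempotent.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    ptp = ws.windows.max(axis=-1) - ws.windows.min(axis=-1)  # n_windows x channels
    retained = (ptp <= threshold).all(axis=1)
    return ws.copy_with(retained=retained)


def resample(ws: WindowSet, rate: float = RESAMPLE_HZ) -> WindowSet:
    """Polyphase resampling of every window to ``rate`` Hz."""
    if rate > ws.sfreq:
        raise ValueError("upsampling is not supported")
    if rate == ws.sfreq:
        return ws.copy_with()
    if BANDPASS[1] >= rate / 2.0:
        raise ValueError(
            f"target rate {rate} Hz would alias the {BANDPASS[1]} Hz passband"
        )
    frac = Fraction(rate / ws.sfreq).limit_denominator(1000)
    out = sp_signal.resample_poly(ws.windows, frac.numerator, frac.denominator, axis=-1)
    expected = int(round(ws.window_length * rate))
    if out.shape[-1] != expected:  # guard: polyphase keeps exact length here
        out = out[..., :expected]
    return ws.copy_with(windows=out, sfreq=rate)


@dataclass
class PreprocessConfig:
    """Constants of the preprocessing chain (defaults match the pipeline)."""

    crop_seconds: float = CROP_SECONDS
    keep_seconds: float = KEEP_SECONDS
    bandpass: tuple[float, float] = BANDPASS
    notch_freqs: tuple[float, ...] = NOTCH_FREQS
    ptp_threshold: float = PTP_THRESHOLD_UV
    resample_hz: float = RESAMPLE_HZ


def preprocess_recording(
    rec: Recording, config: PreprocessConfig | None = None
) -> WindowSet:
    """Run the full chain on one recording.

    Order: crop (meditation only) -> interpolate -> band-pass -> notch ->
    window -> peak-to-peak rejection -> resample.  Rejection is evaluated
    after all filtering.
    """
    cfg = config or PreprocessConfig()
    if rec.modality == "meditation":
        rec = crop_meditation(rec)
    rec = interpolate_missing(rec)
    rec = bandpass_filter(rec, *cfg.bandpass)
    rec = notch_filter(rec, cfg.notch_freqs)
    ws = make_windows(rec)
    ws = reject_ptp(ws, cfg.ptp_threshold)
    ws = resample(ws, cfg.resample_hz)
    return ws


def qc_report(ws: WindowSet) -> dict:
    """Per-recording quality-control counts for the JSON report."""
    report = {
        "n_windows": int(ws.n_windows),
        "n_retained": int(ws.n_retained),
    }
    if ws.stages is not None:
        stages = ws.stages[ws.retained]
        report["retained_per_stage"] = {
            s: int((stages == s).sum()) for s in np.unique(ws.stages)
        }
    return report


def preprocess_or_none(rec: Recording, config: PreprocessConfig | None = None):
    """Like :func:`preprocess_recording` but skips too-short recordings.

    Returns None (with a warning) instead of raising, so one short
    session does not abort a batch.
    """
    try:
        return preprocess_recording(rec, config)
    except TooShortError as err:
        warnings.warn(f"skipping {rec.subject_id}/{rec.session_id}: {err}")
        return None
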