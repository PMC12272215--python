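"""Zero-phase FIR filter design and application.

All filtering in the pipeline uses linear-phase windowed-sinc (Hamming)
FIR kernels of odd length applied by centred convolution, which makes
them exactly zero-phase.  Kernel lengths follow the usual M/EEG rule of
thumb of ~3.3 cycles of the transition bandwidth, optionally capped so
that short windows (10 s) can still be band-filtered.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

#: seconds of kernel per Hz of transition bandwidth (Hamming window rule)
_LENGTH_FACTOR = 3.3


def _odd(n: int) -> int:
    return n if n % 2 == 1 else n + 1


def _numtaps(transition_hz: float, sfreq: float, max_taps: int | None) -> int:
    n = _odd(int(round(_LENGTH_FACTOR / transition_hz * sfreq)))
    n = max(n, 9)
    if max_taps is not None:
        n = min(n, _odd(max_taps) if max_taps % 2 == 1 else max_taps - 1)
    return n


def design_bandpass(
    low: float,
    high: float,
    sfreq: float,
    max_taps: int | None = None,
) -> np.ndarray:
    """Windowed-sinc band-pass kernel with edge-proportional transitions.

    Transition bandwidths: min(max(0.25*low, 0.1 Hz), low) at the low
    edge and 25% of the high edge at the high edge.
    """
    nyq = sfreq / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(f"invalid band edges ({low}, {high}) Hz for sfreq {sfreq} Hz")
    trans_low = min(max(0.25 * low, 0.1), low)
    trans_high = min(0.25 * high, nyq - high)
    numtaps = _numtaps(min(trans_low, trans_high), sfreq, max_taps)
    return signal.firwin(
        numtaps, [low, high], window="hamming", pass_zero=False, fs=sfreq
    )


def design_notch_bank(
    freqs: list[float],
    sfreq: float,
    stop_width: float = 1.0,
    max_taps: int | None = None,
) -> np.ndarray:
    """Single multiband band-stop kernel with one notch per frequency.

    Each notch is a stop band of ``stop_width`` Hz centred on the target
    frequency, realized jointly in one windowed-sinc kernel.
    """
    nyq = sfreq / 2.0
    freqs = sorted(float(f) for f in freqs)
    for f in freqs:
        if f >= nyq:
            raise ValueError(f"notch frequency {f} Hz is at or above Nyquist ({nyq} Hz)")
    half = stop_width / 2.0
    edges: list[float] = []
    for f in freqs:
        edges.extend([f - half, f + half])
    numtaps = _numtaps(half, sfreq, max_taps)
    return signal.firwin(numtaps, edges, window="hamming", pass_zero=True, fs=sfreq)


def apply_fir(data: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Apply an odd-length symmetric FIR kernel zero-phase along the last axis.

    Centred 'same' convolution with a linear-phase kernel exactly
    compensates the group delay, so peak latencies are preserved.
    """
    if kernel.ndim != 1 or kernel.size % 2 != 1:
        raise ValueError("kernel must be 1-D with odd length")
    shape = [1] * data.ndim
    shape[-1] = kernel.size
    return signal.fftconvolve(data, kernel.reshape(shape), mode="same", axes=-1)
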