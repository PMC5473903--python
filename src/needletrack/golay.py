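"""Golay complementary coded excitation and pulse compression.

Tracking transmissions use a 32-bit Golay complementary pair: two ±1
sequences whose aperiodic autocorrelations sum to ``2N·δ[lag]``.  A coded
transmit waveform is the bipolar base pulse convolved with the
zero-stuffed (one impulse per carrier period) code; decoding convolves
each band-passed reception with the time-reversed oversampled code and
sums the pair, which cancels range sidelobes exactly and multiplies the
peak by ``2N`` relative to a single bipolar transmission.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "GolayPair",
    "ExcitationWaveform",
    "FilterSpec",
    "generate_golay_pair",
    "make_base_pulse",
    "encode",
    "bandpass",
    "decode_pair",
    "oversample_code",
    "pulse_peak_offset",
]


@dataclass(frozen=True)
class GolayPair:
    """A complementary pair of ±1 sequences of length ``n_bits``."""

    code_a: np.ndarray
    code_b: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.code_a, dtype=np.int64)
        b = np.asarray(self.code_b, dtype=np.int64)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("codes must be 1-D and of equal length")
        if not (np.all(np.abs(a) == 1) and np.all(np.abs(b) == 1)):
            raise ValueError("codes must be ±1 sequences")
        object.__setattr__(self, "code_a", a)
        object.__setattr__(self, "code_b", b)

    @property
    def n_bits(self) -> int:
        return self.code_a.size


@dataclass(frozen=True)
class ExcitationWaveform:
    """A sampled transmit waveform.

    ``kind`` records whether this is the raw bipolar pulse or a Golay
    encoded waveform (``golay_a`` / ``golay_b``).
    """

    samples: np.ndarray
    sampling_rate: float
    centre_frequency: float
    kind: str = "bipolar"

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "samples", np.asarray(self.samples, dtype=float)
        )


@dataclass(frozen=True)
class FilterSpec:
    """Receive band-pass filter: Chebyshev Type I, 5th order, 2–6 MHz.

    Passband ripple is not a published system parameter; 0.5 dB is the
    package default.
    """

    order: int = 5
    passband: tuple[float, float] = (2.0e6, 6.0e6)
    passband_ripple_db: float = 0.5
    family: str = "Chebyshev Type I"

    def sos(self, sampling_rate: float) -> np.ndarray:
        lo, hi = self.passband
        return sps.cheby1(
            self.order,
            self.passband_ripple_db,
            [lo, hi],
            btype="bandpass",
            fs=sampling_rate,
            output="sos",
        )


def generate_golay_pair(n_bits: int) -> GolayPair:
    """Generate a complementary pair by recursive doubling.

    Starts from ``a=[+1], b=[+1]`` and doubles via ``a' = a‖b``,
    ``b' = a‖−b``; any power-of-two length ≥ 2 is supported.
    """
    n = int(n_bits)
    if n < 2 or n & (n - 1):
        raise ValueError(f"n_bits must be a power of two ≥ 2, got {n_bits}")
    a = np.array([1], dtype=np.int64)
    b = np.array([1], dtype=np.int64)
    while a.size < n:
        a, b = np.concatenate([a, b]), np.concatenate([a, -b])
    return GolayPair(a, b)


def make_base_pulse(
    centre_frequency: float = 4.0e6,
    sampling_rate: float = 1.0e8,
    n_cycles: int = 1,
) -> ExcitationWaveform:
    """Bipolar base pulse: +1 for the first half-period, −1 for the second.

    One carrier period spans ``fs/fc`` samples; the +1 half-period gets
    ``floor(fs/(2 fc))`` samples and the −1 half the remainder, so a
    25-sample period splits 12/13.
    """
    if sampling_rate < 4 * centre_frequency:
        raise ValueError("sampling_rate must be at least 4× the carrier")
    if n_cycles < 1:
        raise ValueError("n_cycles must be ≥ 1")
    period = sampling_rate / centre_frequency
    total = int(round(n_cycles * period))
    per_cycle = int(round(period))
    half = per_cycle // 2
    cycle = np.concatenate([np.ones(half), -np.ones(per_cycle - half)])
    samples = np.tile(cycle, n_cycles)[:total]
    return ExcitationWaveform(samples, sampling_rate, centre_frequency, kind="bipolar")


def oversample_code(code: np.ndarray, oversample: int) -> np.ndarray:
    """Zero-stuff a ±1 code: one impulse every ``oversample`` samples.

    Length is ``(N−1)·oversample + 1``.
    """
    code = np.asarray(code, dtype=float)
    if code.size == 0:
        raise ValueError("empty code")
    if oversample < 1:
        raise ValueError("oversample must be ≥ 1")
    out = np.zeros((code.size - 1) * oversample + 1)
    out[::oversample] = code
    return out


def encode(
    code: np.ndarray,
    base_pulse: ExcitationWaveform,
    oversample: int | None = None,
    kind: str = "golay_a",
) -> ExcitationWaveform:
    """Build a coded transmit waveform.

    The zero-stuffed code (one ±1 impulse per carrier period, by default
    ``round(fs/fc)`` samples) is convolved with the base pulse, yielding
    ``(N−1)·oversample + len(base)`` samples.
    """
    if oversample is None:
        oversample = int(round(base_pulse.sampling_rate / base_pulse.centre_frequency))
    stuffed = oversample_code(code, oversample)
    samples = np.convolve(stuffed, base_pulse.samples)
    return ExcitationWaveform(
        samples, base_pulse.sampling_rate, base_pulse.centre_frequency, kind=kind
    )


def bandpass(
    x: np.ndarray, spec: FilterSpec, sampling_rate: float = 1.0e8
) -> np.ndarray:
    """Zero-phase (forward–backward) band-pass filtering.

    Zero-phase application leaves decoded peak positions unbiased by the
    filter group delay, which matters because peak times feed the
    time-of-flight localiser directly.  Works on a 1-D signal or on a
    2-D ``(n_channels, n_samples)`` matrix along the last axis.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] <= 3 * spec.order:
        raise ValueError("signal too short for the filter order")
    sos = spec.sos(sampling_rate)
    padlen = min(3 * (2 * sos.shape[0] + 1), x.shape[-1] - 1)
    return sps.sosfiltfilt(sos, x, axis=-1, padlen=padlen)


def decode_pair(
    received_a: np.ndarray,
    received_b: np.ndarray,
    pair: GolayPair,
    oversample: int,
) -> np.ndarray:
    """Pulse-compress a Golay reception pair.

    Each reception is convolved with the time-reversed oversampled code
    and the two results are summed.  The full convolution is shifted left
    by ``(N−1)·oversample`` samples so a scatterer at delay ``t`` decodes
    to a peak at the same sample index as a bipolar reception at delay
    ``t``, with amplitude ``2N`` times the bipolar peak and (noise-free)
    zero sidelobes.  Accepts 1-D signals or ``(n_channels, n_samples)``
    matrices.
    """
    ra = np.atleast_2d(np.asarray(received_a, dtype=float))
    rb = np.atleast_2d(np.asarray(received_b, dtype=float))
    if ra.shape != rb.shape:
        raise ValueError("received_a and received_b must have the same shape")
    ka = oversample_code(pair.code_a, oversample)[::-1]
    kb = oversample_code(pair.code_b, oversample)[::-1]
    shift = (pair.n_bits - 1) * oversample
    n = ra.shape[-1]
    out = (
        sps.fftconvolve(ra, ka[None, :], axes=-1)
        + sps.fftconvolve(rb, kb[None, :], axes=-1)
    )[:, shift : shift + n]
    if np.asarray(received_a).ndim == 1:
        return out[0]
    return out


def pulse_peak_offset(
    base_pulse: ExcitationWaveform,
    spec: FilterSpec | None = None,
    mode: str = "amplitude",
) -> float:
    """Sub-sample index of the peak of the (band-passed) reference pulse.

    A reception delayed by ``t`` produces its decoded peak not at
    ``round(t·fs)`` but at that sample plus this constant in-pulse
    offset; the tracking chain subtracts it so measured peak times are
    referenced to the start of the transmit waveform.  ``mode`` selects
    the same detector the chain uses on receptions: ``"amplitude"``
    (3-point parabola on |signal|) or ``"envelope"`` (refined
    analytic-envelope peak).
    """
    pad = 128  # keep filtfilt edge handling away from the pulse
    ref = np.concatenate(
        [np.zeros(pad), base_pulse.samples, np.zeros(pad)]
    )
    if spec is not None:
        ref = bandpass(ref, spec, base_pulse.sampling_rate)
    if mode == "amplitude":
        return parabolic_peak(np.abs(ref))[0] - pad
    if mode == "envelope":
        return refined_envelope_peak(np.abs(sps.hilbert(ref)))[0] - pad
    raise ValueError(f"unknown peak mode {mode!r}")


#: FFT up-sampling factor and half-window (samples) for the refined
#: envelope-peak estimate.
_ENV_UPSAMPLE = 16
_ENV_HALF_WINDOW = 48


def refined_envelope_peak(env: np.ndarray) -> tuple[float, float]:
    """Sub-sample (index, value) of an envelope maximum: FFT-upsample a
    window around the integer argmax, then fit the 3-point parabola.
    The refined value is sampling-phase invariant, which matters when
    near-equal peaks on different columns must be ranked."""
    p = int(np.argmax(env))
    lo = max(p - _ENV_HALF_WINDOW, 0)
    hi = min(p + _ENV_HALF_WINDOW, env.size)
    seg = env[lo:hi]
    if seg.size < 8:
        return parabolic_peak(env)
    up = sps.resample(seg, seg.size * _ENV_UPSAMPLE)
    s, w = parabolic_peak(up)
    return lo + s / _ENV_UPSAMPLE, w


def parabolic_peak(mag: np.ndarray) -> tuple[float, float]:
    """Refine the argmax of a sampled magnitude with a 3-point parabola.

    Returns ``(index, value)`` with a fractional index.  At the array
    edge, or when the neighbours do not bracket a proper vertex, falls
    back to the integer argmax.
    """
    mag = np.asarray(mag, dtype=float)
    p = int(np.argmax(mag))
    if p == 0 or p == mag.size - 1:
        return float(p), float(mag[p])
    y0, y1, y2 = mag[p - 1], mag[p], mag[p + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0:  # not a strict local max of the fitted parabola
        return float(p), float(y1)
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    value = y1 - 0.25 * (y0 - y2) * delta
    return p + delta, float(value)
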