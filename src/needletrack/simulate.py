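"""Forward acoustic model standing in for probe + fibre-optic hydrophone.

Transmissions from each tracking element are received by a single
omnidirectional point sensor at the needle tip.  The model is the
minimum the tracking algorithm is sensitive to: a time-of-flight delay
``r/c`` per element, ``1/r`` spherical spreading, and additive white
Gaussian receiver noise.  Directivity, attenuation and full-wave
propagation are deliberately absent — the localiser only consumes peak
times and relative amplitudes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ProbeGeometry
from .golay import ExcitationWaveform

__all__ = [
    "TipState",
    "MediumModel",
    "RawFrame",
    "simulate_reception",
    "simulate_tof",
    "TIP_BOUNDS_MM",
    "DEFAULT_RECORD_S",
]

#: Allowed tip positions, mm: X out-of-plane, Y lateral, Z depth.
TIP_BOUNDS_MM = ((-20.0, 20.0), (-19.2, 19.2), (0.0, 80.0))

#: Default record length, s — covers an 80 mm depth plus the coded
#: transmission duration at 1540 m/s.
DEFAULT_RECORD_S = 120e-6

#: Reference distance for the 1/r amplitude law, mm; also the clamp below
#: which the amplitude stops growing (a tip essentially on the probe face).
_REF_DISTANCE_MM = 1.0


@dataclass(frozen=True)
class TipState:
    """True needle-tip position (x, y, z) in probe coordinates, mm."""

    position: tuple[float, float, float]

    def __post_init__(self) -> None:
        pos = tuple(float(v) for v in self.position)
        if len(pos) != 3:
            raise ValueError("position must be (x, y, z)")
        if pos[2] < 0:
            raise ValueError("tip depth z must be ≥ 0")
        object.__setattr__(self, "position", pos)

    @property
    def xyz(self) -> np.ndarray:
        return np.array(self.position)


@dataclass(frozen=True)
class MediumModel:
    """Propagation medium: a scalar speed of sound, optionally overridden
    per tracking element (the Monte-Carlo heterogeneity machinery)."""

    sos: float = 1540.0
    per_element_sos: np.ndarray | None = None

    def __post_init__(self) -> None:
        values = [self.sos]
        if self.per_element_sos is not None:
            pes = np.asarray(self.per_element_sos, dtype=float)
            object.__setattr__(self, "per_element_sos", pes)
            values.append(pes)
        for v in values:
            arr = np.atleast_1d(v)
            if np.any(arr < 1000.0) or np.any(arr > 2000.0):
                raise ValueError("speed of sound must lie in [1000, 2000] m/s")

    def element_sos(self, n_elements: int) -> np.ndarray:
        if self.per_element_sos is None:
            return np.full(n_elements, self.sos)
        if self.per_element_sos.size != n_elements:
            raise ValueError(
                f"per_element_sos has {self.per_element_sos.size} entries, "
                f"expected {n_elements}"
            )
        return self.per_element_sos


@dataclass
class RawFrame:
    """Per-element received time series for one transmit sequence.

    ``waveforms`` is ``(n_elements, n_samples)``; rows follow
    ``element_order`` — the acquisition order side1 → side4, each row in
    element order.
    """

    waveforms: np.ndarray
    sampling_rate: float
    element_order: list[tuple[str, int]]
    excitation_kind: str
    medium_sos: float
    noise_std: float
    seed: int

    def __post_init__(self) -> None:
        self.waveforms = np.asarray(self.waveforms, dtype=np.float32)
        if self.waveforms.ndim != 2:
            raise ValueError("waveforms must be 2-D")
        if self.waveforms.shape[0] != len(self.element_order):
            raise ValueError("element_order length must match waveform rows")


#: Guard band, samples, around a fractionally delayed pulse (absorbs the
#: band-limited interpolation's pre/post ringing).
_FRAC_PAD = 64


def _fractional_shift(pulse: np.ndarray, frac: float) -> np.ndarray:
    """Delay a pulse by a sub-sample fraction via an exact frequency-
    domain phase ramp.

    Returns the pulse embedded in a ``_FRAC_PAD``-sample guard band on
    each side; sample ``_FRAC_PAD`` of the output corresponds to sample
    0 of the input delayed by ``frac``.  Unlike few-tap interpolation
    the spectral shift is amplitude-flat, so relative amplitudes across
    elements (which pick the peak column) stay faithful to the 1/r law.
    """
    if frac == 0.0:
        out = np.zeros(pulse.size + 2 * _FRAC_PAD)
        out[_FRAC_PAD : _FRAC_PAD + pulse.size] = pulse
        return out
    n = pulse.size + 2 * _FRAC_PAD
    buf = np.zeros(n)
    buf[_FRAC_PAD : _FRAC_PAD + pulse.size] = pulse
    freqs = np.fft.rfftfreq(n)
    spec = np.fft.rfft(buf) * np.exp(-2j * np.pi * freqs * frac)
    if n % 2 == 0:  # keep the Nyquist bin real
        spec[-1] = spec[-1].real
    return np.fft.irfft(spec, n)


def _check_bounds(tip: TipState) -> None:
    for value, (lo, hi), axis in zip(tip.position, TIP_BOUNDS_MM, "xyz"):
        if not lo <= value <= hi:
            raise ValueError(
                f"tip {axis} = {value} mm outside simulated bounds [{lo}, {hi}]"
            )


def simulate_reception(
    geometry: ProbeGeometry,
    tip: TipState,
    medium: MediumModel,
    excitation: ExcitationWaveform,
    noise_std: float = 0.0,
    seed: int = 0,
    record_length_s: float = DEFAULT_RECORD_S,
) -> RawFrame:
    """Simulate one tracking frame: sequential transmissions from all
    tracking elements, received at the tip.

    Each element's row is the excitation waveform delayed by ``r/c``
    (rounded to the sample grid), scaled by ``1/max(r, 1 mm)`` relative
    to unit amplitude at 1 mm, plus white Gaussian noise of standard
    deviation ``noise_std``.  Bit-reproducible for a fixed seed.
    """
    _check_bounds(tip)
    fs = geometry.sampling_rate
    n_samples = int(round(record_length_s * fs))
    order = geometry.tracking_element_order()
    positions = geometry.tracking_positions()
    sos = medium.element_sos(len(order))

    r_mm = np.linalg.norm(positions - tip.xyz, axis=1)
    delays = (r_mm * 1e-3) / sos
    starts = np.floor(delays * fs).astype(int)
    fracs = delays * fs - starts

    pulse = excitation.samples
    pad = _FRAC_PAD
    if starts.max() + pulse.size + pad > n_samples:
        raise ValueError(
            "record too short: max time of flight plus excitation exceeds "
            f"{record_length_s * 1e6:.1f} µs"
        )

    rng = np.random.default_rng(seed)
    if noise_std > 0:
        wf = rng.normal(0.0, noise_std, size=(len(order), n_samples))
    else:
        wf = np.zeros((len(order), n_samples))
    amps = _REF_DISTANCE_MM / np.maximum(r_mm, _REF_DISTANCE_MM)
    for e, (s, f, a) in enumerate(zip(starts, fracs, amps)):
        shifted = _fractional_shift(pulse, f)
        lo = max(s - pad, 0)
        wf[e, lo : s - pad + shifted.size] += a * shifted[lo - (s - pad) :]

    return RawFrame(
        waveforms=wf,
        sampling_rate=fs,
        element_order=order,
        excitation_kind=excitation.kind,
        medium_sos=medium.sos,
        noise_std=noise_std,
        seed=seed,
    )


def simulate_tof(
    geometry: ProbeGeometry,
    sensor_position: np.ndarray,
    per_element_sos: np.ndarray | float,
    element_subset: list[tuple[str, int]],
) -> np.ndarray:
    """Exact element→sensor times of flight, seconds (no sampling grid).

    ``t_e = ‖element_e − sensor‖ / c_e`` for each element in
    ``element_subset``; ``per_element_sos`` is a scalar or one value per
    subset element, m/s.  Positions in mm.
    """
    if len(element_subset) == 0:
        raise ValueError("element_subset must be non-empty")
    sensor = np.asarray(sensor_position, dtype=float)
    pos = np.array([geometry.element_position(a, i) for a, i in element_subset])
    c = np.broadcast_to(
        np.atleast_1d(np.asarray(per_element_sos, dtype=float)), (len(element_subset),)
    )
    r_mm = np.linalg.norm(pos - sensor, axis=1)
    return (r_mm * 1e-3) / c
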