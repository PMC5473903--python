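"""Needle-tip localisation from tracking images.

Each of the four side arrays yields one tracking image: columns are
transducer element numbers (h), rows map receive samples to distance
(v = sample/fs · c).  The image peak gives one time of flight
``t_m = v/c`` and a weight ``w`` (the peak amplitude).  The lateral
estimate ỹ comes from the mean peak column; the out-of-plane / depth
pair (x̃, z̃) minimises the weighted squared mismatch between measured
and precomputed times of flight on a 0.025 mm X–Z grid:

    (x̃, z̃) = argmin_{(x_i, z_j)}  Σ_k [(t_m⁽ᵏ⁾ − t_s⁽ᵏ⁾(x_i, z_j)) w⁽ᵏ⁾]²
                                   / Σ_k [w⁽ᵏ⁾]²

with ``t_s⁽ᵏ⁾`` the in-plane distance from side row k to the grid node
divided by the assumed speed of sound.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .geometry import ProbeGeometry
from .golay import (
    ExcitationWaveform,
    FilterSpec,
    GolayPair,
    bandpass,
    decode_pair,
    make_base_pulse,
    parabolic_peak,
    pulse_peak_offset,
    refined_envelope_peak,
)
from .simulate import RawFrame

__all__ = [
    "TrackingImage",
    "PeakObservation",
    "TOFGrid",
    "TipEstimate",
    "OverlayAnnotation",
    "build_tracking_images",
    "find_peak",
    "estimate_lateral",
    "precompute_tof_grid",
    "estimate_tip",
    "sos_water",
    "make_overlay",
    "decode_frame_pair",
    "images_from_frame",
    "track_frames",
]

#: Default coarse lattice spacing for the accelerated search, mm.
COARSE_SPACING_MM = 0.5
#: Half-window of the recentred fine search, mm.
FINE_WINDOW_MM = 1.0
#: Recentring step cap before falling back to the exhaustive search.
_MAX_RECENTRE = 200


@dataclass
class TrackingImage:
    """Decoded A-lines of one side array.

    ``amplitudes`` is ``(n_samples, n_elements)``: row index is the
    receive sample (vertical/distance axis v), column index the element
    number (horizontal axis h).
    """

    side_array_id: int
    amplitudes: np.ndarray
    sampling_rate: float
    assumed_sos: float

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.amplitudes.ndim != 2:
            raise ValueError("amplitudes must be 2-D (n_samples, n_elements)")

    def sample_to_mm(self, sample: float) -> float:
        """Distance, mm, of a (possibly fractional) receive sample."""
        return sample / self.sampling_rate * self.assumed_sos * 1e3


@dataclass(frozen=True)
class PeakObservation:
    """Peak of one tracking image.

    ``h`` is the horizontal peak coordinate in element units — an
    integer column in plain amplitude mode, or a sub-element
    interpolated coordinate in envelope mode.  ``h_element`` is the
    integer column whose A-line the time of flight was measured on
    (defaults to the rounded ``h``).  ``v`` is the peak distance (mm),
    ``w`` the peak amplitude, ``t_m = v/c`` the measured time of flight
    (s).
    """

    h: float
    v: float
    w: float
    t_m: float
    h_element: int | None = None

    def __post_init__(self) -> None:
        if self.w < 0 or self.t_m < 0:
            raise ValueError("peak weight and time of flight must be ≥ 0")
        if self.h_element is None:
            object.__setattr__(self, "h_element", int(round(self.h)))


@dataclass
class TOFGrid:
    """Precomputed simulated times of flight ``t_s⁽ᵏ⁾(x_i, z_j)``.

    ``tof`` has shape ``(n_side_rows, nx, nz)``, float64: near the
    depth limit the localiser's objective valley is nearly degenerate
    and single-precision rounding of t_s (~3 ps) is enough to scramble
    the argmin along it.
    """

    x_values: np.ndarray
    z_values: np.ndarray
    tof: np.ndarray
    sos_used: float
    geometry_hash: str

    @property
    def spacing(self) -> float:
        return float(self.x_values[1] - self.x_values[0]) if self.x_values.size > 1 \
            else float(self.z_values[1] - self.z_values[0])


@dataclass
class TipEstimate:
    """Localiser output: grid-constrained (x̃, z̃), lateral ỹ, the side
    of the imaging plane, the minimised objective (s²), and the four
    peak observations that produced it."""

    x: float
    y: float
    z: float
    side: str
    residual: float
    peaks: list[PeakObservation]


@dataclass(frozen=True)
class OverlayAnnotation:
    """Cross annotation for a B-mode overlay: centred at (ỹ, z̃), arm
    length proportional to the out-of-plane distance |x̃|, coloured by
    side.  A record only — rendering is left to the caller."""

    centre: tuple[float, float]
    arm_length_mm: float
    side: str


# ---------------------------------------------------------------------------
# image formation and peak extraction


def build_tracking_images(
    decoded: np.ndarray, geometry: ProbeGeometry, assumed_sos: float
) -> list[TrackingImage]:
    """Split 128 decoded element sequences (side1 → side4 order) into the
    four per-side-array tracking images."""
    decoded = np.asarray(decoded, dtype=float)
    n_expected = geometry.n_tracking
    if decoded.ndim != 2 or decoded.shape[0] != n_expected:
        raise ValueError(
            f"expected {n_expected} decoded element sequences, got "
            f"{decoded.shape[0] if decoded.ndim == 2 else 'non-2D input'}"
        )
    n = geometry.n_side_per_row
    return [
        TrackingImage(
            side_array_id=k + 1,
            amplitudes=decoded[k * n : (k + 1) * n].T,
            sampling_rate=geometry.sampling_rate,
            assumed_sos=assumed_sos,
        )
        for k in range(geometry.n_side_rows)
    ]


#: Half-window, samples, for the per-column energy used to rank columns
#: and interpolate the sub-column coordinate.
_ENERGY_HALF_WINDOW = 64


def _column_energies(amplitudes: np.ndarray, peak_row: int) -> np.ndarray:
    """Per-column signal energy in a window around the peak row.

    A windowed sum of squares is sampling-phase invariant for a
    band-limited pulse (Parseval), so the 1/r amplitude ordering across
    columns survives the fractional arrival-time differences that
    corrupt raw per-sample maxima; the window keeps broadband noise
    energy from swamping the small inter-column contrasts.
    """
    lo = max(peak_row - _ENERGY_HALF_WINDOW, 0)
    hi = min(peak_row + _ENERGY_HALF_WINDOW, amplitudes.shape[0])
    return np.sum(amplitudes[lo:hi] ** 2, axis=0)


def _subcolumn_vertex(energies: np.ndarray, col: int) -> float:
    """Sub-column peak coordinate from per-column energies.

    With point-source 1/r spreading the inverse energy is an exactly
    quadratic function of the column's lateral position, so the vertex
    of a parabola through 1/E at the three columns around the maximum
    recovers the source's lateral coordinate.  Falls back to the integer
    column at array edges or degenerate neighbourhoods; the offset is
    clamped to ±0.75 columns (the true offset of a correctly selected
    column is at most ~half a pitch).
    """
    if col == 0 or col == energies.size - 1:
        return float(col)
    e0, e1, e2 = energies[col - 1 : col + 2]
    if min(e0, e1, e2) <= 0:
        return float(col)
    y0, y1, y2 = 1.0 / e0, 1.0 / e1, 1.0 / e2
    denom = y0 - 2 * y1 + y2
    if denom <= 0:
        return float(col)
    delta = 0.5 * (y0 - y2) / denom
    return col + float(np.clip(delta, -0.75, 0.75))


def find_peak(
    image: TrackingImage,
    refine: bool = True,
    time_offset_samples: float = 0.0,
    mode: str = "amplitude",
) -> PeakObservation:
    """Locate the signal maximum of a tracking image.

    ``mode="amplitude"`` picks the global |amplitude| maximum (ties
    break toward smaller v, then smaller h) and, with ``refine``,
    interpolates the peak sample with a 3-point parabola along the time
    axis (a no-op at isolated single-sample peaks).

    ``mode="envelope"`` — the production tracking configuration —
    detects on the analytic-signal envelope: columns are ranked by
    their refined envelope-peak value (phase-invariant, so the 1/r
    amplitude ordering across columns is preserved), the peak time is
    the refined envelope maximum of the winning column, and ``h`` is
    interpolated to sub-column precision from the neighbouring columns'
    peak amplitudes.

    ``time_offset_samples`` — the known in-pulse peak offset of the
    excitation (see :func:`~needletrack.golay.pulse_peak_offset`) — is
    subtracted before converting the peak sample to distance.
    """
    if mode == "amplitude":
        mag = np.abs(image.amplitudes)
        peak_value = mag.max()
        if peak_value == 0:
            raise ValueError("all-zero tracking image has no peak")
        # row-major argmax: first hit is the smallest sample, then smallest h
        row, col = np.unravel_index(int(np.argmax(mag)), mag.shape)
        sample = float(row)
        w = float(peak_value)
        if refine:
            sample, w = parabolic_peak(mag[:, col])
        h = float(col)
    elif mode == "envelope":
        if not np.any(image.amplitudes):
            raise ValueError("all-zero tracking image has no peak")
        env = np.abs(sps.hilbert(image.amplitudes, axis=0))
        peak_row = int(np.unravel_index(np.argmax(env), env.shape)[0])
        energies = _column_energies(image.amplitudes, peak_row)
        col = int(np.argmax(energies))
        sample, w = refined_envelope_peak(env[:, col])
        h = _subcolumn_vertex(energies, col)
    else:
        raise ValueError(f"unknown peak mode {mode!r}")
    sample = max(sample - time_offset_samples, 0.0)
    v = image.sample_to_mm(sample)
    t_m = v * 1e-3 / image.assumed_sos
    return PeakObservation(h=h, v=v, w=w, t_m=t_m, h_element=int(col))


def estimate_lateral(peaks: list[PeakObservation], geometry: ProbeGeometry) -> float:
    """Lateral estimate ỹ, mm: the mean peak column, offset from the row
    centre and scaled by the side-array pitch."""
    if len(peaks) != geometry.n_side_rows:
        raise ValueError(f"expected {geometry.n_side_rows} peaks")
    mean_h = float(np.mean([p.h for p in peaks]))
    return (mean_h - (geometry.n_side_per_row - 1) / 2.0) * geometry.side_pitch


# ---------------------------------------------------------------------------
# time-of-flight grid and the Eq.-style weighted grid search


def _axis_values(lo: float, hi: float, spacing: float) -> np.ndarray:
    if spacing <= 0:
        raise ValueError("grid spacing must be positive")
    if hi < lo:
        raise ValueError("empty grid range")
    n = int(round((hi - lo) / spacing)) + 1
    return lo + np.arange(n) * spacing


def precompute_tof_grid(
    geometry: ProbeGeometry,
    sos: float = 1540.0,
    x_range: tuple[float, float] = (-20.0, 20.0),
    z_range: tuple[float, float] = (0.0, 80.0),
    spacing: float = 0.025,
) -> TOFGrid:
    """Precompute ``t_s⁽ᵏ⁾(x_i, z_j)`` for every side row.

    The simulated time of flight uses the in-plane distance from side
    row k (elevational offset X_k, probe face z = 0) to the node: the
    lateral coordinate has already been factored out through ỹ, so t_s
    is independent of which element of the row fired.
    """
    x = _axis_values(*x_range, spacing)
    z = _axis_values(*z_range, spacing)
    offsets = np.asarray(geometry.side_row_x_offsets)
    d_mm = np.sqrt(
        (offsets[:, None, None] - x[None, :, None]) ** 2 + z[None, None, :] ** 2
    )
    return TOFGrid(
        x_values=x,
        z_values=z,
        tof=d_mm * 1e-3 / sos,
        sos_used=sos,
        geometry_hash=geometry.hash(),
    )


def _objective_block(
    grid: TOFGrid,
    t_m: np.ndarray,
    weights: np.ndarray,
    ix: np.ndarray,
    iz: np.ndarray,
) -> np.ndarray:
    """Weighted objective on the index block ``ix × iz`` → (nix, niz)."""
    ts = grid.tof[:, ix[:, None], iz[None, :]]
    diff = t_m[:, None, None] - ts
    return np.einsum("k,kij->ij", weights**2, diff**2) / float(np.sum(weights**2))


def _argmin_z_then_x(obj: np.ndarray) -> tuple[int, int]:
    """Argmin of an (nx, nz) objective with ties toward smaller z, then
    smaller x."""
    flat = int(np.argmin(obj.T))  # transpose → z-major flat order
    iz, ix = np.unravel_index(flat, obj.T.shape)
    return int(ix), int(iz)


def _coarse_indices(n: int, stride: int) -> np.ndarray:
    idx = np.arange(0, n, stride)
    if idx[-1] != n - 1:
        idx = np.append(idx, n - 1)
    return idx


def _window_indices(values: np.ndarray, centre: float, half_width: float) -> np.ndarray:
    lo = np.searchsorted(values, centre - half_width, side="left")
    hi = np.searchsorted(values, centre + half_width, side="right")
    return np.arange(lo, hi)


def estimate_tip(
    peaks: list[PeakObservation],
    grid: TOFGrid,
    geometry: ProbeGeometry,
    search: str = "coarse_fine",
) -> TipEstimate:
    """Localise the tip from the four tracking-image peaks.

    The weighted squared time-of-flight mismatch is minimised over the
    grid.  ``search="coarse_fine"`` evaluates a ~0.5 mm coarse lattice,
    then repeatedly minimises over a ±1 mm window recentred on each
    successive argmin until the argmin is the window centre.  The
    objective strictly decreases at every recentring, so the walk
    terminates, and it can slide down the long diagonal valleys the
    objective develops near the depth limit instead of being trapped by
    a fixed refinement window; agreement with ``search="exhaustive"``
    is a tested property.
    """
    if len(peaks) != grid.tof.shape[0]:
        raise ValueError("need one peak per side array")
    weights = np.array([p.w for p in peaks], dtype=float)
    if np.count_nonzero(weights > 0) < 2:
        raise ValueError("at least 2 peaks with positive weight are required")
    t_m = np.array([p.t_m for p in peaks], dtype=float)
    y_hat = estimate_lateral(peaks, geometry)
    # the measured time of flight contains a lateral leg (tip at ~ỹ,
    # measuring element at its column's y) that the in-plane t_s model
    # does not; remove the known part before the X–Z search
    y_cols = (
        np.array([p.h_element for p in peaks], dtype=float)
        - (geometry.n_side_per_row - 1) / 2.0
    ) * geometry.side_pitch
    t_lat = (y_hat - y_cols) * 1e-3 / grid.sos_used
    t_m = np.sqrt(np.maximum(t_m**2 - t_lat**2, 0.0))

    nx, nz = grid.x_values.size, grid.z_values.size
    if search == "exhaustive":
        obj = _objective_block(grid, t_m, weights, np.arange(nx), np.arange(nz))
        ix, iz = _argmin_z_then_x(obj)
        residual = float(obj[ix, iz])
    elif search == "coarse_fine":
        stride = max(1, int(round(COARSE_SPACING_MM / grid.spacing)))
        cix = _coarse_indices(nx, stride)
        ciz = _coarse_indices(nz, stride)
        cobj = _objective_block(grid, t_m, weights, cix, ciz)
        ci, cj = _argmin_z_then_x(cobj)
        ix, iz = int(cix[ci]), int(ciz[cj])
        for _ in range(_MAX_RECENTRE):
            wix = _window_indices(grid.x_values, grid.x_values[ix], FINE_WINDOW_MM)
            wiz = _window_indices(grid.z_values, grid.z_values[iz], FINE_WINDOW_MM)
            obj = _objective_block(grid, t_m, weights, wix, wiz)
            fi, fj = _argmin_z_then_x(obj)
            nix, niz = int(wix[fi]), int(wiz[fj])
            if (nix, niz) == (ix, iz):
                residual = float(obj[fi, fj])
                break
            ix, iz = nix, niz
        else:  # pathological surface — fall back to the full search
            obj = _objective_block(grid, t_m, weights, np.arange(nx), np.arange(nz))
            ix, iz = _argmin_z_then_x(obj)
            residual = float(obj[ix, iz])
    else:
        raise ValueError(f"unknown search mode {search!r}")

    x_hat = float(grid.x_values[ix])
    z_hat = float(grid.z_values[iz])
    side = "in-plane" if x_hat == 0 else ("left" if x_hat < 0 else "right")
    return TipEstimate(
        x=x_hat, y=y_hat, z=z_hat, side=side, residual=residual, peaks=list(peaks)
    )


def sos_water(temperature_c: float) -> float:
    """Speed of sound in pure water, m/s (Marczak polynomial, 0–95 °C)."""
    t = float(temperature_c)
    if not 0.0 <= t <= 95.0:
        raise ValueError("water temperature must lie in [0, 95] °C")
    coeffs = (
        1.402385e3,
        5.038813,
        -5.799136e-2,
        3.287156e-4,
        -1.398845e-6,
        2.787860e-9,
    )
    return float(sum(c * t**i for i, c in enumerate(coeffs)))


def make_overlay(estimate: TipEstimate, scale: float = 1.0) -> OverlayAnnotation:
    """Overlay annotation: cross at (ỹ, z̃) with arm length
    ``scale · |x̃|`` mm, labelled with the side of the imaging plane."""
    return OverlayAnnotation(
        centre=(estimate.y, estimate.z),
        arm_length_mm=scale * abs(estimate.x),
        side=estimate.side,
    )


# ---------------------------------------------------------------------------
# full receive chain: frames → decoded matrix → images → estimate


def decode_frame_pair(
    frame_a: RawFrame,
    frame_b: RawFrame,
    pair: GolayPair,
    filter_spec: FilterSpec | None = None,
) -> np.ndarray:
    """Band-pass filter the two Golay receptions and pulse-compress them
    into one (n_elements, n_samples) decoded matrix."""
    spec = filter_spec or FilterSpec()
    if frame_a.element_order != frame_b.element_order:
        raise ValueError("frame pair element orders differ")
    fs = frame_a.sampling_rate
    fa = bandpass(frame_a.waveforms, spec, fs)
    fb = bandpass(frame_b.waveforms, spec, fs)
    oversample = int(round(fs / 4.0e6))
    return decode_pair(fa, fb, pair, oversample)


def images_from_frame(
    frame: RawFrame,
    geometry: ProbeGeometry,
    assumed_sos: float,
    filter_spec: FilterSpec | None = None,
) -> list[TrackingImage]:
    """Tracking images from a single bipolar frame (band-pass only)."""
    spec = filter_spec or FilterSpec()
    filtered = bandpass(frame.waveforms, spec, frame.sampling_rate)
    return build_tracking_images(filtered, geometry, assumed_sos)


def track_frames(
    frame_a: RawFrame,
    frame_b: RawFrame,
    pair: GolayPair,
    geometry: ProbeGeometry,
    grid: TOFGrid,
    filter_spec: FilterSpec | None = None,
    base_pulse: ExcitationWaveform | None = None,
) -> TipEstimate:
    """Full tracking chain for one Golay frame pair.

    Decodes, forms the four tracking images, extracts sub-sample peak
    times referenced to the transmit-pulse peak, and runs the grid
    localiser with the grid's assumed speed of sound.
    """
    spec = filter_spec or FilterSpec()
    pulse = base_pulse or make_base_pulse(sampling_rate=frame_a.sampling_rate)
    decoded = decode_frame_pair(frame_a, frame_b, pair, spec)
    images = build_tracking_images(decoded, geometry, grid.sos_used)
    offset = pulse_peak_offset(pulse, spec, mode="envelope")
    peaks = [
        find_peak(im, time_offset_samples=offset, mode="envelope") for im in images
    ]
    return estimate_tip(peaks, grid, geometry)
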