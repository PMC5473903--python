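"""Accuracy studies and the SNR statistic.

Two studies quantify the localiser:

* A Monte-Carlo speed-of-sound heterogeneity study: virtual hydrophone
  sensors on a 5 mm X–Z grid receive exact times of flight computed
  with per-element speeds of sound drawn uniformly within ±ε of
  1540 m/s, while the localiser assumes exactly 1540 m/s.  The mean and
  maximum Euclidean error over the grid are the study's headline
  numbers.
* A simulated translation-stage protocol in water: the full waveform
  chain (simulate → band-pass → decode → localise) is run while the tip
  is swept along each axis, mirroring the physical accuracy protocol.

The SNR of a tracking image is the global |amplitude| peak divided by
the amplitude standard deviation in a fixed noise rectangle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import ProbeGeometry, SIDE_ARRAYS
from .golay import encode, generate_golay_pair, make_base_pulse
from .simulate import MediumModel, TipState, simulate_reception
from .tracking import (
    PeakObservation,
    TOFGrid,
    TrackingImage,
    estimate_tip,
    precompute_tof_grid,
    track_frames,
)

__all__ = [
    "MonteCarloSpec",
    "MonteCarloResult",
    "SweepSpec",
    "SNRReport",
    "NoiseRegion",
    "run_sos_monte_carlo",
    "accuracy_metrics",
    "virtual_water_sweep",
    "run_full_water_protocol",
    "compute_snr",
]


# ---------------------------------------------------------------------------
# Monte-Carlo speed-of-sound heterogeneity study


def _default_x_grid() -> np.ndarray:
    return np.arange(-20.0, 20.0 + 1e-9, 5.0)


def _default_z_grid() -> np.ndarray:
    return np.arange(10.0, 60.0 + 1e-9, 5.0)


@dataclass
class MonteCarloSpec:
    """Configuration of the speed-of-sound Monte-Carlo study.

    ``epsilon`` is the maximum fractional deviation of each element's
    speed of sound from ``mean_sos`` (1% and 5% are the two study
    conditions).  ``shared_draw`` replaces the per-element independent
    draws with one shared draw per iteration (sensitivity mode only).
    """

    epsilon: float
    x_grid: np.ndarray = field(default_factory=_default_x_grid)
    z_grid: np.ndarray = field(default_factory=_default_z_grid)
    n_iterations: int = 1000
    mean_sos: float = 1540.0
    assumed_sos: float = 1540.0
    seed: int = 0
    shared_draw: bool = False

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be ≥ 0")
        self.x_grid = np.asarray(self.x_grid, dtype=float)
        self.z_grid = np.asarray(self.z_grid, dtype=float)
        if self.x_grid.size == 0 or self.z_grid.size == 0:
            raise ValueError("study grids must be non-empty")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be ≥ 1")


@dataclass
class MonteCarloResult:
    """Per-grid-point accuracies and their grid-wide summary.

    ``per_point`` columns: x_mm, z_mm, acc_x_mm, acc_z_mm, acc_abs_mm,
    std_abs_mm, n_iterations.  acc_x / acc_z are mean absolute
    coordinate errors; acc_abs is the mean per-iteration Euclidean
    error (so it need not dominate the coordinate accuracies).
    """

    per_point: pd.DataFrame
    epsilon: float
    seed: int

    @property
    def mean_abs(self) -> float:
        return float(self.per_point["acc_abs_mm"].mean())

    @property
    def max_abs(self) -> float:
        return float(self.per_point["acc_abs_mm"].max())

    @property
    def argmax_point(self) -> tuple[float, float]:
        row = self.per_point.loc[self.per_point["acc_abs_mm"].idxmax()]
        return (float(row["x_mm"]), float(row["z_mm"]))

    def mean_abs_standard_error(self) -> float:
        """Standard error of the grid-wide mean, propagated from the
        per-point iteration variances."""
        var = (self.per_point["std_abs_mm"] ** 2 / self.per_point["n_iterations"]).sum()
        return float(np.sqrt(var)) / len(self.per_point)


def in_plane_tracking_elements(geometry: ProbeGeometry) -> list[tuple[str, int]]:
    """The four tracking elements used for the 2-D X–Z study: one per
    side array, at the column nearest the lateral centre (tie toward the
    smaller index)."""
    y = geometry.row_lateral_positions(SIDE_ARRAYS[0])
    col = int(np.argmin(np.abs(y)))  # argmin takes the first (smaller) on a tie
    return [(aid, col) for aid in SIDE_ARRAYS[: geometry.n_side_rows]]


def accuracy_metrics(
    estimates: np.ndarray, truth: tuple[float, float]
) -> tuple[float, float, float]:
    """(acc_x, acc_z, acc_abs): mean absolute coordinate errors and the
    mean Euclidean error of a set of (x̃, z̃) estimates, mm."""
    est = np.asarray(estimates, dtype=float)
    if est.ndim != 2 or est.shape[0] == 0 or est.shape[1] != 2:
        raise ValueError("estimates must be a non-empty (n, 2) array")
    dx = est[:, 0] - truth[0]
    dz = est[:, 1] - truth[1]
    return (
        float(np.mean(np.abs(dx))),
        float(np.mean(np.abs(dz))),
        float(np.mean(np.hypot(dx, dz))),
    )


def _batch_grid_argmin(
    grid: TOFGrid, t_m: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised equal-weight grid search for a batch of TOF sets.

    Runs the identical algorithm as
    :func:`~needletrack.tracking.estimate_tip` (equal weights cancel
    from the objective) but batched over iterations: one shared coarse
    pass via a matrix product, then the recentred ±1 mm fine search
    with iterations grouped by their current centre node so each window
    is evaluated once per group.  Returns (x̃, z̃) arrays, mm.
    """
    from .tracking import (
        COARSE_SPACING_MM,
        FINE_WINDOW_MM,
        _MAX_RECENTRE,
        _coarse_indices,
        _window_indices,
    )

    n_iter = t_m.shape[0]
    nx, nz = grid.x_values.size, grid.z_values.size
    stride = max(1, int(round(COARSE_SPACING_MM / grid.spacing)))
    cix = _coarse_indices(nx, stride)
    ciz = _coarse_indices(nz, stride)

    def score(ix: np.ndarray, iz: np.ndarray, tm: np.ndarray) -> np.ndarray:
        # z-major node ordering so flat argmin ties break toward smaller
        # z then smaller x, matching the per-call estimator
        ts = (
            grid.tof[:, ix[:, None], iz[None, :]]
            .transpose(0, 2, 1)
            .reshape(grid.tof.shape[0], -1)
        )
        return tm @ (-2.0 * ts) + np.sum(ts**2, axis=0)

    cflat = np.argmin(score(cix, ciz, t_m), axis=1)
    ci_z, ci_x = np.unravel_index(cflat, (ciz.size, cix.size))
    centre_x = cix[ci_x].astype(np.int64)
    centre_z = ciz[ci_z].astype(np.int64)

    active = np.arange(n_iter)
    for _ in range(_MAX_RECENTRE):
        if active.size == 0:
            break
        keys = centre_x[active] * nz + centre_z[active]
        still = []
        for key in np.unique(keys):
            members = active[keys == key]
            ix0, iz0 = int(centre_x[members[0]]), int(centre_z[members[0]])
            wix = _window_indices(grid.x_values, grid.x_values[ix0], FINE_WINDOW_MM)
            wiz = _window_indices(grid.z_values, grid.z_values[iz0], FINE_WINDOW_MM)
            fflat = np.argmin(score(wix, wiz, t_m[members]), axis=1)
            fz, fx = np.unravel_index(fflat, (wiz.size, wix.size))
            gx, gz = wix[fx], wiz[fz]
            moved = (gx != ix0) | (gz != iz0)
            centre_x[members] = gx
            centre_z[members] = gz
            still.extend(members[moved].tolist())
        active = np.array(sorted(still), dtype=np.int64)
    else:  # pathological members — finish with the per-call fallback
        for i in active:
            peaks = [
                PeakObservation(h=0, v=t * grid.sos_used * 1e3, w=1.0, t_m=t)
                for t in t_m[i]
            ]
            est = _estimate_from_tofs(peaks, grid)
            centre_x[i] = int(np.argmin(np.abs(grid.x_values - est[0])))
            centre_z[i] = int(np.argmin(np.abs(grid.z_values - est[1])))

    return grid.x_values[centre_x], grid.z_values[centre_z]


def _estimate_from_tofs(peaks: list[PeakObservation], grid: TOFGrid):
    """Run the per-call estimator on bare TOF observations (the lateral
    estimate is meaningless here and discarded)."""
    from .geometry import ProbeGeometry

    geom = ProbeGeometry()  # lateral fields unused by the (x, z) search
    est = estimate_tip(peaks, grid, geom, search="exhaustive")
    return est.x, est.z


def run_sos_monte_carlo(
    geometry: ProbeGeometry,
    spec: MonteCarloSpec,
    grid: TOFGrid | None = None,
) -> MonteCarloResult:
    """Monte-Carlo speed-of-sound heterogeneity study.

    For each study grid point a virtual sensor sits at (x, 0, z).  Each
    iteration draws one speed of sound per tracking element, uniform on
    ``mean_sos·(1±ε)``, generates exact times of flight from the known
    element–sensor distances, and localises with the assumed (constant)
    speed of sound.  Draws are seeded per grid point
    (``SeedSequence([seed, point_index])``) so results are independent
    of evaluation order.
    """
    if grid is None:
        grid = precompute_tof_grid(geometry, sos=spec.assumed_sos)
    elements = in_plane_tracking_elements(geometry)
    n_el = len(elements)
    records = []
    point_index = 0
    for x in spec.x_grid:
        for z in spec.z_grid:
            sensor = np.array([x, 0.0, z])
            rng = np.random.default_rng(
                np.random.SeedSequence([int(spec.seed), point_index])
            )
            lo = spec.mean_sos * (1.0 - spec.epsilon)
            hi = spec.mean_sos * (1.0 + spec.epsilon)
            if spec.shared_draw:
                c = np.repeat(
                    rng.uniform(lo, hi, size=(spec.n_iterations, 1)), n_el, axis=1
                )
            else:
                c = rng.uniform(lo, hi, size=(spec.n_iterations, n_el))
            # vectorised simulate_tof over iterations: t = ‖el − sensor‖/c
            pos = np.array([geometry.element_position(a, i) for a, i in elements])
            r_mm = np.linalg.norm(pos - sensor, axis=1)
            t_m = (r_mm * 1e-3)[None, :] / c
            # remove the known lateral leg (sensor at y=0, element at its
            # column's y) so t_m matches the in-plane t_s model, as the
            # per-call estimator does
            t_lat = (sensor[1] - pos[:, 1]) * 1e-3 / spec.assumed_sos
            t_m = np.sqrt(np.maximum(t_m**2 - t_lat[None, :] ** 2, 0.0))
            x_hat, z_hat = _batch_grid_argmin(grid, t_m)
            dx, dz = x_hat - x, z_hat - z
            eucl = np.hypot(dx, dz)
            records.append(
                {
                    "x_mm": float(x),
                    "z_mm": float(z),
                    "acc_x_mm": float(np.mean(np.abs(dx))),
                    "acc_z_mm": float(np.mean(np.abs(dz))),
                    "acc_abs_mm": float(np.mean(eucl)),
                    "std_abs_mm": float(np.std(eucl, ddof=1))
                    if spec.n_iterations > 1
                    else 0.0,
                    "n_iterations": spec.n_iterations,
                }
            )
            point_index += 1
    return MonteCarloResult(
        per_point=pd.DataFrame.from_records(records),
        epsilon=spec.epsilon,
        seed=spec.seed,
    )


# ---------------------------------------------------------------------------
# simulated water-bath translation protocol


@dataclass
class SweepSpec:
    """One leg of the translation protocol.

    Axis ranges follow the physical protocol: X from 0 to 20 mm (step
    1 mm) at depths 20/40/60 mm; Y across the central aperture at the
    same depths with X = 0; Z from 20 to 60 mm at X = 0/10/20 mm.  The
    published protocol does not state the lateral sweep extent; this
    package sweeps Y over ±8.5 mm (18 positions per depth), which keeps
    the three legs at 240 positions total.
    """

    axis: str
    step: float = 1.0
    noise_std: float = 0.0
    seed: int = 0

    def positions(self) -> list[tuple[float, float, float]]:
        if self.axis == "X":
            return [
                (x, 0.0, z)
                for z in (20.0, 40.0, 60.0)
                for x in np.arange(0.0, 20.0 + 1e-9, self.step)
            ]
        if self.axis == "Y":
            return [
                (0.0, y, z)
                for z in (20.0, 40.0, 60.0)
                for y in np.arange(-8.5, 8.5 + 1e-9, self.step)
            ]
        if self.axis == "Z":
            return [
                (x, 0.0, z)
                for x in (0.0, 10.0, 20.0)
                for z in np.arange(20.0, 60.0 + 1e-9, self.step)
            ]
        raise ValueError(f"axis must be X, Y or Z, got {self.axis!r}")


#: Record length used by the sweeps, s — covers the protocol's deepest
#: position plus the coded transmission.
_SWEEP_RECORD_S = 80e-6


def virtual_water_sweep(
    geometry: ProbeGeometry,
    spec: SweepSpec,
    grid: TOFGrid | None = None,
    sos: float = 1540.0,
    n_bits: int = 32,
) -> pd.DataFrame:
    """Run the full waveform chain along one translation leg.

    Each position is simulated (Golay pair transmissions, additive
    noise), decoded and localised; the table reports true and estimated
    coordinates, per-dimension errors, and the relative accuracy in the
    translation dimension (the |tracked − actual| distance along the
    swept axis, mirroring the stage-referenced physical metric).
    """
    if grid is None:
        grid = precompute_tof_grid(geometry, sos=sos)
    pair = generate_golay_pair(n_bits)
    base = make_base_pulse(sampling_rate=geometry.sampling_rate)
    exc_a = encode(pair.code_a, base, kind="golay_a")
    exc_b = encode(pair.code_b, base, kind="golay_b")
    medium = MediumModel(sos=sos)
    axis_col = {"X": "x", "Y": "y", "Z": "z"}[spec.axis]

    rows = []
    for idx, pos in enumerate(spec.positions()):
        tip = TipState(pos)
        seeds = np.random.SeedSequence([int(spec.seed), idx]).generate_state(2)
        frame_a = simulate_reception(
            geometry, tip, medium, exc_a, spec.noise_std, int(seeds[0]),
            record_length_s=_SWEEP_RECORD_S,
        )
        frame_b = simulate_reception(
            geometry, tip, medium, exc_b, spec.noise_std, int(seeds[1]),
            record_length_s=_SWEEP_RECORD_S,
        )
        est = track_frames(frame_a, frame_b, pair, geometry, grid, base_pulse=base)
        row = {
            "axis": spec.axis,
            "x_true_mm": pos[0],
            "y_true_mm": pos[1],
            "z_true_mm": pos[2],
            "x_est_mm": est.x,
            "y_est_mm": est.y,
            "z_est_mm": est.z,
            "err_x_mm": est.x - pos[0],
            "err_y_mm": est.y - pos[1],
            "err_z_mm": est.z - pos[2],
        }
        row["relative_accuracy_mm"] = abs(row[f"err_{axis_col}_mm"])
        rows.append(row)
    return pd.DataFrame.from_records(rows)


def run_full_water_protocol(
    geometry: ProbeGeometry,
    noise_std: float = 0.0,
    seed: int = 0,
    grid: TOFGrid | None = None,
    sos: float = 1540.0,
) -> pd.DataFrame:
    """All three translation legs (X, Y, Z) — 240 positions."""
    if grid is None:
        grid = precompute_tof_grid(geometry, sos=sos)
    frames = [
        virtual_water_sweep(
            geometry,
            SweepSpec(axis=axis, noise_std=noise_std, seed=seed + k),
            grid=grid,
            sos=sos,
        )
        for k, axis in enumerate(("X", "Y", "Z"))
    ]
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# SNR statistic


@dataclass(frozen=True)
class NoiseRegion:
    """Rectangular noise region in image coordinates: centred at depth
    10 mm / lateral 9.5 mm with widths 20 mm (depth) and 19 mm (lateral
    — 16 side-array elements)."""

    z_centre_mm: float = 10.0
    y_centre_mm: float = 9.5
    z_width_mm: float = 20.0
    y_width_mm: float = 19.0


@dataclass
class SNRReport:
    """Per-image and mean SNR = S/σ for one needle-tip position."""

    per_image_snr: list[float]
    snr: float
    S: float
    sigma: float
    region: NoiseRegion


def compute_snr(
    images: list[TrackingImage],
    geometry: ProbeGeometry,
    region: NoiseRegion | None = None,
) -> SNRReport:
    """SNR of a tracked position: per image, the global |amplitude|
    maximum divided by the amplitude standard deviation inside the noise
    rectangle; the reported SNR is the mean over the four images."""
    region = region or NoiseRegion()
    y = geometry.row_lateral_positions(SIDE_ARRAYS[0])
    cols = np.flatnonzero(np.abs(y - region.y_centre_mm) <= region.y_width_mm / 2)
    if cols.size == 0:
        raise ValueError("noise region selects no columns")
    per = []
    last_S = last_sigma = 0.0
    for im in images:
        n_samples = im.amplitudes.shape[0]
        v = im.sample_to_mm(np.arange(n_samples))
        rows = np.flatnonzero(np.abs(v - region.z_centre_mm) <= region.z_width_mm / 2)
        if rows.size == 0:
            raise ValueError("noise region selects no samples")
        patch = im.amplitudes[np.ix_(rows, cols)]
        sigma = float(np.std(patch))
        if sigma == 0:
            raise ValueError("degenerate noise region (zero variance)")
        S = float(np.max(np.abs(im.amplitudes)))
        per.append(S / sigma)
        last_S, last_sigma = S, sigma
    return SNRReport(
        per_image_snr=per,
        snr=float(np.mean(per)),
        S=last_S,
        sigma=last_sigma,
        region=region,
    )
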