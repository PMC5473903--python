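"""Probe coordinate system and transducer element layout.

The imaging/tracking probe carries a central focused row of 128 imaging
elements flanked by four unfocused 32-element side rows used only for
tracking transmissions.  Coordinates follow the probe convention:

* X — out-of-plane (elevational), perpendicular to the imaging plane
* Y — lateral, along the array
* Z — depth (axial), positive into tissue

The origin sits at the centre of the probe face; every element lies at
z = 0.  The elevational offsets of the side rows are not a published
property of the manufactured probe, so they are fully configurable; the
defaults place the two row pairs at ±3 mm and ±5 mm, just outside the
4 mm-tall central elements.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ProbeGeometry", "build_geometry", "element_position", "SIDE_ARRAYS"]

#: Ordered tracking-array identifiers; transmissions run side1 → side4.
SIDE_ARRAYS = ("side1", "side2", "side3", "side4")


@dataclass(frozen=True)
class ProbeGeometry:
    """Element layout of the imaging/tracking probe.

    Parameters
    ----------
    central_pitch : float
        Lateral pitch of the central imaging row, mm.
    n_central : int
        Number of central imaging elements.
    side_pitch : float
        Lateral pitch of each tracking side row, mm.  Side elements are
        0.3 mm × 1.2 mm mounted with the long side along Y, so adjacent
        elements sit 1.2 mm apart and a 32-element row spans ~38.4 mm,
        matching the central aperture.
    n_side_per_row : int
        Elements per tracking side row.
    n_side_rows : int
        Number of tracking side rows.
    side_row_x_offsets : tuple of float
        Out-of-plane (X) position of each side row, mm, ordered
        side1..side4.
    sampling_rate : float
        Receive digitisation rate, Hz.
    """

    central_pitch: float = 0.3
    n_central: int = 128
    side_pitch: float = 1.2
    n_side_per_row: int = 32
    n_side_rows: int = 4
    side_row_x_offsets: tuple[float, ...] = (-5.0, -3.0, 3.0, 5.0)
    sampling_rate: float = 1.0e8

    def __post_init__(self) -> None:
        if self.central_pitch <= 0 or self.side_pitch <= 0:
            raise ValueError("element pitches must be positive")
        if self.n_central <= 0 or self.n_side_per_row <= 0 or self.n_side_rows <= 0:
            raise ValueError("element counts must be positive")
        if len(self.side_row_x_offsets) != self.n_side_rows:
            raise ValueError(
                f"expected {self.n_side_rows} side-row offsets, "
                f"got {len(self.side_row_x_offsets)}"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        object.__setattr__(
            self, "side_row_x_offsets", tuple(float(v) for v in self.side_row_x_offsets)
        )

    # -- derived layout -------------------------------------------------

    @property
    def n_tracking(self) -> int:
        """Total number of tracking elements across all side rows."""
        return self.n_side_per_row * self.n_side_rows

    def row_lateral_positions(self, array_id: str) -> np.ndarray:
        """Lateral (Y) coordinates, mm, of every element of one row.

        Element ``m`` of an ``M``-element row (0-based) sits at
        ``y_m = (m - (M - 1)/2) * pitch`` so the row is symmetric about
        Y = 0.
        """
        if array_id == "central":
            n, pitch = self.n_central, self.central_pitch
        else:
            self._side_index(array_id)
            n, pitch = self.n_side_per_row, self.side_pitch
        m = np.arange(n, dtype=float)
        return (m - (n - 1) / 2.0) * pitch

    def _side_index(self, array_id: str) -> int:
        try:
            k = SIDE_ARRAYS.index(array_id)
        except ValueError:
            raise KeyError(f"unknown array_id {array_id!r}") from None
        if k >= self.n_side_rows:
            raise KeyError(f"geometry has only {self.n_side_rows} side rows")
        return k

    def element_position(self, array_id: str, index: int) -> np.ndarray:
        """Position (x, y, z) in mm of one element.

        The central row lies in the imaging plane (x = 0); side row *k*
        sits at ``side_row_x_offsets[k]``.  All elements are on the probe
        face, z = 0.
        """
        if array_id == "central":
            n, x = self.n_central, 0.0
        else:
            n = self.n_side_per_row
            x = self.side_row_x_offsets[self._side_index(array_id)]
        if not 0 <= index < n:
            raise IndexError(f"element index {index} out of range for {array_id}")
        y = self.row_lateral_positions(array_id)[index]
        return np.array([x, y, 0.0])

    def tracking_element_order(self) -> list[tuple[str, int]]:
        """Acquisition order of tracking elements: side1 → side4, each in
        element order (the per-frame row order of a raw frame)."""
        return [
            (aid, m)
            for aid in SIDE_ARRAYS[: self.n_side_rows]
            for m in range(self.n_side_per_row)
        ]

    def tracking_positions(self) -> np.ndarray:
        """(n_tracking, 3) array of tracking-element positions, mm, in
        acquisition order."""
        return np.array(
            [self.element_position(aid, m) for aid, m in self.tracking_element_order()]
        )

    def hash(self) -> str:
        """Short content hash identifying the layout (for grid caches)."""
        payload = repr(
            (
                self.central_pitch,
                self.n_central,
                self.side_pitch,
                self.n_side_per_row,
                self.n_side_rows,
                self.side_row_x_offsets,
                self.sampling_rate,
            )
        ).encode()
        return hashlib.sha1(payload).hexdigest()[:12]


def build_geometry(config: dict | None = None, **overrides) -> ProbeGeometry:
    """Build a :class:`ProbeGeometry` from a configuration mapping.

    Keys mirror the dataclass fields; ``*_mm``-suffixed aliases used in
    config files are accepted.  Unknown keys raise.
    """
    cfg = dict(config or {})
    cfg.update(overrides)
    alias = {
        "central_pitch_mm": "central_pitch",
        "side_pitch_mm": "side_pitch",
        "side_row_x_offsets_mm": "side_row_x_offsets",
        "sampling_rate_hz": "sampling_rate",
    }
    out: dict = {}
    valid = set(ProbeGeometry.__dataclass_fields__)
    for key, value in cfg.items():
        name = alias.get(key, key)
        if name not in valid:
            raise KeyError(f"unknown geometry config key {key!r}")
        out[name] = tuple(value) if name == "side_row_x_offsets" else value
    return ProbeGeometry(**out)


def element_position(geometry: ProbeGeometry, array_id: str, index: int) -> np.ndarray:
    """Functional alias for :meth:`ProbeGeometry.element_position`."""
    return geometry.element_position(array_id, index)
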