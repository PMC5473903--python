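"""Frame container I/O, configuration files and run manifests.

A frame on disk is a pair of files: ``<stem>.bin`` holding the waveform
matrix as little-endian 32-bit floats, row-major ``(n_elements,
n_samples)``, and a ``<stem>.yaml`` sidecar with every metadata field of
the in-memory frame.  The container round-trips bit-exactly.
"""

from __future__ import annotations

from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import yaml

from .geometry import ProbeGeometry, build_geometry
from .simulate import RawFrame

__all__ = [
    "write_frame",
    "read_frame",
    "default_config",
    "load_config",
    "write_manifest",
]

_DTYPE = "<f4"


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".yaml")


def write_frame(frame: RawFrame, path: str | Path) -> Path:
    """Write a frame to ``path`` (binary) + YAML sidecar; returns the
    binary path."""
    path = Path(path)
    wf = np.ascontiguousarray(frame.waveforms, dtype=_DTYPE)
    path.write_bytes(wf.tobytes())
    meta = {
        "dtype": _DTYPE,
        "n_elements": int(wf.shape[0]),
        "n_samples": int(wf.shape[1]),
        "sampling_rate": float(frame.sampling_rate),
        "element_order": [[a, int(i)] for a, i in frame.element_order],
        "excitation_kind": frame.excitation_kind,
        "medium_sos": float(frame.medium_sos),
        "noise_std": float(frame.noise_std),
        "seed": int(frame.seed),
    }
    _sidecar(path).write_text(yaml.safe_dump(meta, sort_keys=False))
    return path


def read_frame(path: str | Path) -> RawFrame:
    """Read a frame written by :func:`write_frame`; validates that the
    binary size and sidecar metadata agree."""
    path = Path(path)
    meta = yaml.safe_load(_sidecar(path).read_text())
    n_el, n_samp = int(meta["n_elements"]), int(meta["n_samples"])
    raw = path.read_bytes()
    expected = n_el * n_samp * np.dtype(meta["dtype"]).itemsize
    if len(raw) != expected:
        raise ValueError(
            f"frame binary is {len(raw)} bytes, sidecar implies {expected}"
        )
    order = [(a, int(i)) for a, i in meta["element_order"]]
    if len(order) != n_el:
        raise ValueError("sidecar element count does not match matrix rows")
    wf = np.frombuffer(raw, dtype=meta["dtype"]).reshape(n_el, n_samp)
    return RawFrame(
        waveforms=wf.copy(),
        sampling_rate=float(meta["sampling_rate"]),
        element_order=order,
        excitation_kind=meta["excitation_kind"],
        medium_sos=float(meta["medium_sos"]),
        noise_std=float(meta["noise_std"]),
        seed=int(meta["seed"]),
    )


def default_config() -> dict:
    """Built-in configuration; every numeric default is the system's
    stated operating value."""
    return {
        "geometry": {
            "central_pitch_mm": 0.3,
            "n_central": 128,
            "side_pitch_mm": 1.2,
            "n_side_per_row": 32,
            "n_side_rows": 4,
            "side_row_x_offsets_mm": [-5.0, -3.0, 3.0, 5.0],
            "sampling_rate_hz": 1.0e8,
        },
        "codec": {
            "n_bits": 32,
            "centre_frequency_hz": 4.0e6,
            "n_cycles": 1,
            "filter_order": 5,
            "passband_hz": [2.0e6, 6.0e6],
            "passband_ripple_db": 0.5,
        },
        "tracking": {
            "assumed_sos_m_s": 1540.0,
            "grid_spacing_mm": 0.025,
            "grid_x_range_mm": [-20.0, 20.0],
            "grid_z_range_mm": [0.0, 80.0],
        },
        "mc": {
            "epsilon": 0.01,
            "n_iterations": 1000,
            "mean_sos_m_s": 1540.0,
        },
        "sweep": {"noise_std": 0.0},
        "seed": 0,
    }


def _merge(base: dict, extra: dict) -> dict:
    out = dict(base)
    for key, value in extra.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML config, merged over the built-in defaults."""
    cfg = default_config()
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        user = yaml.safe_load(path.read_text()) or {}
        cfg = _merge(cfg, user)
    return cfg


def geometry_from_config(cfg: dict) -> ProbeGeometry:
    return build_geometry(cfg.get("geometry", {}))


def _package_version() -> str:
    try:
        return version("needletrack")
    except PackageNotFoundError:
        return "unknown"


def write_manifest(out_dir: str | Path, cfg: dict, seed: int,
                   geometry: ProbeGeometry) -> Path:
    """Write the reproducibility manifest: config echo, seed, package
    version and geometry hash."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "needletrack",
        "version": _package_version(),
        "seed": int(seed),
        "geometry_hash": geometry.hash(),
        "config": cfg,
    }
    path = out_dir / "manifest.yaml"
    path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return path
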