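"""File I/O: NIfTI / TIFF / CSV series, PNG masks, YAML config, ring reports.

Velocity stacks are stored as 3D NIfTI volumes with the third axis as time;
the first two axes map to (row, col) of the internal frames.  Which file
holds the x-component (u) and which the y-component (v), and their axis
signs, is a required user declaration (:class:`ComponentLayout`) — scanner
conventions for the in-plane encoding directions vary and are not guessed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .core import ChamberMask, ImageSeries, RingReport, ScanGeometry, VelocitySeries, VortexRing


@dataclass(frozen=True)
class ComponentLayout:
    """Maps component files to the internal (u, v) axes.

    ``u_sign`` / ``v_sign`` flip the stored component onto the internal
    convention (x = col rightward, y = row downward).
    """

    u_path: str | Path
    v_path: str | Path
    u_sign: int = 1
    v_sign: int = 1


def _read_stack(path: str | Path) -> np.ndarray:
    """Read a (T, H, W) stack from a NIfTI volume, a multipage TIFF, or a
    directory of per-frame CSV files (sorted by name)."""
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("*.csv"))
        if not files:
            raise FileNotFoundError(f"no per-frame CSV files in {path}")
        frames = [np.loadtxt(f, delimiter=",") for f in files]
        shapes = {f.shape for f in frames}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent frame shapes in {path}: {shapes}")
        return np.stack(frames)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        data = np.asarray(nib.load(str(path)).dataobj, dtype=float)
        if data.ndim != 3:
            raise ValueError(f"{path}: expected a 3D (H, W, T) volume, got {data.ndim}D")
        return np.moveaxis(data, -1, 0)
    if path.suffix.lower() in {".tif", ".tiff"}:
        data = np.asarray(iio.imread(path), dtype=float)
        if data.ndim == 2:
            data = data[None]
        return data
    raise ValueError(f"unsupported series format: {path}")


def _write_stack(stack: np.ndarray, path: str | Path) -> None:
    """Write a (T, H, W) stack as a 3D NIfTI volume (H, W, T)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.moveaxis(np.asarray(stack, dtype=np.float64), 0, -1), np.eye(4))
    nib.save(img, str(path))


def load_velocity_series(layout: ComponentLayout, geometry: ScanGeometry) -> VelocitySeries:
    """Load a two-component velocity series; frame times are index * frame_interval."""
    u = _read_stack(layout.u_path) * layout.u_sign
    v = _read_stack(layout.v_path) * layout.v_sign
    if u.shape != v.shape:
        raise ValueError(f"component shape mismatch: u {u.shape} vs v {v.shape}")
    times = np.arange(len(u)) * geometry.frame_interval
    return VelocitySeries(u=u, v=v, times=times, geometry=geometry)


def save_velocity_series(series: VelocitySeries, u_path: str | Path, v_path: str | Path) -> None:
    _write_stack(series.u, u_path)
    _write_stack(series.v, v_path)


def load_image_series(path: str | Path, frame_interval: float,
                      intensity_range: tuple[float, float] = (0.0, 255.0)) -> ImageSeries:
    frames = _read_stack(path)
    times = np.arange(len(frames)) * frame_interval
    return ImageSeries(frames=frames, times=times, intensity_range=intensity_range)


def save_image_series(series: ImageSeries, path: str | Path) -> None:
    _write_stack(series.frames, path)


def load_mask(path: str | Path, label: str = "RA") -> ChamberMask:
    """Load a binary mask from PNG (nonzero = inside) or NIfTI."""
    path = Path(path)
    if "".join(path.suffixes).endswith((".nii", ".nii.gz")):
        pixels = np.asarray(nib.load(str(path)).dataobj)
        if pixels.ndim == 3 and pixels.shape[-1] == 1:
            pixels = pixels[..., 0]
    else:
        pixels = iio.imread(path)
        if pixels.ndim == 3:  # collapse RGB(A)
            pixels = pixels[..., :3].max(axis=-1)
    return ChamberMask(pixels=pixels != 0, label=label)


def save_mask(mask: ChamberMask, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if "".join(path.suffixes).endswith((".nii", ".nii.gz")):
        nib.save(nib.Nifti1Image(mask.pixels.astype(np.uint8), np.eye(4)), str(path))
    else:
        iio.imwrite(path, (mask.pixels * np.uint8(255)))


def save_lavd_map(values: np.ndarray, path: str | Path) -> None:
    """Write an LAVD map (rad) as a 2D NIfTI image."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(values, dtype=np.float64), np.eye(4)), str(path))


def load_lavd_map(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=float)


def load_geometry(path: str | Path) -> ScanGeometry:
    """Read the geometry block of a YAML config file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    geo = cfg.get("geometry", cfg)
    return ScanGeometry(
        pixel_spacing=float(geo["pixel_spacing_mm"]),
        slice_thickness=float(geo["slice_thickness_mm"]),
        frame_interval=float(geo["frame_interval_s"]),
        venc=float(geo["venc_cm_s"]),
        n_frames=int(geo.get("n_frames", 25)),
    )


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def save_ring_report(report: RingReport, path: str | Path) -> None:
    """Serialize a ring report as JSON plus a per-frame volume CSV sidecar.

    The JSON roundtrips bit-exactly through :func:`load_ring_report`; the CSV
    (same stem, ``.csv`` suffix) holds columns frame_index, time_s, ring_id,
    sense, volume_ml.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "config_hash": report.config_hash,
        "seed": report.seed,
        "frame_times": {str(k): float(v) for k, v in report.frame_times.items()},
        "rings": [r.to_dict() for r in report.rings],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
    rows = report.volumes_table()
    cols = ["frame_index", "time_s", "ring_id", "sense", "volume_ml"]
    pd.DataFrame(rows, columns=cols).to_csv(path.with_suffix(".csv"), index=False)


def load_ring_report(path: str | Path) -> RingReport:
    with open(path) as fh:
        payload = json.load(fh)
    return RingReport(
        rings=[VortexRing.from_dict(d) for d in payload["rings"]],
        frame_times={int(k): v for k, v in payload["frame_times"].items()},
        config_hash=payload["config_hash"],
        seed=payload["seed"],
    )
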