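"""File formats and run manifests.

Multi-frame TIFF or NIfTI (.nii/.nii.gz) image stacks in; CSV/JSON out.
All CSV tables are comma-separated with a header row, UTF-8, '.' decimal.
Pixel coordinates in files follow the package convention: 0-based,
pixel-centred, x = column, y = row.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .detection import DetectionReport, SegmentResult
from .tracking import TaggedSequence, TrajectoryField

__all__ = [
    "read_sequence",
    "write_sequence",
    "read_mask",
    "write_mask",
    "write_trajectories",
    "read_trajectories",
    "write_report",
    "read_report",
    "build_manifest",
    "write_manifest",
]


def _load_stack(path: Path) -> np.ndarray:
    """Load a (T, rows, cols) stack from TIFF or NIfTI."""
    suffixes = "".join(path.suffixes).lower()
    try:
        if suffixes.endswith((".nii", ".nii.gz")):
            import nibabel as nib

            arr = np.asanyarray(nib.load(path).dataobj)
            if arr.ndim != 3:
                raise ValueError(f"{path}: expected a 3D (x, y, t) NIfTI volume")
            # NIfTI stores (x, y, t); convert to (t, rows=y, cols=x)
            return np.transpose(arr, (2, 1, 0)).astype(np.float64)
        import tifffile

        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise ValueError(f"{path}: expected a multi-frame 2D TIFF")
        return arr.astype(np.float64)
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot read image stack {path}: {exc}") from exc


def read_sequence(path, pixel_size_mm: float, slice_level: str) -> TaggedSequence:
    """Load a cine stack and normalize each frame to zero mean, unit variance.

    Frames are taken in stored order (first = end-diastole).  Raises
    ``IOError`` naming the path for unreadable files and ``ValueError``
    for single-frame input.
    """
    arr = _load_stack(Path(path))
    if arr.shape[0] < 2:
        raise ValueError(f"{path}: need >= 2 frames (ED..ES), got {arr.shape[0]}")
    return TaggedSequence.from_frames(arr, pixel_size_mm, slice_level)


def write_sequence(path, frames: np.ndarray) -> None:
    """Write a (T, rows, cols) stack as multi-frame TIFF or NIfTI."""
    path = Path(path)
    frames = np.asarray(frames, dtype=np.float32)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        nib.save(nib.Nifti1Image(np.transpose(frames, (2, 1, 0)), np.eye(4)), path)
    else:
        import tifffile

        tifffile.imwrite(path, frames)


def read_mask(path) -> np.ndarray:
    """Read a binary mask image (PNG or single-frame TIFF)."""
    import imageio.v3 as iio

    try:
        arr = iio.imread(Path(path))
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot read mask {path}: {exc}") from exc
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 0


def write_mask(path, mask: np.ndarray) -> None:
    import imageio.v3 as iio

    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * 255).astype(np.uint8))


# -- trajectories -------------------------------------------------------------


def write_trajectories(path, traj: TrajectoryField) -> None:
    """Trajectory CSV: point_id, frame, x_px, y_px, ncc_peak."""
    n, T = traj.positions.shape[:2]
    pid = np.repeat(np.arange(n), T)
    frm = np.tile(np.arange(T), n)
    pos = traj.positions.reshape(-1, 2)
    pd.DataFrame(
        {
            "point_id": pid,
            "frame": frm,
            "x_px": pos[:, 0],
            "y_px": pos[:, 1],
            "ncc_peak": traj.ncc_peaks.reshape(-1),
        }
    ).to_csv(path, index=False)


def read_trajectories(path, mask: np.ndarray, pixel_size_mm: float = 1.0,
                      slice_level: str = "midventricular") -> TrajectoryField:
    df = pd.read_csv(path)
    n = df["point_id"].nunique()
    T = df["frame"].nunique()
    df = df.sort_values(["point_id", "frame"])
    positions = df[["x_px", "y_px"]].to_numpy().reshape(n, T, 2)
    peaks = df["ncc_peak"].to_numpy().reshape(n, T)
    return TrajectoryField(
        seed_points=positions[:, 0].copy(),
        positions=positions,
        ncc_peaks=peaks,
        mask=np.asarray(mask, dtype=bool),
        pixel_size_mm=pixel_size_mm,
        slice_level=slice_level,
    )


# -- reports ------------------------------------------------------------------


def write_report(path, report: DetectionReport) -> None:
    payload = {
        "alphas": report.alphas,
        "warnings": report.warnings,
        "segments": {str(k): vars(v) for k, v in sorted(report.segments.items())},
    }
    Path(path).write_text(json.dumps(payload, indent=2, allow_nan=True))


def read_report(path) -> DetectionReport:
    payload = json.loads(Path(path).read_text())
    segments = {
        int(k): SegmentResult(**v) for k, v in payload["segments"].items()
    }
    return DetectionReport(
        segments=segments, alphas=payload["alphas"], warnings=payload["warnings"]
    )


# -- manifests ----------------------------------------------------------------


def _sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def build_manifest(config: dict, inputs: list = (), warnings: list[str] = ()) -> dict:
    """Structured run manifest: version, config hash, input checksums."""
    from . import __version__

    cfg_json = json.dumps(config, sort_keys=True, default=str)
    return {
        "tool": "tagstrain",
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "config": config,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "inputs": {
            str(p): _sha256_file(Path(p)) for p in inputs if Path(p).is_file()
        },
        "warnings": list(warnings),
    }


def write_manifest(path, manifest: dict) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
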