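"""Readers and writers binding the pipeline together.

NIfTI-1 is the primary interchange format (one 4D file, or one 3D file per
contrast) with saturation times in a plain-text sidecar — one value per
line, ``inf`` marking the unprepared image.  DICOM series are read-only
input: one directory per contrast, slices sorted by position along the
series normal.  No resampling is performed anywhere: geometry mismatches
between contrasts are an error, never silently fixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

from .stack import UNPREPARED, ContrastStack

__all__ = [
    "StackManifest",
    "read_times",
    "write_times",
    "read_stack",
    "write_stack",
    "read_dicom_series",
    "write_volume",
    "read_volume",
]

log = logging.getLogger("t1forge")


@dataclass
class StackManifest:
    """Paths making up one multi-contrast stack.

    ``volumes`` is either a list of per-contrast 3D NIfTI paths or a single
    4D NIfTI path.  ``times_file`` holds one saturation time per contrast.
    ``spacing_override_mm``, when set, replaces the header voxel spacing.
    """

    volumes: Sequence[Path] | Path
    times_file: Path
    spacing_override_mm: tuple[float, float, float] | None = None


def read_times(path: Path) -> np.ndarray:
    """Read a times file: one value (ms) per line; ``inf`` = unprepared."""
    times = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        times.append(UNPREPARED if line.lower() in ("inf", "+inf") else float(line))
    if not times:
        raise ValueError(f"no contrast times found in {path}")
    arr = np.asarray(times, dtype=np.float64)
    if np.count_nonzero(np.isinf(arr)) > 1:
        raise ValueError(f"{path}: more than one unprepared (inf) entry")
    return arr


def write_times(times_ms: np.ndarray, path: Path) -> None:
    lines = ["inf" if np.isinf(t) else f"{t:.6g}" for t in np.asarray(times_ms)]
    Path(path).write_text("\n".join(lines) + "\n")


def _load_nifti(path: Path) -> tuple[np.ndarray, tuple[float, ...]]:
    img = nib.as_closest_canonical(nib.load(str(path)))
    data = np.asarray(img.dataobj, dtype=np.float64)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing


def read_stack(manifest: StackManifest) -> ContrastStack:
    """Assemble a ContrastStack from a manifest.

    All contrasts must share one grid shape and voxel spacing; offenders are
    listed in the error.  The number of times must equal the number of
    volumes.
    """
    times = read_times(manifest.times_file)
    if isinstance(manifest.volumes, (str, Path)):
        data4d, spacing = _load_nifti(Path(manifest.volumes))
        if data4d.ndim != 4:
            raise ValueError(
                f"{manifest.volumes}: expected a 4D volume, got ndim={data4d.ndim}"
            )
        vols = [data4d[..., i] for i in range(data4d.shape[-1])]
        spacings = [spacing] * len(vols)
        names = [f"{manifest.volumes}[{i}]" for i in range(len(vols))]
    else:
        vols, spacings, names = [], [], []
        for p in manifest.volumes:
            data, spacing = _load_nifti(Path(p))
            if data.ndim != 3:
                raise ValueError(f"{p}: expected a 3D volume, got ndim={data.ndim}")
            vols.append(data)
            spacings.append(spacing)
            names.append(str(p))

    if len(times) != len(vols):
        raise ValueError(
            f"{len(times)} contrast times for {len(vols)} volumes"
        )
    ref_shape, ref_spacing = vols[0].shape, spacings[0]
    offenders = [
        name
        for name, v, s in zip(names, vols, spacings)
        if v.shape != ref_shape
        or not np.allclose(s, ref_spacing, rtol=1e-4, atol=1e-4)
    ]
    if offenders:
        raise ValueError(
            "inconsistent geometry across contrasts (no resampling is "
            f"performed); offending volumes: {offenders}"
        )
    spacing_mm = manifest.spacing_override_mm or ref_spacing
    return ContrastStack(np.stack(vols), times, spacing_mm)


def write_stack(stack: ContrastStack, volume_path: Path, times_path: Path) -> None:
    """Write a stack as one 4D NIfTI (float32) plus a times sidecar."""
    affine = np.diag(list(stack.voxel_spacing_mm) + [1.0])
    data4d = np.moveaxis(stack.data, 0, -1).astype(np.float32)
    nib.save(nib.Nifti1Image(data4d, affine), str(volume_path))
    write_times(stack.contrast_times_ms, times_path)


def write_volume(
    volume: np.ndarray,
    spacing_mm: tuple[float, float, float],
    path: Path,
) -> None:
    """Write one 3D volume (e.g. a T1 map in ms) as NIfTI."""
    affine = np.diag(list(spacing_mm) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine), str(path))


def read_volume(path: Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    data, spacing = _load_nifti(Path(path))
    if data.ndim == 4 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got ndim={data.ndim}")
    return data, spacing


# --------------------------------------------------------------------------
# DICOM
# --------------------------------------------------------------------------


def _read_dicom_dir(directory: Path, time_tag: str | None):
    import pydicom

    files = sorted(p for p in Path(directory).iterdir() if p.is_file())
    datasets = []
    for p in files:
        try:
            datasets.append(pydicom.dcmread(str(p)))
        except Exception:  # non-DICOM clutter is skipped
            continue
    if not datasets:
        raise ValueError(f"{directory}: no DICOM slices found")

    uids = {getattr(ds, "SeriesInstanceUID", None) for ds in datasets}
    if len(uids) > 1:
        raise ValueError(f"{directory}: mixed SeriesInstanceUIDs {sorted(map(str, uids))}")

    orient = np.asarray(datasets[0].ImageOrientationPatient, dtype=float)
    normal = np.cross(orient[:3], orient[3:])
    positions = [
        float(np.dot(np.asarray(ds.ImagePositionPatient, dtype=float), normal))
        for ds in datasets
    ]
    order = np.argsort(positions)
    datasets = [datasets[i] for i in order]
    positions = [positions[i] for i in order]

    gaps = np.diff(positions)
    if len(gaps):
        median_gap = float(np.median(gaps))
        for k, g in enumerate(gaps):
            if median_gap > 0 and abs(g - median_gap) > 0.25 * median_gap:
                raise ValueError(
                    f"{directory}: missing or irregular slice between positions "
                    f"{positions[k]:.2f} and {positions[k + 1]:.2f} mm"
                )
        dz = median_gap
    else:
        dz = float(getattr(datasets[0], "SliceThickness", 1.0))

    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
    # DICOM pixel arrays are (row, col) = (y, x); transpose to (x, y)
    volume = np.stack([s.T for s in slices], axis=-1)

    ps = [float(v) for v in datasets[0].PixelSpacing]  # (row, col) spacing
    spacing = (ps[1], ps[0], abs(dz))

    time_value = None
    if time_tag is not None:
        time_value = float(getattr(datasets[0], time_tag))
        log.info("%s: contrast time %.1f ms taken from DICOM tag %s",
                 directory, time_value, time_tag)
    return volume, spacing, time_value


def read_dicom_series(
    dirs: Sequence[Path],
    times_ms: Sequence[float] | None = None,
    time_tag: str | None = None,
) -> ContrastStack:
    """Read one DICOM series directory per contrast into a ContrastStack.

    Saturation times come from ``times_ms`` (recommended — vendor timing
    tags are inconsistent).  Alternatively ``time_tag`` names a DICOM
    attribute (e.g. ``"TriggerTime"``) to read per series; the tag used is
    logged.  Exactly one of the two must be provided.
    """
    if (times_ms is None) == (time_tag is None):
        raise ValueError("provide exactly one of times_ms or time_tag")
    volumes, spacings, tag_times = [], [], []
    for d in dirs:
        vol, spacing, tval = _read_dicom_dir(Path(d), time_tag)
        volumes.append(vol)
        spacings.append(spacing)
        tag_times.append(tval)
    shapes = {v.shape for v in volumes}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent volume shapes across series: {shapes}")
    times = np.asarray(times_ms if times_ms is not None else tag_times, float)
    return ContrastStack(np.stack(volumes), times, spacings[0])
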