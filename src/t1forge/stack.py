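"""Core container for multi-contrast T1-weighted image stacks.

A saturation-recovery T1 mapping acquisition produces a set of co-registered
3D magnitude volumes, one per saturation time TS, plus one "unprepared" image
acquired without any magnetization preparation (fully recovered longitudinal
magnetization).  The unprepared image is represented internally by a contrast
time of ``+inf`` — the asymptote of the recovery curve — never by a fake
large finite number.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Sentinel contrast time for the unprepared (fully recovered) image.
UNPREPARED: float = float("inf")


@dataclass
class ContrastStack:
    """A stack of ``n`` co-registered 3D volumes indexed by saturation time.

    Parameters
    ----------
    data:
        Array of shape ``(n, nx, ny, nz)``; intensities in arbitrary signal
        units (magnitude images may legitimately contain negative values
        after Gaussian noise simulation).
    contrast_times_ms:
        ``n`` saturation times in milliseconds; ``inf`` (:data:`UNPREPARED`)
        marks the unprepared image.  At most one unprepared entry is allowed.
    voxel_spacing_mm:
        Physical voxel spacing per axis ``(dx, dy, dz)`` in millimetres.
    """

    data: np.ndarray
    contrast_times_ms: np.ndarray
    voxel_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.contrast_times_ms = np.asarray(self.contrast_times_ms, dtype=np.float64)
        self.voxel_spacing_mm = tuple(float(s) for s in self.voxel_spacing_mm)
        if self.data.ndim != 4:
            raise ValueError(
                f"data must have shape (n, nx, ny, nz); got ndim={self.data.ndim}"
            )
        n = self.data.shape[0]
        if n < 2:
            raise ValueError("a ContrastStack needs at least 2 contrasts")
        if self.contrast_times_ms.shape != (n,):
            raise ValueError(
                f"{len(self.contrast_times_ms)} contrast times for {n} volumes"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("stack intensities must be finite")
        if np.count_nonzero(np.isinf(self.contrast_times_ms)) > 1:
            raise ValueError("at most one unprepared (inf) contrast time allowed")
        finite = self.contrast_times_ms[np.isfinite(self.contrast_times_ms)]
        if np.any(finite <= 0):
            raise ValueError("finite contrast times must be positive")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel spacing must be positive")

    @property
    def n(self) -> int:
        """Number of contrasts."""
        return self.data.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def copy(self) -> "ContrastStack":
        return ContrastStack(
            self.data.copy(),
            self.contrast_times_ms.copy(),
            self.voxel_spacing_mm,
        )
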