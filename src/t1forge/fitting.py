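"""Voxel-wise three-parameter saturation-recovery T1 fitting.

Model per voxel:  ``S(TS) = A * (1 - B * exp(-TS / T1))``, the standard
three-parameter form for saturation-prepared acquisitions, where ``A`` is
the equilibrium signal, ``B`` the effective saturation efficiency (1 for an
ideal saturation pulse) and ``T1`` the spin-lattice relaxation time in ms.
The unprepared image enters the fit as the ``TS -> inf`` asymptote, i.e. its
model value is exactly ``A`` — handled naturally because
``exp(-inf / T1) = 0``.

The nonlinear least-squares problem is separable: for fixed T1 the model is
linear in ``(A, C) = (A, A*B)``, so each candidate T1 reduces to a 2x2
linear solve (variable projection).  The fit scans a fixed logarithmic T1
grid (which subsumes a multi-start over short/typical/long T1), then refines
the best bracket by golden-section search on log T1.  This is fully
vectorized over voxels, deterministic (no RNG), and tie-breaks toward the
smallest T1 because the grid argmin takes the first minimum.

No Rician magnitude-bias correction is applied: magnitude images are fitted
directly, which matches common offline practice but biases very low-SNR
voxels (documented limitation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stack import ContrastStack

__all__ = ["FitOptions", "T1MapResult", "fit_voxel", "fit_t1_map", "fit_signals"]

_GOLD = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass
class FitOptions:
    """Controls for the voxel-wise fit.

    ``t1_bounds`` (ms) bracket the grid and the refinement; ``b_bounds``
    constrain the saturation-efficiency estimate; ``min_b`` flags voxels
    whose recovery curve is essentially flat (B ~ 0) as unidentifiable.
    """

    t1_bounds: tuple[float, float] = (1.0, 5000.0)
    b_bounds: tuple[float, float] = (0.0, 2.0)
    grid_points: int = 64
    refine_iters: int = 40
    min_b: float = 0.01

    def __post_init__(self) -> None:
        lo, hi = self.t1_bounds
        if not (0 < lo < hi):
            raise ValueError("t1_bounds must satisfy 0 < lo < hi")
        if self.grid_points < 4:
            raise ValueError("grid_points must be >= 4")


@dataclass
class T1MapResult:
    """Per-voxel parameter maps; NaN outside ``valid_mask``."""

    t1_map: np.ndarray
    a_map: np.ndarray
    b_map: np.ndarray
    residual_map: np.ndarray
    valid_mask: np.ndarray


def _linear_subfit(signals: np.ndarray, e: np.ndarray):
    """LS solve of ``s ~ A - C*e`` per row; returns (A, C, sse).

    ``signals``: (m, n); ``e``: (m, n) decay factors exp(-TS/T1) (0 for the
    unprepared image).  Closed-form 2x2 normal equations, vectorized.
    """
    n = signals.shape[-1]
    se = e.sum(axis=-1)
    see = (e * e).sum(axis=-1)
    ss = signals.sum(axis=-1)
    sse_cross = (signals * e).sum(axis=-1)
    det = n * see - se * se
    safe = det > 1e-12 * max(n, 1)
    det_safe = np.where(safe, det, 1.0)
    # [ n  -se ] [A]   [ ss        ]
    # [-se  see] [C] = [ sse_cross ]  (sign-folded)
    a = (see * ss - se * sse_cross) / det_safe
    c = (se * ss - n * sse_cross) / det_safe
    a = np.where(safe, a, ss / n)
    c = np.where(safe, c, 0.0)
    resid = signals - (a[..., None] - c[..., None] * e)
    sse = (resid * resid).sum(axis=-1)
    return a, c, sse


def fit_signals(
    signals: np.ndarray,
    times_ms: np.ndarray,
    options: FitOptions | None = None,
):
    """Fit the three-parameter model to many voxels at once.

    Parameters
    ----------
    signals : (m, n) array of intensities (m voxels, n contrasts).
    times_ms : (n,) saturation times; ``inf`` marks the unprepared image.

    Returns
    -------
    (t1, a, b, residual_rms, converged) arrays of length m.
    """
    if options is None:
        options = FitOptions()
    signals = np.atleast_2d(np.asarray(signals, dtype=np.float64))
    times = np.asarray(times_ms, dtype=np.float64)
    m, n = signals.shape
    if times.shape != (n,):
        raise ValueError(f"{times.size} times for {n} signals")
    if n < 4:
        raise ValueError("three-parameter fit needs at least 4 samples")

    ok = np.all(np.isfinite(signals), axis=1) & np.any(signals != 0, axis=1)

    lo, hi = options.t1_bounds
    grid = np.geomspace(lo, hi, options.grid_points)

    with np.errstate(over="ignore", invalid="ignore"):
        # decay factors for the whole grid: (grid, n); inf times -> 0
        e_grid = np.exp(-times[None, :] / grid[:, None])
    e_grid[:, np.isinf(times)] = 0.0

    sse_grid = np.empty((options.grid_points, m))
    for k in range(options.grid_points):
        _, _, sse_grid[k] = _linear_subfit(signals, np.broadcast_to(e_grid[k], (m, n)))
    best = np.argmin(sse_grid, axis=0)  # first minimum -> smallest T1 on ties

    # golden-section refinement on log T1 within the bracketing grid cells
    log_grid = np.log(grid)
    lo_idx = np.maximum(best - 1, 0)
    hi_idx = np.minimum(best + 1, options.grid_points - 1)
    a_log = log_grid[lo_idx]
    b_log = log_grid[hi_idx]

    def sse_at(logt1: np.ndarray) -> np.ndarray:
        e = np.exp(-times[None, :] / np.exp(logt1)[:, None])
        e[:, np.isinf(times)] = 0.0
        return _linear_subfit(signals, e)[2]

    x1 = b_log - _GOLD * (b_log - a_log)
    x2 = a_log + _GOLD * (b_log - a_log)
    f1 = sse_at(x1)
    f2 = sse_at(x2)
    for _ in range(options.refine_iters):
        take_left = f1 <= f2
        b_log = np.where(take_left, x2, b_log)
        a_log = np.where(take_left, a_log, x1)
        x1 = b_log - _GOLD * (b_log - a_log)
        x2 = a_log + _GOLD * (b_log - a_log)
        f1 = sse_at(x1)
        f2 = sse_at(x2)

    t1 = np.exp(0.5 * (a_log + b_log))
    e_fin = np.exp(-times[None, :] / t1[:, None])
    e_fin[:, np.isinf(times)] = 0.0
    a, c, sse = _linear_subfit(signals, e_fin)
    with np.errstate(divide="ignore", invalid="ignore"):
        b = np.where(a != 0, c / a, np.inf)
    residual = np.sqrt(np.maximum(sse, 0.0) / n)

    b_lo, b_hi = options.b_bounds
    interior = (t1 > lo * (1 + 1e-6)) & (t1 < hi * (1 - 1e-6))
    converged = (
        ok
        & (a > 0)
        & (b >= b_lo)
        & (b <= b_hi)
        & (b >= options.min_b)
        & interior
        & np.isfinite(t1)
    )
    bad = ~converged
    for arr in (t1, a, b, residual):
        arr[bad] = np.nan
    return t1, a, b, residual, converged


def fit_voxel(
    signals: np.ndarray,
    times_ms: np.ndarray,
    options: FitOptions | None = None,
) -> tuple[float, float, float, float, bool]:
    """Fit a single voxel; returns ``(T1, A, B, residual_rms, converged)``."""
    t1, a, b, r, conv = fit_signals(np.atleast_2d(signals), times_ms, options)
    return float(t1[0]), float(a[0]), float(b[0]), float(r[0]), bool(conv[0])


def fit_t1_map(
    stack: ContrastStack,
    mask: np.ndarray | None = None,
    options: FitOptions | None = None,
) -> T1MapResult:
    """Apply the three-parameter fit to every (masked) voxel of a stack.

    Voxels outside the mask are NaN with ``valid_mask`` False.  The result
    is independent of voxel ordering (one vectorized solve over all masked
    voxels).
    """
    shape = stack.grid_shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != shape:
            raise ValueError(f"mask shape {mask.shape} != grid shape {shape}")

    t1_map = np.full(shape, np.nan)
    a_map = np.full(shape, np.nan)
    b_map = np.full(shape, np.nan)
    residual_map = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)

    idx = np.nonzero(mask)
    if idx[0].size:
        signals = stack.data[:, idx[0], idx[1], idx[2]].T  # (m, n)
        t1, a, b, r, conv = fit_signals(signals, stack.contrast_times_ms, options)
        t1_map[idx] = t1
        a_map[idx] = a
        b_map[idx] = b
        residual_map[idx] = r
        valid[idx] = conv
    return T1MapResult(t1_map, a_map, b_map, residual_map, valid)
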