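"""Phase averaging of trigger-locked pulsatile velocity recordings."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PhaseAveragedCycle", "phase_average", "cycle_average", "find_peak_phase"]


@dataclass(frozen=True)
class PhaseAveragedCycle:
    """Phase-resolved ensemble mean and spread of a cardiac cycle.

    ``mean`` holds the phase-averaged 3-component velocity (M, ny, nx, 3);
    ``std`` the per-phase cycle-to-cycle standard deviation (N-1
    denominator), or None when only a single cycle was recorded.  Masked
    grid points are NaN throughout.
    """

    mean: np.ndarray
    std: np.ndarray | None
    n_cycles: int
    cycle_duration_s: float
    x_mm: np.ndarray
    y_mm: np.ndarray

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ValueError("at least one cycle required")
        if self.std is not None and np.nanmin(self.std) < 0:
            raise ValueError("standard deviations must be non-negative")

    @property
    def n_phases(self) -> int:
        return self.mean.shape[0]

    @property
    def phase_duration_s(self) -> float:
        return self.cycle_duration_s / self.n_phases

    @property
    def phase_times_s(self) -> np.ndarray:
        return np.arange(self.n_phases) * self.phase_duration_s

    def speed(self) -> np.ndarray:
        """Phase-resolved speed |v|, (M, ny, nx)."""
        return np.linalg.norm(self.mean, axis=-1)


def phase_average(recordings: np.ndarray, cycle_duration_s: float,
                  x_mm: np.ndarray | None = None,
                  y_mm: np.ndarray | None = None) -> PhaseAveragedCycle:
    """Pointwise mean and std over cycles of (N, M, ny, nx, 3) recordings.

    All cycles must share the phase and spatial grids (trigger-locked
    acquisition); masked points are NaN in the input and propagate as NaN.
    """
    rec = np.asarray(recordings, dtype=float)
    if rec.ndim != 5 or rec.shape[-1] != 3:
        raise ValueError("recordings must have shape (cycles, phases, ny, nx, 3)")
    n = rec.shape[0]
    mean = rec.mean(axis=0)
    std = rec.std(axis=0, ddof=1) if n >= 2 else None
    ny, nx = rec.shape[2], rec.shape[3]
    if x_mm is None:
        x_mm = np.arange(nx, dtype=float)
    if y_mm is None:
        y_mm = np.arange(ny, dtype=float)
    return PhaseAveragedCycle(mean=mean, std=std, n_cycles=n,
                              cycle_duration_s=cycle_duration_s,
                              x_mm=np.asarray(x_mm), y_mm=np.asarray(y_mm))


def cycle_average(pac: PhaseAveragedCycle) -> tuple[np.ndarray, np.ndarray]:
    """Time average over the cycle: (speed map, vector map).

    The speed map averages |v| (magnitude first), the vector map averages v
    componentwise; on the uniform phase grid the periodic trapezoid rule
    reduces to the plain mean.
    """
    speed_map = np.linalg.norm(pac.mean, axis=-1).mean(axis=0)
    vector_map = pac.mean.mean(axis=0)
    return speed_map, vector_map


def find_peak_phase(pac: PhaseAveragedCycle, roi_mask: np.ndarray) -> int:
    """Phase index maximising the ROI spatial-mean speed (ties: lowest)."""
    roi = np.asarray(roi_mask, dtype=bool)
    if not np.any(roi):
        raise ValueError("empty ROI mask")
    speeds = pac.speed()[:, roi]
    series = np.nanmean(speeds, axis=1)
    return int(np.argmax(series))
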