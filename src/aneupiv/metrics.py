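"""Hemodynamic efficacy metrics for flow-diverter treatment assessment.

Implements the quantities used to grade a deployment: ROI-mean sac
velocities (cycle mean and peak systole), relative velocity reduction
against the untreated flow, the normalized out-of-plane fluctuation
U_z_STD / U_mean, the oscillatory velocity index

    OVI = 1/2 * (1 - || integral v dt || / integral ||v|| dt)

over one cardiac cycle (0 for unidirectional transport, 1/2 for perfectly
reversing flow with zero net transport), and probe time series.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .cycles import PhaseAveragedCycle, find_peak_phase

__all__ = [
    "roi_mean_speed",
    "velocity_reduction",
    "oop_fluctuation_ratio",
    "ovi_map",
    "probe_timeseries",
    "HemodynamicReport",
    "build_report",
    "ReductionResult",
]


class ReductionResult(NamedTuple):
    percent: float        # unrounded
    percent_rounded: int  # headline integer value


def roi_mean_speed(pac: PhaseAveragedCycle, roi_mask: np.ndarray,
                   mode: str = "cyclic_mean") -> float:
    """ROI spatial-mean speed, averaged (cyclic_mean) or maximised
    (cyclic_max) over the cycle phases."""
    roi = np.asarray(roi_mask, dtype=bool)
    if not np.any(roi):
        raise ValueError("empty ROI mask")
    series = np.nanmean(pac.speed()[:, roi], axis=1)
    if mode == "cyclic_mean":
        return float(np.mean(series))
    if mode == "cyclic_max":
        return float(np.max(series))
    raise ValueError(f"unknown mode {mode!r}")


def velocity_reduction(treated: float, untreated: float) -> ReductionResult:
    """Relative velocity reduction 100 * (1 - treated/untreated) in percent."""
    if untreated <= 0:
        raise ValueError("untreated reference velocity must be positive")
    pct = 100.0 * (1.0 - treated / untreated)
    return ReductionResult(pct, int(round(pct)))


def oop_fluctuation_ratio(pac: PhaseAveragedCycle, roi_mask: np.ndarray,
                          normalize_first: bool = False,
                          noise_std: np.ndarray | float | None = None) -> float:
    """Normalized out-of-plane fluctuation U_z_STD / U_mean.

    Default: ROI-and-cycle mean of the z-component cycle-to-cycle standard
    deviation, divided by the scenario's cyclic-mean ROI speed.  With
    ``normalize_first`` the pointwise ratio is averaged instead (the
    alternative reading of the table normalisation).

    ``noise_std`` (scalar or broadcastable to pac.std[..., 2]) is the
    measurement noise floor of the out-of-plane component; when given it is
    removed from the observed spread in quadrature (stereo reconstruction
    amplifies correlation noise into U_z, which otherwise biases the
    statistic upward wherever the physical fluctuation is small).
    """
    if pac.std is None:
        raise ValueError("per-phase standard deviations require at least 2 cycles")
    roi = np.asarray(roi_mask, dtype=bool)
    u_mean = roi_mean_speed(pac, roi, "cyclic_mean")
    if u_mean == 0:
        raise ValueError("U_mean is zero; ratio undefined")
    sz_full = pac.std[..., 2]
    if noise_std is not None:
        noise = np.broadcast_to(np.asarray(noise_std, dtype=float), sz_full.shape)
        with np.errstate(invalid="ignore"):
            sz_full = np.sqrt(np.maximum(sz_full ** 2 - noise ** 2, 0.0))
    sz = sz_full[:, roi]
    if normalize_first:
        local = np.nanmean(np.linalg.norm(pac.mean, axis=-1), axis=0)[roi]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(local > 0, np.nanmean(sz, axis=0) / local, np.nan)
        return float(np.nanmean(ratio))
    return float(np.nanmean(sz)) / u_mean


def ovi_map(pac: PhaseAveragedCycle, two_component: bool = False,
            floor_m: float = 1e-9) -> np.ndarray:
    """Pointwise oscillatory velocity index in [0, 1/2].

    Periodic trapezoid integration over the uniform phase grid; points
    whose path length integral int ||v|| dt falls below ``floor_m`` metres
    (stagnation) return 0: no transport supports no oscillation claim.
    The norm includes all three components unless ``two_component``.
    """
    v = pac.mean[..., :2] if two_component else pac.mean
    dt = pac.phase_duration_s
    net = np.linalg.norm(np.sum(v, axis=0) * dt, axis=-1)
    path = np.sum(np.linalg.norm(v, axis=-1), axis=0) * dt
    with np.errstate(divide="ignore", invalid="ignore"):
        ovi = 0.5 * (1.0 - net / path)
    ovi = np.where(path < floor_m, 0.0, ovi)
    return np.clip(ovi, 0.0, 0.5)  # NaN (masked) propagates through clip


def probe_timeseries(pac: PhaseAveragedCycle,
                     probes: Mapping[str, tuple[float, float]],
                     lumen_mask: np.ndarray | None = None) -> pd.DataFrame:
    """Bilinear speed-vs-phase series at the probe locations.

    Raises if a probe lies outside the lumen mask (when given) or outside
    the field grid.
    """
    speed = pac.speed()
    if lumen_mask is not None:
        inside = RegularGridInterpolator((pac.y_mm, pac.x_mm),
                                         np.asarray(lumen_mask, float),
                                         bounds_error=False, fill_value=0.0)
    data = {"time_s": pac.phase_times_s}
    for name, (px, py) in probes.items():
        if not (pac.x_mm[0] <= px <= pac.x_mm[-1] and pac.y_mm[0] <= py <= pac.y_mm[-1]):
            raise ValueError(f"probe {name} outside the field grid")
        if lumen_mask is not None and inside([[py, px]])[0] < 0.5:
            raise ValueError(f"probe {name} lies outside the lumen")
        itp = RegularGridInterpolator((pac.y_mm, pac.x_mm),
                                      np.moveaxis(speed, 0, -1),
                                      bounds_error=False, fill_value=np.nan)
        data[name] = np.asarray(itp([[py, px]])[0])
    return pd.DataFrame(data)


# --------------------------------------------------------------------------
# report assembly
# --------------------------------------------------------------------------

@dataclass
class HemodynamicReport:
    """Aggregated treatment-efficacy report across scenarios."""

    u_mean_cyclic_mean: dict[str, float]
    u_mean_cyclic_max: dict[str, float]
    reduction_cyclic_mean: dict[str, ReductionResult]
    reduction_cyclic_max: dict[str, ReductionResult]
    oop_ratio: dict[str, float]
    peak_phase: dict[str, int]
    ovi: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    probe_series: dict[str, pd.DataFrame] = field(repr=False, default_factory=dict)
    untreated: str = "noFD"

    def to_json(self, path) -> None:
        payload = {
            "untreated": self.untreated,
            "U_mean_cyclic_mean_mps": self.u_mean_cyclic_mean,
            "U_mean_cyclic_max_mps": self.u_mean_cyclic_max,
            "reduction_cyclic_mean_pct": {k: {"value": v.percent, "rounded": v.percent_rounded}
                                          for k, v in self.reduction_cyclic_mean.items()},
            "reduction_cyclic_max_pct": {k: {"value": v.percent, "rounded": v.percent_rounded}
                                         for k, v in self.reduction_cyclic_max.items()},
            "Uz_std_over_U_mean": self.oop_ratio,
            "peak_phase_index": self.peak_phase,
            "ovi_roi_mean": {k: float(np.nanmean(v)) for k, v in self.ovi.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    def to_table(self) -> pd.DataFrame:
        """Scenario-by-quantity table mirroring the experimental layout."""
        cols = list(self.u_mean_cyclic_mean)
        rows = {
            "U_mean cyclic max [m/s]": [self.u_mean_cyclic_max[c] for c in cols],
            "U_mean cyclic mean [m/s]": [self.u_mean_cyclic_mean[c] for c in cols],
            "Uz_STD / U_mean [-]": [self.oop_ratio.get(c, np.nan) for c in cols],
        }
        return pd.DataFrame(rows, index=cols).T


def build_report(pacs: Mapping[str, PhaseAveragedCycle], roi_mask: np.ndarray,
                 probes: Mapping[str, tuple[float, float]] | None = None,
                 untreated: str = "noFD",
                 oop_noise: Mapping[str, np.ndarray] | None = None) -> HemodynamicReport:
    """Compute every metric for a set of scenario phase averages.

    ``oop_noise`` optionally maps scenario names to their out-of-plane
    measurement noise floor (see oop_fluctuation_ratio).
    """
    if untreated not in pacs:
        raise ValueError(f"untreated reference {untreated!r} missing")
    umean = {k: roi_mean_speed(p, roi_mask, "cyclic_mean") for k, p in pacs.items()}
    umax = {k: roi_mean_speed(p, roi_mask, "cyclic_max") for k, p in pacs.items()}
    red_mean = {k: velocity_reduction(umean[k], umean[untreated])
                for k in pacs if k != untreated}
    red_max = {k: velocity_reduction(umax[k], umax[untreated])
               for k in pacs if k != untreated}
    oop = {}
    for k, p in pacs.items():
        if p.std is not None:
            noise = oop_noise.get(k) if oop_noise else None
            oop[k] = oop_fluctuation_ratio(p, roi_mask, noise_std=noise)
    report = HemodynamicReport(
        u_mean_cyclic_mean=umean, u_mean_cyclic_max=umax,
        reduction_cyclic_mean=red_mean, reduction_cyclic_max=red_max,
        oop_ratio=oop,
        peak_phase={k: find_peak_phase(p, roi_mask) for k, p in pacs.items()},
        ovi={k: ovi_map(p) for k, p in pacs.items()},
        untreated=untreated)
    if probes:
        for k, p in pacs.items():
            report.probe_series[k] = probe_timeseries(p, probes)
    return report
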