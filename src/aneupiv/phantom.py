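"""Analytic pulsatile flow phantom of an idealized side-wall aneurysm.

The phantom models the sagittal mid-plane of a spherical side-wall aneurysm
(20 mm sac) on a 4 mm parent vessel.  The parent vessel carries a Poiseuille
profile modulated by a one-peak systolic waveform; the sac carries a
divergence-free stream-function field composed of a wall-aligned rotating
cell (stagnation point at the sac centre, no-slip at the wall) plus an
inflow-jet enhancement entering at the distal side of the ostium.  Flow
diverter deployment scenarios are emulated as an effective-medium
attenuation of the in-sac velocity, an optional shift of the jet entry
point, and a stochastic, seed-reproducible out-of-plane velocity
disturbance scaled to the local cycle-mean speed.

Units: lengths in mm, times in s, velocities in m/s.
Coordinates: x along the parent vessel (flow in +x), y from the vessel into
the sac, z out of plane; grids are cell-centred.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from functools import cached_property
from typing import Mapping

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "GeometryConfig",
    "FluidProperties",
    "WaveformConfig",
    "ScenarioConfig",
    "SCENARIO_PRESETS",
    "Geometry",
    "build_geometry",
    "AneurysmFlowModel",
    "default_model",
]


# --------------------------------------------------------------------------
# configuration types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GeometryConfig:
    """Idealized side-wall aneurysm geometry (sagittal plane).

    The sac is a circle of diameter ``sac_diameter_mm`` opening into the
    parent vessel (a straight channel of width ``vessel_diameter_mm`` below
    y = 0) through an ostium of width ``ostium_width_mm``.  The in-vivo
    parent vessel is bent (``bend_angle_deg``); the analytic plane model
    treats the vessel as locally straight near the ostium, the angle is
    carried as a documentation parameter.
    """

    sac_diameter_mm: float = 20.0
    vessel_diameter_mm: float = 4.0
    bend_angle_deg: float = 120.0
    ostium_width_mm: float = 8.0
    extent_mm: tuple[float, float, float, float] = (-12.0, 12.0, -5.0, 20.0)
    pitch_mm: float = 0.2
    roi_erosion_mm: float = 1.0

    def __post_init__(self) -> None:
        if self.sac_diameter_mm <= self.vessel_diameter_mm or self.vessel_diameter_mm <= 0:
            raise ValueError("require sac_diameter > vessel_diameter > 0")
        if not 0.0 < self.bend_angle_deg < 180.0:
            raise ValueError("bend angle must lie in (0, 180) degrees")
        if self.pitch_mm <= 0 or self.pitch_mm > self.vessel_diameter_mm / 2:
            raise ValueError("grid pitch must be positive and at most the vessel radius")
        if not 0 < self.ostium_width_mm < self.sac_diameter_mm:
            raise ValueError("ostium width must be positive and smaller than the sac diameter")

    @property
    def sac_radius_mm(self) -> float:
        return 0.5 * self.sac_diameter_mm

    @property
    def sac_center_mm(self) -> tuple[float, float]:
        """Sac centre, placed so the sac circle cuts y = 0 at +-ostium/2."""
        r = self.sac_radius_mm
        w = 0.5 * self.ostium_width_mm
        return (0.0, float(np.sqrt(r * r - w * w)))


#: Reference blood properties, for documentation/scaling only.
BLOOD_DENSITY = 1060.0          # kg m^-3
BLOOD_VISCOSITY = 3.9e-3        # Pa s


@dataclass(frozen=True)
class FluidProperties:
    """Blood-analogue liquid used for refractive-index-matched PIV."""

    density: float = 1221.0             # kg m^-3
    dynamic_viscosity: float = 5.0e-3   # Pa s

    def __post_init__(self) -> None:
        if self.density <= 0 or self.dynamic_viscosity <= 0:
            raise ValueError("fluid properties must be positive")

    @property
    def kinematic_viscosity(self) -> float:
        """nu = mu / rho, in m^2 s^-1."""
        return self.dynamic_viscosity / self.density


@dataclass(frozen=True)
class WaveformConfig:
    """One-systolic-peak pulsatile waveform.

    The flow-rate shape is a constant plus two periodically wrapped
    Gaussians in cycle phase (main systolic peak + diastolic shoulder),
    normalised to unit maximum; the centreline velocity is
    ``U_peak * shape(t)``.
    """

    cycle_duration_s: float = 1.0
    peak_velocity: float = 1.0            # m/s at the vessel centreline, peak systole
    base: float = 0.45
    amp1: float = 1.0
    phase1: float = 0.20
    width1: float = 0.07
    amp2: float = 0.35
    phase2: float = 0.42
    width2: float = 0.10

    def __post_init__(self) -> None:
        if self.cycle_duration_s <= 0 or self.peak_velocity <= 0:
            raise ValueError("cycle duration and peak velocity must be positive")
        if self.base <= 0:
            raise ValueError("base flow must be positive")

    # -- raw (unnormalised) shape -----------------------------------------
    def _raw(self, phi: np.ndarray) -> np.ndarray:
        phi = np.asarray(phi, dtype=float) % 1.0
        out = np.full_like(phi, self.base)
        for amp, ctr, wid in ((self.amp1, self.phase1, self.width1),
                              (self.amp2, self.phase2, self.width2)):
            for image in (-1.0, 0.0, 1.0):   # periodic wrapping
                out = out + amp * np.exp(-0.5 * ((phi - ctr - image) / wid) ** 2)
        return out

    @cached_property
    def _norm(self) -> tuple[float, float]:
        """(maximum of the raw shape, phase of the maximum)."""
        grid = np.linspace(0.0, 1.0, 4096, endpoint=False)
        i = int(np.argmax(self._raw(grid)))
        span = (grid[max(i - 2, 0)], grid[min(i + 2, 4095)])
        res = minimize_scalar(lambda p: -self._raw(p), bounds=span, method="bounded",
                              options={"xatol": 1e-14})
        return float(self._raw(res.x)), float(res.x)

    @property
    def systolic_peak_phase(self) -> float:
        return self._norm[1]

    def shape(self, t) -> np.ndarray:
        """Normalised waveform (max 1) evaluated at time t (s), periodic."""
        t = np.asarray(t, dtype=float)
        return self._raw(t / self.cycle_duration_s) / self._norm[0]

    @cached_property
    def shape_mean(self) -> float:
        phi = np.linspace(0.0, 1.0, 8192, endpoint=False)
        return float(np.mean(self._raw(phi))) / self._norm[0]

    @cached_property
    def shape_weighted_mean(self) -> float:
        """Flow-weighted mean of the shape, int s^2 / int s."""
        phi = np.linspace(0.0, 1.0, 8192, endpoint=False)
        s = self._raw(phi) / self._norm[0]
        return float(np.sum(s * s) / np.sum(s))

    def velocity(self, t) -> np.ndarray:
        return self.peak_velocity * self.shape(t)

    # -- dimensionless numbers --------------------------------------------
    def reynolds(self, fluid: FluidProperties, vessel_diameter_mm: float) -> float:
        """Peak Reynolds number Re = U_peak D / nu."""
        return self.peak_velocity * vessel_diameter_mm * 1e-3 / fluid.kinematic_viscosity

    def womersley(self, fluid: FluidProperties, vessel_diameter_mm: float) -> float:
        """Wo = (D/2) sqrt(2 pi / (T nu))."""
        radius = 0.5 * vessel_diameter_mm * 1e-3
        return radius * np.sqrt(2.0 * np.pi / (self.cycle_duration_s * fluid.kinematic_viscosity))

    @classmethod
    def from_reynolds(cls, re_max: float, fluid: FluidProperties,
                      vessel_diameter_mm: float, cycle_duration_s: float = 1.0,
                      **kwargs) -> "WaveformConfig":
        u_peak = re_max * fluid.kinematic_viscosity / (vessel_diameter_mm * 1e-3)
        return cls(cycle_duration_s=cycle_duration_s, peak_velocity=u_peak, **kwargs)

    @classmethod
    def from_womersley(cls, re_max: float, womersley: float, fluid: FluidProperties,
                       vessel_diameter_mm: float, **kwargs) -> "WaveformConfig":
        """Choose T so that both the target Re and Wo hold simultaneously."""
        radius = 0.5 * vessel_diameter_mm * 1e-3
        T = 2.0 * np.pi * radius ** 2 / (fluid.kinematic_viscosity * womersley ** 2)
        return cls.from_reynolds(re_max, fluid, vessel_diameter_mm, cycle_duration_s=T, **kwargs)


@dataclass(frozen=True)
class ScenarioConfig:
    """Parametric emulation of one flow-diverter deployment.

    alpha            fraction of in-sac in-plane velocity removed (0 = untreated)
    jet_entry_shift  shift of the jet entry along the wall, mm, proximal negative
    oop_fluctuation  std of the out-of-plane disturbance as a fraction of the
                     local cycle-mean speed (sigma_z)
    peak_damping     extra attenuation at peak systole relative to the cycle
                     mean (negative = peak less attenuated than the mean)
    interframe_us    double-frame interframe time at the reference
                     magnification of 8.8125 um/px
    """

    scenario_id: str
    alpha: float = 0.0
    jet_entry_shift_mm: float = 0.0
    oop_fluctuation: float = 0.036
    peak_damping: float = 0.0
    interframe_us: float = 200.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError("attenuation alpha must lie in [0, 1)")
        if self.oop_fluctuation < 0:
            raise ValueError("oop fluctuation must be non-negative")
        if self.interframe_us <= 0:
            raise ValueError("interframe time must be positive")


#: Baseline out-of-plane fluctuation level of the untreated configuration.
BASELINE_OOP = 0.036

#: Named deployment scenarios.  alpha and oop_fluctuation are calibrated once
#: against the measured treated/untreated velocity table of the reference
#: experiment; peak_damping encodes the stronger device effect at peak systole.
SCENARIO_PRESETS: Mapping[str, ScenarioConfig] = {
    "noFD": ScenarioConfig("noFD", alpha=0.0, oop_fluctuation=BASELINE_OOP,
                           peak_damping=0.0, interframe_us=200.0),
    "FDC1": ScenarioConfig("FDC1", alpha=0.78, oop_fluctuation=0.052,
                           peak_damping=0.0727, interframe_us=800.0),
    "FDC2": ScenarioConfig("FDC2", alpha=0.82, jet_entry_shift_mm=-1.5,
                           oop_fluctuation=0.045, peak_damping=0.0370,
                           interframe_us=800.0),
    "FDC3": ScenarioConfig("FDC3", alpha=0.89, oop_fluctuation=0.364,
                           peak_damping=-0.0171, interframe_us=900.0),
    "FDC4": ScenarioConfig("FDC4", alpha=0.64, oop_fluctuation=0.368,
                           peak_damping=0.1499, interframe_us=500.0),
}


# --------------------------------------------------------------------------
# geometry rasterisation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Geometry:
    """Rasterised masks and landmarks of the phantom plane."""

    config: GeometryConfig
    x: np.ndarray                 # 1-D cell centres, mm
    y: np.ndarray
    sac_mask: np.ndarray          # 2-D bool, (ny, nx)
    vessel_mask: np.ndarray
    lumen_mask: np.ndarray
    roi_mask: np.ndarray          # sac interior eroded by roi_erosion_mm
    wall_points: np.ndarray       # (K, 2) points on the no-slip contour
    ostium_mm: tuple[tuple[float, float], tuple[float, float]]
    probes: Mapping[str, tuple[float, float]]


def build_geometry(config: GeometryConfig) -> Geometry:
    """Rasterise masks, wall contour, ostium segment and probe locations.

    Probes: P1 sits in the inflow-jet region just inside the distal ostium
    edge, P2 two millimetres below the dome apex, P3 just inside the
    proximal ostium edge.  All three are geometric landmarks, declared
    assumptions of the phantom.
    """
    cfg = config
    xmin, xmax, ymin, ymax = cfg.extent_mm
    h = cfg.pitch_mm
    x = np.arange(xmin + h / 2, xmax, h)
    y = np.arange(ymin + h / 2, ymax, h)
    X, Y = np.meshgrid(x, y)

    cx, cy = cfg.sac_center_mm
    R = cfg.sac_radius_mm
    D = cfg.vessel_diameter_mm
    wo = 0.5 * cfg.ostium_width_mm

    r2 = (X - cx) ** 2 + (Y - cy) ** 2
    sac = (r2 < R * R) & (Y > 0)
    vessel = (Y < 0) & (Y > -D)
    lumen = sac | vessel

    er = cfg.roi_erosion_mm
    roi = (r2 < (R - er) ** 2) & (Y > er)

    # no-slip contour: sac arc above y=0 plus vessel walls outside the ostium
    theta = np.linspace(0.0, 2.0 * np.pi, 720, endpoint=False)
    arc = np.stack([cx + R * np.cos(theta), cy + R * np.sin(theta)], axis=1)
    arc = arc[arc[:, 1] > 0.0]
    xs = np.arange(xmin, xmax, h)
    top = np.stack([xs, np.zeros_like(xs)], axis=1)
    top = top[np.abs(top[:, 0]) >= wo]
    bottom = np.stack([xs, np.full_like(xs, -D)], axis=1)
    wall = np.concatenate([arc, top, bottom], axis=0)

    probes = {
        "P1": (wo - 1.0, 2.0),
        "P2": (0.0, cy + R - 2.0),
        "P3": (-wo + 1.0, 2.0),
    }
    return Geometry(config=cfg, x=x, y=y, sac_mask=sac, vessel_mask=vessel,
                    lumen_mask=lumen, roi_mask=roi, wall_points=wall,
                    ostium_mm=((-wo, 0.0), (wo, 0.0)), probes=probes)


# --------------------------------------------------------------------------
# flow model
# --------------------------------------------------------------------------

def _vortex_profile_deriv(s: np.ndarray) -> np.ndarray:
    # f_v(s) = (1-s^2)^2 (1/2 + s^2);  f_v'(s) = -6 s^3 (1 - s^2)
    return -6.0 * s ** 3 * (1.0 - s ** 2)


def _jet_profile(s: np.ndarray) -> np.ndarray:
    return s ** 2 * (1.0 - s ** 2) ** 2


def _jet_profile_deriv(s: np.ndarray) -> np.ndarray:
    return 2.0 * s * (1.0 - s ** 2) * (1.0 - 3.0 * s ** 2)


_S_GRID = np.linspace(0.0, 1.0, 4001)
_FV_MAX = float(np.max(np.abs(_vortex_profile_deriv(_S_GRID))))
_FJ_MAX = float(np.max(np.abs(_jet_profile_deriv(_S_GRID))))

#: low-discrepancy cycle strides (frac(sqrt(prime))) for the disturbance modes
_PRIMES = (2, 3, 5, 7, 11, 13, 17, 19, 23, 29, 31, 37, 41, 43, 47, 53,
           59, 61, 67, 71, 73, 79, 83, 89, 97, 101, 103, 107, 109, 113, 127, 131)


@dataclass(frozen=True)
class AneurysmFlowModel:
    """Closed-form time-dependent velocity field of the phantom.

    The in-plane field factorises into a spatial shape times the waveform,
    so cycle means have closed form.  The out-of-plane disturbance is a sum
    of sac-scale travelling modes whose per-cycle temporal phases follow a
    golden-ratio stride: the disturbance is zero-mean over the recorded
    cycle ensemble and its realised cycle-to-cycle spread matches the
    configured level without iid sampling noise (see docs/methods.md).
    """

    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    fluid: FluidProperties = field(default_factory=FluidProperties)
    waveform: WaveformConfig = field(default_factory=WaveformConfig)
    sac_strength: float = 0.3        # peak in-sac rotating-cell speed / U_peak
    jet_strength: float = 1.2        # jet enhancement relative to the cell
    jet_width_deg: float = 35.0      # azimuthal Gaussian width of the jet
    slab_thickness_mm: float = 1.0   # illuminated light-sheet slab
    scenario: ScenarioConfig | None = None
    seed: int = 0
    oop_modes: int = 12
    oop_wavelength_mm: tuple[float, float] = (10.0, 20.0)

    # -- scenario handling -------------------------------------------------
    def apply_scenario(self, scenario: ScenarioConfig | str) -> "AneurysmFlowModel":
        """Return a copy with the deployment scenario applied (once)."""
        if self.scenario is not None:
            raise ValueError("a scenario has already been applied to this model")
        if isinstance(scenario, str):
            scenario = SCENARIO_PRESETS[scenario]
        return dataclasses.replace(self, scenario=scenario)

    # -- geometric helpers -------------------------------------------------
    @property
    def _sac(self) -> tuple[float, float, float, float]:
        cfg = self.geometry
        cx, cy = cfg.sac_center_mm
        return cx, cy, cfg.sac_radius_mm, 0.5 * cfg.ostium_width_mm

    @property
    def jet_angle_rad(self) -> float:
        """Azimuth (about the sac centre) of the jet entry point."""
        cx, cy, R, wo = self._sac
        base = float(np.arctan2(0.0 - cy, wo - cx))
        shift = self.scenario.jet_entry_shift_mm if self.scenario else 0.0
        return base + shift / R

    def in_lumen(self, points: np.ndarray) -> np.ndarray:
        """Vectorised lumen membership for (..., 2|3) mm coordinates."""
        pts = np.asarray(points, dtype=float)
        x, yy = pts[..., 0], pts[..., 1]
        cx, cy, R, wo = self._sac
        D = self.geometry.vessel_diameter_mm
        xmin, xmax, _, _ = self.geometry.extent_mm
        in_x = (x >= xmin) & (x <= xmax)
        sac = ((x - cx) ** 2 + (yy - cy) ** 2 < R * R) & \
            ((yy > 0) | ((yy == 0) & (np.abs(x) < wo)))
        vessel = (yy < 0) & (yy > -D) & in_x
        inside = sac | vessel
        if pts.shape[-1] >= 3:
            inside = inside & (np.abs(pts[..., 2]) <= 0.5 * self.slab_thickness_mm)
        return inside

    # -- spatial unit field ------------------------------------------------
    def _unit_inplane(self, x: np.ndarray, yy: np.ndarray):
        """In-plane velocity shape at unit waveform multiplier.

        Returns (u, v, region) with region 0 outside, 1 vessel, 2 sac.
        The sac shape carries no attenuation; the vessel shape is the
        Poiseuille profile at unit centreline speed.
        """
        cx, cy, R, wo = self._sac
        D = self.geometry.vessel_diameter_mm
        u = np.zeros_like(x)
        v = np.zeros_like(x)
        region = np.zeros(x.shape, dtype=np.uint8)

        vessel = (yy < 0) & (yy > -D)
        yc = -0.5 * D
        u[vessel] = 1.0 - ((yy[vessel] - yc) / (0.5 * D)) ** 2
        region[vessel] = 1

        xi = x - cx
        eta = yy - cy
        r = np.hypot(xi, eta)
        sac = (r < R) & ((yy > 0) | ((yy == 0) & (np.abs(x) < wo)))
        if np.any(sac):
            s = r[sac] / R
            theta = np.arctan2(eta[sac], xi[sac])
            sig = np.deg2rad(self.jet_width_deg)
            dth = (theta - self.jet_angle_rad + np.pi) % (2.0 * np.pi) - np.pi
            g = np.exp(-0.5 * (dth / sig) ** 2)
            gp = -dth / sig ** 2 * g

            psi_v = self.sac_strength / _FV_MAX          # cell amplitude
            psi_j = self.jet_strength * self.sac_strength / _FJ_MAX
            u_theta = -(psi_v * _vortex_profile_deriv(s)
                        + psi_j * _jet_profile_deriv(s) * g)
            with np.errstate(invalid="ignore", divide="ignore"):
                u_rad = np.where(s > 0, psi_j * _jet_profile(s) / np.maximum(s, 1e-300) * gp, 0.0)
            ct, st = np.cos(theta), np.sin(theta)
            u[sac] = u_rad * ct - u_theta * st
            v[sac] = u_rad * st + u_theta * ct
            region[sac] = 2
        return u, v, region

    # -- time factors ------------------------------------------------------
    def _sac_factor(self, t) -> np.ndarray:
        """In-sac velocity multiplier U_peak * shape * attenuation(t).

        The peak-damping term is constructed to leave the flow-weighted
        cycle mean exactly (1 - alpha) times the untreated one while
        scaling the peak-systolic value by (1 - alpha)(1 - peak_damping).
        """
        wf = self.waveform
        s = wf.shape(t)
        factor = wf.peak_velocity * s
        if self.scenario is not None:
            sc = self.scenario
            att = 1.0 - sc.alpha
            if sc.peak_damping != 0.0:
                sbar = wf.shape_weighted_mean
                att = att * (1.0 - sc.peak_damping * (s - sbar) / (1.0 - sbar))
            factor = factor * att
        return factor

    # -- out-of-plane disturbance -----------------------------------------
    @cached_property
    def _oop_mode_table(self):
        K = self.oop_modes
        if K > len(_PRIMES):
            raise ValueError(f"at most {len(_PRIMES)} out-of-plane modes supported")
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 9001]))
        delta = rng.uniform(0.0, 2.0 * np.pi, K)
        freqs = 2.0 + np.arange(K)
        lam = np.geomspace(self.oop_wavelength_mm[0], self.oop_wavelength_mm[1], K)
        ang = 2.0 * np.pi * np.arange(K) / K + 0.3
        kx = 2.0 * np.pi / lam * np.cos(ang)
        ky = 2.0 * np.pi / lam * np.sin(ang)
        stride = np.sqrt(np.asarray(_PRIMES[:K], dtype=float)) % 1.0
        return freqs, kx, ky, delta, stride

    def _oop_velocity(self, x, yy, region, t: float, cycle: int) -> np.ndarray:
        sc = self.scenario
        w = np.zeros_like(x)
        if sc is None or sc.oop_fluctuation == 0.0:
            return w
        sac = region == 2
        if not np.any(sac):
            return w
        umean = self.cycle_mean_speed_inplane(x[sac], yy[sac])
        freqs, kx, ky, delta, stride = self._oop_mode_table
        T = self.waveform.cycle_duration_s
        acc = np.zeros(umean.shape)
        for f, kxi, kyi, d, st in zip(freqs, kx, ky, delta, stride):
            phase_c = 2.0 * np.pi * ((cycle * st) % 1.0)
            acc += np.sin(2.0 * np.pi * f * t / T + kxi * x[sac] + kyi * yy[sac]
                          + phase_c + d)
        w[sac] = sc.oop_fluctuation * umean * np.sqrt(2.0 / len(freqs)) * acc
        return w

    # -- public sampling ---------------------------------------------------
    def cycle_mean_speed_inplane(self, x, yy) -> np.ndarray:
        """Closed-form cycle-mean in-plane speed (scenario attenuation included)."""
        x = np.asarray(x, dtype=float)
        yy = np.asarray(yy, dtype=float)
        u, v, region = self._unit_inplane(x, yy)
        speed = np.hypot(u, v) * self.waveform.peak_velocity * self.waveform.shape_mean
        if self.scenario is not None:
            speed = np.where(region == 2, speed * (1.0 - self.scenario.alpha), speed)
        return speed

    def sample_velocity(self, points: np.ndarray, t: float, cycle: int = 0):
        """Evaluate the 3-component velocity (m/s) at mm positions.

        Returns ``(vel, inside)``; points outside the lumen or the light
        sheet slab get zero velocity and ``inside=False`` (no exception).
        Periodic in t with the cycle duration, deterministic for fixed
        (model, points, t, cycle).
        """
        pts = np.asarray(points, dtype=float)
        if not np.all(np.isfinite(pts)):
            raise ValueError("sample points must be finite")
        squeeze = pts.ndim == 1
        pts = np.atleast_2d(pts)
        x, yy = pts[:, 0].copy(), pts[:, 1].copy()

        u, v, region = self._unit_inplane(x, yy)
        wf_vessel = self.waveform.velocity(t)
        factor = np.where(region == 2, self._sac_factor(t), wf_vessel)
        vel = np.zeros((pts.shape[0], 3))
        vel[:, 0] = u * factor
        vel[:, 1] = v * factor
        vel[:, 2] = self._oop_velocity(x, yy, region, float(t), int(cycle))

        inside = self.in_lumen(pts if pts.shape[1] >= 3 else
                               np.column_stack([x, yy, np.zeros_like(x)]))
        vel[~inside] = 0.0
        if squeeze:
            return vel[0], bool(inside[0])
        return vel, inside

    # -- documentation helpers --------------------------------------------
    def reynolds(self) -> float:
        return self.waveform.reynolds(self.fluid, self.geometry.vessel_diameter_mm)

    def womersley(self) -> float:
        return self.waveform.womersley(self.fluid, self.geometry.vessel_diameter_mm)


def default_model(re_max: float = 1025.0, cycle_duration_s: float = 1.0,
                  seed: int = 0, **kwargs) -> AneurysmFlowModel:
    """Model with default geometry/fluid and U_peak set from the target Re."""
    fluid = FluidProperties()
    geometry = GeometryConfig()
    waveform = WaveformConfig.from_reynolds(re_max, fluid,
                                            geometry.vessel_diameter_mm,
                                            cycle_duration_s=cycle_duration_s)
    return AneurysmFlowModel(geometry=geometry, fluid=fluid, waveform=waveform,
                             seed=seed, **kwargs)
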