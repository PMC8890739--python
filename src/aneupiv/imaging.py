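"""Virtual stereo imaging: tracer ensembles, cameras, particle images.

Tracers are ideal (no inertia or slip; the Stokes number of 10 um spheres in
the blood-analogue liquid is far below one).  Each particle is rendered as a
2-D Gaussian spot on a virtual sCMOS sensor; two cameras observe the light
sheet from symmetric off-axis directions, providing the parallax used for
three-component reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .phantom import AneurysmFlowModel

__all__ = [
    "ParticleEnsemble",
    "CameraModel",
    "make_stereo_pair",
    "ImagePair",
    "seed_particles",
    "advect_particles",
    "render_image_pair",
]


@dataclass(frozen=True)
class ParticleEnsemble:
    """Tracer particles in a thin slab around the sagittal plane."""

    positions_mm: np.ndarray       # (N, 3)
    diameter_px: np.ndarray        # (N,) rendered e^-2 image diameter
    seeding_density_mm2: float
    seed: int

    def __post_init__(self) -> None:
        if self.positions_mm.ndim != 2 or self.positions_mm.shape[1] != 3:
            raise ValueError("positions must have shape (N, 3)")
        if len(self.diameter_px) != len(self.positions_mm):
            raise ValueError("one diameter per particle required")

    def __len__(self) -> int:
        return len(self.positions_mm)


def seed_particles(model: AneurysmFlowModel, density_mm2: float, seed: int,
                   diameter_px: float = 2.5, diameter_jitter_px: float = 0.1,
                   bbox_mm: tuple[float, float, float, float] | None = None) -> ParticleEnsemble:
    """Uniform random seeding of the lumen slab, reproducible from seed.

    ``density_mm2`` counts particles per mm^2 of in-plane lumen area (the
    full slab thickness projects onto the plane).
    """
    if density_mm2 <= 0:
        raise ValueError("seeding density must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1301]))
    xmin, xmax, ymin, ymax = bbox_mm if bbox_mm is not None else model.geometry.extent_mm
    half_slab = 0.5 * model.slab_thickness_mm

    # estimate lumen area fraction of the bbox once, then rejection-sample
    probe = rng.uniform([xmin, ymin], [xmax, ymax], size=(4096, 2))
    frac = float(np.mean(model.in_lumen(probe)))
    area = (xmax - xmin) * (ymax - ymin)
    n_target = int(round(density_mm2 * area * max(frac, 1e-3)))

    pts = np.empty((0, 3))
    while len(pts) < n_target:
        n_draw = max(int((n_target - len(pts)) / max(frac, 0.05) * 1.2), 64)
        cand = np.column_stack([
            rng.uniform(xmin, xmax, n_draw),
            rng.uniform(ymin, ymax, n_draw),
            rng.uniform(-half_slab, half_slab, n_draw),
        ])
        cand = cand[model.in_lumen(cand)]
        pts = np.vstack([pts, cand])
    pts = pts[:n_target]
    # floor at 2 px: the renderer rejects smaller spots (peak locking)
    dia = np.clip(rng.normal(diameter_px, diameter_jitter_px, len(pts)), 2.0, None)
    return ParticleEnsemble(pts, dia, density_mm2, int(seed))


def advect_particles(particles: ParticleEnsemble, model: AneurysmFlowModel,
                     t: float, dt: float, cycle: int = 0, respawn: bool = True,
                     n_substeps: int = 1) -> ParticleEnsemble:
    """Advance tracers through the flow map with classic RK4.

    ``dt`` is in seconds.  Particles that leave the lumen are respawned at
    the inlet (preserving the count) when ``respawn`` is true, drawing from
    a dedicated stream of the ensemble seed so the operation stays
    deterministic.
    """
    pos = particles.positions_mm.astype(float).copy()
    h = dt / n_substeps

    def vel(p, tt):
        v, _ = model.sample_velocity(p, tt, cycle=cycle)
        if not np.all(np.isfinite(v)):
            raise FloatingPointError("non-finite velocity during advection")
        return v * 1e3  # m/s -> mm/s

    tt = t
    for _ in range(n_substeps):
        k1 = vel(pos, tt)
        k2 = vel(pos + 0.5 * h * k1, tt + 0.5 * h)
        k3 = vel(pos + 0.5 * h * k2, tt + 0.5 * h)
        k4 = vel(pos + h * k3, tt + h)
        pos = pos + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        tt += h

    if respawn:
        lost = ~model.in_lumen(pos)
        if np.any(lost):
            rng = np.random.default_rng(
                np.random.SeedSequence([particles.seed, 2903, int(cycle)]))
            n = int(np.sum(lost))
            xmin = model.geometry.extent_mm[0]
            D = model.geometry.vessel_diameter_mm
            half_slab = 0.5 * model.slab_thickness_mm
            pos[lost] = np.column_stack([
                rng.uniform(xmin, xmin + 1.0, n),
                rng.uniform(-D + 1e-3, -1e-3, n),
                rng.uniform(-half_slab, half_slab, n),
            ])
    return replace(particles, positions_mm=pos)


# --------------------------------------------------------------------------
# cameras
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CameraModel:
    """Telecentric (orthographic) stereo camera.

    The viewing direction is tilted by ``viewing_angle_deg`` about the
    in-plane y axis, so the out-of-plane coordinate z leaks into the sensor
    u coordinate with sensitivity sin(angle) — the basis of the stereo
    reconstruction.  The virtual calibration is exact: ``gradient`` returns
    the mapping Jacobian directly.
    """

    viewing_angle_deg: float
    magnification_um_px: float                  # front-view um per px
    sensor_px: tuple[int, int] = (2160, 2560)   # (rows, cols)
    center_world_mm: tuple[float, float] = (0.0, 0.0)
    camera_id: str = "cam"

    def __post_init__(self) -> None:
        if abs(np.cos(np.deg2rad(self.viewing_angle_deg))) < 1e-6:
            raise ValueError("camera mapping is not invertible at 90 degrees")
        if self.magnification_um_px <= 0:
            raise ValueError("magnification must be positive")

    @property
    def px_per_mm(self) -> float:
        return 1000.0 / self.magnification_um_px

    def project(self, points_mm: np.ndarray) -> np.ndarray:
        """World (x, y, z) mm -> sensor (u, v) px (u = column, v = row)."""
        p = np.atleast_2d(np.asarray(points_mm, dtype=float))
        th = np.deg2rad(self.viewing_angle_deg)
        x0, y0 = self.center_world_mm
        u = (np.cos(th) * (p[:, 0] - x0) - np.sin(th) * p[:, 2]) * self.px_per_mm \
            + 0.5 * self.sensor_px[1]
        v = (p[:, 1] - y0) * self.px_per_mm + 0.5 * self.sensor_px[0]
        return np.column_stack([u, v])

    def back_project(self, uv_px: np.ndarray, z_mm: float = 0.0) -> np.ndarray:
        """Invert the mapping at a known depth plane."""
        uv = np.atleast_2d(np.asarray(uv_px, dtype=float))
        th = np.deg2rad(self.viewing_angle_deg)
        x0, y0 = self.center_world_mm
        x = ((uv[:, 0] - 0.5 * self.sensor_px[1]) / self.px_per_mm
             + np.sin(th) * z_mm) / np.cos(th) + x0
        y = (uv[:, 1] - 0.5 * self.sensor_px[0]) / self.px_per_mm + y0
        return np.column_stack([x, y, np.full(len(uv), z_mm)])

    def gradient(self) -> np.ndarray:
        """d(u, v)/d(x, y, z) in px/mm — exact for the telecentric mapping."""
        th = np.deg2rad(self.viewing_angle_deg)
        return self.px_per_mm * np.array([
            [np.cos(th), 0.0, -np.sin(th)],
            [0.0, 1.0, 0.0],
        ])


def make_stereo_pair(half_angle_deg: float = 35.0, magnification_um_px: float = 8.8125,
                     sensor_px: tuple[int, int] = (2160, 2560),
                     center_world_mm: tuple[float, float] = (0.0, 7.5)):
    """Symmetric +-half_angle stereo camera pair."""
    mk = lambda sgn, name: CameraModel(sgn * half_angle_deg, magnification_um_px,
                                       sensor_px, center_world_mm, name)
    return mk(-1.0, "cam1"), mk(+1.0, "cam2")


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ImagePair:
    """One double-frame recording from one virtual camera."""

    frame_a: np.ndarray
    frame_b: np.ndarray
    interframe_us: float
    camera_id: str = "cam"
    phase_index: int = 0
    cycle_index: int = 0

    def __post_init__(self) -> None:
        if self.frame_a.shape != self.frame_b.shape:
            raise ValueError("double frames must share the sensor shape")
        if self.interframe_us <= 0:
            raise ValueError("interframe time must be positive")
        if np.min(self.frame_a) < 0 or np.min(self.frame_b) < 0:
            raise ValueError("intensities must be non-negative")


def _render_frame(particles: ParticleEnsemble, camera: CameraModel,
                  peak_intensity: float, background: float,
                  noise_level: float, rng: np.random.Generator | None) -> np.ndarray:
    rows, cols = camera.sensor_px
    img = np.zeros((rows, cols))
    uv = camera.project(particles.positions_mm)
    sigma = particles.diameter_px / (2.0 * np.sqrt(2.0))   # e^-2 diameter = 2*sqrt(2)*sigma
    rad = int(np.ceil(4.0 * float(np.max(sigma)))) if len(particles) else 0

    keep = ((uv[:, 0] > -rad) & (uv[:, 0] < cols + rad)
            & (uv[:, 1] > -rad) & (uv[:, 1] < rows + rad))
    uv, sigma = uv[keep], sigma[keep]
    if len(uv):
        off = np.arange(-rad, rad + 1)
        cu = np.round(uv[:, 0]).astype(int)
        cv = np.round(uv[:, 1]).astype(int)
        # (N, P) separable Gaussian stamps
        gx = np.exp(-0.5 * ((cu[:, None] + off[None, :] - uv[:, 0:1]) / sigma[:, None]) ** 2)
        gy = np.exp(-0.5 * ((cv[:, None] + off[None, :] - uv[:, 1:2]) / sigma[:, None]) ** 2)
        stamps = peak_intensity * gy[:, :, None] * gx[:, None, :]
        P = 2 * rad + 1
        iv = np.broadcast_to(cv[:, None, None] + off[None, :, None], (len(uv), P, P))
        iu = np.broadcast_to(cu[:, None, None] + off[None, None, :], (len(uv), P, P))
        ok = (iv >= 0) & (iv < rows) & (iu >= 0) & (iu < cols)
        flat = np.bincount((iv[ok] * cols + iu[ok]).ravel(),
                           weights=stamps[ok].ravel(), minlength=rows * cols)
        img += flat.reshape(rows, cols)

    img += background
    if noise_level > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        img = img + rng.normal(0.0, noise_level, img.shape)
        np.clip(img, 0.0, None, out=img)
    return img


def render_image_pair(particles_t0: ParticleEnsemble, particles_t1: ParticleEnsemble,
                      camera: CameraModel, interframe_us: float,
                      noise_level: float = 0.0, background: float = 100.0,
                      peak_intensity: float = 3000.0,
                      phase_index: int = 0, cycle_index: int = 0) -> ImagePair:
    """Render the double frame for one camera.

    Both ensembles must come from the same seed lineage (frame b is the
    advected copy of frame a).  Gaussian spot diameters below 2 px are
    rejected to avoid peak locking in the downstream correlation.
    """
    if particles_t0.seed != particles_t1.seed:
        raise ValueError("frame ensembles must share their seed lineage")
    if len(particles_t0) and float(np.min(particles_t0.diameter_px)) < 2.0:
        raise ValueError("particle image diameter must be at least 2 px")
    rng = np.random.default_rng(
        np.random.SeedSequence([particles_t0.seed, 4099, cycle_index, phase_index]))
    fa = _render_frame(particles_t0, camera, peak_intensity, background, noise_level, rng)
    fb = _render_frame(particles_t1, camera, peak_intensity, background, noise_level, rng)
    return ImagePair(fa, fb, interframe_us, camera.camera_id, phase_index, cycle_index)
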