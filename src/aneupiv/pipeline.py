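"""End-to-end pipeline: phantom -> particle images -> PIV -> phase average
-> hemodynamic report, with stage caching and a reproducibility manifest.

All randomness derives from one root seed; per-(cycle, phase) particle
streams and camera noise use deterministic child seeds, so two runs with
equal manifests are bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .container import load_cycle, load_cycle_fields, save_cycle, save_cycle_fields
from .cycles import PhaseAveragedCycle, phase_average
from .ensight import write_ensight
from .imaging import advect_particles, make_stereo_pair, render_image_pair, seed_particles
from .metrics import build_report
from .phantom import (SCENARIO_PRESETS, AneurysmFlowModel, GeometryConfig,
                      build_geometry, default_model)
from .piv import PIVConfig, multipass_piv, nan_gaussian_filter, stereo_reconstruct

__all__ = ["RunConfig", "RunResult", "run_scenario", "run_pipeline", "scenario_report"]

logger = logging.getLogger(__name__)

#: reference magnification of the full-scale acquisition, um per px
REFERENCE_MAGNIFICATION_UM_PX = 8.8125


@dataclass(frozen=True)
class RunConfig:
    """One scenario run.  Every default is overridable via YAML."""

    scenario: str = "noFD"
    re_max: float = 1025.0
    cycle_duration_s: float = 1.0
    n_cycles: int = 6
    n_phases: int = 64
    image_px: int = 512
    magnification_um_px: float = 48.0
    camera_half_angle_deg: float = 35.0
    camera_center_mm: tuple[float, float] = (0.0, 7.5)
    seeding_per_px2: float = 0.02
    particle_diameter_px: float = 2.5
    noise_level: float = 2.0
    background: float = 100.0
    interframe_us: float | None = None   # None: preset scaled by magnification
    windows_px: tuple[int, ...] = (64, 32)
    overlap: float = 0.5
    validation_threshold: float = 2.0
    min_peak_ratio: float = 1.15
    w_filter_mm: float = 1.5
    truth_pitch_mm: float = 0.2
    keep_images: bool = False
    export_ensight: bool = False

    # -- derived -----------------------------------------------------------
    def resolve_interframe_us(self) -> float:
        """Interframe time; presets are quoted at the reference magnification
        and scaled with pixel pitch to preserve the displacement dynamic
        range when the virtual sensor is coarser."""
        if self.interframe_us is not None:
            return self.interframe_us
        preset = SCENARIO_PRESETS[self.scenario].interframe_us
        return preset * self.magnification_um_px / REFERENCE_MAGNIFICATION_UM_PX

    def piv_config(self) -> PIVConfig:
        return PIVConfig(windows_px=tuple(self.windows_px), overlap=self.overlap,
                         validation_threshold=self.validation_threshold,
                         min_peak_ratio=self.min_peak_ratio)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["camera_center_mm"] = list(d["camera_center_mm"])
        d["windows_px"] = list(d["windows_px"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "camera_center_mm" in d:
            d["camera_center_mm"] = tuple(d["camera_center_mm"])
        if "windows_px" in d:
            d["windows_px"] = tuple(d["windows_px"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


#: declared assumptions recorded in every run manifest
ASSUMPTIONS = (
    "cycle duration T = 1.0 s (not printed; implied Womersley reported)",
    "reference magnification 8.8125 um/px (16 px vector pitch = 141 um)",
    "probe locations are geometric landmarks (jet, dome apex, proximal ostium)",
    "parent vessel treated as locally straight in the measurement plane",
)


@dataclass
class RunResult:
    config: RunConfig
    seed: int
    x_mm: np.ndarray
    y_mm: np.ndarray
    pac: PhaseAveragedCycle
    truth_pac: PhaseAveragedCycle
    roi_mask: np.ndarray
    lumen_mask: np.ndarray
    probes: dict
    oop_noise_std: np.ndarray | None = None   # (M, ny, nx) m/s
    paths: dict = field(default_factory=dict)
    status: dict = field(default_factory=dict)


def estimate_oop_noise_floor(fields: np.ndarray, half_angle_deg: float,
                             w_filter_mm: float, grid_step_mm: float) -> np.ndarray:
    """Out-of-plane measurement noise floor from the in-plane residuals.

    With a trigger-locked pump the in-plane flow is phase-locked, so the
    cycle-to-cycle residual of the measured u component is pure correlation
    noise.  For a symmetric stereo pair the out-of-plane noise equals the
    in-plane (u) noise times cot(half angle), with the same spatial
    correlation structure; applying the same low-pass used on U_z to the
    residuals therefore reproduces the filtered U_z noise statistics.
    Returns the per-(phase, point) noise std of the U_z channel.
    """
    u = np.asarray(fields, dtype=float)[..., 0]          # (N, M, ny, nx)
    res = u - u.mean(axis=0, keepdims=True)
    if w_filter_mm > 0:
        sig = w_filter_mm / grid_step_mm
        res = np.stack([np.stack([nan_gaussian_filter(res[c, m], sig)
                                  for m in range(res.shape[1])])
                        for c in range(res.shape[0])])
    s = res.std(axis=0, ddof=1)
    return s / np.tan(np.deg2rad(half_angle_deg))


def _child_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2 ** 31))


def _config_key(config: RunConfig, seed: int, stage: str) -> str:
    blob = json.dumps({"config": config.to_dict(), "seed": seed, "stage": stage,
                       "version": __version__}, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()


def _stage_cached(outdir: Path, stage: str, key: str, products: list[Path]) -> bool:
    mpath = outdir / f"{stage}.manifest.json"
    if not mpath.exists() or not all(p.exists() for p in products):
        return False
    try:
        return json.loads(mpath.read_text()).get("key") == key
    except json.JSONDecodeError:
        return False


def _stage_done(outdir: Path, stage: str, key: str, seconds: float) -> None:
    (outdir / f"{stage}.manifest.json").write_text(
        json.dumps({"key": key, "elapsed_s": round(seconds, 3)}))


def build_run_model(config: RunConfig, seed: int) -> AneurysmFlowModel:
    geometry = GeometryConfig(pitch_mm=config.truth_pitch_mm)
    model = default_model(re_max=config.re_max,
                          cycle_duration_s=config.cycle_duration_s,
                          seed=seed)
    model = dataclasses.replace(model, geometry=geometry)
    return model.apply_scenario(config.scenario)


def _reconstruction_grid(config: RunConfig, cam) -> tuple[np.ndarray, np.ndarray]:
    """World grid of the final vector spacing, covering the field of view."""
    pitch_px = int(round(config.windows_px[-1] * (1.0 - config.overlap)))
    half = config.windows_px[-1] // 2
    centers = np.arange(half, config.image_px - half + 1, pitch_px, dtype=float)
    p = cam.back_project(np.column_stack([centers, centers]))
    # use the frontal (y) scale for both axes so the grid is isotropic
    y = p[:, 1]
    x = y - np.mean(y) + np.mean(p[:, 0])
    return x, y


def run_scenario(config: RunConfig, seed: int, outdir: str | Path | None = None,
                 progress: bool = False) -> RunResult:
    """Run one scenario end to end (streaming images in memory).

    When ``outdir`` is given, stage products (truth.h5, fields.h5, pac.h5,
    report.json, manifest.yaml) are written and reused if their manifest
    keys match (caching); otherwise everything stays in memory.
    """
    model = build_run_model(config, seed)
    sc = model.scenario
    cam1, cam2 = make_stereo_pair(config.camera_half_angle_deg,
                                  config.magnification_um_px,
                                  (config.image_px, config.image_px),
                                  config.camera_center_mm)
    dt_us = config.resolve_interframe_us()
    dt_s = dt_us * 1e-6
    M, N = config.n_phases, config.n_cycles
    T = config.cycle_duration_s
    pivcfg = config.piv_config()
    density_mm2 = config.seeding_per_px2 * (1000.0 / config.magnification_um_px) ** 2

    xg, yg = _reconstruction_grid(config, cam1)
    X, Y = np.meshgrid(xg, yg)
    pts_grid = np.column_stack([X.ravel(), Y.ravel()])
    lumen = model.in_lumen(pts_grid).reshape(X.shape)
    cfg_g = model.geometry
    cx, cy = cfg_g.sac_center_mm
    er = cfg_g.roi_erosion_mm
    roi = (((X - cx) ** 2 + (Y - cy) ** 2 < (cfg_g.sac_radius_mm - er) ** 2)
           & (Y > er))

    out = Path(outdir) if outdir is not None else None
    status: dict[str, str] = {}
    paths: dict[str, Path] = {}
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        _write_run_manifest(out, config, seed)
        paths = {"truth": out / "truth.h5", "fields": out / "fields.h5",
                 "pac": out / "pac.h5", "report": out / "report.json",
                 "manifest": out / "manifest.yaml"}

    # ---- stage 1: ground truth -------------------------------------------
    key = _config_key(config, seed, "simulate")
    t0 = time.perf_counter()
    if out is not None and _stage_cached(out, "simulate", key, [paths["truth"]]):
        status["simulate"] = "cached"
        truth_pac, _ = load_cycle(paths["truth"])
    else:
        truth = np.empty((N, M, len(yg), len(xg), 3), dtype=np.float32)
        pts3 = np.column_stack([pts_grid, np.zeros(len(pts_grid))])
        for c in range(N):
            for m in range(M):
                t_mid = (m / M) * T + 0.5 * dt_s
                vel, _ = model.sample_velocity(pts3, t_mid, cycle=c)
                vel[~lumen.ravel()] = np.nan
                truth[c, m] = vel.reshape(len(yg), len(xg), 3)
        truth_pac = phase_average(truth, T, xg, yg)
        if out is not None:
            wf = model.waveform.shape(np.arange(M) / M * T)
            save_cycle(paths["truth"], truth_pac, mask=lumen, waveform=wf,
                       scenario=config.scenario, seed=seed)
            _stage_done(out, "simulate", key, time.perf_counter() - t0)
            status["simulate"] = "computed"

    # ---- stage 2: imaging + PIV ------------------------------------------
    key = _config_key(config, seed, "piv")
    t0 = time.perf_counter()
    if out is not None and _stage_cached(out, "piv", key, [paths["fields"]]):
        status["piv"] = "cached"
        fields, _, _, _ = load_cycle_fields(paths["fields"])
    else:
        masks = {}
        for cam in (cam1, cam2):
            uu, vv = np.meshgrid(np.arange(config.image_px, dtype=float),
                                 np.arange(config.image_px, dtype=float))
            world = cam.back_project(np.column_stack([uu.ravel(), vv.ravel()]))
            masks[cam.camera_id] = model.in_lumen(world[:, :2]).reshape(uu.shape)

        img_dir = out / "images" if (out is not None and config.keep_images) else None
        if img_dir is not None:
            img_dir.mkdir(exist_ok=True)

        fields = np.empty((N, M, len(yg), len(xg), 3), dtype=np.float32)
        n_pairs = 0
        for c in range(N):
            for m in range(M):
                t = (m / M) * T
                p0 = seed_particles(model, density_mm2,
                                    seed=_child_seed(seed, 101, c, m),
                                    diameter_px=config.particle_diameter_px)
                p1 = advect_particles(p0, model, t, dt_s, cycle=c)
                disp = {}
                for cam in (cam1, cam2):
                    pair = render_image_pair(p0, p1, cam, dt_us,
                                             noise_level=config.noise_level,
                                             background=config.background,
                                             phase_index=m, cycle_index=c)
                    if img_dir is not None:
                        _write_tiffs(img_dir, config.scenario, c, m, cam.camera_id, pair)
                    disp[cam.camera_id] = multipass_piv(pair, pivcfg,
                                                        mask=masks[cam.camera_id])
                vf = stereo_reconstruct(disp["cam1"], disp["cam2"], cam1, cam2,
                                        dt_us, grid_mm=(xg, yg),
                                        w_filter_mm=config.w_filter_mm,
                                        phase_index=m, cycle_index=c)
                fields[c, m] = vf.velocity
                n_pairs += 2
            if progress:
                logger.info("scenario %s: cycle %d/%d done (%d image pairs)",
                            config.scenario, c + 1, N, n_pairs)
        if out is not None:
            save_cycle_fields(paths["fields"], fields, xg, yg, T,
                              scenario=config.scenario, seed=seed)
            _stage_done(out, "piv", key, time.perf_counter() - t0)
            status["piv"] = "computed"

    oop_noise = estimate_oop_noise_floor(fields, config.camera_half_angle_deg,
                                         config.w_filter_mm,
                                         float(np.mean(np.diff(xg))))

    # ---- stage 3: phase average ------------------------------------------
    key = _config_key(config, seed, "phase_average")
    t0 = time.perf_counter()
    if out is not None and _stage_cached(out, "phase_average", key, [paths["pac"]]):
        status["phase_average"] = "cached"
        pac, _ = load_cycle(paths["pac"])
    else:
        pac = phase_average(np.asarray(fields, dtype=float), T, xg, yg)
        if out is not None:
            save_cycle(paths["pac"], pac, mask=lumen, scenario=config.scenario, seed=seed,
                       extra={"oop_noise": np.nan_to_num(oop_noise)})
            _stage_done(out, "phase_average", key, time.perf_counter() - t0)
            status["phase_average"] = "computed"
            if config.export_ensight:
                write_ensight(out / f"{config.scenario}_pac", xg, yg, pac.mean,
                              pac.phase_times_s)

    # ---- stage 4: single-scenario metrics --------------------------------
    probes = {k: v for k, v in build_geometry(model.geometry).probes.items()}
    key = _config_key(config, seed, "metrics")
    t0 = time.perf_counter()
    if out is not None and _stage_cached(out, "metrics", key, [paths["report"]]):
        status["metrics"] = "cached"
    else:
        report = build_report({config.scenario: pac}, roi, probes,
                              untreated=config.scenario)
        if out is not None:
            report.to_json(paths["report"])
            _stage_done(out, "metrics", key, time.perf_counter() - t0)
            status["metrics"] = "computed"

    return RunResult(config=config, seed=seed, x_mm=xg, y_mm=yg, pac=pac,
                     truth_pac=truth_pac, roi_mask=roi, lumen_mask=lumen,
                     probes=probes, oop_noise_std=oop_noise,
                     paths={k: str(v) for k, v in paths.items()},
                     status=status)


def _write_tiffs(img_dir: Path, scenario: str, cycle: int, phase: int,
                 cam_id: str, pair) -> None:
    import tifffile
    for frame, tag in ((pair.frame_a, "a"), (pair.frame_b, "b")):
        name = f"{scenario}_{cycle:03d}_{phase:04d}_{cam_id}{tag}.tif"
        tifffile.imwrite(img_dir / name,
                         np.clip(frame, 0, 65535).astype(np.uint16))


def _write_run_manifest(outdir: Path, config: RunConfig, seed: int) -> None:
    manifest = {
        "config": config.to_dict(),
        "seed": seed,
        "version": __version__,
        "assumptions": list(ASSUMPTIONS),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def run_pipeline(config: RunConfig, seed: int, outdir: str | Path,
                 progress: bool = False) -> RunResult:
    """`run_scenario` with mandatory on-disk stage products."""
    return run_scenario(config, seed, outdir=outdir, progress=progress)


def scenario_report(results: dict[str, RunResult], untreated: str = "noFD"):
    """Cross-scenario report from in-memory results (shared grid assumed)."""
    ref = results[untreated]
    pacs = {k: r.pac for k, r in results.items()}
    noise = {k: r.oop_noise_std for k, r in results.items()
             if r.oop_noise_std is not None}
    return build_report(pacs, ref.roi_mask, ref.probes, untreated=untreated,
                        oop_noise=noise or None)
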