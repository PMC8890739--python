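"""Multi-pass cross-correlation PIV and stereoscopic 3C reconstruction.

The correlator follows standard practice: mean-subtracted FFT
cross-correlation per interrogation window, coarse-to-fine passes with
integer window offsetting, three-point Gaussian sub-pixel peak fitting, and
a normalized-median outlier test with neighbourhood-median replacement.
Interrogation windows are Hann-weighted by default (suppresses the
loss-of-pairs bias of particle images truncated at window edges); the
recovered field remains the true displacement convolved with the window
response.

Stereo reconstruction consumes the exact mapping gradients of the virtual
cameras (no calibration-plate stage) and solves the four projected
displacement equations per grid point in a least-squares sense.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
from scipy import fft as spfft
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import gaussian_filter, uniform_filter

from .imaging import CameraModel, ImagePair

__all__ = [
    "PIVConfig",
    "DisplacementField2C",
    "VelocityField3C",
    "CorrelationResult",
    "cross_correlate",
    "multipass_piv",
    "validate_replace",
    "stereo_reconstruct",
    "FLAG_VALID",
    "FLAG_REPLACED",
    "FLAG_MASKED",
]

logger = logging.getLogger(__name__)

FLAG_VALID = 0
FLAG_REPLACED = 1
FLAG_MASKED = 2


@dataclass(frozen=True)
class PIVConfig:
    """Interrogation settings (defaults follow the 32 px / 50 % standard).

    ``weighting``: "hann" tapers each interrogation window before
    correlation, which suppresses the loss-of-pairs bias of truncated
    particle images at the window edges (an order of magnitude on synthetic
    uniform shifts); "uniform" gives the plain top-hat window.
    """

    windows_px: tuple[int, ...] = (64, 32)
    overlap: float = 0.5
    subpixel: str = "gauss3pt"
    weighting: str = "hann"
    validation_threshold: float = 2.0
    min_peak_ratio: float = 1.15
    noise_floor_px: float = 0.1

    def __post_init__(self) -> None:
        w = self.windows_px
        if any(wi & (wi - 1) for wi in w) or any(wi <= 0 for wi in w):
            raise ValueError("window sizes must be powers of two")
        if list(w) != sorted(w, reverse=True):
            raise ValueError("window sizes must be non-increasing")
        if not 0.0 <= self.overlap < 1.0:
            raise ValueError("overlap must lie in [0, 1)")
        if self.subpixel != "gauss3pt":
            raise ValueError(f"unknown sub-pixel estimator {self.subpixel!r}")
        if self.weighting not in ("hann", "uniform"):
            raise ValueError(f"unknown window weighting {self.weighting!r}")

    @property
    def final_window(self) -> int:
        return self.windows_px[-1]

    @property
    def grid_pitch_px(self) -> int:
        return int(round(self.final_window * (1.0 - self.overlap)))


@dataclass(frozen=True)
class DisplacementField2C:
    """Planar displacement field on a regular sensor-aligned grid (px)."""

    x_px: np.ndarray          # 1-D window-centre columns
    y_px: np.ndarray          # 1-D window-centre rows
    dx: np.ndarray            # (ny, nx) displacement along u, px
    dy: np.ndarray
    peak_ratio: np.ndarray
    flags: np.ndarray         # uint8: FLAG_VALID / FLAG_REPLACED / FLAG_MASKED
    pitch_px: int
    window_px: int


@dataclass(frozen=True)
class VelocityField3C:
    """Three-component velocity on a world grid in the light-sheet plane."""

    x_mm: np.ndarray
    y_mm: np.ndarray
    u: np.ndarray             # (ny, nx) m/s
    v: np.ndarray
    w: np.ndarray
    flags: np.ndarray
    phase_index: int = 0
    cycle_index: int = 0

    @property
    def velocity(self) -> np.ndarray:
        return np.stack([self.u, self.v, self.w], axis=-1)


class CorrelationResult(NamedTuple):
    dx: float
    dy: float
    peak_ratio: float
    out_of_range: bool


# --------------------------------------------------------------------------
# correlation primitives
# --------------------------------------------------------------------------

_HANN_CACHE: dict[int, np.ndarray] = {}
_HANN_AC_CACHE: dict[int, np.ndarray] = {}


def _hann2d(W: int) -> np.ndarray:
    if W not in _HANN_CACHE:
        h = np.hanning(W)
        _HANN_CACHE[W] = (h[:, None] * h[None, :]).astype(np.float32)
    return _HANN_CACHE[W]


def _hann_autocorr(W: int) -> np.ndarray:
    """Circular autocorrelation of the Hann weight, floored at half maximum."""
    if W not in _HANN_AC_CACHE:
        wt = _hann2d(W).astype(float)
        ac = np.fft.fftshift(spfft.irfft2(np.abs(spfft.rfft2(wt)) ** 2, s=(W, W)))
        _HANN_AC_CACHE[W] = np.maximum(ac, 0.5 * ac.max())
    return _HANN_AC_CACHE[W]


def _batch_correlate(wa: np.ndarray, wb: np.ndarray, weighting: str = "hann"):
    """Mean-subtracted circular FFT correlation of (n, W, W) window stacks.

    Returns integer peak displacements, sub-pixel corrections, peak ratios
    and a validity mask.  Displacements follow the convention b ~ a shifted
    by (dx, dy).
    """
    n, W, _ = wa.shape
    a = (wa - wa.mean(axis=(1, 2), keepdims=True)).astype(np.float32)
    b = (wb - wb.mean(axis=(1, 2), keepdims=True)).astype(np.float32)
    sa = a.std(axis=(1, 2))
    sb = b.std(axis=(1, 2))
    ok = (sa > 1e-9) & (sb > 1e-9)
    if weighting == "hann":
        wt = _hann2d(W)
        a = a * wt
        b = b * wt
        a -= a.mean(axis=(1, 2), keepdims=True)
        b -= b.mean(axis=(1, 2), keepdims=True)

    fa = spfft.rfft2(a)
    fb = spfft.rfft2(b)
    corr = spfft.irfft2(np.conj(fa) * fb, s=(W, W)).astype(float)
    corr = np.fft.fftshift(corr, axes=(1, 2))
    if weighting == "hann":
        # deconvolve the weight envelope near the centre (floored outside)
        corr = corr / _hann_autocorr(W)[None]
    c0 = W // 2  # zero-displacement bin after fftshift

    flat = corr.reshape(n, -1)
    imax = np.argmax(flat, axis=1)
    py, px = np.unravel_index(imax, (W, W))
    cmax = flat[np.arange(n), imax]

    # second peak outside a 3x3 exclusion zone around the primary peak
    excl = flat.copy()
    for oy in (-1, 0, 1):
        for ox in (-1, 0, 1):
            yy = np.clip(py + oy, 0, W - 1)
            xx = np.clip(px + ox, 0, W - 1)
            excl[np.arange(n), yy * W + xx] = -np.inf
    second = np.max(excl, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(second > 0, cmax / second, np.inf)

    # 3-point Gaussian sub-pixel fit per axis (parabolic fallback)
    def subpix(cm, cp, c0v):
        gauss_ok = (cm > 0) & (cp > 0) & (c0v > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            num_g = np.log(np.where(cm > 0, cm, 1.0)) - np.log(np.where(cp > 0, cp, 1.0))
            den_g = (np.log(np.where(cm > 0, cm, 1.0))
                     + np.log(np.where(cp > 0, cp, 1.0))
                     - 2.0 * np.log(np.where(c0v > 0, c0v, 1.0)))
            delta_g = 0.5 * num_g / np.where(np.abs(den_g) > 1e-12, den_g, np.inf)
            den_p = cm + cp - 2.0 * c0v
            delta_p = 0.5 * (cm - cp) / np.where(np.abs(den_p) > 1e-12, den_p, np.inf)
        delta = np.where(gauss_ok, delta_g, delta_p)
        return np.clip(np.nan_to_num(delta), -1.0, 1.0)

    ar = np.arange(n)
    xl = np.clip(px - 1, 0, W - 1)
    xr = np.clip(px + 1, 0, W - 1)
    yl = np.clip(py - 1, 0, W - 1)
    yr = np.clip(py + 1, 0, W - 1)
    ddx = subpix(corr[ar, py, xl], corr[ar, py, xr], cmax)
    ddy = subpix(corr[ar, yl, px, ], corr[ar, yr, px], cmax)

    out_of_range = (np.abs(px - c0) >= W // 2 - 1) | (np.abs(py - c0) >= W // 2 - 1)
    dx = (px - c0) + ddx
    dy = (py - c0) + ddy
    return dx, dy, ratio, ok, out_of_range


def cross_correlate(window_a: np.ndarray, window_b: np.ndarray,
                    weighting: str = "hann") -> CorrelationResult:
    """Displacement of the strongest correlation peak between two tiles."""
    wa = np.asarray(window_a, dtype=float)
    wb = np.asarray(window_b, dtype=float)
    if wa.shape != wb.shape or wa.ndim != 2 or wa.shape[0] != wa.shape[1]:
        raise ValueError("windows must be equal square tiles")
    if wa.std() < 1e-12 or wb.std() < 1e-12:
        raise ValueError("constant interrogation window has no correlation peak")
    dx, dy, ratio, ok, oor = _batch_correlate(wa[None], wb[None], weighting)
    return CorrelationResult(float(dx[0]), float(dy[0]), float(ratio[0]), bool(oor[0]))


# --------------------------------------------------------------------------
# multipass engine
# --------------------------------------------------------------------------

def _extract(frame: np.ndarray, cy: np.ndarray, cx: np.ndarray, W: int) -> np.ndarray:
    """Gather W x W windows centred at (cy, cx), clamped to the frame."""
    rows, cols = frame.shape
    half = W // 2
    y0 = np.clip(cy - half, 0, rows - W)
    x0 = np.clip(cx - half, 0, cols - W)
    out = np.empty((len(cy), W, W), dtype=float)
    for i, (yy, xx) in enumerate(zip(y0, x0)):
        out[i] = frame[yy:yy + W, xx:xx + W]
    return out


def multipass_piv(pair: ImagePair, config: PIVConfig,
                  mask: np.ndarray | None = None) -> DisplacementField2C:
    """Coarse-to-fine PIV of one double frame.

    All passes are evaluated on the final vector grid (pitch =
    final_window * (1 - overlap)); coarser passes act as integer window
    offsets for the finer ones.  Windows whose footprint lies mostly
    outside the sensor mask yield masked vectors.
    """
    frame_a = np.asarray(pair.frame_a, dtype=np.float32)
    frame_b = np.asarray(pair.frame_b, dtype=np.float32)
    rows, cols = frame_a.shape
    if rows < config.windows_px[0] or cols < config.windows_px[0]:
        raise ValueError("image smaller than the largest interrogation window")

    mask_frac = uniform_filter(mask.astype(np.float32), size=config.final_window,
                               mode="constant") if mask is not None else None
    field = None
    for p, W in enumerate(config.windows_px):
        pitch = max(int(round(W * (1.0 - config.overlap))), config.grid_pitch_px)
        half = config.final_window // 2
        x = np.arange(half, cols - half + 1, pitch)
        y = np.arange(half, rows - half + 1, pitch)
        gx, gy = np.meshgrid(x, y)
        nyv, nxv = gy.shape
        cy, cx = gy.ravel(), gx.ravel()

        keep = (mask_frac[cy, cx] >= 0.5) if mask_frac is not None \
            else np.ones(cy.shape, dtype=bool)

        if field is None:
            pred_x = np.zeros(cy.shape)
            pred_y = np.zeros(cy.shape)
        else:  # interpolate previous-pass predictor onto this grid
            pred_x = _interp_predictor(field, field.dx, cy, cx)
            pred_y = _interp_predictor(field, field.dy, cy, cx)
        off_x = np.round(pred_x).astype(int)
        off_y = np.round(pred_y).astype(int)

        sel = keep
        wa = _extract(frame_a, cy[sel], cx[sel], W)
        wb = _extract(frame_b, cy[sel] + off_y[sel], cx[sel] + off_x[sel], W)
        ddx, ddy, rat, ok, oor = _batch_correlate(wa, wb, config.weighting)
        bad = ~ok | oor | (rat < config.min_peak_ratio)
        ddx[bad] = np.nan
        ddy[bad] = np.nan
        dx = np.full(cy.shape, np.nan)
        dy = np.full(cy.shape, np.nan)
        dx[sel] = off_x[sel] + ddx
        dy[sel] = off_y[sel] + ddy
        ratio = np.zeros(cy.shape)
        ratio[sel] = np.where(np.isfinite(rat), rat, 0.0)

        field = DisplacementField2C(
            x_px=x, y_px=y,
            dx=dx.reshape(nyv, nxv), dy=dy.reshape(nyv, nxv),
            peak_ratio=ratio.reshape(nyv, nxv),
            flags=np.where(keep.reshape(nyv, nxv), FLAG_VALID, FLAG_MASKED).astype(np.uint8),
            pitch_px=pitch, window_px=W)
        field = validate_replace(field, config.validation_threshold,
                                 noise_floor_px=config.noise_floor_px)

    return field


def _interp_predictor(field: DisplacementField2C, comp: np.ndarray,
                      cy: np.ndarray, cx: np.ndarray) -> np.ndarray:
    data = np.nan_to_num(np.where(field.flags == FLAG_MASKED, np.nan, comp))
    itp = RegularGridInterpolator((field.y_px, field.x_px), data,
                                  bounds_error=False, fill_value=None)
    return itp(np.column_stack([np.clip(cy, field.y_px[0], field.y_px[-1]),
                                np.clip(cx, field.x_px[0], field.x_px[-1])]))


def validate_replace(field: DisplacementField2C, threshold: float = 2.0,
                     noise_floor_px: float = 0.1) -> DisplacementField2C:
    """Normalized-median outlier test (3x3 neighbourhood) with replacement.

    A vector is rejected when, for either component, the residual to the
    neighbourhood median exceeds ``threshold`` times the median residual
    (plus the noise floor).  Rejected and missing vectors are replaced by
    the neighbourhood median and flagged ``FLAG_REPLACED``.
    """
    if field.dx.shape[0] < 3 or field.dx.shape[1] < 3:
        raise ValueError("validation requires at least a 3x3 vector grid")

    masked = field.flags == FLAG_MASKED
    comps = []
    suspect = np.zeros(field.dx.shape, dtype=bool)
    for d in (field.dx, field.dy):
        data = np.where(masked, np.nan, d)
        med = _nanmedian3(data)
        resid = np.abs(data - med)
        rmed = _nanmedian3(np.where(np.isnan(data), np.nan, resid))
        norm = resid / (rmed + noise_floor_px)
        suspect |= np.nan_to_num(norm, nan=np.inf) > threshold
        comps.append(med)
    suspect |= np.isnan(field.dx) | np.isnan(field.dy)
    suspect &= ~masked

    med_x, med_y = comps
    dx = np.where(suspect, med_x, field.dx)
    dy = np.where(suspect, med_y, field.dy)
    replaceable = suspect & np.isfinite(med_x) & np.isfinite(med_y)
    flags = field.flags.copy()
    flags[replaceable] = FLAG_REPLACED
    dx = np.where(suspect & ~replaceable, np.nan, dx)
    dy = np.where(suspect & ~replaceable, np.nan, dy)

    n_active = int(np.sum(~masked))
    frac = float(np.sum(replaceable)) / max(n_active, 1)
    if frac > 0.10:
        logger.warning("outlier replacement fraction %.1f%% exceeds 10%%", 100 * frac)
    else:
        logger.debug("outlier replacement fraction %.2f%%", 100 * frac)
    return replace(field, dx=dx, dy=dy, flags=flags)


def _nanmedian3(a: np.ndarray) -> np.ndarray:
    """3x3 neighbourhood nan-median, centre excluded."""
    ny, nx = a.shape
    pad = np.full((ny + 2, nx + 2), np.nan)
    pad[1:-1, 1:-1] = a
    stack = [pad[1 + oy:ny + 1 + oy, 1 + ox:nx + 1 + ox]
             for oy in (-1, 0, 1) for ox in (-1, 0, 1) if not (oy == 0 and ox == 0)]
    with np.errstate(all="ignore"):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return np.nanmedian(np.stack(stack), axis=0)


# --------------------------------------------------------------------------
# stereo reconstruction
# --------------------------------------------------------------------------

class IllConditionedStereoError(ValueError):
    pass


def nan_gaussian_filter(arr: np.ndarray, sigma_samples: float) -> np.ndarray:
    """Gaussian low-pass with normalized convolution across NaN gaps."""
    filled = np.nan_to_num(arr)
    norm = gaussian_filter((~np.isnan(arr)).astype(float), sigma_samples, mode="constant")
    with np.errstate(invalid="ignore"):
        out = gaussian_filter(filled, sigma_samples, mode="constant") / np.maximum(norm, 1e-9)
    return np.where(np.isnan(arr), np.nan, out)


def stereo_reconstruct(field_cam1: DisplacementField2C, field_cam2: DisplacementField2C,
                       cam1: CameraModel, cam2: CameraModel, interframe_us: float,
                       grid_mm: tuple[np.ndarray, np.ndarray] | None = None,
                       w_filter_mm: float = 0.0,
                       phase_index: int = 0, cycle_index: int = 0) -> VelocityField3C:
    """Solve per-point for (u, v, w) from the two projected 2C fields.

    Each world grid node is projected into both sensors; the bilinearly
    interpolated displacements give four equations A d = b with A the
    stacked mapping Jacobians.  ``w_filter_mm`` optionally applies a
    Gaussian low-pass (in mm) to the out-of-plane component, which carries
    the geometrically amplified share of the correlation noise while the
    physical out-of-plane motion in this flow is sac-scale coherent.
    """
    A = np.vstack([cam1.gradient(), cam2.gradient()])
    cond = np.linalg.cond(A)
    if cond > 1e6:
        raise IllConditionedStereoError(
            f"stereo projection system ill-conditioned (cond={cond:.3g}); "
            "viewing directions too close")
    pinv = np.linalg.pinv(A)

    if grid_mm is None:
        # default world grid: cam1's vector grid back-projected at z = 0
        p = cam1.back_project(np.column_stack([field_cam1.x_px,
                                               np.full_like(field_cam1.x_px, field_cam1.y_px[0])]))
        xw = p[:, 0]
        q = cam1.back_project(np.column_stack([np.full_like(field_cam1.y_px, field_cam1.x_px[0]),
                                               field_cam1.y_px]))
        yw = q[:, 1]
    else:
        xw, yw = grid_mm
    X, Y = np.meshgrid(xw, yw)
    pts = np.column_stack([X.ravel(), Y.ravel(), np.zeros(X.size)])

    rhs = []
    masked_any = np.zeros(X.size, dtype=bool)
    for field, cam in ((field_cam1, cam1), (field_cam2, cam2)):
        uv = cam.project(pts)
        for comp in (field.dx, field.dy):
            data = np.where(field.flags == FLAG_MASKED, np.nan, comp)
            itp = RegularGridInterpolator((field.y_px, field.x_px), data,
                                          bounds_error=False, fill_value=np.nan)
            rhs.append(itp(np.column_stack([uv[:, 1], uv[:, 0]])))
        masked_any |= ~np.isfinite(rhs[-1]) | ~np.isfinite(rhs[-2])
    b = np.stack(rhs, axis=0)                       # (4, npts) px

    d_mm = pinv @ np.nan_to_num(b)                  # (3, npts) mm
    d_mm[:, masked_any] = np.nan
    scale = 1e3 / interframe_us                     # mm / us -> m/s
    u = (d_mm[0] * scale).reshape(X.shape)
    v = (d_mm[1] * scale).reshape(X.shape)
    w = (d_mm[2] * scale).reshape(X.shape)

    if w_filter_mm > 0.0:
        sig = w_filter_mm / float(np.mean(np.diff(xw)))
        w = nan_gaussian_filter(w, sig)

    flags = np.where(masked_any.reshape(X.shape), FLAG_MASKED, FLAG_VALID).astype(np.uint8)
    return VelocityField3C(x_mm=np.asarray(xw), y_mm=np.asarray(yw), u=u, v=v, w=w,
                           flags=flags, phase_index=phase_index, cycle_index=cycle_index)
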