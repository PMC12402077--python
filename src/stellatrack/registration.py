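"""Lateral drift estimation and correction for time-lapse stacks.

Two-stage translation estimation: phase-only correlation with subpixel peak
localization (2D quadratic fit on the 3x3 neighborhood of the correlation
peak) followed by least-squares image matching — Gauss–Newton refinement of
the translation that minimizes the squared intensity residual under
bilinear resampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from stellatrack.simcilia import ImageStack


class UndefinedShiftError(ValueError):
    """Raised when the displacement between two images is undefined
    (e.g. an all-constant image with zero spectrum)."""


@dataclass
class Displacement:
    """Subpixel translation (dy, dx) that aligns a moving image to a reference."""

    dy: float
    dx: float
    peak_value: float = 0.0
    converged: bool = True


@dataclass
class DriftTrace:
    """Per-frame displacement relative to a reference frame.

    displacements : (T, 2) array of (dy, dx); row 0 is (0, 0).
    reference_mode : 'first' (every frame registered to frame 0) or
        'previous-accumulated' (frame-to-frame shifts chained cumulatively).
    """

    displacements: np.ndarray
    reference_mode: str = "previous-accumulated"

    def __post_init__(self) -> None:
        self.displacements = np.asarray(self.displacements, float)
        if self.displacements.ndim != 2 or self.displacements.shape[1] != 2:
            raise ValueError("displacements must be (T, 2)")

    def __len__(self) -> int:
        return len(self.displacements)


def _hann2d(shape: tuple[int, int]) -> np.ndarray:
    wy = np.hanning(shape[0])
    wx = np.hanning(shape[1])
    return np.outer(wy, wx)


def _quadratic_subpixel(corr: np.ndarray, peak: tuple[int, int]) -> tuple[float, float]:
    """Refine an integer peak by a separable quadratic fit on the 3x3
    neighborhood (wrap-around indexing; offsets clamped to +-0.5)."""
    py, px = peak
    h, w = corr.shape

    def offset(vm: float, v0: float, vp: float) -> float:
        denom = vm - 2.0 * v0 + vp
        if denom >= 0 or abs(denom) < 1e-300:
            return 0.0
        return float(np.clip(0.5 * (vm - vp) / denom, -0.5, 0.5))

    dy = offset(corr[(py - 1) % h, px], corr[py, px], corr[(py + 1) % h, px])
    dx = offset(corr[py, (px - 1) % w], corr[py, px], corr[py, (px + 1) % w])
    return dy, dx


def phase_correlation_shift(
    ref_img: np.ndarray,
    mov_img: np.ndarray,
    window: str = "hann",
    regularization: float = 1e-12,
    max_shift: float | None = None,
) -> Displacement:
    """Phase-only correlation with quadratic subpixel peak localization.

    Computes the normalized cross-power spectrum
    ``r = F(ref) * conj(F(mov)) / |F(ref) * conj(F(mov))|``, inverse
    transforms it, and locates the correlation peak.  The returned (dy, dx)
    is the translation to apply to ``mov`` to align it to ``ref``.

    window : 'hann' (default, suppresses edge ringing on aperiodic content)
        or 'none' (exact for circularly shifted periodic content).
    max_shift : when given, restrict the peak search to |dy|,|dx| <=
        max_shift.  Sparse movies of bright point emitters produce spurious
        whitened-correlation peaks at emitter-pair displacement vectors;
        bounding the search to the physically plausible drift range rejects
        them.
    """
    ref = np.asarray(ref_img, float)
    mov = np.asarray(mov_img, float)
    if ref.shape != mov.shape:
        raise ValueError("images must have the same shape")
    if min(ref.shape) < 16:
        raise ValueError("images must be at least 16x16")
    if window not in ("hann", "none"):
        raise ValueError("window must be 'hann' or 'none'")
    ref = ref - ref.mean()
    mov = mov - mov.mean()
    if not ref.any() or not mov.any():
        raise UndefinedShiftError("all-constant image: shift is undefined")
    if window == "hann":
        wnd = _hann2d(ref.shape)
        ref = ref * wnd
        mov = mov * wnd
    fr = np.fft.fft2(ref)
    fm = np.fft.fft2(mov)
    cross = np.conj(fr) * fm
    mag = np.abs(cross)
    maxmag = mag.max()
    if maxmag == 0:
        raise UndefinedShiftError("zero cross-power spectrum")
    # phase-only normalization with spectral floor to avoid blow-up
    r = np.where(mag > regularization * maxmag, cross / np.maximum(mag, 1e-300), 0.0)
    corr = np.real(np.fft.ifft2(r))
    if max_shift is not None:
        h, w = corr.shape
        fy = np.minimum(np.arange(h), h - np.arange(h))
        fx = np.minimum(np.arange(w), w - np.arange(w))
        allowed = (fy[:, None] <= max_shift) & (fx[None, :] <= max_shift)
        corr = np.where(allowed, corr, -np.inf)
    peak = np.unravel_index(np.argmax(corr), corr.shape)
    corr = np.where(np.isfinite(corr), corr, 0.0)
    sy, sx = _quadratic_subpixel(corr, peak)
    dy, dx = peak[0] + sy, peak[1] + sx
    h, w = corr.shape
    if dy > h / 2:
        dy -= h
    if dx > w / 2:
        dx -= w
    return Displacement(dy=float(dy), dx=float(dx), peak_value=float(corr[peak]))


def lsm_refine(
    ref_img: np.ndarray,
    mov_img: np.ndarray,
    init: Displacement,
    max_iter: int = 50,
    tol: float = 1e-3,
) -> Displacement:
    """Least-squares image matching: Gauss–Newton refinement of a translation.

    Minimizes ``sum_p [ref(p) - mov(p + d)]**2`` over d starting from
    ``init``, using cubic-spline resampling of the moving image and of its
    gradient fields (linear interpolation is not used here: the best
    linear blend of adjacent rows is systematically biased toward integer
    displacements).  An interior margin of 2 px is excluded from the
    residual to avoid edge effects.  Returns ``init`` with
    ``converged=False`` if the residual increases for 3 consecutive
    iterations or ``max_iter`` is reached without meeting ``tol``.
    """
    ref = np.asarray(ref_img, float)
    mov = np.asarray(mov_img, float)
    if ref.shape != mov.shape:
        raise ValueError("images must have the same shape")
    d = np.array([init.dy, init.dx], float)
    if max_iter <= 0:
        return Displacement(init.dy, init.dx, init.peak_value, converged=False)
    m = 2  # edge margin
    sl = (slice(m, ref.shape[0] - m), slice(m, ref.shape[1] - m))
    gy0, gx0 = np.gradient(mov)
    mov_c = ndimage.spline_filter(mov, order=3)
    gy_c = ndimage.spline_filter(gy0, order=3)
    gx_c = ndimage.spline_filter(gx0, order=3)
    yy, xx = np.mgrid[0 : ref.shape[0], 0 : ref.shape[1]].astype(float)

    def sample(coeffs, dy, dx):
        return ndimage.map_coordinates(
            coeffs, [yy + dy, xx + dx], order=3, mode="nearest", prefilter=False
        )

    best_d = d.copy()
    best_res = np.inf
    n_worse = 0
    converged = False
    for _ in range(max_iter):
        moved = sample(mov_c, d[0], d[1])
        gy = sample(gy_c, d[0], d[1])
        gx = sample(gx_c, d[0], d[1])
        resid = (ref - moved)[sl].ravel()
        res = float(resid @ resid)
        if res < best_res:
            best_res = res
            best_d = d.copy()
            n_worse = 0
        else:
            n_worse += 1
            if n_worse >= 3:
                return Displacement(init.dy, init.dx, init.peak_value, converged=False)
        # moved(p) = mov(p + d): spline-sampled gradients form the Jacobian
        J = np.column_stack([gy[sl].ravel(), gx[sl].ravel()])
        JtJ = J.T @ J
        try:
            delta = np.linalg.solve(JtJ, J.T @ resid)
        except np.linalg.LinAlgError:
            return Displacement(best_d[0], best_d[1], init.peak_value, converged=False)
        # resid = ref - moved, so moving along +delta reduces the residual
        d = d + delta
        if float(np.hypot(*delta)) < tol:
            converged = True
            best_d = d
            break
    return Displacement(float(best_d[0]), float(best_d[1]), init.peak_value, converged=converged)


def estimate_drift(
    stack: ImageStack | np.ndarray,
    reference_mode: str = "previous-accumulated",
    window: str = "hann",
    refine: bool = True,
    max_shift: float | None = 10.0,
) -> DriftTrace:
    """Estimate the per-frame lateral drift of a stack.

    reference_mode 'first' registers every frame against frame 0;
    'previous-accumulated' estimates frame-to-frame shifts and accumulates
    them (robust to slow content change such as photobleaching, at the cost
    of random-walk error accumulation).  Frames whose shift is undefined get
    NaN and are linearly interpolated over afterwards.
    """
    data = stack.data if isinstance(stack, ImageStack) else np.asarray(stack, float)
    n = data.shape[0]
    if n < 2:
        raise ValueError("need at least 2 frames")
    if reference_mode not in ("first", "previous-accumulated"):
        raise ValueError("reference_mode must be 'first' or 'previous-accumulated'")
    disp = np.zeros((n, 2))
    for t in range(1, n):
        ref = data[0] if reference_mode == "first" else data[t - 1]
        try:
            d = phase_correlation_shift(ref, data[t], window=window, max_shift=max_shift)
            if refine:
                d = lsm_refine(ref, data[t], d)
            disp[t] = (d.dy, d.dx)
        except UndefinedShiftError:
            warnings.warn(f"undefined shift at frame {t}; interpolating", stacklevel=2)
            disp[t] = np.nan
    # interpolate over isolated NaN estimates before any accumulation
    for c in range(2):
        col = disp[:, c]
        bad = np.isnan(col)
        if bad.any():
            col[bad] = np.interp(np.flatnonzero(bad), np.flatnonzero(~bad), col[~bad])
    if reference_mode == "previous-accumulated":
        disp = disp.cumsum(axis=0)
    return DriftTrace(displacements=disp, reference_mode=reference_mode)


def apply_drift(
    stack: ImageStack | np.ndarray,
    trace: DriftTrace,
    interpolation: str = "bilinear",
) -> ImageStack | np.ndarray:
    """Translate each frame by the negative of its drift displacement.

    The drift trace gives, for each frame, the translation that maps
    content of frame 0 onto that frame; correcting therefore samples frame t
    at positions p + d_t.  Out-of-field pixels are filled with the frame
    median.  interpolation: 'bilinear' (default) or 'nearest' (exact pixel
    roll for integer traces).
    """
    is_stack = isinstance(stack, ImageStack)
    data = stack.data if is_stack else np.asarray(stack)
    if len(trace) != data.shape[0]:
        raise ValueError("trace length must equal n_frames")
    order = {"bilinear": 1, "nearest": 0}[interpolation]
    out = np.empty_like(data, dtype=float)
    for t in range(data.shape[0]):
        dy, dx = trace.displacements[t]
        if dy == 0 and dx == 0:
            out[t] = data[t]
            continue
        fill = float(np.median(data[t]))
        out[t] = ndimage.shift(
            data[t].astype(float), (-dy, -dx), order=order, mode="constant", cval=fill
        )
    if data.dtype == np.uint16:
        out = np.clip(np.round(out), 0, 65535).astype(np.uint16)
    if is_stack:
        return ImageStack(
            data=out, pixel_size_um=stack.pixel_size_um, frame_interval_s=stack.frame_interval_s
        )
    return out
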