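"""Synthetic stereocilia movie generator with ground truth.

Generates 2D time-lapse stacks that emulate sparse single-molecule labeling
in hair-cell stereocilia imaged in a single focal plane: near-straight
stereocilium axes, molecules following one of four motion regimes
(diffusive one-frame dwellers, stationary binders, processive walkers,
stepwise pause-and-jump walkers), fluorophore photophysics (photobleaching,
optional two-state blinking), an in-focus Airy point-spread function,
Poisson shot noise, Gaussian camera read noise, and slow lateral stage
drift.  Every molecule's subpixel position and visibility is recorded in a
ground-truth table so downstream stages can be scored against truth.

Conventions: arrays are indexed (t, y, x); subpixel positions are in pixel
units with the origin at the center of pixel (0, 0); arclength ``s`` is in
micrometers, 0 at the stereocilium base; tipward displacement is positive.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from scipy.special import j1


class PlacementError(ValueError):
    """Raised when the requested stereocilia cannot be placed in the field."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Scene:
    """Stereocilia geometry for one simulated field of view.

    stereocilia : list of (N, 2) arrays of (y, x) vertices in micrometers,
        ordered base -> tip.
    apical_mask : (M, 2) polygon of (y, x) vertices in micrometers enclosing
        the cell-body region that carries background fluorescence.
    field_size : (height, width) in pixels.
    pixel_size : micrometers per pixel.
    """

    stereocilia: list[np.ndarray]
    apical_mask: np.ndarray
    field_size: tuple[int, int]
    pixel_size: float

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        h, w = self.field_size
        for poly in self.stereocilia:
            if polyline_length(poly) <= 0:
                raise ValueError("stereocilium polyline has zero arclength")
            ypx = poly[:, 0] / self.pixel_size
            xpx = poly[:, 1] / self.pixel_size
            if (ypx < 0).any() or (ypx > h - 1).any() or (xpx < 0).any() or (xpx > w - 1).any():
                raise ValueError("stereocilium polyline vertex outside field")

    def axis_length(self, i: int) -> float:
        """Arclength of stereocilium ``i`` in micrometers."""
        return polyline_length(self.stereocilia[i])

    def polyline_px(self, i: int) -> np.ndarray:
        """Stereocilium ``i`` vertices in pixel units, (N, 2) as (y, x)."""
        return self.stereocilia[i] / self.pixel_size

    def to_dict(self) -> dict:
        return {
            "stereocilia_um": [p.tolist() for p in self.stereocilia],
            "apical_mask_um": self.apical_mask.tolist(),
            "field_size_px": list(self.field_size),
            "pixel_size_um": self.pixel_size,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Scene":
        return cls(
            stereocilia=[np.asarray(p, dtype=float) for p in d["stereocilia_um"]],
            apical_mask=np.asarray(d["apical_mask_um"], dtype=float),
            field_size=tuple(d["field_size_px"]),
            pixel_size=float(d["pixel_size_um"]),
        )


@dataclass
class MotionModel:
    """Kinetic model for one cohort of molecules.

    kind selects the regime:
      - ``diffusive``  : appears at a random axial position, survives each
        frame with probability 2**(-1/dwell_half_life) (geometric dwell).
      - ``stationary`` : holds its position until photobleaching.
      - ``processive`` : advances along the axis by speed*frame_interval per
        frame; per-molecule speed ~ Normal(speed_mean, speed_sd) truncated
        positive and run length ~ Normal(run_length_mean, run_length_sd)
        truncated positive.
      - ``stepwise``   : pauses (geometric, pause_half_life frames) alternate
        with instantaneous jumps of step_size_nm.
    direction: +1 tipward (base -> tip), -1 baseward.
    """

    kind: str
    dwell_half_life: float = 1.0  # frames (diffusive)
    speed_mean: float = 100.0  # nm/s (processive)
    speed_sd: float = 0.0
    run_length_mean: float = 2.0  # um (processive/stepwise)
    run_length_sd: float = 0.0
    pause_half_life: float = 5.0  # frames (stepwise)
    step_size_nm: float = 100.0  # nm (stepwise)
    direction: int = 1

    def __post_init__(self) -> None:
        if self.kind not in {"diffusive", "stationary", "processive", "stepwise"}:
            raise ValueError(f"unknown motion kind {self.kind!r}")
        if self.kind == "processive" and self.speed_mean <= 0:
            raise ValueError("speed_mean must be > 0 for processive motion")
        if self.dwell_half_life <= 0:
            raise ValueError("dwell_half_life must be > 0")
        if self.step_size_nm < 0:
            raise ValueError("step_size_nm must be >= 0")
        if self.direction not in (1, -1):
            raise ValueError("direction must be +1 (tipward) or -1 (baseward)")


@dataclass
class Photophysics:
    """Fluorophore emission and switching parameters.

    photons_per_frame : mean detected photoelectrons per fluorophore per
        exposure.  Default 816 so that a single fluorophore integrates to
        ~408 ADU at the default camera gain of 2 e-/ADU.
    bleach_half_life : frames; per-frame survival is 2**(-1/bleach_half_life).
        ``inf`` disables bleaching.
    blink_off_rate, blink_on_rate : per-frame transition probabilities of the
        two-state (bright/dark) Markov blinking model; both default 0 (off).
    """

    photons_per_frame: float = 816.0
    bleach_half_life: float = 61.0
    blink_off_rate: float = 0.0
    blink_on_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.photons_per_frame < 0:
            raise ValueError("photons_per_frame must be >= 0")
        if not (0 < self.bleach_survival <= 1):
            raise ValueError("bleach survival per frame must lie in (0, 1]")
        if not (0 <= self.blink_off_rate <= 1 and 0 <= self.blink_on_rate <= 1):
            raise ValueError("blink rates must lie in [0, 1]")

    @property
    def bleach_survival(self) -> float:
        if math.isinf(self.bleach_half_life):
            return 1.0
        return 2.0 ** (-1.0 / self.bleach_half_life)


@dataclass
class CameraModel:
    """sCMOS camera and acquisition timing parameters."""

    read_noise_sd: float = 1.5  # electrons rms
    gain: float = 2.0  # electrons per ADU
    offset: float = 100.0  # ADU
    frame_interval: float = 1.0  # s
    exposure: float = 0.1  # s

    def __post_init__(self) -> None:
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be >= 0")
        if not (0 < self.exposure <= self.frame_interval):
            raise ValueError("exposure must satisfy 0 < exposure <= frame_interval")
        if self.gain <= 0:
            raise ValueError("gain must be > 0")


@dataclass
class GroundTruthTrack:
    """Per-frame truth for one simulated molecule.

    Frames run contiguously from appearance to final disappearance; the
    ``visible`` flag is False during dark (blinking) frames.  Positions are
    subpixel (pixel units) plus the arclength ``s`` in micrometers.
    """

    molecule_id: int
    kind: str
    n_fluorophores: int
    stereocilium: int
    frames: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray
    s_um: np.ndarray
    visible: np.ndarray
    true_speed_nm_s: float = float("nan")
    true_run_length_um: float = float("nan")

    def __post_init__(self) -> None:
        if len(self.frames) and (np.diff(self.frames) <= 0).any():
            raise ValueError("frames must be strictly increasing")


@dataclass
class ImageStack:
    """T x Y x X movie with physical calibration."""

    data: np.ndarray
    pixel_size_um: float
    frame_interval_s: float

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------


def polyline_length(poly: np.ndarray) -> float:
    """Total arclength of a polyline given as (N, 2) vertices."""
    return float(np.sum(np.hypot(*np.diff(np.asarray(poly, float), axis=0).T)))


def point_at_arclength(poly: np.ndarray, s: float | np.ndarray) -> np.ndarray:
    """Interpolate (y, x) at arclength(s) ``s`` along a polyline.

    ``s`` outside [0, length] is clamped to the ends.  Returns shape (2,) for
    a scalar ``s`` or (n, 2) for a vector.
    """
    poly = np.asarray(poly, float)
    seg = np.diff(poly, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    s_arr = np.atleast_1d(np.clip(s, 0.0, cum[-1]))
    idx = np.clip(np.searchsorted(cum, s_arr, side="right") - 1, 0, len(seglen) - 1)
    frac = (s_arr - cum[idx]) / np.where(seglen[idx] > 0, seglen[idx], 1.0)
    pts = poly[idx] + frac[:, None] * seg[idx]
    return pts[0] if np.isscalar(s) else pts


# ---------------------------------------------------------------------------
# scene construction
# ---------------------------------------------------------------------------


def make_scene(
    n_stereocilia: int,
    length_range_um: tuple[float, float],
    field_px: tuple[int, int] = (128, 128),
    pixel_size_um: float = 0.1625,
    seed: int | None = None,
    max_tilt_deg: float = 5.0,
) -> Scene:
    """Place ``n_stereocilia`` near-straight, non-overlapping axes in a field.

    Axes are oriented base -> tip, tips pointing toward the top of the field,
    with a small random tilt and sub-pixel waviness.  Vestibular stereocilia
    are straight and up to ~10 um long, which is what the default length
    range downstream code uses.

    Raises ``PlacementError`` when the requested geometry cannot fit.
    """
    if n_stereocilia < 1:
        raise PlacementError("n_stereocilia must be >= 1")
    rng = np.random.default_rng(seed)
    h, w = field_px
    lo, hi = length_range_um
    if lo > hi or lo <= 0:
        raise ValueError("invalid length_range_um")
    margin_px = 4.0
    base_band_px = 12.0  # apical cell-body band below the stereocilia bases
    max_len_px = hi / pixel_size_um
    if max_len_px > h - margin_px - base_band_px:
        raise PlacementError(
            f"field height {h} px cannot hold a {hi} um stereocilium at "
            f"{pixel_size_um} um/px"
        )
    # lateral slots with spacing that accounts for tilt excursion
    tilt_max = math.radians(max_tilt_deg)
    spacing = max(8.0, max_len_px * math.sin(tilt_max) + 6.0)
    n_slots = int((w - 2 * margin_px) // spacing)
    if n_slots < n_stereocilia:
        raise PlacementError(
            f"field width {w} px holds at most {n_slots} stereocilia at the "
            f"required spacing; {n_stereocilia} requested"
        )
    slots = margin_px + spacing * (np.arange(n_slots) + 0.5)
    chosen = rng.choice(n_slots, size=n_stereocilia, replace=False)
    chosen.sort()
    polylines = []
    for i in chosen:
        length_um = rng.uniform(lo, hi)
        length_px = length_um / pixel_size_um
        tilt = rng.uniform(-tilt_max, tilt_max)
        x0 = slots[i] + rng.uniform(-1.0, 1.0)
        y0 = h - 1 - base_band_px  # base just above the apical band
        n_vert = 6
        t = np.linspace(0.0, 1.0, n_vert)
        ys = y0 - t * length_px * math.cos(tilt)
        xs = x0 + t * length_px * math.sin(tilt)
        # sub-pixel waviness, zero at both ends to keep endpoints exact
        wav = rng.normal(0.0, 0.3, n_vert) * np.sin(np.pi * t)
        xs = xs + wav
        poly_px = np.column_stack([ys, xs])
        if (poly_px < 0).any() or (poly_px[:, 0] > h - 1).any() or (poly_px[:, 1] > w - 1).any():
            raise PlacementError("stereocilium left the field during placement")
        poly_um = poly_px * pixel_size_um
        # rescale to the exact requested arclength (waviness perturbs it)
        cur = polyline_length(poly_um)
        base = poly_um[0]
        poly_um = base + (poly_um - base) * (length_um / cur)
        polylines.append(poly_um)
    # apical cell-body band along the bottom of the field
    apical = np.array(
        [
            [(h - 1 - base_band_px) * pixel_size_um, 0.0],
            [(h - 1) * pixel_size_um, 0.0],
            [(h - 1) * pixel_size_um, (w - 1) * pixel_size_um],
            [(h - 1 - base_band_px) * pixel_size_um, (w - 1) * pixel_size_um],
        ]
    )
    return Scene(
        stereocilia=polylines,
        apical_mask=apical,
        field_size=(h, w),
        pixel_size=pixel_size_um,
    )


# ---------------------------------------------------------------------------
# dwell sampling and track simulation
# ---------------------------------------------------------------------------


def sample_dwell_frames(half_life_frames: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` dwell durations (whole frames, >= 1) from the frame-wise
    geometric dwell model with per-frame survival ``2**(-1/half_life)``.

    The survival function is S(t) = P(dwell >= t) = p**(t-1) for integer
    t >= 1, so a one-phase decay fit (free Y0, plateau 0) to S(t) recovers
    ``half_life_frames`` in expectation.
    """
    if half_life_frames <= 0:
        raise ValueError("half_life_frames must be > 0")
    p = 2.0 ** (-1.0 / half_life_frames)
    # geometric with success prob (1 - p): number of trials until first loss
    return rng.geometric(1.0 - p, size=n)


def _truncated_normal(mean: float, sd: float, rng: np.random.Generator) -> float:
    """One positive draw from Normal(mean, sd) by rejection."""
    if sd == 0:
        if mean <= 0:
            raise ValueError("degenerate truncated normal with mean <= 0")
        return mean
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v > 0:
            return v
    raise RuntimeError("truncated normal rejection failed (mean too negative?)")


def _blink_visibility(
    n: int, photo: Photophysics, rng: np.random.Generator
) -> np.ndarray:
    """Two-state Markov bright/dark visibility over ``n`` frames (starts bright)."""
    vis = np.ones(n, dtype=bool)
    if photo.blink_off_rate == 0 and photo.blink_on_rate == 0:
        return vis
    state = True
    for i in range(n):
        vis[i] = state
        if state:
            if rng.random() < photo.blink_off_rate:
                state = False
        else:
            if rng.random() < photo.blink_on_rate:
                state = True
    return vis


def _bleach_frames(photo: Photophysics, rng: np.random.Generator) -> int:
    """Number of frames until photobleaching (>= 1); large sentinel if off."""
    if photo.bleach_survival >= 1.0:
        return 1 << 30
    return int(rng.geometric(1.0 - photo.bleach_survival))


def simulate_tracks(
    scene: Scene,
    motion_model: MotionModel,
    photophysics: Photophysics,
    n_molecules: int,
    n_frames: int,
    seed: int | None = None,
    frame_interval_s: float = 1.0,
    n_fluorophores: int = 1,
    stereocilium: int | None = None,
) -> list[GroundTruthTrack]:
    """Simulate molecule trajectories on the scene's stereocilia.

    Start frames are staggered so that, where possible, a molecule's full
    excursion fits inside the movie.  Processive molecules whose run would
    overrun the tip are truncated there with a warning.  ``stereocilium``
    pins all molecules to one axis; by default each molecule picks one at
    random.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    mm = motion_model
    dt = frame_interval_s
    tracks: list[GroundTruthTrack] = []
    for mol in range(n_molecules):
        if stereocilium is None:
            ci = int(rng.integers(len(scene.stereocilia)))
        else:
            ci = int(stereocilium)
        axis_len = scene.axis_length(ci)
        poly = scene.stereocilia[ci]
        speed = float("nan")
        run_len = float("nan")
        bleach_at = _bleach_frames(photophysics, rng)

        if mm.kind == "diffusive":
            n_vis = int(sample_dwell_frames(mm.dwell_half_life, 1, rng)[0])
            n_vis = min(n_vis, bleach_at)
            s0 = rng.uniform(0.0, axis_len)
            start = int(rng.integers(0, n_frames))
            n_vis = min(n_vis, n_frames - start)
            s = np.full(n_vis, s0)
        elif mm.kind == "stationary":
            n_vis = min(bleach_at, 1 << 30)
            s0 = rng.uniform(0.0, axis_len)
            start = int(rng.integers(0, n_frames))
            n_vis = min(n_vis, n_frames - start)
            s = np.full(n_vis, s0)
        elif mm.kind == "processive":
            speed = _truncated_normal(mm.speed_mean, mm.speed_sd, rng)
            run_len = _truncated_normal(mm.run_length_mean, mm.run_length_sd, rng)
            step_um = speed * dt / 1000.0
            if step_um > axis_len:
                warnings.warn(
                    "per-frame displacement exceeds axis length; track truncated at tip",
                    stacklevel=2,
                )
            need = int(math.ceil(run_len / max(step_um, 1e-12))) + 1
            margin = 0.3
            if run_len + 2 * margin < axis_len:
                s0 = rng.uniform(margin, axis_len - run_len - margin)
            else:
                s0 = margin
                warnings.warn("run length close to axis length; truncating at tip", stacklevel=2)
            start = int(rng.integers(0, max(1, n_frames - need)))
            n_vis = min(need, bleach_at, n_frames - start)
            s_raw = s0 + mm.direction * step_um * np.arange(n_vis)
            # stop at run-length exhaustion or at the tip/base
            dist = np.abs(s_raw - s0)
            s = np.where(dist <= run_len, s_raw, s0 + mm.direction * run_len)
            inside = (s >= 0.0) & (s <= axis_len)
            s = np.clip(s, 0.0, axis_len)
            done = (dist >= run_len) | ~inside
            if done.any():
                last = int(np.argmax(done)) + 1
                s = s[:last]
                n_vis = last
        else:  # stepwise
            q = 1.0 - 2.0 ** (-1.0 / mm.pause_half_life)
            step_um = mm.step_size_nm / 1000.0
            run_len = (
                _truncated_normal(mm.run_length_mean, mm.run_length_sd, rng)
                if mm.run_length_sd > 0 or mm.run_length_mean > 0
                else float("inf")
            )
            margin = 0.3
            if run_len + 2 * margin < axis_len:
                s0 = rng.uniform(margin, axis_len - run_len - margin)
            else:
                s0 = margin
            # stagger starts so the staircase has room to complete
            reach = min(run_len, axis_len - s0)
            need = int(math.ceil(reach / max(q * step_um, 1e-12))) + 2
            start = int(rng.integers(0, max(1, n_frames - need)))
            n_vis = min(bleach_at, n_frames - start)
            jumps = (rng.random(n_vis) < q).astype(float)
            jumps[0] = 0.0
            s = s0 + mm.direction * step_um * np.cumsum(jumps)
            dist = np.abs(s - s0)
            over = (dist > run_len) | (s < 0.0) | (s > axis_len)
            s = np.clip(s, 0.0, axis_len)
            if over.any():
                last = int(np.argmax(over)) + 1
                s = s[:last]
                n_vis = last

        if n_vis < 1:
            continue
        frames = start + np.arange(n_vis)
        vis = _blink_visibility(n_vis, photophysics, rng)
        pts_px = point_at_arclength(poly, s) / scene.pixel_size
        tracks.append(
            GroundTruthTrack(
                molecule_id=mol,
                kind=mm.kind,
                n_fluorophores=n_fluorophores,
                stereocilium=ci,
                frames=frames,
                x_px=pts_px[:, 1].copy(),
                y_px=pts_px[:, 0].copy(),
                s_um=np.asarray(s, float),
                visible=vis,
                true_speed_nm_s=speed,
                true_run_length_um=run_len,
            )
        )
    return tracks


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def airy_intensity(r_um: np.ndarray, wavelength_um: float, na: float) -> np.ndarray:
    """In-focus Airy intensity I(r) = [2 J1(v)/v]^2, v = 2*pi*NA*r/lambda."""
    v = 2.0 * np.pi * na * np.asarray(r_um, float) / wavelength_um
    out = np.ones_like(v)
    nz = v != 0
    out[nz] = (2.0 * j1(v[nz]) / v[nz]) ** 2
    return out


def _psf_kernel(
    dy: float,
    dx: float,
    pixel_size_um: float,
    wavelength_um: float,
    na: float,
    radius_px: int,
) -> np.ndarray:
    """Airy kernel sampled at pixel centers around a subpixel-offset emitter.

    Normalized to unit sum so that each emitter deposits exactly its photon
    budget (kernel truncation does not leak photons)."""
    ax = np.arange(-radius_px, radius_px + 1)
    yy, xx = np.meshgrid(ax - dy, ax - dx, indexing="ij")
    r = np.hypot(yy, xx) * pixel_size_um
    k = airy_intensity(r, wavelength_um, na)
    return k / k.sum()


def random_walk_drift(
    n_frames: int, sd_px_per_frame: float = 0.05, seed: int | None = None
) -> np.ndarray:
    """Smooth lateral stage drift: cumulative Gaussian random walk, (T, 2)."""
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, sd_px_per_frame, size=(n_frames, 2))
    steps[0] = 0.0
    return np.cumsum(steps, axis=0)


def _scene_background_masks(
    scene: Scene, half_width_px: float = 2.0
) -> tuple[np.ndarray, np.ndarray]:
    """(stereocilia ribbon mask, apical cell-body mask) as booleans."""
    from skimage.draw import polygon as draw_polygon

    h, w = scene.field_size
    ribbon = np.zeros((h, w), dtype=bool)
    for i in range(len(scene.stereocilia)):
        poly_px = scene.polyline_px(i)
        n_samp = max(2, int(polyline_length(poly_px)) * 2)
        s_grid = np.linspace(0.0, polyline_length(poly_px), n_samp)
        pts = point_at_arclength(poly_px, s_grid)
        for py, px in pts:
            y0, y1 = int(max(0, py - half_width_px)), int(min(h, py + half_width_px + 1))
            x0, x1 = int(max(0, px - half_width_px)), int(min(w, px + half_width_px + 1))
            ribbon[y0:y1, x0:x1] = True
    ap = scene.apical_mask / scene.pixel_size
    rr, cc = draw_polygon(ap[:, 0], ap[:, 1], shape=(h, w))
    apical = np.zeros((h, w), dtype=bool)
    apical[rr, cc] = True
    return ribbon, apical


def background_rate_map(
    scene: Scene,
    background_photons: float,
    apical_brightness: float = 25.0,
    texture_sd: float = 0.6,
    texture_seed: int | None = None,
) -> np.ndarray:
    """Static per-pixel expected background photon rates.

    Stereocilium shafts carry a dim smooth diffuse rate of
    ``background_photons``; the apical cell body carries a much brighter
    (``apical_brightness`` x) band of granular autofluorescence (the
    densely labeled cuticular plate).  That bright static structure is what
    anchors drift registration in real recordings, so it must dominate the
    image energy over the handful of moving single molecules here too.
    """
    ribbon, apical = _scene_background_masks(scene)
    rate = background_photons * ndimage.gaussian_filter(ribbon.astype(float), 2.0)
    if texture_sd > 0:
        rng = np.random.default_rng(texture_seed)
        g = ndimage.gaussian_filter(rng.normal(0.0, 1.0, apical.shape), 1.0)
        g = g / g.std()
        tex = np.clip(1.0 + texture_sd * g, 0.05, None)
    else:
        tex = 1.0
    ap = background_photons * apical_brightness * ndimage.gaussian_filter(
        apical.astype(float), 1.0
    )
    rate = rate + ap * tex
    return rate


def render_movie(
    scene: Scene,
    tracks: list[GroundTruthTrack],
    photophysics: Photophysics,
    camera: CameraModel,
    drift_trace: np.ndarray | None = None,
    psf_params: dict | None = None,
    seed: int | None = None,
    n_frames: int | None = None,
    background_photons: float = 0.0,
    apical_brightness: float = 25.0,
    texture_sd: float = 0.6,
    apply_shot_noise: bool = True,
    quantize: bool = True,
) -> ImageStack:
    """Render tracks into a camera movie.

    Each visible fluorophore contributes ``photons_per_frame * n_fluorophores``
    expected photoelectrons spread by the in-focus Airy PSF; a uniform
    background rate is added inside the stereocilia/cell mask; Poisson shot
    noise is applied to signal + background, Gaussian read noise added, and
    the result converted to ADU (``adu = electrons / gain + offset``).  The
    whole frame content is translated by the per-frame drift.  Saturation is
    not modeled.

    With ``apply_shot_noise=False``, ``read_noise_sd=0`` and
    ``quantize=False`` the output is the exact expected image (used by
    conservation and linearity tests).
    """
    psf = {"wavelength_um": 0.576, "na": 0.8, "radius_px": 10}
    if psf_params:
        psf.update(psf_params)
    if n_frames is None:
        n_frames = max((int(t.frames[-1]) + 1 for t in tracks), default=1)
    if drift_trace is None:
        drift_trace = np.zeros((n_frames, 2))
    drift_trace = np.asarray(drift_trace, float)
    if len(drift_trace) != n_frames:
        raise ValueError("drift_trace length must equal n_frames")
    rng = np.random.default_rng(seed)
    h, w = scene.field_size
    r = int(psf["radius_px"])
    signal = np.zeros((n_frames, h, w))

    for tr in tracks:
        photons = photophysics.photons_per_frame * tr.n_fluorophores
        for k, f in enumerate(tr.frames):
            if f >= n_frames or not tr.visible[k]:
                continue
            y = tr.y_px[k] + drift_trace[f, 0]
            x = tr.x_px[k] + drift_trace[f, 1]
            iy, ix = int(round(y)), int(round(x))
            if not (0 <= iy < h and 0 <= ix < w):
                continue
            kern = _psf_kernel(
                y - iy, x - ix, scene.pixel_size, psf["wavelength_um"], psf["na"], r
            )
            y0, y1 = iy - r, iy + r + 1
            x0, x1 = ix - r, ix + r + 1
            ky0, kx0 = max(0, -y0), max(0, -x0)
            ky1 = kern.shape[0] - max(0, y1 - h)
            kx1 = kern.shape[1] - max(0, x1 - w)
            signal[f, max(0, y0) : min(h, y1), max(0, x0) : min(w, x1)] += (
                photons * kern[ky0:ky1, kx0:kx1]
            )

    if background_photons > 0:
        bg0 = background_rate_map(
            scene,
            background_photons,
            apical_brightness=apical_brightness,
            texture_sd=texture_sd,
            texture_seed=None if seed is None else (seed + 7919) % (2**31),
        )
        for f in range(n_frames):
            dy, dx = drift_trace[f]
            if dy == 0 and dx == 0:
                signal[f] += bg0
            else:
                signal[f] += ndimage.shift(bg0, (dy, dx), order=1, mode="constant")

    if apply_shot_noise:
        electrons = rng.poisson(signal).astype(float)
    else:
        electrons = signal
    if camera.read_noise_sd > 0:
        electrons = electrons + rng.normal(0.0, camera.read_noise_sd, electrons.shape)
    adu = electrons / camera.gain + camera.offset
    if quantize:
        adu = np.clip(np.round(adu), 0, 65535).astype(np.uint16)
    return ImageStack(
        data=adu, pixel_size_um=scene.pixel_size, frame_interval_s=camera.frame_interval
    )


# ---------------------------------------------------------------------------
# fixture I/O
# ---------------------------------------------------------------------------

TRUTH_COLUMNS = ["molecule_id", "frame", "x_px", "y_px", "s_um", "visible", "n_fluorophores", "kind"]


def tracks_to_table(tracks: list[GroundTruthTrack]) -> pd.DataFrame:
    """Flatten ground-truth tracks to the canonical truth table."""
    rows = []
    for tr in tracks:
        for k in range(len(tr.frames)):
            rows.append(
                (
                    tr.molecule_id,
                    int(tr.frames[k]),
                    tr.x_px[k],
                    tr.y_px[k],
                    tr.s_um[k],
                    int(tr.visible[k]),
                    tr.n_fluorophores,
                    tr.kind,
                )
            )
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def write_fixture(
    stack: ImageStack,
    tracks: list[GroundTruthTrack],
    scene: Scene,
    config: dict,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write movie TIFF (uint16, T->Y->X), truth CSV, scene and config JSON.

    Returns the mapping of artifact names to paths.  Arrays already in
    uint16 round-trip bit-exactly; float stacks are rounded and clipped to
    the uint16 range on write.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "movie": out / "movie.tif",
        "truth": out / "truth.csv",
        "scene": out / "scene.json",
        "config": out / "config.json",
    }
    data = stack.data
    if data.dtype != np.uint16:
        data = np.clip(np.round(data), 0, 65535).astype(np.uint16)
    tifffile.imwrite(paths["movie"], data, imagej=True)
    meta = {
        "pixel_size_um": stack.pixel_size_um,
        "frame_interval_s": stack.frame_interval_s,
        "seed": config.get("seed"),
    }
    (out / "movie.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    tracks_to_table(tracks).to_csv(paths["truth"], index=False, float_format="%.6g")
    paths["scene"].write_text(json.dumps(scene.to_dict(), indent=1, sort_keys=True))
    paths["config"].write_text(json.dumps(config, indent=1, sort_keys=True, default=str))
    return paths


def read_fixture(out_dir: str | Path) -> tuple[ImageStack, pd.DataFrame, Scene, dict]:
    """Read back a fixture written by :func:`write_fixture`."""
    out = Path(out_dir)
    data = tifffile.imread(out / "movie.tif")
    if data.ndim == 2:
        data = data[None]
    meta = json.loads((out / "movie.json").read_text())
    stack = ImageStack(
        data=data,
        pixel_size_um=meta["pixel_size_um"],
        frame_interval_s=meta["frame_interval_s"],
    )
    truth = pd.read_csv(out / "truth.csv")
    scene = Scene.from_dict(json.loads((out / "scene.json").read_text()))
    config = json.loads((out / "config.json").read_text())
    return stack, truth, scene, config
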