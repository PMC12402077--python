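"""Kymographs, track linking, axial projection, and motion classification.

A kymograph is a distance-versus-time intensity matrix sampled along a
stereocilium axis: stationary molecules appear as lines parallel to the
time axis, processive walkers as continuous diagonals, and pause-and-jump
walkers as staircases.  Tracks (from automated nearest-neighbor linking or
imported manual tracking tables) are projected onto the axis, and each
axial trajectory is classified by the operational rule used throughout the
analysis: a molecule is *directional* when it shows a trajectory in the
same direction for more than three frames; molecules moving back and forth
are presumed to be in random motion and excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from stellatrack.simcilia import ImageStack, point_at_arclength, polyline_length


@dataclass
class Kymograph:
    """Distance x time intensity matrix along a polyline.

    Orientation: row 0 is the base (s = 0), so tipward motion appears as
    increasing row index over time (positive slope).
    """

    matrix: np.ndarray
    polyline_px: np.ndarray
    distance_step_um: float
    frame_interval_s: float


@dataclass
class Track:
    """A linked 2D trajectory: per-frame subpixel positions in pixels."""

    molecule_id: int
    frames: np.ndarray
    y_px: np.ndarray
    x_px: np.ndarray
    intensity: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, int)
        if len(self.frames) and (np.diff(self.frames) <= 0).any():
            raise ValueError("track frames must be strictly increasing")


@dataclass
class AxialTrack:
    """A trajectory projected onto a stereocilium axis (arclength in um)."""

    molecule_id: int
    frames: np.ndarray
    s_um: np.ndarray
    off_axis: np.ndarray = field(default_factory=lambda: np.empty(0, bool))
    intensity: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, int)
        self.s_um = np.asarray(self.s_um, float)
        if len(self.off_axis) == 0:
            self.off_axis = np.zeros(len(self.frames), bool)


@dataclass
class MotionRun:
    """One directional excursion within an axial track."""

    start_frame: int
    end_frame: int
    direction: int  # +1 tipward, -1 baseward
    displacement_um: float
    n_frames: int
    pause_fraction: float
    klass: str  # 'processive' | 'stepwise'


@dataclass
class MotionSummary:
    """Classification of one axial track."""

    molecule_id: int
    track_class: str  # 'directional' | 'stationary' | 'excluded-random'
    runs: list[MotionRun]


# ---------------------------------------------------------------------------
# kymograph extraction
# ---------------------------------------------------------------------------


def extract_kymograph(
    stack: ImageStack | np.ndarray,
    polyline_px: np.ndarray,
    width_px: int = 3,
    sampling: str = "bilinear",
    pixel_size_um: float | None = None,
    frame_interval_s: float | None = None,
) -> Kymograph:
    """Sample intensity along a polyline in every frame and stack columns.

    Per frame, intensity is sampled at 1-px arclength steps along the
    polyline, taking the maximum across ``width_px`` perpendicular offsets
    (matching how multi-pixel-wide kymograph line scans are drawn).
    sampling: 'bilinear' or 'nearest' (bit-exact for axes along pixel rows).
    """
    if isinstance(stack, ImageStack):
        data = stack.data
        pixel_size_um = pixel_size_um or stack.pixel_size_um
        frame_interval_s = frame_interval_s or stack.frame_interval_s
    else:
        data = np.asarray(stack)
        pixel_size_um = pixel_size_um or 1.0
        frame_interval_s = frame_interval_s or 1.0
    poly = np.asarray(polyline_px, float)
    h, w = data.shape[1:]
    if (poly[:, 0] < 0).any() or (poly[:, 0] > h - 1).any() or (poly[:, 1] < 0).any() or (
        poly[:, 1] > w - 1
    ).any():
        raise ValueError("polyline exits the field")
    length = polyline_length(poly)
    s_grid = np.arange(0.0, np.floor(length) + 1e-9)
    pts = point_at_arclength(poly, s_grid)
    tang = np.gradient(pts, axis=0)
    tn = np.hypot(tang[:, 0], tang[:, 1])
    tang /= np.where(tn > 0, tn, 1.0)[:, None]
    normal = np.column_stack([-tang[:, 1], tang[:, 0]])
    offsets = np.arange(width_px) - (width_px - 1) / 2.0
    order = {"bilinear": 1, "nearest": 0}[sampling]
    n_frames = data.shape[0]
    mat = np.zeros((len(s_grid), n_frames))
    coords = [pts + off * normal for off in offsets]
    for t in range(n_frames):
        img = data[t].astype(float)
        samples = np.stack(
            [
                ndimage.map_coordinates(img, [c[:, 0], c[:, 1]], order=order, mode="nearest")
                for c in coords
            ]
        )
        mat[:, t] = samples.max(axis=0)
    return Kymograph(
        matrix=mat,
        polyline_px=poly,
        distance_step_um=pixel_size_um,
        frame_interval_s=frame_interval_s,
    )


# ---------------------------------------------------------------------------
# linking
# ---------------------------------------------------------------------------


def link_tracks(
    detections: pd.DataFrame,
    max_jump_px: float = 5.0,
    max_gap_frames: int = 2,
    min_track_length: int = 1,
) -> list[Track]:
    """Greedy nearest-neighbor frame-to-frame linking of detections.

    ``detections`` needs columns frame, y_px, x_px (sum_intensity optional).
    Candidate links beyond ``max_jump_px`` (per elapsed frame) are rejected;
    gaps up to ``max_gap_frames`` are bridged; conflicts are resolved
    smallest-distance-first.  Greedy linking is adequate at the sparse
    labeling densities this workflow targets.
    """
    req = {"frame", "y_px", "x_px"}
    if not req.issubset(detections.columns):
        raise ValueError(f"detections must have columns {sorted(req)}")
    det = detections.sort_values("frame").reset_index()
    has_int = "sum_intensity" in det.columns
    active: list[dict] = []
    done: list[dict] = []
    for f, grp in det.groupby("frame", sort=True):
        f = int(f)
        # retire tracks whose gap exceeded the limit
        still = []
        for tr in active:
            if f - tr["frames"][-1] > max_gap_frames + 1:
                done.append(tr)
            else:
                still.append(tr)
        active = still
        # candidate pairs sorted by distance
        pairs = []
        for ti, tr in enumerate(active):
            gap = f - tr["frames"][-1]
            for ri, row in enumerate(grp.itertuples()):
                dist = np.hypot(row.y_px - tr["y"][-1], row.x_px - tr["x"][-1])
                if dist <= max_jump_px * gap:
                    pairs.append((dist, ti, ri))
        pairs.sort()
        used_t: set[int] = set()
        used_r: set[int] = set()
        rows = list(grp.itertuples())
        for dist, ti, ri in pairs:
            if ti in used_t or ri in used_r:
                continue
            used_t.add(ti)
            used_r.add(ri)
            tr = active[ti]
            row = rows[ri]
            tr["frames"].append(f)
            tr["y"].append(row.y_px)
            tr["x"].append(row.x_px)
            tr["i"].append(getattr(row, "sum_intensity", np.nan) if has_int else np.nan)
        for ri, row in enumerate(rows):
            if ri not in used_r:
                active.append(
                    {
                        "frames": [f],
                        "y": [row.y_px],
                        "x": [row.x_px],
                        "i": [getattr(row, "sum_intensity", np.nan) if has_int else np.nan],
                    }
                )
    done.extend(active)
    tracks = []
    for mid, tr in enumerate(sorted(done, key=lambda d: (d["frames"][0], d["y"][0]))):
        if len(tr["frames"]) < min_track_length:
            continue
        tracks.append(
            Track(
                molecule_id=mid,
                frames=np.array(tr["frames"]),
                y_px=np.array(tr["y"]),
                x_px=np.array(tr["x"]),
                intensity=np.array(tr["i"]),
            )
        )
    return tracks


# ---------------------------------------------------------------------------
# axial projection
# ---------------------------------------------------------------------------


def project_onto_axis(
    track: Track,
    polyline_px: np.ndarray,
    pixel_size_um: float = 0.1625,
    off_axis_px: float = 3.0,
) -> AxialTrack:
    """Project a 2D track onto a stereocilium axis.

    Each point maps to the arclength of its nearest point on the polyline
    (interpolated within segments).  Points farther than ``off_axis_px``
    from the axis are flagged and excluded from run analysis downstream.
    """
    poly = np.asarray(polyline_px, float)
    seg = np.diff(poly, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    pts = np.column_stack([track.y_px, track.x_px])
    s_out = np.empty(len(pts))
    d_out = np.empty(len(pts))
    for i, p in enumerate(pts):
        best_d, best_s = np.inf, 0.0
        for j in range(len(seg)):
            if seglen[j] == 0:
                continue
            t = np.clip(np.dot(p - poly[j], seg[j]) / seglen[j] ** 2, 0.0, 1.0)
            proj = poly[j] + t * seg[j]
            d = float(np.hypot(*(p - proj)))
            if d < best_d:
                best_d = d
                best_s = cum[j] + t * seglen[j]
        s_out[i] = best_s
        d_out[i] = best_d
    return AxialTrack(
        molecule_id=track.molecule_id,
        frames=track.frames.copy(),
        s_um=s_out * pixel_size_um,
        off_axis=d_out > off_axis_px,
        intensity=None if track.intensity is None else track.intensity.copy(),
    )


# ---------------------------------------------------------------------------
# motion classification
# ---------------------------------------------------------------------------


def classify_motion(
    axial_track: AxialTrack,
    min_run_frames: int = 4,
    min_step_um: float = 0.05,
    pause_fraction_threshold: float = 0.25,
    backtrack_um: float = 0.15,
) -> MotionSummary:
    """Classify an axial trajectory as directional, stationary, or excluded.

    Frame-to-frame displacement rates below ``min_step_um`` (per frame)
    count as pauses.  A run extends in one direction while the trajectory
    stays within ``backtrack_um`` of its running extremum; a larger
    backtrack terminates it — on a kymogram, reversals below one distance
    bin (~0.16 um at default pixel size) are invisible, so the default
    0.15 um treats sub-pixel reversals as localization noise rather than
    direction changes.  Run endpoints are trimmed to the first/last moving
    interval.  Runs spanning at least ``min_run_frames`` frames qualify as
    directional — the default of 4 frames encodes "more than three frames
    in the same direction".  Directional runs are *processive* when their
    pause-frame fraction is at most ``pause_fraction_threshold`` and
    *stepwise* otherwise.  Tracks with qualifying runs in both directions,
    or with above-threshold movement in both directions and no qualifying
    run, are *excluded-random* (back-and-forth motion); everything else is
    *stationary*.
    """
    ok = ~axial_track.off_axis
    frames = axial_track.frames[ok]
    s = axial_track.s_um[ok]
    if len(frames) < 2:
        return MotionSummary(axial_track.molecule_id, "stationary", [])
    df = np.diff(frames)
    ds = np.diff(s)
    rate = ds / df
    sign = np.where(np.abs(rate) >= min_step_um, np.sign(ds).astype(int), 0)
    n = len(sign)

    def emit(i: int, j: int, d: int) -> None:
        """Append intervals i..j (inclusive) as a run if they qualify.

        The run is measured between its extremal positions — the *last*
        attainment of the least-advanced and the *first* attainment of the
        most-advanced position, i.e. from where motion actually begins to
        where it ends.  This keeps slowly accumulating displacement
        (per-frame steps below the pause threshold) inside the run while
        trimming stationary plateaus at both ends, and the convention is
        its own dual under time reversal combined with direction flip."""
        if j < i:
            return
        seg = d * s[i : j + 2]
        a = len(seg) - 1 - int(np.argmin(seg[::-1]))  # last minimum
        b = int(np.argmax(seg))  # first maximum
        if b <= a:
            return
        a += i
        b += i
        if d * (s[b] - s[a]) < min_step_um:
            return
        span = int(frames[b] - frames[a]) + 1
        if span < min_run_frames:
            return
        interval_frames = int(frames[b] - frames[a])
        pause_frames = int(np.sum(df[a:b] * (sign[a:b] != d)))
        pf = pause_frames / interval_frames if interval_frames > 0 else 0.0
        runs.append(
            MotionRun(
                start_frame=int(frames[a]),
                end_frame=int(frames[b]),
                direction=int(d),
                displacement_um=float(s[b] - s[a]),
                n_frames=span,
                pause_fraction=float(pf),
                klass="processive" if pf <= pause_fraction_threshold else "stepwise",
            )
        )

    runs: list[MotionRun] = []
    i = 0
    prev_end = -1  # last interval consumed by the previous segment
    while i < n:
        if sign[i] == 0:
            i += 1
            continue
        d = sign[i]
        # extend while the trajectory stays within backtrack_um of its
        # extremum in direction d
        ext = s[i + 1] * d  # most advanced signed position so far
        ext_j = i
        j = i
        while j + 1 < n:
            nxt = s[j + 2] * d
            if nxt >= ext:
                ext = nxt
                ext_j = j + 1
            elif ext - nxt > backtrack_um:
                break
            j += 1
        # include the leading pause plateau (mirror of the trailing pauses
        # the scan already covers) so the segment is reversal-symmetric
        i_seg = i
        while i_seg - 1 > prev_end and sign[i_seg - 1] == 0:
            i_seg -= 1
        emit(i_seg, ext_j, d)
        prev_end = ext_j
        i = max(ext_j + 1, i + 1)

    dirs = {r.direction for r in runs}
    if len(dirs) == 2:
        return MotionSummary(axial_track.molecule_id, "excluded-random", [])
    if len(dirs) == 1:
        return MotionSummary(axial_track.molecule_id, "directional", runs)
    moving = set(sign[sign != 0])
    if len(moving) == 2:
        return MotionSummary(axial_track.molecule_id, "excluded-random", [])
    return MotionSummary(axial_track.molecule_id, "stationary", [])


def run_metrics(runs: list[MotionRun], frame_interval: float) -> pd.DataFrame:
    """Velocity (nm/s) and run length (um) per directional run.

    Velocity is the endpoint slope |displacement| / duration — the measure
    one would read off a kymogram — and run length the total |displacement|
    of the run.
    """
    if not runs:
        raise ValueError("runs must be non-empty")
    rows = []
    for r in runs:
        duration_s = (r.end_frame - r.start_frame) * frame_interval
        rows.append(
            {
                "start_frame": r.start_frame,
                "end_frame": r.end_frame,
                "direction": r.direction,
                "displacement_um": r.displacement_um,
                "velocity_nm_s": abs(r.displacement_um) * 1000.0 / duration_s,
                "run_length_um": abs(r.displacement_um),
                "class": r.klass,
            }
        )
    return pd.DataFrame(rows)


def summarize_runs(metrics: pd.DataFrame) -> dict:
    """Cohort mean +- SD of velocity and run length."""
    return {
        "n": int(len(metrics)),
        "velocity_mean_nm_s": float(metrics["velocity_nm_s"].mean()),
        "velocity_sd_nm_s": float(metrics["velocity_nm_s"].std(ddof=1)),
        "run_length_mean_um": float(metrics["run_length_um"].mean()),
        "run_length_sd_um": float(metrics["run_length_um"].std(ddof=1)),
    }


def event_frequency(
    per_cell_runs: dict[str, int],
    per_cell_frames: dict[str, int],
    min_frames: int = 500,
) -> pd.DataFrame:
    """Per-cell directional-event frequency (events per observed frame).

    Cells observed for fewer than ``min_frames`` frames (the "more than 500
    frames" acquisition rule) are flagged and excluded by default from the
    returned comparison table's ``included`` column.
    """
    rows = []
    for cell, frames in per_cell_frames.items():
        events = per_cell_runs.get(cell, 0)
        rows.append(
            {
                "cell": cell,
                "n_events": events,
                "n_frames": frames,
                "frequency_per_frame": events / frames if frames > 0 else np.nan,
                "included": frames >= min_frames,
            }
        )
    return pd.DataFrame(rows)
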