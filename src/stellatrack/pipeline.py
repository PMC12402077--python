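"""Configuration, orchestration, and reporting for end-to-end runs.

``run_pipeline`` chains the analysis stages — drift registration, puncta
detection and photometry, fluorophore-count mixture fitting, kymograph
extraction, track linking, axial projection, motion classification, and
dwell/velocity kinetics — over a movie plus stereocilium-axis definitions,
writing every intermediate artifact and a deterministic run report.

Every stochastic stage derives its seed from the master seed and the stage
name, so a rerun of the same configuration is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from stellatrack import kinetics, kymotrack, mixture, puncta, registration
from stellatrack.kymotrack import Track
from stellatrack.simcilia import ImageStack

__pipeline_version__ = "0.1.0"


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 derived from the master seed."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """All parameters of an end-to-end run.

    ``axes_px`` are the stereocilium polylines (base -> tip) in pixel
    coordinates; stage parameter blocks are plain dicts forwarded to the
    corresponding module functions.
    """

    movie_path: str = ""
    out_dir: str = "stellatrack_out"
    pixel_size_um: float = 0.1625
    frame_interval_s: float = 1.0
    axes_px: list = field(default_factory=list)
    master_seed: int = 0
    register: dict = field(
        default_factory=lambda: {"enabled": True, "reference_mode": "previous-accumulated", "window": "hann"}
    )
    detect: dict = field(default_factory=lambda: {"sigma_px": 1.3, "threshold_snr": 5.0})
    count: dict = field(default_factory=lambda: {"enabled": True, "k": 3, "n_init": 10})
    kymo: dict = field(default_factory=lambda: {"width_px": 3})
    track: dict = field(default_factory=lambda: {"max_jump_px": 5.0, "max_gap_frames": 2})
    classify: dict = field(
        default_factory=lambda: {
            "min_run_frames": 4,
            "min_step_um": 0.05,
            "pause_fraction_threshold": 0.25,
            "off_axis_px": 3.0,
        }
    )
    kinetics: dict = field(default_factory=lambda: {"fix_plateau_zero": True})
    version: str = __pipeline_version__

    def validate(self) -> None:
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ConfigError("pixel_size_um and frame_interval_s must be > 0")
        if not self.axes_px:
            raise ConfigError("at least one stereocilium axis (axes_px) is required")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["axes_px"] = [np.asarray(a).tolist() for a in self.axes_px]
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class RunReport:
    """Summary of one pipeline run: parameter echo, artifact hashes, and
    headline statistics."""

    config_echo: dict
    artifact_hashes: dict
    summary: dict
    warnings: list


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def import_manual_tracks(csv_path) -> list[Track]:
    """Load externally curated tracks (e.g. from manual GUI tracking).

    Schema: molecule_id, frame, y_px, x_px.  Frames must be strictly
    increasing within each molecule; violations are reported with the
    offending molecule ids.
    """
    df = pd.read_csv(csv_path)
    required = {"molecule_id", "frame", "y_px", "x_px"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"track CSV missing columns: {sorted(missing)}")
    tracks = []
    bad = []
    for mid, grp in df.groupby("molecule_id", sort=True):
        frames = grp["frame"].to_numpy()
        if (np.diff(frames) <= 0).any():
            bad.append(mid)
            continue
        tracks.append(
            Track(
                molecule_id=int(mid),
                frames=frames.astype(int),
                y_px=grp["y_px"].to_numpy(float),
                x_px=grp["x_px"].to_numpy(float),
            )
        )
    if bad:
        raise ValueError(f"non-increasing frame numbers for molecule_id(s) {bad}")
    return tracks


def analyze_stack(
    stack: ImageStack,
    axes_px: list,
    config: PipelineConfig | None = None,
) -> dict:
    """In-memory core of the pipeline: register, detect, link, project,
    classify.  Returns dicts of intermediate tables and per-track results.

    Used directly by tests and simulation studies; ``run_pipeline`` wraps
    it with file I/O and reporting.
    """
    cfg = config or PipelineConfig(axes_px=[np.asarray(a) for a in axes_px])
    warnings_log: list[str] = []

    # --- registration ---
    data = stack
    trace = None
    if cfg.register.get("enabled", True) and stack.n_frames >= 2:
        trace = registration.estimate_drift(
            stack,
            reference_mode=cfg.register.get("reference_mode", "previous-accumulated"),
            window=cfg.register.get("window", "hann"),
        )
        data = registration.apply_drift(stack, trace)

    # --- detection + photometry ---
    # optional region of interest around the stereocilium axes (the
    # equivalent of tracking only within the drawn line scans)
    r_axis = cfg.detect.get("restrict_to_axes_px")
    roi = None
    if r_axis is not None:
        from stellatrack.simcilia import point_at_arclength, polyline_length

        h, w = data.data.shape[1:]
        axis_pts = np.vstack(
            [
                point_at_arclength(
                    np.asarray(ax), np.arange(0.0, polyline_length(np.asarray(ax)) + 1e-9, 0.5)
                )
                for ax in cfg.axes_px
            ]
        )
        roi = np.zeros((h, w), bool)
        r_int = int(np.ceil(r_axis))
        for py, px in axis_pts:
            y0, y1 = max(0, int(py) - r_int), min(h, int(py) + r_int + 1)
            x0, x1 = max(0, int(px) - r_int), min(w, int(px) + r_int + 1)
            roi[y0:y1, x0:x1] = True
    det_rows = []
    for t in range(data.n_frames):
        dets = puncta.detect_puncta(
            data.data[t],
            sigma_px=cfg.detect.get("sigma_px", 1.3),
            threshold_snr=cfg.detect.get("threshold_snr", 5.0),
            frame=t,
            roi_mask=roi,
        )
        puncta.measure_detections(data.data[t], dets)
        for d in dets:
            det_rows.append(
                {
                    "frame": d.frame,
                    "y_px": d.y,
                    "x_px": d.x,
                    "sum_intensity": d.sum_intensity,
                    "background": d.background,
                    "edge_flag": int(d.edge),
                }
            )
    detections = pd.DataFrame(
        det_rows, columns=["frame", "y_px", "x_px", "sum_intensity", "background", "edge_flag"]
    )

    if r_axis is not None and len(detections):
        pts = detections[["y_px", "x_px"]].to_numpy()
        d2 = ((pts[:, None, :] - axis_pts[None, :, :]) ** 2).sum(axis=2).min(axis=1)
        detections = detections[np.sqrt(d2) <= r_axis + 0.5].reset_index(drop=True)

    # --- fluorophore counting ---
    mixture_fit = None
    populations = None
    if cfg.count.get("enabled", True) and len(detections) >= 3 * cfg.count.get("k", 3):
        try:
            mixture_fit = mixture.fit_intensity_mixture(
                detections["sum_intensity"].to_numpy(),
                k=cfg.count.get("k", 3),
                n_init=cfg.count.get("n_init", 10),
                seed=stage_seed(cfg.master_seed, "count"),
            )
            _, populations = mixture.classify_puncta(
                mixture_fit, detections["sum_intensity"].to_numpy()
            )
        except mixture.DegenerateMixtureError as e:
            warnings_log.append(f"count: mixture fit degenerate ({e})")

    # --- kymographs ---
    kymographs = []
    if cfg.kymo.get("enabled", True):
        kymographs = [
            kymotrack.extract_kymograph(data, np.asarray(ax), width_px=cfg.kymo.get("width_px", 3))
            for ax in cfg.axes_px
        ]

    # --- linking, projection, classification ---
    tracks = kymotrack.link_tracks(
        detections,
        max_jump_px=cfg.track.get("max_jump_px", 5.0),
        max_gap_frames=cfg.track.get("max_gap_frames", 2),
    )
    summaries = []
    run_rows = []
    for tr in tracks:
        # assign to the nearest axis
        best = None
        for ai, ax in enumerate(cfg.axes_px):
            at = kymotrack.project_onto_axis(
                tr,
                np.asarray(ax),
                pixel_size_um=stack.pixel_size_um,
                off_axis_px=cfg.classify.get("off_axis_px", 3.0),
            )
            frac_on = 1.0 - at.off_axis.mean() if len(at.off_axis) else 0.0
            if best is None or frac_on > best[0]:
                best = (frac_on, ai, at)
        _, axis_idx, axial = best
        ms = kymotrack.classify_motion(
            axial,
            min_run_frames=cfg.classify.get("min_run_frames", 4),
            min_step_um=cfg.classify.get("min_step_um", 0.05),
            pause_fraction_threshold=cfg.classify.get("pause_fraction_threshold", 0.25),
        )
        summaries.append(ms)
        if ms.track_class == "directional":
            rm = kymotrack.run_metrics(ms.runs, stack.frame_interval_s)
            rm.insert(0, "molecule_id", tr.molecule_id)
            rm.insert(1, "axis", axis_idx)
            run_rows.append(rm)
    runs = (
        pd.concat(run_rows, ignore_index=True)
        if run_rows
        else pd.DataFrame(
            columns=[
                "molecule_id",
                "axis",
                "start_frame",
                "end_frame",
                "direction",
                "displacement_um",
                "velocity_nm_s",
                "run_length_um",
                "class",
            ]
        )
    )

    # --- dwell kinetics ---
    decay_fit = None
    dwells = kinetics.dwell_times(tracks)
    if len(dwells) >= 3 and dwells.max() >= 3:
        try:
            decay_fit = kinetics.fit_one_phase_decay(
                kinetics.survival_curve(dwells),
                fix_plateau_zero=cfg.kinetics.get("fix_plateau_zero", True),
            )
        except kinetics.FitError as e:
            warnings_log.append(f"kinetics: decay fit failed ({e})")

    return {
        "drift_trace": trace,
        "registered": data,
        "detections": detections,
        "mixture_fit": mixture_fit,
        "populations": populations,
        "kymographs": kymographs,
        "tracks": tracks,
        "summaries": summaries,
        "runs": runs,
        "dwells": dwells,
        "decay_fit": decay_fit,
        "warnings": warnings_log,
    }


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full pipeline per ``config`` and write all artifacts.

    Stages: register -> detect -> count -> kymo/track -> classify ->
    kinetics.  Any stage error aborts with a stage-tagged ``StageError``.
    """
    config.validate()
    movie = Path(config.movie_path)
    if not movie.exists():
        raise ConfigError(f"movie not found: {movie}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    data = tifffile.imread(movie)
    if data.ndim == 2:
        data = data[None]
    stack = ImageStack(
        data=data,
        pixel_size_um=config.pixel_size_um,
        frame_interval_s=config.frame_interval_s,
    )
    try:
        res = analyze_stack(stack, config.axes_px, config)
    except (ValueError, RuntimeError) as e:
        raise StageError(f"pipeline failed: {e}") from e

    artifacts: dict[str, Path] = {}
    if res["drift_trace"] is not None:
        tr = res["drift_trace"]
        pd.DataFrame(
            {
                "frame": np.arange(len(tr)),
                "dy_px": tr.displacements[:, 0],
                "dx_px": tr.displacements[:, 1],
            }
        ).to_csv(out / "drift.csv", index=False, float_format="%.6g")
        artifacts["drift"] = out / "drift.csv"
        reg = res["registered"].data
        if reg.dtype != np.uint16:
            reg = np.clip(np.round(reg), 0, 65535).astype(np.uint16)
        tifffile.imwrite(out / "movie_reg.tif", reg, imagej=True)
        artifacts["movie_reg"] = out / "movie_reg.tif"
    res["detections"].to_csv(out / "detections.csv", index=False, float_format="%.6g")
    artifacts["detections"] = out / "detections.csv"
    if res["mixture_fit"] is not None:
        mf = res["mixture_fit"]
        (out / "mixture.json").write_text(
            json.dumps(
                {
                    "k": mf.k,
                    "means": mf.means.tolist(),
                    "sds": mf.sds.tolist(),
                    "weights": mf.weights.tolist(),
                    "log_likelihood": mf.log_likelihood,
                    "converged": mf.converged,
                },
                indent=1,
                sort_keys=True,
            )
        )
        artifacts["mixture"] = out / "mixture.json"
    for i, ky in enumerate(res["kymographs"]):
        p = out / f"kymograph_{i}.tif"
        tifffile.imwrite(p, ky.matrix.astype(np.float32))
        (out / f"kymograph_{i}.json").write_text(
            json.dumps(
                {
                    "distance_step_um": ky.distance_step_um,
                    "frame_interval_s": ky.frame_interval_s,
                    "polyline_px": ky.polyline_px.tolist(),
                },
                indent=1,
                sort_keys=True,
            )
        )
        artifacts[f"kymograph_{i}"] = p
    track_rows = []
    for tr in res["tracks"]:
        for k in range(len(tr.frames)):
            track_rows.append((tr.molecule_id, int(tr.frames[k]), tr.y_px[k], tr.x_px[k]))
    pd.DataFrame(track_rows, columns=["molecule_id", "frame", "y_px", "x_px"]).to_csv(
        out / "tracks.csv", index=False, float_format="%.6g"
    )
    artifacts["tracks"] = out / "tracks.csv"
    res["runs"].to_csv(out / "runs.csv", index=False, float_format="%.6g")
    artifacts["runs"] = out / "runs.csv"

    summary: dict = {
        "n_frames": stack.n_frames,
        "n_detections": int(len(res["detections"])),
        "n_tracks": len(res["tracks"]),
        "n_directional": sum(1 for s in res["summaries"] if s.track_class == "directional"),
        "n_stationary": sum(1 for s in res["summaries"] if s.track_class == "stationary"),
        "n_excluded_random": sum(
            1 for s in res["summaries"] if s.track_class == "excluded-random"
        ),
    }
    if len(res["runs"]):
        summary.update(kymotrack.summarize_runs(res["runs"]))
    if res["decay_fit"] is not None:
        fit = res["decay_fit"]
        summary["dwell_t_half_frames"] = fit.t_half
        summary["dwell_t_half_ci95"] = list(fit.ci95)
    if res["mixture_fit"] is not None:
        summary["population_weights"] = res["mixture_fit"].weights.tolist()
        summary["population_means"] = res["mixture_fit"].means.tolist()

    report = RunReport(
        config_echo=json.loads(config.to_json()),
        artifact_hashes={k: _sha256(p) for k, p in sorted(artifacts.items())},
        summary=summary,
        warnings=res["warnings"],
    )
    (out / "report.json").write_text(
        json.dumps(dataclasses.asdict(report), indent=1, sort_keys=True, default=str)
    )
    return report
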