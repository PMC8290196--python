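"""End-to-end orchestration: images -> probability maps -> refined
masks -> labelled graphs -> RSML + trait tables.

A run consumes a directory of lexicographically ordered frames plus a
pixel-size calibration and per-plant ROIs, and produces, per plant:
the accumulated masks, labelled graphs, one RSML document per frame,
a tidy TraitSeries CSV and spectral CSVs, together with a manifest
that records the full configuration and per-stage counts.  Runs are
deterministic given the seed and model weights, and resumable: a
state checkpoint is written after every frame, so re-invoking on a
partially complete output directory recomputes only missing frames.
"""

from __future__ import annotations

import json
import logging
import pickle
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import __version__, phenotype, refine, rsa_graph, segnets

__all__ = ["PipelineConfig", "FrameSequence", "load_sequence", "run_pipeline"]

log = logging.getLogger("chronorsa")

_MODEL_ALIASES = {"fast": "dsresunet", "accurate": "ensemble"}


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a run."""

    input_dir: str
    output_dir: str
    mm_per_px: float = 0.04
    frame_interval_h: float = 0.25
    roi_file: str | None = None       # JSON: {"plant1": [r0,c0,r1,c1], ...}
    model: str = "fast"               # fast=dsresunet, accurate=ensemble
    model_weights: str | list[str] | None = None
    alpha: float = 0.9                # temporal trailing-average decay
    use_crf: bool = True
    crf_params: refine.CRFParams = field(default_factory=refine.CRFParams)
    accumulator_threshold: float = 1.0
    start_offset_days: float = 0.0    # discard pre-germination frames
    rng_seed: int = 0

    def resolved_model(self) -> str:
        return _MODEL_ALIASES.get(self.model, self.model)

    def validate(self):
        if not Path(self.input_dir).is_dir():
            raise FileNotFoundError(f"input directory {self.input_dir!r}")
        if self.roi_file is not None and not Path(self.roi_file).is_file():
            raise FileNotFoundError(f"ROI file {self.roi_file!r}")
        if self.resolved_model() not in ("unet", "resunet", "dsresunet",
                                         "ensemble"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.mm_per_px <= 0 or self.frame_interval_h <= 0:
            raise ValueError("mm_per_px and frame_interval_h must be > 0")


@dataclass
class FrameSequence:
    """Time-indexed grayscale frames with acquisition metadata."""

    frames: list
    times_h: np.ndarray
    paths: list

    def __len__(self):
        return len(self.frames)

    @property
    def shape(self):
        return self.frames[0].shape


_IMAGE_SUFFIXES = {".png", ".tif", ".tiff", ".jpg", ".jpeg"}


def load_sequence(directory, frame_interval_h: float = 0.25) -> FrameSequence:
    """Load a frame directory, ordered by file stem.

    Timestamps are index * frame interval.  Mixed shapes or unreadable
    files abort with the offending filename.
    """
    directory = Path(directory)
    paths = sorted(p for p in directory.iterdir()
                   if p.suffix.lower() in _IMAGE_SUFFIXES)
    if not paths:
        raise FileNotFoundError(f"no image frames found in {directory}")
    frames = []
    for p in paths:
        try:
            img = np.asarray(iio.imread(p))
        except Exception as exc:
            raise IOError(f"cannot read frame {p.name}: {exc}") from exc
        if img.ndim == 3:
            img = img[..., 0]
        frames.append(img)
        if img.shape != frames[0].shape:
            raise ValueError(
                f"frame {p.name} has shape {img.shape}, expected "
                f"{frames[0].shape}")
    times = np.arange(len(frames)) * frame_interval_h
    return FrameSequence(frames=frames, times_h=times, paths=paths)


def _build_models(config: PipelineConfig):
    name = config.resolved_model()
    builders = {"unet": segnets.build_unet, "resunet": segnets.build_resunet,
                "dsresunet": segnets.build_dsresunet}
    if name == "ensemble":
        models = [b() for b in builders.values()]
    else:
        models = [builders[name]()]
    if config.model_weights:
        weights = (config.model_weights
                   if isinstance(config.model_weights, list)
                   else [config.model_weights])
        if len(weights) != len(models):
            raise ValueError("one weights file per ensemble member required")
        for m, w in zip(models, weights):
            m.load(w)
    return models


def _load_rois(config: PipelineConfig, shape):
    if config.roi_file is None:
        return {"plant1": (0, 0, shape[0], shape[1])}
    data = json.loads(Path(config.roi_file).read_text())
    return {k: tuple(int(x) for x in v) for k, v in data.items()}


class _RunState:
    """Per-plant sequential state, checkpointed for crash-resume."""

    def __init__(self, plants):
        self.next_frame = 0
        self.accumulator = refine.TemporalAccumulator()
        self.prev_graph = {p: None for p in plants}
        self.rows = {p: [] for p in plants}
        self.flags = []

    def save(self, path: Path):
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path: Path):
        with open(path, "rb") as fh:
            return pickle.load(fh)


def run_pipeline(config: PipelineConfig, models=None) -> dict:
    """Run the full pipeline; returns the manifest dict.

    ``models`` may inject pre-built (e.g. freshly trained) model
    objects, bypassing ``model_weights``.  Per-frame failures are
    logged, flagged in the manifest, and do not stop the run.
    """
    config.validate()
    out = Path(config.output_dir)
    (out / "rsml").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(exist_ok=True)
    np.random.seed(config.rng_seed % (2 ** 31))

    seq = load_sequence(config.input_dir, config.frame_interval_h)
    rois = _load_rois(config, seq.shape)
    if models is None:
        models = _build_models(config)

    state_path = out / "state.pkl"
    if state_path.exists():
        state = _RunState.load(state_path)
        log.info("resuming at frame %d", state.next_frame)
    else:
        state = _RunState(list(rois))
    state.accumulator.alpha = config.alpha

    skip = int(round(config.start_offset_days * 24 / config.frame_interval_h))
    for i in range(state.next_frame, len(seq)):
        frame, t = seq.frames[i], float(seq.times_h[i])
        try:
            prob = segnets.ensemble_predict(models, frame)
            if config.use_crf:
                prob = refine.crf_refine(prob, frame,
                                         refine.CRFParams(
                                             **{**asdict(config.crf_params),
                                                "soft": True}))
            refine.accumulate_temporal(prob, state.accumulator)
        except Exception as exc:        # flagged, run continues
            log.warning("frame %d segmentation failed: %s", i, exc)
            state.flags.append({"frame": i, "stage": "segment",
                                "error": str(exc)})
            state.next_frame = i + 1
            state.save(state_path)
            continue
        for plant, roi in rois.items():
            try:
                mask = refine.extract_plant_mask(
                    state.accumulator, roi, config.accumulator_threshold)
                if mask is None:
                    raise RuntimeError("no plant detected")
                sk = rsa_graph.skeletonize_mask(mask)
                g = rsa_graph.graph_from_skeleton(
                    sk, mm_per_px=config.mm_per_px, timestamp_h=t)
                g = rsa_graph.label_roots(g, state.prev_graph[plant])
                state.prev_graph[plant] = g
                if g.tracking_failure:
                    state.flags.append({"frame": i, "plant": plant,
                                        "stage": "track",
                                        "error": "tracking failure"})
                if i >= skip:
                    state.rows[plant].append(phenotype.measure_frame(g) | {
                        "hull_area_mm2": phenotype.convex_hull_area(
                            mask, config.mm_per_px)})
                    rsa_graph.write_rsml(
                        [rsa_graph.simplify_graph(g)], out / "rsml",
                        plant_id=plant)
                    # write_rsml names files by list position; rename to
                    # the absolute frame index
                    src = out / "rsml" / f"{plant}_00000.rsml"
                    src.replace(out / "rsml" / f"{plant}_{i:05d}.rsml")
                    np.save(out / "masks" / f"{plant}_{i:05d}.npy", mask)
            except Exception as exc:
                log.warning("frame %d plant %s failed: %s", i, plant, exc)
                state.flags.append({"frame": i, "plant": plant,
                                    "stage": "graph", "error": str(exc)})
        state.next_frame = i + 1
        state.save(state_path)

    # ---- tables -------------------------------------------------
    cohort = []
    for plant in rois:
        df = pd.DataFrame(state.rows[plant])
        if df.empty:
            continue
        df.insert(0, "plant", plant)
        df["lr_density_over_hull_per_mm"] = [
            phenotype.lr_density_over_hull(l, h) for l, h in
            zip(df["lr_total_length_mm"], df["hull_area_mm2"])]
        df.to_csv(out / f"{plant}_traits.csv", index=False,
                  float_format="%.9g")
        cohort.append(df)
        _write_spectra(df, out, plant, config)
    if cohort:
        pd.concat(cohort, ignore_index=True).to_csv(
            out / "cohort_traits.csv", index=False, float_format="%.9g")

    manifest = {
        "version": __version__,
        "config": {**asdict(config),
                   "crf_params": asdict(config.crf_params)},
        "n_frames": len(seq),
        "plants": list(rois),
        "rows_per_plant": {p: len(r) for p, r in state.rows.items()},
        "flagged": state.flags,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _write_spectra(df: pd.DataFrame, out: Path, plant: str,
                   config: PipelineConfig):
    if len(df) < 3:
        return
    t, speed = phenotype.growth_speed(
        df["mr_length_mm"].to_numpy(), df["time_h"].to_numpy(),
        interval_h=config.frame_interval_h)
    pd.DataFrame({"time_h": t, "mr_speed_mm_per_h": speed}).to_csv(
        out / f"{plant}_speed.csv", index=False, float_format="%.9g")
    feats = phenotype.spectral_energy(speed, config.frame_interval_h)
    pd.DataFrame({"frequency_per_h": feats.frequencies_per_h,
                  "energy": feats.energy}).to_csv(
        out / f"{plant}_spectrum.csv", index=False, float_format="%.9g")
    n_week = int(round(phenotype.WINDOW_7D_H / config.frame_interval_h))
    if len(speed) >= n_week:
        for freq, tag in ((1 / 24, "24h"), (1 / 12, "12h")):
            c, e = phenotype.windowed_energy_series(
                speed, freq, interval_h=config.frame_interval_h)
            pd.DataFrame({"center_time_h": c, "energy": e}).to_csv(
                out / f"{plant}_windowed_energy_{tag}.csv", index=False,
                float_format="%.9g")
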