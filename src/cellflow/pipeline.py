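"""End-to-end convenience drivers: render → classify → measure → track →
fit → summarize, shared by the command-line interface and the test
suite."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from . import growth, measure, report, segment, synth

__all__ = [
    "train_classifier_on_scene",
    "process_frames",
    "run_condition",
    "run_shear_cohort",
]


def train_classifier_on_scene(
    scene: synth.SceneSpec,
    config: report.ExperimentConfig,
    n_per_class: int = 400,
    n_frames: int = 3,
) -> segment.PixelClassifier:
    """Render a few frames of a scene and train the pixel classifier on
    ground-truth-labelled pixels (simulated manual labelling)."""
    frames, masks = [], []
    for i in range(n_frames):
        frame, truth = synth.render_frame(scene, i * config.frame_interval_min)
        frames.append(frame)
        masks.append(truth.mask)
    X, y = synth.sample_training_pixels(frames, masks, n_per_class, rng_seed=config.seed)
    train, val, test = segment.split_samples(X, y, (0.70, 0.15, 0.15), rng_seed=config.seed)
    return segment.train_pixel_classifier(
        train, val, test,
        hidden_size=config.hidden_size,
        mse_target=config.mse_target,
        max_epochs=config.max_epochs,
        rng_seed=config.seed,
    )


def process_frames(
    frames: Sequence[synth.RawFrame],
    classifier: segment.PixelClassifier,
    config: report.ExperimentConfig,
) -> list[segment.DetectionSet]:
    """Classify every frame, extract components and annotate volumes."""
    dsets = []
    for frame in frames:
        mask = segment.classify_image(classifier, frame)
        ds = segment.extract_cells(mask, min_area=config.min_area_px, frame_time=frame.t_min)
        measure.annotate_volumes(ds, config.calibration, config.volume_model)
        dsets.append(ds)
    return dsets


def run_condition(
    frames: Sequence[synth.RawFrame],
    classifier: segment.PixelClassifier,
    config: report.ExperimentConfig,
):
    """Full downstream pipeline for one experiment's frames.

    Returns ``(tracks, fits, divisions, summary)`` where tracks are the
    presented (longest-cultivated) cells, fits are cubic growth fits on
    their smoothed series and summary aggregates the condition.
    """
    dsets = process_frames(frames, classifier, config)
    tracks = growth.track_cells(dsets, max_displacement=config.max_displacement_px)
    growth.smooth_tracks(tracks, config.alpha)
    presented = report.select_presented_cells(tracks, k=config.n_presented_cells)
    fits, divisions = [], []
    for tr in presented:
        res = growth.CubicGrowthModel.from_track(tr, use_smoothed=True).fit()
        res.cell_id = tr.cell_id
        fits.append(res)
        rec = growth.detect_division(tr, drop_fraction=config.drop_fraction)
        if rec is not None:
            divisions.append(rec)
    summary = report.summarize_condition(fits, divisions, config.flow_rate_ul_min)
    return presented, fits, divisions, summary


def run_shear_cohort(
    seed: int,
    flow_rates: Sequence[float] = synth.FLOW_CONDITIONS_UL_MIN,
    interval_min: float = 30.0,
    **scene_kwargs,
):
    """Simulate and analyse the full shear-stress cohort.

    One scene of three cells per flow condition is rendered, a single
    classifier is trained on the first condition's scene, and every
    condition is pushed through the complete pipeline.  Returns
    ``(summaries, per_flow)`` where ``per_flow`` maps flow rate to
    ``(scene, tracks, fits, divisions)``.
    """
    rng = np.random.default_rng(seed)
    cond_seeds = {f: int(rng.integers(2**31 - 1)) for f in flow_rates}
    summaries, per_flow = [], {}
    classifier = None
    for flow in flow_rates:
        scene = synth.shear_cohort_scene(flow, rng_seed=cond_seeds[flow], **scene_kwargs)
        config = report.ExperimentConfig(
            flow_rate_ul_min=flow,
            frame_interval_min=interval_min,
            seed=cond_seeds[flow],
        )
        if classifier is None:
            classifier = train_classifier_on_scene(scene, config)
        t_div = scene.cells[0].division_time
        t_end = (np.ceil(t_div / interval_min) + 2) * interval_min
        frames, _ = synth.generate_timelapse(scene, 0.0, float(t_end), interval_min)
        tracks, fits, divisions, summary = run_condition(frames, classifier, config)
        summaries.append(summary)
        per_flow[flow] = (scene, tracks, fits, divisions)
    return summaries, per_flow
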