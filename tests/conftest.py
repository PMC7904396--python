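"""Shared fixtures: phantoms and tracked results are expensive, so anything
used by more than one test is session-scoped and computed once."""

import warnings

import numpy as np
import pytest

import tagstrain as ts
from tagstrain.strain import SLICE_SEGMENT_IDS
from tagstrain.tracking import TrajectoryField


@pytest.fixture(scope="session")
def default_phantom():
    """Clean phantom at default study conditions: frames, mask, ground truth."""
    cfg = ts.PhantomConfig()
    frames, mask, gt = ts.generate_phantom(cfg)
    return cfg, frames, mask, gt


@pytest.fixture(scope="session")
def tracked_default(default_phantom):
    """Trajectories tracked on the clean default phantom."""
    cfg, frames, mask, gt = default_phantom
    seq = ts.TaggedSequence.from_frames(frames, cfg.pixel_size_mm, "basal")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        traj = ts.track_sequence(seq, mask)
    return cfg, mask, gt, traj


def ground_truth_trajectories(cfg, mask, gt) -> TrajectoryField:
    """Exact trajectories from the analytic forward map (no tracking)."""
    ys, xs = np.nonzero(mask)
    seeds = np.column_stack([xs, ys]).astype(float)
    pos = np.stack(
        [gt.map_forward(seeds, t) for t in range(cfg.n_frames)], axis=1
    )
    pos[:, 0] = seeds
    return TrajectoryField(
        seed_points=seeds,
        positions=pos,
        ncc_peaks=np.ones((len(seeds), cfg.n_frames)),
        mask=mask,
        pixel_size_mm=cfg.pixel_size_mm,
        slice_level="basal",
    )


@pytest.fixture(scope="session")
def infarcted_lv():
    """Three-slice phantom LV with one contiguous two-segment akinetic
    territory per slice, plus its full-pipeline detection report."""
    territory = {2, 3, 7, 8, 13, 16}  # adjacent pairs in each slice
    lv = ts.simulate_lv(infarcted_segments=territory, contractility=0.2, seed=11)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report, series = ts.analyze_lv(lv.sequences)
    return lv, report, series


@pytest.fixture(scope="session")
def phantom_population():
    """20 synthetic LVs with contiguous 2-segment infarct territories,
    scored by the full pipeline (the evaluation-harness test bed)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ts.simulate_population(n_lvs=20, n_infarcted_segments=2, seed=9)
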