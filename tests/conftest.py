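"""Shared fixtures: seeded generators and the big rendered benchmark batch."""

from __future__ import annotations

import numpy as np
import pytest

import coccomorph as cm


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def batch500():
    """500 coccoliths rendered with realistic noise and re-measured.

    Returns (shapes, measurements) aligned one-to-one: each frame holds
    well-separated coccoliths so segmentation recovers exactly one
    particle per placement, matched by centroid order.
    """
    rng = np.random.default_rng(500)
    optics = cm.OpticsConfig()
    varieties = ["A1", "A2", "A3a", "A3b"]
    shapes = [cm.sample_shape(varieties[i % 4], rng=rng) for i in range(500)]

    per_frame = 16
    matched_shapes, measurements = [], []
    for lo in range(0, len(shapes), per_frame):
        batch = shapes[lo:lo + per_frame]
        placements = cm.place_on_grid(batch, optics, (640, 640), rng=rng)
        image, _ = cm.render_plm_image(placements, optics, rng,
                                       frame_shape=(640, 640))
        parts = [p for p in cm.measure_image(image) if p.intact_isolated]
        assert len(parts) == len(batch)
        # match each measured particle to the nearest placement
        centers = np.array([[pl.y_um, pl.x_um] for pl in placements])
        for p in parts:
            pos = np.array([p.centroid[0], p.centroid[1]]) * optics.pixel_size
            i = int(np.argmin(((centers - pos) ** 2).sum(axis=1)))
            matched_shapes.append(placements[i].shape)
            measurements.append(p)
    return matched_shapes, measurements


@pytest.fixture(scope="session")
def transect_run():
    """End-to-end pipeline on a 20-station, 2-depth synthetic transect."""
    import warnings

    config = cm.TransectConfig(
        n_stations=20, depths=(5.0, 100.0), coccoliths_per_sample=150, seed=42
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return cm.run_pipeline(config)
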