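"""Per-particle mass and length measurement against ground truth."""

import numpy as np
import pytest
from scipy import stats as sps

import coccomorph as cm


OPTICS = cm.OpticsConfig(noise_sd=0.0)


def render_single(shape, frame=(320, 320), optics=OPTICS, angle=0.0):
    image, truth = cm.render_plm_image(
        [cm.Placement(shape, frame[1] * optics.pixel_size / 2,
                      frame[0] * optics.pixel_size / 2, angle)],
        optics, np.random.default_rng(0), frame_shape=frame)
    return image, truth


def test_mass_recovered_from_known_thickness_map(rng):
    """Oracle: direct summation over the ground-truth thickness raster."""
    for variety in ("A1", "A2", "A3a", "A3b"):
        s = cm.sample_shape(variety, rng=rng)
        image, truth = render_single(s, angle=0.4)
        p = cm.measure_image(image)[0]
        assert p.mass == pytest.approx(truth.loc[0, "rendered_mass_pg"],
                                       rel=0.02)
        assert p.mass == pytest.approx(s.true_mass, rel=0.02)


def test_uniform_disc_feret_equals_diameter():
    d_px = 60
    optics = cm.OpticsConfig(noise_sd=0.0)
    radius_um = (d_px / 2) * optics.pixel_size
    s = cm.CoccolithShape(
        distal_shield_length=2 * radius_um, shield_ellipticity=1.0,
        tube_width=0.2, slit_length=0.2, central_area_closure=1.0,
        thickness_tube=0.5, thickness_shield=0.5, thickness_central=0.5,
        variety_label="A2")
    image, _ = render_single(s, optics=optics)
    p = cm.measure_image(image)[0]
    assert abs(p.apparent_length - d_px * optics.pixel_size) <= \
        2 * optics.pixel_size


def test_dim_shield_shortens_apparent_length(rng):
    """Thin distal shield below threshold -> apparent length < DSL."""
    for variety in ("A1", "A2", "A3b"):
        s = cm.sample_shape(variety, rng=rng)
        image, _ = render_single(s)
        p = cm.measure_image(image)[0]
        assert p.apparent_length < s.distal_shield_length


def test_mass_invariant_under_gain_rescaling(rng):
    """Doubling grey_gain while doubling recorded grey leaves mass fixed."""
    s = cm.sample_shape("A2", rng=rng)
    image, _ = render_single(s)
    masks = cm.segment_particles(image)
    m1 = cm.measure_particle(masks[0], image).mass

    o = OPTICS
    grey2 = o.background_level + 2.0 * (image.raster.astype(float)
                                        - o.background_level)
    image2 = cm.PLMImage(raster=np.clip(grey2, 0, 2**17).astype(np.uint32),
                         pixel_size=o.pixel_size, grey_gain=2 * o.grey_gain,
                         saturation_thickness=o.saturation_thickness,
                         background_level=o.background_level)
    masks2 = cm.segment_particles(image2)
    m2 = cm.measure_particle(masks2[0], image2).mass
    assert m2 == pytest.approx(m1, rel=1e-6)


def test_empty_mask_rejected(rng):
    s = cm.sample_shape("A1", rng=rng)
    image, _ = render_single(s)
    with pytest.raises(ValueError, match="empty mask"):
        cm.measure_particle(np.zeros_like(image.raster, dtype=bool), image)


def test_batch_mass_accuracy_and_length_bias(batch500):
    """Median |mass error| < 2% over 500 rendered coccoliths, and the
    apparent-vs-DSL regression slope is < 1 (systematic shortening)."""
    shapes, measurements = batch500
    err = np.array([m.mass / s.true_mass - 1.0
                    for s, m in zip(shapes, measurements)])
    assert np.median(np.abs(err)) < 0.02

    dsl = np.array([s.distal_shield_length for s in shapes])
    app = np.array([m.apparent_length for m in measurements])
    fit = sps.linregress(dsl, app)
    assert fit.slope < 1.0
    assert np.mean(app < dsl) > 0.99


@pytest.mark.parametrize(
    "dsl,sl,expected",
    [(3.5, 0.4, 2.7), (3.0, 0.0, 3.0)],
)
def test_sem_ca_tube_length_arithmetic(dsl, sl, expected):
    m = cm.measure_sem({"distal_shield_length": dsl, "tube_width": 0.3,
                        "slit_length": sl, "central_area_closure": 0.1})
    assert m.ca_tube_length == pytest.approx(expected)
    assert m.total_length == pytest.approx(dsl)


def test_sem_rejects_impossible_geometry():
    with pytest.raises(ValueError, match="negative"):
        cm.measure_sem({"distal_shield_length": 1.0, "tube_width": 0.2,
                        "slit_length": 0.6, "central_area_closure": 0.0})
    with pytest.raises(ValueError, match="finite"):
        cm.measure_sem({"distal_shield_length": float("nan"),
                        "tube_width": 0.2, "slit_length": 0.1,
                        "central_area_closure": 0.0})


def test_sem_measurement_noise_is_reproducible(rng):
    s = cm.sample_shape("A2", rng=rng)
    m1 = cm.measure_sem(s, noise_sd=0.05, rng=np.random.default_rng(3))
    m2 = cm.measure_sem(s, noise_sd=0.05, rng=np.random.default_rng(3))
    assert m1 == m2
    assert m1.total_length != s.distal_shield_length
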