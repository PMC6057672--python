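"""Ground-truth coccolith geometry: variety invariants and analytic mass."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import coccomorph as cm
from coccomorph.shapes import DEFAULT_VARIETY_MARGIN, DEFAULT_VARIETY_PARAMS


def grid_mass_oracle(shape: cm.CoccolithShape, step: float = 0.004) -> float:
    """Independent numeric integral of the three-region thickness field.

    Dense Cartesian sampling of the concentric-ellipse model, written
    from the geometric definition (not from the package's rasterizer).
    """
    a = shape.distal_shield_length / 2.0
    b = a * shape.shield_ellipticity
    r_t = a - shape.slit_length
    r_c = r_t - shape.tube_width
    r_closed = np.sqrt(shape.central_area_closure) * r_c
    xs = np.arange(-a, a + step, step)
    ys = np.arange(-b, b + step, step)
    xg, yg = np.meshgrid(xs, ys)
    rho = np.sqrt((xg / a) ** 2 + (yg / b) ** 2) * a
    t = np.zeros_like(rho)
    t[rho <= a] = shape.thickness_shield
    t[(rho <= r_t)] = shape.thickness_tube
    t[(rho <= r_c)] = shape.thickness_shield
    t[(rho <= r_closed)] = shape.thickness_central
    return float(t.sum()) * step**2 * cm.RHO_CALCITE


@pytest.mark.parametrize("variety", ["A1", "A2", "A3a", "A3b", "BC"])
def test_true_mass_matches_numeric_integral(variety, rng):
    for _ in range(3):
        s = cm.sample_shape(variety, rng=rng)
        assert s.true_mass == pytest.approx(grid_mass_oracle(s), rel=5e-3)


@pytest.mark.parametrize("variety,seed", [(v, s) for v in ("A1", "A2", "A3a", "A3b")
                                          for s in range(25)])
def test_variety_defining_invariant_holds_by_construction(variety, seed):
    s = cm.sample_shape(variety, rng=np.random.default_rng(seed))
    eps = DEFAULT_VARIETY_MARGIN
    assert s.slit_length + s.tube_width <= s.distal_shield_length / 2
    if variety == "A1":
        assert s.slit_length > s.tube_width * (1 + eps) * (1 - 1e-12)
        assert s.central_area_closure < 0.75
    elif variety == "A2":
        assert abs(s.slit_length - s.tube_width) <= eps * max(
            s.slit_length, s.tube_width)
    elif variety == "A3b":
        assert s.slit_length < s.tube_width * (1 - eps) * (1 + 1e-12)
        assert s.central_area_closure < 0.75
    elif variety == "A3a":
        assert s.central_area_closure >= 0.75


def test_a3b_larger_and_thicker_than_a1():
    """The size-calcification covariance is built into the generator."""
    p1, p3 = DEFAULT_VARIETY_PARAMS["A1"], DEFAULT_VARIETY_PARAMS["A3b"]
    assert p3.dsl_mean > p1.dsl_mean
    assert p3.thickness_tube_range[0] > p1.thickness_tube_range[1]


def test_sample_shape_rejects_bad_inputs(rng):
    with pytest.raises(ValueError, match="unknown variety"):
        cm.sample_shape("A9", rng=rng)
    bad = cm.VarietyParams(dsl_mean=0.0, dsl_sd=0.3, tw_frac_range=(0.08, 0.1),
                           sl_tw_ratio_range=(1.2, 1.5),
                           closure_range=(0, 0.3),
                           thickness_tube_range=(0.3, 0.5))
    with pytest.raises(ValueError):
        cm.sample_shape("A1", params=bad, rng=rng)


def test_shape_constructor_enforces_geometry():
    kwargs = dict(shield_ellipticity=0.8, central_area_closure=0.2,
                  thickness_tube=0.5, thickness_shield=0.04,
                  thickness_central=0.2, variety_label="A1")
    with pytest.raises(ValueError, match="SL \\+ TW"):
        cm.CoccolithShape(distal_shield_length=2.0, tube_width=0.6,
                          slit_length=0.7, **kwargs)
    with pytest.raises(ValueError):
        cm.CoccolithShape(distal_shield_length=-1.0, tube_width=0.1,
                          slit_length=0.2, **kwargs)


def test_scaled_copy_mass_cubes(rng):
    s = cm.sample_shape("A2", rng=rng)
    for f in (0.5, 1.3, 2.0):
        assert cm.scaled_copy(s, f).true_mass == pytest.approx(
            s.true_mass * f**3, rel=1e-12)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    dsl=st.floats(1.5, 6.0),
    ell=st.floats(0.5, 1.0),
    tw_frac=st.floats(0.01, 0.45),
    sl_frac=st.floats(0.0, 0.45),
    closure=st.floats(0.0, 1.0),
)
def test_analytic_mass_is_additive_over_regions(dsl, ell, tw_frac, sl_frac,
                                                closure):
    """Mass equals the sum of the per-region closed-form ellipse areas."""
    budget = dsl / 2
    tw = tw_frac * budget
    sl = sl_frac * budget * (1 - tw_frac)
    s = cm.CoccolithShape(
        distal_shield_length=dsl, shield_ellipticity=ell, tube_width=tw,
        slit_length=sl, central_area_closure=closure, thickness_tube=0.6,
        thickness_shield=0.04, thickness_central=0.25, variety_label="A2")
    a = dsl / 2
    area_total = np.pi * a**2 * ell
    # zero thickness everywhere except the tube ring isolates that term
    bare = cm.CoccolithShape(
        distal_shield_length=dsl, shield_ellipticity=ell, tube_width=tw,
        slit_length=sl, central_area_closure=closure, thickness_tube=0.6,
        thickness_shield=0.0, thickness_central=0.0, variety_label="A2")
    r_c, r_t, _ = s.region_radii()
    tube_area = np.pi * ell * (r_t**2 - r_c**2)
    assert bare.true_mass == pytest.approx(2.7 * 0.6 * tube_area, rel=1e-10)
    assert s.true_mass <= 2.7 * 0.6 * area_total + 1e-9
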