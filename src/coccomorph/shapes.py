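"""Parametric coccolith geometry and analytic calcite mass.

A coccolith of *Emiliania huxleyi* Type A is modelled, in plan view, as a
set of concentric similar ellipses on the distal shield:

* the **central area**, reaching a semi-major radius ``r_c``; a fraction
  ``central_area_closure`` of its area is covered by calcite of thickness
  ``thickness_central`` (1 = fully closed, diagnostic for variety A3a);
  the uncovered remainder carries the thin base-plate thickness
  ``thickness_shield`` (the proximal plate beneath the open area);
* the **tube**, the optically bright calcite ring of radial width ``TW``
  (``tube_width``) carrying most of the mass, thickness ``thickness_tube``;
* the outer **distal shield** of radial extent ``SL`` (``slit_length``, the
  region crossed by inter-element slits), thin calcite of thickness
  ``thickness_shield``.

With semi-major radius ``a = DSL / 2`` the radial budget is
``r_c + TW + SL = a``, hence the geometric constraint ``SL + TW <= DSL/2``.
The true calcite mass is the analytic integral of thickness x area x
``rho_c`` over the three regions (``rho_c`` = 2.7 pg/um^3, density of
calcite).

The relation between slit length and tube width defines the Type A
calcification varieties: A1 (low-calcified, SL > TW), A2 (medium,
SL ~ TW), A3b (high, SL < TW) and A3a (high, nearly/completely closed
central area regardless of SL/TW). "BC" labels the Type B/C morphotype,
which is carried through as a label only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

#: density of calcite, pg per cubic micron
RHO_CALCITE = 2.7

VARIETY_LABELS = ("A1", "A2", "A3a", "A3b", "BC")
TYPE_A_VARIETIES = ("A1", "A2", "A3a", "A3b")


@dataclass(frozen=True)
class CoccolithShape:
    """Ground-truth geometry and thickness of a single coccolith.

    Lengths in um, thicknesses in um, mass in pg.
    """

    distal_shield_length: float
    shield_ellipticity: float
    tube_width: float
    slit_length: float
    central_area_closure: float
    thickness_tube: float
    thickness_shield: float
    thickness_central: float
    variety_label: str
    true_mass: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        dsl = self.distal_shield_length
        if not dsl > 0:
            raise ValueError(f"distal_shield_length must be > 0, got {dsl}")
        if not 0 < self.shield_ellipticity <= 1:
            raise ValueError("shield_ellipticity must be in (0, 1]")
        if self.tube_width < 0 or self.slit_length < 0:
            raise ValueError("tube_width and slit_length must be >= 0")
        if self.slit_length + self.tube_width > dsl / 2 + 1e-12:
            raise ValueError(
                f"SL + TW = {self.slit_length + self.tube_width:.4f} exceeds "
                f"DSL/2 = {dsl / 2:.4f}"
            )
        if not 0 <= self.central_area_closure <= 1:
            raise ValueError("central_area_closure must be in [0, 1]")
        for name in ("thickness_tube", "thickness_shield", "thickness_central"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.variety_label not in VARIETY_LABELS:
            raise ValueError(f"unknown variety label {self.variety_label!r}")
        if math.isnan(self.true_mass):
            object.__setattr__(self, "true_mass", analytic_mass(self))

    @property
    def semi_major(self) -> float:
        return self.distal_shield_length / 2.0

    @property
    def semi_minor(self) -> float:
        return self.semi_major * self.shield_ellipticity

    def region_radii(self) -> tuple[float, float, float]:
        """Semi-major radii (r_central, r_tube_outer, r_shield_outer)."""
        a = self.semi_major
        r_tube_outer = a - self.slit_length
        r_central = r_tube_outer - self.tube_width
        return r_central, r_tube_outer, a


def _ellipse_area(semi_major: float, ellipticity: float) -> float:
    return math.pi * semi_major**2 * ellipticity


def analytic_mass(shape: CoccolithShape, rho_c: float = RHO_CALCITE) -> float:
    """Closed-form calcite mass (pg) of the three-region model.

    mass = rho_c * sum over regions of thickness * plan area, where the
    calcified part of the central area is the concentric ellipse covering
    the fraction ``central_area_closure`` of the central area and the
    open remainder carries the thin base-plate thickness.
    """
    e = shape.shield_ellipticity
    r_c, r_t, a = shape.region_radii()
    area_central = _ellipse_area(r_c, e)
    area_closed = area_central * shape.central_area_closure
    area_tube = _ellipse_area(r_t, e) - area_central
    area_shield = _ellipse_area(a, e) - _ellipse_area(r_t, e)
    return rho_c * (
        shape.thickness_central * area_closed
        + shape.thickness_shield * (area_central - area_closed)
        + shape.thickness_tube * area_tube
        + shape.thickness_shield * area_shield
    )


@dataclass(frozen=True)
class VarietyParams:
    """Sampling distribution for one calcification variety.

    ``dsl_mean/dsl_sd``: normal distribution of distal shield length (um),
    truncated at ``dsl_min``. ``tw_frac_range``: uniform range of tube
    width as a fraction of DSL — slits and tubes scale with coccolith
    size, so a population is geometrically similar in plan view.
    ``sl_tw_ratio_range``: uniform range of SL/TW enforcing the variety's
    defining inequality by construction. ``closure_range``: uniform range
    of the central-area closure fraction. ``thickness_tube_range`` etc.:
    uniform thickness ranges (um).
    """

    dsl_mean: float
    dsl_sd: float
    tw_frac_range: tuple[float, float]
    sl_tw_ratio_range: tuple[float, float]
    closure_range: tuple[float, float]
    thickness_tube_range: tuple[float, float]
    thickness_shield_range: tuple[float, float] = (0.03, 0.05)
    thickness_central_range: tuple[float, float] = (0.15, 0.30)
    ellipticity_range: tuple[float, float] = (0.75, 0.90)
    dsl_min: float = 1.5

    def validate(self) -> None:
        if self.dsl_mean <= 0 or self.dsl_sd <= 0:
            raise ValueError("dsl_mean and dsl_sd must be positive")
        for name in (
            "tw_frac_range",
            "sl_tw_ratio_range",
            "closure_range",
            "thickness_tube_range",
            "thickness_shield_range",
            "thickness_central_range",
            "ellipticity_range",
        ):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
        if self.tw_frac_range[0] <= 0:
            raise ValueError("tube width fraction range must be strictly positive")
        if self.tw_frac_range[1] >= 0.5:
            raise ValueError("tube width cannot exceed half the shield radius")


#: Generator separation margin between the SL/TW classes: A1 draws
#: SL/TW >= 1 + margin, A3b draws SL/TW <= 1 - margin, A2 stays inside
#: (1 - margin/3, 1 + margin/3).  A classifier with epsilon <= margin and
#: epsilon > margin/3 recovers the labels exactly.
DEFAULT_VARIETY_MARGIN = 0.15

# Size/thickness distributions per variety.  The field literature gives no
# quantitative per-variety distributions; these defaults produce Type A
# coccoliths of 2.5-4.5 um DSL and single-coccolith masses of a few pg,
# with A3b drawn larger and thicker-tubed than A1 so that the positive
# size-calcification covariance emerges in aggregate statistics.  Tube
# widths are fractions of DSL (heavier-calcified varieties have
# proportionally wider tubes), so slit extents grow with coccolith size
# and the apparent-length shortening is roughly proportional.
DEFAULT_VARIETY_PARAMS: Mapping[str, VarietyParams] = {
    "A1": VarietyParams(
        dsl_mean=3.0, dsl_sd=0.30,
        tw_frac_range=(0.070, 0.100),
        sl_tw_ratio_range=(1.0 + DEFAULT_VARIETY_MARGIN, 1.9),
        closure_range=(0.0, 0.30),
        thickness_tube_range=(0.30, 0.50),
    ),
    "A2": VarietyParams(
        dsl_mean=3.2, dsl_sd=0.30,
        tw_frac_range=(0.095, 0.125),
        sl_tw_ratio_range=(
            1.0 - DEFAULT_VARIETY_MARGIN / 3.0,
            1.0 + DEFAULT_VARIETY_MARGIN / 3.0,
        ),
        closure_range=(0.05, 0.40),
        thickness_tube_range=(0.45, 0.70),
    ),
    "A3a": VarietyParams(
        dsl_mean=3.1, dsl_sd=0.30,
        tw_frac_range=(0.115, 0.155),
        sl_tw_ratio_range=(0.4, 1.3),
        closure_range=(0.80, 1.00),
        thickness_tube_range=(0.60, 0.90),
        thickness_central_range=(0.30, 0.50),
    ),
    "A3b": VarietyParams(
        dsl_mean=3.8, dsl_sd=0.32,
        tw_frac_range=(0.145, 0.185),
        sl_tw_ratio_range=(0.50, 1.0 - DEFAULT_VARIETY_MARGIN),
        closure_range=(0.10, 0.50),
        thickness_tube_range=(0.75, 1.10),
    ),
    # Type B/C: delicate, lightly calcified; geometry is a placeholder
    # (the B/C morphotype enters the analysis only as a labelled fraction).
    "BC": VarietyParams(
        dsl_mean=3.4, dsl_sd=0.35,
        tw_frac_range=(0.055, 0.085),
        sl_tw_ratio_range=(0.8, 1.6),
        closure_range=(0.0, 0.20),
        thickness_tube_range=(0.20, 0.35),
    ),
}


def sample_shape(
    variety: str,
    params: VarietyParams | None = None,
    rng: np.random.Generator | None = None,
) -> CoccolithShape:
    """Draw one ground-truth coccolith of the given calcification variety.

    The returned shape satisfies its variety's defining SL/TW (or closure)
    inequality by construction, with the generator margin baked into the
    per-variety ``sl_tw_ratio_range``.

    Parameters
    ----------
    variety:
        One of ``A1, A2, A3a, A3b, BC``.
    params:
        Sampling distribution; defaults to ``DEFAULT_VARIETY_PARAMS[variety]``.
    rng:
        Seeded ``numpy.random.Generator``; a fresh one is created if omitted.
    """
    if variety not in VARIETY_LABELS:
        raise ValueError(
            f"unknown variety {variety!r}; expected one of {VARIETY_LABELS}"
        )
    if params is None:
        params = DEFAULT_VARIETY_PARAMS[variety]
    params.validate()
    if rng is None:
        rng = np.random.default_rng()

    dsl = float(rng.normal(params.dsl_mean, params.dsl_sd))
    dsl = max(dsl, params.dsl_min)
    tw = float(rng.uniform(*params.tw_frac_range)) * dsl
    ratio = float(rng.uniform(*params.sl_tw_ratio_range))
    sl = tw * ratio
    # radial budget: keep SL + TW within 45% of DSL so a central area remains
    budget = 0.45 * dsl
    if sl + tw > budget:
        scale = budget / (sl + tw)
        sl *= scale
        tw *= scale
    closure = float(rng.uniform(*params.closure_range))
    return CoccolithShape(
        distal_shield_length=dsl,
        shield_ellipticity=float(rng.uniform(*params.ellipticity_range)),
        tube_width=tw,
        slit_length=sl,
        central_area_closure=closure,
        thickness_tube=float(rng.uniform(*params.thickness_tube_range)),
        thickness_shield=float(rng.uniform(*params.thickness_shield_range)),
        thickness_central=float(rng.uniform(*params.thickness_central_range)),
        variety_label=variety,
    )


def scaled_copy(shape: CoccolithShape, factor: float) -> CoccolithShape:
    """Geometrically similar copy: all lengths and thicknesses x factor.

    Mass scales as factor^3, which is the similarity assumption behind the
    length-normalized mass M_n = k_s * L^3 * rho_c.
    """
    if factor <= 0:
        raise ValueError("scale factor must be positive")
    return replace(
        shape,
        distal_shield_length=shape.distal_shield_length * factor,
        tube_width=shape.tube_width * factor,
        slit_length=shape.slit_length * factor,
        thickness_tube=shape.thickness_tube * factor,
        thickness_shield=shape.thickness_shield * factor,
        thickness_central=shape.thickness_central * factor,
        true_mass=float("nan"),
    )
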