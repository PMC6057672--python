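"""Per-coccolith measurement from polarized-light rasters.

Mass follows the birefringence principle: below the first-order plateau,
grey level is proportional to calcite thickness, so

    mass = sum over the particle of (grey - background) / gain
           * pixel_area * rho_c          [pg]

Apparent length is the maximum Feret diameter of the segmented bright
region.  Because the thin distal shield renders dimmer than the tube, the
segmented region stops at the tube's outer edge and the apparent length
systematically underestimates the true distal shield length — the bias
the length-correction calibration exists to fix.

Segmentation replaces neural-network coccolith recognition with
thresholded connected components plus "intact and isolated" filters:
components touching the frame border, smaller than a minimum area, or
with overlapping convex hulls are flagged and excluded from statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import Polygon, Point
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .optics import PLMImage
from .shapes import RHO_CALCITE, CoccolithShape


@dataclass(frozen=True)
class ParticleMask:
    """One segmented connected component with its intact/isolated flags."""

    label: int
    mask: np.ndarray  # full-frame boolean mask
    touching_border: bool
    too_small: bool
    isolated: bool

    @property
    def retained(self) -> bool:
        return not self.touching_border and not self.too_small and self.isolated


@dataclass(frozen=True)
class ParticleMeasurement:
    """Mass and apparent length of one segmented coccolith."""

    mass: float  # pg
    apparent_length: float  # um, max Feret diameter of the bright region
    centroid: tuple[float, float]  # (row, col) px, 0-based pixel centers
    touching_border: bool
    intact_isolated: bool

    def __post_init__(self) -> None:
        if self.mass < 0:
            raise ValueError("mass must be >= 0")
        if self.apparent_length < 0:
            raise ValueError("apparent_length must be >= 0")


@dataclass(frozen=True)
class SEMMeasurement:
    """Shape descriptors as measured on a scanning-electron micrograph."""

    total_length: float  # um, distal shield length (DSL)
    ca_tube_length: float  # um, central area + tube extent = DSL - 2*SL
    tube_width: float  # um (TW)
    slit_length: float  # um (SL)
    central_area_closure: float  # fraction in [0, 1]

    def __post_init__(self) -> None:
        for name in ("total_length", "ca_tube_length", "tube_width",
                     "slit_length"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.ca_tube_length > self.total_length + 1e-9:
            raise ValueError("ca_tube_length cannot exceed total_length")


def _convex_hull_polygon(coords: np.ndarray) -> Polygon:
    """Convex hull of (row, col) pixel-center coordinates as a polygon."""
    try:
        hull = ConvexHull(coords)
        return Polygon(coords[hull.vertices])
    except QhullError:  # degenerate: collinear or single pixel
        return Polygon(Point(coords[0]).buffer(0.5))


def segment_particles(
    image: PLMImage,
    threshold_policy: str = "otsu",
    min_area_px: int = 30,
    fixed_threshold: float | None = None,
) -> list[ParticleMask]:
    """Segment bright particles from a polarized-light raster.

    Parameters
    ----------
    threshold_policy:
        "otsu" — Otsu's threshold computed on the non-background part of
        the histogram (pixels above the calibrated background level);
        "fixed" — use ``fixed_threshold`` (grey levels).
    min_area_px:
        Components smaller than this are flagged ``too_small``.

    Returns all components with flags; use ``.retained`` to keep only the
    intact-and-isolated ones.  Raises on an all-saturated raster, which
    carries no usable grey information.
    """
    raster = np.asarray(image.raster)
    if raster.size == 0:
        raise ValueError("raster is empty")
    saturation_grey = image.background_level + image.grey_gain * image.saturation_thickness
    max_grey = min(saturation_grey, np.iinfo(raster.dtype).max
                   if np.issubdtype(raster.dtype, np.integer) else np.inf)
    if np.all(raster >= max_grey):
        raise ValueError("raster is fully saturated; grey levels are uncalibratable")

    if threshold_policy == "fixed":
        if fixed_threshold is None:
            raise ValueError("fixed_threshold required with policy 'fixed'")
        thr = fixed_threshold
    elif threshold_policy == "otsu":
        # non-background histogram: drop the read-noise floor (5 sigma by
        # MAD, background pixels dominate the frame) before Otsu so the
        # split falls between dim shields and bright tubes
        flat = raster.astype(float)
        sigma = 1.4826 * np.median(np.abs(flat - np.median(flat)))
        cut = image.background_level + max(5.0 * sigma, 1.0)
        fg = raster[raster > cut]
        if fg.size == 0:
            return []
        if fg.min() == fg.max():  # flat foreground: split it from background
            thr = 0.5 * (image.background_level + float(fg.min()))
        else:
            # Otsu on log(grey - background): the tube/shield contrast is
            # multiplicative, and the log keeps the wide bright-tube tail
            # from dragging the split into the tube class
            logfg = np.log(fg.astype(float) - image.background_level)
            thr = max(
                image.background_level + float(np.exp(threshold_otsu(logfg))),
                cut,
            )
    else:
        raise ValueError(f"unknown threshold policy {threshold_policy!r}")

    binary = raster > thr
    if not binary.any():
        return []
    # a coccolith's bright tube is an annulus; fill it so ring + closed
    # center form one intact component
    binary = ndi.binary_fill_holes(binary)
    labelled = label(binary, connectivity=2)

    props = regionprops(labelled)
    h, w = raster.shape
    hulls: dict[int, Polygon] = {}
    masks: list[ParticleMask] = []
    for p in props:
        r0, c0, r1, c1 = p.bbox
        touching = r0 == 0 or c0 == 0 or r1 == h or c1 == w
        too_small = p.area < min_area_px
        hulls[p.label] = _convex_hull_polygon(p.coords.astype(float))
        masks.append(
            ParticleMask(
                label=p.label,
                mask=labelled == p.label,
                touching_border=bool(touching),
                too_small=bool(too_small),
                isolated=True,
            )
        )

    # isolation: convex hulls of distinct components must not overlap
    not_isolated: set[int] = set()
    labels_ = [m.label for m in masks]
    for i, li in enumerate(labels_):
        for lj in labels_[i + 1:]:
            if hulls[li].intersects(hulls[lj]):
                not_isolated.add(li)
                not_isolated.add(lj)
    return [
        ParticleMask(m.label, m.mask, m.touching_border, m.too_small,
                     m.label not in not_isolated)
        for m in masks
    ]


def _extended_mass_mask(mask: np.ndarray, image: PLMImage) -> np.ndarray:
    """Grow the bright detection mask to every above-background pixel
    connected to it (hysteresis), so the dim distal shield contributes
    its calcite to the mass even though it falls below the detection
    threshold.  Robust background cut: background + 5 sigma of the
    sub-threshold noise (at least 1 grey level)."""
    raster = np.asarray(image.raster, dtype=float)
    below = raster[~mask]
    noise = 1.4826 * np.median(np.abs(below - np.median(below))) if below.size else 0.0
    cut = image.background_level + max(5.0 * noise, 1.0)
    above = raster > cut
    lab, _ = ndi.label(above, structure=np.ones((3, 3), dtype=int))
    hit = np.unique(lab[mask & above])
    hit = hit[hit > 0]
    if hit.size == 0:
        return mask
    return np.isin(lab, hit) | mask


def measure_particle(mask: ParticleMask | np.ndarray,
                     image: PLMImage,
                     extend_mass_mask: bool = True) -> ParticleMeasurement:
    """Measure mass (pg) and apparent length (um) of one segmented particle.

    Mass sums the background-subtracted grey over the particle's
    above-background connected region (the detection mask grown by
    hysteresis to include the dim shield; disable with
    ``extend_mass_mask=False`` to integrate over the given mask only),
    converted to thickness by the calibration gain.  Apparent length is
    the maximum Feret diameter of the *bright* detection mask times the
    pixel size — which is what makes it underestimate the distal shield
    length when the shield renders below the detection threshold.
    """
    if isinstance(mask, ParticleMask):
        m = mask.mask
        touching, retained = mask.touching_border, mask.retained
    else:
        m = np.asarray(mask, dtype=bool)
        touching, retained = False, True
    if m.shape != image.raster.shape:
        raise ValueError("mask shape does not match raster shape")
    if not m.any():
        raise ValueError("empty mask")

    mass_mask = _extended_mass_mask(m, image) if extend_mass_mask else m
    grey = image.raster[mass_mask].astype(float) - image.background_level
    thickness = np.clip(grey, 0.0, None) / image.grey_gain
    mass = float(thickness.sum()) * image.pixel_size**2 * RHO_CALCITE

    p = regionprops(m.astype(np.uint8))[0]
    feret = float(p.feret_diameter_max)
    return ParticleMeasurement(
        mass=mass,
        apparent_length=feret * image.pixel_size,
        centroid=tuple(map(float, p.centroid)),
        touching_border=touching,
        intact_isolated=retained,
    )


def measure_image(
    image: PLMImage,
    threshold_policy: str = "otsu",
    min_area_px: int = 30,
    fixed_threshold: float | None = None,
) -> list[ParticleMeasurement]:
    """Segment and measure every particle in a frame (flags attached)."""
    masks = segment_particles(image, threshold_policy, min_area_px,
                              fixed_threshold)
    return [measure_particle(m, image) for m in masks]


def measure_sem(
    record: CoccolithShape | SEMMeasurement | dict,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> SEMMeasurement:
    """SEM-style shape measurement from a ground-truth record.

    The SEM stage is table-driven: given true DSL, TW, SL and closure,
    it returns the descriptors an analyst would read off a micrograph,
    with the central area + tube extent derived as DSL - 2*SL and
    optional Gaussian measurement noise on the lengths.
    """
    if isinstance(record, CoccolithShape):
        dsl, tw, sl = (record.distal_shield_length, record.tube_width,
                       record.slit_length)
        closure = record.central_area_closure
    elif isinstance(record, SEMMeasurement):
        dsl, tw, sl, closure = (record.total_length, record.tube_width,
                                record.slit_length,
                                record.central_area_closure)
    else:
        dsl = record["distal_shield_length"]
        tw = record["tube_width"]
        sl = record["slit_length"]
        closure = record["central_area_closure"]
    for v, name in ((dsl, "distal_shield_length"), (tw, "tube_width"),
                    (sl, "slit_length"), (closure, "central_area_closure")):
        if not np.isfinite(v):
            raise ValueError(f"{name} is not finite")

    ca_tube = dsl - 2.0 * sl
    if ca_tube < 0:
        raise ValueError(
            f"derived ca_tube_length = DSL - 2*SL = {ca_tube:.4f} um is "
            "negative; geometry violated"
        )
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        dsl = dsl + float(rng.normal(0, noise_sd))
        tw = max(0.0, tw + float(rng.normal(0, noise_sd)))
        sl = max(0.0, sl + float(rng.normal(0, noise_sd)))
        ca_tube = max(0.0, min(dsl, dsl - 2.0 * sl))
        if dsl <= 0:
            warnings.warn("noise drove total_length non-positive; clipping")
            dsl = 1e-6
    return SEMMeasurement(
        total_length=dsl,
        ca_tube_length=ca_tube,
        tube_width=tw,
        slit_length=sl,
        central_area_closure=float(np.clip(closure, 0.0, 1.0)),
    )
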