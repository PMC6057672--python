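"""Polarized-light image model: grey level <-> calcite thickness.

Under crossed polarizers a calcite particle thinner than ~1.55 um (the
first-order birefringence plateau) appears with a brightness close to
proportional to its thickness, which is what makes grey-level mass
estimation possible.  The model here is deliberately first-order:

    grey = background + gain * thickness,  clipped at the saturation
    thickness and at the detector's bit depth.

No interference colours, no retardation non-linearity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class OpticsConfig:
    """Camera/microscope calibration used both to render and to measure.

    pixel_size: um per pixel (0.05 um/px ~ x1000 with a typical camera).
    grey_gain: grey levels per um of calcite thickness.
    saturation_thickness: um; thickness at which grey response plateaus.
    background_level: grey value of empty (birefringence-free) field.
    noise_sd: additive Gaussian read noise, grey levels.
    """

    pixel_size: float = 0.05
    grey_gain: float = 30000.0
    saturation_thickness: float = 1.55
    background_level: float = 800.0
    noise_sd: float = 40.0
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.grey_gain <= 0:
            raise ValueError("grey_gain must be > 0")
        if self.saturation_thickness <= 0:
            raise ValueError("saturation_thickness must be > 0")
        if not 0 <= self.background_level < self.max_grey:
            raise ValueError("background_level outside grey range")

    @property
    def max_grey(self) -> int:
        return 2**self.bit_depth - 1

    def thickness_to_grey(self, thickness: np.ndarray) -> np.ndarray:
        """Apply the linear+saturation response (float grey, no noise)."""
        t = np.clip(thickness, 0.0, self.saturation_thickness)
        return np.clip(self.background_level + self.grey_gain * t, 0, self.max_grey)

    def grey_to_thickness(self, grey: np.ndarray) -> np.ndarray:
        """Invert the linear response; valid below saturation."""
        return (np.asarray(grey, dtype=float) - self.background_level) / self.grey_gain


@dataclass(frozen=True)
class PLMImage:
    """A cross-polarized-light raster plus its calibration.

    raster is row-major with origin at the top-left; coordinates are
    0-based pixel centers.
    """

    raster: np.ndarray
    pixel_size: float
    grey_gain: float
    saturation_thickness: float
    background_level: float

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.grey_gain <= 0:
            raise ValueError("grey_gain must be > 0")
        if self.raster.ndim != 2:
            raise ValueError("raster must be a 2-D array")

    @classmethod
    def from_optics(cls, raster: np.ndarray, optics: OpticsConfig) -> "PLMImage":
        return cls(
            raster=raster,
            pixel_size=optics.pixel_size,
            grey_gain=optics.grey_gain,
            saturation_thickness=optics.saturation_thickness,
            background_level=optics.background_level,
        )
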