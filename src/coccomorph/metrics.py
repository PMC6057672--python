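"""Calcification index: size-normalized degree of coccolith calcification.

The measured mean coccolith mass of a sample confounds size and
calcification.  Normalizing by the mass expected for a coccolith of the
sample's mean length under geometric similarity,

    M_n = k_s * L_c^3 * rho_c        (expected mass, pg)
    C_i = M_s / M_n                  (calcification index, dimensionless)

isolates the calcification degree.  k_s = 0.02 is the published shape
constant for normally calcified *E. huxleyi* Type A coccoliths and
rho_c = 2.7 pg/um^3 the density of calcite; L_c is the sample-mean
corrected length (um) and M_s the sample-mean measured mass (pg).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .shapes import RHO_CALCITE

#: published shape constant for E. huxleyi Type A
K_SHAPE = 0.02


@dataclass(frozen=True)
class CalciteConstants:
    k_s: float = K_SHAPE
    rho_c: float = RHO_CALCITE

    def __post_init__(self) -> None:
        if self.k_s <= 0 or self.rho_c <= 0:
            raise ValueError("k_s and rho_c must be positive")


DEFAULT_CONSTANTS = CalciteConstants()


def normalized_mass(corrected_length,
                    constants: CalciteConstants = DEFAULT_CONSTANTS):
    """Expected coccolith mass M_n = k_s * L_c^3 * rho_c (pg)."""
    L = np.asarray(corrected_length, dtype=float)
    if np.any(L <= 0):
        raise ValueError("corrected length must be > 0")
    out = constants.k_s * L**3 * constants.rho_c
    return float(out) if out.ndim == 0 else out


def calcification_index(mean_mass, mean_corrected_length,
                        constants: CalciteConstants = DEFAULT_CONSTANTS):
    """C_i = M_s / M_n: >1 means heavier than the length-expected mass."""
    M = np.asarray(mean_mass, dtype=float)
    if np.any(M <= 0):
        raise ValueError("mean mass must be > 0")
    out = M / normalized_mass(mean_corrected_length, constants)
    return float(out) if out.ndim == 0 else out


def calcification_index_per_coccolith(masses, corrected_lengths,
                                      constants: CalciteConstants = DEFAULT_CONSTANTS,
                                      ) -> float:
    """Alternative averaging order: mean of individual mass/M_n ratios.

    The default (:func:`calcification_index`) divides the sample-mean mass
    by the normalized mass of the sample-mean length; this variant averages
    per-coccolith indices instead.  The two differ whenever mass and length
    vary jointly within a sample.
    """
    m = np.asarray(masses, dtype=float)
    L = np.asarray(corrected_lengths, dtype=float)
    if m.shape != L.shape or m.size == 0:
        raise ValueError("masses and lengths must be equal-length, non-empty")
    return float(np.mean(m / normalized_mass(L, constants)))


@dataclass(frozen=True)
class SampleSummary:
    """Per-sample morphometric aggregate."""

    station: int
    depth_m: float
    mean_mass: float  # M_s, pg
    mean_corrected_length: float  # L_c, um
    normalized_mass: float  # M_n, pg
    calcification_index: float  # C_i = M_s / M_n
    n_coccoliths: int
    typeA_percent: float = float("nan")
    variety_percent: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_coccoliths < 0:
            raise ValueError("n_coccoliths must be >= 0")
        expected = self.mean_mass / self.normalized_mass
        if np.isfinite(expected) and not np.isclose(
            self.calcification_index, expected, rtol=1e-12, atol=0
        ):
            raise ValueError("calcification_index must equal M_s / M_n")
        if self.variety_percent:
            total = sum(self.variety_percent.values())
            if self.n_coccoliths > 0 and abs(total - 100.0) > 1e-9:
                raise ValueError(
                    f"variety percentages sum to {total}, expected 100"
                )
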