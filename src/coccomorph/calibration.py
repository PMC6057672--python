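"""Length-correction calibration between image-derived and SEM lengths.

Birefringence-based apparent lengths stop at the bright tube edge and so
are biased relative to the total distal shield length measured on SEM
micrographs.  A cross-instrument ordinary-least-squares calibration,
corrected = slope * apparent + intercept, maps one scale onto the other.
The published coefficients for *E. huxleyi* Type A are slope 0.585 and
intercept 0.4537 um; a calibration can also be refit from paired
measurements of the dataset at hand, which is the default workflow.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

#: published coefficients of the apparent-to-corrected length regression
PUBLISHED_SLOPE = 0.585
PUBLISHED_INTERCEPT = 0.4537


class LengthCalibration(RegressorMixin, BaseEstimator):
    """OLS calibration mapping apparent (image) length to corrected length.

    Follows the scikit-learn estimator protocol: ``fit(X, y)`` with X the
    apparent lengths (um, column vector or 1-D) and y the SEM total
    lengths (um); ``predict(X)`` returns corrected lengths.

    Attributes
    ----------
    slope_ : float
        Fitted slope (dimensionless).
    intercept_ : float
        Fitted intercept (um).
    r_squared_ : float
        Coefficient of determination of the fit.
    n_pairs_ : int
        Number of calibration pairs.
    slope_se_, intercept_se_ : float
        Standard errors of the coefficients.

    Examples
    --------
    >>> model = LengthCalibration.published()
    >>> round(model.correct(3.0), 4)
    2.2087
    """

    def __init__(self) -> None:
        pass

    @classmethod
    def published(cls) -> "LengthCalibration":
        """The shipped fallback model with the published coefficients."""
        return cls.from_coefficients(PUBLISHED_SLOPE, PUBLISHED_INTERCEPT)

    @classmethod
    def from_coefficients(cls, slope: float, intercept: float,
                          r_squared: float = float("nan"),
                          n_pairs: int = 2) -> "LengthCalibration":
        """Build an already-calibrated model from known coefficients."""
        if n_pairs < 2:
            raise ValueError("n_pairs must be >= 2")
        m = cls()
        m.slope_ = float(slope)
        m.intercept_ = float(intercept)
        m.r_squared_ = float(r_squared)
        m.n_pairs_ = int(n_pairs)
        m.slope_se_ = float("nan")
        m.intercept_se_ = float("nan")
        return m

    @classmethod
    def identity(cls) -> "LengthCalibration":
        return cls.from_coefficients(1.0, 0.0, 1.0)

    def fit(self, X, y) -> "LengthCalibration":
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.shape != y.shape:
            raise ValueError("X and y must have the same length")
        if x.size < 2:
            raise ValueError("need at least 2 calibration pairs")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValueError("calibration pairs must be finite")
        if np.ptp(x) == 0:
            raise ValueError("apparent lengths are all identical; slope undefined")
        res = stats.linregress(x, y)
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        self.r_squared_ = float(res.rvalue**2)
        self.n_pairs_ = int(x.size)
        self.slope_se_ = float(res.stderr)
        self.intercept_se_ = float(res.intercept_stderr)
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "slope_")
        x = np.asarray(X, dtype=float).reshape(-1)
        return self.slope_ * x + self.intercept_

    def correct(self, apparent_length):
        """Correct apparent length(s); flags non-positive outputs as NaN.

        Raises on non-positive inputs (a zero-length particle is a
        segmentation failure, not a length).
        """
        check_is_fitted(self, "slope_")
        x = np.asarray(apparent_length, dtype=float)
        if np.any(x <= 0):
            raise ValueError("apparent_length must be > 0")
        out = self.slope_ * x + self.intercept_
        bad = out <= 0
        if np.any(bad):
            warnings.warn(
                "corrected length non-positive for some inputs; flagged as NaN"
            )
            out = np.where(bad, np.nan, out)
        return float(out) if np.isscalar(apparent_length) else out

    def inverse(self, corrected_length):
        """The opposite orientation: corrected -> apparent scale."""
        check_is_fitted(self, "slope_")
        if self.slope_ == 0:
            raise ValueError("slope is zero; inverse undefined")
        return (np.asarray(corrected_length, dtype=float) - self.intercept_) / self.slope_


def fit_length_correction(pairs) -> LengthCalibration:
    """Fit the calibration from (apparent_length, sem_total_length) pairs."""
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be a sequence of (apparent, sem) tuples")
    return LengthCalibration().fit(arr[:, 0], arr[:, 1])


def correct_length(apparent_length, model: LengthCalibration | None = None):
    """Apply a calibration (the published one by default) to lengths."""
    if model is None:
        model = LengthCalibration.published()
    return model.correct(apparent_length)
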