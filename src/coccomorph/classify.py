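"""Type A calcification-variety classification from SEM measurements.

The four varieties of the *E. huxleyi* Type A morphotype are defined by
the relation between slit length (SL) and tube width (TW) on the distal
shield, and by the state of the central area:

* **A3a** (high-calcified): central area nearly or completely closed;
  the SL/TW ratio is variable and is not consulted (precedence rule);
* **A1** (low-calcified): SL > TW;
* **A3b** (high-calcified): SL < TW;
* **A2** (medium-calcified): SL ~ TW — the middle class catches ties.

"SL ~ TW" is operationalized by a relative tolerance ``epsilon``:
A1 requires SL > TW*(1+epsilon), A3b requires SL < TW*(1-epsilon), and
everything between — boundaries included — is A2.  "Nearly closed" is a
closure-fraction cut ``closure_cut``.  Both are free parameters of the
rule, configurable and surfaced in the CLI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .imaging import SEMMeasurement

TYPE_A = ("A1", "A2", "A3a", "A3b")


@dataclass(frozen=True)
class ClassificationPolicy:
    epsilon: float = 0.10
    closure_cut: float = 0.75

    def __post_init__(self) -> None:
        if not 0 < self.epsilon < 0.5:
            raise ValueError("epsilon must be in (0, 0.5)")
        if not 0.5 < self.closure_cut <= 1:
            raise ValueError("closure_cut must be in (0.5, 1]")


DEFAULT_POLICY = ClassificationPolicy()


@dataclass(frozen=True)
class VarietyTable:
    """Counts and percentages of the four Type A varieties in a sample."""

    counts: dict
    n_total: int

    def __post_init__(self) -> None:
        if set(self.counts) != set(TYPE_A):
            raise ValueError(f"counts must cover exactly {TYPE_A}")
        if any(c < 0 or int(c) != c for c in self.counts.values()):
            raise ValueError("counts must be non-negative integers")
        if sum(self.counts.values()) != self.n_total:
            raise ValueError("counts must sum to n_total")

    @property
    def percentages(self) -> dict:
        if self.n_total == 0:
            raise ValueError("percentages undefined for an empty sample")
        return {v: 100.0 * self.counts[v] / self.n_total for v in TYPE_A}


def classify_variety(meas: SEMMeasurement,
                     policy: ClassificationPolicy = DEFAULT_POLICY) -> str:
    """Assign one coccolith to A1/A2/A3a/A3b.

    The closure rule has precedence: a (nearly) closed central area is
    A3a regardless of SL/TW.  At the tolerance boundaries
    SL = TW*(1 +/- epsilon) exactly, the label is A2.
    """
    sl, tw, closure = meas.slit_length, meas.tube_width, meas.central_area_closure
    if closure >= policy.closure_cut:
        return "A3a"
    if tw <= 0:
        raise ValueError(
            "tube width must be > 0 for SL/TW classification of an "
            "open-central-area coccolith"
        )
    if sl > tw * (1.0 + policy.epsilon):
        return "A1"
    if sl < tw * (1.0 - policy.epsilon):
        return "A3b"
    return "A2"


class VarietyClassifier(ClassifierMixin, BaseEstimator):
    """Rule-based variety classifier with a scikit-learn interface.

    X rows are ``(slit_length, tube_width, central_area_closure)`` — as an
    (n, 3) array or a DataFrame with those columns.  The rule has no free
    parameters learned from data, so ``fit`` only records the class
    labels; ``epsilon`` and ``closure_cut`` are hyperparameters.
    """

    def __init__(self, epsilon: float = 0.10, closure_cut: float = 0.75):
        self.epsilon = epsilon
        self.closure_cut = closure_cut

    def _policy(self) -> ClassificationPolicy:
        return ClassificationPolicy(self.epsilon, self.closure_cut)

    def fit(self, X=None, y=None) -> "VarietyClassifier":
        self._policy()  # validate hyperparameters
        self.classes_ = np.array(TYPE_A)
        return self

    @staticmethod
    def _columns(X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            return X[["slit_length", "tube_width", "central_area_closure"]].to_numpy(
                dtype=float
            )
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValueError(
                "X must be (n, 3): slit_length, tube_width, central_area_closure"
            )
        return arr

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "classes_"):
            self.fit()
        policy = self._policy()
        arr = self._columns(X)
        labels = [
            classify_variety(
                SEMMeasurement(
                    total_length=2.0 * (sl + tw) + 1.0,  # any valid geometry
                    ca_tube_length=2.0 * tw + 1.0,
                    tube_width=tw,
                    slit_length=sl,
                    central_area_closure=cl,
                ),
                policy,
            )
            for sl, tw, cl in arr
        ]
        return np.array(labels)


def tabulate_varieties(labels) -> VarietyTable:
    """Tabulate Type A variety counts and percentages.

    Percentages are relative to the total Type A coccoliths of the sample
    and therefore sum to 100.  Type B/C coccoliths must be excluded
    upstream; an empty list is an error (percentages undefined).
    """
    labels = list(labels)
    if not labels:
        raise ValueError("no Type A coccoliths; percentages undefined")
    bad = sorted(set(labels) - set(TYPE_A))
    if bad:
        raise ValueError(f"non-Type-A labels present: {bad}")
    counts = {v: labels.count(v) for v in TYPE_A}
    return VarietyTable(counts=counts, n_total=len(labels))
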