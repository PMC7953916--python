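"""Gap-based classification of composite scores.

Observed composite scores fall into two clusters: a conventional cluster
anchored near zero and a regenerative cluster near the rubric maximum.
The dividing score is derived from the widest gap between consecutive
distinct observed scores — no model-based clustering, just the visible
gap.  Scores from systems with different maxima (full cropland, corn
subset, rangeland) are never pooled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .errors import NoGapError, ValidationError

REGENERATIVE = "regenerative"
CONVENTIONAL = "conventional"


@dataclass(frozen=True)
class GapThreshold:
    """The widest gap in a set of composite scores.

    ``gap_low`` is the highest score below the gap, ``gap_high`` the lowest
    score above it; ``dividing_score`` is the midpoint rounded half up.
    """

    gap_low: int
    gap_high: int

    def __post_init__(self) -> None:
        if self.gap_high - self.gap_low < 1:
            raise ValidationError("gap_high must exceed gap_low by >= 1")

    @property
    def gap_width(self) -> int:
        return self.gap_high - self.gap_low

    @property
    def midpoint(self) -> float:
        return (self.gap_low + self.gap_high) / 2.0

    @property
    def dividing_score(self) -> int:
        # round half up, not banker's rounding
        return int(math.floor(self.midpoint + 0.5))

    def to_dict(self) -> dict:
        return {
            "gap_low": self.gap_low,
            "gap_high": self.gap_high,
            "gap_width": self.gap_width,
            "midpoint": self.midpoint,
            "dividing_score": self.dividing_score,
        }


def find_threshold(scores: Sequence[int]) -> GapThreshold:
    """Locate the widest gap between consecutive distinct sorted scores.

    Ties between equally wide gaps break toward the gap at higher scores,
    keeping the conventional cluster anchored at zero.  Deterministic and
    invariant to input order and duplication.
    """
    scores = list(scores)
    if len(scores) == 0:
        raise ValidationError("cannot threshold an empty score sequence")
    distinct = sorted(set(int(s) for s in scores))
    if len(distinct) < 2:
        raise NoGapError(
            "all scores are identical; no gap exists to divide on"
        )
    best = None
    for lo, hi in zip(distinct[:-1], distinct[1:]):
        width = hi - lo
        if best is None or width >= best[0]:  # >= : later (higher) gap wins ties
            best = (width, lo, hi)
    _, lo, hi = best
    return GapThreshold(gap_low=lo, gap_high=hi)


@dataclass(frozen=True)
class Classification:
    label: str
    in_gap: bool


def classify_score(score: int, threshold: GapThreshold) -> Classification:
    """Label one composite score against a fitted threshold.

    Scores at or above ``gap_high`` are regenerative, at or below
    ``gap_low`` conventional.  A score strictly inside the gap (possible
    only for new operations scored after the threshold was fitted) is
    labelled by the dividing score and flagged ``in_gap``.
    """
    score = int(score)
    if score >= threshold.gap_high:
        return Classification(REGENERATIVE, False)
    if score <= threshold.gap_low:
        return Classification(CONVENTIONAL, False)
    label = REGENERATIVE if score >= threshold.dividing_score else CONVENTIONAL
    return Classification(label, True)


class GapThresholdClassifier(ClassifierMixin, BaseEstimator):
    """Classifier splitting operations at the widest score gap.

    ``fit`` consumes the composite scores of one system's operations and
    locates the widest gap between consecutive distinct values; ``predict``
    labels scores ``"regenerative"`` or ``"conventional"``.

    Attributes
    ----------
    threshold_ : GapThreshold
        The fitted gap.
    dividing_score_ : int
        Midpoint of the gap rounded half up.
    classes_ : ndarray of shape (2,)
    """

    def fit(self, X, y=None):
        scores = np.asarray(X).ravel()
        self.threshold_ = find_threshold(scores)
        self.gap_low_ = self.threshold_.gap_low
        self.gap_high_ = self.threshold_.gap_high
        self.dividing_score_ = self.threshold_.dividing_score
        self.classes_ = np.array([CONVENTIONAL, REGENERATIVE])
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "threshold_")
        scores = np.asarray(X).ravel()
        return np.array(
            [classify_score(s, self.threshold_).label for s in scores]
        )

    def in_gap(self, X):
        """Boolean mask of scores falling strictly inside the fitted gap."""
        check_is_fitted(self, "threshold_")
        scores = np.asarray(X).ravel()
        return np.array(
            [classify_score(s, self.threshold_).in_gap for s in scores]
        )
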