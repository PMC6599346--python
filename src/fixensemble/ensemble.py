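"""Combined pathogenicity scores: gP, wgP6, wgP4 and accuracy-proportional weights.

The combined score of a variant is a (weighted) mean of the member tools'
rescaled scores.  Unweighted:

    gP = (1/n) * sum_i s_i

Weighted, with per-tool weights w_i in (0, 1]:

    wgP = sum_i w_i * s_i / sum_i w_i

so the result is always a convex combination in [0, 1] and the same 0.5
cut point applies: score >= 0.5 is called deleterious.  Weights are
proportional to per-tool accuracy, with the most accurate tool anchored at
1 (``compute_weights``); the published default weight set for the six
sequence tools is available as :data:`TABLE2_WEIGHTS`.

wgP6 combines SIFT, PolyPhen-2 HumDiv, SNAP2, MutationAssessor, PANTHER
and PROVEAN; wgP4 drops the two least accurate members (PANTHER, PROVEAN).
PolyPhen-2 HumVar is evaluated alone but never enters a combined score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .tools import BENIGN, DELETERIOUS, ScoreScaler, ToolBinarizer

__all__ = [
    "SIX_TOOLS",
    "FOUR_TOOLS",
    "TABLE2_WEIGHTS",
    "WeightSet",
    "EnsembleConfig",
    "compute_weights",
    "combine",
    "call_combined",
    "EnsembleClassifier",
    "ENSEMBLES",
]

SIX_TOOLS: tuple[str, ...] = (
    "sift",
    "polyphen_humdiv",
    "snap2",
    "mutationassessor",
    "panther",
    "provean",
)
FOUR_TOOLS: tuple[str, ...] = SIX_TOOLS[:4]

#: Published default weights (most accurate tool = 1, others proportional).
TABLE2_WEIGHTS: dict[str, float] = {
    "sift": 1.0,
    "polyphen_humdiv": 0.974,
    "snap2": 0.924,
    "mutationassessor": 0.896,
    "panther": 0.850,
    "provean": 0.772,
}


@dataclass(frozen=True)
class WeightSet:
    """Per-tool weights in (0, 1] with their provenance."""

    weights: Mapping[str, float]
    provenance: str = "user"  # {"computed", "table2_default", "user"}

    def __post_init__(self) -> None:
        if not self.weights:
            raise ValueError("empty weight set")
        if any(w <= 0 for w in self.weights.values()):
            raise ValueError("weights must be positive")
        if self.provenance == "computed":
            if not np.isclose(max(self.weights.values()), 1.0):
                raise ValueError("computed weights must have max exactly 1")

    def __getitem__(self, tool: str) -> float:
        return self.weights[tool]


@dataclass(frozen=True)
class EnsembleConfig:
    """Membership and cut point of one combined score."""

    name: str
    members: tuple[str, ...]
    weighted: bool
    cutoff: float = 0.5

    @property
    def n(self) -> int:
        return len(self.members)


ENSEMBLES: dict[str, EnsembleConfig] = {
    "gP": EnsembleConfig("gP", SIX_TOOLS, weighted=False),
    "wgP6": EnsembleConfig("wgP6", SIX_TOOLS, weighted=True),
    "wgP4": EnsembleConfig("wgP4", FOUR_TOOLS, weighted=True),
}


def compute_weights(accuracies: Mapping[str, float]) -> WeightSet:
    """Accuracy-proportional weights: w_i = accuracy_i / max_j accuracy_j."""
    if not accuracies:
        raise ValueError("no accuracies supplied")
    if any(a <= 0 for a in accuracies.values()):
        raise ValueError("accuracies must be positive")
    top = max(accuracies.values())
    return WeightSet(
        {tool: acc / top for tool, acc in accuracies.items()}, provenance="computed"
    )


def combine(
    scaled: Mapping[str, float | None],
    cfg: EnsembleConfig,
    weights: WeightSet | Mapping[str, float] | None = None,
) -> float | None:
    """Combined score of one variant; ``None`` if any member score is missing."""
    values = []
    for tool in cfg.members:
        v = scaled.get(tool)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return None
        values.append(float(v))
    if not cfg.weighted:
        return float(np.mean(values))
    if weights is None:
        raise ValueError(f"{cfg.name} is weighted but no weights were given")
    w = np.array([weights[t] for t in cfg.members], dtype=float)
    return float(np.dot(w, values) / w.sum())


def call_combined(score: float, cutoff: float = 0.5) -> str:
    """Threshold a combined score: >= cutoff is deleterious."""
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"combined score {score} outside [0, 1]")
    return DELETERIOUS if score >= cutoff else BENIGN


class EnsembleClassifier(ClassifierMixin, BaseEstimator):
    """Weighted-mean meta-predictor over rescaled tool scores.

    Takes a DataFrame of *raw* tool scores (columns named by tool id),
    rescales each member onto [0, 1], averages with per-tool weights and
    thresholds at ``cutoff``.

    Parameters
    ----------
    members:
        Tool ids entering the combination (default: the wgP4 four).
    weights:
        ``"table2"`` for the published defaults, ``"uniform"`` for the
        unweighted mean (gP), ``"accuracy"`` to estimate accuracy-
        proportional weights from ``y`` during :meth:`fit`, or an explicit
        mapping tool id -> weight.
    cutoff:
        Decision threshold on the combined score (default 0.5; the score at
        exactly the cutoff is called deleterious).

    Attributes
    ----------
    weights_ : dict
        Per-member weight actually used.
    classes_ : ndarray
        ``["benign", "deleterious"]``.
    """

    def __init__(
        self,
        members: Sequence[str] = FOUR_TOOLS,
        weights: str | Mapping[str, float] = "table2",
        cutoff: float = 0.5,
    ):
        self.members = members
        self.weights = weights
        self.cutoff = cutoff

    def fit(self, X: pd.DataFrame, y=None) -> "EnsembleClassifier":
        members = tuple(self.members)
        if isinstance(self.weights, str):
            if self.weights == "table2":
                self.weights_ = {t: TABLE2_WEIGHTS[t] for t in members}
                self.weight_provenance_ = "table2_default"
            elif self.weights == "uniform":
                self.weights_ = {t: 1.0 for t in members}
                self.weight_provenance_ = "user"
            elif self.weights == "accuracy":
                if y is None:
                    raise ValueError("weights='accuracy' requires y during fit")
                self.weights_ = dict(
                    compute_weights(self._member_accuracies(X, y)).weights
                )
                self.weight_provenance_ = "computed"
            else:
                raise ValueError(f"unknown weight source {self.weights!r}")
        else:
            self.weights_ = {t: float(self.weights[t]) for t in members}
            self.weight_provenance_ = "user"
        self.members_ = members
        self.classes_ = np.array([BENIGN, DELETERIOUS])
        self.n_features_in_ = X.shape[1]
        return self

    def _member_accuracies(self, X: pd.DataFrame, y) -> dict[str, float]:
        calls = ToolBinarizer(tools=list(self.members), as_int=True).fit_transform(X)
        truth = pd.Series(np.asarray(y), index=X.index).map(
            {DELETERIOUS: 1.0, SEVERE_ALIAS: 1.0, BENIGN: 0.0, NONSEVERE_ALIAS: 0.0}
        )
        if truth.isna().any():
            raise ValueError(
                "y must contain 'severe'/'nonsevere' or 'deleterious'/'benign'"
            )
        acc = {}
        for tool in self.members:
            ok = calls[tool].notna()
            if not ok.any():
                raise ValueError(f"no usable calls for {tool}")
            acc[tool] = float((calls[tool][ok] == truth[ok]).mean() * 100.0)
        return acc

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        """Combined score per row (NaN where any member score is missing)."""
        self._check_fitted()
        scaled = ScoreScaler(tools=list(self.members_)).fit_transform(X)
        w = np.array([self.weights_[t] for t in self.members_])
        mat = scaled[list(self.members_)].to_numpy(dtype=float)
        scores = mat @ w / w.sum()
        scores[np.isnan(mat).any(axis=1)] = np.nan
        return scores

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Binary call per row ('deleterious'/'benign'; None where missing)."""
        scores = self.decision_function(X)
        out = np.empty(len(scores), dtype=object)
        for i, s in enumerate(scores):
            out[i] = None if np.isnan(s) else call_combined(s, self.cutoff)
        return out

    def _check_fitted(self) -> None:
        if not hasattr(self, "weights_"):
            raise AttributeError(
                "EnsembleClassifier is not fitted; call fit(X) first"
            )


SEVERE_ALIAS = "severe"
NONSEVERE_ALIAS = "nonsevere"
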