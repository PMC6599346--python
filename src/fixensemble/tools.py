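"""Per-predictor score conventions: binarization thresholds and [0, 1] rescaling.

Each of the seven predictor outputs lives on its own scale (SIFT on [0, 1]
with low = damaging, SNAP2 on [-100, 100], PANTHER subPSEC negative, ...).
This module holds the registry of those conventions (:class:`ToolSpec`), the
dichotomisation of a raw score into a deleterious/benign call, and the
monotone rescaling of each score onto [0, 1] so scores from different tools
can be averaged.  Transformer classes (:class:`ScoreScaler`,
:class:`ToolBinarizer`) expose the same operations over whole score tables
and compose with scikit-learn pipelines.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "ToolSpec",
    "TOOL_REGISTRY",
    "TOOL_IDS",
    "DELETERIOUS",
    "BENIGN",
    "binarize",
    "scale",
    "ScoreScaler",
    "ToolBinarizer",
]

logger = logging.getLogger(__name__)

DELETERIOUS = "deleterious"
BENIGN = "benign"

#: Categorical strings accepted for the two classifiers that emit labels
#: (PANTHER, PROVEAN) and, defensively, for any tool.
_CATEGORY_ALIASES = {
    "deleterious": DELETERIOUS,
    "damaging": DELETERIOUS,
    "probably damaging": DELETERIOUS,
    "possibly damaging": DELETERIOUS,
    "effect": DELETERIOUS,
    "benign": BENIGN,
    "probably benign": BENIGN,
    "neutral": BENIGN,
    "tolerated": BENIGN,
}


@dataclass(frozen=True)
class ToolSpec:
    """Score conventions for one predictor.

    Parameters
    ----------
    tool_id:
        Canonical lower-case identifier, also the expected table column name.
    native_range:
        Closed interval of raw scores the tool emits.  Out-of-range inputs
        are clamped with a warning (web exports occasionally overshoot).
    threshold:
        The dichotomisation cut point on the native scale.
    deleterious_side:
        ``"below"`` — deleterious iff raw < threshold (strict);
        ``"at_or_below"`` — raw <= threshold;
        ``"at_or_above"`` — raw >= threshold;
        ``"above"`` — raw > threshold.
    scaler_id:
        Which [0, 1] rescaling applies: ``one_minus`` (1 - raw),
        ``identity``, ``div100_square`` ((raw/100)^2), ``log5_piecewise``
        (0 below threshold, log_5 of the clamped score above) or
        ``binary_code`` (1 for deleterious, 0 for benign).
    """

    tool_id: str
    native_range: tuple[float, float]
    threshold: float
    deleterious_side: str
    scaler_id: str
    accepts_categorical: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.native_range
        if not lo <= self.threshold <= hi:
            raise ValueError(
                f"{self.tool_id}: threshold {self.threshold} outside native range"
            )


#: MutationAssessor scores above this are clamped so log_5 stays <= 1.
_MA_LOG_CAP = 5.0

TOOL_REGISTRY: dict[str, ToolSpec] = {
    spec.tool_id: spec
    for spec in (
        # SIFT: tolerated >= 0.05, damaging < 0.05
        ToolSpec("sift", (0.0, 1.0), 0.05, "below", "one_minus"),
        # PolyPhen-2 (both classifier models): benign < 0.5
        ToolSpec("polyphen_humdiv", (0.0, 1.0), 0.5, "at_or_above", "identity"),
        ToolSpec("polyphen_humvar", (0.0, 1.0), 0.5, "at_or_above", "identity"),
        # SNAP2: positive percentage = effect, negative = neutral
        ToolSpec("snap2", (-100.0, 100.0), 0.0, "above", "div100_square"),
        # MutationAssessor: neutral/low impact < 1.9, medium/high >= 1.9
        ToolSpec("mutationassessor", (-6.0, 6.0), 1.9, "at_or_above", "log5_piecewise"),
        # PANTHER subPSEC: probably benign 0 to -3, damaging < -3
        ToolSpec("panther", (-10.0, 0.0), -3.0, "below", "binary_code", True),
        # PROVEAN: neutral > -2.5, deleterious <= -2.5
        ToolSpec("provean", (-14.0, 4.0), -2.5, "at_or_below", "binary_code", True),
    )
}

TOOL_IDS: tuple[str, ...] = tuple(TOOL_REGISTRY)


def _is_missing(raw: object) -> bool:
    if raw is None:
        return True
    if isinstance(raw, float) and math.isnan(raw):
        return True
    return False


def _clamp(spec: ToolSpec, raw: float) -> float:
    lo, hi = spec.native_range
    if raw < lo or raw > hi:
        logger.warning(
            "%s score %.4g outside native range [%g, %g]; clamping",
            spec.tool_id, raw, lo, hi,
        )
        return min(max(raw, lo), hi)
    return raw


def _resolve(tool: ToolSpec | str) -> ToolSpec:
    if isinstance(tool, ToolSpec):
        return tool
    try:
        return TOOL_REGISTRY[tool]
    except KeyError:
        raise KeyError(f"unknown tool id {tool!r}") from None


def binarize(tool: ToolSpec | str, raw: object) -> str | None:
    """Dichotomise a raw score into ``"deleterious"`` / ``"benign"``.

    Missing input (None/NaN) propagates as ``None`` — a variant with no
    score is never silently called benign.  Categorical inputs (PANTHER,
    PROVEAN exports often carry the label, not the number) are accepted.
    """
    spec = _resolve(tool)
    if _is_missing(raw):
        return None
    if isinstance(raw, str):
        key = raw.strip().lower()
        if key in _CATEGORY_ALIASES:
            return _CATEGORY_ALIASES[key]
        try:
            raw = float(raw)
        except ValueError:
            raise ValueError(f"{spec.tool_id}: unrecognized category {raw!r}") from None
    value = _clamp(spec, float(raw))
    t = spec.threshold
    if spec.deleterious_side == "below":
        hit = value < t
    elif spec.deleterious_side == "at_or_below":
        hit = value <= t
    elif spec.deleterious_side == "at_or_above":
        hit = value >= t
    elif spec.deleterious_side == "above":
        hit = value > t
    else:  # pragma: no cover - registry is static
        raise ValueError(f"bad deleterious_side {spec.deleterious_side!r}")
    return DELETERIOUS if hit else BENIGN


def scale(tool: ToolSpec | str, raw: object) -> float | None:
    """Rescale a raw score onto [0, 1] with 1 = most damaging.

    The transforms, per tool:

    * SIFT: ``1 - raw`` (SIFT is inverted relative to PolyPhen-2).
    * PolyPhen-2: used as-is.
    * SNAP2: ``(raw / 100) ** 2`` — note this is even in ``raw``.
    * MutationAssessor: scores below 1.9 (neutral/low impact) collapse to 0;
      otherwise ``log5(raw)`` with ``raw`` clamped to [1.9, 5] so the result
      stays in (0, 1].
    * PANTHER / PROVEAN: 1 if the call is deleterious else 0.
    """
    spec = _resolve(tool)
    if _is_missing(raw):
        return None
    if spec.scaler_id == "binary_code":
        return 1.0 if binarize(spec, raw) == DELETERIOUS else 0.0
    value = _clamp(spec, float(raw))
    if spec.scaler_id == "one_minus":
        return 1.0 - value
    if spec.scaler_id == "identity":
        return value
    if spec.scaler_id == "div100_square":
        return (value / 100.0) ** 2
    if spec.scaler_id == "log5_piecewise":
        if value < spec.threshold:
            return 0.0
        return math.log(min(value, _MA_LOG_CAP)) / math.log(5.0)
    raise ValueError(f"bad scaler_id {spec.scaler_id!r}")  # pragma: no cover


def _frame_apply(X: pd.DataFrame, tools: Sequence[str], fn) -> pd.DataFrame:
    missing = [t for t in tools if t not in X.columns]
    if missing:
        raise KeyError(f"score columns absent from input: {missing}")
    out = {}
    for t in tools:
        out[t] = X[t].map(lambda v, _t=t: fn(_t, v))
    return pd.DataFrame(out, index=X.index)


class ScoreScaler(TransformerMixin, BaseEstimator):
    """Stateless transformer: raw predictor scores -> [0, 1] scaled scores.

    Operates column-wise on a DataFrame whose columns are tool ids; columns
    not in the registry are ignored (set ``tools`` to restrict explicitly).
    """

    def __init__(self, tools: Sequence[str] | None = None):
        self.tools = tools

    def fit(self, X: pd.DataFrame, y=None) -> "ScoreScaler":
        X = self._validate(X)
        self.tools_ = self._selected(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "tools_"):
            self.fit(X)
        X = self._validate(X)
        scaled = _frame_apply(X, self.tools_, scale)
        return scaled.astype(float)

    def _validate(self, X) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            raise TypeError("ScoreScaler expects a pandas DataFrame of raw scores")
        return X

    def _selected(self, X: pd.DataFrame) -> list[str]:
        if self.tools is not None:
            return list(self.tools)
        return [c for c in X.columns if c in TOOL_REGISTRY]


class ToolBinarizer(TransformerMixin, BaseEstimator):
    """Stateless transformer: raw predictor scores -> binary calls.

    Output cells are ``"deleterious"``, ``"benign"`` or ``None`` (missing
    score).  ``as_int=True`` yields floats 1.0 / 0.0 / NaN instead, which is
    what the evaluation routines consume.
    """

    def __init__(self, tools: Sequence[str] | None = None, as_int: bool = False):
        self.tools = tools
        self.as_int = as_int

    def fit(self, X: pd.DataFrame, y=None) -> "ToolBinarizer":
        if not isinstance(X, pd.DataFrame):
            raise TypeError("ToolBinarizer expects a pandas DataFrame of raw scores")
        self.tools_ = (
            list(self.tools)
            if self.tools is not None
            else [c for c in X.columns if c in TOOL_REGISTRY]
        )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "tools_"):
            self.fit(X)
        calls = _frame_apply(X, self.tools_, binarize)
        if self.as_int:
            return calls.apply(
                lambda col: col.map(
                    {DELETERIOUS: 1.0, BENIGN: 0.0}, na_action="ignore"
                ).astype(float)
            )
        return calls
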