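"""Classifier evaluation against clinical severity, overall and per domain.

A deleterious call on a variant with a severe phenotype is a true
positive; the four cells of the confusion matrix follow, and

    sensitivity = TP / (TP + FN) * 100
    specificity = TN / (TN + FP) * 100
    accuracy    = (TP + TN) / (TP + FP + TN + FN) * 100

Degenerate strata occur in this data (the propeptide carries no non-severe
variants at all), so each metric carries a ``defined`` flag; an undefined
metric is reported as 0% with the flag cleared rather than dropped, which
keeps stratified report tables rectangular.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ensemble import ENSEMBLES, EnsembleClassifier, TABLE2_WEIGHTS
from .tools import BENIGN, DELETERIOUS, ToolBinarizer
from .variant_table import GROUPINGS, NONSEVERE, SEVERE, select_group, severity_column

__all__ = [
    "ConfusionMatrix",
    "EvalMetrics",
    "Metric",
    "confusion",
    "sensitivity",
    "specificity",
    "accuracy",
    "deleterious_fraction",
    "concordance",
    "score_table",
    "evaluate_by_group",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.fp + other.fp,
            self.tn + other.tn, self.fn + other.fn,
        )


@dataclass(frozen=True)
class Metric:
    """A percentage with a definedness flag (0/0 ratios report 0%, undefined)."""

    value: float
    defined: bool = True

    def __float__(self) -> float:
        return self.value


@dataclass(frozen=True)
class EvalMetrics:
    sensitivity: Metric
    specificity: Metric
    accuracy: Metric
    deleterious_fraction: Metric
    n: int


def confusion(
    labels: Sequence[str], calls: Sequence[object]
) -> tuple[ConfusionMatrix, int]:
    """Tally calls against severity labels.

    Returns the matrix and the number of variants dropped for missing
    calls.  ``labels`` are 'severe'/'nonsevere'; ``calls`` are
    'deleterious'/'benign' (None/NaN = missing).
    """
    labels = list(labels)
    calls = list(calls)
    if len(labels) != len(calls):
        raise ValueError(
            f"length mismatch: {len(labels)} labels vs {len(calls)} calls"
        )
    tp = fp = tn = fn = dropped = 0
    for lab, call in zip(labels, calls):
        if call is None or (isinstance(call, float) and np.isnan(call)):
            dropped += 1
            continue
        if lab not in (SEVERE, NONSEVERE):
            raise ValueError(f"bad severity label {lab!r}")
        if call not in (DELETERIOUS, BENIGN):
            raise ValueError(f"bad call {call!r}")
        if lab == SEVERE:
            if call == DELETERIOUS:
                tp += 1
            else:
                fn += 1
        else:
            if call == DELETERIOUS:
                fp += 1
            else:
                tn += 1
    return ConfusionMatrix(tp, fp, tn, fn), dropped


def _ratio_pct(num: int, den: int) -> Metric:
    if den == 0:
        return Metric(0.0, defined=False)
    return Metric(num / den * 100.0)


def sensitivity(cm: ConfusionMatrix) -> Metric:
    """TP / (TP + FN) x 100."""
    return _ratio_pct(cm.tp, cm.tp + cm.fn)


def specificity(cm: ConfusionMatrix) -> Metric:
    """TN / (TN + FP) x 100."""
    return _ratio_pct(cm.tn, cm.tn + cm.fp)


def accuracy(cm: ConfusionMatrix) -> Metric:
    """(TP + TN) / n x 100."""
    return _ratio_pct(cm.tp + cm.tn, cm.n)


def deleterious_fraction(calls: Sequence[object]) -> Metric:
    """Percent of non-missing calls that are deleterious."""
    usable = [
        c for c in calls
        if c is not None and not (isinstance(c, float) and np.isnan(c))
    ]
    if not usable:
        return Metric(0.0, defined=False)
    return Metric(sum(c == DELETERIOUS for c in usable) / len(usable) * 100.0)


def concordance(*call_vectors: Sequence[object]) -> tuple[int, Metric]:
    """Count and percent of variants on which all given call vectors agree.

    Positions where any vector has a missing call are excluded.
    """
    if len(call_vectors) < 2:
        raise ValueError("concordance needs at least two call vectors")
    lengths = {len(v) for v in call_vectors}
    if len(lengths) != 1:
        raise ValueError(f"call vectors have unequal lengths {sorted(lengths)}")
    agree = total = 0
    for calls in zip(*call_vectors):
        if any(
            c is None or (isinstance(c, float) and np.isnan(c)) for c in calls
        ):
            continue
        total += 1
        if len(set(calls)) == 1:
            agree += 1
    if total == 0:
        return 0, Metric(0.0, defined=False)
    return agree, Metric(agree / total * 100.0)


def score_table(
    df: pd.DataFrame,
    weights: str | Mapping[str, float] = "table2",
    cutoff: float = 0.5,
    ensembles: Iterable[str] = ("gP", "wgP6", "wgP4"),
) -> pd.DataFrame:
    """Append per-tool calls, combined scores and combined calls to a table.

    Adds ``severity`` (dichotomised phenotype), ``call_<tool>`` for every
    tool with a score column, ``scaled_<tool>`` for combination members,
    and ``score_<ens>`` / ``call_<ens>`` for each requested combined
    function.  The unweighted gP always uses uniform weights regardless of
    ``weights``.
    """
    out = df.copy()
    out["severity"] = severity_column(df)
    binarizer = ToolBinarizer().fit(df)
    calls = binarizer.transform(df)
    for tool in binarizer.tools_:
        out[f"call_{tool}"] = calls[tool]
    for name in ensembles:
        cfg = ENSEMBLES[name]
        clf = EnsembleClassifier(
            members=cfg.members,
            weights="uniform" if not cfg.weighted else weights,
            cutoff=cutoff,
        ).fit(df)
        scaled = clf.decision_function(df)
        from .tools import ScoreScaler

        sc = ScoreScaler(tools=list(cfg.members)).fit_transform(df)
        for tool in cfg.members:
            col = f"scaled_{tool}"
            if col not in out.columns:
                out[col] = sc[tool]
        out[f"score_{name}"] = scaled
        out[f"call_{name}"] = clf.predict(df)
    return out


def evaluate_by_group(
    scored: pd.DataFrame,
    toolset: Sequence[str] | None = None,
    groupings: Sequence[str] = ("all_five",) + tuple(GROUPINGS)[:5],
) -> pd.DataFrame:
    """Stratified metrics: one row per (grouping, tool-or-ensemble).

    ``scored`` is the output of :func:`score_table`.  ``toolset`` defaults
    to every ``call_*`` column present.  Columns: grouping, tool, tp, fp,
    tn, fn, n, n_missing, sensitivity_pct, specificity_pct, accuracy_pct,
    deleterious_pct plus ``*_defined`` flags.
    """
    if toolset is None:
        toolset = [c.removeprefix("call_") for c in scored.columns
                   if c.startswith("call_")]
    rows = []
    for grouping in groupings:
        subset = select_group(scored, grouping)
        labels = list(subset["severity"])
        for tool in toolset:
            col = f"call_{tool}"
            if col not in scored.columns:
                raise KeyError(f"no call column for {tool!r}; run score_table first")
            calls = list(subset[col])
            cm, dropped = confusion(labels, calls)
            sens, spec, acc = sensitivity(cm), specificity(cm), accuracy(cm)
            frac = deleterious_fraction(calls)
            rows.append({
                "grouping": grouping,
                "tool": tool,
                "tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn,
                "n": cm.n,
                "n_missing": dropped,
                "sensitivity_pct": sens.value,
                "sensitivity_defined": sens.defined,
                "specificity_pct": spec.value,
                "specificity_defined": spec.defined,
                "accuracy_pct": acc.value,
                "accuracy_defined": acc.defined,
                "deleterious_pct": frac.value,
                "deleterious_count": cm.tp + cm.fp,
            })
    return pd.DataFrame(rows)
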