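"""Genotype-phenotype association: 2x2 tests of call vs. clinical severity.

For each domain grouping and each tool or combined function, the 2x2 table

                     severe   nonsevere
    call deleterious   a          b
    call benign        c          d

is tested with the two-tailed Pearson chi-square test (no continuity
correction, 1 df) and Fisher's exact test (two-sided, point-probability
rule — the SPSS/R convention).  Both p-values are always reported;
significance at alpha = 0.05 is emitted as a flag column, never used to
filter rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tools import BENIGN, DELETERIOUS
from .variant_table import NONSEVERE, SEVERE, select_group

__all__ = [
    "AssociationResult",
    "chi2_2x2",
    "fisher_exact_2x2",
    "contingency_from_calls",
    "associate_by_group",
    "TABLE3_GROUPINGS",
]

#: The stratification used for the association report: all five domains
#: together, the Gla domain, EGF-2, and the light chain (Gla+EGF-1+EGF-2).
TABLE3_GROUPINGS: tuple[str, ...] = ("leader_plus_light", "gla", "egf2", "light_chain")

ALPHA = 0.05


@dataclass(frozen=True)
class AssociationResult:
    """One tested 2x2 table with both test results."""

    table: tuple[tuple[int, int], tuple[int, int]]
    chi2: float | None
    chi2_p: float | None
    fisher_p: float
    df: int = 1

    @property
    def significant(self) -> bool:
        p = self.chi2_p if self.chi2_p is not None else self.fisher_p
        return p < ALPHA


def _as_table(table) -> np.ndarray:
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    if (arr < 0).any():
        raise ValueError("table cells must be non-negative")
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("table cells must be integer counts")
    return arr.astype(np.int64)


def chi2_2x2(table) -> tuple[float, float]:
    """Pearson chi-square statistic (uncorrected) and its p-value, df = 1.

    Algebraically n(ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)); undefined when a
    margin is zero.
    """
    arr = _as_table(table)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("chi-square is undefined for a table with a zero margin")
    chi2, p, dof, _ = stats.chi2_contingency(arr, correction=False)
    assert dof == 1
    return float(chi2), float(p)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p: sum of hypergeometric point probabilities
    (over tables with the observed margins) no larger than the observed
    table's.  Degenerate margins give p = 1."""
    arr = _as_table(table)
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


def contingency_from_calls(
    labels: Sequence[str], calls: Sequence[object]
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Build the call-by-severity 2x2 table, dropping missing calls.

    Cells: [[deleterious & severe, deleterious & nonsevere],
            [benign & severe,      benign & nonsevere]] — i.e. [[TP, FP],
    [FN, TN]] in the evaluation module's terms.
    """
    if len(labels) != len(calls):
        raise ValueError("labels and calls must be aligned")
    a = b = c = d = 0
    for lab, call in zip(labels, calls):
        if call is None or (isinstance(call, float) and np.isnan(call)):
            continue
        if lab == SEVERE:
            if call == DELETERIOUS:
                a += 1
            else:
                c += 1
        elif lab == NONSEVERE:
            if call == DELETERIOUS:
                b += 1
            else:
                d += 1
        else:
            raise ValueError(f"bad severity label {lab!r}")
    return ((a, b), (c, d))


def analyze_table(table) -> AssociationResult:
    """Run both tests on one 2x2 table; chi-square is None on zero margins."""
    arr = _as_table(table)
    zero_margin = (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any()
    if zero_margin:
        chi2 = chi2_p = None
    else:
        chi2, chi2_p = chi2_2x2(arr)
    fisher_p = fisher_exact_2x2(arr)
    return AssociationResult(
        table=tuple(map(tuple, arr.tolist())), chi2=chi2, chi2_p=chi2_p,
        fisher_p=fisher_p,
    )


def associate_by_group(
    scored: pd.DataFrame,
    toolset: Sequence[str] | None = None,
    groupings: Sequence[str] = TABLE3_GROUPINGS,
) -> pd.DataFrame:
    """Association report: one row per (grouping, tool-or-ensemble).

    ``scored`` is the output of :func:`fixensemble.evaluation.score_table`.
    Rows with a zero margin (e.g. a stratum with no non-severe variants)
    carry NaN chi-square fields and a ``degenerate`` flag instead of being
    dropped.
    """
    if toolset is None:
        toolset = [c.removeprefix("call_") for c in scored.columns
                   if c.startswith("call_")]
    rows = []
    for grouping in groupings:
        subset = select_group(scored, grouping)
        labels = list(subset["severity"])
        for tool in toolset:
            calls = list(subset[f"call_{tool}"])
            table = contingency_from_calls(labels, calls)
            res = analyze_table(table)
            (a, b), (c, d) = res.table
            rows.append({
                "grouping": grouping,
                "tool": tool,
                "del_severe": a, "del_nonsevere": b,
                "ben_severe": c, "ben_nonsevere": d,
                "chi2": np.nan if res.chi2 is None else res.chi2,
                "chi2_p": np.nan if res.chi2_p is None else res.chi2_p,
                "fisher_p": res.fisher_p,
                "degenerate": res.chi2 is None,
                "significant": res.significant,
            })
    return pd.DataFrame(rows)
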