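"""Per-variant score table: data model, I/O, phenotype dichotomisation, domain groups.

The unit of analysis is one missense variant of coagulation factor IX,
restricted to the five N-terminal domains encoded by F9 exons 1-5: signal
peptide, propeptide (the prepro leader, negative Yoshitake residue
numbers), then the Gla, EGF-1 and EGF-2 domains that form the light chain.
Phenotype is residual FIX activity as percent of normal, dichotomised into
severe (0-5%) versus non-severe (> 5%); a three-level clinical label
(severe < 1%, moderate 1-5%, mild > 5%) is accepted as a fallback when no
activity measurement is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import math
import numpy as np
import pandas as pd
import yaml

from .tools import TOOL_IDS

__all__ = [
    "DOMAINS",
    "GROUPINGS",
    "SEVERE",
    "NONSEVERE",
    "VariantRecord",
    "TableConfig",
    "TableParseError",
    "parse_variant_table",
    "write_scored_table",
    "records_to_frame",
    "frame_to_records",
    "dichotomize_phenotype",
    "severity_column",
    "select_group",
    "assign_domain",
]

logger = logging.getLogger(__name__)

DOMAINS: tuple[str, ...] = ("signal_peptide", "propeptide", "gla", "egf1", "egf2")

SEVERE = "severe"
NONSEVERE = "nonsevere"

#: Domain groupings used for stratified evaluation and association:
#: each single domain, the light chain (Gla + EGF-1 + EGF-2) and the full
#: leader + light chain set (all five domains).
GROUPINGS: dict[str, frozenset[str]] = {
    **{d: frozenset({d}) for d in DOMAINS},
    "light_chain": frozenset({"gla", "egf1", "egf2"}),
    "leader_plus_light": frozenset(DOMAINS),
    "all_five": frozenset(DOMAINS),
}

_META_COLUMNS = (
    "variant_id",
    "protein_change",
    "position",
    "domain",
    "fix_activity_pct",
    "severity_label",
)
CANONICAL_COLUMNS: tuple[str, ...] = _META_COLUMNS + TOOL_IDS


class TableParseError(ValueError):
    """Raised when a variant table cannot be interpreted."""


@dataclass
class VariantRecord:
    """One missense variant with its phenotype and raw predictor scores.

    ``position`` uses Yoshitake numbering: mature-chain residues are
    positive, prepro-leader residues negative; zero does not exist.
    ``raw_scores`` maps tool id -> raw score (float, or a categorical call
    string for PANTHER/PROVEAN); absent tools are simply missing keys.
    """

    variant_id: str
    protein_change: str
    position: int
    domain: str
    fix_activity_pct: float | None = None
    severity_label: str | None = None
    raw_scores: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.position == 0:
            raise ValueError(f"{self.variant_id}: position 0 does not exist "
                             "(Yoshitake numbering skips zero)")
        if self.domain not in DOMAINS:
            raise ValueError(f"{self.variant_id}: unknown domain {self.domain!r}")
        if self.fix_activity_pct is not None and self.fix_activity_pct < 0:
            raise ValueError(f"{self.variant_id}: negative FIX activity")


@dataclass
class TableConfig:
    """Parsing configuration: dialect, column-name mapping, missing tokens.

    ``column_map`` maps canonical column names to the names used in the
    file; identity for names absent from the map.  ``domain_intervals``
    optionally assigns domains from residue positions for rows whose domain
    cell is empty (only EGF-1, residues 93-129, ships as a default — the
    other boundaries are numbering-scheme dependent and must be supplied).
    """

    sep: str = "\t"
    column_map: dict[str, str] = field(default_factory=dict)
    missing_tokens: tuple[str, ...] = ("", "NA", ".")
    domain_intervals: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"egf1": (93, 129)}
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TableConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        if "sep" in raw:
            kwargs["sep"] = str(raw["sep"])
        if "column_map" in raw:
            kwargs["column_map"] = dict(raw["column_map"])
        if "missing_tokens" in raw:
            kwargs["missing_tokens"] = tuple(raw["missing_tokens"])
        if "domain_intervals" in raw:
            kwargs["domain_intervals"] = {
                k: (int(v[0]), int(v[1])) for k, v in raw["domain_intervals"].items()
            }
        return cls(**kwargs)

    def file_name(self, canonical: str) -> str:
        return self.column_map.get(canonical, canonical)


def assign_domain(position: int, intervals: Mapping[str, tuple[int, int]]) -> str | None:
    """Look up the domain whose residue interval contains ``position``."""
    for domain, (lo, hi) in intervals.items():
        if lo <= position <= hi:
            return domain
    return None


def _coerce_score(tool: str, value: object, row: int) -> object:
    if isinstance(value, str):
        try:
            return float(value)
        except ValueError:
            # categorical calls are legitimate for PANTHER/PROVEAN
            if tool in ("panther", "provean"):
                return value
            raise TableParseError(
                f"row {row}: non-numeric score {value!r} in column {tool!r}"
            ) from None
    return float(value)


def parse_variant_table(
    path: str | Path, config: TableConfig | None = None
) -> list[VariantRecord]:
    """Read a delimited variant table into :class:`VariantRecord` objects.

    Row order is preserved; empty score cells become missing values, never
    zeros.  Required columns: variant_id, protein_change, position, domain
    (may be blank if ``config.domain_intervals`` covers the position) and at
    least one of fix_activity_pct / severity_label per row for downstream
    evaluation.
    """
    config = config or TableConfig()
    df = pd.read_csv(
        path,
        sep=config.sep,
        dtype=str,
        keep_default_na=False,
        na_values=list(config.missing_tokens),
        skipinitialspace=True,
    )
    rename = {config.file_name(c): c for c in CANONICAL_COLUMNS}
    df = df.rename(columns=rename)
    required = ("variant_id", "protein_change", "position", "domain")
    for col in required:
        if col not in df.columns:
            raise TableParseError(f"required column {col!r} not found "
                                  f"(have: {list(df.columns)})")
    records: list[VariantRecord] = []
    for idx, row in df.iterrows():
        try:
            position = int(float(row["position"]))
        except (TypeError, ValueError):
            raise TableParseError(
                f"row {idx}: non-integer position {row['position']!r}"
            ) from None
        domain = row["domain"] if pd.notna(row["domain"]) else None
        if domain is None:
            domain = assign_domain(position, config.domain_intervals)
            if domain is None:
                raise TableParseError(
                    f"row {idx}: no domain given and position {position} is not "
                    "covered by the configured domain intervals"
                )
        activity = None
        if "fix_activity_pct" in df.columns and pd.notna(row["fix_activity_pct"]):
            activity = float(row["fix_activity_pct"])
        label = None
        if "severity_label" in df.columns and pd.notna(row["severity_label"]):
            label = str(row["severity_label"]).strip().lower()
        raw_scores: dict[str, object] = {}
        for tool in TOOL_IDS:
            if tool in df.columns and pd.notna(row[tool]):
                raw_scores[tool] = _coerce_score(tool, row[tool], idx)
        records.append(
            VariantRecord(
                variant_id=str(row["variant_id"]),
                protein_change=str(row["protein_change"]),
                position=position,
                domain=domain,
                fix_activity_pct=activity,
                severity_label=label,
                raw_scores=raw_scores,
            )
        )
    return records


def records_to_frame(records: Iterable[VariantRecord]) -> pd.DataFrame:
    """Flatten records into the canonical-column DataFrame."""
    rows = []
    for r in records:
        row: dict[str, object] = {
            "variant_id": r.variant_id,
            "protein_change": r.protein_change,
            "position": r.position,
            "domain": r.domain,
            "fix_activity_pct": r.fix_activity_pct,
            "severity_label": r.severity_label,
        }
        for tool in TOOL_IDS:
            row[tool] = r.raw_scores.get(tool)
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))
    return df


def frame_to_records(df: pd.DataFrame) -> list[VariantRecord]:
    """Inverse of :func:`records_to_frame` (extra columns are ignored)."""
    records = []
    for _, row in df.iterrows():
        raw_scores = {
            t: row[t]
            for t in TOOL_IDS
            if t in df.columns and row[t] is not None and not _isna(row[t])
        }
        activity = row.get("fix_activity_pct")
        label = row.get("severity_label")
        records.append(
            VariantRecord(
                variant_id=str(row["variant_id"]),
                protein_change=str(row["protein_change"]),
                position=int(row["position"]),
                domain=str(row["domain"]),
                fix_activity_pct=None if _isna(activity) else float(activity),
                severity_label=None if _isna(label) else str(label),
                raw_scores=raw_scores,
            )
        )
    return records


def _isna(v: object) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


def dichotomize_phenotype(record: VariantRecord) -> str:
    """Collapse phenotype into ``"severe"`` (FIX activity 0-5%) / ``"nonsevere"``.

    The activity interval for severe is closed at 5: the clinical moderate
    category (1-5%) belongs to the severe side of the dichotomy.  When both
    an activity value and a clinical label are present, activity wins; a
    disagreement is logged.
    """
    activity = record.fix_activity_pct
    label = record.severity_label
    if activity is None and label is None:
        raise ValueError(
            f"{record.variant_id}: neither FIX activity nor severity label present"
        )
    if activity is not None:
        if activity < 0:
            raise ValueError(f"{record.variant_id}: negative FIX activity")
        result = SEVERE if activity <= 5.0 else NONSEVERE
        if label is not None:
            from_label = _label_to_binary(record.variant_id, label)
            if from_label != result:
                logger.warning(
                    "%s: activity %.3g%% and label %r disagree; using activity",
                    record.variant_id, activity, label,
                )
        return result
    return _label_to_binary(record.variant_id, label)


def _label_to_binary(variant_id: str, label: str) -> str:
    key = label.strip().lower()
    if key in ("severe", "moderate"):
        return SEVERE
    if key == "mild":
        return NONSEVERE
    raise ValueError(f"{variant_id}: unknown severity label {label!r}")


def severity_column(df: pd.DataFrame) -> pd.Series:
    """Vectorised dichotomisation over a canonical-column frame."""
    return pd.Series(
        [dichotomize_phenotype(r) for r in frame_to_records(df)],
        index=df.index,
        name="severity",
    )


def select_group(
    records: Sequence[VariantRecord] | pd.DataFrame, grouping: str | Iterable[str]
):
    """Subset records (or a frame) to one domain grouping, preserving order.

    ``grouping`` is a name from :data:`GROUPINGS` or an explicit iterable of
    domain names.
    """
    if isinstance(grouping, str):
        try:
            members = GROUPINGS[grouping]
        except KeyError:
            raise KeyError(
                f"unknown grouping {grouping!r}; known: {sorted(GROUPINGS)}"
            ) from None
    else:
        members = frozenset(grouping)
        unknown = members - set(DOMAINS)
        if unknown:
            raise KeyError(f"unknown domains in grouping: {sorted(unknown)}")
    if isinstance(records, pd.DataFrame):
        return records[records["domain"].isin(members)]
    return [r for r in records if r.domain in members]


def write_scored_table(
    df: pd.DataFrame | Sequence[VariantRecord], path: str | Path, sep: str = "\t"
) -> None:
    """Write a (possibly scored) table as delimited UTF-8 text, re-parseable."""
    if not isinstance(df, pd.DataFrame):
        df = records_to_frame(df)
    df.to_csv(path, sep=sep, index=False)
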