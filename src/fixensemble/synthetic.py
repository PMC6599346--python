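"""Seeded generator of synthetic variant tables with known ground truth.

Emulates the structure of the study data: 215 F9 missense variants spread
over the five N-terminal domains with a fixed severe/non-severe
composition per domain, plus raw scores for the seven predictors on their
native scales.  Each tool is given an operating point (sensitivity,
specificity); per variant the tool's *intended* binary call is drawn at
that operating point and a raw score is then drawn uniformly on the
matching side of the tool's threshold, so binarization recovers the
intended call exactly.  Composition counts are exact, not expected values;
tool errors are independent across tools (real conservation-based
predictors are correlated — a documented limitation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .tools import DELETERIOUS, TOOL_REGISTRY, TOOL_IDS, ToolSpec, binarize
from .variant_table import DOMAINS, VariantRecord

__all__ = [
    "GeneratorConfig",
    "STUDY_COMPOSITION",
    "STUDY_OPERATING_POINTS",
    "study_mimic_config",
    "generate_variant_table",
    "recover_operating_characteristics",
]

#: Per-domain (n_severe, n_nonsevere) composition of the 215-variant study
#: set: 11/2 signal peptide, 16/0 propeptide, 55/16 Gla, 41/27 EGF-1,
#: 39/8 EGF-2 (162 severe, 53 non-severe in total).
STUDY_COMPOSITION: dict[str, tuple[int, int]] = {
    "signal_peptide": (11, 2),
    "propeptide": (16, 0),
    "gla": (55, 16),
    "egf1": (41, 27),
    "egf2": (39, 8),
}

#: Demonstration operating points (sensitivity, specificity) per tool.
#: SIFT and MutationAssessor use the study's printed overall values
#: (93.2/18.9 and 92/26.4); the rest are fixed so that the expected number
#: of deleterious calls at the 162/53 composition matches each tool's
#: published deleterious count (see docs/methods.md).
STUDY_OPERATING_POINTS: dict[str, tuple[float, float]] = {
    "sift": (0.932, 0.189),
    "polyphen_humdiv": (0.914, 0.226),
    "polyphen_humvar": (0.864, 0.264),
    "snap2": (0.877, 0.208),
    "mutationassessor": (0.920, 0.264),
    "panther": (0.870, 0.189),
    "provean": (0.840, 0.245),
}

#: Residue intervals per domain used for synthetic positions (Yoshitake
#: numbering: prepro leader negative, zero skipped).
_DOMAIN_POSITIONS: dict[str, tuple[int, int]] = {
    "signal_peptide": (-46, -19),
    "propeptide": (-18, -1),
    "gla": (1, 92),
    "egf1": (93, 129),
    "egf2": (130, 192),
}

_AA3 = (
    "Ala Arg Asn Asp Cys Gln Glu Gly His Ile Leu Lys Met Phe Pro Ser Thr Trp"
    " Tyr Val"
).split()


@dataclass(frozen=True)
class GeneratorConfig:
    """Composition, per-tool operating points, and seed.

    Same seed, same config -> byte-identical output tables.
    """

    composition: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(STUDY_COMPOSITION)
    )
    operating_points: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(STUDY_OPERATING_POINTS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for domain in self.composition:
            if domain not in DOMAINS:
                raise ValueError(f"unknown domain {domain!r}")
        if any(n < 0 for pair in self.composition.values() for n in pair):
            raise ValueError("composition counts must be non-negative")
        if sum(n for pair in self.composition.values() for n in pair) == 0:
            raise ValueError("empty table requested")
        for tool, (sens, spec) in self.operating_points.items():
            if tool not in TOOL_REGISTRY:
                raise ValueError(f"unknown tool {tool!r}")
            if not (0 <= sens <= 1 and 0 <= spec <= 1):
                raise ValueError(f"{tool}: operating point outside [0, 1]^2")

    @property
    def n_total(self) -> int:
        return sum(n for pair in self.composition.values() for n in pair)


def study_mimic_config(seed: int = 0) -> GeneratorConfig:
    """The demonstration preset: study composition + operating points."""
    return GeneratorConfig(seed=seed)


def _draw_raw_score(
    spec: ToolSpec, deleterious: bool, rng: np.random.Generator
) -> float:
    """Uniform raw score on the requested side of the tool's threshold.

    Uniform-within-side is deliberately assumption-free: no score
    distribution is available to emulate.  A draw landing exactly on the
    threshold boundary of the wrong side is redrawn, guaranteeing the
    round trip ``binarize(draw) == intended``.
    """
    lo, hi = spec.native_range
    t = spec.threshold
    if spec.deleterious_side in ("below", "at_or_below"):
        interval = (lo, t) if deleterious else (t, hi)
    else:
        interval = (t, hi) if deleterious else (lo, t)
    want = DELETERIOUS if deleterious else "benign"
    for _ in range(100):
        value = float(rng.uniform(*interval))
        if binarize(spec, value) == want:
            return round(value, 4)
    raise RuntimeError(  # pragma: no cover - interval would have to be empty
        f"{spec.tool_id}: could not draw a {want} score in {interval}"
    )


def generate_variant_table(cfg: GeneratorConfig) -> list[VariantRecord]:
    """Generate one synthetic variant table.

    Per variant: domain and true severity follow the composition exactly;
    FIX activity is uniform on [0, 5] for severe and (5, 100] for
    non-severe, with a consistent clinical label (severe < 1%, moderate
    1-5%, mild > 5%); each tool's raw score realises an intended call
    drawn at the tool's operating point.
    """
    rng = np.random.default_rng(cfg.seed)
    records: list[VariantRecord] = []
    idx = 0
    for domain in DOMAINS:
        n_severe, n_nonsevere = cfg.composition.get(domain, (0, 0))
        for severe in [True] * n_severe + [False] * n_nonsevere:
            idx += 1
            lo, hi = _DOMAIN_POSITIONS[domain]
            position = int(rng.integers(lo, hi + 1))
            if position == 0:  # pragma: no cover - intervals exclude 0
                position = 1
            ref, alt = rng.choice(_AA3, size=2, replace=False)
            if severe:
                activity = round(float(rng.uniform(0.0, 5.0)), 3)
                label = "severe" if activity < 1.0 else "moderate"
            else:
                activity = round(float(rng.uniform(5.0, 100.0)), 3)
                if activity <= 5.0:
                    activity = 5.001
                label = "mild"
            raw_scores: dict[str, object] = {}
            for tool in TOOL_IDS:
                if tool not in cfg.operating_points:
                    continue
                sens, spec_target = cfg.operating_points[tool]
                p_del = sens if severe else 1.0 - spec_target
                intended = bool(rng.random() < p_del)
                raw_scores[tool] = _draw_raw_score(
                    TOOL_REGISTRY[tool], intended, rng
                )
            records.append(
                VariantRecord(
                    variant_id=f"SYN{idx:04d}",
                    protein_change=f"p.{ref}{position}{alt}",
                    position=position,
                    domain=domain,
                    fix_activity_pct=activity,
                    severity_label=label,
                    raw_scores=raw_scores,
                )
            )
    return records


def recover_operating_characteristics(
    records: list[VariantRecord], tool: str
) -> tuple[float, float]:
    """Empirical (sensitivity, specificity) of one tool's binarized calls.

    Parameter-recovery harness for the generator: on large tables the
    estimates converge to the configured operating point.
    """
    from .evaluation import confusion, sensitivity, specificity
    from .variant_table import dichotomize_phenotype

    labels = [dichotomize_phenotype(r) for r in records]
    calls = [binarize(tool, r.raw_scores.get(tool)) for r in records]
    cm, _ = confusion(labels, calls)
    return sensitivity(cm).value / 100.0, specificity(cm).value / 100.0
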