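"""Confusion matrices, sensitivity/specificity/accuracy, concordance, stratified reports."""

import numpy as np
import pandas as pd
import pytest

import fixensemble as fx
from fixensemble.evaluation import ConfusionMatrix


def brute_confusion(labels, calls):
    """Independent tally, written as a flat quadruple count."""
    pairs = [(l, c) for l, c in zip(labels, calls) if c in ("deleterious", "benign")]
    return ConfusionMatrix(
        tp=sum(1 for l, c in pairs if l == "severe" and c == "deleterious"),
        fp=sum(1 for l, c in pairs if l == "nonsevere" and c == "deleterious"),
        tn=sum(1 for l, c in pairs if l == "nonsevere" and c == "benign"),
        fn=sum(1 for l, c in pairs if l == "severe" and c == "benign"),
    )


def test_confusion_all_severe_all_deleterious():
    cm, dropped = fx.confusion(["severe"] * 16, ["deleterious"] * 16)
    assert (cm.tp, cm.fp, cm.tn, cm.fn, dropped) == (16, 0, 0, 0, 0)


def test_confusion_empty_and_mismatch():
    cm, _ = fx.confusion([], [])
    assert cm.n == 0
    with pytest.raises(ValueError):
        fx.confusion(["severe"], [])


def test_confusion_matches_brute_force_on_random_vectors():
    rng = np.random.default_rng(42)
    for _ in range(25):
        n = int(rng.integers(1, 60))
        labels = list(rng.choice(["severe", "nonsevere"], size=n))
        calls = list(rng.choice(["deleterious", "benign", None], size=n))
        cm, dropped = fx.confusion(labels, calls)
        assert cm == brute_confusion(labels, calls)
        assert cm.n + dropped == n


@pytest.mark.parametrize(
    "cm,sens,spec,acc",
    [
        # exon-1 style stratum: 11 severe / 2 nonsevere
        (ConfusionMatrix(tp=7, fp=1, tn=1, fn=4), 7 / 11 * 100, 50.0, 61.538461538),
        (ConfusionMatrix(tp=14, fp=0, tn=0, fn=2), 87.5, 0.0, 87.5),
        (ConfusionMatrix(tp=151, fp=43, tn=10, fn=11), 93.2098765, 18.8679245, 74.8837209),
        (ConfusionMatrix(tp=0, fp=2, tn=0, fn=5), 0.0, 0.0, 0.0),
    ],
)
def test_metric_formulas(cm, sens, spec, acc):
    assert fx.sensitivity(cm).value == pytest.approx(sens)
    assert fx.specificity(cm).value == pytest.approx(spec)
    assert fx.accuracy(cm).value == pytest.approx(acc)


def test_undefined_metrics_report_zero_with_flag():
    no_negatives = ConfusionMatrix(tp=3, fp=0, tn=0, fn=1)
    spec = fx.specificity(no_negatives)
    assert spec.value == 0.0 and not spec.defined
    assert fx.sensitivity(no_negatives).defined
    empty = ConfusionMatrix(0, 0, 0, 0)
    assert not fx.accuracy(empty).defined


def test_accuracy_prevalence_identity():
    rng = np.random.default_rng(7)
    for _ in range(50):
        tp, fp, tn, fn = (int(x) for x in rng.integers(1, 40, size=4))
        cm = ConfusionMatrix(tp, fp, tn, fn)
        prev = (tp + fn) / cm.n
        expect = fx.sensitivity(cm).value * prev + fx.specificity(cm).value * (1 - prev)
        assert fx.accuracy(cm).value == pytest.approx(expect)


def test_deleterious_fraction():
    calls = ["deleterious"] * 194 + ["benign"] * 21
    assert fx.deleterious_fraction(calls).value == pytest.approx(194 / 215 * 100)
    assert fx.deleterious_fraction(["benign"] * 5).value == 0.0
    assert not fx.deleterious_fraction([None, float("nan")]).defined


def test_concordance_extremes_and_oracle():
    a = ["deleterious", "benign", "deleterious"]
    assert fx.concordance(a, list(a))[1].value == 100.0
    flipped = ["benign", "deleterious", "benign"]
    assert fx.concordance(a, flipped)[1].value == 0.0
    rng = np.random.default_rng(3)
    for _ in range(20):
        n = int(rng.integers(1, 80))
        u = list(rng.choice(["deleterious", "benign"], size=n))
        v = list(rng.choice(["deleterious", "benign"], size=n))
        count, pct = fx.concordance(u, v)
        expect = sum(x == y for x, y in zip(u, v))
        assert count == expect and pct.value == pytest.approx(expect / n * 100)


def test_concordance_three_way_requires_unanimity():
    a = ["deleterious", "deleterious"]
    b = ["deleterious", "benign"]
    c = ["deleterious", "deleterious"]
    count, pct = fx.concordance(a, b, c)
    assert count == 1 and pct.value == 50.0
    with pytest.raises(ValueError):
        fx.concordance(a, ["deleterious"])


def test_score_table_adds_expected_columns(scored_frame):
    for name in ("gP", "wgP6", "wgP4"):
        assert f"score_{name}" in scored_frame and f"call_{name}" in scored_frame
        s = scored_frame[f"score_{name}"].dropna()
        assert (s >= 0).all() and (s <= 1).all()
        assert (
            (scored_frame[f"call_{name}"] == "deleterious")
            == (scored_frame[f"score_{name}"] >= 0.5)
        ).all()
    assert scored_frame["severity"].isin(["severe", "nonsevere"]).all()


def test_evaluate_by_group_equals_direct_subset_computation(scored_frame):
    report = fx.evaluate_by_group(
        scored_frame,
        groupings=["all_five", "gla", "light_chain"],
    )
    for _, row in report.iterrows():
        subset = fx.select_group(scored_frame, row["grouping"])
        cm, _ = fx.confusion(
            list(subset["severity"]), list(subset[f"call_{row['tool']}"])
        )
        assert (row.tp, row.fp, row.tn, row.fn) == (cm.tp, cm.fp, cm.tn, cm.fn)
        assert row.sensitivity_pct == pytest.approx(fx.sensitivity(cm).value)
        assert row.specificity_pct == pytest.approx(fx.specificity(cm).value)
        assert row.accuracy_pct == pytest.approx(fx.accuracy(cm).value)


def test_per_domain_matrices_sum_to_all_five(scored_frame):
    report = fx.evaluate_by_group(
        scored_frame, toolset=["sift"], groupings=["all_five", *fx.DOMAINS]
    )
    total = report[report.grouping == "all_five"].iloc[0]
    parts = report[report.grouping != "all_five"]
    for cell in ("tp", "fp", "tn", "fn"):
        assert parts[cell].sum() == total[cell]


def test_metrics_invariant_under_row_permutation(scored_frame):
    rng = np.random.default_rng(0)
    shuffled = scored_frame.sample(frac=1.0, random_state=rng).reset_index(drop=True)
    a = fx.evaluate_by_group(scored_frame, toolset=["wgP4"], groupings=["all_five"])
    b = fx.evaluate_by_group(shuffled, toolset=["wgP4"], groupings=["all_five"])
    pd.testing.assert_frame_equal(a, b)


def test_perfect_predictor_everywhere(study_frame):
    scored = fx.score_table(study_frame)
    scored["call_oracle"] = np.where(
        scored["severity"] == "severe", "deleterious", "benign"
    )
    report = fx.evaluate_by_group(
        scored, toolset=["oracle"], groupings=["all_five", *fx.DOMAINS]
    )
    assert (report.accuracy_pct == 100.0).all()
    assert (report.sensitivity_pct[report.sensitivity_defined] == 100.0).all()
    assert (report.specificity_pct[report.specificity_defined] == 100.0).all()
    # the propeptide has no non-severe variants: specificity undefined there
    propep = report[report.grouping == "propeptide"].iloc[0]
    assert not propep.specificity_defined and propep.specificity_pct == 0.0
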