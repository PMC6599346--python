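"""Variant-table parsing, phenotype dichotomisation and domain grouping."""

import math

import pandas as pd
import pytest

import fixensemble as fx
from fixensemble.variant_table import TableConfig, assign_domain, severity_column

TSV_FIXTURE = """\
variant_id\tprotein_change\tposition\tdomain\tfix_activity_pct\tseverity_label\tsift\tpolyphen_humdiv\tpolyphen_humvar\tsnap2\tmutationassessor\tpanther\tprovean
V1\tp.Leu-24Pro\t-24\tsignal_peptide\t0.5\tsevere\t0.01\t0.99\t0.97\t60\t3.2\t-5.1\t-6.0
V2\tp.Gln96Pro\t96\tegf1\t2.0\t\t\t0.40\t0.35\t-20\t0.5\t-1.0\t-1.2
V3\tp.Gly105Asp\t105\tegf1\t40\tmild\t0.30\t0.10\t0.20\t-55\t0.2\tprobably benign\t1.0
"""


@pytest.fixture()
def fixture_path(tmp_path):
    p = tmp_path / "variants.tsv"
    p.write_text(TSV_FIXTURE)
    return p


def test_parse_preserves_rows_order_and_missing_cells(fixture_path):
    records = fx.parse_variant_table(fixture_path)
    assert [r.variant_id for r in records] == ["V1", "V2", "V3"]
    # empty SIFT cell on row 2 is missing, not zero
    assert "sift" not in records[1].raw_scores
    assert records[0].raw_scores["sift"] == 0.01
    # categorical PANTHER call is kept as a string
    assert records[2].raw_scores["panther"] == "probably benign"
    assert records[1].severity_label is None


def test_parse_respects_column_name_mapping_and_order(fixture_path, tmp_path):
    df = pd.read_csv(fixture_path, sep="\t")
    df = df.rename(columns={"sift": "SIFT_score"})
    df = df[list(df.columns[::-1])]  # scramble column order
    p = tmp_path / "renamed.tsv"
    df.to_csv(p, sep="\t", index=False)
    cfg = TableConfig(column_map={"sift": "SIFT_score"})
    records = fx.parse_variant_table(p, cfg)
    assert records[0].raw_scores["sift"] == 0.01


def test_parse_errors_name_the_problem(tmp_path):
    p = tmp_path / "bad.tsv"
    p.write_text("variant_id\tprotein_change\tposition\n")
    with pytest.raises(fx.TableParseError, match="domain"):
        fx.parse_variant_table(p)
    p.write_text(
        "variant_id\tprotein_change\tposition\tdomain\tsift\n"
        "V1\tp.A1B\t1\tgla\tnot-a-number\n"
    )
    with pytest.raises(fx.TableParseError, match="row 0"):
        fx.parse_variant_table(p)


def test_domain_interval_fallback_covers_egf1_only(tmp_path):
    p = tmp_path / "nodomain.tsv"
    p.write_text(
        "variant_id\tprotein_change\tposition\tdomain\n"
        "V1\tp.Gln96Pro\t96\t\n"
    )
    (rec,) = fx.parse_variant_table(p)
    assert rec.domain == "egf1"
    assert assign_domain(50, TableConfig().domain_intervals) is None


@pytest.mark.parametrize(
    "activity,label,expected",
    [
        (5.0, None, "severe"),      # the severe interval is closed at 5%
        (5.01, None, "nonsevere"),
        (0.0, None, "severe"),
        (None, "moderate", "severe"),
        (None, "severe", "severe"),
        (None, "mild", "nonsevere"),
        (0.4, "mild", "severe"),    # activity wins on disagreement
    ],
)
def test_dichotomize_phenotype(activity, label, expected):
    rec = fx.VariantRecord("V", "p.A1B", 1, "gla",
                           fix_activity_pct=activity, severity_label=label)
    assert fx.dichotomize_phenotype(rec) == expected


def test_dichotomize_requires_some_phenotype_and_is_idempotent():
    rec = fx.VariantRecord("V", "p.A1B", 1, "gla")
    with pytest.raises(ValueError):
        fx.dichotomize_phenotype(rec)
    rec2 = fx.VariantRecord("V", "p.A1B", 1, "gla", fix_activity_pct=3.0)
    assert fx.dichotomize_phenotype(rec2) == fx.dichotomize_phenotype(rec2)


def test_position_zero_and_negative_activity_rejected():
    with pytest.raises(ValueError):
        fx.VariantRecord("V", "p.A0B", 0, "gla")
    with pytest.raises(ValueError):
        fx.VariantRecord("V", "p.A1B", 1, "gla", fix_activity_pct=-1.0)


def test_select_group_counts_on_study_composition(study_records):
    light = fx.select_group(study_records, "light_chain")
    assert len(light) == 186  # 55+41+39 severe + 16+27+8 nonsevere
    labels = [fx.dichotomize_phenotype(r) for r in light]
    assert labels.count("severe") == 135 and labels.count("nonsevere") == 51
    propep = fx.select_group(study_records, "propeptide")
    assert len(propep) == 16
    assert all(fx.dichotomize_phenotype(r) == "severe" for r in propep)
    assert fx.select_group(study_records, "all_five") == study_records


def test_single_domains_partition_the_table(study_records):
    sizes = [len(fx.select_group(study_records, d)) for d in fx.DOMAINS]
    assert sum(sizes) == len(study_records)
    seen = set()
    for d in fx.DOMAINS:
        ids = {r.variant_id for r in fx.select_group(study_records, d)}
        assert not ids & seen
        seen |= ids


def test_unknown_grouping_raises(study_records):
    with pytest.raises(KeyError, match="heavy_chain"):
        fx.select_group(study_records, "heavy_chain")


def test_write_parse_round_trip(study_records, tmp_path):
    p = tmp_path / "table.tsv"
    fx.write_scored_table(study_records, p)
    back = fx.parse_variant_table(p)
    assert len(back) == len(study_records)
    for orig, rt in zip(study_records, back):
        assert rt.variant_id == orig.variant_id
        assert rt.position == orig.position
        assert rt.domain == orig.domain
        assert rt.fix_activity_pct == pytest.approx(orig.fix_activity_pct)
        assert set(rt.raw_scores) == set(orig.raw_scores)
        for tool, v in orig.raw_scores.items():
            assert rt.raw_scores[tool] == pytest.approx(v)


def test_write_empty_set_gives_header_only(tmp_path):
    p = tmp_path / "empty.tsv"
    fx.write_scored_table([], p)
    lines = p.read_text().splitlines()
    assert len(lines) == 1 and lines[0].startswith("variant_id")


def test_severity_column_matches_record_level(study_frame, study_records):
    col = severity_column(study_frame)
    assert list(col) == [fx.dichotomize_phenotype(r) for r in study_records]
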