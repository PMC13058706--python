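"""Slide enumeration, cumulative cohort aggregation, derived proportions."""

import numpy as np
import pandas as pd
import pytest

import mifquant as mq
from mifquant import datasets
from mifquant.report import (
    SlideSummary, aggregate_cohort, cohort_from_counts, cohort_from_json,
    cohort_table, enumerate_slide, read_report_json, slide_table, write_report,
)


def _summary(slide_id="s", area=1.0, total=100, **counts) -> SlideSummary:
    base = {"b_cell": 0, "plasma_cell": 0, "permissive_pb": 0, "bona_fide_pb": 0}
    base.update(counts)
    return SlideSummary(slide_id, area, total, base)


def test_density_is_count_over_area(pipeline_small):
    s = _summary(b_cell=500, area=2.0)
    assert s.density("b_cell") == 250.0


def test_empty_phenotype_table_gives_zero_counts():
    empty = pd.DataFrame()
    s = enumerate_slide(empty, area_mm2=1.0, slide_id="e")
    assert all(v == 0 for v in s.counts.values())
    assert s.total_cells == 0
    assert s.fraction("b_cell") == 0.0  # zero-safe


def test_nonpositive_area_rejected():
    with pytest.raises(ValueError, match="area"):
        enumerate_slide(pd.DataFrame(), area_mm2=0.0, slide_id="x")


def test_phantom_slide_counts_match_planted_truth(pipeline_small):
    _, truth, res = pipeline_small
    assert res.summary.counts == mq.expected_gate_counts(truth)
    assert res.summary.total_cells == (~truth["is_artifact"]).sum()


def test_denominator_toggle(pipeline_small):
    _, truth, res = pipeline_small
    s_all = enumerate_slide(res.phenotypes, res.tissue_mask.area_mm2, "s",
                            denominator="all")
    assert s_all.total_cells == len(truth)  # artifacts back in the denominator


# ------------------------------------------------- published-count arithmetic

def test_published_tonsil_derived_proportions():
    c = cohort_from_counts("TN", {"b_cell": 355850, "plasma_cell": 31831,
                                  "permissive_pb": 3812, "bona_fide_pb": 3352})
    assert round(c.pct_bona_fide_of_permissive, 2) == 87.93
    assert round(c.pct_bona_fide_of_asc, 2) == 9.53


def test_published_kidney_derived_proportions():
    c = cohort_from_counts("KD", {"plasma_cell": 3807, "permissive_pb": 282,
                                  "bona_fide_pb": 212})
    assert c.asc_count == 4019
    assert round(c.pct_bona_fide_of_asc, 2) == 5.27
    assert round(c.pct_bona_fide_of_permissive, 2) == 75.18


def test_tonsil_b_to_pc_ratio_rounds_to_11():
    cohorts = datasets.validation_cohorts()
    tn = cohorts["TN"]
    assert round(tn.counts["b_cell"] / tn.counts["plasma_cell"]) == 11


def test_single_slide_cohort_equals_slide():
    s = _summary(b_cell=10, plasma_cell=4, area=2.5, total=50)
    c = aggregate_cohort([s], "solo")
    assert c.counts == s.counts
    assert c.area_mm2 == s.area_mm2
    assert c.density("b_cell") == s.density("b_cell")
    assert c.fraction("b_cell") == s.fraction("b_cell")


def test_aggregation_additive_and_order_invariant():
    a = _summary("a", 1.0, 40, b_cell=10, bona_fide_pb=2)
    b = _summary("b", 3.0, 60, b_cell=5, plasma_cell=7)
    c = _summary("c", 2.0, 0, permissive_pb=3)
    c1 = aggregate_cohort([a, b, c], "x")
    c2 = aggregate_cohort([c, a, b], "x")
    assert c1.counts == c2.counts == {"b_cell": 15, "plasma_cell": 7,
                                      "permissive_pb": 3, "bona_fide_pb": 2}
    assert c1.area_mm2 == 6.0 and c1.total_cells == 100
    # splitting one slide into two with the same union changes nothing
    b1 = _summary("b1", 1.5, 30, b_cell=2, plasma_cell=7)
    b2 = _summary("b2", 1.5, 30, b_cell=3)
    c3 = aggregate_cohort([a, b1, b2, c], "x")
    assert c3.counts == c1.counts and c3.area_mm2 == c1.area_mm2
    assert c3.total_cells == c1.total_cells


def test_cohort_density_is_count_weighted():
    # cumulative count / cumulative area, not the mean of slide densities
    a = _summary("a", 1.0, 10, b_cell=100)   # 100 /mm2
    b = _summary("b", 9.0, 10, b_cell=0)     # 0 /mm2
    c = aggregate_cohort([a, b], "x")
    assert c.density("b_cell") == pytest.approx(10.0)


def test_empty_cohort_rejected():
    with pytest.raises(ValueError):
        aggregate_cohort([], "none")


def test_zero_denominator_reports_missing_not_zero():
    c = cohort_from_counts("empty", {"b_cell": 0, "plasma_cell": 0,
                                     "permissive_pb": 0, "bona_fide_pb": 0})
    assert c.pct_bona_fide_of_permissive is None
    assert c.pct_bona_fide_of_asc is None
    assert c.pct_cd19_of_bcells is None


def test_report_round_trip_and_schema(tmp_path):
    cohorts = list(datasets.validation_cohorts().values())
    slides = [_summary("s1", 2.0, 100, b_cell=10)]
    paths = write_report(cohorts, slides, tmp_path / "report",
                         config_hash="deadbeef")
    doc = read_report_json(paths["json"])
    assert doc["schema_version"] == 1
    assert doc["config_hash"] == "deadbeef"
    for entry, orig in zip(doc["cohorts"], cohorts):
        back = cohort_from_json(entry)
        assert back == orig
        assert entry["derived"]["pct_bona_fide_of_permissive"] == pytest.approx(
            orig.pct_bona_fide_of_permissive)

    table = pd.read_csv(paths["cohorts_csv"], comment="#")
    # one value column per cohort, mirroring the two-cohort layout
    assert {"TN", "KD"} <= set(table.columns)
    # rows per gate follow count / density / fraction / derived order
    b_rows = table[table["gate"] == "bona_fide_pb"]["metric"].tolist()
    assert b_rows[:3] == ["count", "density_per_mm2", "pct_of_total"]
    assert "pct_bona_fide_of_permissive" in b_rows
    assert "pct_bona_fide_of_asc" in b_rows
    got = table[(table["gate"] == "bona_fide_pb")
                & (table["metric"] == "pct_bona_fide_of_permissive")]
    assert got["TN"].iloc[0] == 87.93 and got["KD"].iloc[0] == 75.18


def test_slide_table_layout(pipeline_small):
    _, _, res = pipeline_small
    df = slide_table([res.summary])
    assert list(df.columns) == ["slide_id", "gate", "count", "density_per_mm2",
                                "pct_of_total"]
    assert np.allclose(df["count"] / res.tissue_mask.area_mm2,
                       df["density_per_mm2"])


def test_unwritable_path_raises(tmp_path):
    with pytest.raises(OSError):
        write_report([cohort_from_counts("x", {"b_cell": 1})], [],
                     tmp_path / "no_such_dir" / "report")
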