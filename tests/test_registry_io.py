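"""Parsing the registry XML dialect and flattening to result rows."""

import zipfile

import pytest

from trialkg.registry_io import (
    EFFICACY_COLUMNS,
    RegistryParseError,
    read_records,
    read_trial_xml,
    scan_corpus,
    to_efficacy_rows,
    write_records,
)
from trialkg.synthetic import GeneratorConfig, generate_trial

from conftest import analysis_stats, make_trial_xml


def test_full_document_parses_all_sections():
    xml = make_trial_xml(
        "NCT01050998",
        arms=[("Abatacept", "Experimental"), ("Placebo", "Placebo Comparator")],
        outcomes=[
            (
                "Percentage of Participants Who Achieved Disease Activity Score of 28 Joints",
                "primary",
                [{"group_titles": ["Abatacept", "Placebo"], "stats": analysis_stats(p_value="0.003")}],
            )
        ],
        events=[
            {
                "arm_title": "Abatacept",
                "event_title": "Pneumonia",
                "category": "Infections and infestations",
                "severity": "serious",
                "affected": 2,
                "at_risk": 100,
            }
        ],
        conditions=["rheumatoid arthritis"],
    )
    rec = read_trial_xml(xml.encode())
    assert rec.nct_id == "NCT01050998"
    assert [a.role for a in rec.design_arms] == ["experimental", "comparator"]
    assert len(rec.outcomes) == 1 and len(rec.outcomes[0].analyses) == 1
    assert rec.outcomes[0].rank == "primary"
    an = rec.outcomes[0].analyses[0]
    assert an.group_titles == ["Abatacept", "Placebo"]
    assert an.p_value_raw == "0.003"
    assert len(rec.events) == 1
    ev = rec.events[0]
    assert (ev.affected, ev.at_risk, ev.severity) == (2, 100, "serious")


def test_design_only_document_yields_empty_results():
    xml = make_trial_xml("NCT00000001", arms=[("A", "Experimental"), ("B", "Placebo Comparator")])
    rec = read_trial_xml(xml.encode())
    assert rec.outcomes == [] and rec.events == []


def test_counts_accepted_as_attributes_and_child_elements():
    for as_attrs in (True, False):
        xml = make_trial_xml(
            "NCT00000002",
            arms=[("A", "Experimental"), ("B", "Placebo Comparator")],
            events=[
                {
                    "arm_title": "A",
                    "event_title": "Syncope",
                    "category": "Nervous system disorders",
                    "severity": "serious",
                    "affected": 3,
                    "at_risk": 50,
                    "counts_as_attrs": as_attrs,
                }
            ],
        )
        rec = read_trial_xml(xml.encode())
        assert rec.events[0].affected == 3 and rec.events[0].at_risk == 50


@pytest.mark.parametrize(
    "arm_type,role",
    [
        ("Experimental", "experimental"),
        ("Placebo Comparator", "comparator"),
        ("Active Comparator", "comparator"),
        ("Sham Comparator", "comparator"),
        ("Other", "other"),
        ("No Intervention", "other"),
    ],
)
def test_arm_role_mapping(arm_type, role):
    xml = make_trial_xml("NCT00000003", arms=[("Arm X", arm_type)])
    assert read_trial_xml(xml.encode()).design_arms[0].role == role


def test_malformed_xml_and_missing_nct_id_are_rejected(tmp_path):
    bad = tmp_path / "broken.xml"
    bad.write_text("<clinical_study><id_info>")
    with pytest.raises(RegistryParseError) as err:
        read_trial_xml(bad)
    assert "broken.xml" in str(err.value)
    with pytest.raises(RegistryParseError, match="nct_id"):
        read_trial_xml(b"<clinical_study><brief_title>x</brief_title></clinical_study>")


def test_parser_reproduces_generator_manifest_counts():
    cfg = GeneratorConfig(n_trials=0, seed=11)
    for index in range(10):
        xml, fragment = generate_trial(cfg, seed=11, index=index)
        rec = read_trial_xml(xml.encode())
        counts = fragment["counts"]
        assert len(rec.design_arms) == counts["n_arms"]
        assert len(rec.outcomes) == counts["n_outcomes"]
        assert sum(len(o.analyses) for o in rec.outcomes) == counts["n_analyses"]
        assert len(rec.events) == counts["n_events"]


def test_scan_corpus_sorted_and_skips_unreadable(tmp_path):
    names = ["NCT00000005.xml", "NCT00000001.xml", "NCT00000003.xml"]
    for name in names:
        nct = name[:-4]
        (tmp_path / name).write_text(make_trial_xml(nct, arms=[("A", "Experimental")]))
    (tmp_path / "NCT00000002.xml").write_text("<clinical_study><truncated")
    scan = scan_corpus(tmp_path)
    records = list(scan)
    assert [r.nct_id for r in records] == ["NCT00000001", "NCT00000003", "NCT00000005"]
    assert scan.skipped == ["NCT00000002.xml"]


def test_scan_corpus_reads_zip_archives(tmp_path):
    zpath = tmp_path / "corpus.zip"
    with zipfile.ZipFile(zpath, "w") as zf:
        for i in (2, 1):
            nct = f"NCT0000000{i}"
            zf.writestr(f"{nct}.xml", make_trial_xml(nct, arms=[("A", "Experimental")]))
    assert [r.nct_id for r in scan_corpus(zpath)] == ["NCT00000001", "NCT00000002"]


def test_efficacy_rows_flag_non_two_group_analyses():
    xml = make_trial_xml(
        "NCT03400800",
        arms=[("Inclisiran", "Experimental"), ("Placebo", "Placebo Comparator")],
        outcomes=[
            (
                "Percentage Change in LDL-C From Baseline to Day 510",
                "primary",
                [
                    {"group_titles": ["Inclisiran", "Placebo"], "stats": analysis_stats(p_value="<0.0001")},
                    {"group_titles": ["Inclisiran", "Placebo"], "stats": analysis_stats(p_value="0.2")},
                ],
            ),
            (
                "Secondary endpoint",
                "secondary",
                [{"group_titles": ["Inclisiran", "Placebo", "Inclisiran High"], "stats": analysis_stats()}],
            ),
        ],
    )
    rows = to_efficacy_rows(read_trial_xml(xml.encode()))
    assert len(rows) == 3
    assert [r.excluded for r in rows] == [False, False, True]
    assert rows[0].p_value_raw == "<0.0001"
    assert rows[0].group_titles == ["Inclisiran", "Placebo"]


def test_write_records_round_trip(tmp_path):
    rows = [
        {"nct_id": "NCT00000001", "groups": ["A", "B"], "p": "<0.05", "x": 1.5, "flag": True, "none": None},
        {"nct_id": "NCT00000002", "groups": [], "p": None, "x": 2, "flag": False, "none": None},
    ]
    for fmt in ("csv", "jsonl"):
        p1 = tmp_path / f"a.{fmt}"
        write_records(rows, p1, fmt)
        back = read_records(p1, fmt)
        assert [r["groups"] for r in back] == [["A", "B"], []]
        assert back[0]["p"] == "<0.05" and back[1]["p"] is None
        p2 = tmp_path / f"b.{fmt}"
        write_records(back, p2, fmt)
        assert p1.read_bytes() == p2.read_bytes()


def test_write_records_empty_gives_header_only(tmp_path):
    p = tmp_path / "empty.csv"
    write_records([], p, "csv", columns=EFFICACY_COLUMNS)
    lines = p.read_text().strip().splitlines()
    assert len(lines) == 1 and lines[0].split(",")[0] == "nct_id"
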