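"""Knowledge-graph assembly, export round trips, and queries."""

import networkx as nx
import pytest

from trialkg.arm_resolution import ArmAssignment
from trialkg.kg_builder import (
    GraphBuildError,
    build_graph,
    export_graph,
    query_subgraph,
    summarize,
    to_networkx,
)
from trialkg.outcome_typing import MeshTerm, OutcomeLabel
from trialkg.registry_io import EfficacyRow
from trialkg.safety_linkage import SafetyRecord
from trialkg.significance import ClassifiedRow


def _crow(nct="NCT00000001", outcome="Outcome O", label="positive", groups=("Drug X", "Placebo"),
          conditions=("infection",), itypes=("Drug",)):
    row = EfficacyRow(
        nct_id=nct, group_titles=list(groups), outcome_title=outcome, outcome_rank="primary",
        p_value_raw="0.01", method=None, param_name_raw=None, param_value=None,
        ci_percent=None, ci_lower_raw=None, ci_upper_raw=None, non_inferiority=None,
        conditions=list(conditions), intervention_types=list(itypes), excluded=False,
    )
    return ClassifiedRow(row=row, label=label, basis="p_value" if label != "indeterminate" else "none")


def _assign(nct="NCT00000001", i="Drug X", c="Placebo"):
    return ArmAssignment(nct_id=nct, intervention_group=i, comparator_group=c,
                         score_intervention=1.0, score_comparator=1.0, method="exact")


def _safety(nct="NCT00000001", arm="Drug X", event="Pneumonia", cat="Infections and infestations"):
    return SafetyRecord(nct, arm, event, cat, "serious", 2, 100, matched_group=arm, match_method="string")


def test_one_row_one_safety_record_graph_shape():
    nodes, edges = build_graph([_crow()], [_assign()], [_safety()])
    by_type = {}
    for n in nodes.values():
        by_type.setdefault(n.node_type, []).append(n)
    assert len(by_type["intervention_arm"]) == 1
    assert len(by_type["outcome"]) == 1
    assert len(by_type["adverse_event"]) == 1
    kinds = [e.edge_type for e in edges]
    assert kinds.count("positive") == 1 and kinds.count("has_ae") == 1
    pos = next(e for e in edges if e.edge_type == "positive")
    attrs = dict(pos.attrs)
    assert attrs["comparator"] == "Placebo" and attrs["nct_id"] == "NCT00000001"
    assert attrs["condition"] == "infection"
    ae = next(e for e in edges if e.edge_type == "has_ae")
    assert dict(ae.attrs)["ratio"] == pytest.approx(0.02)


def test_empty_inputs_give_empty_graph():
    nodes, edges = build_graph([], [])
    assert nodes == {} and edges == []


def test_indeterminate_and_unassigned_rows_omitted():
    rows = [_crow(label="indeterminate"), _crow(outcome="O2")]
    nodes, edges = build_graph(rows, [None, _assign()])
    assert [e.edge_type for e in edges] == ["positive"]


def test_title_level_dedup_across_trials():
    rows = [_crow(nct="NCT00000001"), _crow(nct="NCT00000002", label="negative")]
    nodes, edges = build_graph(rows, [_assign("NCT00000001"), _assign("NCT00000002")])
    arm_nodes = [n for n in nodes.values() if n.node_type == "intervention_arm"]
    outcome_nodes = [n for n in nodes.values() if n.node_type == "outcome"]
    assert len(arm_nodes) == 1 and len(outcome_nodes) == 1  # same titles, one node
    assert sorted(e.edge_type for e in edges) == ["negative", "positive"]


def test_taxonomy_edges_and_dangling_detection():
    label = OutcomeLabel("Outcome O", [MeshTerm("D12.776", "Proteins")], frozenset({"biomarker"}))
    nodes, edges = build_graph(
        [_crow()], [_assign()], [_safety()],
        outcome_labels={"Outcome O": label},
        concept_maps={"Drug X": ["Imipenem"]},
    )
    is_a = [e for e in edges if e.edge_type == "is_a"]
    dst_types = sorted(nodes[e.dst].node_type for e in is_a)
    assert dst_types == ["adverse_event_category", "concept", "outcome_type"]
    with pytest.raises(GraphBuildError, match="dangling"):
        build_graph([_crow()], [_assign(i="Not A Group")])
    with pytest.raises(GraphBuildError, match="misaligned"):
        build_graph([_crow()], [])


def test_conservation_and_no_orphans(small_result):
    """Edges conserve counts and every main node is reachable."""
    res = small_result
    classified_assigned = sum(
        1 for c, a in zip(res.classified, res.assignments)
        if c.label in ("positive", "negative") and a is not None
    )
    kinds = [e.edge_type for e in res.edges]
    assert kinds.count("positive") + kinds.count("negative") == classified_assigned
    assert kinds.count("has_ae") == len(res.safety)
    touched = {e.src for e in res.edges} | {e.dst for e in res.edges}
    assert set(res.nodes) == touched  # no orphan nodes of any type


def test_deterministic_ids_across_runs(small_corpus):
    from trialkg.pipeline import run_pipeline

    corpus_dir, _ = small_corpus
    r1 = run_pipeline(corpus_dir)
    r2 = run_pipeline(corpus_dir)
    assert sorted(r1.nodes) == sorted(r2.nodes)
    assert r1.edges == r2.edges


def test_graphml_round_trip(tmp_path):
    nodes, edges = build_graph([_crow()], [_assign()], [_safety()])
    (path,) = export_graph(nodes, edges, tmp_path, format="graphml")
    g = nx.read_graphml(path)
    assert g.number_of_nodes() == len(nodes)
    assert g.number_of_edges() == len(edges)


def test_neo4j_csv_headers_and_byte_stability(tmp_path):
    nodes, edges = build_graph([_crow()], [_assign()], [_safety()])
    out1 = export_graph(nodes, edges, tmp_path / "a", format="neo4j_csv")
    header = (tmp_path / "a" / "nodes.csv").read_text().splitlines()[0]
    assert header.startswith("id:ID,:LABEL")
    eheader = (tmp_path / "a" / "edges.csv").read_text().splitlines()[0]
    assert eheader.startswith(":START_ID,:END_ID,:TYPE")
    out2 = export_graph(nodes, edges, tmp_path / "b", format="neo4j_csv")
    for f1, f2 in zip(out1, out2):
        assert f1.read_bytes() == f2.read_bytes()


def test_empty_graph_exports_header_only(tmp_path):
    files = export_graph({}, [], tmp_path, format="neo4j_csv")
    for f in files:
        assert len(f.read_text().strip().splitlines()) == 1


def test_cypher_and_jsonl_exports(tmp_path):
    nodes, edges = build_graph([_crow()], [_assign()])
    (cypher,) = export_graph(nodes, edges, tmp_path, format="cypher")
    text = cypher.read_text()
    assert "MERGE (n:intervention_arm" in text
    assert "MERGE (a)-[r:positive]->(b)" in text
    (jl,) = export_graph(nodes, edges, tmp_path, format="jsonl")
    lines = jl.read_text().strip().splitlines()
    assert len(lines) == len(nodes) + len(edges)
    with pytest.raises(ValueError):
        export_graph(nodes, edges, tmp_path, format="parquet")


def test_query_subgraph_matches_title_concept_and_event_pattern():
    rows = [_crow(groups=("DrugX 10 mg", "Placebo"))]
    assigns = [_assign(i="DrugX 10 mg")]
    safety = [
        _safety(arm="DrugX 10 mg", event="Wound infection", cat="Infections and infestations"),
        _safety(arm="DrugX 10 mg", event="Sepsis", cat="Infections and infestations"),
        _safety(arm="DrugX 10 mg", event="Headache", cat="Nervous system disorders"),
    ]
    nodes, edges = build_graph(rows, assigns, safety, concept_maps={"DrugX 10 mg": ["Imipenem"]})
    sub_n, sub_e = query_subgraph(nodes, edges, "drugx", "infection")
    kinds = [e.edge_type for e in sub_e]
    assert kinds.count("has_ae") == 2  # Wound infection + Sepsis (category match)
    assert kinds.count("positive") == 1
    # concept-only match: pattern hits the linked concept, not the arm title
    sub_n2, sub_e2 = query_subgraph(nodes, edges, "imipenem", "infection")
    assert len(sub_e2) == len(sub_e)
    empty_n, empty_e = query_subgraph(nodes, edges, "nonexistent")
    assert empty_n == {} and empty_e == []


def test_summarize_splits_and_coverage():
    rows = [
        _crow(outcome="LDL Cholesterol", label="positive"),
        _crow(outcome="LDL Cholesterol", label="negative", nct="NCT00000002"),
        _crow(outcome="Quality of Life Score", label="negative", nct="NCT00000003"),
    ]
    assigns = [_assign(), _assign("NCT00000002"), _assign("NCT00000003")]
    labels = {
        "LDL Cholesterol": OutcomeLabel("LDL Cholesterol", [], frozenset({"biomarker"})),
        "Quality of Life Score": OutcomeLabel("Quality of Life Score", [], frozenset({"PRO"})),
    }
    tables = summarize(rows, assigns, outcome_labels=labels,
                       condition_categories={"infection": ["Infections"]})
    by_type = tables["by_outcome_type"].set_index("outcome_type")
    assert by_type.loc["biomarker", "positive"] == 1
    assert by_type.loc["biomarker", "negative"] == 1
    assert by_type.loc["PRO", "positive_pct"] == 0.0
    hp = tables["by_health_problem"].set_index("health_problems")
    assert hp.loc["Infections", "positive"] == 1 and hp.loc["Infections", "negative"] == 2
    cov = tables["coverage_by_rank"].set_index("rank")
    assert cov.loc["primary", "results_coverage_pct"] == 100.0
    bm = tables["biomarker_outcomes"]
    assert list(bm["outcome_title"]) == ["LDL Cholesterol"]


def test_summarize_all_positive_has_zero_negative_column():
    rows = [_crow(outcome="LDL Cholesterol")]
    labels = {"LDL Cholesterol": OutcomeLabel("LDL Cholesterol", [], frozenset({"biomarker"}))}
    tables = summarize(rows, [_assign()], outcome_labels=labels)
    assert (tables["by_outcome_type"]["negative"] == 0).all()


def test_to_networkx_preserves_multiedges():
    rows = [_crow(), _crow(outcome="O2", label="negative")]
    nodes, edges = build_graph(rows, [_assign(), _assign()])
    g = to_networkx(nodes, edges)
    assert isinstance(g, nx.MultiDiGraph)
    assert g.number_of_edges() == len(edges)
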