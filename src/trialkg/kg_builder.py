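"""Assembly and export of the arm-level efficacy/safety knowledge graph.

Three main node types — intervention_arm, outcome, adverse_event — carry the
results; taxonomy nodes (concept, outcome_type, adverse_event_category) hang
off them via ``is_a`` edges. Efficacy lives on typed ``positive`` /
``negative`` edges from an intervention arm to an outcome, with the
comparator arm, the reported statistics, the NCT id and the trial conditions
as edge attributes; safety lives on ``has_ae`` edges from an arm to an
adverse event, attributed with the affected/at-risk ratio. Node identity is
(node_type, normalized title): the same arm or outcome title reported across
trials maps to one node, while per-trial provenance stays on the edges. Ids
are content-derived hashes, so two runs over the same corpus export
byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import networkx as nx
import pandas as pd

from trialkg.arm_resolution import ArmAssignment
from trialkg.outcome_typing import OutcomeLabel
from trialkg.records import normalize_ws
from trialkg.safety_linkage import SafetyRecord
from trialkg.significance import ClassifiedRow

NODE_TYPES = (
    "intervention_arm",
    "outcome",
    "adverse_event",
    "concept",
    "outcome_type",
    "adverse_event_category",
)
EDGE_TYPES = ("positive", "negative", "has_ae", "is_a")


@dataclass(frozen=True)
class KGNode:
    id: str
    node_type: str
    attrs: tuple  # sorted (key, value) pairs; hashable for dedup

    @property
    def title(self) -> str:
        return dict(self.attrs)["title"]


@dataclass(frozen=True)
class KGEdge:
    src: str
    dst: str
    edge_type: str
    attrs: tuple


def _node_id(node_type: str, title: str) -> str:
    key = f"{node_type}:{normalize_ws(title).lower()}"
    return hashlib.sha1(key.encode("utf-8")).hexdigest()[:16]


def _attrs(**kwargs: object) -> tuple:
    return tuple(sorted((k, v) for k, v in kwargs.items() if v is not None))


class GraphBuildError(ValueError):
    """Inconsistent inputs; message lists the offending references."""


def build_graph(
    classified: Sequence[ClassifiedRow],
    assignments: Sequence[Optional[ArmAssignment]],
    safety: Sequence[SafetyRecord] = (),
    outcome_labels: Mapping[str, OutcomeLabel] = {},
    concept_maps: Mapping[str, Sequence[str]] = {},
) -> tuple[dict[str, KGNode], list[KGEdge]]:
    """Build the node and edge sets.

    ``assignments`` aligns positionally with ``classified``; rows that are
    indeterminate or lack an arm assignment contribute no edge. Every
    matched safety record contributes one ``has_ae`` edge. ``outcome_labels``
    maps outcome titles to their category label sets; ``concept_maps`` maps
    intervention-arm titles to MeSH concept names.

    Raises :class:`GraphBuildError` on dangling references (an assignment
    whose titles are not the row's group titles, or an unmatched safety
    record).
    """
    if len(classified) != len(assignments):
        raise GraphBuildError(
            f"classified rows ({len(classified)}) and assignments ({len(assignments)}) misaligned"
        )
    offenders: list[str] = []
    nodes: dict[str, KGNode] = {}
    edges: list[KGEdge] = []
    seen_is_a: set[tuple[str, str]] = set()

    def add_node(node_type: str, title: str, **attrs: object) -> str:
        nid = _node_id(node_type, title)
        if nid not in nodes:
            nodes[nid] = KGNode(id=nid, node_type=node_type, attrs=_attrs(title=normalize_ws(title), **attrs))
        return nid

    for crow, assign in zip(classified, assignments):
        if crow.label == "indeterminate" or assign is None:
            continue
        titles = {normalize_ws(t).lower() for t in crow.row.group_titles}
        for t in (assign.intervention_group, assign.comparator_group):
            if normalize_ws(t).lower() not in titles:
                offenders.append(f"{crow.row.nct_id}: assignment title {t!r} not among groups")
        arm_id = add_node("intervention_arm", assign.intervention_group)
        outcome_id = add_node("outcome", crow.row.outcome_title, rank=crow.row.outcome_rank)
        edges.append(
            KGEdge(
                src=arm_id,
                dst=outcome_id,
                edge_type=crow.label,
                attrs=_attrs(
                    comparator=assign.comparator_group,
                    nct_id=crow.row.nct_id,
                    basis=crow.basis,
                    p_value=crow.row.p_value_raw,
                    param_name=crow.row.param_name_raw,
                    param_value=crow.row.param_value,
                    ci_lower=crow.row.ci_lower_raw,
                    ci_upper=crow.row.ci_upper_raw,
                    condition="|".join(crow.row.conditions) or None,
                ),
            )
        )

    for rec in safety:
        if rec.matched_group is None:
            offenders.append(f"{rec.nct_id}: safety record {rec.event_title!r} has no matched group")
            continue
        arm_id = add_node("intervention_arm", rec.matched_group)
        ev_id = add_node("adverse_event", rec.event_title)
        ratio = rec.affected / rec.at_risk if rec.at_risk else None
        edges.append(
            KGEdge(
                src=arm_id,
                dst=ev_id,
                edge_type="has_ae",
                attrs=_attrs(
                    nct_id=rec.nct_id,
                    severity=rec.severity,
                    affected=rec.affected,
                    at_risk=rec.at_risk,
                    ratio=round(ratio, 6) if ratio is not None else None,
                ),
            )
        )
        cat_id = add_node("adverse_event_category", rec.category)
        if (ev_id, cat_id) not in seen_is_a:
            seen_is_a.add((ev_id, cat_id))
            edges.append(KGEdge(src=ev_id, dst=cat_id, edge_type="is_a", attrs=()))

    if offenders:
        raise GraphBuildError("dangling references: " + "; ".join(offenders[:10]))

    # taxonomy edges for nodes actually present in the graph
    outcome_ids = {n.title: n.id for n in nodes.values() if n.node_type == "outcome"}
    for title, label in outcome_labels.items():
        nid = outcome_ids.get(normalize_ws(title))
        if nid is None:
            continue
        for lab in sorted(label.labels):
            type_id = add_node("outcome_type", lab)
            if (nid, type_id) not in seen_is_a:
                seen_is_a.add((nid, type_id))
                edges.append(KGEdge(src=nid, dst=type_id, edge_type="is_a", attrs=()))
    arm_ids = {n.title: n.id for n in nodes.values() if n.node_type == "intervention_arm"}
    for title, concepts in concept_maps.items():
        nid = arm_ids.get(normalize_ws(title))
        if nid is None:
            continue
        for concept in concepts:
            concept_id = add_node("concept", concept)
            if (nid, concept_id) not in seen_is_a:
                seen_is_a.add((nid, concept_id))
                edges.append(KGEdge(src=nid, dst=concept_id, edge_type="is_a", attrs=()))

    return nodes, edges


def to_networkx(nodes: Mapping[str, KGNode], edges: Sequence[KGEdge]) -> nx.MultiDiGraph:
    g = nx.MultiDiGraph()
    for node in nodes.values():
        g.add_node(node.id, node_type=node.node_type, **dict(node.attrs))
    for edge in edges:
        g.add_edge(edge.src, edge.dst, edge_type=edge.edge_type, **dict(edge.attrs))
    return g


def _sorted_edges(edges: Sequence[KGEdge]) -> list[KGEdge]:
    return sorted(edges, key=lambda e: (e.edge_type, e.src, e.dst, e.attrs))


def export_graph(
    nodes: Mapping[str, KGNode],
    edges: Sequence[KGEdge],
    out_dir: Union[str, Path],
    format: str = "neo4j_csv",
) -> list[Path]:
    """Write the graph in one of: neo4j_csv, graphml, cypher, jsonl.

    ``neo4j_csv`` follows the bulk-import header dialect (``id:ID``,
    ``:LABEL``, ``:START_ID``, ``:END_ID``, ``:TYPE``). The Cypher script
    uses MERGE on (type, title) so replaying it is idempotent. Output is
    deterministically ordered, so identical graphs export byte-identically.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ordered_nodes = sorted(nodes.values(), key=lambda n: (n.node_type, n.id))
    ordered_edges = _sorted_edges(edges)
    written: list[Path] = []

    if format == "neo4j_csv":
        node_attr_keys = sorted({k for n in ordered_nodes for k, _ in n.attrs})
        edge_attr_keys = sorted({k for e in ordered_edges for k, _ in e.attrs})
        npath, epath = out_dir / "nodes.csv", out_dir / "edges.csv"
        ndf = pd.DataFrame(
            [
                {"id:ID": n.id, ":LABEL": n.node_type, **{k: dict(n.attrs).get(k, "") for k in node_attr_keys}}
                for n in ordered_nodes
            ],
            columns=["id:ID", ":LABEL", *node_attr_keys],
        )
        edf = pd.DataFrame(
            [
                {
                    ":START_ID": e.src,
                    ":END_ID": e.dst,
                    ":TYPE": e.edge_type,
                    **{k: dict(e.attrs).get(k, "") for k in edge_attr_keys},
                }
                for e in ordered_edges
            ],
            columns=[":START_ID", ":END_ID", ":TYPE", *edge_attr_keys],
        )
        ndf.to_csv(npath, index=False)
        edf.to_csv(epath, index=False)
        written += [npath, epath]
    elif format == "graphml":
        path = out_dir / "graph.graphml"
        nx.write_graphml(to_networkx(nodes, ordered_edges), path)
        written.append(path)
    elif format == "cypher":
        path = out_dir / "graph.cypher"
        with open(path, "w", encoding="utf-8") as fh:
            for n in ordered_nodes:
                props = json.dumps(dict(n.attrs), ensure_ascii=False)
                fh.write(f"MERGE (n:{n.node_type} {{title: {json.dumps(n.title)}}}) SET n += {props};\n")
            for e in ordered_edges:
                src, dst = nodes[e.src], nodes[e.dst]
                props = json.dumps(dict(e.attrs), ensure_ascii=False)
                fh.write(
                    f"MATCH (a:{src.node_type} {{title: {json.dumps(src.title)}}}), "
                    f"(b:{dst.node_type} {{title: {json.dumps(dst.title)}}}) "
                    f"MERGE (a)-[r:{e.edge_type}]->(b) SET r += {props};\n"
                )
        written.append(path)
    elif format == "jsonl":
        path = out_dir / "graph.jsonl"
        with open(path, "w", encoding="utf-8") as fh:
            for n in ordered_nodes:
                fh.write(json.dumps({"kind": "node", "id": n.id, "type": n.node_type, **dict(n.attrs)}) + "\n")
            for e in ordered_edges:
                fh.write(
                    json.dumps({"kind": "edge", "src": e.src, "dst": e.dst, "type": e.edge_type, **dict(e.attrs)})
                    + "\n"
                )
        written.append(path)
    else:
        raise ValueError(f"unknown export format {format!r}")
    return written


def summarize(
    classified: Sequence[ClassifiedRow],
    assignments: Sequence[Optional[ArmAssignment]],
    safety: Sequence[SafetyRecord] = (),
    outcome_labels: Mapping[str, OutcomeLabel] = {},
    condition_categories: Mapping[str, Sequence[str]] = {},
) -> dict[str, pd.DataFrame]:
    """Descriptive summary tables over the pipeline outputs.

    Returns a dict of DataFrames: graph element counts; positive/negative
    splits by outcome type (single-label precedence biomarker > PRO >
    clinical_endpoint), by intervention type (single-type trials only) and
    by health-problem category; label coverage per outcome rank; and ranked
    biomarker outcomes per health problem with positive/negative counts.
    """
    nodes, edges = build_graph(classified, assignments, safety, outcome_labels, concept_maps={})
    node_counts = Counter(n.node_type for n in nodes.values())
    edge_counts = Counter(e.edge_type for e in edges)
    counts_df = pd.DataFrame(
        [{"element": f"node:{t}", "count": node_counts.get(t, 0)} for t in NODE_TYPES]
        + [{"element": f"edge:{t}", "count": edge_counts.get(t, 0)} for t in EDGE_TYPES]
    )

    rows = []
    for crow, assign in zip(classified, assignments):
        if crow.label == "indeterminate" or assign is None:
            continue
        label_obj = outcome_labels.get(crow.row.outcome_title)
        cats = sorted({c for cond in crow.row.conditions for c in condition_categories.get(cond, [])})
        rows.append(
            {
                "nct_id": crow.row.nct_id,
                "label": crow.label,
                "outcome_title": crow.row.outcome_title,
                "outcome_rank": crow.row.outcome_rank,
                "outcome_type": label_obj.primary_label() if label_obj else None,
                "intervention_type": (
                    crow.row.intervention_types[0] if len(crow.row.intervention_types) == 1 else None
                ),
                "health_problems": cats,
            }
        )
    df = pd.DataFrame(rows)

    def split(by: str, explode: bool = False) -> pd.DataFrame:
        if df.empty:
            return pd.DataFrame(columns=[by, "positive", "negative", "positive_pct"])
        sub = df.explode(by) if explode else df
        sub = sub.dropna(subset=[by])
        if sub.empty:
            return pd.DataFrame(columns=[by, "positive", "negative", "positive_pct"])
        tab = sub.pivot_table(index=by, columns="label", aggfunc="size", fill_value=0)
        for col in ("positive", "negative"):
            if col not in tab:
                tab[col] = 0
        tab = tab[["positive", "negative"]].reset_index()
        tab["positive_pct"] = 100 * tab["positive"] / (tab["positive"] + tab["negative"])
        return tab.sort_values(by).reset_index(drop=True)

    coverage_rows = []
    if not df.empty:
        for rank, grp in df.groupby("outcome_rank"):
            labelled = grp["outcome_type"].notna()
            uniq = grp.drop_duplicates("outcome_title")
            coverage_rows.append(
                {
                    "rank": rank,
                    "results_total": len(grp),
                    "results_labelled": int(labelled.sum()),
                    "results_coverage_pct": 100 * labelled.mean(),
                    "outcomes_total": len(uniq),
                    "outcomes_labelled": int(uniq["outcome_type"].notna().sum()),
                    "outcomes_coverage_pct": 100 * uniq["outcome_type"].notna().mean(),
                }
            )
    coverage_df = pd.DataFrame(coverage_rows)

    if df.empty:
        biomarker_df = pd.DataFrame(columns=["health_problem", "outcome_title", "positive", "negative"])
    else:
        bm = df[df["outcome_type"] == "biomarker"].explode("health_problems").dropna(subset=["health_problems"])
        if bm.empty:
            biomarker_df = pd.DataFrame(columns=["health_problem", "outcome_title", "positive", "negative"])
        else:
            tab = bm.pivot_table(
                index=["health_problems", "outcome_title"], columns="label", aggfunc="size", fill_value=0
            )
            for col in ("positive", "negative"):
                if col not in tab:
                    tab[col] = 0
            biomarker_df = (
                tab[["positive", "negative"]]
                .reset_index()
                .rename(columns={"health_problems": "health_problem"})
                .sort_values(["health_problem", "positive", "negative"], ascending=[True, False, False])
                .reset_index(drop=True)
            )

    return {
        "graph_counts": counts_df,
        "by_outcome_type": split("outcome_type"),
        "by_intervention_type": split("intervention_type"),
        "by_health_problem": split("health_problems", explode=True),
        "coverage_by_rank": coverage_df,
        "biomarker_outcomes": biomarker_df,
    }


def query_subgraph(
    nodes: Mapping[str, KGNode],
    edges: Sequence[KGEdge],
    arm_pattern: str,
    event_pattern: Optional[str] = None,
) -> tuple[dict[str, KGNode], list[KGEdge]]:
    """Retrieve the subgraph around arms matching a pattern.

    An intervention arm matches when ``arm_pattern`` appears
    (case-insensitive substring) in its title or in the title of a concept
    node it links to. All efficacy edges from matching arms are returned;
    ``has_ae`` edges are kept only when ``event_pattern`` matches the event
    title or the event's category.
    """
    arm_pat = arm_pattern.lower()
    ev_pat = event_pattern.lower() if event_pattern else None

    concept_of: dict[str, list[str]] = defaultdict(list)
    category_of: dict[str, list[str]] = defaultdict(list)
    for e in edges:
        if e.edge_type == "is_a":
            dst = nodes[e.dst]
            if dst.node_type == "concept":
                concept_of[e.src].append(dst.title.lower())
            elif dst.node_type == "adverse_event_category":
                category_of[e.src].append(dst.title.lower())

    matching_arms = {
        n.id
        for n in nodes.values()
        if n.node_type == "intervention_arm"
        and (arm_pat in n.title.lower() or any(arm_pat in c for c in concept_of[n.id]))
    }

    kept_edges: list[KGEdge] = []
    for e in edges:
        if e.src not in matching_arms:
            continue
        if e.edge_type in ("positive", "negative"):
            kept_edges.append(e)
        elif e.edge_type == "has_ae":
            ev_node = nodes[e.dst]
            if ev_pat is None or ev_pat in ev_node.title.lower() or any(
                ev_pat in c for c in category_of[ev_node.id]
            ):
                kept_edges.append(e)

    kept_ids = {e.src for e in kept_edges} | {e.dst for e in kept_edges}
    kept_nodes = {nid: nodes[nid] for nid in kept_ids}
    return kept_nodes, kept_edges
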