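"""End-to-end orchestration: corpus directory in, tables and graph out.

Stage order mirrors the data flow: parse the corpus, flatten to efficacy
rows, drop rows from trials without valid experimental/comparator design
labels or with other than two compared groups, classify significance,
resolve arms, type outcomes, link safety, build the knowledge graph.
Each stage is a pure function of its inputs plus the configuration, so
re-running any stage reproduces identical artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

from trialkg.arm_resolution import ArmAssignment, get_backend, resolve_arms
from trialkg.kg_builder import KGEdge, KGNode, build_graph, summarize
from trialkg.outcome_typing import (
    DictionaryExtractor,
    MeshExtractor,
    OutcomeLabel,
    classify_outcome,
    map_condition_category,
)
from trialkg.records import TrialRecord
from trialkg.registry_io import EfficacyRow, scan_corpus, to_efficacy_rows
from trialkg.safety_linkage import (
    CooccurrenceMatrix,
    SafetyRecord,
    compute_cooccurrence,
    extract_safety,
    filter_to_efficacy_trials,
    match_safety_records,
)
from trialkg.significance import BranchCounts, ClassifiedRow, classify_rows

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Everything the pipeline computes on one corpus."""

    trials: list[TrialRecord]
    rows: list[EfficacyRow]
    classified: list[ClassifiedRow]
    branch_counts: BranchCounts
    assignments: list[Optional[ArmAssignment]]
    outcome_labels: dict[str, OutcomeLabel]
    condition_categories: dict[str, list[str]]
    safety: list[SafetyRecord]
    safety_retained_fraction: float
    cooccurrence: CooccurrenceMatrix
    nodes: dict[str, KGNode]
    edges: list[KGEdge]
    skipped_files: list[str] = field(default_factory=list)

    def summary_tables(self):
        return summarize(
            self.classified,
            self.assignments,
            self.safety,
            self.outcome_labels,
            self.condition_categories,
        )


def run_pipeline(
    corpus: Union[str, Path, Sequence[TrialRecord]],
    backend_name: str = "char3gram",
    extractor: Optional[MeshExtractor] = None,
    min_score: Optional[float] = None,
) -> PipelineResult:
    """Run every stage on a corpus directory/zip or pre-parsed records."""
    backend = get_backend(backend_name)
    extractor = extractor or DictionaryExtractor()

    skipped: list[str] = []
    if isinstance(corpus, (str, Path)):
        scan = scan_corpus(corpus)
        trials = list(scan)
        skipped = scan.skipped
    else:
        trials = list(corpus)
    by_id = {t.nct_id: t for t in trials}

    rows: list[EfficacyRow] = []
    for trial in trials:
        has_valid_design = bool(trial.experimental_arms) and bool(trial.comparator_arms)
        for row in to_efficacy_rows(trial):
            if not has_valid_design:
                row.excluded = True
            rows.append(row)

    classified, branch_counts = classify_rows(rows)

    assignments: list[Optional[ArmAssignment]] = []
    for crow in classified:
        assignments.append(
            resolve_arms(
                crow.row.group_titles,
                by_id[crow.row.nct_id].design_arms,
                backend,
                nct_id=crow.row.nct_id,
                min_score=min_score,
            )
        )

    outcome_titles = sorted({c.row.outcome_title for c in classified})
    outcome_labels = {t: classify_outcome(t, extractor) for t in outcome_titles}
    conditions = sorted({c for t in trials for c in t.conditions})
    condition_categories = {c: map_condition_category(c, extractor) for c in conditions}

    # efficacy group titles per trial, the candidates for adverse-event matching
    groups_by_trial: dict[str, list[str]] = {}
    for crow in classified:
        groups_by_trial.setdefault(crow.row.nct_id, [])
        for t in crow.row.group_titles:
            if t not in groups_by_trial[crow.row.nct_id]:
                groups_by_trial[crow.row.nct_id].append(t)

    raw_safety = [rec for trial in trials for rec in extract_safety(trial)]
    matched = match_safety_records(raw_safety, groups_by_trial, backend)
    safety, retained_fraction = filter_to_efficacy_trials(matched, classified)
    cooccurrence = compute_cooccurrence(safety)

    arm_titles = sorted(
        {a.intervention_group for a in assignments if a is not None}
        | {r.matched_group for r in safety if r.matched_group}
    )
    concept_maps = {}
    for title in arm_titles:
        names = [t.name for t in extractor.extract(title)]
        if names:
            concept_maps[title] = names

    kg_classified, kg_assignments = [], []
    for crow, assign in zip(classified, assignments):
        kg_classified.append(crow)
        kg_assignments.append(assign)
    nodes, edges = build_graph(kg_classified, kg_assignments, safety, outcome_labels, concept_maps)

    logger.info(
        "pipeline: %d trials, %d rows (%d excluded), %d classified, %d safety records, %d nodes, %d edges",
        len(trials), len(rows), branch_counts.excluded,
        branch_counts.positive + branch_counts.negative, len(safety), len(nodes), len(edges),
    )
    return PipelineResult(
        trials=trials,
        rows=rows,
        classified=classified,
        branch_counts=branch_counts,
        assignments=assignments,
        outcome_labels=outcome_labels,
        condition_categories=condition_categories,
        safety=safety,
        safety_retained_fraction=retained_fraction,
        cooccurrence=cooccurrence,
        nodes=nodes,
        edges=edges,
        skipped_files=skipped,
    )
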