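"""Scoring pipeline output against a synthetic corpus's truth manifest."""

from __future__ import annotations

from collections import Counter

from trialkg.pipeline import PipelineResult
from trialkg.synthetic import TruthManifest


def evaluate_against_manifest(result: PipelineResult, manifest: TruthManifest) -> dict:
    """Agreement metrics between pipeline output and planted ground truth.

    Rows align positionally: the corpus scan is in lexicographic NCT-id
    order, which is the generator's emission order, and analyses keep
    document order within each trial.
    """
    truth_rows = manifest.efficacy_rows
    if len(result.rows) != len(truth_rows):
        raise ValueError(f"row count mismatch: pipeline {len(result.rows)}, manifest {len(truth_rows)}")

    label_of = {id(c.row): c.label for c in result.classified}
    assign_of = {id(c.row): a for c, a in zip(result.classified, result.assignments)}

    n_labelled = n_label_ok = 0
    n_assigned = n_int_ok = n_comp_ok = 0
    n_typed = n_type_ok = 0
    for row, truth in zip(result.rows, truth_rows):
        if row.nct_id != truth["nct_id"] or row.outcome_title != truth["outcome_title"]:
            raise ValueError(f"row misalignment at {row.nct_id}/{row.outcome_title}")
        if truth["intended_label"] == "excluded":
            continue
        n_labelled += 1
        if label_of.get(id(row)) == truth["intended_label"]:
            n_label_ok += 1
        assign = assign_of.get(id(row))
        if truth["intended_intervention"] is not None and assign is not None:
            n_assigned += 1
            n_int_ok += assign.intervention_group == truth["intended_intervention"]
            n_comp_ok += assign.comparator_group == truth["intended_comparator"]
        label_obj = result.outcome_labels.get(row.outcome_title)
        if label_obj is not None:
            n_typed += 1
            n_type_ok += set(label_obj.labels) == set(truth["intended_outcome_types"])

    edge_counts = Counter(e.edge_type for e in result.edges)
    intended = manifest.intended_edge_counts()

    classified_trials = {
        r["nct_id"] for r in truth_rows if r["intended_label"] in ("positive", "negative")
    }
    truth_safety = sorted(
        (r for r in manifest.safety_records if r["nct_id"] in classified_trials),
        key=lambda r: (r["nct_id"], r["arm_title"], r["event_title"], r["category"], r["affected"]),
    )
    pipe_safety = sorted(
        result.safety,
        key=lambda r: (r.nct_id, r.arm_title, r.event_title, r.category, r.affected),
    )
    n_safety = min(len(truth_safety), len(pipe_safety))
    n_safety_ok = sum(
        1
        for t, p in zip(truth_safety, pipe_safety)
        if p.matched_group == t["intended_matched_group"]
    )

    return {
        "n_rows": len(result.rows),
        "n_scored_rows": n_labelled,
        "label_agreement": n_label_ok / n_labelled if n_labelled else 1.0,
        "intervention_accuracy": n_int_ok / n_assigned if n_assigned else 1.0,
        "comparator_accuracy": n_comp_ok / n_assigned if n_assigned else 1.0,
        "outcome_type_agreement": n_type_ok / n_typed if n_typed else 1.0,
        "edge_counts": {
            "positive": edge_counts.get("positive", 0),
            "negative": edge_counts.get("negative", 0),
            "has_ae": edge_counts.get("has_ae", 0),
        },
        "intended_edge_counts": intended,
        "edge_counts_match": all(
            edge_counts.get(k, 0) == v for k, v in intended.items()
        ),
        "safety_records": len(pipe_safety),
        "safety_match_accuracy": n_safety_ok / n_safety if n_safety else 1.0,
    }
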