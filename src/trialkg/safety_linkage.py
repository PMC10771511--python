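"""Serious-adverse-event extraction, arm matching, and co-occurrence weights.

Serious adverse events (SAEs) are reported per arm with affected / at-risk
subject counts, filed under MedDRA-style body-system categories. This module

* keeps serious events with at least one affected subject, dropping the
  registry's "Total, serious adverse events" aggregation rows;
* matches each event's arm title to the efficacy analysis groups — exact
  string match first (case- and whitespace-insensitive), embedding-cosine
  argmax as fallback — so efficacy and safety can be joined arm-to-arm;
* restricts safety records to trials that also carry classified efficacy
  results;
* computes a ratio-weighted category co-occurrence statistic: for each
  trial t and category x let r_t(x) = (sum affected)/(sum at_risk) over the
  trial's records in x; every unordered pair (a, b) of categories both
  reporting affected subjects in t contributes r_t(a) * r_t(b), summed over
  trials. The result is a symmetric, zero-diagonal weight matrix measuring
  how strongly SAE categories co-occur, weighted by how much of each trial's
  population they touched.

Co-occurrence is a descriptive statistic about reporting, not a causal claim
about the interventions.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from trialkg.arm_resolution import EmbeddingBackend, cosine_similarity, get_backend
from trialkg.records import TrialRecord, normalize_ws
from trialkg.significance import ClassifiedRow

logger = logging.getLogger(__name__)

TOTAL_ROW_TITLE = "total, serious adverse events"


@dataclass
class SafetyRecord:
    """One retained serious adverse event count on one arm."""

    nct_id: str
    arm_title: str
    event_title: str
    category: str
    severity: str
    affected: int
    at_risk: Optional[int] = None
    matched_group: Optional[str] = None
    match_method: Optional[str] = None  # string | embedding


SAFETY_COLUMNS = [
    "nct_id",
    "arm_title",
    "event_title",
    "category",
    "severity",
    "affected",
    "at_risk",
    "matched_group",
    "match_method",
]


def extract_safety(trial: TrialRecord) -> list[SafetyRecord]:
    """Serious events with affected >= 1, aggregation totals removed.

    Records whose affected count exceeds the at-risk denominator are
    quarantined (dropped with a warning) rather than silently kept: such a
    row cannot yield a valid ratio and indicates a reporting error.
    """
    records: list[SafetyRecord] = []
    for ev in trial.events:
        if ev.severity != "serious" or ev.affected < 1:
            continue
        if ev.event_title.lower() == TOTAL_ROW_TITLE:
            continue
        if ev.at_risk is not None and ev.affected > ev.at_risk:
            logger.warning(
                "%s: quarantined event %r on arm %r: affected %d > at_risk %d",
                trial.nct_id, ev.event_title, ev.arm_title, ev.affected, ev.at_risk,
            )
            continue
        records.append(
            SafetyRecord(
                nct_id=trial.nct_id,
                arm_title=ev.arm_title,
                event_title=ev.event_title,
                category=ev.category,
                severity=ev.severity,
                affected=ev.affected,
                at_risk=ev.at_risk,
            )
        )
    return records


def match_ae_group(
    arm_title: str,
    efficacy_group_titles: Sequence[str],
    backend: Optional[EmbeddingBackend] = None,
) -> tuple[str, str]:
    """Match an adverse-event arm title to an efficacy analysis group.

    Exact match (case-insensitive, whitespace-normalized) wins outright;
    otherwise the cosine-argmax candidate under the embedding backend is
    returned, ties broken by candidate order.
    """
    if not efficacy_group_titles:
        raise ValueError("no efficacy group titles to match against")
    key = normalize_ws(arm_title).lower()
    for cand in efficacy_group_titles:
        if normalize_ws(cand).lower() == key:
            return cand, "string"
    backend = backend or get_backend()
    vecs = backend.embed([arm_title] + list(efficacy_group_titles))
    best_i, best_s = 0, -2.0
    for i in range(len(efficacy_group_titles)):
        try:
            s = cosine_similarity(vecs[0], vecs[1 + i])
        except ValueError:
            s = -1.0
        if s > best_s:
            best_i, best_s = i, s
    return efficacy_group_titles[best_i], "embedding"


def match_safety_records(
    records: Iterable[SafetyRecord],
    efficacy_groups_by_trial: dict[str, Sequence[str]],
    backend: Optional[EmbeddingBackend] = None,
) -> list[SafetyRecord]:
    """Fill matched_group/match_method for records whose trial has efficacy groups."""
    backend = backend or get_backend()
    out = []
    for rec in records:
        cands = efficacy_groups_by_trial.get(rec.nct_id)
        if not cands:
            continue
        matched, method = match_ae_group(rec.arm_title, list(cands), backend)
        rec.matched_group = matched
        rec.match_method = method
        out.append(rec)
    return out


def filter_to_efficacy_trials(
    safety: Sequence[SafetyRecord],
    efficacy: Sequence[ClassifiedRow],
) -> tuple[list[SafetyRecord], float]:
    """Keep safety records from trials with >= 1 classified efficacy row.

    Returns the subset plus the retained/total fraction (1.0 for empty input).
    """
    valid_ids = {c.row.nct_id for c in efficacy if c.label != "indeterminate"}
    kept = [r for r in safety if r.nct_id in valid_ids]
    frac = len(kept) / len(safety) if safety else 1.0
    logger.info("safety filter: retained %d/%d records (%.1f%%)", len(kept), len(safety), 100 * frac)
    return kept, frac


@dataclass
class CooccurrenceMatrix:
    """Symmetric ratio-weighted co-occurrence of SAE categories."""

    categories: list[str]
    weights: np.ndarray  # square, symmetric, zero diagonal

    def weight(self, a: str, b: str) -> float:
        i, j = self.categories.index(a), self.categories.index(b)
        return float(self.weights[i, j])

    def edge_list(self) -> list[tuple[str, str, float]]:
        """Nonzero upper-triangle entries, heaviest first."""
        edges = []
        for i in range(len(self.categories)):
            for j in range(i + 1, len(self.categories)):
                w = float(self.weights[i, j])
                if w > 0:
                    edges.append((self.categories[i], self.categories[j], w))
        return sorted(edges, key=lambda e: (-e[2], e[0], e[1]))


def compute_cooccurrence(records: Sequence[SafetyRecord]) -> CooccurrenceMatrix:
    """Sum r_t(a) * r_t(b) over trials where categories a and b co-report.

    Per-trial category ratios pool all of a category's records by summing
    affected and at-risk counts (the only order-independent pooling when a
    category spans several arms). Records without an at-risk denominator are
    skipped here, with a logged tally; they still count in the affected
    tables.
    """
    pooled: dict[str, dict[str, list[int]]] = defaultdict(lambda: defaultdict(lambda: [0, 0]))
    skipped = 0
    for rec in records:
        if rec.at_risk is None or rec.at_risk < 1:
            skipped += 1
            continue
        acc = pooled[rec.nct_id][rec.category]
        acc[0] += rec.affected
        acc[1] += rec.at_risk
    if skipped:
        logger.info("co-occurrence: skipped %d record(s) without at_risk", skipped)

    categories = sorted({c for per_trial in pooled.values() for c in per_trial})
    idx = {c: i for i, c in enumerate(categories)}
    weights = np.zeros((len(categories), len(categories)))
    for per_trial in pooled.values():
        cats = sorted(per_trial)
        ratios = {c: per_trial[c][0] / per_trial[c][1] for c in cats}
        for i, a in enumerate(cats):
            for b in cats[i + 1 :]:
                w = ratios[a] * ratios[b]
                weights[idx[a], idx[b]] += w
                weights[idx[b], idx[a]] += w
    return CooccurrenceMatrix(categories=categories, weights=weights)


def aggregate_affected(
    records: Sequence[SafetyRecord],
    key: str = "category",
    intervention_types_by_trial: Optional[dict[str, Sequence[str]]] = None,
) -> list[tuple[str, int]]:
    """Total affected subjects per category or per intervention type, descending.

    For ``key="intervention_type"`` records are joined to their trial's
    intervention types; trials with zero or multiple types are excluded so
    each affected count attributes to exactly one type.
    """
    totals: dict[str, int] = defaultdict(int)
    if key == "category":
        for rec in records:
            totals[rec.category] += rec.affected
    elif key == "intervention_type":
        if intervention_types_by_trial is None:
            raise ValueError("intervention_types_by_trial required for key='intervention_type'")
        for rec in records:
            types = intervention_types_by_trial.get(rec.nct_id, [])
            if len(types) != 1:
                continue
            totals[types[0]] += rec.affected
    else:
        raise ValueError(f"unknown aggregation key {key!r}")
    return sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))
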