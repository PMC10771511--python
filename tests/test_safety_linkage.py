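"""Serious-adverse-event extraction, arm matching, and co-occurrence weights."""

import random

import numpy as np
import pytest

from trialkg.records import ReportedEvent, TrialRecord
from trialkg.safety_linkage import (
    SafetyRecord,
    aggregate_affected,
    compute_cooccurrence,
    extract_safety,
    filter_to_efficacy_trials,
    match_ae_group,
)
from trialkg.significance import classify_rows
from trialkg.registry_io import EfficacyRow


def _trial(nct, events):
    return TrialRecord(nct_id=nct, events=events)


def _event(**kw):
    base = dict(
        arm_title="Arm A",
        event_title="Abdominal pain",
        category="Gastrointestinal disorders",
        severity="serious",
        affected=1,
        at_risk=72,
    )
    base.update(kw)
    return ReportedEvent(**base)


def test_extract_keeps_serious_nonzero_and_drops_totals():
    trial = _trial(
        "NCT00977080",
        [
            _event(arm_title="Oral Paricalcitol in the Oral Stratum"),
            _event(event_title="Total, serious adverse events", affected=5),
            _event(affected=0),
            _event(severity="other", event_title="Nausea"),
        ],
    )
    records = extract_safety(trial)
    assert len(records) == 1
    rec = records[0]
    assert rec.arm_title == "Oral Paricalcitol in the Oral Stratum"
    assert (rec.affected, rec.at_risk, rec.severity) == (1, 72, "serious")


def test_extract_quarantines_impossible_counts(caplog):
    trial = _trial("NCT00000001", [_event(affected=80, at_risk=72)])
    with caplog.at_level("WARNING"):
        assert extract_safety(trial) == []
    assert "quarantined" in caplog.text


def test_match_exact_string_beats_embedding(backend):
    matched, method = match_ae_group("  tocilizumab + placebo ", ["Tocilizumab + Placebo", "Placebo"], backend)
    assert matched == "Tocilizumab + Placebo" and method == "string"


def test_match_falls_back_to_embedding(backend):
    matched, method = match_ae_group("Laquinimod 0.6 mg", ["Laquinimod", "Placebo"], backend)
    assert matched == "Laquinimod" and method == "embedding"


def test_match_single_candidate_and_empty(backend):
    assert match_ae_group("anything", ["Only Arm"], backend) == ("Only Arm", "embedding")
    with pytest.raises(ValueError):
        match_ae_group("x", [], backend)


def _classified(nct, label):
    row = EfficacyRow(
        nct_id=nct, group_titles=["A", "B"], outcome_title="o", outcome_rank="primary",
        p_value_raw="0.01" if label == "positive" else ("0.5" if label == "negative" else "NA"),
        method=None, param_name_raw=None, param_value=None, ci_percent=None,
        ci_lower_raw=None, ci_upper_raw=None, non_inferiority=None,
        conditions=[], intervention_types=[], excluded=False,
    )
    out, _ = classify_rows([row])
    return out[0]


def test_filter_to_trials_with_classified_efficacy():
    safety = [
        SafetyRecord("NCT00000001", "A", "e", "c", "serious", 1, 10),
        SafetyRecord("NCT00000002", "A", "e", "c", "serious", 1, 10),
        SafetyRecord("NCT00000003", "A", "e", "c", "serious", 1, 10),
    ]
    efficacy = [_classified("NCT00000001", "positive"), _classified("NCT00000002", "negative"),
                _classified("NCT00000003", "indeterminate")]
    kept, frac = filter_to_efficacy_trials(safety, efficacy)
    assert {r.nct_id for r in kept} == {"NCT00000001", "NCT00000002"}
    assert frac == pytest.approx(2 / 3)
    none_kept, frac0 = filter_to_efficacy_trials(safety, [])
    assert none_kept == [] and frac0 == 0.0


def test_cooccurrence_hand_example():
    """One trial, category A at 5/10 and B at 2/10 -> weight 0.5 * 0.2."""
    records = [
        SafetyRecord("NCT00000001", "arm", "e1", "A", "serious", 5, 10),
        SafetyRecord("NCT00000001", "arm", "e2", "B", "serious", 2, 10),
    ]
    co = compute_cooccurrence(records)
    assert co.weight("A", "B") == pytest.approx(0.10)
    assert co.weight("B", "A") == pytest.approx(0.10)


def test_cooccurrence_pools_within_category_and_sums_over_trials():
    records = [
        # trial 1: A pooled (1+3)/(10+10)=0.2, B 4/10=0.4 -> 0.08
        SafetyRecord("NCT00000001", "x", "e", "A", "serious", 1, 10),
        SafetyRecord("NCT00000001", "y", "e", "A", "serious", 3, 10),
        SafetyRecord("NCT00000001", "x", "e", "B", "serious", 4, 10),
        # trial 2: A 1/2, B 1/2 -> 0.25
        SafetyRecord("NCT00000002", "x", "e", "A", "serious", 1, 2),
        SafetyRecord("NCT00000002", "x", "e", "B", "serious", 1, 2),
    ]
    co = compute_cooccurrence(records)
    assert co.weight("A", "B") == pytest.approx(0.08 + 0.25)
    assert co.edge_list() == [("A", "B", pytest.approx(0.33))]


def _random_safety_corpus(rng, max_trials=20):
    cats = ["A", "B", "C", "D", "E", "F"]
    records = []
    for t in range(rng.randint(1, max_trials)):
        nct = f"NCT{t + 1:08d}"
        for _ in range(rng.randint(0, 8)):
            at_risk = rng.randint(1, 200)
            records.append(
                SafetyRecord(nct, "arm", "e", rng.choice(cats), "serious",
                             rng.randint(1, at_risk), at_risk)
            )
    return records


def _brute_force_weight(records, a, b):
    """Direct enumeration over (trial, category-pair) tuples."""
    trials = sorted({r.nct_id for r in records})
    total = 0.0
    for t in trials:
        in_t = [r for r in records if r.nct_id == t]
        def ratio(cat):
            rs = [r for r in in_t if r.category == cat]
            if not rs:
                return None
            return sum(r.affected for r in rs) / sum(r.at_risk for r in rs)
        ra, rb = ratio(a), ratio(b)
        if ra is not None and rb is not None:
            total += ra * rb
    return total


def test_cooccurrence_equals_brute_force_on_seeded_corpora():
    rng = random.Random(2024)
    for _ in range(25):
        records = _random_safety_corpus(rng)
        co = compute_cooccurrence(records)
        assert np.allclose(co.weights, co.weights.T)
        assert np.all(np.diag(co.weights) == 0)
        n_trials = len({r.nct_id for r in records})
        assert np.all(co.weights >= 0) and np.all(co.weights <= n_trials)
        for i, a in enumerate(co.categories):
            for b in co.categories[i + 1 :]:
                assert co.weight(a, b) == pytest.approx(_brute_force_weight(records, a, b), abs=1e-12)


def test_missing_at_risk_skipped_in_cooccurrence_but_counted_in_tables():
    records = [
        SafetyRecord("NCT00000001", "x", "e", "A", "serious", 5, None),
        SafetyRecord("NCT00000001", "x", "e", "B", "serious", 2, 10),
    ]
    co = compute_cooccurrence(records)
    assert co.categories == ["B"]
    assert aggregate_affected(records, "category") == [("A", 5), ("B", 2)]


def test_aggregate_by_intervention_type_excludes_multi_type_trials():
    records = [
        SafetyRecord("NCT00000001", "x", "e", "A", "serious", 1, 10),
        SafetyRecord("NCT00000001", "x", "e", "A", "serious", 2, 10),
        SafetyRecord("NCT00000002", "x", "e", "A", "serious", 3, 10),
        SafetyRecord("NCT00000003", "x", "e", "A", "serious", 100, 200),
    ]
    types = {"NCT00000001": ["Drug"], "NCT00000002": ["Biological"], "NCT00000003": ["Drug", "Device"]}
    table = aggregate_affected(records, "intervention_type", intervention_types_by_trial=types)
    assert table == [("Biological", 3), ("Drug", 3)]
    with pytest.raises(ValueError):
        aggregate_affected(records, "intervention_type")
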