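"""Seeded generator of registry-dialect trial XML with known ground truth.

Each generated document conforms to the legacy registry dialect accepted by
:func:`trialkg.registry_io.read_trial_xml`: design arms with
experimental/comparator types, outcomes with statistical-analysis blocks
(group-id indirection included), and reported events with per-arm counts.
Alongside every document the generator emits a manifest fragment recording
every planted truth — arm roles, the intended significance label and basis
of every analysis row, the intended intervention/comparator titles, outcome
category label sets, and the retained safety records with their intended
arm matches — so the whole downstream pipeline can be checked against known
answers without any network access.

The defaults define the study conditions the generator emulates: a positive
share of 0.44 (the share of statistically significant results observed in
registry-wide efficacy data), a mix of p-value spellings dominated by plain
decimals with operator-prefixed and unparseable strings mixed in, 30 % of
decisive results reported by confidence interval only, and MedDRA
system-organ-class category names for adverse events.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from lxml import etree

DEFAULT_P_DIALECT_MIX = {
    "plain": 0.45,
    "lt": 0.20,
    "le": 0.05,
    "scientific": 0.10,
    "unparseable": 0.20,
}

#: MedDRA-style system-organ-class names used for generated adverse events.
DEFAULT_AE_CATEGORIES = [
    "Infections and infestations",
    "Cardiac disorders",
    "General disorders",
    "Gastrointestinal disorders",
    "Respiratory, thoracic and mediastinal disorders",
    "Neoplasms benign, malignant and unspecified",
    "Nervous system disorders",
    "Injury, poisoning and procedural complications",
    "Vascular disorders",
    "Blood and lymphatic system disorders",
    "Metabolism and nutrition disorders",
    "Musculoskeletal and connective tissue disorders",
    "Renal and urinary disorders",
    "Investigations",
    "Surgical and medical procedures",
    "Hepatobiliary disorders",
    "Psychiatric disorders",
    "Skin and subcutaneous tissue disorders",
    "Eye disorders",
    "Reproductive system and breast disorders",
    "Endocrine disorders",
    "Immune system disorders",
    "Ear and labyrinth disorders",
]

_EVENT_TITLES = {
    "Infections and infestations": ["Pneumonia", "Sepsis", "Urinary tract infection", "Cellulitis"],
    "Cardiac disorders": ["Myocardial infarction", "Atrial fibrillation", "Cardiac failure"],
    "Gastrointestinal disorders": ["Abdominal pain", "Nausea", "Gastrointestinal haemorrhage"],
    "Nervous system disorders": ["Syncope", "Headache", "Seizure"],
    "Respiratory, thoracic and mediastinal disorders": ["Dyspnoea", "Pulmonary embolism"],
    "Vascular disorders": ["Hypertension", "Deep vein thrombosis"],
    "Psychiatric disorders": ["Anxiety", "Insomnia"],
}

_DRUGS = [
    "Metformin", "Adalimumab", "Sertraline", "Atorvastatin", "Canagliflozin",
    "Tocilizumab", "Laquinimod", "Inclisiran", "Baloxavir", "Caplacizumab",
    "Paricalcitol", "Sunitinib", "Ibuprofen", "Aripiprazole", "Oseltamivir",
    "Dupilumab", "Semaglutide", "Rivaroxaban", "Ustekinumab", "Lisinopril",
]
_COMPARATORS = ["Placebo", "Standard of Care", "Sham Treatment", "Active Control"]
_CONDITIONS = [
    "rheumatoid arthritis", "type 2 diabetes", "hypertension", "asthma",
    "major depressive disorder", "breast cancer", "heart failure", "psoriasis",
    "chronic kidney disease", "migraine", "osteoporosis", "atrial fibrillation",
]
_INTERVENTION_TYPES = ["Drug", "Biological", "Device", "Behavioral", "Dietary Supplement"]

# outcome-title building blocks with known typing-rule results
_BIOMARKER_PHRASES = [
    "LDL Cholesterol", "Glycated Hemoglobin", "C-Reactive Protein", "Blood Glucose",
    "Triglycerides", "Creatinine", "Interleukin-6", "Forced Expiratory Volume",
    "Blood Pressure", "Glomerular Filtration Rate",
]
_CLINICAL_PHRASES = [
    "Myocardial Infarction", "Stroke", "Heart Failure", "Pneumonia",
    "Major Depressive Disorder", "Fracture", "Migraine",
]
_NEUTRAL_PHRASES = [
    "Time to First Hospitalization", "Duration of Hospital Stay",
    "Number of Participants Completing Treatment", "Time to Treatment Discontinuation",
]

_RATIO_PARAMS = ["Odds Ratio (OR)", "Hazard Ratio (HR)", "Risk Ratio (RR)", "Relative Risk"]
_DIFF_PARAMS = ["Mean Difference (Final Values)", "Risk Difference (RD)", "Slope", "Mean Change"]


@dataclass
class GeneratorConfig:
    """Study conditions for a synthetic corpus; identical config + seed is byte-stable."""

    n_trials: int = 100
    p_value_dialect_mix: dict = field(default_factory=lambda: dict(DEFAULT_P_DIALECT_MIX))
    ci_only_fraction: float = 0.30
    ratio_kind_fraction: float = 0.5
    target_positive_fraction: float = 0.44
    title_noise: float = 0.1
    ae_categories: list = field(default_factory=lambda: list(DEFAULT_AE_CATEGORIES))
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ci_only_fraction", "ratio_kind_fraction", "target_positive_fraction", "title_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_trials < 0:
            raise ValueError("n_trials must be >= 0")


@dataclass
class TruthManifest:
    """Planted ground truth for a generated corpus, one fragment per trial."""

    trials: list = field(default_factory=list)

    @property
    def efficacy_rows(self) -> list[dict]:
        return [r for t in self.trials for r in t["efficacy_rows"]]

    @property
    def safety_records(self) -> list[dict]:
        return [r for t in self.trials for r in t["safety_records"]]

    def intended_edge_counts(self) -> dict[str, int]:
        """Expected positive / negative / has_ae edge counts for the KG."""
        pos = sum(1 for r in self.efficacy_rows if r["intended_label"] == "positive")
        neg = sum(1 for r in self.efficacy_rows if r["intended_label"] == "negative")
        classified_trials = {
            r["nct_id"] for r in self.efficacy_rows if r["intended_label"] in ("positive", "negative")
        }
        has_ae = sum(1 for r in self.safety_records if r["nct_id"] in classified_trials)
        return {"positive": pos, "negative": neg, "has_ae": has_ae}

    def positive_share(self) -> float:
        decisive = [r for r in self.efficacy_rows if r["intended_label"] in ("positive", "negative")]
        if not decisive:
            return 0.0
        return sum(1 for r in decisive if r["intended_label"] == "positive") / len(decisive)

    def write_jsonl(self, path: Union[str, Path]) -> Path:
        path = Path(path)
        with open(path, "w", encoding="utf-8") as fh:
            for t in self.trials:
                fh.write(json.dumps(t, ensure_ascii=False) + "\n")
        return path

    @classmethod
    def read_jsonl(cls, path: Union[str, Path]) -> "TruthManifest":
        with open(path, encoding="utf-8") as fh:
            return cls(trials=[json.loads(line) for line in fh if line.strip()])


def perturb_title(title: str, noise: float, seed: int) -> str:
    """Apply seeded title drift scaling with ``noise``; ``noise=0`` is identity.

    Edits emulate the ways analysis-section group titles drift from the
    design-section titles: dose suffixes, casing changes, small typos, and
    dropped parentheticals. Each edit fires independently with probability
    ``noise``.
    """
    if not 0.0 <= noise <= 1.0:
        raise ValueError("noise must be in [0, 1]")
    if noise == 0.0:
        return title
    rng = random.Random(f"perturb:{seed}:{title}")
    out = title
    if rng.random() < noise:  # dose suffix
        out = f"{out} {rng.choice(['10 mg', '50 mg', '0.6 mg', '25 mcg', '100 mg'])}"
    if rng.random() < noise:  # casing drift
        out = out.upper() if rng.random() < 0.5 else out.lower()
    if rng.random() < noise and "(" in out:  # drop parenthetical
        out = out[: out.index("(")].strip()
    if rng.random() < noise and len(out) > 4:  # adjacent-character typo
        i = rng.randrange(1, len(out) - 2)
        out = out[:i] + out[i + 1] + out[i] + out[i + 2 :]
    return out


def _choose_weighted(rng: random.Random, weights: dict) -> str:
    items = sorted(weights.items())
    total = sum(w for _, w in items)
    x = rng.random() * total
    acc = 0.0
    for name, w in items:
        acc += w
        if x < acc:
            return name
    return items[-1][0]


def _plant_statistics(rng: random.Random, cfg: GeneratorConfig) -> dict:
    """Choose a cascade branch and statistics guaranteeing an intended label."""
    dialect = _choose_weighted(rng, cfg.p_value_dialect_mix)
    stat: dict = {
        "p_value": None, "method": None, "param_name": None, "param_value": None,
        "ci_percent": None, "ci_lower": None, "ci_upper": None,
    }
    if dialect == "unparseable":
        stat["p_value"] = rng.choice(["NA", "N/A", "p<.05*", "not reported"])
        return {**stat, "intended_label": "indeterminate", "intended_basis": "none"}
    if rng.random() < cfg.ci_only_fraction:
        positive = rng.random() < cfg.target_positive_fraction
        stat["ci_percent"] = 95.0
        if rng.random() < 0.05:  # unrecognized parameter: cascade exhausts
            stat["param_name"] = rng.choice(["Cohen's d", "Eta squared"])
            stat["ci_lower"], stat["ci_upper"] = "0.10", "0.90"
            return {**stat, "intended_label": "indeterminate", "intended_basis": "none"}
        if rng.random() < cfg.ratio_kind_fraction:
            stat["param_name"] = rng.choice(_RATIO_PARAMS)
            basis = "ci_ratio"
            if positive:
                lo = round(rng.uniform(1.05, 1.8), 2) if rng.random() < 0.5 else round(rng.uniform(0.2, 0.6), 2)
                hi = round(lo + rng.uniform(0.05, 0.8), 2)
                if lo < 1.0 and hi >= 1.0:
                    hi = round(rng.uniform(lo + 0.01, 0.99), 2)
            else:
                lo = round(rng.uniform(0.5, 0.95), 2)
                hi = round(rng.uniform(1.05, 2.2), 2)
        else:
            stat["param_name"] = rng.choice(_DIFF_PARAMS)
            basis = "ci_difference"
            if positive:
                lo = round(rng.uniform(0.1, 2.0), 2) if rng.random() < 0.5 else round(rng.uniform(-3.0, -0.5), 2)
                hi = round(lo + rng.uniform(0.05, 1.0), 2)
                if lo < 0.0 and hi >= 0.0:
                    hi = round(rng.uniform(lo + 0.01, -0.01), 2)
            else:
                lo = round(rng.uniform(-1.5, -0.1), 2)
                hi = round(rng.uniform(0.1, 1.5), 2)
        stat["ci_lower"], stat["ci_upper"] = f"{lo}", f"{hi}"
        stat["param_value"] = round((lo + hi) / 2, 3)
        return {**stat, "intended_label": "positive" if positive else "negative", "intended_basis": basis}
    # p-value branch
    positive = rng.random() < cfg.target_positive_fraction
    stat["method"] = rng.choice(["ANCOVA", "t-test, 2 sided", "Regression, Cox", "Wilcoxon"])
    if positive:
        if dialect == "lt":
            stat["p_value"] = rng.choice(["<0.0001", "<0.001", "<0.01", "<0.05"])
        elif dialect == "le":
            stat["p_value"] = rng.choice(["≤0.05", "<=0.01"])
        elif dialect == "scientific":
            stat["p_value"] = f"{rng.uniform(1, 9):.1f}e-{rng.randint(3, 6)}"
        else:
            stat["p_value"] = f"{rng.uniform(0.0001, 0.05):.4f}"
    else:
        # a decisive negative needs an equality-style or scientific spelling
        if dialect == "scientific":
            stat["p_value"] = f"{rng.uniform(1.0, 9.9):.2f}e-1"
        else:
            stat["p_value"] = f"{rng.uniform(0.051, 0.95):.4f}"
    return {**stat, "intended_label": "positive" if positive else "negative", "intended_basis": "p_value"}


def _outcome_template(rng: random.Random) -> tuple[str, list[str]]:
    """An outcome title plus the category label set it is built to receive."""
    kind = _choose_weighted(
        rng, {"biomarker": 0.30, "pro": 0.20, "clinical": 0.20, "bio_pro": 0.10, "survey_only": 0.08, "none": 0.12}
    )
    if kind == "biomarker":
        return f"Change From Baseline in {rng.choice(_BIOMARKER_PHRASES)}", ["biomarker"]
    if kind == "pro":
        instrument = rng.choice(
            ["Quality of Life", "Sleep Quality", "Treatment Satisfaction", "Daily Functioning"]
        )
        suffix = rng.choice(["Score", "Scale", "Questionnaire Response"])
        return f"{instrument} {suffix} at Week {rng.randint(4, 52)}", ["PRO"]
    if kind == "clinical":
        return f"Incidence of {rng.choice(_CLINICAL_PHRASES)}", ["clinical_endpoint"]
    if kind == "bio_pro":
        return (
            f"{rng.choice(_BIOMARKER_PHRASES)} Response Score at Day {rng.randint(30, 510)}",
            ["PRO", "biomarker"],
        )
    if kind == "survey_only":
        # survey-branch MeSH term only: the biomarker rule must NOT fire,
        # the PRO keyword rule fires on "Questionnaire"
        return "Participants Completing the Health Survey Questionnaire", ["PRO"]
    return rng.choice(_NEUTRAL_PHRASES), []


def _trial_xml(trial: dict) -> str:
    """Serialize one trial dict (see generate_trial) to registry-dialect XML."""
    root = etree.Element("clinical_study")
    id_info = etree.SubElement(root, "id_info")
    etree.SubElement(id_info, "nct_id").text = trial["nct_id"]
    etree.SubElement(root, "brief_title").text = f"A Study of {trial['arms'][0]['title']}"
    for cond in trial["conditions"]:
        etree.SubElement(root, "condition").text = cond
    for itype in trial["intervention_types"]:
        iv = etree.SubElement(root, "intervention")
        etree.SubElement(iv, "intervention_type").text = itype
        etree.SubElement(iv, "intervention_name").text = trial["arms"][0]["title"]
    for arm in trial["arms"]:
        ag = etree.SubElement(root, "arm_group")
        etree.SubElement(ag, "arm_group_label").text = arm["title"]
        etree.SubElement(ag, "arm_group_type").text = arm["type"]
    results = etree.SubElement(root, "clinical_results")
    outcome_list = etree.SubElement(results, "outcome_list")
    for outcome in trial["outcomes"]:
        o = etree.SubElement(outcome_list, "outcome")
        etree.SubElement(o, "type").text = outcome["rank"].capitalize()
        etree.SubElement(o, "title").text = outcome["title"]
        titles: list[str] = []
        for an in outcome["analyses"]:
            for t in an["group_titles"]:
                if t not in titles:
                    titles.append(t)
        gl = etree.SubElement(o, "group_list")
        gid = {t: f"O{i + 1}" for i, t in enumerate(titles)}
        for t in titles:
            g = etree.SubElement(gl, "group", group_id=gid[t])
            etree.SubElement(g, "title").text = t
        al = etree.SubElement(o, "analysis_list")
        for an in outcome["analyses"]:
            a = etree.SubElement(al, "analysis")
            gidl = etree.SubElement(a, "group_id_list")
            for t in an["group_titles"]:
                etree.SubElement(gidl, "group_id").text = gid[t]
            s = an["stats"]
            if s["p_value"] is not None:
                etree.SubElement(a, "p_value").text = s["p_value"]
            if s["method"] is not None:
                etree.SubElement(a, "method").text = s["method"]
            if s["param_name"] is not None:
                etree.SubElement(a, "param_type").text = s["param_name"]
                if s["param_value"] is not None:
                    etree.SubElement(a, "param_value").text = str(s["param_value"])
            if s["ci_lower"] is not None:
                etree.SubElement(a, "ci_percent").text = str(s["ci_percent"])
                etree.SubElement(a, "ci_lower_limit").text = s["ci_lower"]
                etree.SubElement(a, "ci_upper_limit").text = s["ci_upper"]
    if trial["events"]:
        rep = etree.SubElement(results, "reported_events")
        arm_titles: list[str] = []
        for ev in trial["events"]:
            if ev["arm_title"] not in arm_titles:
                arm_titles.append(ev["arm_title"])
        gl = etree.SubElement(rep, "group_list")
        gid = {t: f"E{i + 1}" for i, t in enumerate(arm_titles)}
        for t in arm_titles:
            g = etree.SubElement(gl, "group", group_id=gid[t])
            etree.SubElement(g, "title").text = t
        for severity, section in (("serious", "serious_events"), ("other", "other_events")):
            evs = [e for e in trial["events"] if e["severity"] == severity]
            if not evs:
                continue
            sec = etree.SubElement(rep, section)
            cl = etree.SubElement(sec, "category_list")
            by_cat: dict[str, list[dict]] = {}
            for e in evs:
                by_cat.setdefault(e["category"], []).append(e)
            for cat in by_cat:
                c = etree.SubElement(cl, "category")
                etree.SubElement(c, "title").text = cat
                el = etree.SubElement(c, "event_list")
                for e in by_cat[cat]:
                    ev_el = etree.SubElement(el, "event")
                    etree.SubElement(ev_el, "sub_title").text = e["event_title"]
                    if e["counts_as_attrs"]:
                        etree.SubElement(
                            ev_el, "counts", group_id=gid[e["arm_title"]],
                            subjects_affected=str(e["affected"]), subjects_at_risk=str(e["at_risk"]),
                        )
                    else:
                        counts = etree.SubElement(ev_el, "counts", group_id=gid[e["arm_title"]])
                        etree.SubElement(counts, "subjects_affected").text = str(e["affected"])
                        etree.SubElement(counts, "subjects_at_risk").text = str(e["at_risk"])
    return etree.tostring(root, pretty_print=True, encoding="unicode")


def generate_trial(config: GeneratorConfig, seed: int, index: int) -> tuple[str, dict]:
    """Generate one trial: registry-dialect XML text plus its manifest fragment.

    The random stream is derived from ``(seed, index)`` only, so corpora are
    extensible without reshuffling earlier trials.
    """
    rng = random.Random(f"trial:{seed}:{index}")
    nct_id = f"NCT{index + 1:08d}"
    drug = _DRUGS[index % len(_DRUGS)]
    comparator = rng.choice(_COMPARATORS)
    arms = [
        {"title": drug, "type": "Experimental", "role": "experimental"},
        {"title": comparator, "type": rng.choice(["Placebo Comparator", "Active Comparator"]), "role": "comparator"},
    ]
    if rng.random() < 0.10:
        arms.append({"title": f"{drug} Open Label Extension", "type": "Other", "role": "other"})
    conditions = rng.sample(_CONDITIONS, k=rng.choice([1, 1, 1, 2]))
    n_types = 2 if rng.random() < 0.10 else 1
    intervention_types = rng.sample(_INTERVENTION_TYPES, k=n_types) if n_types > 1 else [
        _choose_weighted(rng, {"Drug": 0.7, "Biological": 0.12, "Device": 0.08, "Behavioral": 0.06, "Dietary Supplement": 0.04})
    ]

    # analysis-section spellings of the two main arms, fixed per trial
    analysis_titles = {
        drug: perturb_title(drug, config.title_noise, rng.randrange(2**31)),
        comparator: perturb_title(comparator, config.title_noise, rng.randrange(2**31)),
    }

    outcomes, efficacy_rows = [], []
    for oi in range(rng.randint(1, 4)):
        title, intended_types = _outcome_template(rng)
        rank = "primary" if oi == 0 else ("secondary" if rng.random() < 0.9 else "other")
        analyses = []
        for _ in range(1 if rng.random() < 0.8 else 2):
            stats = _plant_statistics(rng, config)
            if rng.random() < 0.04:  # three-group comparison: excluded downstream
                group_titles = [analysis_titles[drug], analysis_titles[comparator], f"{drug} High Dose"]
                excluded = True
            else:
                group_titles = [analysis_titles[drug], analysis_titles[comparator]]
                if rng.random() < 0.5:
                    group_titles = group_titles[::-1]
                excluded = False
            analyses.append({"group_titles": group_titles, "stats": stats})
            efficacy_rows.append(
                {
                    "nct_id": nct_id,
                    "outcome_title": title,
                    "outcome_rank": rank,
                    "group_titles": group_titles,
                    "excluded": excluded,
                    "intended_label": stats["intended_label"] if not excluded else "excluded",
                    "intended_basis": stats["intended_basis"] if not excluded else "none",
                    "intended_intervention": analysis_titles[drug] if not excluded else None,
                    "intended_comparator": analysis_titles[comparator] if not excluded else None,
                    "intended_outcome_types": intended_types,
                }
            )
        outcomes.append({"title": title, "rank": rank, "analyses": analyses})

    events, safety_records = [], []
    efficacy_groups = [analysis_titles[drug], analysis_titles[comparator]]
    for _ in range(rng.randint(0, 6)):
        design_arm = rng.choice(arms[:2])
        arm_title = design_arm["title"]
        if rng.random() < 0.3:
            arm_title = perturb_title(arm_title, max(config.title_noise, 0.3), rng.randrange(2**31))
        category = rng.choice(config.ae_categories)
        event_title = rng.choice(_EVENT_TITLES.get(category, ["Procedural complication", "Device malfunction"]))
        at_risk = rng.randint(20, 500)
        affected = rng.randint(1, max(1, at_risk // 10))
        events.append(
            {
                "arm_title": arm_title, "event_title": event_title, "category": category,
                "severity": "serious", "affected": affected, "at_risk": at_risk,
                "counts_as_attrs": rng.random() < 0.7,
            }
        )
        # the intended efficacy-arm match: exact spelling wins, otherwise the
        # analysis-section spelling of the same design arm
        intended_group = analysis_titles[design_arm["title"]]
        intended_method = "string" if arm_title.strip().lower() == intended_group.strip().lower() else "embedding"
        safety_records.append(
            {
                "nct_id": nct_id, "arm_title": arm_title, "event_title": event_title,
                "category": category, "affected": affected, "at_risk": at_risk,
                "intended_matched_group": intended_group, "intended_match_method": intended_method,
            }
        )
    # rows the safety extractor must drop: aggregation totals, zero-affected,
    # and non-serious events
    if rng.random() < 0.3:
        events.append(
            {
                "arm_title": arms[0]["title"], "event_title": "Total, serious adverse events",
                "category": "Total", "severity": "serious",
                "affected": rng.randint(1, 50), "at_risk": 200, "counts_as_attrs": True,
            }
        )
    if rng.random() < 0.3:
        events.append(
            {
                "arm_title": arms[0]["title"], "event_title": "Headache",
                "category": "Nervous system disorders", "severity": "serious",
                "affected": 0, "at_risk": 200, "counts_as_attrs": True,
            }
        )
    if rng.random() < 0.3:
        events.append(
            {
                "arm_title": arms[1]["title"], "event_title": "Nausea",
                "category": "Gastrointestinal disorders", "severity": "other",
                "affected": rng.randint(1, 20), "at_risk": 200, "counts_as_attrs": True,
            }
        )

    trial = {
        "nct_id": nct_id,
        "conditions": conditions,
        "intervention_types": intervention_types,
        "arms": arms,
        "outcomes": outcomes,
        "events": events,
        "efficacy_rows": efficacy_rows,
        "safety_records": safety_records,
        "counts": {
            "n_arms": len(arms),
            "n_outcomes": len(outcomes),
            "n_analyses": sum(len(o["analyses"]) for o in outcomes),
            "n_events": len(events),
        },
        "efficacy_group_titles": efficacy_groups,
    }
    return _trial_xml(trial), trial


def generate_corpus(
    config: GeneratorConfig,
    out_dir: Union[str, Path],
) -> tuple[Path, TruthManifest]:
    """Write ``n_trials`` XML files plus a JSONL manifest to ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = TruthManifest()
    for index in range(config.n_trials):
        xml_text, fragment = generate_trial(config, config.seed, index)
        (out_dir / f"{fragment['nct_id']}.xml").write_text(xml_text, encoding="utf-8")
        manifest.trials.append(fragment)
    manifest.write_jsonl(out_dir / "manifest.jsonl")
    return out_dir, manifest
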