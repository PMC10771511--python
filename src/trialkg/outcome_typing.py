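"""MeSH-based typing of outcomes and conditions.

Outcome titles are free text; attaching MeSH (Medical Subject Headings)
terms lets heterogeneous titles be grouped by concept and typed by position
in the MeSH tree. Three outcome categories are assigned, multi-label:

* **biomarker** — any extracted term under tree root D (Chemicals and
  Drugs) or E (Analytical, Diagnostic and Therapeutic Techniques), except
  the E05.318.308.980 branch (Surveys and Questionnaires), which signals a
  patient-reported instrument rather than a measured analyte;
* **PRO** (patient-reported outcome) — keyword match of Survey /
  Questionnaire / Patient Reported / Patient-Reported / Scale / Score,
  case-insensitive, in the title or any extracted MeSH name;
* **clinical_endpoint** — any term under root C (Diseases) or F03
  (Mental Disorders).

Term extraction is behind a pluggable contract. The default
:class:`DictionaryExtractor` matches a shipped toy dictionary (a synthetic
subset of the MeSH tree, ~200 entries over D/E/C/F03 branches) by
word-boundary phrase lookup, so tests and corpus runs need no network; a
web-service indexer can be wrapped as another extractor satisfying the same
contract.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Protocol, Sequence, Union

logger = logging.getLogger(__name__)

TREE_NUMBER_RE = re.compile(r"^[A-Z]\d{2}(\.\d+)*$|^[A-Z]\d{2}$|^[A-Z]$")

PRO_KEYWORDS = ("survey", "questionnaire", "patient reported", "patient-reported", "scale", "score")

#: The Surveys-and-Questionnaires branch excluded from the biomarker rule.
SURVEY_BRANCH = "E05.318.308.980"

#: First-level MeSH disease branches, for condition-category reporting.
DISEASE_CATEGORY_NAMES = {
    "C01": "Infections",
    "C04": "Neoplasms",
    "C05": "Musculoskeletal Diseases",
    "C06": "Digestive System Diseases",
    "C07": "Stomatognathic Diseases",
    "C08": "Respiratory Tract Diseases",
    "C09": "Otorhinolaryngologic Diseases",
    "C10": "Nervous System Diseases",
    "C11": "Eye Diseases",
    "C12": "Urogenital Diseases",
    "C13": "Female Urogenital Diseases and Pregnancy Complications",
    "C14": "Cardiovascular Diseases",
    "C15": "Hemic and Lymphatic Diseases",
    "C16": "Congenital, Hereditary, and Neonatal Diseases and Abnormalities",
    "C17": "Skin and Connective Tissue Diseases",
    "C18": "Nutritional and Metabolic Diseases",
    "C19": "Endocrine System Diseases",
    "C20": "Immune System Diseases",
    "C21": "Disorders of Environmental Origin",
    "C22": "Animal Diseases",
    "C23": "Pathological Conditions, Signs and Symptoms",
    "C24": "Occupational Diseases",
    "C25": "Chemically-Induced Disorders",
    "C26": "Wounds and Injuries",
    "F03": "Mental Disorders",
}


@dataclass(frozen=True, order=True)
class MeshTerm:
    """A MeSH term located by its dotted tree number."""

    tree_number: str
    name: str

    def __post_init__(self) -> None:
        if not TREE_NUMBER_RE.match(self.tree_number):
            raise ValueError(f"invalid MeSH tree number {self.tree_number!r}")

    def is_under(self, prefix: str) -> bool:
        """Prefix match on dotted segments: F03 covers F03.600, not F030."""
        if self.tree_number == prefix:
            return True
        if self.tree_number.startswith(prefix):
            rest = self.tree_number[len(prefix):]
            # either the prefix ends a segment (next char '.') or the prefix
            # is a bare root letter followed by digits of the same segment
            return rest.startswith(".") or (len(prefix) == 1 and prefix.isalpha())
        return False


class MeshExtractor(Protocol):
    """Contract: map free text to MeSH terms, deterministic per version."""

    name: str
    version: str

    def extract(self, text: str) -> list[MeshTerm]: ...


class DictionaryExtractor:
    """Word-boundary phrase lookup against a plain-text dictionary.

    The shipped table (``data/mesh_toy.tsv``) is a synthetic toy subset of
    MeSH covering the D, E, C and F03 branches, including the
    E05.318.308.980 survey branch; it exists so the typing rules are
    exercisable offline, not as a redistribution of MeSH.
    """

    def __init__(self, table: Optional[Union[str, Path]] = None) -> None:
        self.name = "toy-dictionary"
        self.version = "1"
        if table is None:
            text = resources.files("trialkg").joinpath("data/mesh_toy.tsv").read_text("utf-8")
        else:
            text = Path(table).read_text("utf-8")
        self._entries: list[tuple[re.Pattern, MeshTerm]] = []
        for i, line in enumerate(text.splitlines()):
            if i == 0 or not line.strip():
                continue
            phrase, tree_number, name = line.split("\t")
            pat = re.compile(r"(?<!\w)" + re.escape(phrase.strip().lower()) + r"(?!\w)")
            self._entries.append((pat, MeshTerm(tree_number.strip(), name.strip())))

    def extract(self, text: str) -> list[MeshTerm]:
        if not text or not text.strip():
            return []
        hay = re.sub(r"\s+", " ", text.lower())
        found = {term for pat, term in self._entries if pat.search(hay)}
        return sorted(found)


class CachedExtractor:
    """Wrap an extractor with a resumable JSONL cache (text, version, terms)."""

    def __init__(self, inner: MeshExtractor, cache_path: Union[str, Path]) -> None:
        self.inner = inner
        self.name = inner.name
        self.version = inner.version
        self.cache_path = Path(cache_path)
        self._cache: dict[str, list[MeshTerm]] = {}
        if self.cache_path.exists():
            with open(self.cache_path, encoding="utf-8") as fh:
                for line in fh:
                    rec = json.loads(line)
                    if rec.get("version") == self.version:
                        self._cache[rec["text"]] = [MeshTerm(*t) for t in rec["terms"]]

    def extract(self, text: str) -> list[MeshTerm]:
        if text in self._cache:
            return list(self._cache[text])
        terms = self.inner.extract(text)
        self._cache[text] = terms
        with open(self.cache_path, "a", encoding="utf-8") as fh:
            fh.write(
                json.dumps(
                    {"text": text, "version": self.version, "terms": [[t.tree_number, t.name] for t in terms]},
                    ensure_ascii=False,
                )
                + "\n"
            )
        return list(terms)


@dataclass
class OutcomeLabel:
    """MeSH terms plus the category label set for one outcome title."""

    outcome_title: str
    mesh_terms: list[MeshTerm] = field(default_factory=list)
    labels: frozenset = frozenset()
    pro_source: Optional[str] = None  # title | mesh | both, when PRO fired
    extractor_version: Optional[str] = None

    #: Precedence used when a single label is needed for tabulation.
    PRECEDENCE = ("biomarker", "PRO", "clinical_endpoint")

    def primary_label(self, precedence: Sequence[str] = PRECEDENCE) -> Optional[str]:
        for lab in precedence:
            if lab in self.labels:
                return lab
        return None


def label_biomarker(terms: Iterable[MeshTerm]) -> bool:
    """True iff any term sits under root D or E, survey branch excluded."""
    return any(
        (t.tree_number.startswith("D") or t.tree_number.startswith("E"))
        and not t.is_under(SURVEY_BRANCH)
        for t in terms
    )


def label_pro(outcome_title: str, mesh_names: Iterable[str]) -> tuple[bool, Optional[str]]:
    """PRO keyword match on the title and the extracted MeSH names.

    Returns the flag plus where the match came from (title / mesh / both).
    """
    title_hit = any(k in outcome_title.lower() for k in PRO_KEYWORDS)
    mesh_hit = any(k in name.lower() for name in mesh_names for k in PRO_KEYWORDS)
    if title_hit and mesh_hit:
        return True, "both"
    if title_hit:
        return True, "title"
    if mesh_hit:
        return True, "mesh"
    return False, None


def label_clinical(terms: Iterable[MeshTerm]) -> bool:
    """True iff any term sits under root C (Diseases) or F03 (Mental Disorders)."""
    return any(t.tree_number.startswith("C") or t.is_under("F03") for t in terms)


def classify_outcome(title: str, extractor: MeshExtractor) -> OutcomeLabel:
    """Apply the three typing rules to one outcome title; multi-label.

    Extractor failure degrades gracefully: the PRO keyword rule still runs
    on the bare title and the event is logged.
    """
    try:
        terms = extractor.extract(title)
    except Exception as exc:  # noqa: BLE001 - adapter may wrap a remote service
        logger.warning("MeSH extractor %s failed on %r: %s", extractor.name, title, exc)
        terms = []
    labels = set()
    if label_biomarker(terms):
        labels.add("biomarker")
    pro, pro_source = label_pro(title, [t.name for t in terms])
    if pro:
        labels.add("PRO")
    if label_clinical(terms):
        labels.add("clinical_endpoint")
    return OutcomeLabel(
        outcome_title=title,
        mesh_terms=terms,
        labels=frozenset(labels),
        pro_source=pro_source,
        extractor_version=getattr(extractor, "version", None),
    )


def map_condition_category(condition: str, extractor: MeshExtractor) -> list[str]:
    """Top-level MeSH disease categories (C01..C26, F03) for a condition string."""
    cats: set[str] = set()
    for term in extractor.extract(condition):
        tn = term.tree_number
        if tn.startswith("C"):
            root = tn.split(".")[0]
        elif term.is_under("F03"):
            root = "F03"
        else:
            continue
        name = DISEASE_CATEGORY_NAMES.get(root)
        if name:
            cats.add(name)
    return sorted(cats)


def coverage(labels: Sequence[OutcomeLabel]) -> float:
    """Fraction of outcomes that received at least one category label."""
    if not labels:
        return 0.0
    return sum(1 for l in labels if l.labels) / len(labels)
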