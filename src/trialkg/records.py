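"""Domain model for registered-trial records.

One :class:`TrialRecord` corresponds to one registry XML document (one NCT id):
the study-design arms with their experimental/comparator roles, the outcome
measures with their statistical-analysis blocks, and the reported adverse
events. Raw strings (p-values, confidence-interval bounds) are preserved
verbatim for provenance; parsing into numbers happens downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

NCT_ID_RE = re.compile(r"^NCT\d{8}$")

ARM_ROLES = ("experimental", "comparator", "other")
OUTCOME_RANKS = ("primary", "secondary", "other")
SEVERITIES = ("serious", "other")


def normalize_ws(text: str) -> str:
    """Collapse whitespace runs and strip ends."""
    return re.sub(r"\s+", " ", text).strip()


def arm_role_from_type(arm_type: Optional[str]) -> str:
    """Map a design-section arm-type string to a role.

    ``Experimental`` (case-insensitive) maps to experimental; any type
    containing ``comparator`` (covers "Placebo Comparator", "Active
    Comparator", "Sham Comparator") maps to comparator; everything else,
    including a missing type, is other.
    """
    if not arm_type:
        return "other"
    t = arm_type.strip().lower()
    if t == "experimental":
        return "experimental"
    if "comparator" in t:
        return "comparator"
    return "other"


@dataclass
class DesignArm:
    """An arm group as declared in the study-design section."""

    title: str
    role: str  # experimental | comparator | other
    description: Optional[str] = None

    def __post_init__(self) -> None:
        self.title = normalize_ws(self.title)
        if not self.title:
            raise ValueError("design arm title is empty after whitespace normalization")
        if self.role not in ARM_ROLES:
            raise ValueError(f"unknown arm role {self.role!r}")


@dataclass
class StatAnalysis:
    """One statistical-analysis block under an outcome measure.

    ``group_titles`` are the compared groups in document order. All
    statistics fields keep the registry's raw strings; ``param_value`` and
    ``ci_percent`` are coerced because the dialect stores them numerically.
    """

    group_titles: list[str]
    p_value_raw: Optional[str] = None
    method: Optional[str] = None
    param_name_raw: Optional[str] = None
    param_value: Optional[float] = None
    ci_percent: Optional[float] = None
    ci_lower_raw: Optional[str] = None
    ci_upper_raw: Optional[str] = None
    non_inferiority: Optional[bool] = None

    def __post_init__(self) -> None:
        self.group_titles = [normalize_ws(t) for t in self.group_titles]
        if not self.group_titles:
            raise ValueError("analysis block has no group titles")


@dataclass
class OutcomeMeasure:
    """An outcome measure with its analysis blocks."""

    title: str
    rank: str  # primary | secondary | other
    analyses: list[StatAnalysis] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.title = normalize_ws(self.title)
        if self.rank not in OUTCOME_RANKS:
            raise ValueError(f"unknown outcome rank {self.rank!r}")


@dataclass
class ReportedEvent:
    """One adverse-event count on one arm.

    ``category`` is the MedDRA-style body-system class the event is filed
    under (e.g. "Cardiac disorders"); ``affected``/``at_risk`` are the
    subject counts for the arm.
    """

    arm_title: str
    event_title: str
    category: str
    severity: str  # serious | other
    affected: int
    at_risk: Optional[int] = None

    def __post_init__(self) -> None:
        self.arm_title = normalize_ws(self.arm_title)
        self.event_title = normalize_ws(self.event_title)
        self.category = normalize_ws(self.category)
        if self.severity not in SEVERITIES:
            raise ValueError(f"unknown severity {self.severity!r}")
        if self.affected < 0:
            raise ValueError("affected count is negative")
        if self.at_risk is not None and self.at_risk < 0:
            raise ValueError("at_risk count is negative")


@dataclass
class TrialRecord:
    """One registered study, flattened from its registry XML document."""

    nct_id: str
    conditions: list[str] = field(default_factory=list)
    intervention_types: list[str] = field(default_factory=list)
    design_arms: list[DesignArm] = field(default_factory=list)
    outcomes: list[OutcomeMeasure] = field(default_factory=list)
    events: list[ReportedEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not NCT_ID_RE.match(self.nct_id):
            raise ValueError(f"invalid NCT id {self.nct_id!r}")

    @property
    def experimental_arms(self) -> list[DesignArm]:
        return [a for a in self.design_arms if a.role == "experimental"]

    @property
    def comparator_arms(self) -> list[DesignArm]:
        return [a for a in self.design_arms if a.role == "comparator"]
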