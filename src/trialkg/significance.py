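"""Statistical-significance labelling of two-arm efficacy results.

Registry analysis blocks report significance heterogeneously: a p-value
string (possibly carrying an operator, ``<0.0001``), or only a confidence
interval around an effect parameter. The rule cascade applied here labels
each result positive (statistically significant at the 0.05 level) or
negative, in a fixed order:

1. If the p-value string parses: positive when the stated relation
   guarantees p <= 0.05, negative when it guarantees p > 0.05, otherwise
   indeterminate (an unresolvable bound such as ``<0.1`` is never guessed).
2. Otherwise, with a confidence interval and a ratio-type parameter (odds,
   hazard, risk ratio — null value 1): negative iff the closed interval
   contains 1, else positive.
3. Same with a difference-type parameter (mean/risk difference — null value
   0): negative iff the interval contains 0, else positive.
4. Otherwise indeterminate.

No multiple-testing adjustment is applied: results are labelled row by row
exactly as reported.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from trialkg.registry_io import EfficacyRow

logger = logging.getLogger(__name__)

ALPHA = 0.05

_OPS = {
    "<": "lt",
    "<=": "le",
    "≤": "le",
    "=<": "le",
    ">": "gt",
    ">=": "ge",
    "≥": "ge",
    "=>": "ge",
    "=": "eq",
}

# operator (optional) then a decimal / scientific-notation number, nothing else
_P_RE = re.compile(
    r"^(?P<op><=|>=|=<|=>|≤|≥|<|>|=)?(?P<num>[+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?)$"
)


@dataclass(frozen=True)
class PValue:
    """A parsed p-value: relational operator plus numeric value."""

    op: str  # lt | le | eq | ge | gt
    value: float


@dataclass(frozen=True)
class ConfidenceInterval:
    percent: Optional[float]
    lower: float
    upper: float


@dataclass(frozen=True)
class SignificanceLabel:
    label: str  # positive | negative | indeterminate
    basis: str  # p_value | ci_ratio | ci_difference | none


RATIO_KEYWORDS = (
    "odds ratio",
    "hazard ratio",
    "risk ratio",
    "relative risk",
    "rate ratio",
    "ratio",
)
DIFFERENCE_KEYWORDS = (
    "mean difference",
    "risk difference",
    "difference",
    "slope",
    "change",
)


def parse_p_value(raw: Optional[str]) -> Optional[PValue]:
    """Parse a registry p-value string; ``None`` signals fall-through.

    Blanks are removed before coercion; a leading operator is recognized
    (``<``, ``<=``, ``≤``, ``>``, ``>=``, ``≥``, ``=``) and defaults to
    equality. Plain decimals and scientific notation are accepted. Values
    outside [0, 1] are rejected.
    """
    if raw is None:
        return None
    compact = re.sub(r"\s+", "", raw)
    m = _P_RE.match(compact)
    if not m:
        return None
    try:
        value = float(m.group("num"))
    except ValueError:  # pragma: no cover - regex guarantees a float
        return None
    if not (0.0 <= value <= 1.0):
        return None
    return PValue(op=_OPS.get(m.group("op") or "=", "eq"), value=value)


def parse_ci(
    lower_raw: Optional[str],
    upper_raw: Optional[str],
    percent: Optional[float] = None,
) -> Optional[ConfidenceInterval]:
    """Parse confidence-interval bound strings; both must be finite numbers.

    Bounds the registry stores as "NA" or with stray operators fail to
    parse; a reversed interval is rejected rather than silently swapped.
    """

    def _num(raw: Optional[str]) -> Optional[float]:
        if raw is None:
            return None
        compact = re.sub(r"\s+", "", raw)
        try:
            v = float(compact)
        except ValueError:
            return None
        return v if v == v and abs(v) != float("inf") else None

    lower, upper = _num(lower_raw), _num(upper_raw)
    if lower is None or upper is None or lower > upper:
        return None
    return ConfidenceInterval(percent=percent, lower=lower, upper=upper)


def classify_param_kind(param_name: Optional[str]) -> str:
    """Classify an effect-parameter name as ratio-type, difference-type, or unknown.

    Ratio-type parameters have null value 1; difference-type have null
    value 0. Case-insensitive keyword matching; an unrecognized name maps
    to unknown (such CI-only results stay indeterminate).
    """
    if not param_name:
        return "unknown"
    name = param_name.lower()
    if any(k in name for k in RATIO_KEYWORDS):
        return "ratio"
    if any(k in name for k in DIFFERENCE_KEYWORDS):
        return "difference"
    return "unknown"


def classify_significance(
    p: Optional[PValue],
    ci: Optional[ConfidenceInterval],
    kind: str = "unknown",
) -> SignificanceLabel:
    """Apply the fixed rule cascade; see the module docstring.

    The p-value branch takes strict precedence: when the p-value string
    yields a decisive relation, the confidence interval never influences
    the label. Interval containment is closed (``lower <= null <= upper``).
    """
    if p is not None:
        if p.op in ("eq", "le", "lt") and p.value <= ALPHA:
            return SignificanceLabel("positive", "p_value")
        if p.op == "eq" and p.value > ALPHA:
            return SignificanceLabel("negative", "p_value")
        if p.op in ("ge", "gt") and p.value >= ALPHA:
            return SignificanceLabel("negative", "p_value")
        # bound does not resolve against 0.05 (e.g. "<0.1"): never guessed,
        # and a reported p-value pre-empts the CI branch
        return SignificanceLabel("indeterminate", "none")
    if ci is not None:
        if kind == "ratio":
            contained = ci.lower <= 1.0 <= ci.upper
            if ci.lower == 1.0 or ci.upper == 1.0:
                logger.debug("CI boundary touches null value 1: [%s, %s]", ci.lower, ci.upper)
            return SignificanceLabel("negative" if contained else "positive", "ci_ratio")
        if kind == "difference":
            contained = ci.lower <= 0.0 <= ci.upper
            if ci.lower == 0.0 or ci.upper == 0.0:
                logger.debug("CI boundary touches null value 0: [%s, %s]", ci.lower, ci.upper)
            return SignificanceLabel("negative" if contained else "positive", "ci_difference")
    return SignificanceLabel("indeterminate", "none")


@dataclass
class ClassifiedRow:
    """An efficacy row plus its significance label and parsed statistics."""

    row: EfficacyRow
    label: str
    basis: str
    p: Optional[PValue] = None
    ci: Optional[ConfidenceInterval] = None
    param_kind: str = "unknown"


@dataclass
class BranchCounts:
    """Funnel counts over the cascade branches, for pipeline reporting."""

    total: int = 0
    excluded: int = 0
    p_value: int = 0
    ci_ratio: int = 0
    ci_difference: int = 0
    indeterminate: int = 0
    positive: int = 0
    negative: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def classify_rows(rows: Sequence[EfficacyRow]) -> tuple[list[ClassifiedRow], BranchCounts]:
    """Label every non-excluded row and tally the cascade funnel."""
    out: list[ClassifiedRow] = []
    counts = BranchCounts()
    for row in rows:
        counts.total += 1
        if row.excluded:
            counts.excluded += 1
            continue
        p = parse_p_value(row.p_value_raw)
        ci = parse_ci(row.ci_lower_raw, row.ci_upper_raw, row.ci_percent)
        kind = classify_param_kind(row.param_name_raw)
        sig = classify_significance(p, ci, kind)
        out.append(ClassifiedRow(row=row, label=sig.label, basis=sig.basis, p=p, ci=ci, param_kind=kind))
        if sig.basis == "p_value":
            counts.p_value += 1
        elif sig.basis == "ci_ratio":
            counts.ci_ratio += 1
        elif sig.basis == "ci_difference":
            counts.ci_difference += 1
        else:
            counts.indeterminate += 1
        if sig.label == "positive":
            counts.positive += 1
        elif sig.label == "negative":
            counts.negative += 1
    return out, counts
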